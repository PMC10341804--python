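"""Expression quantification (FPKM) and a simplified negative-binomial
differential-expression test.

The test follows the familiar count-model recipe: median-of-ratios library
normalization, per-gene method-of-moments dispersion (floored), a Wald test
on the log2 ratio of normalized condition means with an NB variance model,
and Benjamini-Hochberg adjustment. Calls use the standard thresholds
(FDR <= 0.05 and |log2FC| > 1, i.e. fold change >= 2).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .genome import GeneModel


def fpkm(
    counts: pd.DataFrame, genes: Sequence[GeneModel] | dict[str, int]
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM = count * 1e9 / (column total * exonic gene length).
    """
    if isinstance(genes, dict):
        lengths = pd.Series(genes)
    else:
        lengths = pd.Series({g.gene_id: g.exonic_length for g in genes})
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:3].tolist()
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("zero total fragments in a sample")
    return counts.mul(1e9).div(totals, axis=1).div(lengths, axis=0)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up FDR adjustment, order-preserving w.r.t. input indexing."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def median_of_ratios(counts: np.ndarray) -> np.ndarray:
    """Size factors: per-sample median of count ratios to the per-gene
    geometric mean, over genes positive in every sample. Falls back to
    total-count scaling when no gene qualifies."""
    counts = np.asarray(counts, dtype=float)
    positive = (counts > 0).all(axis=1)
    if positive.sum() == 0:
        totals = counts.sum(axis=0)
        return totals / np.exp(np.mean(np.log(np.maximum(totals, 1))))
    logc = np.log(counts[positive])
    log_geo = logc.mean(axis=1, keepdims=True)
    return np.exp(np.median(logc - log_geo, axis=0))


class NegativeBinomialDE(BaseEstimator):
    """Two-condition Wald test on NB count data (vectorized over genes).

    Parameters
    ----------
    alpha : float
        FDR threshold for up/down calls (default 0.05).
    lfc_threshold : float
        |log2FC| must exceed this for a call (default 1.0).
    min_dispersion : float
        Floor for the method-of-moments dispersion estimate.

    After :meth:`fit`, ``results_`` holds one row per gene with
    log2_fold_change (alt over ref), raw_p, fdr and call (up/down/ns).
    """

    def __init__(
        self,
        alpha: float = 0.05,
        lfc_threshold: float = 1.0,
        min_dispersion: float = 1e-6,
    ):
        self.alpha = alpha
        self.lfc_threshold = lfc_threshold
        self.min_dispersion = min_dispersion

    def fit(self, counts: pd.DataFrame, conditions: Sequence[str], ref: str, alt: str):
        """``counts``: genes x samples; ``conditions``: per-sample labels.

        log2_fold_change is log2(mean_alt / mean_ref), so swapping ref and
        alt flips every sign.
        """
        conditions = np.asarray(conditions)
        for label in (ref, alt):
            if (conditions == label).sum() < 2:
                raise ValueError(f"need >= 2 replicates for condition {label!r}")
        mask = np.isin(conditions, (ref, alt))
        sub = counts.loc[:, mask]
        cond = conditions[mask]
        raw = sub.to_numpy(dtype=float)
        sf = median_of_ratios(raw)
        normed = raw / sf
        a = normed[:, cond == ref]
        b = normed[:, cond == alt]
        mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
        n_a, n_b = a.shape[1], b.shape[1]

        # method-of-moments dispersion pooled across the two conditions
        with np.errstate(invalid="ignore", divide="ignore"):
            disp_a = (a.var(axis=1, ddof=1) - mu_a) / mu_a**2
            disp_b = (b.var(axis=1, ddof=1) - mu_b) / mu_b**2
        pair = np.stack([disp_a, disp_b])
        valid = np.isfinite(pair)
        num = np.where(valid, pair, 0.0).sum(axis=0)
        cnt = valid.sum(axis=0)
        disp = np.where(cnt > 0, num / np.maximum(cnt, 1), self.min_dispersion)
        disp = np.maximum(disp, self.min_dispersion)

        pseudo = 0.5
        l2fc = np.log2((mu_b + pseudo) / (mu_a + pseudo))
        # delta-method variance of log(mean) under NB: (1/mu + disp)/n
        var_log = (1.0 / np.maximum(mu_a, pseudo) + disp) / n_a + (
            1.0 / np.maximum(mu_b, pseudo) + disp
        ) / n_b
        se_l2 = np.sqrt(var_log) / np.log(2)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = l2fc / se_l2
        raw_p = 2 * norm.sf(np.abs(z))
        all_zero = raw.sum(axis=1) == 0
        raw_p = np.where(all_zero, 1.0, raw_p)
        l2fc = np.where(all_zero, 0.0, l2fc)
        fdr = benjamini_hochberg(raw_p)
        call = np.where(
            (fdr <= self.alpha) & (l2fc > self.lfc_threshold), "up",
            np.where((fdr <= self.alpha) & (l2fc < -self.lfc_threshold), "down", "ns"),
        )
        self.results_ = pd.DataFrame(
            {
                "gene_id": counts.index,
                "log2_fold_change": l2fc,
                "raw_p": raw_p,
                "fdr": fdr,
                "call": call,
            }
        ).reset_index(drop=True)
        self.size_factors_ = sf
        self.dispersion_ = disp
        return self


def nb_de_test(
    counts: pd.DataFrame,
    conditions: Sequence[str],
    cond_ref: str,
    cond_alt: str,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Functional wrapper around :class:`NegativeBinomialDE`."""
    est = NegativeBinomialDE(alpha=alpha, lfc_threshold=lfc_threshold)
    return est.fit(counts, conditions, cond_ref, cond_alt).results_
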