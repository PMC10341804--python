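"""Homoeolog detection and subgenome-bias analysis.

Reciprocal best hits (RBH) between A- and D-subgenome protein sets define
homoeologous pairs (E-value < 1e-5, coverage >= 50%, identity >= 50%);
genes whose every cross-subgenome hit fails the coverage/identity cuts (or
that have no hit) are subgenome-unique. Pair-level expression bias reuses
the NB test with the two pair members as pseudo-conditions. Group-level
mark/expression comparisons use the Wilcoxon rank-sum test; gene histone
profiles are k-means clustered on per-mark z-scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .de import NegativeBinomialDE
from .gene_states import EnrichmentResult, fisher_enrichment

logger = logging.getLogger(__name__)

HIT_COLUMNS = ["query_id", "target_id", "e_value", "coverage", "identity"]


@dataclass
class HomoeologSet:
    """RBH pairs plus subgenome-unique and unclassified leftovers."""

    pairs: list[tuple[str, str]]  # (A gene, D gene)
    a_unique: set[str] = field(default_factory=set)
    d_unique: set[str] = field(default_factory=set)
    a_other: set[str] = field(default_factory=set)
    d_other: set[str] = field(default_factory=set)
    bias_category: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "a_gene": a,
                    "d_gene": d,
                    "bias": self.bias_category.get((a, d), ""),
                }
                for a, d in self.pairs
            ]
        )


def _best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Best hit per query: lowest e_value, ties by highest identity then
    lexicographic target id. Duplicate (query,target) rows keep the best."""
    h = hits.copy()
    dups = h.duplicated(subset=["query_id", "target_id"]).sum()
    if dups:
        logger.warning("dropping %d duplicate (query,target) hit rows", dups)
    h = h.sort_values(
        ["query_id", "e_value", "identity", "target_id"],
        ascending=[True, True, False, True],
    )
    h = h.drop_duplicates(subset=["query_id", "target_id"], keep="first")
    return h.drop_duplicates(subset="query_id", keep="first").set_index("query_id")


def reciprocal_best_hits(
    hits_ad: pd.DataFrame,
    hits_da: pd.DataFrame,
    a_genes: list[str] | None = None,
    d_genes: list[str] | None = None,
    e_cut: float = 1e-5,
    cov_cut: float = 50.0,
    id_cut: float = 50.0,
) -> HomoeologSet:
    """Mutual-best-hit homoeolog pairing with unique-gene classification.

    A pair (a, d) is kept iff a's best hit is d, d's best hit is a, and both
    hits pass all three cuts. A gene with no cross-subgenome hit, or whose
    every hit fails the coverage/identity cuts, is subgenome-unique. Genes
    that are neither (e.g. best-hit asymmetry with passing similarity) are
    reported as unclassified "other".
    """
    best_ad = _best_hits(hits_ad)
    best_da = _best_hits(hits_da)

    def passes(row) -> bool:
        return (
            row.e_value < e_cut and row.coverage >= cov_cut and row.identity >= id_cut
        )

    pairs = []
    paired_a, paired_d = set(), set()
    for a, row in best_ad.iterrows():
        d = row.target_id
        if d in best_da.index and best_da.loc[d].target_id == a:
            if passes(row) and passes(best_da.loc[d]):
                pairs.append((a, d))
                paired_a.add(a)
                paired_d.add(d)

    def classify(universe, hits, paired):
        unique, other = set(), set()
        sim_ok = hits[(hits["coverage"] >= cov_cut) & (hits["identity"] >= id_cut)]
        has_similar = set(sim_ok["query_id"])
        seen = set(hits["query_id"])
        for g in universe:
            if g in paired:
                continue
            if g not in seen or g not in has_similar:
                unique.add(g)
            else:
                other.add(g)
        return unique, other

    a_universe = a_genes if a_genes is not None else sorted(set(hits_ad["query_id"]))
    d_universe = d_genes if d_genes is not None else sorted(set(hits_da["query_id"]))
    a_unique, a_other = classify(a_universe, hits_ad, paired_a)
    d_unique, d_other = classify(d_universe, hits_da, paired_d)
    return HomoeologSet(sorted(pairs), a_unique, d_unique, a_other, d_other)


def categorize_bias(
    homoeologs: HomoeologSet,
    counts: pd.DataFrame,
    a_samples: list[str],
    d_samples: list[str],
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
) -> HomoeologSet:
    """Per-pair expression bias: A>D / A<D / A=D.

    The NB test is run once over all pairs, treating the two pair members
    as the two conditions across replicates (D member = reference, so an
    "up" call means A>D at fold change >= 2 and FDR <= alpha). A pair whose
    member lacks expression data is categorized A=D and logged.
    """
    rows_a, rows_d, kept = [], [], []
    for a, d in homoeologs.pairs:
        if a in counts.index and d in counts.index:
            rows_a.append(a)
            rows_d.append(d)
            kept.append((a, d))
        else:
            homoeologs.bias_category[(a, d)] = "A=D"
            logger.info("pair (%s, %s) missing expression; categorized A=D", a, d)
    if not kept:
        return homoeologs
    a_mat = counts.loc[rows_a, a_samples].to_numpy()
    d_mat = counts.loc[rows_d, d_samples].to_numpy()
    pair_counts = pd.DataFrame(
        np.hstack([d_mat, a_mat]),
        index=[f"{a}|{d}" for a, d in kept],
        columns=[f"D_{s}" for s in d_samples] + [f"A_{s}" for s in a_samples],
    )
    conditions = ["D"] * len(d_samples) + ["A"] * len(a_samples)
    res = (
        NegativeBinomialDE(alpha=alpha, lfc_threshold=lfc_threshold)
        .fit(pair_counts, conditions, ref="D", alt="A")
        .results_
    )
    for (a, d), call in zip(kept, res["call"]):
        homoeologs.bias_category[(a, d)] = {
            "up": "A>D", "down": "A<D", "ns": "A=D"
        }[call]
    return homoeologs


def bias_summary(homoeologs: HomoeologSet) -> dict[str, float]:
    cats = pd.Series(
        [homoeologs.bias_category.get(p, "A=D") for p in homoeologs.pairs]
    )
    counts = cats.value_counts()
    return summarize_bias_counts(
        int(counts.get("A>D", 0)), int(counts.get("A<D", 0)), homoeologs.n_pairs
    )


def summarize_bias_counts(n_a_higher: int, n_d_higher: int, n_pairs: int) -> dict[str, float]:
    """Worked-example arithmetic on pair-category counts: the biased
    percentage is (A>D + A<D) / pairs."""
    biased = n_a_higher + n_d_higher
    return {
        "A>D": n_a_higher,
        "A<D": n_d_higher,
        "A=D": n_pairs - biased,
        "n_pairs": n_pairs,
        "biased_fraction": biased / n_pairs if n_pairs else np.nan,
        "biased_percent": 100.0 * biased / n_pairs if n_pairs else np.nan,
    }


def wilcoxon_rank_sum(x, y, exact_max_n: int = 10) -> float:
    """Two-sided Wilcoxon rank-sum p.

    Exact enumeration when both samples have <= ``exact_max_n``
    observations and there are no ties; otherwise the tie-corrected normal
    approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group in rank-sum comparison")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= exact_max_n and len(y) <= exact_max_n and not ties) \
        else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def mark_level_compare(
    signal: pd.DataFrame, groups: dict[str, list[str]]
) -> pd.DataFrame:
    """Per-mark group means and pairwise Wilcoxon rank-sum p-values.

    ``signal`` is genes x marks (mean RPKM over gene bodies); ``groups``
    maps a label to a gene-id list.
    """
    for name, ids in groups.items():
        if len(ids) == 0:
            raise ValueError(f"group {name!r} is empty")
    rows = []
    names = list(groups)
    for mark in signal.columns:
        values = {n: signal.loc[signal.index.intersection(groups[n]), mark] for n in names}
        for i, n1 in enumerate(names):
            for n2 in names[i + 1:]:
                rows.append(
                    {
                        "mark": mark,
                        "group_a": n1,
                        "group_b": n2,
                        "mean_a": float(values[n1].mean()),
                        "mean_b": float(values[n2].mean()),
                        "p_value": wilcoxon_rank_sum(values[n1], values[n2]),
                    }
                )
    return pd.DataFrame(rows)


class GeneSignalKMeans(BaseEstimator):
    """K-means over per-mark z-scored gene signal rows.

    Cluster labels are relabeled by descending cluster size (cluster 1 is
    the largest); same seed, same labels.

    Attributes
    ----------
    labels_ : pd.Series of 1-based cluster ids indexed by gene.
    cluster_means_ : per-cluster mark means on the original signal scale.
    """

    def __init__(self, n_clusters: int = 5, random_state: int | None = None):
        self.n_clusters = n_clusters
        self.random_state = random_state

    def fit(self, signal: pd.DataFrame):
        if self.n_clusters > len(signal):
            raise ValueError("more clusters than genes")
        X = signal.to_numpy(dtype=float)
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        Z = (X - mu) / np.where(sd > 0, sd, 1.0)
        km = KMeans(
            n_clusters=self.n_clusters,
            random_state=self.random_state,
            n_init=10,
        ).fit(Z)
        raw = km.labels_
        sizes = np.bincount(raw, minlength=self.n_clusters)
        order = np.argsort(-sizes, kind="stable")
        remap = np.empty_like(order)
        remap[order] = np.arange(self.n_clusters)
        labels = remap[raw] + 1
        self.labels_ = pd.Series(labels, index=signal.index, name="cluster")
        self.cluster_means_ = signal.groupby(self.labels_).mean()
        return self


def kmeans_gene_clusters(
    signal: pd.DataFrame, k: int = 5, seed: int | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    est = GeneSignalKMeans(n_clusters=k, random_state=seed).fit(signal)
    return est.labels_, est.cluster_means_


def newgene_cluster_enrichment(
    labels: pd.Series, new_genes: set[str], total_genes: int | None = None
) -> list[EnrichmentResult]:
    """Per-cluster Fisher test of new-gene over-representation.

    The 2x2 is {new, not-new} x {in-cluster, not}; the background fraction
    is cluster size / total genes.
    """
    new_in_universe = set(labels.index) & set(new_genes)
    if not new_genes:
        raise ValueError("empty new-gene set")
    total = total_genes if total_genes is not None else len(labels)
    is_new = labels.index.isin(new_in_universe)
    results = []
    for c in sorted(labels.unique()):
        in_c = (labels == c).values
        table = [
            [int((is_new & in_c).sum()), int((is_new & ~in_c).sum())],
            [int((~is_new & in_c).sum()), int((~is_new & ~in_c).sum())],
        ]
        results.append(
            fisher_enrichment(f"cluster{c} x new", table, in_c.sum() / total)
        )
    return results
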