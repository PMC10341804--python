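"""Multivariate hidden Markov model over binarized chromatin tracks.

The genome is cut into fixed-width bins (200 bp by default); each of the
M tracks (five histone marks + DNase) is reduced to a presence/absence call
per bin with a Poisson upper-tail test against a depth-scaled mock control.
A K-state HMM with independent Bernoulli emissions per mark is then learned
by Baum-Welch (random restarts, log-likelihood monotone per restart) and
decoded by Viterbi or posterior marginals into a segmentation that
partitions the binned genome into chromatin states S1..SK.

Chromosomes are treated as independent observation sequences. The
forward/backward/Viterbi inner loops are numba-compiled; everything else is
vectorized numpy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import linear_sum_assignment
from scipy.stats import poisson
from sklearn.base import BaseEstimator

from .genome import BinnedTrack, GenomeLayout, Interval

# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------


def binarize(
    chip: BinnedTrack,
    control: BinnedTrack | None = None,
    p_threshold: float = 1e-4,
) -> dict[str, np.ndarray]:
    """Presence/absence call per bin.

    The expected rate is the control count scaled to ChIP depth, floored at
    the global ChIP mean; a bin is called 1 iff P(X >= c | lambda) <=
    ``p_threshold`` under a Poisson model.
    """
    from .peaks import scaled_control_rate

    for c in chip.counts.values():
        if np.any(c < 0):
            raise ValueError("negative counts")
    rates = scaled_control_rate(chip, control)
    out = {}
    for chrom, counts in chip.counts.items():
        pvals = poisson.sf(counts - 1, rates[chrom])
        out[chrom] = (pvals <= p_threshold).astype(np.uint8)
    return out


def pool_tracks(tracks: Sequence[BinnedTrack]) -> BinnedTrack:
    """Sum replicate tracks bin-wise (replicates are pooled before
    binarization to maximize depth)."""
    first = tracks[0]
    counts = {c: v.copy() for c, v in first.counts.items()}
    for t in tracks[1:]:
        if not t.same_layout_as(first):
            raise ValueError("cannot pool tracks with different layouts")
        for c in counts:
            counts[c] = counts[c] + t.counts[c]
    return BinnedTrack(first.mark, first.condition, 0, first.bin_width, counts)


@dataclass
class BinaryMatrix:
    """Per-chromosome 0/1 observation matrix, one column per mark."""

    marks: tuple[str, ...]
    data: dict[str, np.ndarray]  # chrom -> (T, M) uint8
    bin_width: int = 200

    def __post_init__(self) -> None:
        for chrom, m in self.data.items():
            m = np.ascontiguousarray(m, dtype=np.uint8)
            if m.ndim != 2 or m.shape[1] != len(self.marks):
                raise ValueError(f"{chrom}: expected (T, {len(self.marks)}) matrix")
            if not np.isin(m, (0, 1)).all():
                raise ValueError(f"{chrom}: entries must be 0/1")
            self.data[chrom] = m

    @property
    def n_bins(self) -> int:
        return sum(m.shape[0] for m in self.data.values())

    def stacked(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        chroms = list(self.data)
        X = np.concatenate([self.data[c] for c in chroms])
        lengths = np.array([self.data[c].shape[0] for c in chroms])
        return X, lengths, chroms

    @classmethod
    def from_tracks(
        cls,
        chip: dict[str, BinnedTrack],
        control: BinnedTrack | None = None,
        p_threshold: float = 1e-4,
    ) -> "BinaryMatrix":
        marks = tuple(chip)
        calls = {m: binarize(t, control, p_threshold) for m, t in chip.items()}
        chroms = list(next(iter(chip.values())).counts)
        data = {
            c: np.stack([calls[m][c] for m in marks], axis=1).astype(np.uint8)
            for c in chroms
        }
        return cls(marks, data, next(iter(chip.values())).bin_width)

    # ChromHMM-style text dialect: one file per chromosome, two header lines
    def write(self, directory, prefix: str = "track") -> None:
        import os

        for chrom, m in self.data.items():
            path = os.path.join(directory, f"{prefix}_{chrom}_binary.txt")
            with open(path, "w") as fh:
                fh.write(f"genome\t{chrom}\n")
                fh.write("\t".join(self.marks) + "\n")
                np.savetxt(fh, m, fmt="%d", delimiter="\t")

    @classmethod
    def read(cls, paths: Sequence[str], bin_width: int = 200) -> "BinaryMatrix":
        data = {}
        marks: tuple[str, ...] | None = None
        for path in paths:
            with open(path) as fh:
                _, chrom = fh.readline().rstrip("\n").split("\t")
                file_marks = tuple(fh.readline().rstrip("\n").split("\t"))
                m = np.loadtxt(fh, dtype=np.uint8, delimiter="\t", ndmin=2)
            if marks is None:
                marks = file_marks
            elif marks != file_marks:
                raise ValueError("inconsistent mark headers across chromosomes")
            data[chrom] = m
        assert marks is not None
        return cls(marks, data, bin_width)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _forward(frame: np.ndarray, start: np.ndarray, trans: np.ndarray):
    """Scaled forward pass. Returns (alpha, log-likelihood)."""
    T, K = frame.shape
    alpha = np.empty((T, K))
    loglik = 0.0
    a = start * frame[0]
    norm = a.sum()
    if norm <= 0.0:
        return alpha, -np.inf
    alpha[0] = a / norm
    loglik += np.log(norm)
    for t in range(1, T):
        norm = 0.0
        for j in range(K):
            acc = 0.0
            for i in range(K):
                acc += alpha[t - 1, i] * trans[i, j]
            acc *= frame[t, j]
            alpha[t, j] = acc
            norm += acc
        if norm <= 0.0:
            return alpha, -np.inf
        for j in range(K):
            alpha[t, j] /= norm
        loglik += np.log(norm)
    return alpha, loglik


@njit(cache=True)
def _backward(frame: np.ndarray, trans: np.ndarray):
    """Backward pass, renormalized per position (scale-free)."""
    T, K = frame.shape
    beta = np.empty((T, K))
    fb = np.empty(K)
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        for j in range(K):
            fb[j] = frame[t + 1, j] * beta[t + 1, j]
        norm = 0.0
        for i in range(K):
            acc = 0.0
            for j in range(K):
                acc += trans[i, j] * fb[j]
            beta[t, i] = acc
            norm += acc
        if norm > 0.0:
            for i in range(K):
                beta[t, i] /= norm
    return beta


@njit(cache=True)
def _posteriors(frame, start, trans):
    """Returns (loglik, gamma, xi_sum, gamma0)."""
    T, K = frame.shape
    alpha, loglik = _forward(frame, start, trans)
    beta = _backward(frame, trans)
    gamma = alpha * beta
    for t in range(T):
        s = gamma[t].sum()
        if s > 0.0:
            gamma[t] /= s
    xi_sum = np.zeros((K, K))
    fb = np.empty(K)
    for t in range(T - 1):
        for j in range(K):
            fb[j] = frame[t + 1, j] * beta[t + 1, j]
        s = 0.0
        for i in range(K):
            for j in range(K):
                s += alpha[t, i] * trans[i, j] * fb[j]
        if s > 0.0:
            for i in range(K):
                ai = alpha[t, i] / s
                for j in range(K):
                    xi_sum[i, j] += ai * trans[i, j] * fb[j]
    return loglik, gamma, xi_sum, gamma[0].copy()


@njit(cache=True)
def _viterbi(logframe: np.ndarray, logstart: np.ndarray, logtrans: np.ndarray):
    T, K = logframe.shape
    delta = logstart + logframe[0]
    psi = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        nxt = np.empty(K)
        for j in range(K):
            best = -np.inf
            arg = 0
            for i in range(K):
                v = delta[i] + logtrans[i, j]
                if v > best:
                    best = v
                    arg = i
            nxt[j] = best + logframe[t, j]
            psi[t, j] = arg
        delta = nxt
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = np.argmax(delta)
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


def _frame_prob(X: np.ndarray, emission: np.ndarray, log: bool = False) -> np.ndarray:
    """Per-bin emission probability matrix (T, K) for 0/1 observations
    under independent Bernoulli marks. Exact 0/1 emission entries are
    handled (a conflicting observation gets probability 0)."""
    T, M = X.shape
    K = emission.shape[0]
    frame = np.ones((T, K))
    for m in range(M):
        on = X[:, m: m + 1].astype(bool)
        frame *= np.where(on, emission[None, :, m], 1.0 - emission[None, :, m])
    if log:
        with np.errstate(divide="ignore"):
            return np.log(frame)
    return frame


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class BernoulliHMM(BaseEstimator):
    """HMM with independent Bernoulli emissions per mark, fit by Baum-Welch.

    Parameters
    ----------
    n_states : int
        Number of hidden chromatin states K (default 6).
    n_restarts : int
        Random EM restarts; the restart with the highest final
        log-likelihood wins. Ignored when explicit ``*_init`` arrays are
        supplied.
    max_iter, tol : int, float
        EM stops when the log-likelihood improves by less than ``tol`` or
        after ``max_iter`` iterations.
    emission_floor : float
        Emission probabilities are clipped to
        ``[emission_floor, 1 - emission_floor]`` after each M-step to avoid
        degenerate zeros.
    random_state : int or None
        Seed for restart initialization; same seed, same model, bit for bit.

    Attributes
    ----------
    emissionprob_ : (K, M) array of Bernoulli success probabilities.
    transmat_ : (K, K) row-stochastic transition matrix.
    startprob_ : (K,) initial distribution.
    loglik_ : final log-likelihood of the winning restart.
    history_ : list of per-restart log-likelihood trajectories.
    """

    def __init__(
        self,
        n_states: int = 6,
        n_restarts: int = 10,
        max_iter: int = 200,
        tol: float = 1e-4,
        emission_floor: float = 1e-6,
        random_state: int | None = None,
        startprob_init: np.ndarray | None = None,
        transmat_init: np.ndarray | None = None,
        emissionprob_init: np.ndarray | None = None,
    ):
        self.n_states = n_states
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.emission_floor = emission_floor
        self.random_state = random_state
        self.startprob_init = startprob_init
        self.transmat_init = transmat_init
        self.emissionprob_init = emissionprob_init

    # -- helpers ----------------------------------------------------------
    @staticmethod
    def _split(X: np.ndarray, lengths: np.ndarray | None) -> list[np.ndarray]:
        X = np.asarray(X)
        if lengths is None:
            return [X]
        if sum(lengths) != len(X):
            raise ValueError("lengths do not sum to n_bins")
        idx = np.cumsum(lengths)[:-1]
        return np.split(X, idx)

    def _random_init(self, rng: np.random.Generator, M: int):
        K = self.n_states
        start = rng.uniform(0.1, 1.0, K)
        start /= start.sum()
        trans = rng.uniform(0.1, 1.0, (K, K)) + 2.0 * np.eye(K)
        trans /= trans.sum(axis=1, keepdims=True)
        emission = rng.uniform(0.1, 0.9, (K, M))
        return start, trans, emission

    def _em(self, seqs, start, trans, emission):
        floor = self.emission_floor
        history = []
        prev = -np.inf
        for _ in range(self.max_iter):
            ll = 0.0
            K, M = emission.shape
            gamma_sum = np.zeros(K)
            obs_sum = np.zeros((K, M))
            xi_total = np.zeros((K, K))
            start_acc = np.zeros(K)
            for X in seqs:
                frame = _frame_prob(X, emission)
                l, gamma, xi, g0 = _posteriors(frame, start, trans)
                ll += l
                gamma_sum += gamma.sum(axis=0)
                obs_sum += gamma.T @ X.astype(np.float64)
                xi_total += xi
                start_acc += g0
            history.append(ll)
            if ll - prev < self.tol and np.isfinite(prev):
                break
            prev = ll
            # closed-form M-step
            start = start_acc / start_acc.sum()
            denom = xi_total.sum(axis=1, keepdims=True)
            trans = np.where(denom > 0, xi_total / np.where(denom > 0, denom, 1.0),
                             1.0 / K)
            with np.errstate(invalid="ignore"):
                emission = obs_sum / gamma_sum[:, None]
            emission = np.where(np.isfinite(emission), emission, 0.5)
            emission = np.clip(emission, floor, 1.0 - floor)
        return start, trans, emission, np.array(history)

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, lengths=None):
        seqs = self._split(X, lengths)
        M = seqs[0].shape[1]
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.n_states > sum(len(s) for s in seqs):
            raise ValueError("more states than observations")
        explicit = self.emissionprob_init is not None
        if explicit:
            inits = [(
                np.asarray(self.startprob_init, dtype=float)
                if self.startprob_init is not None
                else np.full(self.n_states, 1.0 / self.n_states),
                np.asarray(self.transmat_init, dtype=float)
                if self.transmat_init is not None
                else np.full((self.n_states,) * 2, 1.0 / self.n_states),
                np.asarray(self.emissionprob_init, dtype=float),
            )]
        else:
            seeds = np.random.SeedSequence(self.random_state).spawn(self.n_restarts)
            inits = [
                self._random_init(np.random.default_rng(s), M) for s in seeds
            ]
        best = None
        self.history_ = []
        for start, trans, emission in inits:
            s, t, e, hist = self._em(seqs, start, trans, emission)
            self.history_.append(hist)
            if best is None or hist[-1] > best[3][-1]:
                best = (s, t, e, hist)
        self.startprob_, self.transmat_, self.emissionprob_, hist = best
        self.loglik_ = float(hist[-1])
        self.n_iter_ = len(hist)
        self.converged_ = len(hist) < self.max_iter
        return self

    def score(self, X, lengths=None) -> float:
        """Total forward log-likelihood over all sequences."""
        total = 0.0
        for seq in self._split(X, lengths):
            frame = _frame_prob(seq, self.emissionprob_)
            _, ll = _forward(frame, self.startprob_, self.transmat_)
            total += ll
        return float(total)

    def predict(self, X, lengths=None, method: str = "viterbi") -> np.ndarray:
        """Per-bin state labels (0-based)."""
        paths = []
        for seq in self._split(X, lengths):
            if method == "viterbi":
                logframe = _frame_prob(seq, self.emissionprob_, log=True)
                with np.errstate(divide="ignore"):
                    paths.append(
                        _viterbi(
                            logframe,
                            np.log(self.startprob_),
                            np.log(self.transmat_),
                        )
                    )
            elif method == "posterior":
                frame = _frame_prob(seq, self.emissionprob_)
                _, gamma, _, _ = _posteriors(frame, self.startprob_, self.transmat_)
                paths.append(np.argmax(gamma, axis=1))
            else:
                raise ValueError(f"unknown decode method {method!r}")
        return np.concatenate(paths)

    def predict_proba(self, X, lengths=None) -> np.ndarray:
        out = []
        for seq in self._split(X, lengths):
            frame = _frame_prob(seq, self.emissionprob_)
            _, gamma, _, _ = _posteriors(frame, self.startprob_, self.transmat_)
            out.append(gamma)
        return np.concatenate(out)

    # -- persistence ------------------------------------------------------
    def to_json(self, path, marks: Sequence[str] | None = None) -> None:
        doc = {
            "n_states": self.n_states,
            "marks": list(marks) if marks else None,
            "startprob": self.startprob_.tolist(),
            "transmat": self.transmat_.tolist(),
            "emissionprob": self.emissionprob_.tolist(),
            "loglik": self.loglik_,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "BernoulliHMM":
        with open(path) as fh:
            doc = json.load(fh)
        model = cls(n_states=doc["n_states"])
        model.startprob_ = np.array(doc["startprob"])
        model.transmat_ = np.array(doc["transmat"])
        model.emissionprob_ = np.array(doc["emissionprob"])
        model.loglik_ = doc.get("loglik", np.nan)
        return model


def baum_welch(
    data: BinaryMatrix,
    K: int = 6,
    n_restarts: int = 10,
    seed: int | None = None,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> BernoulliHMM:
    """Functional wrapper: learn a K-state model from a BinaryMatrix."""
    X, lengths, _ = data.stacked()
    return BernoulliHMM(
        n_states=K, n_restarts=n_restarts, tol=tol, max_iter=max_iter,
        random_state=seed,
    ).fit(X, lengths)


def log_likelihood(model: BernoulliHMM, data: BinaryMatrix) -> float:
    X, lengths, _ = data.stacked()
    return model.score(X, lengths)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


@dataclass
class Segmentation:
    """Per-bin state labels (0-based internally; reported as S1..SK)."""

    states: dict[str, np.ndarray]
    n_states: int
    bin_width: int

    def intervals(self, layout: GenomeLayout) -> list[tuple[Interval, int]]:
        """Maximal runs of equal state as half-open intervals; the run
        intervals partition each chromosome exactly once."""
        out = []
        bw = self.bin_width
        for chrom, s in self.states.items():
            length = layout.lengths[chrom]
            boundaries = np.flatnonzero(np.diff(s)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [len(s)]])
            for a, b in zip(starts, ends):
                out.append(
                    (Interval(chrom, int(a) * bw, min(int(b) * bw, length)),
                     int(s[a]))
                )
        return out

    def state_name(self, k: int) -> str:
        return f"S{k + 1}"

    def to_bed(self, layout: GenomeLayout, path) -> None:
        with open(path, "w") as fh:
            for iv, k in self.intervals(layout):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{self.state_name(k)}\n")

    @classmethod
    def from_bed(cls, path, bin_width: int = 200, n_states: int | None = None) -> "Segmentation":
        per_chrom: dict[str, list[tuple[int, int, int]]] = {}
        max_state = 0
        with open(path) as fh:
            for line in fh:
                chrom, start, end, name = line.rstrip("\n").split("\t")[:4]
                k = int(name.lstrip("S")) - 1
                max_state = max(max_state, k)
                per_chrom.setdefault(chrom, []).append((int(start), int(end), k))
        states = {}
        for chrom, rows in per_chrom.items():
            rows.sort()
            n_bins = (rows[-1][1] + bin_width - 1) // bin_width
            s = np.zeros(n_bins, dtype=np.int64)
            for start, end, k in rows:
                s[start // bin_width: (end + bin_width - 1) // bin_width] = k
            states[chrom] = s
        return cls(states, n_states or max_state + 1, bin_width)


def decode(
    model: BernoulliHMM, data: BinaryMatrix, method: str = "viterbi"
) -> Segmentation:
    """Decode a BinaryMatrix into a Segmentation (Viterbi or posterior)."""
    X, lengths, chroms = data.stacked()
    labels = model.predict(X, lengths, method=method)
    states = dict(zip(chroms, np.split(labels, np.cumsum(lengths)[:-1])))
    return Segmentation(states, model.n_states, data.bin_width)


def relabel_states(
    model: BernoulliHMM,
    seg: Segmentation | None = None,
    signature_order: Sequence[str] | None = None,
    marks: Sequence[str] | None = None,
) -> tuple[BernoulliHMM, Segmentation | None, np.ndarray]:
    """Canonical state order: lexicographic descending sort of emission
    vectors under ``signature_order`` (ties broken by original index).

    Returns (relabelled model, relabelled segmentation, order) where
    ``order[new] = old``. Idempotent.
    """
    em = model.emissionprob_
    if signature_order is not None and marks is not None:
        cols = [list(marks).index(m) for m in signature_order]
        key = em[:, cols]
    else:
        key = em
    order = sorted(
        range(em.shape[0]), key=lambda k: (tuple(-key[k]), k)
    )
    order = np.asarray(order)
    new = BernoulliHMM(**model.get_params())
    new.emissionprob_ = em[order]
    new.transmat_ = model.transmat_[np.ix_(order, order)]
    new.startprob_ = model.startprob_[order]
    new.loglik_ = getattr(model, "loglik_", np.nan)
    new_seg = None
    if seg is not None:
        inverse = np.empty_like(order)
        inverse[order] = np.arange(len(order))
        new_seg = Segmentation(
            {c: inverse[s] for c, s in seg.states.items()}, seg.n_states, seg.bin_width
        )
    return new, new_seg, order


def match_states(emission_a: np.ndarray, emission_b: np.ndarray) -> np.ndarray:
    """Map states of model B onto model A by minimal total-variation
    distance between emission rows (Hungarian assignment).

    Returns ``mapping`` with ``mapping[b_state] = a_state``.
    """
    cost = np.abs(emission_a[None, :, :] - emission_b[:, None, :]).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    mapping = np.empty(emission_a.shape[0], dtype=np.int64)
    mapping[rows] = cols
    return mapping


def state_coverage(
    seg: Segmentation, layout: GenomeLayout, by_subgenome: bool = False
) -> pd.DataFrame:
    """Bases and fraction of the genome in each state (whole genome, or per
    subgenome with fractions relative to each subgenome's length)."""
    rows = []
    groups = (
        [("A",), ("D",)] if by_subgenome else [("A", "D")]
    )
    for sgs in groups:
        bases = np.zeros(seg.n_states, dtype=np.int64)
        total = 0
        for chrom, s in seg.states.items():
            if layout.subgenome[chrom] not in sgs:
                continue
            sizes = layout.bin_sizes(chrom, seg.bin_width)
            total += layout.lengths[chrom]
            bases += np.bincount(s, weights=sizes, minlength=seg.n_states).astype(np.int64)
        for k in range(seg.n_states):
            rows.append(
                {
                    "subgenome": "+".join(sgs),
                    "state": f"S{k + 1}",
                    "bases": int(bases[k]),
                    "fraction": bases[k] / total if total else np.nan,
                }
            )
    return pd.DataFrame(rows)
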