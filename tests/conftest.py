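import itertools
import math

import numpy as np
import pytest

from allostate.genome import BinnedTrack, GeneModel, GenomeLayout, Interval


@pytest.fixture
def toy_layout():
    return GenomeLayout.from_records([("A01", 1000, "A"), ("D01", 2000, "D")])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_track(layout, counts_by_chrom, bin_width=200, mark="H3K4me3",
               condition="wild", replicate=1):
    counts = {c: np.asarray(v, dtype=np.int64) for c, v in counts_by_chrom.items()}
    return BinnedTrack(mark, condition, replicate, bin_width, counts)


def make_gene(gene_id, chrom, start, end, strand="+", exons=None, subgenome="A",
              is_new=False):
    body = Interval(chrom, start, end, strand)
    if exons is None:
        exons = [body]
    return GeneModel(gene_id, body, list(exons), subgenome, is_new)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def bernoulli_emit_prob(emission, state, obs):
    p = 1.0
    for m, o in enumerate(obs):
        p *= emission[state, m] if o else (1.0 - emission[state, m])
    return p


def brute_force_loglik(start, trans, emission, obs):
    """Exhaustive sum over all K^T hidden paths."""
    K = len(start)
    T = len(obs)
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = start[path[0]] * bernoulli_emit_prob(emission, path[0], obs[0])
        for t in range(1, T):
            p *= trans[path[t - 1], path[t]]
            p *= bernoulli_emit_prob(emission, path[t], obs[t])
        total += p
    return math.log(total) if total > 0 else -math.inf


def brute_force_best_path_logprob(start, trans, emission, obs):
    """Max joint log-probability over all K^T hidden paths."""
    K = len(start)
    T = len(obs)
    best = -math.inf
    for path in itertools.product(range(K), repeat=T):
        p = start[path[0]] * bernoulli_emit_prob(emission, path[0], obs[0])
        for t in range(1, T):
            p *= trans[path[t - 1], path[t]]
            p *= bernoulli_emit_prob(emission, path[t], obs[t])
        if p > 0:
            best = max(best, math.log(p))
    return best


def path_logprob(start, trans, emission, obs, path):
    p = start[path[0]] * bernoulli_emit_prob(emission, path[0], obs[0])
    for t in range(1, len(obs)):
        p *= trans[path[t - 1], path[t]]
        p *= bernoulli_emit_prob(emission, path[t], obs[t])
    return math.log(p) if p > 0 else -math.inf


def fisher_exact_enumeration(table):
    """Two-sided Fisher exact p by enumerating all tables with the same
    margins and summing hypergeometric probabilities <= that of the
    observed table (with a small relative tolerance, as is conventional)."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def hyper(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = hyper(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = hyper(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


def wilcoxon_exact_enumeration(x, y):
    """Two-sided rank-sum p by enumerating all assignments of the pooled
    ranks to the first group (no ties assumed)."""
    pooled = sorted(list(x) + list(y))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1 = len(x)
    obs = sum(ranks[v] for v in x)
    all_ranks = list(range(1, len(pooled) + 1))
    stats = [sum(c) for c in itertools.combinations(all_ranks, n1)]
    mean = n1 * (len(pooled) + 1) / 2
    dev = abs(obs - mean)
    extreme = sum(1 for s in stats if abs(s - mean) >= dev - 1e-12)
    return extreme / len(stats)


def random_tiny_hmm(rng, K, M, T):
    start = rng.dirichlet(np.ones(K))
    trans = rng.dirichlet(np.ones(K), size=K)
    emission = rng.uniform(0.05, 0.95, size=(K, M))
    obs = rng.integers(0, 2, size=(T, M)).astype(np.uint8)
    return start, trans, emission, obs
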