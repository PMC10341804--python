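"""Synthetic study generator: every pipeline input with planted truth.

The generator emulates the statistical structure of a two-subgenome
allotetraploid chromatin study at desk scale: an A subgenome twice the
size of the D subgenome; a planted Markov chain of six chromatin states
per 200-bp bin emitting per-mark Poisson fragment counts (high rate where
the planted Bernoulli emission fires); genes with promoters; planted
homoeolog pairs (balanced expression), subgenome-unique genes (A-biased
expression) and unclassified leftovers in a fabricated protein-similarity
table; and a second condition whose promoter states are switched for a
planted gene subset, coupled to planted differential expression (switches
into the open state are preferentially upregulated, and vice versa).

Counts are Poisson per bin rather than read-level: sufficient for
binarization and HMM testing. Everything is deterministic given the seed,
and all truth labels are exported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import MARKS, BinnedTrack, GeneModel, GenomeLayout, Interval

TE_MIXTURE = {
    "Gypsy": 0.45,
    "Copia": 0.07,
    "hAT": 0.05,
    "Helitron": 0.05,
    "CACTA": 0.05,
    "other_retro": 0.18,
    "other_dna": 0.15,
}

OPEN_STATE = 2  # S3: DNase-only open chromatin
EMPTY_STATE = 1  # S2: devoid of marks


def default_emission() -> np.ndarray:
    """Planted per-state Bernoulli emission probabilities.

    Rows S1..S6, columns H3K4me3, H3K27me3, H3K36me3, H3K27ac, H3K9ac,
    DNase: a repressed state, an unmarked majority state, an open state,
    an active promoter state, a bivalent open state, and a transcribed
    but inaccessible state.
    """
    return np.array(
        [
            [0.05, 0.90, 0.05, 0.05, 0.05, 0.05],  # S1 repressed
            [0.02, 0.02, 0.02, 0.02, 0.02, 0.02],  # S2 unmarked
            [0.05, 0.05, 0.05, 0.05, 0.05, 0.90],  # S3 open
            [0.80, 0.05, 0.10, 0.90, 0.85, 0.90],  # S4 active
            [0.30, 0.70, 0.10, 0.80, 0.80, 0.85],  # S5 bivalent
            [0.85, 0.05, 0.90, 0.10, 0.10, 0.03],  # S6 transcribed, closed
        ]
    )


def default_transition(n_states: int = 6) -> np.ndarray:
    """Sticky planted transition matrix with a dominant unmarked state."""
    T = np.zeros((n_states, n_states))
    for i in range(n_states):
        self_p = 0.97 if i == EMPTY_STATE else 0.85
        T[i, i] = self_p
        rest = 1.0 - self_p
        others = [j for j in range(n_states) if j != i]
        for j in others:
            T[i, j] = rest * (0.6 if j == EMPTY_STATE else 0.4 / (len(others) - 1))
        if i == EMPTY_STATE:
            T[i, others] = rest / len(others)
    return T / T.sum(axis=1, keepdims=True)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator (toy scale ~3 Mb)."""

    seed: int = 0
    # genome layout: A subgenome ~2x the D subgenome
    n_chroms_a: int = 2
    chrom_len_a: int = 1_000_000
    n_chroms_d: int = 2
    chrom_len_d: int = 500_000
    bin_width: int = 200
    # planted chromatin-state model
    n_states: int = 6
    marks: tuple[str, ...] = MARKS
    emission: np.ndarray = field(default_factory=default_emission)
    transition: np.ndarray = field(default_factory=default_transition)
    # fragment-count model (per replicate, per bin)
    rate_high: float = 25.0
    rate_low: float = 0.5
    mock_rate: float = 1.0
    n_reps: int = 2
    conditions: tuple[str, str] = ("wild", "domesticated")
    # gene / TE structure
    n_genes_a: int = 700
    n_genes_d: int = 600
    gene_length: int = 1000
    pair_fraction: float = 0.75
    unique_fraction: float = 0.08
    new_gene_fraction: float = 0.065
    tes_per_mb: float = 150.0
    # expression model
    mean_log_mu: float = float(np.log(100.0))
    mean_log_sigma: float = 1.0
    dispersion: float = 0.05
    a_bias_factor: float = 2.5
    de_fraction: float = 0.2
    de_effect: float = 4.0
    # planted promoter-state switches between conditions
    switch_fraction: float = 0.15
    coupling_prob: float = 0.8
    switch_pad_bins: int = 2

    def validate(self) -> None:
        for name in ("pair_fraction", "unique_fraction", "new_gene_fraction",
                     "de_fraction", "switch_fraction", "coupling_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        em = np.asarray(self.emission)
        tr = np.asarray(self.transition)
        if em.shape != (self.n_states, len(self.marks)):
            raise ValueError("emission shape mismatch")
        if np.any((em < 0) | (em > 1)):
            raise ValueError("emission entries must lie in [0, 1]")
        if not np.allclose(tr.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")


# ---------------------------------------------------------------------------
# genome, genes, TEs
# ---------------------------------------------------------------------------


def simulate_genome(config: SimulationConfig):
    """Layout + non-overlapping genes (>= 500 bp upstream clearance) + TEs."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    chroms = [
        (f"A{i + 1:02d}", config.chrom_len_a, "A") for i in range(config.n_chroms_a)
    ] + [
        (f"D{i + 1:02d}", config.chrom_len_d, "D") for i in range(config.n_chroms_d)
    ]
    layout = GenomeLayout.from_records(chroms)

    genes: list[GeneModel] = []
    for sg, n_sub in (("A", config.n_genes_a), ("D", config.n_genes_d)):
        sub_chroms = [c for c in layout.names if layout.subgenome[c] == sg]
        per = [n_sub // len(sub_chroms)] * len(sub_chroms)
        per[-1] += n_sub - sum(per)
        for chrom, n in zip(sub_chroms, per):
            length = layout.lengths[chrom]
            slot = length // n
            if slot < config.gene_length + 600:
                raise ValueError(f"gene density infeasible on {chrom}")
            for i in range(n):
                lo = i * slot + 550
                hi = (i + 1) * slot - config.gene_length - 50
                start = int(rng.integers(lo, max(lo + 1, hi)))
                end = start + config.gene_length
                strand = "+" if rng.random() < 0.5 else "-"
                gid = f"Gd{chrom}G{i + 1:04d}"
                body = Interval(chrom, start, end, strand)
                third = config.gene_length // 3
                exons = [
                    Interval(chrom, start, start + third, strand),
                    Interval(chrom, end - third, end, strand),
                ]
                genes.append(GeneModel(gid, body, exons, sg))
    n_new = round(config.new_gene_fraction * len(genes))
    for idx in rng.choice(len(genes), size=n_new, replace=False):
        genes[idx].is_new_gene = True

    te_rows = []
    classes = list(TE_MIXTURE)
    probs = np.array(list(TE_MIXTURE.values()))
    probs = probs / probs.sum()
    for chrom in layout.names:
        n_te = int(config.tes_per_mb * layout.lengths[chrom] / 1e6)
        starts = rng.integers(0, layout.lengths[chrom] - 2000, size=n_te)
        lengths = rng.integers(200, 2000, size=n_te)
        cls = rng.choice(classes, size=n_te, p=probs)
        for s, l, c in zip(starts, lengths, cls):
            te_rows.append(
                {"chrom": chrom, "start": int(s),
                 "end": int(min(s + l, layout.lengths[chrom])), "te_class": str(c)}
            )
    tes = pd.DataFrame(te_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    return layout, genes, tes


# ---------------------------------------------------------------------------
# chromatin states and tracks
# ---------------------------------------------------------------------------


def _sample_chain(rng, transition: np.ndarray, start: np.ndarray, n: int) -> np.ndarray:
    cum = np.cumsum(transition, axis=1)
    states = np.empty(n, dtype=np.int64)
    u = rng.random(n)
    states[0] = np.searchsorted(np.cumsum(start), u[0])
    for t in range(1, n):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t])
    return states


def _promoter_bin_range(gene: GeneModel, layout: GenomeLayout, bin_width: int,
                        pad: int = 0) -> tuple[int, int]:
    p = gene.promoter()
    start = max(0, p.start)
    end = min(p.end, layout.lengths[p.chrom])
    n = layout.n_bins(p.chrom, bin_width)
    b0 = max(0, start // bin_width - pad)
    b1 = min(n, (end + bin_width - 1) // bin_width + pad)
    return b0, b1


def simulate_state_tracks(config: SimulationConfig, layout: GenomeLayout,
                          genes: list[GeneModel]):
    """Planted segmentations for both conditions, the per-gene promoter
    switch table, and Poisson fragment tracks (marks + mock, per rep).

    Returns (seg_by_condition, tracks, switches) where ``tracks`` maps
    (condition, mark, replicate) -> BinnedTrack and mark "Mock" is the
    control. A switched gene's condition-2 promoter bins (padded by
    ``switch_pad_bins``) are set to the target state.
    """
    from .hmm import Segmentation

    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    bw = config.bin_width
    K, M = config.n_states, len(config.marks)
    start = np.full(K, 1.0 / K)

    states1 = {
        c: _sample_chain(rng, np.asarray(config.transition), start,
                         layout.n_bins(c, bw))
        for c in layout.names
    }
    states2 = {c: s.copy() for c, s in states1.items()}

    # planted promoter switches in condition 2
    promoter_state = {}
    for g in genes:
        b0, b1 = _promoter_bin_range(g, layout, bw)
        vals, counts = np.unique(states1[g.body.chrom][b0:b1], return_counts=True)
        promoter_state[g.gene_id] = int(vals[np.argmax(counts)])
    n_switch = round(config.switch_fraction * len(genes))
    s2_genes = [g for g in genes if promoter_state[g.gene_id] == EMPTY_STATE]
    s3_genes = [g for g in genes if promoter_state[g.gene_id] == OPEN_STATE]
    n_s2s3 = min(len(s2_genes), round(0.4 * n_switch))
    n_s3s2 = min(len(s3_genes), round(0.2 * n_switch))
    chosen = []
    picked_ids = set()
    for pool, n_pick, target in (
        (s2_genes, n_s2s3, OPEN_STATE),
        (s3_genes, n_s3s2, EMPTY_STATE),
    ):
        idx = rng.choice(len(pool), size=n_pick, replace=False)
        for i in idx:
            g = pool[i]
            chosen.append((g, promoter_state[g.gene_id], target))
            picked_ids.add(g.gene_id)
    remaining = [g for g in genes if g.gene_id not in picked_ids]
    n_rand = max(0, n_switch - len(chosen))
    for i in rng.choice(len(remaining), size=min(n_rand, len(remaining)), replace=False):
        g = remaining[i]
        src = promoter_state[g.gene_id]
        target = int(rng.choice([k for k in range(K) if k != src]))
        chosen.append((g, src, target))

    switch_rows = []
    for g, src, target in chosen:
        b0, b1 = _promoter_bin_range(g, layout, bw, pad=config.switch_pad_bins)
        states2[g.body.chrom][b0:b1] = target
        switch_rows.append(
            {"gene_id": g.gene_id, "state_from": f"S{src + 1}",
             "state_to": f"S{target + 1}"}
        )
    switches = pd.DataFrame(
        switch_rows, columns=["gene_id", "state_from", "state_to"]
    )

    seg = {
        config.conditions[0]: Segmentation(states1, K, bw),
        config.conditions[1]: Segmentation(states2, K, bw),
    }

    emission = np.asarray(config.emission)
    tracks: dict[tuple[str, str, int], BinnedTrack] = {}
    for cond, states in ((config.conditions[0], states1), (config.conditions[1], states2)):
        for m, mark in enumerate(config.marks):
            # biological on/off latent shared across replicates
            on = {
                c: rng.random(len(states[c])) < emission[states[c], m]
                for c in layout.names
            }
            for rep in range(1, config.n_reps + 1):
                counts = {
                    c: rng.poisson(
                        np.where(on[c], config.rate_high, config.rate_low)
                    ).astype(np.int64)
                    for c in layout.names
                }
                tracks[(cond, mark, rep)] = BinnedTrack(mark, cond, rep, bw, counts)
        for rep in range(1, config.n_reps + 1):
            counts = {
                c: rng.poisson(config.mock_rate, layout.n_bins(c, bw)).astype(np.int64)
                for c in layout.names
            }
            tracks[(cond, "Mock", rep)] = BinnedTrack("Mock", cond, rep, bw, counts)
    return seg, tracks, switches


# ---------------------------------------------------------------------------
# expression and homoeologs
# ---------------------------------------------------------------------------


def _nb_draw(rng, mean, dispersion):
    """NB counts with Var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_expression_and_homoeologs(
    config: SimulationConfig,
    genes: list[GeneModel],
    switches: pd.DataFrame | None = None,
):
    """Counts (2 conditions x n_reps), the protein-similarity tables, and
    truth labels.

    Homoeolog pairs share a baseline mean (balanced); A-subgenome-unique
    genes get the A-bias multiplier; a ``de_fraction`` of genes change
    between conditions by ``de_effect`` (half up, half down); genes with a
    planted promoter switch into (out of) the open state are upregulated
    (downregulated) with probability ``coupling_prob``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    a_ids = [g.gene_id for g in genes if g.subgenome == "A"]
    d_ids = [g.gene_id for g in genes if g.subgenome == "D"]
    n_pairs = round(config.pair_fraction * min(len(a_ids), len(d_ids)))
    n_a_unique = round(config.unique_fraction * len(a_ids))
    n_d_unique = round(config.unique_fraction * len(d_ids))

    a_perm = list(rng.permutation(a_ids))
    d_perm = list(rng.permutation(d_ids))
    pairs = list(zip(a_perm[:n_pairs], d_perm[:n_pairs]))
    a_unique = set(a_perm[n_pairs: n_pairs + n_a_unique])
    d_unique = set(d_perm[n_pairs: n_pairs + n_d_unique])
    a_other = set(a_perm[n_pairs + n_a_unique:])
    d_other = set(d_perm[n_pairs + n_d_unique:])

    # --- similarity tables (BLAST-tabular-like) ---
    def _e(lo, hi, size=None):
        return 10.0 ** (-rng.uniform(lo, hi, size=size))

    rows_ad, rows_da = [], []
    paired_targets_d = [d for _, d in pairs]
    paired_targets_a = [a for a, _ in pairs]
    for a, d in pairs:
        rows_ad.append((a, d, _e(20, 50), rng.uniform(60, 100), rng.uniform(55, 95)))
        rows_da.append((d, a, _e(20, 50), rng.uniform(60, 100), rng.uniform(55, 95)))
    for g, rows, targets in (
        (a_other, rows_ad, paired_targets_d),
        (d_other, rows_da, paired_targets_a),
    ):
        for q in sorted(g):
            if targets:
                t = targets[int(rng.integers(len(targets)))]
                rows.append((q, t, _e(6, 10), rng.uniform(55, 90), rng.uniform(55, 90)))
    for g, rows, targets in (
        (a_unique, rows_ad, paired_targets_d),
        (d_unique, rows_da, paired_targets_a),
    ):
        for q in sorted(g):
            if targets and rng.random() < 0.7:  # weak sub-threshold hit
                t = targets[int(rng.integers(len(targets)))]
                rows.append((q, t, _e(1, 4), rng.uniform(5, 45), rng.uniform(5, 45)))
    cols = ["query_id", "target_id", "e_value", "coverage", "identity"]
    hits_ad = pd.DataFrame(rows_ad, columns=cols)
    hits_da = pd.DataFrame(rows_da, columns=cols)

    # --- expression means ---
    ids = [g.gene_id for g in genes]
    mu = pd.Series(
        np.exp(rng.normal(config.mean_log_mu, config.mean_log_sigma, len(ids))),
        index=ids,
    )
    for a, d in pairs:  # balanced pairs share the baseline
        mu[d] = mu[a]
    mu[list(a_unique)] = mu[list(a_unique)] * config.a_bias_factor

    # --- condition effects ---
    direction = pd.Series("none", index=ids)
    coupled: set[str] = set()
    if switches is not None and len(switches):
        for row in switches.itertuples(index=False):
            to_open = row.state_to == f"S{OPEN_STATE + 1}" and row.state_from == f"S{EMPTY_STATE + 1}"
            to_closed = row.state_from == f"S{OPEN_STATE + 1}" and row.state_to == f"S{EMPTY_STATE + 1}"
            if (to_open or to_closed) and rng.random() < config.coupling_prob:
                direction[row.gene_id] = "up" if to_open else "down"
                coupled.add(row.gene_id)
    free = [g for g in ids if g not in coupled]
    n_de = max(0, round(config.de_fraction * len(ids)) - len(coupled))
    de_idx = rng.choice(len(free), size=min(n_de, len(free)), replace=False)
    for j, i in enumerate(de_idx):
        direction[free[i]] = "up" if j % 2 == 0 else "down"

    cond1, cond2 = config.conditions
    mu2 = mu.copy()
    mu2[direction == "up"] = mu2[direction == "up"] * config.de_effect
    mu2[direction == "down"] = mu2[direction == "down"] / config.de_effect

    data = {}
    for cond, m in ((cond1, mu), (cond2, mu2)):
        for rep in range(1, config.n_reps + 1):
            data[f"{cond}_rep{rep}"] = _nb_draw(rng, m.values, config.dispersion)
    counts = pd.DataFrame(data, index=ids)

    truth = {
        "pairs": pairs,
        "a_unique": a_unique,
        "d_unique": d_unique,
        "a_other": a_other,
        "d_other": d_other,
        "de_direction": direction,
        "baseline_mu": mu,
    }
    return counts, hits_ad, hits_da, truth


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    layout: GenomeLayout
    genes: list[GeneModel]
    tes: pd.DataFrame
    true_segmentation: dict
    tracks: dict
    switches: pd.DataFrame
    counts: pd.DataFrame
    hits_ad: pd.DataFrame
    hits_da: pd.DataFrame
    truth: dict


def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Run the full generator and bundle inputs + truth."""
    config = config or SimulationConfig()
    layout, genes, tes = simulate_genome(config)
    seg, tracks, switches = simulate_state_tracks(config, layout, genes)
    counts, hits_ad, hits_da, truth = simulate_expression_and_homoeologs(
        config, genes, switches
    )
    return SimulatedStudy(
        config, layout, genes, tes, seg, tracks, switches,
        counts, hits_ad, hits_da, truth,
    )
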