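"""Broad-peak calling against a mock control, replicate consensus,
cross-mark overlap statistics, genome coverage and midpoint annotation.

The caller is a deliberately simple Poisson model: per bin the expected
rate is the depth-scaled control floored at the global ChIP mean, a bin is
enriched when the upper-tail Poisson probability beats ``p_cut`` and the
count/rate ratio beats ``fc_cut``, and enriched bins within ``merge_gap``
bins of each other are merged into one peak. Defaults are the broad-mark
thresholds used throughout (p < 1e-10, fold change > 5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import poisson

from .genome import BinnedTrack, GeneModel, GenomeLayout, Interval


@dataclass(frozen=True)
class Peak:
    interval: Interval
    mark: str
    p_value: float
    fold_change: float

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must be in (0, 1]")
        if self.fold_change < 0:
            raise ValueError("fold_change must be >= 0")


@dataclass(frozen=True)
class PeakAnnotation:
    peak: Peak
    category: str  # genic | TE | intergenic


def scaled_control_rate(chip: BinnedTrack, control: BinnedTrack | None) -> dict[str, np.ndarray]:
    """Expected per-bin rate: control scaled to ChIP depth, floored at the
    global ChIP mean. With no (or empty) control the global mean is used."""
    n_bins = sum(len(v) for v in chip.counts.values())
    global_mean = max(chip.total / n_bins, 1e-9)
    rates = {}
    for chrom, c in chip.counts.items():
        if control is not None and control.total > 0:
            scale = chip.total / control.total
            lam = np.maximum(control.counts[chrom] * scale, global_mean)
        else:
            lam = np.full(len(c), global_mean)
        rates[chrom] = lam
    return rates


def call_broad_peaks(
    chip: BinnedTrack,
    control: BinnedTrack | None,
    p_cut: float = 1e-10,
    fc_cut: float = 5.0,
    merge_gap: int = 1,
) -> list[Peak]:
    """Call enriched-bin runs as broad peaks.

    ``merge_gap`` is the maximum number of consecutive non-enriched bins
    bridged when merging enriched bins into one peak (0 = only adjacent).
    """
    if control is not None and not chip.same_layout_as(control):
        raise ValueError("chip and control layouts differ")
    rates = scaled_control_rate(chip, control)
    bw = chip.bin_width
    peaks: list[Peak] = []
    for chrom, counts in chip.counts.items():
        lam = rates[chrom]
        pvals = poisson.sf(counts - 1, lam)  # P(X >= c)
        ratio = counts / lam
        enriched = (pvals < p_cut) & (ratio > fc_cut)
        idx = np.flatnonzero(enriched)
        if idx.size == 0:
            continue
        run_start = idx[0]
        prev = idx[0]
        runs = []
        for i in idx[1:]:
            if i - prev - 1 > merge_gap:
                runs.append((run_start, prev))
                run_start = i
            prev = i
        runs.append((run_start, prev))
        for a, b in runs:
            sl = slice(a, b + 1)
            peaks.append(
                Peak(
                    Interval(chrom, a * bw, (b + 1) * bw),
                    chip.mark,
                    float(max(pvals[sl].min(), np.nextafter(0, 1))),
                    float(ratio[sl].max()),
                )
            )
    return peaks


def consensus_peaks(rep1: Sequence[Peak], rep2: Sequence[Peak]) -> list[Peak]:
    """Peaks of rep1 that overlap (>= 1 bp) a rep2 peak, with the interval
    widened to the union span of the rep1 peak and all overlapping rep2
    peaks. The p-value/fold-change of the rep1 peak are retained."""
    trees: dict[str, IntervalTree] = {}
    for p in rep2:
        trees.setdefault(p.interval.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.end, p
        )
    out = []
    for p in rep1:
        tree = trees.get(p.interval.chrom)
        if tree is None:
            continue
        hits = tree.overlap(p.interval.start, p.interval.end)
        if not hits:
            continue
        start = min(p.interval.start, min(h.begin for h in hits))
        end = max(p.interval.end, max(h.end for h in hits))
        out.append(
            Peak(Interval(p.interval.chrom, start, end), p.mark, p.p_value, p.fold_change)
        )
    return out


def _merged(intervals: Iterable[Interval]) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        out = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = [(s, e) for s, e in out]
    return merged


def peak_overlap_fraction(peaks_a: Sequence[Peak], peaks_b: Sequence[Peak]) -> float:
    """Fraction of A peaks whose bases are covered >= 50% by B peaks."""
    if not peaks_a:
        raise ValueError("peaks_a is empty: overlap fraction undefined")
    merged_b = _merged(p.interval for p in peaks_b)
    n_hit = 0
    for p in peaks_a:
        covered = 0
        for s, e in merged_b.get(p.interval.chrom, []):
            covered += max(0, min(e, p.interval.end) - max(s, p.interval.start))
        if 2 * covered >= p.interval.length:  # at least 50%, boundary inclusive
            n_hit += 1
    return n_hit / len(peaks_a)


def genome_coverage(
    peak_sets: dict[str, Sequence[Peak]], layout: GenomeLayout
) -> dict[str, dict[str, float]]:
    """Bases and genome fraction covered per peak set plus their union."""
    total = layout.total_length
    result = {}
    all_ivs: list[Interval] = []
    for name, peaks in peak_sets.items():
        ivs = [p.interval for p in peaks]
        all_ivs.extend(ivs)
        bases = sum(e - s for spans in _merged(ivs).values() for s, e in spans)
        result[name] = {"bases": bases, "fraction": bases / total}
    union_bases = sum(e - s for spans in _merged(all_ivs).values() for s, e in spans)
    result["union"] = {"bases": union_bases, "fraction": union_bases / total}
    return result


def annotate_by_midpoint(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    tes: Sequence[Interval],
) -> list[PeakAnnotation]:
    """Category by peak midpoint: gene body > TE > intergenic."""
    gene_trees: dict[str, IntervalTree] = {}
    for g in genes:
        gene_trees.setdefault(g.body.chrom, IntervalTree()).addi(
            g.body.start, g.body.end
        )
    te_trees: dict[str, IntervalTree] = {}
    for t in tes:
        te_trees.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end)
    out = []
    for p in peaks:
        mid = p.interval.midpoint
        chrom = p.interval.chrom
        if chrom in gene_trees and gene_trees[chrom].at(mid):
            cat = "genic"
        elif chrom in te_trees and te_trees[chrom].at(mid):
            cat = "TE"
        else:
            cat = "intergenic"
        out.append(PeakAnnotation(p, cat))
    return out


def write_peaks_bed(peaks: Sequence[Peak], path) -> None:
    """BED6+2 with p_value and fold_change extra columns."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                f"\t{p.mark}_peak{i + 1}\t0\t.\t{p.p_value:.6g}\t{p.fold_change:.4f}\n"
            )


def read_peaks_bed(path, mark: str = "") -> list[Peak]:
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                Peak(Interval(f[0], int(f[1]), int(f[2])), mark or f[3].rsplit("_", 1)[0],
                     float(f[6]), float(f[7]))
            )
    return out
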