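"""Chromatin-state composition of genomic elements and TE classes.

The genome is partitioned at base resolution into promoter / exon /
intron / intergenic (promoter = the 500 bases immediately upstream of each
TSS, strand-aware, clamped at chromosome ends; base-level precedence
promoter > exon > intron > intergenic). State-by-element and state-by-TE
composition tables are descriptive proportions with an explicit Background
row, exactly as presented in a state-composition heatmap.

Base-resolution label arrays are used throughout; this is intended for
the desk-scale genomes the synthetic generator produces (a few Mb).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomeLayout
from .hmm import Segmentation

ELEMENT_LABELS = ("intergenic", "intron", "exon", "promoter")
TE_CLASSES = ("Gypsy", "Copia", "hAT", "Helitron", "CACTA", "other_retro", "other_dna")


@dataclass
class ElementMap:
    """Per-base element labels (codes index into ELEMENT_LABELS)."""

    labels: dict[str, np.ndarray]

    def element_bases(self) -> pd.Series:
        counts = np.zeros(len(ELEMENT_LABELS), dtype=np.int64)
        for arr in self.labels.values():
            counts += np.bincount(arr, minlength=len(ELEMENT_LABELS))
        return pd.Series(counts, index=list(ELEMENT_LABELS))

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, arr in self.labels.items():
                boundaries = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate([[0], boundaries])
                ends = np.concatenate([boundaries, [len(arr)]])
                for a, b in zip(starts, ends):
                    fh.write(f"{chrom}\t{a}\t{b}\t{ELEMENT_LABELS[arr[a]]}\n")


def build_element_map(
    genes: Sequence[GeneModel], layout: GenomeLayout, promoter_length: int = 500
) -> ElementMap:
    """Partition each chromosome into promoter/exon/intron/intergenic.

    Painting order is intron, then exon, then promoter (rising precedence);
    within one precedence level genes are painted in reverse coordinate
    order so the first gene by sorted coordinate wins on overlaps.
    """
    labels = {
        c: np.zeros(layout.lengths[c], dtype=np.uint8) for c in layout.names
    }
    order = sorted(genes, key=lambda g: (g.body.chrom, g.body.start), reverse=True)
    code = {name: i for i, name in enumerate(ELEMENT_LABELS)}
    for g in order:
        layout.validate_interval(g.body)
        labels[g.body.chrom][g.body.start: g.body.end] = code["intron"]
    for g in order:
        for e in g.exons:
            labels[e.chrom][e.start: e.end] = code["exon"]
    for g in order:
        p = g.promoter(promoter_length)
        end = min(p.end, layout.lengths[p.chrom])
        if p.start < end:
            labels[p.chrom][p.start: end] = code["promoter"]
    return ElementMap(labels)


def _state_bases_per_base_labels(
    seg: Segmentation, layout: GenomeLayout, chrom: str
) -> np.ndarray:
    """Expand per-bin states into a per-base state array."""
    s = seg.states[chrom]
    reps = layout.bin_sizes(chrom, seg.bin_width)
    return np.repeat(s, reps)


def _with_views(counts: pd.DataFrame, background: pd.Series) -> dict[str, pd.DataFrame]:
    row_norm = counts.div(counts.sum(axis=1), axis=0)
    col_norm = counts.div(counts.sum(axis=0), axis=1)
    bg = background / background.sum()
    row_norm.loc["Background"] = bg
    return {"counts": counts, "by_state": row_norm, "by_element": col_norm}


def state_by_element(
    seg: Segmentation, elements: ElementMap, layout: GenomeLayout
) -> dict[str, pd.DataFrame]:
    """Base-count matrix state x element plus row- and column-normalized
    views; the Background row is the element composition of the genome."""
    n_states = seg.n_states
    n_elem = len(ELEMENT_LABELS)
    counts = np.zeros((n_states, n_elem), dtype=np.int64)
    for chrom in seg.states:
        state_base = _state_bases_per_base_labels(seg, layout, chrom)
        elem_base = elements.labels[chrom]
        combined = state_base.astype(np.int64) * n_elem + elem_base
        flat = np.bincount(combined, minlength=n_states * n_elem)
        counts += flat.reshape(n_states, n_elem)
    df = pd.DataFrame(
        counts,
        index=[f"S{k + 1}" for k in range(n_states)],
        columns=list(ELEMENT_LABELS),
    )
    return _with_views(df, elements.element_bases())


def state_by_te(
    seg: Segmentation,
    tes: pd.DataFrame,
    layout: GenomeLayout,
) -> dict[str, pd.DataFrame]:
    """TE-count (midpoint rule) and base-count (apportioned) matrices
    state x TE-class, with normalized views and Background columns.

    ``tes`` needs columns chrom/start/end/te_class.
    """
    n_states = seg.n_states
    classes = list(TE_CLASSES)
    extra = [c for c in tes.get("te_class", pd.Series(dtype=str)).unique() if c not in classes]
    classes = classes + sorted(extra)
    cls_idx = {c: i for i, c in enumerate(classes)}
    count_mat = np.zeros((n_states, len(classes)), dtype=np.int64)
    base_mat = np.zeros((n_states, len(classes)), dtype=np.int64)
    per_base = {
        chrom: _state_bases_per_base_labels(seg, layout, chrom) for chrom in seg.states
    }
    for row in tes.itertuples(index=False):
        chrom, start, end = row.chrom, int(row.start), int(row.end)
        j = cls_idx[row.te_class]
        states = per_base[chrom][start:end]
        mid_state = per_base[chrom][(start + end) // 2]
        count_mat[mid_state, j] += 1
        base_mat[:, j] += np.bincount(states, minlength=n_states)
    index = [f"S{k + 1}" for k in range(n_states)]
    counts = pd.DataFrame(count_mat, index=index, columns=classes)
    bases = pd.DataFrame(base_mat, index=index, columns=classes)
    te_background = counts.sum(axis=0)
    out = {
        "te_counts": counts,
        "te_bases": bases,
        "by_state": counts.div(counts.sum(axis=1).replace(0, np.nan), axis=0),
        "by_class": counts.div(counts.sum(axis=0).replace(0, np.nan), axis=1),
    }
    if te_background.sum() > 0:
        out["by_state"].loc["Background"] = te_background / te_background.sum()
    return out
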