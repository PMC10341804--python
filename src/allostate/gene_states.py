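"""Promoter-based gene-state assignment, the cross-condition transition
ledger, and transition x differential-expression enrichment.

A gene carries the chromatin state that covers the most bases of its
promoter (the 500 bp upstream of the TSS); when two states tie, the state
at the promoter's 5'-most base wins. Genes assigned in two conditions form
a transition ledger; Fisher's exact test asks whether transition genes (or
a specific from->to group) are enriched for differentially expressed genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .genome import GeneModel, GenomeLayout
from .hmm import Segmentation

logger = logging.getLogger(__name__)

UNSEGMENTED = "unsegmented"


@dataclass(frozen=True)
class EnrichmentResult:
    """A 2x2 enrichment outcome: label, counts, odds ratio, two-sided
    Fisher exact p, and the background fraction for context."""

    label: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    background_fraction: float


def fisher_enrichment(label: str, table, background_fraction: float) -> EnrichmentResult:
    odds, p = fisher_exact(np.asarray(table), alternative="two-sided")
    return EnrichmentResult(label, tuple(map(tuple, table)), float(odds), float(p),
                            background_fraction)


def assign_gene_state(
    gene: GeneModel,
    seg: Segmentation,
    layout: GenomeLayout,
    promoter_length: int = 500,
) -> str:
    """State covering the most promoter bases; tie -> state at the
    promoter's 5'-most base (nearest the chromosome start on '+',
    nearest the chromosome end on '-')."""
    p = gene.promoter(promoter_length)
    start = max(0, p.start)
    end = min(p.end, layout.lengths[p.chrom])
    if start >= end:
        return UNSEGMENTED
    per_base = np.repeat(
        seg.states[p.chrom], layout.bin_sizes(p.chrom, seg.bin_width)
    )[start:end]
    counts = np.bincount(per_base, minlength=seg.n_states)
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    if len(tied) == 1:
        k = tied[0]
    else:
        # 5'-most base of the promoter in gene orientation
        anchor = per_base[0] if gene.body.strand == "+" else per_base[-1]
        k = anchor if anchor in tied else tied[0]
    return f"S{k + 1}"


def assign_gene_states(
    genes: Sequence[GeneModel],
    seg: Segmentation,
    layout: GenomeLayout,
    condition: str = "",
    promoter_length: int = 500,
) -> pd.DataFrame:
    rows = [
        {
            "gene_id": g.gene_id,
            "condition": condition,
            "state": assign_gene_state(g, seg, layout, promoter_length),
        }
        for g in genes
    ]
    return pd.DataFrame(rows)


def build_transition_ledger(
    assign_a: pd.DataFrame, assign_b: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair per-gene states across two conditions.

    Returns the ledger (gene_id, state_from, state_to, is_transition) and
    the K x K transition count matrix. Genes present in only one condition
    are excluded and logged.
    """
    a = assign_a.set_index("gene_id")["state"]
    b = assign_b.set_index("gene_id")["state"]
    shared = a.index.intersection(b.index)
    dropped = len(a.index.symmetric_difference(b.index))
    if dropped:
        logger.info("build_transition_ledger: %d genes missing in one condition", dropped)
    ledger = pd.DataFrame(
        {
            "gene_id": shared,
            "state_from": a.loc[shared].values,
            "state_to": b.loc[shared].values,
        }
    )
    ledger["is_transition"] = ledger["state_from"] != ledger["state_to"]
    states = sorted(set(ledger["state_from"]) | set(ledger["state_to"]))
    matrix = (
        pd.crosstab(ledger["state_from"], ledger["state_to"])
        .reindex(index=states, columns=states, fill_value=0)
    )
    return ledger, matrix


def transition_fraction(ledger: pd.DataFrame) -> float:
    """Fraction of assignable genes whose promoter state changed."""
    assigned = ledger[
        (ledger["state_from"] != UNSEGMENTED) & (ledger["state_to"] != UNSEGMENTED)
    ]
    return float(assigned["is_transition"].mean())


def transition_deg_enrichment(
    ledger: pd.DataFrame,
    deg: pd.DataFrame,
    direction: str = "any",
    min_group: int = 1,
) -> list[EnrichmentResult]:
    """Fisher enrichment of DEGs among transition genes.

    The first result ("overall") tests {transition, no-transition} x
    {DEG, non-DEG}; one result per from->to transition group follows,
    testing {in-group, not-in-group} x {direction-DEG, not}.

    ``deg`` needs columns gene_id and call (up/down/ns); ``direction``
    restricts which calls count as DEG (any/up/down).
    """
    if direction not in ("any", "up", "down"):
        raise ValueError("direction must be any/up/down")
    calls = deg.set_index("gene_id")["call"]
    led = ledger[ledger["gene_id"].isin(calls.index)].copy()
    led["call"] = calls.loc[led["gene_id"]].values
    is_deg = (
        led["call"].isin(("up", "down")) if direction == "any"
        else led["call"] == direction
    )
    results = []
    trans = led["is_transition"].values
    table = [
        [int((trans & is_deg).sum()), int((trans & ~is_deg).sum())],
        [int((~trans & is_deg).sum()), int((~trans & ~is_deg).sum())],
    ]
    results.append(fisher_enrichment(f"overall x {direction}", table, float(is_deg.mean())))
    groups = led[led["is_transition"]].groupby(["state_from", "state_to"])
    for (sf, st), sub in groups:
        if len(sub) < min_group:
            logger.info("skipping empty/small group %s-%s", sf, st)
            continue
        in_group = led.index.isin(sub.index)
        table = [
            [int((in_group & is_deg).sum()), int((in_group & ~is_deg).sum())],
            [int((~in_group & is_deg).sum()), int((~in_group & ~is_deg).sum())],
        ]
        results.append(
            fisher_enrichment(f"{sf}-{st} x {direction}", table, float(is_deg.mean()))
        )
    return results
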