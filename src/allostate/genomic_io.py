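"""Coverage binning, normalization, replicate QC, metagene profiles and
readers/writers for the plain-text formats the pipeline speaks
(BED, GFF3, bedGraph, fragment TSV).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import BinnedTrack, GeneModel, GenomeLayout, Interval

# ---------------------------------------------------------------------------
# binning and normalization
# ---------------------------------------------------------------------------


def bin_fragments(
    fragments: Iterable[Interval],
    layout: GenomeLayout,
    bin_width: int,
    *,
    mark: str = "",
    condition: str = "",
    replicate: int = 1,
) -> BinnedTrack:
    """Assign each fragment to the bin containing its midpoint.

    Every fragment increments exactly one bin, so the total count equals the
    number of fragments. Fragments outside the layout are rejected.
    """
    counts = {
        c: np.zeros(layout.n_bins(c, bin_width), dtype=np.int64) for c in layout.names
    }
    for frag in fragments:
        layout.validate_interval(frag)
        counts[frag.chrom][frag.midpoint // bin_width] += 1
    return BinnedTrack(mark, condition, replicate, bin_width, counts)


def rpkm_normalize(track: BinnedTrack, total_fragments: int) -> dict[str, np.ndarray]:
    """Reads-per-kilobase-per-million scaling of per-bin counts.

    value = count * 1e9 / (total_fragments * bin_width). The nominal
    bin_width is used even for a partial last bin.
    """
    if total_fragments <= 0:
        raise ValueError("total_fragments must be positive")
    scale = 1e9 / (total_fragments * track.bin_width)
    return {c: v.astype(float) * scale for c, v in track.counts.items()}


def replicate_correlation(a: BinnedTrack, b: BinnedTrack) -> float:
    """Pearson r between two tracks over all bins.

    Raises ``ValueError`` when either track has zero variance (r undefined).
    """
    if not a.same_layout_as(b):
        raise ValueError("tracks have different layouts")
    order = sorted(a.counts)
    x = a.stacked(order).astype(float)
    y = b.stacked(order).astype(float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance track: Pearson r undefined")
    return float(np.corrcoef(x, y)[0, 1])


def metagene_profile(
    signal: dict[str, np.ndarray],
    anchors: Sequence[GeneModel],
    layout: GenomeLayout,
    bin_width: int,
    flank: int = 2000,
    n_points: int | None = None,
) -> np.ndarray:
    """Strand-aware mean signal profile around TSSs.

    The window spans ``[TSS - flank, TSS + flank)`` in gene orientation,
    sampled once per bin (``n_points`` defaults to ``2*flank//bin_width``).
    Minus-strand windows are reversed before averaging. Positions that fall
    off a chromosome end are excluded from the mean at that offset; an
    offset with no contributing gene is NaN.
    """
    if not anchors:
        raise ValueError("anchors must be non-empty")
    if n_points is None:
        n_points = max(1, (2 * flank) // bin_width)
    offsets = np.linspace(-flank, flank, n_points, endpoint=False)
    total = np.zeros(n_points)
    n_obs = np.zeros(n_points)
    for g in anchors:
        vec = signal[g.body.chrom]
        tss = g.tss
        if g.body.strand == "+":
            pos = tss + offsets
        else:
            pos = tss - offsets
        bins = np.floor(pos / bin_width).astype(int)
        ok = (pos >= 0) & (pos < layout.lengths[g.body.chrom]) & (bins < len(vec))
        total[ok] += vec[bins[ok]]
        n_obs[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_obs > 0, total / n_obs, np.nan)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """Read BED3/6(+) into a DataFrame with canonical column names."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    df.columns = _BED_COLS[:ncol] + [f"extra{i}" for i in range(max(0, ncol - 6))]
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def intervals_from_bed(df: pd.DataFrame) -> list[Interval]:
    strand = df["strand"] if "strand" in df.columns else ["."] * len(df)
    return [
        Interval(c, int(s), int(e), st)
        for c, s, e, st in zip(df["chrom"], df["start"], df["end"], strand)
    ]


def read_fragments_tsv(path) -> list[Interval]:
    """Read a chrom/start/end fragment list (TSV, no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end"])
    return [Interval(c, int(s), int(e)) for c, s, e in df.itertuples(index=False)]


def _gff3_attr(attrs: str, key: str) -> str | None:
    for field in attrs.strip().split(";"):
        if "=" in field:
            k, v = field.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


def read_gff3_genes(path) -> list[GeneModel]:
    """Read gene/exon features from GFF3 (1-based inclusive -> half-open).

    Recognised attributes: ``ID`` on genes, ``Parent`` on exons,
    ``subgenome`` and ``is_new`` as optional gene attributes.
    """
    genes: dict[str, GeneModel] = {}
    exons: dict[str, list[Interval]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, _, ftype, start, end, _, strand, _, attrs = f[:9]
            iv = Interval(chrom, int(start) - 1, int(end), strand)
            if ftype == "gene":
                gid = _gff3_attr(attrs, "ID") or f"gene_{len(genes)}"
                genes[gid] = GeneModel(
                    gid,
                    iv,
                    [],
                    subgenome=_gff3_attr(attrs, "subgenome") or "A",
                    is_new_gene=(_gff3_attr(attrs, "is_new") == "1"),
                )
            elif ftype == "exon":
                parent = _gff3_attr(attrs, "Parent")
                if parent is not None:
                    exons.setdefault(parent, []).append(iv)
    out = []
    for gid, g in genes.items():
        out.append(
            GeneModel(gid, g.body, exons.get(gid, [g.body]), g.subgenome, g.is_new_gene)
        )
    return out


def write_gff3_genes(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};subgenome={g.subgenome};is_new={int(g.is_new_gene)}"
            fh.write(
                f"{g.body.chrom}\tallostate\tgene\t{g.body.start + 1}\t{g.body.end}"
                f"\t.\t{g.body.strand}\t.\t{attrs}\n"
            )
            for e in g.exons:
                fh.write(
                    f"{e.chrom}\tallostate\texon\t{e.start + 1}\t{e.end}"
                    f"\t.\t{g.body.strand}\t.\tParent={g.gene_id}\n"
                )


def write_bedgraph(track: BinnedTrack, layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for chrom in layout.names:
            v = track.counts[chrom]
            bw = track.bin_width
            for i, val in enumerate(v):
                end = min((i + 1) * bw, layout.lengths[chrom])
                fh.write(f"{chrom}\t{i * bw}\t{end}\t{val}\n")


def read_bedgraph(path, layout: GenomeLayout, bin_width: int, **meta) -> BinnedTrack:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    counts = {
        c: np.zeros(layout.n_bins(c, bin_width), dtype=np.int64) for c in layout.names
    }
    for chrom, start, _, value in df.itertuples(index=False):
        counts[chrom][int(start) // bin_width] = value
    return BinnedTrack(
        meta.get("mark", ""), meta.get("condition", ""), meta.get("replicate", 1),
        bin_width, counts,
    )


def write_layout(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for c in layout.names:
            fh.write(f"{c}\t{layout.lengths[c]}\t{layout.subgenome[c]}\n")


def read_layout(path) -> GenomeLayout:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length", "subgenome"])
    return GenomeLayout.from_records(
        [(c, int(l), s) for c, l, s in df.itertuples(index=False)]
    )
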