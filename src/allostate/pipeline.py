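"""End-to-end orchestration: study parameters, the in-memory analysis
chain over a synthetic study, and file-based stage running with manifests.

`PipelineConfig` collects every analysis threshold with the defaults used
throughout (200-bp bins, binarization p 1e-4, K=6 states, peak p 1e-10 /
fold change 5, promoter 500 bp, DE FDR 0.05 with |log2FC| > 1, RBH cuts
1e-5/50%/50%, k=5 gene clusters), so the zero-edit configuration is the
reference analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import bias as bias_mod
from . import de as de_mod
from . import gene_states as gs_mod
from . import peaks as peaks_mod
from .elements import build_element_map, state_by_element, state_by_te
from .genome import HISTONE_MARKS, MARKS, GeneModel, Interval
from .genomic_io import rpkm_normalize
from .hmm import (
    BernoulliHMM,
    BinaryMatrix,
    Segmentation,
    decode,
    match_states,
    pool_tracks,
    relabel_states,
    state_coverage,
)
from .simulate import SimulatedStudy, SimulationConfig, simulate_study

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Analysis thresholds; defaults are the reference values."""

    bin_width: int = 200
    binarization_p: float = 1e-4
    n_states: int = 6
    n_restarts: int = 10
    peak_p: float = 1e-10
    peak_fc: float = 5.0
    peak_merge_gap: int = 1
    promoter_length: int = 500
    de_alpha: float = 0.05
    lfc_threshold: float = 1.0
    rbh_e: float = 1e-5
    rbh_cov: float = 50.0
    rbh_id: float = 50.0
    k_clusters: int = 5
    seed: int = 0

    def validate(self) -> None:
        for name in ("bin_width", "binarization_p", "n_states", "peak_p",
                     "peak_fc", "promoter_length", "de_alpha", "rbh_e"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)


def permute_model_states(model: BernoulliHMM, mapping: np.ndarray) -> BernoulliHMM:
    """Return a copy of ``model`` with state k renamed to ``mapping[k]``."""
    order = np.empty_like(mapping)
    order[mapping] = np.arange(len(mapping))  # order[new] = old
    out = BernoulliHMM(**model.get_params())
    out.emissionprob_ = model.emissionprob_[order]
    out.transmat_ = model.transmat_[np.ix_(order, order)]
    out.startprob_ = model.startprob_[order]
    out.loglik_ = getattr(model, "loglik_", np.nan)
    return out


def permute_segmentation(seg: Segmentation, mapping: np.ndarray) -> Segmentation:
    return Segmentation(
        {c: mapping[s] for c, s in seg.states.items()}, seg.n_states, seg.bin_width
    )


def analyze_study(
    study: SimulatedStudy, params: PipelineConfig | None = None
) -> dict:
    """Run the full analysis chain on a synthetic study.

    The HMM is trained on condition-1 binarized tracks and decode-only
    applied to condition 2 so state identities match across conditions;
    learned states are then mapped onto the planted state labels by
    minimal total-variation distance between emission rows, so reported
    states S1..S6 carry the planted semantics.
    """
    params = params or PipelineConfig()
    params.validate()
    cond1, cond2 = study.config.conditions
    layout, genes = study.layout, study.genes
    results: dict = {}

    # ---- peaks (condition 1) --------------------------------------------
    mock1 = pool_tracks([study.tracks[(cond1, "Mock", r)]
                         for r in range(1, study.config.n_reps + 1)])
    te_intervals = [
        Interval(r.chrom, int(r.start), int(r.end))
        for r in study.tes.itertuples(index=False)
    ]
    consensus: dict[str, list] = {}
    for mark in HISTONE_MARKS:
        reps = [
            peaks_mod.call_broad_peaks(
                study.tracks[(cond1, mark, r)], mock1,
                p_cut=params.peak_p, fc_cut=params.peak_fc,
                merge_gap=params.peak_merge_gap,
            )
            for r in range(1, study.config.n_reps + 1)
        ]
        consensus[mark] = peaks_mod.consensus_peaks(reps[0], reps[1])
    results["peaks"] = consensus
    results["peak_coverage"] = peaks_mod.genome_coverage(consensus, layout)
    results["peak_annotation"] = {
        mark: peaks_mod.annotate_by_midpoint(p, genes, te_intervals)
        for mark, p in consensus.items()
    }

    # ---- binarize + HMM --------------------------------------------------
    binmats = {}
    for cond in (cond1, cond2):
        mock = pool_tracks([study.tracks[(cond, "Mock", r)]
                            for r in range(1, study.config.n_reps + 1)])
        chip = {
            mark: pool_tracks([study.tracks[(cond, mark, r)]
                               for r in range(1, study.config.n_reps + 1)])
            for mark in MARKS
        }
        binmats[cond] = BinaryMatrix.from_tracks(chip, mock, params.binarization_p)
    X, lengths, _ = binmats[cond1].stacked()
    model = BernoulliHMM(
        n_states=params.n_states, n_restarts=params.n_restarts,
        random_state=params.seed,
    ).fit(X, lengths)
    seg1 = decode(model, binmats[cond1])
    seg2 = decode(model, binmats[cond2])
    # map learned states onto planted labels for reporting
    mapping = match_states(np.asarray(study.config.emission), model.emissionprob_)
    model_mapped = permute_model_states(model, mapping)
    seg1 = permute_segmentation(seg1, mapping)
    seg2 = permute_segmentation(seg2, mapping)
    results["model"] = model_mapped
    results["state_mapping"] = mapping
    results["binary"] = binmats
    results["segmentation"] = {cond1: seg1, cond2: seg2}
    results["state_coverage"] = state_coverage(seg1, layout)
    results["state_coverage_subgenome"] = state_coverage(seg1, layout, by_subgenome=True)

    # ---- elements / TEs --------------------------------------------------
    elements = build_element_map(genes, layout, params.promoter_length)
    results["element_map"] = elements
    results["state_by_element"] = state_by_element(seg1, elements, layout)
    results["state_by_te"] = state_by_te(seg1, study.tes, layout)

    # ---- gene states and transitions ------------------------------------
    assign1 = gs_mod.assign_gene_states(genes, seg1, layout, cond1,
                                        params.promoter_length)
    assign2 = gs_mod.assign_gene_states(genes, seg2, layout, cond2,
                                        params.promoter_length)
    ledger, matrix = gs_mod.build_transition_ledger(assign1, assign2)
    results["assignments"] = {cond1: assign1, cond2: assign2}
    results["ledger"] = ledger
    results["transition_matrix"] = matrix
    results["transition_fraction"] = gs_mod.transition_fraction(ledger)

    # ---- differential expression ----------------------------------------
    samples = list(study.counts.columns)
    conditions = [s.rsplit("_rep", 1)[0] for s in samples]
    deg = de_mod.nb_de_test(
        study.counts, conditions, cond_ref=cond1, cond_alt=cond2,
        alpha=params.de_alpha, lfc_threshold=params.lfc_threshold,
    )
    results["deg"] = deg
    results["enrichment"] = {
        d: gs_mod.transition_deg_enrichment(ledger, deg, direction=d)
        for d in ("any", "up", "down")
    }

    # ---- homoeologs and subgenome bias -----------------------------------
    a_ids = [g.gene_id for g in genes if g.subgenome == "A"]
    d_ids = [g.gene_id for g in genes if g.subgenome == "D"]
    homoeologs = bias_mod.reciprocal_best_hits(
        study.hits_ad, study.hits_da, a_ids, d_ids,
        e_cut=params.rbh_e, cov_cut=params.rbh_cov, id_cut=params.rbh_id,
    )
    rep_samples = [s for s in samples if s.startswith(cond1)]
    homoeologs = bias_mod.categorize_bias(
        homoeologs, study.counts, rep_samples, rep_samples,
        alpha=params.de_alpha, lfc_threshold=params.lfc_threshold,
    )
    results["homoeologs"] = homoeologs
    results["bias_summary"] = bias_mod.bias_summary(homoeologs)

    lengths_by_gene = {g.gene_id: g.exonic_length for g in genes}
    expr = de_mod.fpkm(study.counts[rep_samples], lengths_by_gene).mean(axis=1)
    results["expression"] = expr
    groups = {
        "A_unique": sorted(homoeologs.a_unique),
        "D_unique": sorted(homoeologs.d_unique),
        "A_paired": [a for a, _ in homoeologs.pairs],
        "D_paired": [d for _, d in homoeologs.pairs],
    }
    expr_df = expr.to_frame("expression")
    results["expression_compare"] = bias_mod.mark_level_compare(expr_df, groups)

    # ---- gene histone signal, clustering, new genes ----------------------
    signal = gene_signal_matrix(study.tracks, genes, cond1, study.config.n_reps)
    results["gene_signal"] = signal
    peak_trees = {}
    for mark, plist in consensus.items():
        for p in plist:
            peak_trees.setdefault(p.interval.chrom, []).append(
                (p.interval.start, p.interval.end)
            )
    with_peak = []
    for g in genes:
        spans = peak_trees.get(g.body.chrom, [])
        if any(s < g.body.end and g.body.start < e for s, e in spans):
            with_peak.append(g.gene_id)
    cluster_input = signal.loc[signal.index.intersection(with_peak)]
    if len(cluster_input) >= params.k_clusters:
        labels, cluster_means = bias_mod.kmeans_gene_clusters(
            cluster_input, k=params.k_clusters, seed=params.seed
        )
        results["clusters"] = labels
        results["cluster_means"] = cluster_means
        new_genes = {g.gene_id for g in genes if g.is_new_gene}
        new_in = new_genes & set(labels.index)
        if new_in:
            results["newgene_enrichment"] = bias_mod.newgene_cluster_enrichment(
                labels, new_in, total_genes=len(labels)
            )
    results["mark_compare"] = bias_mod.mark_level_compare(
        signal, {"A_genes": a_ids, "D_genes": d_ids}
    )
    return results


def gene_signal_matrix(
    tracks: dict, genes: list[GeneModel], condition: str, n_reps: int = 2
) -> pd.DataFrame:
    """Mean RPKM per gene body per histone mark (replicates pooled)."""
    rows = {}
    for mark in HISTONE_MARKS:
        pooled = pool_tracks([tracks[(condition, mark, r)]
                              for r in range(1, n_reps + 1)])
        normed = rpkm_normalize(pooled, pooled.total)
        bw = pooled.bin_width
        vals = {}
        for g in genes:
            b0 = g.body.start // bw
            b1 = (g.body.end + bw - 1) // bw
            vals[g.gene_id] = float(np.mean(normed[g.body.chrom][b0:b1]))
        rows[mark] = vals
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file-based stages
# ---------------------------------------------------------------------------

STAGES = (
    "simulate", "binarize", "learn", "segment", "annotate", "assign",
    "transitions", "bias", "cluster", "de", "report",
)


def _checksum(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir, stage, config, inputs, outputs) -> None:
    manifest = {
        "stage": stage,
        "config": dataclasses.asdict(config),
        "inputs": {os.path.basename(p): _checksum(p) for p in inputs},
        "outputs": [os.path.basename(p) for p in outputs],
    }
    with open(os.path.join(outdir, f"manifest_{stage}.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)


def _require(*paths) -> None:
    for p in paths:
        if not os.path.exists(p):
            raise FileNotFoundError(f"missing stage input: {p}")


def run_stage(
    name: str,
    config: PipelineConfig,
    outdir: str,
    sim_config: SimulationConfig | None = None,
) -> list[str]:
    """Run one pipeline stage against files under ``outdir``.

    Stages read the outputs of earlier stages from ``outdir`` and write
    their own outputs plus a manifest there. Returns the output paths.
    """
    from . import genomic_io as gio

    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; stages are {STAGES}")
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    j = lambda *p: os.path.join(outdir, *p)

    if name == "simulate":
        sim = sim_config or SimulationConfig(seed=config.seed)
        study = simulate_study(sim)
        outputs = []
        gio.write_layout(study.layout, j("layout.tsv"))
        gio.write_gff3_genes(study.genes, j("genes.gff3"))
        study.tes.to_csv(j("tes.tsv"), sep="\t", index=False)
        study.counts.to_csv(j("counts.tsv"), sep="\t")
        study.hits_ad.to_csv(j("hits_ad.tsv"), sep="\t", index=False)
        study.hits_da.to_csv(j("hits_da.tsv"), sep="\t", index=False)
        outputs += [j("layout.tsv"), j("genes.gff3"), j("tes.tsv"),
                    j("counts.tsv"), j("hits_ad.tsv"), j("hits_da.tsv")]
        for (cond, mark, rep), track in study.tracks.items():
            path = j(f"track_{cond}_{mark}_rep{rep}.bedgraph")
            gio.write_bedgraph(track, study.layout, path)
            outputs.append(path)
        os.makedirs(j("truth"), exist_ok=True)
        study.switches.to_csv(j("truth", "switches.tsv"), sep="\t", index=False)
        pd.DataFrame(study.truth["pairs"], columns=["a_gene", "d_gene"]).to_csv(
            j("truth", "pairs.tsv"), sep="\t", index=False)
        pd.Series(sorted(study.truth["a_unique"])).to_csv(
            j("truth", "a_unique.tsv"), sep="\t", index=False, header=False)
        pd.Series(sorted(study.truth["d_unique"])).to_csv(
            j("truth", "d_unique.tsv"), sep="\t", index=False, header=False)
        study.truth["de_direction"].to_csv(j("truth", "de_direction.tsv"), sep="\t",
                                           header=False)
        for cond, seg in study.true_segmentation.items():
            seg.to_bed(study.layout, j("truth", f"segmentation_{cond}.bed"))
        _write_manifest(outdir, name, config, [], outputs)
        return outputs

    _require(j("layout.tsv"))
    layout = gio.read_layout(j("layout.tsv"))
    conds = _discover_conditions(outdir)

    if name == "binarize":
        outputs = []
        for cond in conds:
            tracks = {}
            for mark in list(MARKS) + ["Mock"]:
                reps = []
                rep = 1
                while os.path.exists(j(f"track_{cond}_{mark}_rep{rep}.bedgraph")):
                    reps.append(gio.read_bedgraph(
                        j(f"track_{cond}_{mark}_rep{rep}.bedgraph"), layout,
                        config.bin_width, mark=mark, condition=cond, replicate=rep))
                    rep += 1
                if not reps:
                    raise FileNotFoundError(f"no tracks for {cond}/{mark}")
                tracks[mark] = pool_tracks(reps)
            mock = tracks.pop("Mock")
            bm = BinaryMatrix.from_tracks(tracks, mock, config.binarization_p)
            os.makedirs(j(f"binary_{cond}"), exist_ok=True)
            bm.write(j(f"binary_{cond}"))
            outputs.append(j(f"binary_{cond}"))
        _write_manifest(outdir, name, config, [j("layout.tsv")], [])
        return outputs

    if name == "learn":
        cond1 = conds[0]
        bdir = j(f"binary_{cond1}")
        _require(bdir)
        paths = sorted(
            os.path.join(bdir, f) for f in os.listdir(bdir) if f.endswith("_binary.txt")
        )
        bm = BinaryMatrix.read(paths, config.bin_width)
        X, lengths, _ = bm.stacked()
        model = BernoulliHMM(
            n_states=config.n_states, n_restarts=config.n_restarts,
            random_state=config.seed,
        ).fit(X, lengths)
        model, _, _ = relabel_states(model, None, list(bm.marks), list(bm.marks))
        model.to_json(j("model.json"), marks=bm.marks)
        _write_manifest(outdir, name, config, paths, [j("model.json")])
        return [j("model.json")]

    if name == "segment":
        _require(j("model.json"))
        model = BernoulliHMM.from_json(j("model.json"))
        outputs = []
        for cond in conds:
            bdir = j(f"binary_{cond}")
            _require(bdir)
            paths = sorted(
                os.path.join(bdir, f) for f in os.listdir(bdir)
                if f.endswith("_binary.txt")
            )
            bm = BinaryMatrix.read(paths, config.bin_width)
            seg = decode(model, bm)
            seg.to_bed(layout, j(f"segmentation_{cond}.bed"))
            outputs.append(j(f"segmentation_{cond}.bed"))
        _write_manifest(outdir, name, config, [j("model.json")], outputs)
        return outputs

    if name == "annotate":
        cond1 = conds[0]
        _require(j(f"segmentation_{cond1}.bed"), j("genes.gff3"), j("tes.tsv"))
        seg = Segmentation.from_bed(j(f"segmentation_{cond1}.bed"), config.bin_width,
                                    config.n_states)
        genes = gio.read_gff3_genes(j("genes.gff3"))
        tes = pd.read_csv(j("tes.tsv"), sep="\t")
        elements = build_element_map(genes, layout, config.promoter_length)
        tabs = state_by_element(seg, elements, layout)
        tabs["counts"].to_csv(j("state_by_element.tsv"), sep="\t")
        tabs["by_state"].to_csv(j("state_by_element_rownorm.tsv"), sep="\t")
        te_tabs = state_by_te(seg, tes, layout)
        te_tabs["te_counts"].to_csv(j("state_by_te.tsv"), sep="\t")
        cov = state_coverage(seg, layout, by_subgenome=True)
        cov.to_csv(j("state_coverage.tsv"), sep="\t", index=False)
        outs = [j("state_by_element.tsv"), j("state_by_te.tsv"), j("state_coverage.tsv")]
        _write_manifest(outdir, name, config, [j(f"segmentation_{cond1}.bed")], outs)
        return outs

    if name == "assign":
        _require(j("genes.gff3"))
        genes = gio.read_gff3_genes(j("genes.gff3"))
        outputs = []
        for cond in conds:
            _require(j(f"segmentation_{cond}.bed"))
            seg = Segmentation.from_bed(j(f"segmentation_{cond}.bed"),
                                        config.bin_width, config.n_states)
            df = gs_mod.assign_gene_states(genes, seg, layout, cond,
                                           config.promoter_length)
            df.to_csv(j(f"gene_states_{cond}.tsv"), sep="\t", index=False)
            outputs.append(j(f"gene_states_{cond}.tsv"))
        _write_manifest(outdir, name, config, [j("genes.gff3")], outputs)
        return outputs

    if name == "de":
        _require(j("counts.tsv"))
        counts = pd.read_csv(j("counts.tsv"), sep="\t", index_col=0)
        labels = [c.rsplit("_rep", 1)[0] for c in counts.columns]
        deg = de_mod.nb_de_test(counts, labels, conds[0], conds[1],
                                alpha=config.de_alpha,
                                lfc_threshold=config.lfc_threshold)
        deg.to_csv(j("de_results.tsv"), sep="\t", index=False)
        _write_manifest(outdir, name, config, [j("counts.tsv")], [j("de_results.tsv")])
        return [j("de_results.tsv")]

    if name == "transitions":
        ins = [j(f"gene_states_{c}.tsv") for c in conds] + [j("de_results.tsv")]
        _require(*ins)
        a1 = pd.read_csv(ins[0], sep="\t")
        a2 = pd.read_csv(ins[1], sep="\t")
        deg = pd.read_csv(j("de_results.tsv"), sep="\t")
        ledger, matrix = gs_mod.build_transition_ledger(a1, a2)
        ledger.to_csv(j("transition_ledger.tsv"), sep="\t", index=False)
        matrix.to_csv(j("transition_matrix.tsv"), sep="\t")
        rows = []
        for direction in ("any", "up", "down"):
            for r in gs_mod.transition_deg_enrichment(ledger, deg, direction):
                rows.append({
                    "label": r.label, "odds_ratio": r.odds_ratio,
                    "p_value": r.p_value,
                    "background_fraction": r.background_fraction,
                })
        pd.DataFrame(rows).to_csv(j("transition_enrichment.tsv"), sep="\t", index=False)
        outs = [j("transition_ledger.tsv"), j("transition_matrix.tsv"),
                j("transition_enrichment.tsv")]
        _write_manifest(outdir, name, config, ins, outs)
        return outs

    if name == "bias":
        ins = [j("hits_ad.tsv"), j("hits_da.tsv"), j("counts.tsv"), j("genes.gff3")]
        _require(*ins)
        genes = gio.read_gff3_genes(j("genes.gff3"))
        hits_ad = pd.read_csv(ins[0], sep="\t")
        hits_da = pd.read_csv(ins[1], sep="\t")
        counts = pd.read_csv(j("counts.tsv"), sep="\t", index_col=0)
        a_ids = [g.gene_id for g in genes if g.subgenome == "A"]
        d_ids = [g.gene_id for g in genes if g.subgenome == "D"]
        hom = bias_mod.reciprocal_best_hits(
            hits_ad, hits_da, a_ids, d_ids,
            e_cut=config.rbh_e, cov_cut=config.rbh_cov, id_cut=config.rbh_id)
        rep_samples = [c for c in counts.columns if c.startswith(conds[0])]
        hom = bias_mod.categorize_bias(hom, counts, rep_samples, rep_samples,
                                       alpha=config.de_alpha,
                                       lfc_threshold=config.lfc_threshold)
        hom.to_frame().to_csv(j("homoeolog_pairs.tsv"), sep="\t", index=False)
        summary = bias_mod.bias_summary(hom)
        with open(j("bias_summary.json"), "w") as fh:
            json.dump(summary, fh, indent=1)
        outs = [j("homoeolog_pairs.tsv"), j("bias_summary.json")]
        _write_manifest(outdir, name, config, ins, outs)
        return outs

    if name == "cluster":
        _require(j("genes.gff3"))
        genes = gio.read_gff3_genes(j("genes.gff3"))
        cond1 = conds[0]
        tracks = {}
        for mark in HISTONE_MARKS:
            rep = 1
            while os.path.exists(j(f"track_{cond1}_{mark}_rep{rep}.bedgraph")):
                tracks[(cond1, mark, rep)] = gio.read_bedgraph(
                    j(f"track_{cond1}_{mark}_rep{rep}.bedgraph"), layout,
                    config.bin_width, mark=mark, condition=cond1, replicate=rep)
                rep += 1
        n_reps = max(r for (_, _, r) in tracks)
        signal = gene_signal_matrix(tracks, genes, cond1, n_reps)
        labels, means = bias_mod.kmeans_gene_clusters(
            signal, k=config.k_clusters, seed=config.seed)
        labels.to_csv(j("gene_clusters.tsv"), sep="\t")
        means.to_csv(j("cluster_means.tsv"), sep="\t")
        outs = [j("gene_clusters.tsv"), j("cluster_means.tsv")]
        _write_manifest(outdir, name, config, [j("genes.gff3")], outs)
        return outs

    if name == "report":
        pieces = {}
        for f in ("bias_summary.json",):
            if os.path.exists(j(f)):
                with open(j(f)) as fh:
                    pieces[f.split(".")[0]] = json.load(fh)
        if os.path.exists(j("transition_ledger.tsv")):
            ledger = pd.read_csv(j("transition_ledger.tsv"), sep="\t")
            pieces["transition_percent"] = round(
                100.0 * gs_mod.transition_fraction(ledger), 2)
        with open(j("report.json"), "w") as fh:
            json.dump(pieces, fh, indent=1)
        _write_manifest(outdir, name, config, [], [j("report.json")])
        return [j("report.json")]

    raise ValueError(f"unknown stage {name!r}; stages are {STAGES}")


def _discover_conditions(outdir: str) -> list[str]:
    conds = []
    for f in sorted(os.listdir(outdir)):
        if f.startswith("track_") and f.endswith(".bedgraph"):
            cond = f[len("track_"):].split("_")[0]
            if cond not in conds:
                conds.append(cond)
    if not conds:
        raise FileNotFoundError("no track files found; run the simulate stage first")
    # wild-type condition first if present
    return sorted(conds, key=lambda c: (c != "wild", c))
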