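"""Config-driven orchestration of the full analysis.

Stages run in the analysis order: simulate -> preprocess -> quantify ->
normalize -> de -> grade -> features -> cluster.  Every stage reads its
inputs from, and writes its outputs to, documented files under the run
directory, so any stage can be resumed from disk.  A run manifest (config
hash, seed, per-stage record counts, thresholds in force) is written at
the end; identical config + seed yields byte-identical outputs.

Every study threshold surfaces as a named config key with its standard
value as the default: quality Q>=20 on >=80% of bases, minimum insert
15 nt, maximum counted read 27 nt, +/-4 nt 5' window, mean-count-< 2
filter, FDR 0.05, CAG cutoff 55.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import assoc_stats, io_formats, normalize, preprocess, quantify, synthetic_data

STAGES = ("simulate", "preprocess", "quantify", "normalize",
          "de", "grade", "features", "cluster")


@dataclass
class PipelineConfig:
    """One YAML document with per-stage sections."""

    seed: int = 0
    simulate: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=lambda: {
        "adapter": preprocess.DEFAULT_ADAPTER,
        "min_quality": 20,
        "min_quality_fraction": 0.8,
        "min_length": 15,
        "error_rate": 0.1,
        "min_overlap": 3,
    })
    quantify: dict = field(default_factory=lambda: {
        "window": 4,
        "max_read_len": 27,
        "max_loci": None,
    })
    normalize: dict = field(default_factory=lambda: {
        "min_mean": 2.0,
        "batch_col": "batch",
    })
    stats: dict = field(default_factory=lambda: {
        "fdr": 0.05,
        "cag_max": 55,
        "pairwise_adjust": "tukey",
    })

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls()
        unknown = set(raw) - {"seed", "simulate", "preprocess", "quantify",
                              "normalize", "stats"}
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        cfg.seed = int(raw.get("seed", 0))
        cfg.simulate = dict(raw.get("simulate", {}))
        for section in ("preprocess", "quantify", "normalize", "stats"):
            base = getattr(cfg, section)
            base.update(raw.get(section, {}))
        return cfg

    def sim_config(self) -> synthetic_data.SimulationConfig:
        d = dict(self.simulate)
        d["seed"] = self.seed
        return synthetic_data.SimulationConfig.from_dict(d)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _outputs(outdir: Path) -> dict[str, list[Path]]:
    return {
        "simulate": [outdir / "genome.fasta", outdir / "annotation.gff3",
                     outdir / "samples.tsv", outdir / "reference_cohort.tsv",
                     outdir / "truth" / "per_mirna.tsv", outdir / "reads"],
        "preprocess": [outdir / "collapsed", outdir / "preprocess_stats.tsv"],
        "quantify": [outdir / "counts.tsv", outdir / "assignment_summary.tsv"],
        "normalize": [outdir / "expression.tsv", outdir / "size_factors.tsv"],
        "de": [outdir / "de_results.tsv"],
        "grade": [outdir / "grade_results.tsv", outdir / "grade_pairwise.tsv"],
        "features": [outdir / "feature_results.tsv",
                     outdir / "multivariate_striatal.tsv",
                     outdir / "residualized_features.tsv"],
        "cluster": [outdir / "cluster_matrix.tsv", outdir / "cluster_orders.tsv"],
    }


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, outdir: Path, counts_log: dict) -> None:
    sim_cfg = cfg.sim_config()
    rng = np.random.default_rng(sim_cfg.seed)
    genome, matures = synthetic_data.simulate_annotation(sim_cfg, rng)
    samples, true_counts, truth = synthetic_data.simulate_cohort(
        sim_cfg, [m for m in dict.fromkeys(x.mature_id for x in matures)], rng
    )
    reference = synthetic_data.simulate_reference_cohort(sim_cfg, rng)
    # the sequenced HD brains are a subset of the neuropathology reference
    # cohort, so residual models fitted on the reference cover them
    hd_cols = ["condition", "grade", "cag", "onset_age", "duration",
               "age_death", "hv_striatal", "hv_cortical", "pmi", "rin"]
    seq_hd = samples[samples["condition"] == "HD"][hd_cols]
    reference = pd.concat([seq_hd[seq_hd["grade"] > 0], reference])

    io_formats.write_fasta(genome, outdir / "genome.fasta")
    precursors = []
    io_formats.write_annotation_gff3(matures, outdir / "annotation.gff3", precursors)
    io_formats.write_sample_table(samples, outdir / "samples.tsv")
    io_formats.write_sample_table(reference, outdir / "reference_cohort.tsv")
    io_formats.write_count_matrix(true_counts, outdir / "true_counts.tsv")
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    truth.per_mirna.to_csv(truth_dir / "per_mirna.tsv", sep="\t")
    truth.per_sample.to_csv(truth_dir / "per_sample.tsv", sep="\t", na_rep="NA")

    reads_dir = outdir / "reads"
    reads_dir.mkdir(exist_ok=True)
    sim = synthetic_data.ReadSimulator(sim_cfg, genome, matures,
                                       window=cfg.quantify["window"])
    n_reads = 0
    truth_read_frames = []
    for sample_id in samples.index:
        reads, per_read = sim.sample_reads(sample_id, true_counts[sample_id], rng)
        n_reads += io_formats.write_fastq(reads, reads_dir / f"{sample_id}.fastq")
        truth_read_frames.append(per_read)
    pd.concat(truth_read_frames, ignore_index=True).to_csv(
        truth_dir / "per_read.tsv", sep="\t", index=False
    )
    counts_log["simulate"] = {"samples": len(samples), "mirnas": len(true_counts),
                              "reads": n_reads}


def stage_preprocess(cfg: PipelineConfig, outdir: Path, counts_log: dict) -> None:
    reads_dir = outdir / "reads"
    collapsed_dir = outdir / "collapsed"
    collapsed_dir.mkdir(exist_ok=True)
    pc = cfg.preprocess
    stat_rows = []
    for fastq in sorted(reads_dir.glob("*.fastq")):
        sample_id = fastq.stem
        collapsed, stats = preprocess.preprocess_sample(
            io_formats.read_fastq(fastq),
            adapter=pc["adapter"],
            min_quality=pc["min_quality"],
            min_quality_fraction=pc["min_quality_fraction"],
            min_length=pc["min_length"],
            error_rate=pc["error_rate"],
            min_overlap=pc["min_overlap"],
        )
        io_formats.write_collapsed_fasta(collapsed, collapsed_dir / f"{sample_id}.fasta")
        stat_rows.append({"sample_id": sample_id, **stats})
    stats_df = pd.DataFrame(stat_rows).set_index("sample_id")
    stats_df.to_csv(outdir / "preprocess_stats.tsv", sep="\t")
    counts_log["preprocess"] = {
        "input_reads": int(stats_df["input"].sum()),
        "surviving_reads": int(stats_df["surviving_mass"].sum()),
    }


def stage_quantify(cfg: PipelineConfig, outdir: Path, counts_log: dict) -> None:
    genome = io_formats.read_fasta(outdir / "genome.fasta")
    annotation = io_formats.read_annotation_gff3(outdir / "annotation.gff3")
    index = quantify.AnnotationIndex(annotation)
    qc = cfg.quantify
    aln_dir = outdir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    ref_lengths = {c: len(s) for c, s in genome.items()}
    per_sample = {}
    summaries = []
    for fasta in sorted((outdir / "collapsed").glob("*.fasta")):
        sample_id = fasta.stem
        collapsed = io_formats.read_collapsed_fasta(fasta)
        records = synthetic_data.exhaustive_align(
            [(rid, seq) for rid, seq, _m in collapsed], genome
        )
        io_formats.write_alignments_sam(records, aln_dir / f"{sample_id}.sam",
                                        ref_lengths)
        counts, outcomes = quantify.quantify_sample(
            records, index, window=qc["window"], max_len=qc["max_read_len"],
            max_loci=qc["max_loci"],
        )
        per_sample[sample_id] = counts
        summary = quantify.outcome_summary(outcomes)
        summary.insert(0, "sample_id", sample_id)
        summaries.append(summary.reset_index())
    matrix = quantify.build_count_matrix(per_sample, index)
    io_formats.write_count_matrix(matrix, outdir / "counts.tsv")
    pd.concat(summaries, ignore_index=True).to_csv(
        outdir / "assignment_summary.tsv", sep="\t", index=False
    )
    counts_log["quantify"] = {
        "mirnas": int(matrix.shape[0]),
        "samples": int(matrix.shape[1]),
        "assigned_mass": int(matrix.values.sum()),
    }


def stage_normalize(cfg: PipelineConfig, outdir: Path, counts_log: dict) -> None:
    counts = io_formats.read_count_matrix(outdir / "counts.tsv")
    samples = io_formats.read_sample_table(outdir / "samples.tsv")
    nc = cfg.normalize
    batch_col = nc["batch_col"]
    if batch_col not in samples.columns:
        raise ValueError(f"metadata lacks batch column {batch_col!r}")
    batch = samples.loc[counts.columns, batch_col]
    if batch.isna().any():
        raise ValueError("missing batch label; batches must be supplied, never guessed")
    expr, sf, trend = normalize.normalize_counts(counts, batch,
                                                 min_mean=nc["min_mean"])
    io_formats.write_expression_matrix(expr, outdir / "expression.tsv")
    sf.to_frame().to_csv(outdir / "size_factors.tsv", sep="\t",
                         float_format="%.10g")
    counts_log["normalize"] = {
        "mirnas_after_filter": int(expr.shape[0]),
        "alpha0": round(trend.alpha0, 8),
        "alpha1": round(trend.alpha1, 8),
    }


def _load_expr_samples(outdir: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    expr = io_formats.read_expression_matrix(outdir / "expression.tsv")
    samples = io_formats.read_sample_table(outdir / "samples.tsv")
    return expr, samples


def stage_de(cfg: PipelineConfig, outdir: Path, counts_log: dict) -> None:
    expr, samples = _load_expr_samples(outdir)
    # contrast: symptomatic HD (grades 2-4) vs control; grade-0 excluded
    keep = samples.loc[expr.columns].apply(
        lambda r: r["condition"] == "control" or
        (r["condition"] == "HD" and r["grade"] > 0), axis=1)
    sub = expr.loc[:, keep[keep].index]
    meta = samples.loc[sub.columns]
    res = assoc_stats.moderated_de(
        sub, meta["condition"], covariates=meta[["age_death"]].astype(float)
    )
    res = res[["average_expression", "log2_fold_change", "moderated_t",
               "p_value", "q_value", "residual_df"]]
    res.index.name = "miRNA"
    res.to_csv(outdir / "de_results.tsv", sep="\t", float_format="%.10g")
    counts_log["de"] = {
        "tested": int(res.shape[0]),
        "significant": int((res["q_value"] < cfg.stats["fdr"]).sum()),
    }


def _de_set(outdir: Path, fdr: float) -> list[str]:
    de = pd.read_csv(outdir / "de_results.tsv", sep="\t", index_col=0)
    return list(de.index[de["q_value"] < fdr])


def stage_grade(cfg: PipelineConfig, outdir: Path, counts_log: dict) -> None:
    expr, samples = _load_expr_samples(outdir)
    de_set = _de_set(outdir, cfg.stats["fdr"])
    if not de_set:
        pd.DataFrame().to_csv(outdir / "grade_results.tsv", sep="\t")
        pd.DataFrame().to_csv(outdir / "grade_pairwise.tsv", sep="\t")
        counts_log["grade"] = {"tested": 0, "significant_both": 0}
        return
    meta = samples.loc[expr.columns]
    labels = meta.apply(
        lambda r: "control" if r["condition"] == "control" else str(int(r["grade"])),
        axis=1)
    # drop groups too small for a within-group variance estimate
    sizes = labels.value_counts()
    usable = labels.isin(sizes[sizes >= 2].index)
    res = assoc_stats.grade_association(
        expr.loc[:, usable[usable].index], samples, de_set=de_set,
        alpha=cfg.stats["fdr"], pairwise_adjust=cfg.stats["pairwise_adjust"],
    )
    pairwise = []
    for mirna, frame in res["pairwise"].items():
        frame = frame.copy()
        frame.insert(0, "miRNA", mirna)
        pairwise.append(frame)
    res.drop(columns=["pairwise"]).to_csv(outdir / "grade_results.tsv", sep="\t",
                                          float_format="%.10g")
    pd.concat(pairwise, ignore_index=True).to_csv(
        outdir / "grade_pairwise.tsv", sep="\t", index=False, float_format="%.10g")
    counts_log["grade"] = {
        "tested": int(res.shape[0]),
        "significant_both": int(res["significant_both"].sum()),
    }


def stage_features(cfg: PipelineConfig, outdir: Path, counts_log: dict) -> None:
    expr, samples = _load_expr_samples(outdir)
    de_set = _de_set(outdir, cfg.stats["fdr"])
    reference = io_formats.read_sample_table(outdir / "reference_cohort.tsv")
    meta = samples.loc[expr.columns]
    symptomatic = meta[(meta["condition"] == "HD") & (meta["grade"] > 0)]
    resid, _fits = assoc_stats.residualize_features(
        symptomatic, reference=reference, cag_max=cfg.stats["cag_max"]
    )
    resid.to_csv(outdir / "residualized_features.tsv", sep="\t", na_rep="NA",
                 float_format="%.10g")
    if not de_set:
        pd.DataFrame().to_csv(outdir / "feature_results.tsv", sep="\t")
        pd.DataFrame().to_csv(outdir / "multivariate_striatal.tsv", sep="\t")
        counts_log["features"] = {"tested": 0}
        return
    sub = expr.loc[:, symptomatic.index]
    frames = []
    for feature in assoc_stats.CLINICAL_FEATURES:
        frames.append(assoc_stats.feature_regression(
            sub, resid[feature], de_set, feature_name=feature))
    feat_res = pd.concat(frames)
    feat_res.index.name = "miRNA"
    feat_res.to_csv(outdir / "feature_results.tsv", sep="\t", float_format="%.10g")
    multi = assoc_stats.multivariate_feature_regression(
        sub.loc[[m for m in de_set if m in sub.index]],
        resid["striatal"], resid["cortical"])
    multi.index.name = "miRNA"
    multi.to_csv(outdir / "multivariate_striatal.tsv", sep="\t",
                 float_format="%.10g")
    counts_log["features"] = {
        "tested": int(len(de_set)),
        "significant": int((feat_res["q"] < cfg.stats["fdr"]).sum()),
    }


def stage_cluster(cfg: PipelineConfig, outdir: Path, counts_log: dict) -> None:
    expr, samples = _load_expr_samples(outdir)
    de_set = _de_set(outdir, cfg.stats["fdr"])
    resid = pd.read_csv(outdir / "residualized_features.tsv", sep="\t",
                        index_col=0, na_values="NA")
    meta = samples.loc[expr.columns]
    symptomatic = meta[(meta["condition"] == "HD") & (meta["grade"] > 0)]
    sub = expr.loc[[m for m in de_set if m in expr.index], symptomatic.index]
    if sub.shape[0] < 2:
        pd.DataFrame().to_csv(outdir / "cluster_matrix.tsv", sep="\t")
        pd.DataFrame().to_csv(outdir / "cluster_orders.tsv", sep="\t")
        counts_log["cluster"] = {"mirnas": 0}
        return
    ordered, row_order, col_order, _rl, _cl = assoc_stats.correlation_cluster(
        sub, resid)
    ordered.to_csv(outdir / "cluster_matrix.tsv", sep="\t", float_format="%.10g")
    orders = pd.DataFrame({
        "axis": ["row"] * len(row_order) + ["column"] * len(col_order),
        "name": list(row_order) + list(col_order),
    })
    orders.to_csv(outdir / "cluster_orders.tsv", sep="\t", index=False)
    counts_log["cluster"] = {"mirnas": int(ordered.shape[0])}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "quantify": stage_quantify,
    "normalize": stage_normalize,
    "de": stage_de,
    "grade": stage_grade,
    "features": stage_features,
    "cluster": stage_cluster,
}


def run_stage(stage: str, cfg: PipelineConfig, outdir: str | Path,
              counts_log: dict | None = None) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts_log = counts_log if counts_log is not None else {}
    try:
        _STAGE_FUNCS[stage](cfg, outdir, counts_log)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc
    return counts_log


def run_all(cfg: PipelineConfig, outdir: str | Path, resume: bool = False) -> dict:
    """Run every stage in order; returns the manifest dict.

    With ``resume=True`` a stage is skipped when all its outputs already
    exist and no upstream stage was rerun; downstream stages of a rerun
    stage always rerun, so a resumed run reproduces a fresh one exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = _outputs(outdir)
    counts_log: dict = {}
    upstream_rerun = False
    for stage in STAGES:
        have = all(p.exists() for p in outputs[stage])
        if resume and have and not upstream_rerun:
            counts_log[stage] = {"skipped": True}
            continue
        run_stage(stage, cfg, outdir, counts_log)
        upstream_rerun = True
    manifest = {
        "software": f"mirhd {__version__}",
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "thresholds": {
            "min_quality": cfg.preprocess["min_quality"],
            "min_quality_fraction": cfg.preprocess["min_quality_fraction"],
            "min_length": cfg.preprocess["min_length"],
            "window": cfg.quantify["window"],
            "max_read_len": cfg.quantify["max_read_len"],
            "min_mean": cfg.normalize["min_mean"],
            "fdr": cfg.stats["fdr"],
            "cag_max": cfg.stats["cag_max"],
        },
        "stages": counts_log,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
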