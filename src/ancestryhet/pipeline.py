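"""End-to-end orchestration: genotype tables in, result tables out.

Stages mirror the analysis order: diagnostic-marker selection ->
ancestry polarization -> matrix filtering -> individual and locus
summaries -> enabled statistical analyses.  Every output table is
stamped with a hash of the run configuration so outputs from different
configurations cannot be mixed silently.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import ancestry, inference, io
from .containers import AncestryMatrix, CrossGenotypes
from .errors import AncestryHetError, ValidationError
from .simulate import SimBundleConfig, generate_study_bundle

logger = logging.getLogger(__name__)

KNOWN_ANALYSES = ("model", "correlation", "bootstrap", "resampling", "error_sim")


@dataclass
class RunConfig:
    """Configuration of a pipeline run.

    Exactly one of ``input_paths`` (genotype TSVs plus ``manifest_path``)
    or ``sim_config`` must be provided.
    """

    input_paths: tuple[str, ...] | None = None
    manifest_path: str | None = None
    sim_config: SimBundleConfig | None = None
    outdir: str = "ancestryhet_results"
    min_coverage: int = ancestry.DEFAULT_MIN_COVERAGE
    min_loci: int = ancestry.DEFAULT_MIN_LOCI
    min_individuals: int = ancestry.DEFAULT_MIN_INDIVIDUALS
    sex_chrom_label: str = ancestry.DEFAULT_SEX_CHROMOSOME
    statistic: str = "excess"
    correction: str = "none"
    analyses: tuple[str, ...] = ("model", "correlation")
    resampling_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        has_paths = bool(self.input_paths)
        if has_paths == (self.sim_config is not None):
            raise ValidationError(
                "exactly one of input_paths and sim_config must be set")
        if has_paths and not self.manifest_path:
            raise ValidationError("input_paths requires manifest_path")
        unknown = set(self.analyses) - set(KNOWN_ANALYSES)
        if unknown:
            raise ValidationError(f"unknown analyses: {sorted(unknown)}")
        if min(self.min_coverage, self.min_loci, self.min_individuals) < 0:
            raise ValidationError("thresholds must be non-negative")


@dataclass
class PipelineReport:
    """Everything a run produced, plus where it was written."""

    outdir: Path
    config_hash: str
    individual_summaries: pd.DataFrame
    locus_summaries: pd.DataFrame
    filter_report: pd.DataFrame
    model: inference.LmmResult | None = None
    correlations: dict = field(default_factory=dict)
    bootstrap: inference.BootstrapResult | None = None
    resampling: inference.ResamplingResult | None = None
    error_sim: inference.SimulationReport | None = None
    timings: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)


def _load_inputs(config: RunConfig):
    if config.sim_config is not None:
        bundle = generate_study_bundle(config.sim_config)
        return bundle.datasets, bundle.manifest
    datasets = {}
    for p in config.input_paths:
        cross = io.read_genotype_tsv(p)
        for ds in cross.datasets:
            sub = CrossGenotypes(cross.data[cross.data["dataset_id"] == ds])
            if ds in datasets:
                raise ValidationError(f"dataset id {ds!r} appears in multiple inputs")
            datasets[ds] = sub
    manifest = io.read_manifest(config.manifest_path)
    return datasets, manifest


def _process_dataset(config: RunConfig, cross: CrossGenotypes):
    panel = ancestry.select_diagnostic_markers(
        cross, sex_chrom_label=config.sex_chrom_label,
        min_coverage=config.min_coverage)
    matrix = ancestry.polarize_to_ancestry(cross, panel)
    matrix = ancestry.apply_matrix_filters(
        matrix, min_loci=config.min_loci, min_individuals=config.min_individuals)
    return panel, matrix


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Run every stage and write result TSVs plus a metadata sidecar."""
    t0 = time.time()
    timings = {}
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # hash the analytic configuration only: where results are written must
    # not change what they contain
    h = io.config_hash({k: v for k, v in asdict(config).items() if k != "outdir"})

    datasets, manifest = _load_inputs(config)
    timings["load"] = time.time() - t0

    matrices: dict[str, AncestryMatrix] = {}
    ind_parts, loc_parts, filter_rows = [], [], []
    stage = time.time()
    for ds, cross in datasets.items():
        try:
            panel, matrix = _process_dataset(config, cross)
        except AncestryHetError as exc:
            raise AncestryHetError(f"dataset {ds!r} failed in filtering: {exc}") from exc
        matrices[ds] = matrix
        ind = ancestry.summarize_individuals(
            matrix, statistic=config.statistic, correction=config.correction)
        loc = ancestry.summarize_loci(
            matrix, statistic=config.statistic, correction=config.correction)
        loc.insert(0, "dataset_id", ds)
        ind_parts.append(ind)
        loc_parts.append(loc)
        counts = panel.rejection_counts()
        filter_rows.append({
            "dataset_id": ds,
            "n_markers_input": len(panel.table),
            "n_diagnostic": len(panel.diagnostic_markers),
            "n_retained": matrix.shape[1],
            "n_individuals_retained": int(matrix.recombinant_mask.sum()),
            "f1_validation_rate": panel.f1_validation_rate,
            **{f"rejected_{k}": int(v) for k, v in counts.items()},
        })
    individual_summaries = pd.concat(ind_parts, ignore_index=True)
    locus_summaries = pd.concat(loc_parts, ignore_index=True)
    filter_report = pd.DataFrame(filter_rows)
    timings["summaries"] = time.time() - stage

    report = PipelineReport(outdir, h, individual_summaries, locus_summaries,
                            filter_report, timings=timings)

    pooled = inference.attach_manifest(individual_summaries, manifest)
    stage = time.time()
    if "model" in config.analyses:
        report.model = inference.fit_environment_model(pooled)
    if "correlation" in config.analyses:
        for env in sorted(pooled["environment"].unique()):
            try:
                report.correlations[env] = inference.hybrid_index_deviation_correlation(
                    pooled, group=env)
            except AncestryHetError as exc:
                logger.warning("correlation in %s skipped: %s", env, exc)
    if "bootstrap" in config.analyses and set(pooled["environment"]) == {"lab", "pond"}:
        report.bootstrap = inference.bootstrap_correlation_difference(
            pooled[pooled["environment"] == "pond"],
            pooled[pooled["environment"] == "lab"],
            seed=config.seed)
    if "resampling" in config.analyses:
        report.resampling = inference.single_marker_resampling(
            matrices, manifest, n_reps=config.resampling_reps, seed=config.seed)
    if "error_sim" in config.analyses:
        report.error_sim = inference.genotyping_error_threshold(seed=config.seed)
    timings["analyses"] = time.time() - stage

    _write_outputs(config, report, manifest)
    timings["total"] = time.time() - t0
    return report


def _write_tsv(df: pd.DataFrame, path: Path, h: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# config_hash={h}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def _write_outputs(config: RunConfig, report: PipelineReport, manifest) -> None:
    out, h = report.outdir, report.config_hash
    _write_tsv(report.individual_summaries, out / "individual_summaries.tsv", h)
    _write_tsv(report.locus_summaries, out / "locus_summaries.tsv", h)
    _write_tsv(report.filter_report, out / "filter_report.tsv", h)
    report.paths = {
        "individual_summaries": out / "individual_summaries.tsv",
        "locus_summaries": out / "locus_summaries.tsv",
        "filter_report": out / "filter_report.tsv",
    }
    lines = [f"datasets: {len(report.filter_report)}",
             f"individuals summarized: {len(report.individual_summaries)}"]
    if report.model is not None:
        _write_tsv(report.model.contrasts, out / "environment_contrasts.tsv", h)
        report.paths["environment_contrasts"] = out / "environment_contrasts.tsv"
        for _, row in report.model.contrasts.iterrows():
            lines.append(
                f"{row['cross']}: pond-lab excess het contrast "
                f"{row['estimate']:+.4f} +/- {row['se']:.4f} "
                f"(z={row['z']:.2f}, P={row['p']:.3g})")
        if report.model.note:
            lines.append(f"model note: {report.model.note}")
    for env, corr in report.correlations.items():
        lines.append(f"{env}: rho(|h-0.5|, excess) = {corr.rho:+.3f} (P={corr.p:.3g})")
    if report.resampling is not None:
        lines.append(
            "single-marker resampling sign agreement: "
            f"{report.resampling.fraction_same_direction:.1%}")
    if report.error_sim is not None and report.error_sim.threshold is not None:
        lines.append(
            f"error rate needed for {report.error_sim.target_excess:.0%} excess: "
            f"{report.error_sim.threshold:.1%}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    meta = {
        "config_hash": h,
        "seed": int(config.seed),
        "statistic": config.statistic,
        "correction": config.correction,
        "analyses": list(config.analyses),
        "timings_s": {k: round(v, 3) for k, v in report.timings.items()},
    }
    with open(out / "run_metadata.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    report.paths["metadata"] = out / "run_metadata.yaml"
    report.paths["summary"] = out / "summary.txt"
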