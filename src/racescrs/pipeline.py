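"""End-to-end orchestration: cohort → preprocess → classify → type → PCA → sort.

One :class:`PipelineConfig` (serializable to YAML) drives a fully seeded run;
the resolved configuration is written next to the outputs, and identical
config + seed gives byte-identical outputs.  The summary report assembles the
cohort's headline numbers: cells analysed, fluorescence-screened and
distinguishable fractions, carotenoid prevalence, carotenoid types, PC1
loading windows, and the sort-session tallies.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import carotenoid_types as ctypes
from .classify import ClassifierConfig, CohortReport, classify_cohort
from .ordination import pca, top_loading_windows
from .preprocess import PreprocessConfig, preprocess_set
from .sorter import ChipLayout, build_sort_plan, simulate_session
from .spectral_io import SpectrumSet, write_cohort_csv
from .synthetic import (CompositionPreset, NoiseModel, PRESETS,
                        simulate_cohort, sorted_samples_reference)

logger = logging.getLogger("racescrs")

#: Stage names used to derive independent child seeds from the run seed.
_STAGES = ("cohort", "session")


def child_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the run seed (below 2^31)."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(seed), _STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Fully serializable run configuration."""

    seed: int = 1
    preset: str = "red_sea_default"
    n_cells: int = 5321
    noise: dict = field(default_factory=dict)        # NoiseModel overrides
    preprocess: dict = field(default_factory=dict)   # PreprocessConfig overrides
    classify: dict = field(default_factory=dict)     # ClassifierConfig overrides
    typing_tol_cm1: float = ctypes.DEFAULT_TOL_CM1
    pca_components: int = 5
    pca_exclude_fluorescent: bool = True
    pca_alpha: float = 0.5
    sort_query: str = "carotenoid"
    n_wells: int = 12
    cells_per_well: int = 1
    success_prob: float = 1.0
    write_cohort: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class PipelineResult:
    """In-memory results of one pipeline run."""

    cohort: SpectrumSet
    report: CohortReport
    type_assignment: ctypes.TypeAssignment
    loading_windows: list
    summary: dict


def _stage(name: str, **params) -> None:
    logger.info("stage %s: %s", name,
                ", ".join(f"{k}={v}" for k, v in params.items()))


def run_pipeline(config: PipelineConfig,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Execute every stage under one seed; optionally write all artifacts."""
    cfg = config
    if cfg.preset not in PRESETS:
        raise ValueError(f"unknown preset {cfg.preset!r}")
    preset: CompositionPreset = PRESETS[cfg.preset](cfg.n_cells)
    noise = NoiseModel(**cfg.noise)
    pre_cfg = PreprocessConfig(**cfg.preprocess)
    cls_cfg = ClassifierConfig(**cfg.classify)

    _stage("simulate", preset=preset.name, n=preset.n_cells, seed=cfg.seed)
    cohort = simulate_cohort(preset, noise=noise,
                             seed=child_seed(cfg.seed, "cohort"))

    _stage("preprocess", lam=pre_cfg.lam, p=pre_cfg.p, norm=pre_cfg.norm_method)
    processed = preprocess_set(cohort, pre_cfg)

    _stage("classify", theta_f=cls_cfg.theta_f, snr_min=cls_cfg.snr_min)
    report = classify_cohort(processed, cls_cfg)

    _stage("type", tol_cm1=cfg.typing_tol_cm1)
    triplets = ctypes.triplets_from_calls(report.calls)
    assignment = ctypes.cluster_types(triplets, tol_cm1=cfg.typing_tol_cm1)

    _stage("pca", components=cfg.pca_components,
           exclude_fluorescent=cfg.pca_exclude_fluorescent)
    pca_result = pca(processed, n_components=cfg.pca_components,
                     exclude_fluorescent=cfg.pca_exclude_fluorescent,
                     calls=report.calls)
    windows = top_loading_windows(pca_result, component=0, alpha=cfg.pca_alpha)

    _stage("sort", query=cfg.sort_query, wells=cfg.n_wells,
           cells_per_well=cfg.cells_per_well)
    layout = ChipLayout(n_wells=cfg.n_wells)
    # One chip holds at most (n_wells - controls) * cells_per_well cells:
    # plan a single chip's worth of the highest-scoring targets.
    capacity = len(layout.target_wells) * cfg.cells_per_well
    matching = sorted((c for c in report.calls if c.label == cfg.sort_query),
                      key=lambda c: -c.carotenoid_score)
    chip_targets = {c.cell_id for c in matching[:capacity]}
    plan = build_sort_plan(
        report.calls,
        query=lambda c: c.cell_id in chip_targets,
        layout=layout, cells_per_well=cfg.cells_per_well)
    manifest = simulate_session(
        plan, rng=np.random.default_rng(child_seed(cfg.seed, "session")),
        success_prob=cfg.success_prob)

    summary = {
        "seed": cfg.seed,
        "preset": preset.name,
        "n_analysed": report.n_cells,
        "fractions": report.fractions,
        "counts": report.counts,
        "fraction_fluorescent": report.fractions["fluorescent"],
        "fraction_distinguishable": (report.n_distinguishable / report.n_cells
                                     if report.n_cells else 0.0),
        "n_carotenoid": report.counts["carotenoid"],
        "n_carotenoid_types": assignment.n_types,
        "pc1_explained_variance": float(pca_result.explained_variance_ratio[0]),
        "pc1_loading_windows": [[w.lo, w.hi] for w in windows],
        "sort": {
            "query": cfg.sort_query,
            "n_planned": plan.n_targets,
            "n_collected": manifest.n_collected,
            "n_failed": manifest.n_failed,
            "control_wells": plan.controls,
        },
    }
    if report.accuracy is not None:
        summary["classification_accuracy_vs_truth"] = report.accuracy

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(outdir / "config.resolved.yaml")
        if cfg.write_cohort:
            write_cohort_csv(cohort, outdir / "cohort.csv")
        report.to_dataframe().to_csv(outdir / "calls.tsv", sep="\t", index=False)
        _write_types_tsv(assignment, outdir / "types.tsv")
        plan.to_dataframe().to_csv(outdir / "plan.tsv", sep="\t", index=False)
        manifest.to_dataframe().to_csv(outdir / "manifest.tsv", sep="\t",
                                       index=False)
        with open(outdir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        with open(outdir / "report.txt", "w", encoding="utf-8") as fh:
            fh.write(render_report(summary))

    return PipelineResult(cohort=cohort, report=report,
                          type_assignment=assignment,
                          loading_windows=windows, summary=summary)


def _write_types_tsv(assignment: ctypes.TypeAssignment, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cell_id\ttype\n")
        for cid in sorted(assignment.assignments):
            fh.write(f"{cid}\t{assignment.assignments[cid]}\n")


def render_report(summary: dict) -> str:
    """Human-readable summary of a pipeline run."""
    lines = [
        "Single-cell Raman phenotyping summary",
        "=" * 38,
        f"preset:                 {summary['preset']} (seed {summary['seed']})",
        f"cells analysed:         {summary['n_analysed']}",
        f"fluorescence-dominated: {summary['fraction_fluorescent']:.1%}",
        f"distinguishable SCRS:   {summary['fraction_distinguishable']:.1%}",
        f"carotenoid-containing:  {summary['n_carotenoid']} "
        f"({summary['fractions']['carotenoid']:.1%})",
        f"carotenoid types:       {summary['n_carotenoid_types']}",
        f"PC1 explained variance: {summary['pc1_explained_variance']:.1%}",
        "PC1 loading windows:    " + ", ".join(
            f"{lo:g}-{hi:g} cm-1" for lo, hi in summary["pc1_loading_windows"]),
        f"sort: {summary['sort']['n_planned']} planned, "
        f"{summary['sort']['n_collected']} collected, "
        f"{summary['sort']['n_failed']} failed",
    ]
    if "classification_accuracy_vs_truth" in summary:
        lines.append(
            "accuracy vs truth:      "
            f"{summary['classification_accuracy_vs_truth']:.2%}")
    return "\n".join(lines) + "\n"


def sorted_samples_summary(tol_cm1: float = ctypes.DEFAULT_TOL_CM1) -> dict:
    """Type-resolve the seven noiseless sorted-sample reference spectra."""
    ref = sorted_samples_reference()
    processed = preprocess_set(ref)
    report = classify_cohort(processed)
    triplets = ctypes.triplets_from_calls(report.calls)
    assignment = ctypes.cluster_types(triplets, tol_cm1=tol_cm1)
    return {
        "n_samples": len(ref),
        "n_types": assignment.n_types,
        "assignments": assignment.assignments,
        "centroids": [list(c) for c in assignment.centroids],
    }
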