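"""Reproducible end-to-end runs: simulate → clean → metrics → stats.

One YAML config drives a whole run; each stage writes its outputs under the
run directory so any stage can be re-run from cached upstream outputs, and a
provenance record (config hash, seed, versions) pins the result. The global
seed is fanned out to stages by fixed offsets so stages are independently
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import MetricParams, compute_cohort_metrics
from .icp import ICPParams
from .io import (
    read_label_volume,
    read_manifest,
    read_metrics_table,
    write_label_volume,
    write_metrics_table,
)
from .metrics import AnteriorWindow
from .postprocess import DEFAULT_MIN_COMPONENT_ML, clean_scan
from .stats import (
    CohortTable,
    StatConfig,
    choose_sensitivity_references,
    run_association_analysis,
    run_correlation_analysis,
    run_multivariate_analysis,
    run_predictor_analysis,
)
from .synthetic import CohortSimConfig, PhantomSpec, generate_cohort, write_cohort
from .volume import ScanRecord

_STAGE_SEED_OFFSETS = {"simulate": 0, "clean": 1, "metrics": 2, "stats": 3}


def _build(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"{context}: unknown keys {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs, loadable from one YAML file."""

    out_dir: str = "abdovar_run"
    seed: int = 0
    simulate: CohortSimConfig | None = None
    manifest_path: str | None = None
    min_component_ml: float = DEFAULT_MIN_COMPONENT_ML
    window: AnteriorWindow = field(default_factory=AnteriorWindow)
    icp: ICPParams = field(default_factory=ICPParams)
    stats: StatConfig = field(default_factory=StatConfig)
    sensitivity: bool = True
    make_plots: bool = False

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "simulate" in data and data["simulate"] is not None:
            sim = dict(data["simulate"])
            if "phantom" in sim and sim["phantom"] is not None:
                sim["phantom"] = _build(PhantomSpec, dict(sim["phantom"]), "phantom")
            data["simulate"] = _build(CohortSimConfig, sim, "simulate")
        for key, klass in (
            ("window", AnteriorWindow), ("icp", ICPParams), ("stats", StatConfig)
        ):
            if key in data and data[key] is not None:
                data[key] = _build(klass, dict(data[key]), key)
        return _build(cls, data, "run config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence([self.seed, _STAGE_SEED_OFFSETS[stage]])
        return int(ss.generate_state(1)[0] % (2**31))


def _config_digest(config: RunConfig) -> str:
    def encode(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (np.ndarray, tuple, list)):
            return [encode(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    blob = json.dumps(encode(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


# -- stages -----------------------------------------------------------------

def stage_simulate(config: RunConfig, run_dir: Path) -> pd.DataFrame:
    if config.simulate is None:
        raise ValueError("config has no simulate block")
    cohort = generate_cohort(config.simulate, seed=config.stage_seed("simulate"))
    return write_cohort(cohort, run_dir / "raw")


def _load_scans(manifest_table: pd.DataFrame) -> dict[str, list[ScanRecord]]:
    out: dict[str, list[ScanRecord]] = {}
    for _, row in manifest_table.iterrows():
        scan = ScanRecord(
            str(row["patient_id"]),
            str(row["timepoint"]),
            read_label_volume(row["body_path"]),
            read_label_volume(row["gas_path"]),
        )
        out.setdefault(scan.patient_id, []).append(scan)
    return out


def stage_clean(config: RunConfig, run_dir: Path) -> pd.DataFrame:
    manifest = read_manifest(run_dir / "raw" / "manifest.csv")
    table = manifest.table.copy()
    clean_dir = run_dir / "cleaned"
    clean_dir.mkdir(parents=True, exist_ok=True)
    for i, row in table.iterrows():
        scan = ScanRecord(
            str(row["patient_id"]), str(row["timepoint"]),
            read_label_volume(row["body_path"]),
            read_label_volume(row["gas_path"]),
        )
        cleaned = clean_scan(scan, min_component_ml=config.min_component_ml)
        stem = f"{scan.patient_id}_{scan.timepoint}"
        body_path = clean_dir / f"{stem}_body.nii.gz"
        gas_path = clean_dir / f"{stem}_gas.nii.gz"
        write_label_volume(cleaned.body, body_path)
        write_label_volume(cleaned.gas, gas_path)
        table.loc[i, "body_path"] = str(body_path)
        table.loc[i, "gas_path"] = str(gas_path)
    table.to_csv(clean_dir / "manifest.csv", index=False, float_format="%.12g")
    return table


def stage_metrics(config: RunConfig, run_dir: Path) -> None:
    manifest = read_manifest(run_dir / "cleaned" / "manifest.csv")
    scans = _load_scans(manifest.table)
    params = MetricParams(window=config.window, icp=config.icp)
    fractions, patients = compute_cohort_metrics(scans, params)
    cov = manifest.covariates()
    patients = patients.merge(cov, on="patient_id")
    write_metrics_table(fractions, patients, run_dir / "metrics.csv")

    if config.sensitivity:
        refs = choose_sensitivity_references(
            {pid: [s.timepoint for s in ss] for pid, ss in scans.items()},
            seed=config.stage_seed("metrics"),
        )
        params_s = MetricParams(
            window=config.window, icp=config.icp,
            include_planning=False, reference=refs,
        )
        frac_s, pat_s = compute_cohort_metrics(scans, params_s)
        pat_s = pat_s.merge(cov, on="patient_id")
        write_metrics_table(frac_s, pat_s, run_dir / "metrics_sensitivity.csv")


def _run_stats(fractions: pd.DataFrame, patients: pd.DataFrame, cfg: StatConfig):
    table = CohortTable.from_frames(
        patients, fractions, age_cutoff_years=cfg.age_cutoff_years
    )
    analyses = {
        "predictors": lambda: run_predictor_analysis(table, cfg),
        "correlations": lambda: run_correlation_analysis(table, cfg),
        "associations": lambda: run_association_analysis(table, cfg),
        "multivariate": lambda: run_multivariate_analysis(table),
    }
    results = {}
    for name, fn in analyses.items():
        try:
            results[name] = fn()
        except ValueError as exc:
            # cohorts too small for an analysis report the reason instead
            results[name] = pd.DataFrame([{"error": str(exc)}])
    return results


def stage_stats(config: RunConfig, run_dir: Path) -> dict:
    stats_dir = run_dir / "stats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.replace(config.stats, seed=config.stage_seed("stats"))
    fractions, patients = read_metrics_table(run_dir / "metrics.csv")
    results = _run_stats(fractions, patients, cfg)
    for name, frame in results.items():
        frame.to_csv(stats_dir / f"{name}.csv", index=False, float_format="%.12g")
    sens_path = run_dir / "metrics_sensitivity.csv"
    if config.sensitivity and sens_path.exists():
        frac_s, pat_s = read_metrics_table(sens_path)
        for name, frame in _run_stats(frac_s, pat_s, cfg).items():
            frame.to_csv(
                stats_dir / f"{name}_sensitivity.csv", index=False,
                float_format="%.12g",
            )
    return results


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages; returns the run directory.

    Fails loudly with the stage name on any stage error; writes a provenance
    record sufficient to reproduce the run bit-identically.
    """
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    stages = [
        ("simulate", stage_simulate),
        ("clean", stage_clean),
        ("metrics", stage_metrics),
        ("stats", stage_stats),
    ]
    log = []
    for name, fn in stages:
        if name == "simulate" and config.simulate is None:
            # external data: copy the user's manifest into the raw slot
            if config.manifest_path is None:
                raise RuntimeError("stage simulate: no simulate block and no manifest_path")
            raw = run_dir / "raw"
            raw.mkdir(parents=True, exist_ok=True)
            read_manifest(config.manifest_path).table.to_csv(
                raw / "manifest.csv", index=False, float_format="%.12g"
            )
            log.append(name)
            continue
        try:
            fn(config, run_dir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log.append(name)

    if config.make_plots:
        from .plots import make_run_figures

        make_run_figures(run_dir)

    provenance = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config_sha256": _config_digest(config),
        "seed": config.seed,
        "stages": log,
    }
    (run_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return run_dir
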