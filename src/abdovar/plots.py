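"""Cohort figures: predictor boxplots and gas-correlation scatters."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .io import read_metrics_table


def predictor_boxplots(patients: pd.DataFrame, path: Path) -> Path:
    """Boxplots of Gas_std by age group and anaesthesia, and of body-contour
    variation by feeding tube."""
    panels = [
        ("age_group", "gas_std_ml", "Gas$_{std}$ [ml]"),
        ("ga", "gas_std_ml", "Gas$_{std}$ [ml]"),
        ("feeding_tube", "body_avg_unsigned_mm", "Body$_{avg}$(unsigned) [mm]"),
    ]
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2))
    for ax, (var, metric, label) in zip(axes, panels):
        groups = [
            (str(level), grp[metric].dropna().values)
            for level, grp in patients.groupby(var)
        ]
        ax.boxplot([g[1] for g in groups], tick_labels=[g[0] for g in groups])
        ax.set_xlabel(var)
        ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def correlation_scatters(
    fractions: pd.DataFrame, correlations: pd.DataFrame, path: Path
) -> Path:
    """Gas_rel against each correlated metric with its regression line."""
    metrics = list(correlations["metric"])
    ncol = 4
    nrow = (len(metrics) + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.0 * ncol, 2.6 * nrow))
    gas = fractions["gas_rel_ml"].values
    for ax, metric in zip(axes.ravel(), metrics):
        row = correlations[correlations["metric"] == metric].iloc[0]
        ax.scatter(gas, fractions[metric], s=8, alpha=0.6)
        xs = pd.Series(gas).quantile([0.01, 0.99]).values
        ax.plot(xs, row["slope"] * xs + row["intercept"], "r-", lw=1)
        ax.set_title(f"{metric} (R={row['rho']:.2f})", fontsize=9)
        ax.set_xlabel("Gas$_{rel}$ [ml]", fontsize=8)
    for ax in axes.ravel()[len(metrics):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def make_run_figures(run_dir: str | Path) -> list[Path]:
    run_dir = Path(run_dir)
    fig_dir = run_dir / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    fractions, patients = read_metrics_table(run_dir / "metrics.csv")
    if "age_group" not in patients.columns:
        patients = patients.copy()
        patients["age_group"] = patients["age_years"] < 3.5
    out = [predictor_boxplots(patients, fig_dir / "predictors.png")]
    corr_path = run_dir / "stats" / "correlations.csv"
    if corr_path.exists():
        correlations = pd.read_csv(corr_path)
        out.append(
            correlation_scatters(fractions, correlations, fig_dir / "correlations.png")
        )
    return out
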