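"""Cohort statistics: predictor tests, correlations, exact conditional
logistic regression, multivariate regression and the sensitivity re-analysis.

Small-sample inference is exact wherever the cohort sizes this design deals
with (~21 patients) allow it: the Mann-Whitney test enumerates the full
conditional rank distribution (midranks for ties) up to 20 observations, the
Spearman p-value enumerates all rank permutations up to n = 9, and the
logistic association of a binary outcome with a continuous covariate is
tested conditionally on the outcome total (the one non-routine estimator
here, so it is implemented from first principles rather than delegated).
All p-values are two-sided unless stated; significance threshold defaults to
0.05 with no multiplicity correction (a Holm-adjusted column is emitted
alongside for reference).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

_TOL = 1e-9


@dataclass(frozen=True)
class StatConfig:
    alpha: float = 0.05
    exact_test_n_threshold: int = 20
    mc_samples: int = 100_000
    seed: int = 0
    include_planning: bool = True
    age_cutoff_years: float = 3.5

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


# -- Mann-Whitney -----------------------------------------------------------

@dataclass
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    method: str
    n_a: int
    n_b: int


def _rank_sum_distribution(ranks2: np.ndarray, n_a: int) -> np.ndarray:
    """Counts of doubled-rank sums over all C(n, n_a) group-A assignments.

    Midranks doubled to integers; dynamic programme over (chosen count, sum).
    Returns an array ``counts`` where ``counts[s]`` is the number of subsets
    of size ``n_a`` with doubled-rank sum ``s``.
    """
    total = int(ranks2.sum())
    table = np.zeros((n_a + 1, total + 1), dtype=float)
    table[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        upper = min(n_a, len(ranks2))
        for k in range(upper - 1, -1, -1):
            row = table[k]
            nz = np.flatnonzero(row)
            if nz.size:
                table[k + 1, nz + r] += row[nz]
    return table[n_a]


def mann_whitney_test(
    group_a, group_b, exact_threshold: int = 20
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney test, exact by enumeration for small samples.

    For ``n_a + n_b <= exact_threshold`` the conditional distribution of the
    rank sum (midranks for ties) is enumerated exactly; otherwise the normal
    approximation with tie correction is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) < _TOL:
        warnings.warn("all values identical across both groups", stacklevel=2)
        return MannWhitneyResult(
            len(a) * len(b) / 2.0, 1.0, "degenerate", len(a), len(b)
        )
    ranks = sps.rankdata(pooled)
    t_obs = ranks[: len(a)].sum()
    u_obs = t_obs - len(a) * (len(a) + 1) / 2.0

    if len(pooled) <= exact_threshold:
        ranks2 = np.rint(2 * ranks).astype(int)
        counts = _rank_sum_distribution(ranks2, len(a))
        total = counts.sum()
        s_obs = int(round(2 * t_obs))
        p_le = counts[: s_obs + 1].sum() / total
        p_ge = counts[s_obs:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "asymptotic"
    return MannWhitneyResult(float(u_obs), float(p), method, len(a), len(b))


# -- Spearman ---------------------------------------------------------------

@dataclass
class SpearmanResult:
    rho: float
    p_value: float
    method: str
    n: int


def spearman_correlation(x, y, exact_max_n: int = 9) -> SpearmanResult:
    """Spearman rank correlation with exact permutation p for n <= 9."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) < _TOL or np.ptp(y) < _TOL:
        raise ValueError("zero variance in x or y")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(ry)))
        stat = perms @ rx  # rho is monotone in this sum
        centre = n * rx.mean() * ry.mean()
        p = float(
            np.mean(np.abs(stat - centre) >= abs((ry @ rx) - centre) - _TOL)
        )
        method = "exact"
    else:
        if abs(rho) >= 1.0 - 1e-12:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2 * sps.t.sf(abs(t), df=n - 2))
        method = "t-approx"
    return SpearmanResult(rho, p, method, n)


# -- exact conditional logistic regression ---------------------------------

@dataclass
class ExactLogisticResult:
    coef: float
    p_two_sided: float
    p_one_sided: float
    boundary: bool
    method: str
    n: int


def _conditional_stats(
    x: np.ndarray, m: int, max_enum: int, mc_samples: int, seed: int
) -> tuple[np.ndarray, str]:
    """Values of T = sum(x[S]) over size-m subsets (full enumeration or MC)."""
    n = len(x)
    from math import comb

    if comb(n, m) <= max_enum:
        idx = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(n), m)),
            dtype=np.intp,
        ).reshape(-1, m)
        return x[idx].sum(axis=1), "enumeration"
    rng = np.random.default_rng(seed)
    draws = np.empty(mc_samples)
    for i in range(mc_samples):
        draws[i] = x[rng.choice(n, size=m, replace=False)].sum()
    return draws, "monte-carlo"


def exact_logistic_binary(
    y,
    x,
    max_enum: int = 2_000_000,
    mc_samples: int = 100_000,
    seed: int = 0,
) -> ExactLogisticResult:
    """Exact conditional logistic regression of a binary outcome on one
    continuous covariate.

    Inference conditions on the observed outcome total: under the null the
    sufficient statistic ``T = sum(x_i y_i)`` is uniform over all outcome
    vectors with the same total, giving the exact conditional p-value. The
    coefficient is the conditional maximum-likelihood estimate (solving
    ``E_beta[T] = T_obs``); when the observed T sits on the boundary of the
    conditional support (complete separation) the median-unbiased estimate
    is returned and the result flagged.
    """
    y = np.asarray(y).astype(int)
    x = np.asarray(x, dtype=float)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("y must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("y must contain both classes")
    m = int(y.sum())
    t_obs = float(x[y == 1].sum())
    if np.ptp(x) < _TOL:
        return ExactLogisticResult(0.0, 1.0, 0.5, False, "degenerate", len(y))

    t_vals, method = _conditional_stats(x, m, max_enum, mc_samples, seed)
    p_le = float(np.mean(t_vals <= t_obs + _TOL))
    p_ge = float(np.mean(t_vals >= t_obs - _TOL))
    p_one = min(p_le, p_ge)
    p_two = min(1.0, 2.0 * p_one)

    t_min, t_max = t_vals.min(), t_vals.max()
    at_upper = t_obs >= t_max - _TOL
    at_lower = t_obs <= t_min + _TOL
    boundary = bool(at_upper or at_lower)

    centred = t_vals - t_vals.mean()  # stabilises the exponentials

    def mean_t(beta: float) -> float:
        w = np.exp(beta * centred - (beta * centred).max())
        return float((t_vals * w).sum() / w.sum())

    def tail_prob(beta: float, upper: bool) -> float:
        w = np.exp(beta * centred - (beta * centred).max())
        mask = t_vals >= t_obs - _TOL if upper else t_vals <= t_obs + _TOL
        return float(w[mask].sum() / w.sum())

    scale = max(np.ptp(t_vals), _TOL)
    lo, hi = -200.0 / scale, 200.0 / scale
    from scipy.optimize import brentq

    if not boundary:
        f = lambda beta: mean_t(beta) - t_obs
        coef = float(brentq(f, lo, hi, xtol=1e-10))
    else:
        # median-unbiased estimate at the boundary
        if at_upper:
            f = lambda beta: tail_prob(beta, upper=True) - 0.5
        else:
            f = lambda beta: tail_prob(beta, upper=False) - 0.5
        coef = float(brentq(f, lo, hi, xtol=1e-10))
    return ExactLogisticResult(coef, p_two, p_one, boundary, method, len(y))


# -- ordinary least squares -------------------------------------------------

def multivariate_ols(response, covariates: pd.DataFrame):
    """OLS with intercept and t-based p-values; names collinear columns."""
    X = pd.DataFrame(covariates).astype(float)
    y = np.asarray(response, dtype=float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > number of covariates + 1")
    design = sm.add_constant(X)
    rank = np.linalg.matrix_rank(design.values)
    if rank < design.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        i, j = np.unravel_index(np.nanargmax(corr.values), corr.shape)
        raise ValueError(
            f"design matrix is rank deficient; collinear columns include "
            f"{corr.index[i]!r} and {corr.columns[j]!r}"
        )
    return sm.OLS(y, design).fit()


# -- cohort-level analyses --------------------------------------------------

PREDICTOR_VARIABLES = ("sex", "age_group", "ga", "feeding_tube")
PREDICTED_METRICS = ("gas_std_ml", "body_avg_unsigned_mm", "surface_avg_unsigned_mm")
SGRT_PARAMS = ("t_x", "t_y", "t_z", "r_x", "r_y", "r_z")


@dataclass
class CohortTable:
    """Per-patient summaries + per-fraction metrics feeding the statistics."""

    patients: pd.DataFrame
    fractions: pd.DataFrame

    def __post_init__(self) -> None:
        if self.patients["patient_id"].duplicated().any():
            raise ValueError("one summary row per patient required")

    @classmethod
    def from_frames(
        cls,
        patients: pd.DataFrame,
        fractions: pd.DataFrame,
        age_cutoff_years: float = 3.5,
    ) -> "CohortTable":
        patients = patients.copy()
        patients["age_group"] = np.where(
            patients["age_years"] < age_cutoff_years,
            f"<{age_cutoff_years}",
            f">={age_cutoff_years}",
        )
        return cls(patients, fractions.copy())


def _binary_split(patients: pd.DataFrame, variable: str):
    values = patients[variable]
    levels = sorted(values.unique(), key=str)
    if len(levels) != 2:
        return None
    return values == levels[1], levels


def run_predictor_analysis(
    table: CohortTable, cfg: StatConfig | None = None
) -> pd.DataFrame:
    """Mann-Whitney grid: each binary patient variable × each summary metric.

    One row per (variable, metric) cell with the two-sided p-value and a
    significance flag at ``alpha``; a Holm-adjusted column is appended for
    reference. Cells whose groups have fewer than 2 patients are reported as
    not computable.
    """
    cfg = cfg or StatConfig()
    rows = []
    for variable in PREDICTOR_VARIABLES:
        split = _binary_split(table.patients, variable)
        for metric in PREDICTED_METRICS:
            row = dict(variable=variable, metric=metric)
            if split is None:
                row.update(p_value=np.nan, note="variable not binary")
                rows.append(row)
                continue
            mask, levels = split
            vals_a = table.patients.loc[~mask, metric].dropna()
            vals_b = table.patients.loc[mask, metric].dropna()
            row.update(
                group_a=str(levels[0]), group_b=str(levels[1]),
                n_a=len(vals_a), n_b=len(vals_b),
            )
            if len(vals_a) < 2 or len(vals_b) < 2:
                row.update(p_value=np.nan, note="group with < 2 patients")
            else:
                res = mann_whitney_test(
                    vals_a, vals_b, exact_threshold=cfg.exact_test_n_threshold
                )
                row.update(
                    u_statistic=res.u_statistic, p_value=res.p_value,
                    method=res.method, note="",
                )
            rows.append(row)
    out = pd.DataFrame(rows)
    out["significant"] = out["p_value"] < cfg.alpha
    out["p_holm"] = _holm(out["p_value"].values)
    return out


def _holm(p_values: np.ndarray) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    ps = p[ok]
    order = np.argsort(ps)
    m = len(ps)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * ps[idx])
        adj[idx] = min(1.0, running)
    out[ok] = adj
    return out


def run_correlation_analysis(
    table: CohortTable, cfg: StatConfig | None = None
) -> pd.DataFrame:
    """Spearman correlations of per-fraction Gas_rel with the signed
    separation metrics and each SGRT parameter, plus regression lines."""
    cfg = cfg or StatConfig()
    frac = table.fractions
    gas = frac["gas_rel_ml"].values
    rows = []
    metrics = ["body_avg_signed_mm", "surface_avg_signed_mm", *SGRT_PARAMS]
    for metric in metrics:
        vals = frac[metric].values
        res = spearman_correlation(gas, vals, exact_max_n=0)
        slope, intercept = np.polyfit(gas, vals, 1)
        rows.append(
            dict(
                metric=metric, rho=res.rho, p_value=res.p_value, n=res.n,
                slope=float(slope), intercept=float(intercept),
                significant=res.p_value < cfg.alpha,
            )
        )
    return pd.DataFrame(rows)


def run_association_analysis(
    table: CohortTable, cfg: StatConfig | None = None
) -> pd.DataFrame:
    """Patient-level associations: age↔Gas_std (Spearman), GA↔Gas_std and
    GA↔age (exact conditional logistic)."""
    cfg = cfg or StatConfig()
    pat = table.patients
    rows = []
    sp = spearman_correlation(pat["age_years"], pat["gas_std_ml"])
    rows.append(
        dict(
            pair="age~gas_std", statistic="spearman_rho", estimate=sp.rho,
            p_value=sp.p_value, method=sp.method,
        )
    )
    for xcol, label in (("gas_std_ml", "ga~gas_std"), ("age_years", "ga~age")):
        res = exact_logistic_binary(
            pat["ga"].astype(int), pat[xcol],
            mc_samples=cfg.mc_samples, seed=cfg.seed,
        )
        rows.append(
            dict(
                pair=label, statistic="exact_logistic_coef", estimate=res.coef,
                p_value=res.p_two_sided, method=res.method,
                boundary=res.boundary,
            )
        )
    return pd.DataFrame(rows)


def run_multivariate_analysis(
    table: CohortTable, covariates: tuple[str, ...] = ("age_years", "ga")
) -> pd.DataFrame:
    """Multivariate linear model of Gas_std on patient covariates."""
    pat = table.patients
    X = pat[list(covariates)].copy()
    for col in X.columns:
        if X[col].dtype == bool or X[col].dtype == object:
            X[col] = X[col].astype(str).astype("category").cat.codes
    fit = multivariate_ols(pat["gas_std_ml"], X)
    return pd.DataFrame(
        dict(term=fit.params.index, coef=fit.params.values, p_value=fit.pvalues.values)
    )


def choose_sensitivity_references(
    scan_timepoints: dict[str, list[str]], seed: int
) -> dict[str, str]:
    """Seeded random treatment-scan reference per patient (planning excluded).

    Patients with fewer than 2 treatment scans are dropped with a warning.
    """
    rng = np.random.default_rng(seed)
    refs: dict[str, str] = {}
    for pid in sorted(scan_timepoints):
        weekly = [tp for tp in scan_timepoints[pid] if tp != "planning"]
        if len(weekly) < 2:
            warnings.warn(
                f"patient {pid}: fewer than 2 treatment scans, dropped from "
                "sensitivity analysis",
                stacklevel=2,
            )
            continue
        refs[pid] = weekly[int(rng.integers(len(weekly)))]
    return refs
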