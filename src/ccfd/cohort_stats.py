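"""Cohort-level statistics for flow-deficit studies.

Implements the statistical layer used to compare a non-neovascular and a
neovascular group of eyes and to search for clinical factors associated
with the FD metrics:

* group summaries (mean, sample SD, n);
* Fisher's exact test (two-sided, minimum-likelihood rule, exact integer
  arithmetic) for binary imaging flags;
* Mann-Whitney U (exact for small untied samples, otherwise normal
  approximation with tie and continuity corrections) for quantitative
  variables;
* ordinary least squares with a univariate screen (p < 0.20 by default)
  feeding a multivariate model, with configurable log10 transforms of
  outcome and covariates;
* the log-log regression of FD count on mean FD size.

No multiple-testing correction is applied; two-sided p < 0.05 is the
conventional significance level for these cohort tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .image_io import FLAG_COLUMNS, CohortTable

__all__ = [
    "ContingencyTable2x2",
    "RegressionResult",
    "ScreenResult",
    "LogLogFit",
    "Table2",
    "summarize_group",
    "mean_sd",
    "fisher_exact_two_sided",
    "mann_whitney",
    "loglog_size_number_fit",
    "regression_screen",
    "build_table2",
]

QUANTITATIVE_FIELDS = ("age_years", "bcva_logmar", "cmt_um", "ct_um")
DEFAULT_COVARIATES = QUANTITATIVE_FIELDS + FLAG_COLUMNS
#: Covariates conventionally modelled on the log10 scale.
DEFAULT_LOG10_COVARIATES = frozenset({"age_years", "cmt_um", "ct_um"})


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts; rows = group, columns = flag present / absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name, v in zip("abcd", (self.a, self.b, self.c, self.d)):
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")


def mean_sd(values: Sequence[float]) -> tuple[float, float, int]:
    """Arithmetic mean and sample (n-1) standard deviation."""
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n == 0:
        raise ValueError("empty selection")
    sd = float(arr.std(ddof=1)) if n >= 2 else float("nan")
    return float(arr.mean()), sd, int(n)


def summarize_group(
    cohort: CohortTable | pd.DataFrame, fieldname: str, group: str | None = None
) -> tuple[float, float, int]:
    """Mean, sample SD and n of one field, optionally within one group."""
    df = cohort.to_frame() if isinstance(cohort, CohortTable) else cohort
    if group is not None:
        df = df[df["group"] == group]
    if len(df) == 0:
        raise ValueError(f"empty selection for field {fieldname!r}, group {group!r}")
    return mean_sd(df[fieldname].astype(float).to_numpy())


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value by the minimum-likelihood rule.

    Sums the hypergeometric point probabilities of every table with the
    observed margins whose probability does not exceed that of the
    observed table.  Computed in exact integer arithmetic (probabilities
    share the common denominator C(N, row1), so the comparison and the
    sum are both exact); the result is returned as a float.

    A table with any zero margin carries no information; by convention
    p = 1 is returned with a warning.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n_total = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 == 0 or col1 == 0 or row1 == n_total or col1 == n_total:
        warnings.warn("degenerate 2x2 table (zero margin); returning p = 1", stacklevel=2)
        return 1.0
    lo = max(0, row1 + col1 - n_total)
    hi = min(row1, col1)
    # Numerator weights share the denominator C(N, row1); integers are exact.
    weights = {
        k: math.comb(col1, k) * math.comb(n_total - col1, row1 - k)
        for k in range(lo, hi + 1)
    }
    observed = weights[a]
    numerator = sum(w for w in weights.values() if w <= observed)
    p = Fraction(numerator, math.comb(n_total, row1))
    return float(p)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value.

    Uses the exact null distribution when the pooled sample has at most
    20 observations and no ties; otherwise the normal approximation with
    tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 20 and no_ties) else "asymptotic"
    result = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(result.pvalue)


@dataclass
class LogLogFit:
    """OLS fit of log10(FD count) on log10(mean FD size)."""

    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    slope_ci: tuple[float, float]
    n: int


def loglog_size_number_fit(
    n_fd: Sequence[float], mean_fd_size_um2: Sequence[float]
) -> LogLogFit:
    """Regress log10(FD count) on log10(mean FD size) across eyes.

    Both inputs must be strictly positive; the fit needs at least two
    eyes (two points determine the line exactly, three or more give a
    meaningful residual).
    """
    import statsmodels.api as sm

    n_arr = np.asarray(n_fd, dtype=float)
    s_arr = np.asarray(mean_fd_size_um2, dtype=float)
    if n_arr.size != s_arr.size:
        raise ValueError("count and size vectors differ in length")
    bad = np.flatnonzero((n_arr <= 0) | (s_arr <= 0))
    if bad.size:
        raise ValueError(
            f"log-log fit needs positive counts and sizes; offending eye index(es): {bad.tolist()}"
        )
    if n_arr.size < 2:
        raise ValueError("log-log fit needs at least 2 eyes")
    y = np.log10(n_arr)
    x = sm.add_constant(np.log10(s_arr))
    fit = sm.OLS(y, x).fit()
    ci = fit.conf_int()
    return LogLogFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        slope_se=float(fit.bse[1]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        n=int(n_arr.size),
    )


@dataclass
class RegressionResult:
    """One covariate's row in a univariate or multivariate OLS table."""

    outcome: str
    covariate: str
    coefficient: float
    std_err: float
    p_value: float
    ci_low: float
    ci_high: float
    stage: str  # "univariate" | "multivariate"
    log10_outcome: bool
    log10_covariate: bool


@dataclass
class ScreenResult:
    """Univariate screen plus the multivariate model it selects."""

    outcome: str
    univariate: list[RegressionResult]
    multivariate: list[RegressionResult]
    selected: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "stage": r.stage,
                "outcome": r.outcome,
                "covariate": r.covariate,
                "coefficient": r.coefficient,
                "std_err": r.std_err,
                "p_value": r.p_value,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
            }
            for r in self.univariate + self.multivariate
        ]
        return pd.DataFrame(rows)


def _design_column(df: pd.DataFrame, name: str, log10_covariates: frozenset) -> np.ndarray:
    col = df[name].astype(float).to_numpy()
    if name in log10_covariates:
        if np.any(col <= 0):
            raise ValueError(f"covariate {name!r} must be positive for a log10 transform")
        col = np.log10(col)
    return col


def _check_collinearity(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        dependent = []
        for j in range(1, design.shape[1]):  # skip intercept
            others = np.delete(design, j, axis=1)
            resid = design[:, j] - others @ np.linalg.lstsq(others, design[:, j], rcond=None)[0]
            if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(design[:, j])):
                dependent.append(names[j - 1])
        raise ValueError(f"collinear covariate set; dependent column(s): {dependent}")


def regression_screen(
    cohort: CohortTable | pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    *,
    screen_threshold: float = 0.20,
    forced: Sequence[str] = (),
    log10_outcome: bool = True,
    log10_covariates: Iterable[str] = DEFAULT_LOG10_COVARIATES,
) -> ScreenResult:
    """Univariate OLS screen feeding a multivariate OLS model.

    Stage 1 regresses the outcome on each covariate alone; stage 2 fits a
    single model on every covariate with univariate p below
    ``screen_threshold`` plus any ``forced`` covariates (the explicit,
    reproducible replacement for an "or clinical significance" clause).
    ``log10_outcome`` / ``log10_covariates`` control the transforms; by
    convention the FD outcomes and age/CMT/CT are modelled in log10.
    """
    import statsmodels.api as sm

    df = cohort.to_frame() if isinstance(cohort, CohortTable) else cohort
    log10_cov = frozenset(log10_covariates)
    y = df[outcome].astype(float).to_numpy()
    if log10_outcome:
        if np.any(y <= 0):
            raise ValueError(f"outcome {outcome!r} must be positive for a log10 transform")
        y = np.log10(y)

    def fit_model(names: list[str], stage: str) -> list[RegressionResult]:
        cols = [_design_column(df, n, log10_cov) for n in names]
        design = sm.add_constant(np.column_stack(cols))
        if stage == "multivariate":
            _check_collinearity(design, names)
        fit = sm.OLS(y, design).fit()
        ci = fit.conf_int()
        return [
            RegressionResult(
                outcome=outcome,
                covariate=name,
                coefficient=float(fit.params[j + 1]),
                std_err=float(fit.bse[j + 1]),
                p_value=float(fit.pvalues[j + 1]),
                ci_low=float(ci[j + 1][0]),
                ci_high=float(ci[j + 1][1]),
                stage=stage,
                log10_outcome=log10_outcome,
                log10_covariate=name in log10_cov,
            )
            for j, name in enumerate(names)
        ]

    univariate = [r for name in covariates for r in fit_model([name], "univariate")]
    by_name = {r.covariate: r for r in univariate}
    selected = [
        name
        for name in covariates
        if by_name[name].p_value < screen_threshold or name in forced
    ]
    multivariate = fit_model(selected, "multivariate") if selected else []
    return ScreenResult(
        outcome=outcome, univariate=univariate, multivariate=multivariate, selected=selected
    )


@dataclass
class Table2:
    """Group-comparison table plus the neovascular prevalence."""

    table: pd.DataFrame
    n_non_neovascular: int
    n_neovascular: int

    @property
    def prevalence_percent(self) -> float:
        total = self.n_non_neovascular + self.n_neovascular
        return 100.0 * self.n_neovascular / total


def build_table2(
    cohort: CohortTable, extra_quantitative: Sequence[str] = ()
) -> Table2:
    """Compare the non-neovascular and neovascular groups.

    Quantitative fields get group mean (SD) and a Mann-Whitney p-value;
    binary flags get group counts (%) and a Fisher exact p-value.
    """
    counts = cohort.group_counts()
    n_non, n_neo = counts["non_neovascular"], counts["neovascular"]
    if n_non == 0 or n_neo == 0:
        raise ValueError(
            f"both groups must be nonempty (non_neovascular={n_non}, neovascular={n_neo})"
        )
    df = cohort.to_frame()
    non = df[df["group"] == "non_neovascular"]
    neo = df[df["group"] == "neovascular"]
    rows = []
    for fieldname in tuple(QUANTITATIVE_FIELDS) + tuple(extra_quantitative):
        xs = non[fieldname].astype(float).to_numpy()
        ys = neo[fieldname].astype(float).to_numpy()
        rows.append(
            {
                "variable": fieldname,
                "kind": "quantitative",
                "non_neovascular": f"{xs.mean():.2f} (±{xs.std(ddof=1):.2f})",
                "neovascular": f"{ys.mean():.2f} (±{ys.std(ddof=1):.2f})",
                "p_value": mann_whitney(xs, ys),
                "test": "mann_whitney",
            }
        )
    for flag in FLAG_COLUMNS:
        a = int(neo[flag].sum())
        b = n_neo - a
        c = int(non[flag].sum())
        d = n_non - c
        rows.append(
            {
                "variable": flag,
                "kind": "flag",
                "non_neovascular": f"{c} ({100.0 * c / n_non:.2f}%)",
                "neovascular": f"{a} ({100.0 * a / n_neo:.2f}%)",
                "p_value": fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d)),
                "test": "fisher_exact",
            }
        )
    return Table2(table=pd.DataFrame(rows), n_non_neovascular=n_non, n_neovascular=n_neo)
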