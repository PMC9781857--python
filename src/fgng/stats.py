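"""Factorial statistics for per-animal fGNG (and other cohort responses).

The cohort is an unbalanced 2x2 between-subjects design (feeding AL/CR x
injury Con/TBI, n = 3/6/6/5).  The battery mirrors common practice with
SPSS-style defaults: two-way ANOVA with Type III sums of squares and
sum-to-zero contrasts, pooled-variance (Student) independent t-tests with
Welch available behind a flag, and Tukey's HSD post hoc in its Tukey-Kramer
form for unequal cell sizes.  ``anova_from_summary`` rebuilds the same
Type III table from per-cell (mean, sd, n) summaries alone, via the
closed-form weighted cell-means decomposition, and serves as an independent
cross-check on the raw-data route.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import DegenerateDataError, DesignError, DomainError

__all__ = [
    "AnimalRecord",
    "AnovaTable",
    "TTestResult",
    "two_way_anova",
    "independent_t_test",
    "tukey_hsd",
    "anova_from_summary",
    "FEEDING_LEVELS",
    "INJURY_LEVELS",
    "TIMEPOINTS",
]

FEEDING_LEVELS = ("AL", "CR")
INJURY_LEVELS = ("Con", "TBI")
TIMEPOINTS = ("pre", "post")


@dataclass(frozen=True)
class AnimalRecord:
    """One animal at one timepoint with its estimated fGNG."""

    animal_id: str
    feeding: str
    injury: str
    timepoint: str
    fgng: float
    weight_g: float | None = None
    food_g: float | None = None
    glucose_mg_dl: float | None = None

    def __post_init__(self) -> None:
        if self.feeding not in FEEDING_LEVELS:
            raise DomainError(f"feeding must be one of {FEEDING_LEVELS}, got {self.feeding!r}")
        if self.injury not in INJURY_LEVELS:
            raise DomainError(f"injury must be one of {INJURY_LEVELS}, got {self.injury!r}")
        if self.timepoint not in TIMEPOINTS:
            raise DomainError(f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}")
        if not 0.0 <= self.fgng <= 1.0:
            raise DomainError(f"fgng must be in [0, 1], got {self.fgng}")


@dataclass(frozen=True)
class EffectRow:
    sum_sq: float
    df: float
    F: float | None
    p: float | None


@dataclass(frozen=True)
class AnovaTable:
    """Per-effect decomposition: factor mains, interaction, residual."""

    effects: Mapping[str, EffectRow]

    def __getitem__(self, effect: str) -> EffectRow:
        return self.effects[effect]

    def to_frame(self) -> pd.DataFrame:
        rows = {
            name: {"sum_sq": e.sum_sq, "df": e.df, "F": e.F, "p": e.p}
            for name, e in self.effects.items()
        }
        return pd.DataFrame.from_dict(rows, orient="index")


def _as_frame(
    records: Iterable[AnimalRecord] | pd.DataFrame, response: str
) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([vars(r) for r in records])
    if response not in df.columns:
        raise DomainError(f"response column {response!r} missing")
    return df.dropna(subset=[response])


def _check_design(df: pd.DataFrame, factors: Sequence[str]) -> None:
    fa, fb = factors
    counts = df.groupby([fa, fb], observed=True).size()
    for a in df[fa].unique():
        for b in df[fb].unique():
            if (a, b) not in counts.index:
                raise DesignError(f"empty design cell {fa}={a!r} x {fb}={b!r}")
    n_cells = counts.size
    if n_cells < 2:
        raise DesignError("need >= 2 populated cells")
    if len(df) - n_cells < 1:
        raise DesignError(
            f"residual df = {len(df) - n_cells} < 1 (n={len(df)}, cells={n_cells})"
        )


def two_way_anova(
    records: Iterable[AnimalRecord] | pd.DataFrame,
    response: str = "fgng",
    factors: Sequence[str] = ("feeding", "injury"),
    ss_type: int = 3,
) -> AnovaTable:
    """Two-way ANOVA with interaction on an (possibly unbalanced) design.

    Type III sums of squares with sum-to-zero contrasts by default (the
    SPSS GLM convention); ``ss_type=1`` gives sequential sums of squares.
    """
    if ss_type not in (1, 3):
        raise DomainError(f"ss_type must be 1 or 3, got {ss_type}")
    df = _as_frame(records, response)
    fa, fb = factors
    _check_design(df, factors)
    formula = f'Q("{response}") ~ C(Q("{fa}"), Sum) * C(Q("{fb}"), Sum)'
    fit = ols(formula, data=df).fit()
    table = anova_lm(fit, typ=ss_type)

    term_a = f'C(Q("{fa}"), Sum)'
    term_b = f'C(Q("{fb}"), Sum)'
    term_ab = f"{term_a}:{term_b}"
    resid = table.loc["Residual"]
    resid_ms = resid["sum_sq"] / resid["df"] if resid["df"] > 0 else np.nan

    def _effect(row: pd.Series) -> EffectRow:
        ss, dof = float(row["sum_sq"]), float(row["df"])
        if resid["sum_sq"] <= 1e-12 * max(1.0, ss):
            # zero residual variance: boundary case reported as F=inf, p=0
            f = np.inf if ss > 0 else 0.0
            p = 0.0 if ss > 0 else 1.0
        else:
            f = (ss / dof) / resid_ms
            p = float(sps.f.sf(f, dof, resid["df"]))
        return EffectRow(sum_sq=ss, df=dof, F=float(f), p=p)

    effects = {
        fa: _effect(table.loc[term_a]),
        fb: _effect(table.loc[term_b]),
        "interaction": _effect(table.loc[term_ab]),
        "residual": EffectRow(float(resid["sum_sq"]), float(resid["df"]), None, None),
    }
    return AnovaTable(effects=effects)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def independent_t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    variant: str = "student",
) -> TTestResult:
    """Two-sided independent-samples t-test.

    ``variant="student"`` (pooled variance, the SPSS-reported default line)
    or ``"welch"``.  Zero variance in both groups with equal means returns
    t=0, p=1 by convention; with unequal means there is no finite statistic
    and an error is raised.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateDataError(f"each group needs n >= 2, got {a.size} and {b.size}")
    if variant not in ("student", "welch"):
        raise DomainError(f"variant must be 'student' or 'welch', got {variant!r}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=float(a.size + b.size - 2), p=1.0)
        raise DegenerateDataError("zero variance in both groups with unequal means")
    res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def tukey_hsd(
    records: Iterable[AnimalRecord] | pd.DataFrame,
    response: str = "fgng",
    factors: Sequence[str] = ("feeding", "injury"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons across the factorial cells.

    Cells are labeled ``"<feeding>:<injury>"``; unequal cell sizes use the
    Tukey-Kramer harmonic-mean form (statsmodels' default).  Returns a frame
    with columns group1, group2, mean_diff, p_adj, lower, upper, reject.
    """
    df = _as_frame(records, response)
    _check_design(df, factors)
    labels = df[factors[0]].astype(str) + ":" + df[factors[1]].astype(str)
    values = df[response].to_numpy(dtype=float)

    cell_means = pd.Series(values).groupby(labels.to_numpy()).mean()
    within_var = pd.Series(values).groupby(labels.to_numpy()).var(ddof=1)
    if np.nansum(within_var.to_numpy()) == 0:
        # degenerate zero-variance design: identical cells are indistinguishable
        # (p=1); separated cells differ with certainty (p=0)
        rows = []
        cells = sorted(cell_means.index)
        for i, g1 in enumerate(cells):
            for g2 in cells[i + 1 :]:
                diff = cell_means[g2] - cell_means[g1]
                p = 1.0 if diff == 0 else 0.0
                rows.append(
                    {"group1": g1, "group2": g2, "mean_diff": diff,
                     "p_adj": p, "lower": diff, "upper": diff, "reject": p < alpha}
                )
        return pd.DataFrame(rows)

    res = pairwise_tukeyhsd(values, labels.to_numpy(), alpha=alpha)
    groups = res.groupsunique
    rows = []
    k = 0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append(
                {
                    "group1": groups[i],
                    "group2": groups[j],
                    "mean_diff": float(res.meandiffs[k]),
                    "p_adj": float(res.pvalues[k]),
                    "lower": float(res.confint[k, 0]),
                    "upper": float(res.confint[k, 1]),
                    "reject": bool(res.reject[k]),
                }
            )
            k += 1
    return pd.DataFrame(rows)


def _sum_coding(levels: Sequence[str]) -> dict[str, np.ndarray]:
    """Sum-to-zero contrast rows per level (last level = -1 on all columns)."""
    k = len(levels)
    coding = {}
    for i, level in enumerate(levels):
        row = np.zeros(k - 1)
        if i < k - 1:
            row[i] = 1.0
        else:
            row[:] = -1.0
        coding[level] = row
    return coding


def anova_from_summary(
    summary: pd.DataFrame,
    factors: Sequence[str] = ("feeding", "injury"),
) -> AnovaTable:
    """Type III two-way ANOVA from per-cell (mean, sd, n) summaries only.

    Implements the weighted cell-means decomposition directly: with X the
    cell-level sum-coded design matrix and W = diag(n), the effect sum of
    squares for coefficient block J of beta = (X'WX)^-1 X'W m is
    beta_J' [ (X'WX)^-1 ]_JJ^-1 beta_J, and the residual sum of squares is
    sum (n_i - 1) sd_i^2.  On any raw dataset sharing the summaries this
    reproduces :func:`two_way_anova` exactly; no statsmodels machinery is
    involved, so the two routes are independent.

    ``summary`` needs columns ``factors[0]``, ``factors[1]``, ``mean``,
    ``sd``, ``n``; one row per populated cell, n >= 2 everywhere.
    """
    fa, fb = factors
    for col in (fa, fb, "mean", "sd", "n"):
        if col not in summary.columns:
            raise DomainError(f"summary column {col!r} missing")
    if (summary["n"] < 2).any():
        raise DegenerateDataError("every cell needs n >= 2 to carry a variance")
    if summary.duplicated(subset=[fa, fb]).any():
        raise DesignError("duplicate cells in summary")

    levels_a = sorted(summary[fa].unique())
    levels_b = sorted(summary[fb].unique())
    for a in levels_a:
        for b in levels_b:
            if not ((summary[fa] == a) & (summary[fb] == b)).any():
                raise DesignError(f"empty design cell {fa}={a!r} x {fb}={b!r}")

    code_a = _sum_coding(levels_a)
    code_b = _sum_coding(levels_b)
    da, db = len(levels_a) - 1, len(levels_b) - 1

    X_rows, w, m = [], [], []
    for _, row in summary.iterrows():
        ca, cb = code_a[row[fa]], code_b[row[fb]]
        X_rows.append(np.concatenate([[1.0], ca, cb, np.outer(ca, cb).ravel()]))
        w.append(float(row["n"]))
        m.append(float(row["mean"]))
    X = np.array(X_rows)
    W = np.diag(w)
    M = X.T @ W @ X
    Minv = np.linalg.inv(M)
    beta = Minv @ X.T @ W @ np.array(m)

    idx_a = np.arange(1, 1 + da)
    idx_b = np.arange(1 + da, 1 + da + db)
    idx_ab = np.arange(1 + da + db, 1 + da + db + da * db)

    def _ss(idx: np.ndarray) -> float:
        bj = beta[idx]
        return float(bj @ np.linalg.solve(Minv[np.ix_(idx, idx)], bj))

    ss_res = float(((summary["n"] - 1) * summary["sd"] ** 2).sum())
    df_res = float(summary["n"].sum() - len(summary))
    ms_res = ss_res / df_res

    def _effect(ss: float, dof: float) -> EffectRow:
        if ss_res <= 1e-12 * max(1.0, ss):
            f = np.inf if ss > 0 else 0.0
            p = 0.0 if ss > 0 else 1.0
        else:
            f = (ss / dof) / ms_res
            p = float(sps.f.sf(f, dof, df_res))
        return EffectRow(sum_sq=ss, df=dof, F=float(f), p=p)

    effects = {
        fa: _effect(_ss(idx_a), float(da)),
        fb: _effect(_ss(idx_b), float(db)),
        "interaction": _effect(_ss(idx_ab), float(da * db)),
        "residual": EffectRow(ss_res, df_res, None, None),
    }
    return AnovaTable(effects=effects)
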