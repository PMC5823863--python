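"""Gradient profiles, the study's statistical tests, and the true-affinity
correction.

Cell-level measurements (one cell per condition per experimental day = one
replicate) aggregate into mean +/- SEM profiles along distance or incubation
time.  Local concentrations are compared to the added bulk concentration by
one-sample t-tests, and across distances/conditions by two-way ANOVA with
Dunnett (versus a reference level) or Tukey (all pairwise) post-hoc tests.

The micro-pharmacokinetic correction replaces the bulk ligand concentration
in an affinity calculation with the measured local concentration near the
membrane: an apparent Kd measured at bulk concentration L_bulk corresponds
to a true Kd of Kd_app * (L_micro / L_bulk), because occupancy actually
reflects the higher local concentration the receptor saw.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GradientProfile",
    "StatResult",
    "MicroPKResult",
    "build_profile",
    "one_sample_ttest",
    "two_way_anova",
    "posthoc",
    "true_affinity",
]


@dataclass(frozen=True)
class GradientProfile:
    """Mean +/- SEM concentration (and diffusion) along distance or time."""

    condition: str
    axis: Literal["distance", "time"]
    positions: np.ndarray        # um or min, strictly increasing
    mean_conc: np.ndarray        # nM
    sem_conc: np.ndarray         # nM
    n: np.ndarray                # cells per position
    mean_d: np.ndarray | None = None
    sem_d: np.ndarray | None = None

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(np.asarray(self.n) < 1) or np.any(np.asarray(self.sem_conc) < 0):
            raise ValueError("need n >= 1 and sem >= 0")


@dataclass(frozen=True)
class StatResult:
    test: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    comparison: str = ""
    adjusted: bool = False
    flag: str = ""

    def __post_init__(self):
        if np.isfinite(self.p_value) and not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class MicroPKResult:
    """Apparent vs local-concentration-corrected affinity."""

    kd_apparent: float   # nM
    l_bulk: float        # nM
    l_micro: float       # nM
    fold: float          # l_micro / l_bulk
    kd_true: float       # nM


_AXIS_COL = {"distance": "distance_um", "time": "time_min"}


def build_profile(
    measurements: pd.DataFrame,
    condition: str,
    axis: Literal["distance", "time"] = "distance",
) -> GradientProfile:
    """Aggregate a measurement table into a mean +/- SEM profile.

    One row per cell per position is expected (extra rows per cell are
    averaged within the cell first, so each cell stays one replicate).
    Positions with no retained measurements are dropped.
    """
    col = _AXIS_COL[axis]
    sub = measurements[measurements["condition"] == condition]
    if sub.empty:
        raise ValueError(f"no measurements for condition {condition!r}")
    per_cell = (sub.groupby([col, "cell_id"], as_index=False)
                   .agg(conc=("conc_nM", "mean"), d=("diff_coeff_m2s", "mean")))
    g = per_cell.groupby(col)
    mean = g["conc"].mean()
    n = g["conc"].count()
    sd = g["conc"].std(ddof=1).fillna(0.0)
    sem = (sd / np.sqrt(n)).to_numpy()
    mean_d = g["d"].mean().to_numpy()
    sem_d = (g["d"].std(ddof=1).fillna(0.0) / np.sqrt(n)).to_numpy()
    return GradientProfile(
        condition=condition,
        axis=axis,
        positions=mean.index.to_numpy(dtype=float),
        mean_conc=mean.to_numpy(),
        sem_conc=sem,
        n=n.to_numpy(),
        mean_d=mean_d,
        sem_d=sem_d,
    )


def one_sample_ttest(
    values: Sequence[float] | None = None,
    *,
    mean: float | None = None,
    sem: float | None = None,
    n: int | None = None,
    mu0: float,
) -> StatResult:
    """Two-sided one-sample t-test against a fixed value mu0 (nM).

    Accepts either raw per-cell values or a printed summary triple
    (mean, sem, n); the two routes agree exactly when the summary is
    computed from the same values.  t = (mean - mu0)/sem with n-1 df.
    """
    if values is not None:
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValueError("need at least 2 values")
        n = v.size
        mean = float(v.mean())
        sem = float(v.std(ddof=1) / np.sqrt(n))
    if mean is None or sem is None or n is None or n < 2:
        raise ValueError("provide raw values or (mean, sem, n >= 2)")
    if sem == 0:
        if mean == mu0:
            return StatResult("one-sample t", 0.0, (n - 1,), 1.0,
                              f"mean vs {mu0}", flag="zero-variance")
        return StatResult("one-sample t", np.inf, (n - 1,), 0.0,
                          f"mean vs {mu0}", flag="degenerate: sem = 0")
    t = (mean - mu0) / sem
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return StatResult("one-sample t", float(t), (n - 1,), float(p),
                      f"mean vs {mu0}")


def two_way_anova(
    table: pd.DataFrame,
    factor_a: str,
    factor_b: str,
    response: str = "conc_nM",
) -> list[StatResult]:
    """Two-way ANOVA (Type-II sums of squares) with interaction.

    Returns F tests for both main effects and the interaction.  The
    synthetic generator yields balanced designs, where Type-II and Type-I
    agree; unbalanced input triggers a warning flag on the results (Type-II
    tests each main effect adjusted for the other, not for the interaction).
    Zero-variance input is flagged rather than raising.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table[[factor_a, factor_b, response]].dropna().copy()
    for f in (factor_a, factor_b):
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
        df[f] = df[f].astype(str)
    balanced = df.groupby([factor_a, factor_b]).size().nunique() == 1
    flag = "" if balanced else "unbalanced design: Type-II SS"
    if np.allclose(df[response].var(ddof=1), 0.0):
        return [StatResult("two-way ANOVA", np.nan, (np.nan, np.nan), np.nan,
                           comparison=c, flag="zero-variance")
                for c in (factor_a, factor_b, f"{factor_a}:{factor_b}")]
    model = smf.ols(f"Q('{response}') ~ C(Q('{factor_a}')) * C(Q('{factor_b}'))",
                    data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    out = []
    names = {
        f"C(Q('{factor_a}'))": factor_a,
        f"C(Q('{factor_b}'))": factor_b,
        f"C(Q('{factor_a}')):C(Q('{factor_b}'))": f"{factor_a}:{factor_b}",
    }
    resid_df = float(tab.loc["Residual", "df"])
    for row, label in names.items():
        out.append(StatResult(
            "two-way ANOVA",
            float(tab.loc[row, "F"]),
            (float(tab.loc[row, "df"]), resid_df),
            float(tab.loc[row, "PR(>F)"]),
            comparison=label,
            flag=flag,
        ))
    return out


def posthoc(
    table: pd.DataFrame,
    factor: str,
    method: Literal["tukey", "dunnett"] = "tukey",
    reference: str | None = None,
    response: str = "conc_nM",
    by: str | None = None,
) -> list[StatResult]:
    """Family-wise adjusted multiple comparisons after an ANOVA.

    ``tukey`` compares all level pairs of ``factor``; ``dunnett`` compares
    every level against ``reference``.  ``by`` optionally stratifies the
    comparisons within each level of another column (e.g. per distance),
    mirroring per-position condition comparisons.
    """
    if by is not None:
        out = []
        for level, sub in table.groupby(by):
            for r in posthoc(sub, factor, method, reference, response):
                out.append(StatResult(r.test, r.statistic, r.df, r.p_value,
                                      f"{by}={level}: {r.comparison}",
                                      r.adjusted, r.flag))
        return out

    groups = {k: np.asarray(v, dtype=float)
              for k, v in table.groupby(factor)[response]}
    levels = sorted(groups)
    if len(levels) < 2:
        raise ValueError("post-hoc comparison needs >= 2 levels")
    results = []
    if method == "tukey":
        res = sps.tukey_hsd(*[groups[k] for k in levels])
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                results.append(StatResult(
                    "Tukey HSD", float(res.statistic[i, j]), (np.nan,),
                    float(res.pvalue[i, j]),
                    comparison=f"{levels[i]} vs {levels[j]}", adjusted=True))
    elif method == "dunnett":
        if reference is None or reference not in groups:
            raise ValueError("dunnett requires a reference level present in the data")
        others = [k for k in levels if k != reference]
        res = sps.dunnett(*[groups[k] for k in others], control=groups[reference])
        for k, stat, p in zip(others, np.atleast_1d(res.statistic),
                              np.atleast_1d(res.pvalue)):
            results.append(StatResult(
                "Dunnett", float(stat), (np.nan,), float(p),
                comparison=f"{k} vs {reference}", adjusted=True))
    else:
        raise ValueError("method must be 'tukey' or 'dunnett'")
    return results


def true_affinity(kd_apparent: float, l_bulk: float, l_micro: float) -> MicroPKResult:
    """Local-concentration-corrected ("true") affinity.

    fold = L_micro / L_bulk;  Kd_true = Kd_apparent * fold.  A fold > 1
    means the receptor saw more ligand than the bulk phase suggests, so its
    true affinity is weaker (numerically larger Kd) than the apparent one.
    """
    if min(kd_apparent, l_bulk, l_micro) <= 0:
        raise ValueError("all inputs must be positive")
    fold = l_micro / l_bulk
    return MicroPKResult(kd_apparent, l_bulk, l_micro, fold, kd_apparent * fold)
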