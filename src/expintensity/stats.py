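"""Descriptive and inferential statistics for monitoring data.

Covers the summary and hypothesis-testing toolkit used to evaluate the
scoring algorithm against biomarker measurements: geometric-mean/GSD group
summaries, a two-way ANOVA on log concentrations, geometric-mean-ratio and
percent-change calibration arithmetic, Spearman rank correlation, and a
Cuzick-type nonparametric trend test across ordered exposure groups.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import MonitoringRecord
from .synth import eq1_covariates

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "gm_gsd",
    "monitoring_frame",
    "summarize_groups",
    "percent_reduction",
    "gm_ratio",
    "percent_increase",
    "two_way_anova_log",
    "spearman_rho",
    "trend_test",
]


@dataclass(frozen=True)
class GroupSummary:
    """One stratum row of a concentration summary table."""

    stratum: tuple
    n: int
    am: float
    gm: float
    gsd: float  # NaN when n == 1 (undefined)


@dataclass(frozen=True)
class AnovaResult:
    """Per-factor partial F tests from the two-way log-scale ANOVA."""

    p_glove: float
    p_method: float
    f_glove: float
    f_method: float
    df_glove: int
    df_method: int
    df_resid: int


def _round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed tables)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def gm_gsd(values: Sequence[float]) -> tuple[float, float]:
    """Geometric mean and geometric standard deviation.

    ``gm = exp(mean(ln v))``; ``gsd = exp(sd(ln v))`` with the n-1
    denominator.  A single observation has an undefined GSD, reported as
    NaN.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("gm_gsd requires at least one value")
    bad = np.flatnonzero(~(v > 0))
    if bad.size:
        raise ValueError(
            f"all values must be strictly positive; offending indices "
            f"{bad.tolist()} with values {v[bad].tolist()}"
        )
    logs = np.log(v)
    gm = float(np.exp(logs.mean()))
    gsd = float(np.exp(logs.std(ddof=1))) if v.size > 1 else float("nan")
    return gm, gsd


def monitoring_frame(
    records: Iterable[MonitoringRecord],
    method_coded_one=frozenset({"hand_spray"}),
) -> pd.DataFrame:
    """Tabular view of monitoring records for grouping and model fitting.

    Columns: id, method (first reported), gloves, mix, repair, ppe_other
    (0/1 indicators), concentration, analyte.
    """
    rows = []
    for r in records:
        mix, method01, repair, gloves, other = eq1_covariates(
            r, method_coded_one
        )
        rows.append(
            {
                "id": r.id,
                "method": r.methods[0],
                "method01": method01,
                "gloves": gloves,
                "mix": mix,
                "repair": repair,
                "ppe_other": other,
                "concentration": r.concentration,
                "analyte": r.analyte,
            }
        )
    return pd.DataFrame(rows)


def summarize_groups(
    records: Union[Iterable[MonitoringRecord], pd.DataFrame],
    stratifiers: Sequence[str] = ("method", "gloves"),
) -> list[GroupSummary]:
    """N/AM/GM/GSD per stratum of the given factors.

    ``records`` may be monitoring records or a frame from
    :func:`monitoring_frame`; ``stratifiers`` are column names of that
    frame.  Returns one row per nonempty stratum, in sorted stratum order.
    """
    df = (
        records
        if isinstance(records, pd.DataFrame)
        else monitoring_frame(records)
    )
    if df.empty:
        return []
    missing = set(stratifiers) - set(df.columns)
    if missing:
        raise ValueError(f"unknown stratifiers {sorted(missing)}")
    out = []
    for key, grp in df.groupby(list(stratifiers), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        vals = grp["concentration"].to_numpy()
        gm, gsd = gm_gsd(vals)
        out.append(
            GroupSummary(
                stratum=tuple(key),
                n=len(vals),
                am=float(vals.mean()),
                gm=gm,
                gsd=gsd,
            )
        )
    return out


def percent_reduction(gm_with: float, gm_without: float) -> int:
    """Percent reduction of ``gm_with`` relative to ``gm_without``.

    Rounded half away from zero to the nearest integer percent, the
    precision at which such reductions are reported.
    """
    if not (gm_with > 0 and gm_without > 0):
        raise ValueError("geometric means must be positive")
    return int(_round_half_away(100.0 * (1.0 - gm_with / gm_without)))


def gm_ratio(gm_a: float, gm_b: float) -> float:
    """Ratio of two geometric means, rounded to one decimal."""
    if not (gm_a > 0 and gm_b > 0):
        raise ValueError("geometric means must be positive")
    return _round_half_away(gm_a / gm_b, 1)


def percent_increase(a: float, b: float) -> int:
    """Percent by which ``a`` exceeds ``b``, to the nearest integer."""
    if not (a > 0 and b > 0):
        raise ValueError("inputs must be positive")
    return int(_round_half_away(100.0 * (a / b - 1.0)))


def two_way_anova_log(
    records: Union[Iterable[MonitoringRecord], pd.DataFrame],
    factors: Sequence[str] = ("gloves", "method"),
) -> AnovaResult:
    """Main-effects two-way ANOVA of log concentration on two factors.

    Concentrations are log-transformed (they are right-skewed on the raw
    scale); each factor is tested by its partial F statistic, i.e. the
    extra sum of squares over the model holding only the other factor.
    For a main-effects model this matches the Type III (and Type II)
    tests reported by standard GLM software on unbalanced data.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = (
        records.copy()
        if isinstance(records, pd.DataFrame)
        else monitoring_frame(records)
    )
    f1, f2 = factors
    for f in (f1, f2):
        if df[f].nunique() < 2:
            raise ValueError(
                f"factor {f!r} is constant across records; "
                "two-way ANOVA needs >= 2 levels of each factor"
            )
    if (df["concentration"] <= 0).any():
        raise ValueError("concentrations must be positive to log-transform")
    df["_logc"] = np.log(df["concentration"])
    model = smf.ols(f"_logc ~ C({f1}) + C({f2})", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)  # == typ 3 for main effects
    row1, row2 = table.loc[f"C({f1})"], table.loc[f"C({f2})"]
    return AnovaResult(
        p_glove=float(row1["PR(>F)"]),
        p_method=float(row2["PR(>F)"]),
        f_glove=float(row1["F"]),
        f_method=float(row2["F"]),
        df_glove=int(row1["df"]),
        df_method=int(row2["df"]),
        df_resid=int(table.loc["Residual", "df"]),
    )


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN (undefined) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(sps.spearmanr(x, y).statistic)


def _cuzick_stat(
    ranks: np.ndarray, group_idx: np.ndarray, scores: np.ndarray
) -> tuple[float, float, float]:
    """(T, E[T], Var[T]) of the rank trend statistic with tie correction."""
    n = ranks.size
    li = scores[group_idx]
    t_stat = float(li @ ranks)
    ni = np.bincount(group_idx, minlength=scores.size).astype(float)
    sum_l = float(scores @ ni)
    sum_l2 = float((scores**2) @ ni)
    e_t = sum_l * (n + 1) / 2.0
    var_t = (n + 1) / 12.0 * (n * sum_l2 - sum_l**2)
    # tie correction on the rank variance
    _, counts = np.unique(ranks, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n) if n > 1 else 0.0
    return t_stat, e_t, var_t * tie


def trend_test(
    values: Sequence[float],
    groups: Sequence,
    group_scores: Optional[Sequence[float]] = None,
    method: str = "normal",
) -> tuple[float, float]:
    """Nonparametric test for trend across ordered groups.

    An extension of the Wilcoxon rank-sum test to k ordered groups
    (Cuzick's test): observations are ranked jointly (average ranks for
    ties) and the rank sums are weighted by ordered group scores
    (1, 2, ... by default).  Returns ``(z, p)`` with a two-sided p-value
    from the normal approximation, or from the exact permutation null when
    ``method="exact"`` (n <= 10).
    """
    v = np.asarray(values, dtype=float)
    groups = list(groups)
    if len(groups) != v.size:
        raise ValueError("values and groups must have equal length")
    labels = sorted(set(groups))
    if len(labels) < 2:
        raise ValueError("trend test needs >= 2 groups")
    if group_scores is None:
        scores = np.arange(1.0, len(labels) + 1.0)
    else:
        scores = np.asarray(group_scores, dtype=float)
        if scores.size != len(labels):
            raise ValueError("one group score per group required")
    gidx = np.array([labels.index(g) for g in groups])
    ranks = sps.rankdata(v)
    t_obs, e_t, var_t = _cuzick_stat(ranks, gidx, scores)
    if var_t <= 0:
        return 0.0, 1.0
    z = (t_obs - e_t) / math.sqrt(var_t)

    if method == "normal":
        p = 2.0 * sps.norm.sf(abs(z))
    elif method == "exact":
        if v.size > 10:
            raise ValueError("exact permutation null limited to n <= 10")
        li = scores[gidx]
        perms = np.array(list(itertools.permutations(ranks)))
        t_all = perms @ li
        p = float(np.mean(np.abs(t_all - e_t) >= abs(t_obs - e_t) - 1e-12))
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(z), float(min(p, 1.0))
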