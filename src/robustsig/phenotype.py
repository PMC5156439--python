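"""Growth and stress-survival phenotype statistics.

This layer turns CFU counts and growth curves into survival/robustness
phenotypes and provides the descriptive statistics used to characterise a
factorial fermentation design: dynamic ranges, assay-timepoint selection,
Pearson correlations of growth against survival, and per-parameter Welch
t-tests.

Robustness is the log10 reduction in viable counts, ``log10(Nt) -
log10(N0)``, equivalently ``log10(survival_pct / 100)``. All correlation
and t-test work on survival is done on this log scale.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import survival_columns

logger = logging.getLogger(__name__)

__all__ = [
    "GrowthSummary",
    "SurvivalResult",
    "TTestResult",
    "CensoredSurvivalError",
    "estimate_growth",
    "compute_survival",
    "robustness_from_pct",
    "dynamic_range",
    "select_timepoint",
    "pearson",
    "parameter_effect_ttest",
    "phenotype_report",
]


class CensoredSurvivalError(ValueError):
    """All post-stress CFU counts fell below the detection limit."""


@dataclass(frozen=True)
class GrowthSummary:
    """Maximum specific growth rate and final biomass of one fermentation."""

    mu_max: float          # h^-1, steepest slope of ln(OD600) vs time
    od_final: float        # last OD600 reading
    window: tuple[float, float]  # (t_start, t_end) hours of the best window


@dataclass(frozen=True)
class SurvivalResult:
    survival_pct: float
    robustness: float      # log10(Nt) - log10(N0)


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_value: float
    group_means: dict


def estimate_growth(times: Sequence[float], od: Sequence[float],
                    window_points: int = 4) -> GrowthSummary:
    """Estimate mu_max by a sliding log-linear fit over the growth curve.

    Parameters
    ----------
    times : sequence of float
        Sampling times in hours, strictly increasing.
    od : sequence of float
        OD600 readings, all positive.
    window_points : int
        Number of consecutive observations per regression window (>= 3).

    Returns
    -------
    GrowthSummary
        ``mu_max`` is the largest window slope of ln(OD) vs time (clipped
        at zero), ``od_final`` the last reading.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    if window_points < 3:
        raise ValueError("window_points must be >= 3")
    if t.size != y.size or t.size < window_points:
        raise ValueError(
            f"need at least {window_points} paired observations, got {t.size}")
    if np.any(y <= 0):
        raise ValueError("all OD values must be positive")
    log_od = np.log(y)
    best_slope = -np.inf
    best_window = (float(t[0]), float(t[window_points - 1]))
    for i in range(t.size - window_points + 1):
        sl = i, i + window_points
        slope = np.polyfit(t[sl[0]:sl[1]], log_od[sl[0]:sl[1]], 1)[0]
        if slope > best_slope:
            best_slope = slope
            best_window = (float(t[sl[0]]), float(t[sl[1] - 1]))
    return GrowthSummary(mu_max=max(0.0, float(best_slope)),
                         od_final=float(y[-1]), window=best_window)


def compute_survival(n0: Sequence[float], nt: Sequence[float]) -> SurvivalResult:
    """Percent survival and log10 reduction from technical-duplicate CFU counts.

    Duplicates are averaged on the CFU scale before taking the ratio.
    Raises :class:`CensoredSurvivalError` if every post-stress count is
    zero (below the plating detection limit).
    """
    n0 = np.asarray(n0, dtype=float)
    nt = np.asarray(nt, dtype=float)
    if n0.size == 0 or nt.size == 0:
        raise ValueError("need at least one CFU count per side")
    if np.any(n0 <= 0):
        raise ValueError("all pre-stress CFU counts must be positive")
    if np.all(nt == 0):
        raise CensoredSurvivalError(
            "all post-stress CFU counts are zero (below detection limit)")
    if np.any(nt < 0):
        raise ValueError("negative CFU count")
    mean_n0 = float(n0.mean())
    mean_nt = float(nt.mean())
    return SurvivalResult(
        survival_pct=100.0 * mean_nt / mean_n0,
        robustness=float(np.log10(mean_nt) - np.log10(mean_n0)))


def robustness_from_pct(survival_pct):
    """log10 of fractional survival; vectorised."""
    arr = np.asarray(survival_pct, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("survival percentages must be positive")
    return np.log10(arr / 100.0)


def dynamic_range(survival_pcts: Sequence[float]) -> float:
    """log10 ratio of the largest to the smallest survival value."""
    arr = np.asarray(survival_pcts, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two survival values")
    if np.any(arr <= 0):
        raise ValueError("survival values must be positive")
    return float(np.log10(arr.max() / arr.min()))


def select_timepoint(per_timepoint_survival: Mapping[int, Sequence[float]]) -> int:
    """Pick the assay timepoint whose survival has the largest dynamic range.

    Ties are broken toward the earlier timepoint.
    """
    if not per_timepoint_survival:
        raise ValueError("no timepoints supplied")
    ranges = {tp: dynamic_range(v) for tp, v in per_timepoint_survival.items()}
    best = max(ranges.values())
    return min(tp for tp, r in ranges.items() if r == best)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


def parameter_effect_ttest(values: Sequence[float], grouping: Sequence) -> TTestResult:
    """Two-sided Welch two-sample t-test of *values* split by a binary factor.

    Matches R's default ``t.test`` (unequal variances). The grouping factor
    must take exactly two levels with >= 2 observations each.
    """
    values = np.asarray(values, dtype=float)
    grouping = np.asarray(grouping)
    if values.size != grouping.size:
        raise ValueError("values and grouping must have equal length")
    levels = pd.unique(grouping)
    if len(levels) != 2:
        raise ValueError(f"grouping must have exactly 2 levels, got {len(levels)}")
    a = values[grouping == levels[0]]
    b = values[grouping == levels[1]]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.array_equal(np.sort(a), np.sort(b)):
        # identical samples: Welch statistic is 0/0 when variances vanish
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            return TTestResult(0.0, 1.0, {levels[0]: float(a.mean()),
                                          levels[1]: float(b.mean())})
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(float(t), float(p),
                       {levels[0]: float(a.mean()), levels[1]: float(b.mean())})


# -- report over a full phenotype table --------------------------------------

_FACTORS = ("salt_mM", "initial_pH", "oxygen", "temperature_C")


def _factor_contrasts(df: pd.DataFrame):
    """Yield (label, mask_a, mask_b, level_a, level_b) per factor contrast.

    Two-level factors give one contrast; temperature (three levels) is
    expanded to all pairwise contrasts.
    """
    for factor in _FACTORS:
        levels = sorted(df[factor].unique())
        if len(levels) < 2:
            continue
        if len(levels) == 2:
            pairs = [(levels[0], levels[1])]
        else:
            pairs = list(itertools.combinations(levels, 2))
        for a, b in pairs:
            label = factor if len(pairs) == 1 else f"{factor}:{a}vs{b}"
            yield label, df[factor] == a, df[factor] == b, a, b


def phenotype_report(df: pd.DataFrame, strain: str = "") -> dict[str, pd.DataFrame]:
    """Descriptive statistics for one strain's phenotype table.

    Returns a dict of data frames: ``dynamic_ranges`` (per stress and
    timepoint, plus the selected timepoint flag), ``pearson`` (growth
    statistics vs log10 survival at the selected timepoint), and
    ``ttests`` (Welch tests of every factor contrast against growth and
    robustness responses).
    """
    surv_cols = survival_columns(df)
    if not surv_cols:
        raise ValueError("phenotype table has no <stress>_<t>min_pct columns")
    stresses = sorted({s for s, _ in surv_cols})

    selected: dict[str, int] = {}
    dr_rows = []
    for stress in stresses:
        per_tp = {tp: df[col].to_numpy()
                  for (s, tp), col in surv_cols.items() if s == stress}
        sel = select_timepoint(per_tp)
        selected[stress] = sel
        for tp, vals in sorted(per_tp.items()):
            dr_rows.append({"strain": strain, "stress": stress,
                            "timepoint_min": tp,
                            "dynamic_range_log10": dynamic_range(vals),
                            "selected": tp == sel})
    dynamic_ranges = pd.DataFrame(dr_rows)

    pearson_rows = []
    for stress in stresses:
        col = surv_cols[(stress, selected[stress])]
        log_surv = robustness_from_pct(df[col])
        for growth_col in ("mu", "od_final"):
            pearson_rows.append({
                "strain": strain, "stress": stress,
                "timepoint_min": selected[stress], "growth_statistic": growth_col,
                "pearson_r": pearson(df[growth_col], log_surv)})
    pearson_table = pd.DataFrame(pearson_rows)

    ttest_rows = []
    responses = {"mu": df["mu"].to_numpy(),
                 "od_final": df["od_final"].to_numpy()}
    for stress in stresses:
        col = surv_cols[(stress, selected[stress])]
        responses[f"{stress}_robustness"] = robustness_from_pct(df[col])
    for label, mask_a, mask_b, lev_a, lev_b in _factor_contrasts(df):
        sub = mask_a | mask_b
        grouping = np.where(mask_a[sub], str(lev_a), str(lev_b))
        for resp_name, resp in responses.items():
            res = parameter_effect_ttest(resp[sub.to_numpy()], grouping)
            ttest_rows.append({
                "strain": strain, "contrast": label, "response": resp_name,
                "level_a": lev_a, "level_b": lev_b,
                "mean_a": res.group_means[str(lev_a)],
                "mean_b": res.group_means[str(lev_b)],
                "t": res.statistic, "p_value": res.p_value})
    ttests = pd.DataFrame(ttest_rows)

    return {"dynamic_ranges": dynamic_ranges, "pearson": pearson_table,
            "ttests": ttests}
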