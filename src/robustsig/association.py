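"""Per-gene linear-model association of expression with robustness.

Each gene's 2-log expression across fermentations is regressed on the
robustness phenotype (log10 fractional survival); the two-sided P-value of
the slope's t-statistic (n - 2 df) measures the association. A strain's
signature keeps genes significant at both assay timepoints with a
consistent direction, ranked by the product of the two P-values. A
parameter-wise differential-expression screen (Welch t-test per factor)
with pairwise overlaps is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import FermentationCondition, OXYGEN_HIGH

__all__ = [
    "GeneAssociationResult",
    "fit_gene_linear",
    "fit_all_genes",
    "strain_signature",
    "parameter_differential_expression",
    "ParameterDEResult",
]

_P_FLOOR = np.finfo(float).tiny  # keep p in (0, 1] even for exact fits


@dataclass(frozen=True)
class GeneAssociationResult:
    gene_id: str
    slope: float        # expression (2-log) per log10-robustness unit
    intercept: float
    p_value: float      # two-sided, slope t-statistic with n-2 df
    direction: str      # "positive" | "negative"


def _ols_slope_p(Y: np.ndarray, x: np.ndarray):
    """Vectorised OLS of each row of Y on x: slope, intercept, p (two-sided)."""
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise ValueError("zero-variance robustness")
    ybar = Y.mean(axis=1)
    slope = (Y - ybar[:, None]) @ xc / sxx
    intercept = ybar - slope * x.mean()
    resid = Y - intercept[:, None] - np.outer(slope, x)
    s2 = (resid ** 2).sum(axis=1) / (n - 2)
    se = np.sqrt(s2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, slope / np.where(se > 0, se, 1.0), np.inf)
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return slope, intercept, np.clip(p, _P_FLOOR, 1.0)


def fit_gene_linear(expr: Sequence[float], robustness: Sequence[float],
                    gene_id: str = "") -> GeneAssociationResult:
    """OLS of one gene's expression on robustness; two-sided P for slope != 0."""
    y = np.asarray(expr, dtype=float)
    x = np.asarray(robustness, dtype=float)
    if y.size != x.size:
        raise ValueError("expression and robustness must have equal length")
    slope, intercept, p = _ols_slope_p(y[None, :], x)
    return GeneAssociationResult(
        gene_id=gene_id, slope=float(slope[0]), intercept=float(intercept[0]),
        p_value=float(p[0]),
        direction="positive" if slope[0] >= 0 else "negative")


def fit_all_genes(expr: pd.DataFrame, robustness: pd.Series | Sequence[float]
                  ) -> pd.DataFrame:
    """Fit every gene (rows of *expr*) against the robustness vector.

    If *robustness* is a Series its index must cover the expression
    columns, which are aligned to it. Returns a frame indexed by gene_id
    with columns slope, intercept, p_value, direction.
    """
    if isinstance(robustness, pd.Series):
        missing = expr.columns.difference(robustness.index)
        if len(missing):
            raise ValueError(f"robustness missing fermentations: {list(missing)}")
        x = robustness.reindex(expr.columns).to_numpy(dtype=float)
    else:
        x = np.asarray(robustness, dtype=float)
        if x.size != expr.shape[1]:
            raise ValueError("robustness length does not match expression columns")
    slope, intercept, p = _ols_slope_p(expr.to_numpy(dtype=float), x)
    return pd.DataFrame(
        {"slope": slope, "intercept": intercept, "p_value": p,
         "direction": np.where(slope >= 0, "positive", "negative")},
        index=expr.index.rename("gene_id"))


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted values (informational column only)."""
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.clip(adj, 0.0, 1.0)


def strain_signature(results_t1: pd.DataFrame, results_t2: pd.DataFrame,
                     alpha: float = 0.05,
                     product_threshold: float = 5e-5) -> pd.DataFrame:
    """Select and rank a strain's robustness signature from two timepoints.

    Keeps genes with ``p < alpha`` at both timepoints and the same slope
    sign at both; ranks ascending by the product of the two P-values and
    flags the subset below *product_threshold* as ``most_significant``.
    ``avg_slope`` is the mean of the two timepoint slopes; ``slope``
    mirrors the reported layout (magnitude, with the ``direction`` column
    carrying the sign). ``p_bh`` is a Benjamini-Hochberg adjustment of the
    product, emitted for information only.
    """
    for name, val in (("alpha", alpha), ("product_threshold", product_threshold)):
        if not 0 < val < 1:
            raise ValueError(f"{name} must be in (0, 1)")
    if not results_t1.index.equals(results_t2.index):
        if set(results_t1.index) != set(results_t2.index):
            raise ValueError("timepoints cover different gene universes")
        results_t2 = results_t2.reindex(results_t1.index)
    p1 = results_t1["p_value"].to_numpy()
    p2 = results_t2["p_value"].to_numpy()
    s1 = results_t1["slope"].to_numpy()
    s2 = results_t2["slope"].to_numpy()
    keep = (p1 < alpha) & (p2 < alpha) & (np.sign(s1) == np.sign(s2)) & (s1 != 0)
    out = pd.DataFrame({
        "gene_id": results_t1.index[keep],
        "direction": np.where(s1[keep] > 0, "positive", "negative"),
        "p_t1": p1[keep], "p_t2": p2[keep],
        "p_product": p1[keep] * p2[keep],
        "avg_slope": (s1[keep] + s2[keep]) / 2.0,
    })
    out["slope"] = out["avg_slope"].abs()
    out["most_significant"] = out["p_product"] < product_threshold
    out["p_bh"] = _bh_adjust(out["p_product"].to_numpy()) if len(out) else []
    out = out.sort_values(["p_product", "gene_id"], kind="mergesort")
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class ParameterDEResult:
    """Per-parameter differentially expressed gene sets and their overlaps."""

    gene_sets: dict            # parameter -> frozenset of gene ids
    p_values: pd.DataFrame     # genes x parameters
    overlap_counts: pd.DataFrame
    overlap_pct: pd.DataFrame  # 100 * |A & B| / |A | B|


_TEMP_EXTREMES = (27, 35)


def parameter_differential_expression(expr: pd.DataFrame,
                                      design: Sequence[FermentationCondition],
                                      alpha: float = 0.05) -> ParameterDEResult:
    """Welch-t differential expression per fermentation parameter.

    Contrasts: salt 0 vs 100 mM, oxygen high vs low, initial pH 6.0 vs
    6.5, temperature 27 vs 35 C (intermediate fermentations excluded).
    Overlap percentage between two parameters is the Jaccard overlap of
    their significant gene sets, in percent.
    """
    by_id = {c.fermentation_id: c for c in design}
    missing = [c for c in expr.columns if c not in by_id]
    if missing:
        raise ValueError(f"design missing fermentations: {missing}")
    conds = [by_id[c] for c in expr.columns]
    masks = {
        "salt": (np.array([c.salt == 100 for c in conds]),
                 np.array([c.salt == 0 for c in conds])),
        "oxygen": (np.array([c.oxygen == OXYGEN_HIGH for c in conds]),
                   np.array([c.oxygen != OXYGEN_HIGH for c in conds])),
        "pH": (np.array([c.initial_ph == 6.5 for c in conds]),
               np.array([c.initial_ph == 6.0 for c in conds])),
        "temperature": (np.array([c.temperature == _TEMP_EXTREMES[1] for c in conds]),
                        np.array([c.temperature == _TEMP_EXTREMES[0] for c in conds])),
    }
    Y = expr.to_numpy(dtype=float)
    pvals = {}
    for param, (ma, mb) in masks.items():
        if ma.sum() < 2 or mb.sum() < 2:
            raise ValueError(f"parameter {param!r} has a level with < 2 fermentations")
        _, p = stats.ttest_ind(Y[:, ma], Y[:, mb], axis=1, equal_var=False)
        pvals[param] = p
    p_values = pd.DataFrame(pvals, index=expr.index)
    gene_sets = {param: frozenset(expr.index[p_values[param] < alpha])
                 for param in masks}
    params = list(masks)
    counts = pd.DataFrame(0, index=params, columns=params)
    pct = pd.DataFrame(0.0, index=params, columns=params)
    for a in params:
        for b in params:
            inter = len(gene_sets[a] & gene_sets[b])
            union = len(gene_sets[a] | gene_sets[b])
            counts.loc[a, b] = inter
            pct.loc[a, b] = 100.0 * inter / union if union else 100.0
    return ParameterDEResult(gene_sets=gene_sets, p_values=p_values,
                             overlap_counts=counts, overlap_pct=pct)
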