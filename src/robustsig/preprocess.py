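"""Probe-level two-color intensities to gene-level 2-log expression.

Steps: MA transform, per-array lowess correction of the intensity-dependent
dye bias followed by median-centering ("scaling"), least-squares placement
of all samples of a loop hybridization design on one relative log2 scale,
and per-ORF median aggregation over probes.

The per-sample scale carries an arbitrary additive constant per gene; the
zero-sum gauge (sample values of each probe sum to zero) is used, which
leaves downstream slopes, correlations and P-values unchanged.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .simulate import LoopDesign

logger = logging.getLogger(__name__)

__all__ = [
    "ma_transform",
    "floor_intensities",
    "lowess_normalize",
    "loop_to_sample_expression",
    "aggregate_probes",
    "preprocess_pipeline",
]


def ma_transform(cy5, cy3):
    """(M, A) = (log2 ratio, mean log2 intensity) of the two channels."""
    cy5 = np.asarray(cy5, dtype=float)
    cy3 = np.asarray(cy3, dtype=float)
    if np.any(cy5 <= 0) or np.any(cy3 <= 0):
        raise ValueError("intensities must be positive")
    l5, l3 = np.log2(cy5), np.log2(cy3)
    return l5 - l3, (l5 + l3) / 2.0


def floor_intensities(values, floor: float = 1.0):
    """Raise non-positive intensities to *floor*; returns (floored, count)."""
    arr = np.asarray(values, dtype=float).copy()
    mask = arr <= 0
    n = int(mask.sum())
    if n:
        arr[mask] = floor
        logger.warning("floored %d non-positive intensities to %g", n, floor)
    return arr, n


def lowess_normalize(M, A, span: float = 0.3, center: bool = True):
    """Subtract a lowess fit of M on A; optionally median-center the result.

    Parameters
    ----------
    M, A : array-like, equal length >= 20
        Log ratios and mean log intensities of one array.
    span : float in (0, 1]
        Lowess smoothing fraction.
    center : bool
        Subtract the median of the corrected values (the per-array scale
        step); the returned vector then has median exactly 0.
    """
    M = np.asarray(M, dtype=float)
    A = np.asarray(A, dtype=float)
    if M.size != A.size:
        raise ValueError("M and A must have equal length")
    if M.size < 20:
        raise ValueError("need at least 20 spots for lowess normalization")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if np.ptp(A) == 0:
        raise ValueError("degenerate A values (all equal)")
    fit = sm.nonparametric.lowess(M, A, frac=span, return_sorted=False)
    corrected = M - fit
    if center:
        corrected = corrected - np.median(corrected)
    return corrected


def loop_to_sample_expression(normalized_ratios: pd.DataFrame,
                              design: LoopDesign) -> pd.DataFrame:
    """Solve per-sample relative expression from per-hybridization log ratios.

    *normalized_ratios* is a probes x arrays frame of corrected M values;
    each array's column corresponds to one hybridization of *design* and
    measures ``x[cy5] - x[cy3]``. The least-squares solution under the
    zero-sum gauge (each probe's sample values sum to 0) is returned as a
    probes x samples frame. Raises if the design graph is disconnected.
    """
    if not design.is_connected():
        raise ValueError("hybridization design graph is disconnected; "
                         "samples cannot be placed on one scale")
    samples = design.samples
    arrays = [h[0] for h in design.hybridizations]
    missing = set(arrays) - set(normalized_ratios.columns)
    if missing:
        raise ValueError(f"no ratio column for arrays: {sorted(missing)}")
    col_of = {s: j for j, s in enumerate(samples)}
    n_hyb = len(design.hybridizations)
    X = np.zeros((n_hyb + 1, len(samples)))
    for i, (_, s5, s3) in enumerate(design.hybridizations):
        X[i, col_of[s5]] = 1.0
        X[i, col_of[s3]] = -1.0
    X[n_hyb, :] = 1.0  # zero-sum gauge; orthogonal to the data rows
    B = np.vstack([normalized_ratios[a].to_numpy(dtype=float) for a in arrays]
                  + [np.zeros(normalized_ratios.shape[0])])
    sol, *_ = np.linalg.lstsq(X, B, rcond=None)
    return pd.DataFrame(sol.T, index=normalized_ratios.index, columns=samples)


def aggregate_probes(probe_expression: pd.DataFrame,
                     probe_map: pd.DataFrame) -> pd.DataFrame:
    """Per-ORF median over its probes, per sample.

    *probe_map* has columns ``probe_id`` and ``orf_id``; every probe in
    *probe_expression* must be mapped to exactly one ORF.
    """
    mapping = probe_map.set_index("probe_id")["orf_id"]
    if mapping.index.has_duplicates:
        dup = mapping.index[mapping.index.duplicated()].unique().tolist()
        raise ValueError(f"probes mapped more than once: {dup[:5]}")
    unmapped = probe_expression.index.difference(mapping.index)
    if len(unmapped):
        raise ValueError(f"unmapped probe ids: {list(unmapped[:5])}")
    orf = mapping.reindex(probe_expression.index)
    out = probe_expression.groupby(orf.to_numpy()).median()
    out.index.name = "gene_id"
    return out


def preprocess_pipeline(intensities: pd.DataFrame,
                        probe_map: pd.DataFrame,
                        design: LoopDesign,
                        span: float = 0.3,
                        scale: str = "per-array",
                        floor: float = 1.0) -> pd.DataFrame:
    """Full probe-intensity to gene-expression pipeline.

    *intensities* is the long table (array_id, probe_id, cy5, cy3).
    ``scale`` is "per-array" (median-center each array's corrected M) or
    "global" (one median over all arrays). Returns a genes x samples
    relative 2-log expression frame.
    """
    if scale not in ("per-array", "global"):
        raise ValueError("scale must be 'per-array' or 'global'")
    cols = {}
    for array_id, grp in intensities.groupby("array_id", sort=False):
        cy5, _ = floor_intensities(grp["cy5"], floor)
        cy3, _ = floor_intensities(grp["cy3"], floor)
        M, A = ma_transform(cy5, cy3)
        mprime = lowess_normalize(M, A, span=span, center=(scale == "per-array"))
        cols[array_id] = pd.Series(mprime, index=grp["probe_id"].to_numpy())
    ratios = pd.DataFrame(cols)
    if ratios.isna().any().any():
        raise ValueError("probe sets differ between arrays")
    if scale == "global":
        ratios = ratios - np.median(ratios.to_numpy())
    probe_expr = loop_to_sample_expression(ratios, design)
    return aggregate_probes(probe_expr, probe_map)
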