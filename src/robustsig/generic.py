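"""Cross-strain generic signature over orthologous groups.

An orthologous group (OG) enters the generic signature when every strain's
member gene shows an association P-value below the screening threshold and
all members share one correlation direction; qualifying OGs are ranked on
the average of the per-strain P-values.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["generic_rank"]


def generic_rank(per_strain_results: Mapping[str, pd.DataFrame],
                 og_map: pd.DataFrame,
                 p_threshold: float = 0.2,
                 top_k: int | None = 10,
                 require_complete: bool = True) -> pd.DataFrame:
    """Rank orthologous groups by cross-strain association strength.

    Parameters
    ----------
    per_strain_results : mapping strain -> frame
        Per-gene association results (index gene_id, columns ``slope`` and
        ``p_value``) at each strain's selected timepoint.
    og_map : frame
        One row per OG: an ``og_id`` column plus one gene-id column per
        strain (NaN/empty = no member in that strain).
    p_threshold : float
        Per-strain screening threshold on the association P-value.
    top_k : int or None
        Number of top entries returned (None = all qualifying OGs).
    require_complete : bool
        If True (default) only OGs with a member in every strain qualify.

    Returns
    -------
    frame with og_id, per-strain gene and P-value columns, the shared
    ``direction``, ``avg_p`` and ``max_p``; ranked ascending by avg_p with
    ties broken by max_p then og_id.
    """
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must be in (0, 1]")
    strains = list(per_strain_results)
    if not strains:
        raise ValueError("no strain results supplied")
    for strain, res in per_strain_results.items():
        if res is None or len(res) == 0:
            raise ValueError(f"empty association results for strain {strain!r}")
    missing_cols = [s for s in strains if s not in og_map.columns]
    if missing_cols:
        raise ValueError(f"og_map lacks columns for strains: {missing_cols}")
    if og_map["og_id"].duplicated().any():
        dup = og_map.loc[og_map["og_id"].duplicated(), "og_id"].tolist()
        raise ValueError(f"og_map has duplicated OG ids (multiple members "
                         f"per strain?): {dup[:5]}")

    rows = []
    for rec in og_map.itertuples(index=False):
        rec = rec._asdict()
        members = {s: rec[s] for s in strains}
        present = {s: g for s, g in members.items()
                   if isinstance(g, str) and g != ""}
        if require_complete and len(present) != len(strains):
            continue
        if not present:
            continue
        ps, slopes = {}, {}
        ok = True
        for s, g in present.items():
            res = per_strain_results[s]
            if g not in res.index:
                ok = False
                break
            ps[s] = float(res.loc[g, "p_value"])
            slopes[s] = float(res.loc[g, "slope"])
        if not ok:
            continue
        pvals = np.array(list(ps.values()))
        signs = np.sign(list(slopes.values()))
        if np.any(pvals >= p_threshold):
            continue
        if not (np.all(signs > 0) or np.all(signs < 0)):
            continue
        row = {"og_id": rec["og_id"]}
        for s in strains:
            row[f"gene_{s}"] = present.get(s, "")
            row[f"p_{s}"] = ps.get(s, np.nan)
        row["direction"] = "positive" if signs[0] > 0 else "negative"
        row["avg_p"] = float(pvals.mean())
        row["max_p"] = float(pvals.max())
        rows.append(row)

    columns = (["og_id"] + [f"gene_{s}" for s in strains]
               + [f"p_{s}" for s in strains] + ["direction", "avg_p", "max_p"])
    out = pd.DataFrame(rows, columns=columns)
    out = out.sort_values(["avg_p", "max_p", "og_id"],
                          kind="mergesort").reset_index(drop=True)
    if top_k is not None:
        out = out.head(top_k).reset_index(drop=True)
    return out
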