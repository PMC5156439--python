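"""Seeded generators for every input the analysis pipeline consumes.

The generators produce, on a known statistical model, the artifacts a real
study would supply: the 13-fermentation factorial design, CFU-based
stress-survival phenotypes, gene-level 2-log expression matrices with a
planted linear robustness signal, probe-level two-color intensities under
a loop hybridization design with intensity-dependent dye bias, and a
cross-strain orthologous-group map. Every generator takes an explicit
integer seed and is byte-deterministic given that seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FermentationCondition",
    "SyntheticTruth",
    "LoopDesign",
    "generate_design",
    "design_frame",
    "generate_phenotypes",
    "make_truth",
    "generate_expression",
    "generate_probe_intensities",
    "generate_og_map",
]

OXYGEN_HIGH = "high"
OXYGEN_LOW = "low"


@dataclass(frozen=True)
class FermentationCondition:
    """One row of the 13-fermentation factorial design."""

    fermentation_id: int
    salt: int            # mM NaCl, 0 or 100
    initial_ph: float    # 6.0 or 6.5
    temperature: int     # degrees C: 27, 30 or 35
    oxygen: str          # "high" (shaken) or "low" (static)
    day: int             # fermentation day, 1 or 2


# The fixed design: 12 distinct factor combinations run over two days plus
# fermentation 13, a day-2 replicate of the factor settings of fermentation 6.
_DESIGN_ROWS: tuple[tuple[int, int, float, int, str, int], ...] = (
    (1, 0, 6.0, 27, OXYGEN_HIGH, 1),
    (2, 100, 6.5, 27, OXYGEN_HIGH, 1),
    (3, 0, 6.5, 27, OXYGEN_LOW, 1),
    (4, 100, 6.0, 27, OXYGEN_LOW, 1),
    (5, 0, 6.0, 30, OXYGEN_LOW, 1),
    (6, 100, 6.5, 30, OXYGEN_LOW, 1),
    (7, 0, 6.5, 30, OXYGEN_HIGH, 2),
    (8, 100, 6.0, 30, OXYGEN_HIGH, 2),
    (9, 0, 6.0, 35, OXYGEN_HIGH, 2),
    (10, 100, 6.5, 35, OXYGEN_HIGH, 2),
    (11, 0, 6.5, 35, OXYGEN_LOW, 2),
    (12, 100, 6.0, 35, OXYGEN_LOW, 2),
    (13, 100, 6.5, 30, OXYGEN_LOW, 2),
)


def generate_design() -> list[FermentationCondition]:
    """Return the fixed 13-fermentation design (deterministic)."""
    return [FermentationCondition(*row) for row in _DESIGN_ROWS]


def design_frame(design: Sequence[FermentationCondition] | None = None) -> pd.DataFrame:
    """Design as a data frame with the canonical phenotype-table columns."""
    design = design if design is not None else generate_design()
    return pd.DataFrame(
        {"fermentation_id": [c.fermentation_id for c in design],
         "salt_mM": [c.salt for c in design],
         "initial_pH": [c.initial_ph for c in design],
         "temperature_C": [c.temperature for c in design],
         "oxygen": [c.oxygen for c in design],
         "day": [c.day for c in design]})


# -- phenotypes ---------------------------------------------------------------

#: default per-factor effects on robustness, log10 units (before rescaling)
DEFAULT_RESPONSE_PROFILE: dict[str, dict[str, float]] = {
    "heat": {"oxygen": 1.8, "temperature": 0.6, "salt": 0.2, "initial_ph": -0.3},
    "oxidative": {"oxygen": 0.8, "temperature": -0.5, "salt": 0.5, "initial_ph": 0.4},
}

#: default assay timepoints, minutes, first entry = reference timepoint
DEFAULT_TIMEPOINTS: dict[str, tuple[int, int]] = {
    "heat": (10, 30),
    "oxidative": (30, 60),
}


def _deterministic_robustness(design: Sequence[FermentationCondition],
                              effects: Mapping[str, float],
                              dynamic_range_target: float | None,
                              anchor: float) -> np.ndarray:
    """Additive factor effects, max anchored at *anchor*.

    Coding: salt effect applies at 100 mM, pH effect at 6.5, oxygen effect
    at the high level, temperature linearly per +5 degrees C around 30.
    If *dynamic_range_target* is given, effects are rescaled jointly so
    the deterministic spread equals the target.
    """
    d = np.zeros(len(design))
    for i, c in enumerate(design):
        d[i] = (effects.get("salt", 0.0) * (c.salt == 100)
                + effects.get("initial_ph", 0.0) * (c.initial_ph == 6.5)
                + effects.get("oxygen", 0.0) * (c.oxygen == OXYGEN_HIGH)
                + effects.get("temperature", 0.0) * (c.temperature - 30) / 5.0)
    spread = d.max() - d.min()
    if dynamic_range_target is not None and spread > 0:
        d *= dynamic_range_target / spread
    return d + (anchor - d.max())


def generate_phenotypes(design: Sequence[FermentationCondition],
                        response_profile: Mapping[str, Mapping[str, float]] | None = None,
                        dynamic_range_target: float | None = 5.0,
                        timepoints: Mapping[str, Sequence[int]] | None = None,
                        seed: int = 0,
                        noise_sd: float = 0.3,
                        n0: float = 1e8,
                        anchor: float = -0.5,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate robustness phenotypes and paired technical-duplicate CFU counts.

    The true robustness of fermentation f at the reference timepoint (the
    first listed per stress) is an additive combination of factor effects,
    rescaled so its deterministic spread equals ``dynamic_range_target``,
    anchored with maximum *anchor*, plus N(0, noise_sd). Later timepoints
    shift the whole distribution down by ``log10(t / t_ref)`` (more killing
    with longer exposure) while keeping the spread, so duplicate counts
    stay above the plating detection limit. CFU counts are Poisson: N0
    duplicates around *n0* and Nt duplicates around ``n0 * 10**robustness``.

    Returns ``(robustness, cfu)``: one row per fermentation/stress/timepoint
    with the true (pre-discretization) robustness and survival percent, and
    the duplicate CFU records.
    """
    if dynamic_range_target is not None and dynamic_range_target < 0:
        raise ValueError("dynamic_range_target must be non-negative")
    response_profile = (DEFAULT_RESPONSE_PROFILE if response_profile is None
                        else response_profile)
    timepoints = DEFAULT_TIMEPOINTS if timepoints is None else timepoints
    for stress, tps in timepoints.items():
        if len(tps) < 2:
            raise ValueError(f"stress {stress!r} needs >= 2 timepoints")
    rng = np.random.default_rng(seed)
    rob_rows, cfu_rows = [], []
    for stress in timepoints:
        tps = list(timepoints[stress])
        ref = tps[0]
        det = _deterministic_robustness(design, response_profile.get(stress, {}),
                                        dynamic_range_target, anchor)
        for tp in tps:
            r = det - np.log10(tp / ref) + rng.normal(0.0, noise_sd, len(design))
            true_surv = 100.0 * 10.0 ** r
            lam_nt = n0 * 10.0 ** r
            n0_dup = rng.poisson(n0, size=(len(design), 2))
            nt_dup = rng.poisson(lam_nt[:, None], size=(len(design), 2))
            for i, c in enumerate(design):
                rob_rows.append({
                    "fermentation_id": c.fermentation_id, "stress": stress,
                    "timepoint_min": tp, "true_robustness": r[i],
                    "true_survival_pct": true_surv[i]})
                for rep in (0, 1):
                    cfu_rows.append({
                        "fermentation_id": c.fermentation_id, "stress": stress,
                        "timepoint_min": tp, "replicate": rep + 1,
                        "n0": int(n0_dup[i, rep]), "nt": int(nt_dup[i, rep])})
    return pd.DataFrame(rob_rows), pd.DataFrame(cfu_rows)


# -- expression ---------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a planted expression-robustness signal."""

    planted_genes: dict[str, frozenset]   # stress -> gene ids
    slopes: dict[str, dict[str, float]]   # stress -> gene -> slope (2-log per log10)
    noise_sd: float
    seed: int
    n_genes: int
    strains: tuple[str, ...] = ()

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for stress, genes in self.planted_genes.items():
            for g in genes:
                if self.slopes.get(stress, {}).get(g, 0.0) == 0.0:
                    raise ValueError(f"planted gene {g!r} has zero slope")

    def frame(self) -> pd.DataFrame:
        """Truth sidecar table: one row per planted (gene, stress)."""
        rows = [{"gene_id": g, "stress": s, "slope": self.slopes[s][g]}
                for s in sorted(self.planted_genes)
                for g in sorted(self.planted_genes[s])]
        return pd.DataFrame(rows, columns=["gene_id", "stress", "slope"])


def gene_ids(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]


def make_truth(n_genes: int,
               planted_per_stress: Mapping[str, int],
               slope_range: tuple[float, float] = (1.5, 3.0),
               noise_sd: float = 0.5,
               seed: int = 0,
               strains: Sequence[str] = (),
               sign: str = "both") -> SyntheticTruth:
    """Pick planted gene sets and slopes for a :class:`SyntheticTruth`.

    ``sign`` is "both" (random per gene), "positive" or "negative".
    Planted sets are disjoint across stresses.
    """
    rng = np.random.default_rng(seed)
    ids = gene_ids(n_genes)
    total = sum(planted_per_stress.values())
    if total > n_genes:
        raise ValueError("more planted genes than genes")
    chosen = rng.choice(n_genes, size=total, replace=False)
    planted, slopes = {}, {}
    start = 0
    for stress in planted_per_stress:
        k = planted_per_stress[stress]
        sel = [ids[j] for j in chosen[start:start + k]]
        start += k
        mags = rng.uniform(*slope_range, size=k)
        if sign == "both":
            signs = rng.choice([-1.0, 1.0], size=k)
        elif sign == "positive":
            signs = np.ones(k)
        elif sign == "negative":
            signs = -np.ones(k)
        else:
            raise ValueError(f"unknown sign mode {sign!r}")
        planted[stress] = frozenset(sel)
        slopes[stress] = {g: float(m * s) for g, m, s in zip(sel, mags, signs)}
    return SyntheticTruth(planted_genes=planted, slopes=slopes,
                          noise_sd=noise_sd, seed=seed, n_genes=n_genes,
                          strains=tuple(strains))


def generate_expression(robustness: pd.DataFrame | pd.Series,
                        n_genes: int,
                        truth: SyntheticTruth,
                        ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a genes x fermentations 2-log expression matrix.

    *robustness* holds one value per fermentation (index) per stress
    (columns; a Series is treated as a single stress named by its name).
    A planted gene g for stress s takes ``a_g + slope_g * r_s + noise``;
    all other genes are noise around their baseline ``a_g ~ N(8, 1)``.
    """
    if isinstance(robustness, pd.Series):
        robustness = robustness.to_frame(robustness.name or "stress")
    planted_union = set().union(*truth.planted_genes.values()) \
        if truth.planted_genes else set()
    if n_genes < len(planted_union):
        raise ValueError("n_genes is smaller than the number of planted genes")
    ids = gene_ids(n_genes)
    known = set(ids)
    if not planted_union <= known:
        raise ValueError("planted gene ids outside the gene universe")
    rng = np.random.default_rng(truth.seed)
    baseline = rng.normal(8.0, 1.0, n_genes)
    expr = baseline[:, None] + rng.normal(0.0, truth.noise_sd,
                                          (n_genes, robustness.shape[0]))
    index = pd.Index(ids, name="gene_id")
    df = pd.DataFrame(expr, index=index, columns=robustness.index)
    for stress in truth.planted_genes:
        if stress not in robustness.columns:
            continue
        r = robustness[stress].to_numpy(dtype=float)
        for g in truth.planted_genes[stress]:
            df.loc[g] += truth.slopes[stress][g] * r
    return df, truth


# -- probe-level two-color intensities ---------------------------------------

@dataclass(frozen=True)
class LoopDesign:
    """Loop hybridization layout for a two-color array experiment.

    Each hybridization co-hybridizes two samples on one array; the graph
    over samples must be connected for all samples to be placed on one
    relative expression scale.
    """

    hybridizations: tuple[tuple[str, int, int], ...]  # (array_id, cy5, cy3)
    days: dict = field(default_factory=dict)          # day -> sample ids

    @property
    def samples(self) -> list[int]:
        out: set[int] = set()
        for _, s5, s3 in self.hybridizations:
            out.update((s5, s3))
        return sorted(out)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.samples)
        g.add_edges_from((s5, s3) for _, s5, s3 in self.hybridizations)
        return g

    def is_connected(self) -> bool:
        g = self.graph()
        return g.number_of_nodes() > 0 and nx.is_connected(g)

    def dye_counts(self) -> pd.DataFrame:
        """Per-sample counts of Cy5 and Cy3 appearances (dye balance)."""
        rows = {s: {"cy5": 0, "cy3": 0} for s in self.samples}
        for _, s5, s3 in self.hybridizations:
            rows[s5]["cy5"] += 1
            rows[s3]["cy3"] += 1
        df = pd.DataFrame(rows).T
        df.index.name = "sample"
        return df

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.hybridizations,
                            columns=["array_id", "cy5_sample", "cy3_sample"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LoopDesign":
        hybs = tuple((str(r.array_id), int(r.cy5_sample), int(r.cy3_sample))
                     for r in df.itertuples())
        return cls(hybridizations=hybs)

    @classmethod
    def two_loops(cls,
                  day1_samples: Sequence[int] = tuple(range(1, 7)),
                  day2_samples: Sequence[int] = tuple(range(7, 14)),
                  ) -> "LoopDesign":
        """Default topology: one loop per day plus one bridging hybridization.

        Within each loop consecutive samples are co-hybridized with
        alternating dye orientation around the cycle, so every sample
        appears once per dye within its loop.
        """
        hybs: list[tuple[str, int, int]] = []
        counter = 1
        for loop in (list(day1_samples), list(day2_samples)):
            for i in range(len(loop)):
                a, b = loop[i], loop[(i + 1) % len(loop)]
                hybs.append((f"A{counter:02d}", b, a))  # cy5 <- next, cy3 <- current
                counter += 1
        hybs.append((f"A{counter:02d}", list(day2_samples)[-1],
                     list(day1_samples)[-1]))
        return cls(hybridizations=tuple(hybs),
                   days={1: tuple(day1_samples), 2: tuple(day2_samples)})


def generate_probe_intensities(expr: pd.DataFrame,
                               probes_per_gene: int,
                               design: LoopDesign,
                               dye_bias: Callable[[np.ndarray], np.ndarray] | None = None,
                               seed: int = 0,
                               noise_sd: float = 0.0,
                               a_range: tuple[float, float] = (7.0, 13.0),
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate probe-level Cy5/Cy3 intensities under a loop design.

    Each gene gets ``probes_per_gene`` probes with a fixed baseline mean
    log2 intensity A. Per hybridization the observed log-ratio is the true
    expression difference of the co-hybridized samples plus ``dye_bias(A)``
    plus N(0, noise_sd). Returns the long intensity table (array_id,
    probe_id, cy5, cy3) and the probe -> ORF map.
    """
    if probes_per_gene < 1:
        raise ValueError("probes_per_gene must be >= 1")
    unknown = set(design.samples) - set(expr.columns)
    if unknown:
        raise ValueError(f"design references unknown fermentation ids: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    genes = list(expr.index)
    probe_ids = [f"{g}_p{j}" for g in genes for j in range(1, probes_per_gene + 1)]
    probe_gene = np.repeat(np.arange(len(genes)), probes_per_gene)
    base_a = rng.uniform(*a_range, size=len(probe_ids))
    expr_arr = expr.to_numpy(dtype=float)

    frames = []
    for array_id, s5, s3 in design.hybridizations:
        m_true = (expr_arr[:, expr.columns.get_loc(s5)]
                  - expr_arr[:, expr.columns.get_loc(s3)])[probe_gene]
        a = base_a
        m = m_true.copy()
        if dye_bias is not None:
            m = m + np.asarray(dye_bias(a), dtype=float)
        if noise_sd > 0:
            m = m + rng.normal(0.0, noise_sd, size=m.shape)
        frames.append(pd.DataFrame({
            "array_id": array_id, "probe_id": probe_ids,
            "cy5": 2.0 ** (a + m / 2.0), "cy3": 2.0 ** (a - m / 2.0)}))
    intensities = pd.concat(frames, ignore_index=True)
    probe_map = pd.DataFrame({"probe_id": probe_ids,
                              "orf_id": [genes[i] for i in probe_gene]})
    return intensities, probe_map


# -- orthologous groups -------------------------------------------------------

def generate_og_map(strains: Sequence[str], n_genes: int,
                    fraction_shared: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """Orthologous-group map: one row per OG, one gene column per strain.

    OG i corresponds to gene i of each strain (per-strain gene namespaces
    are independent, so the shared ids are just positional). A
    ``fraction_shared`` subset of OGs has members in every strain; each
    remaining OG is missing its member in one randomly chosen strain
    (empty cell).
    """
    if len(strains) < 2:
        raise ValueError("need at least 2 strains")
    if not 0.0 <= fraction_shared <= 1.0:
        raise ValueError("fraction_shared must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = gene_ids(n_genes)
    width = max(4, len(str(n_genes)))
    og_ids = [f"OG{i:0{width}d}" for i in range(1, n_genes + 1)]
    df = pd.DataFrame({"og_id": og_ids})
    for strain in strains:
        df[strain] = ids
    n_shared = int(round(fraction_shared * n_genes))
    incomplete = rng.choice(n_genes, size=n_genes - n_shared, replace=False)
    drop_strain = rng.integers(0, len(strains), size=incomplete.size)
    for row, col in zip(incomplete, drop_strain):
        df.iloc[row, 1 + col] = np.nan
    return df
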