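"""End-to-end pipeline driver binding the analysis stages together.

Stages: ``simulate`` (generate every downstream input), ``phenotype``
(descriptive statistics of the phenotype tables), ``preprocess``
(probe intensities -> gene expression), ``associate`` (per-strain
signatures and parameter-wise differential expression) and ``generic``
(cross-strain orthologous-group signature). Each stage reads/writes TSVs
in the configured output directory, so stages can be re-run individually.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, generic, phenotype, preprocess, simulate, tables
from .config import PipelineConfig

logger = logging.getLogger(__name__)

STAGES = ("simulate", "phenotype", "preprocess", "associate", "generic")
STRESSES = ("heat", "oxidative")


def _strain_seeds(cfg: PipelineConfig, n_streams: int = 4) -> dict:
    """Deterministic per-strain integer seeds derived from the master seed."""
    state = np.random.SeedSequence(cfg.seed).generate_state(
        len(cfg.strains) * n_streams, dtype=np.uint32)
    return {s: [int(v) for v in state[i * n_streams:(i + 1) * n_streams]]
            for i, s in enumerate(cfg.strains)}


def _out(cfg: PipelineConfig) -> Path:
    p = Path(cfg.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _log_table(out: Path, stage: str, name: str, df: pd.DataFrame) -> None:
    logger.info("[%s] wrote %s (%d rows)", stage, name, len(df))
    with open(out / "run.log", "a") as fh:
        fh.write(f"{stage}\t{name}\t{len(df)}\n")


def _wide_phenotypes(design_df: pd.DataFrame, cfu: pd.DataFrame,
                     growth: pd.DataFrame) -> pd.DataFrame:
    """Assemble the canonical phenotype-table layout from CFU duplicates."""
    rows = design_df.merge(growth, on="fermentation_id")
    for (stress, tp), grp in cfu.groupby(["stress", "timepoint_min"]):
        col = f"{stress}_{tp}min_pct"
        values = {}
        for fid, g in grp.groupby("fermentation_id"):
            try:
                res = phenotype.compute_survival(g["n0"], g["nt"])
                values[fid] = res.survival_pct
            except phenotype.CensoredSurvivalError:
                # below plating detection: impute at half a colony
                values[fid] = 100.0 * 0.5 / float(g["n0"].mean())
                logger.warning("censored survival for fermentation %s %s "
                               "%smin imputed at detection limit", fid, stress, tp)
        rows[col] = rows["fermentation_id"].map(values)
    return rows


def run_simulate(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    design = simulate.generate_design()
    design_df = simulate.design_frame(design)
    tables.write_tsv(design_df, out / "design.tsv", {"seed": cfg.seed})
    _log_table(out, "simulate", "design.tsv", design_df)

    loop = simulate.LoopDesign.two_loops()
    tables.write_tsv(loop.frame(), out / "loop_design.tsv", {"seed": cfg.seed})

    og_map = simulate.generate_og_map(cfg.strains, cfg.n_genes,
                                      fraction_shared=0.9, seed=cfg.seed)
    tables.write_tsv(og_map, out / "og_map.tsv", {"seed": cfg.seed})
    _log_table(out, "simulate", "og_map.tsv", og_map)

    # shared planted signal: same gene ids and slope signs in every strain
    shared_truth = simulate.make_truth(
        cfg.n_genes, {s: cfg.planted_per_stress for s in STRESSES},
        noise_sd=cfg.expression_noise_sd, seed=cfg.seed, strains=cfg.strains)
    tables.write_tsv(shared_truth.frame(), out / "truth.tsv", {"seed": cfg.seed})

    seeds = _strain_seeds(cfg)
    amp = cfg.dye_bias_amplitude
    dye_bias = (lambda a: amp * np.sin(a)) if amp else None
    for strain in cfg.strains:
        s_phen, s_expr, s_probe, s_growth = seeds[strain]
        rob, cfu = simulate.generate_phenotypes(
            design, dynamic_range_target=cfg.dynamic_range_target,
            timepoints=cfg.timepoints, seed=s_phen,
            noise_sd=cfg.robustness_noise_sd)
        tables.write_tsv(cfu, out / f"cfu_{strain}.tsv",
                         {"seed": s_phen, "strain": strain})

        grng = np.random.default_rng(s_growth)
        mu = (0.4 + 0.05 * (design_df["temperature_C"] - 27)
              + grng.normal(0, 0.05, len(design_df))).round(3)
        odf = (1.5 + 0.8 * (design_df["initial_pH"] == 6.5)
               + grng.normal(0, 0.1, len(design_df))).round(3)
        growth = pd.DataFrame({"fermentation_id": design_df["fermentation_id"],
                               "mu": mu, "od_final": odf})
        phen = _wide_phenotypes(design_df, cfu, growth)
        tables.write_tsv(phen, out / f"phenotypes_{strain}.tsv",
                         {"seed": s_phen, "strain": strain})
        _log_table(out, "simulate", f"phenotypes_{strain}.tsv", phen)

        ref = rob[rob.groupby("stress")["timepoint_min"].transform("min")
                  == rob["timepoint_min"]]
        regressors = ref.pivot(index="fermentation_id", columns="stress",
                               values="true_robustness")
        truth = dataclasses.replace(shared_truth, seed=s_expr)
        expr, _ = simulate.generate_expression(regressors, cfg.n_genes, truth)
        tables.write_tsv(expr.reset_index(), out / f"expression_true_{strain}.tsv",
                         {"seed": s_expr, "strain": strain})

        intens, probe_map = simulate.generate_probe_intensities(
            expr, cfg.probes_per_gene, loop, dye_bias=dye_bias,
            seed=s_probe, noise_sd=cfg.probe_noise_sd)
        tables.write_tsv(intens, out / f"probe_intensities_{strain}.tsv",
                         {"seed": s_probe, "strain": strain})
        tables.write_tsv(probe_map, out / f"probe_map_{strain}.tsv",
                         {"strain": strain})
        _log_table(out, "simulate", f"probe_intensities_{strain}.tsv", intens)


def _load_phenotype_tables(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    found = {}
    for strain in cfg.strains:
        path = out / f"phenotypes_{strain}.tsv"
        if path.exists():
            found[strain], _ = tables.read_tsv(path)
    if not found:
        raise FileNotFoundError(
            f"no phenotypes_<strain>.tsv found in {out}; run the simulate "
            "stage or point the phenotype command at a table")
    return found


def run_phenotype(cfg: PipelineConfig, phen_tables: dict | None = None) -> None:
    out = _out(cfg)
    phen_tables = phen_tables or _load_phenotype_tables(cfg)
    reports = {"dynamic_ranges": [], "pearson": [], "ttests": []}
    for strain, df in phen_tables.items():
        rep = phenotype.phenotype_report(df, strain=strain)
        for key in reports:
            reports[key].append(rep[key])
    for key, parts in reports.items():
        table = pd.concat(parts, ignore_index=True)
        tables.write_tsv(table, out / f"phenotype_{key}.tsv", {"seed": cfg.seed})
        _log_table(out, "phenotype", f"phenotype_{key}.tsv", table)


def run_preprocess(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    loop_df, _ = tables.read_tsv(out / "loop_design.tsv")
    loop = simulate.LoopDesign.from_frame(loop_df)
    for strain in cfg.strains:
        intens, _ = tables.read_tsv(out / f"probe_intensities_{strain}.tsv")
        probe_map, _ = tables.read_tsv(out / f"probe_map_{strain}.tsv")
        expr = preprocess.preprocess_pipeline(
            intens, probe_map, loop, span=cfg.lowess_span, scale=cfg.scale)
        tables.write_tsv(expr.reset_index(), out / f"expression_{strain}.tsv",
                         {"strain": strain, "lowess_span": cfg.lowess_span})
        _log_table(out, "preprocess", f"expression_{strain}.tsv", expr)


def _robustness_by_timepoint(phen: pd.DataFrame) -> dict:
    """(stress, timepoint) -> robustness Series indexed by fermentation_id."""
    surv = tables.survival_columns(phen)
    idx = phen["fermentation_id"]
    return {(stress, tp): pd.Series(
                phenotype.robustness_from_pct(phen[col].to_numpy()),
                index=idx)
            for (stress, tp), col in surv.items()}


def run_associate(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    design = simulate.generate_design()
    for strain in cfg.strains:
        expr_path = out / f"expression_{strain}.tsv"
        if not expr_path.exists():
            expr_path = out / f"expression_true_{strain}.tsv"
        expr, _ = tables.read_tsv(expr_path, index_col="gene_id")
        expr.columns = expr.columns.astype(int)
        phen, _ = tables.read_tsv(out / f"phenotypes_{strain}.tsv")
        rob = _robustness_by_timepoint(phen)
        for stress in sorted({s for s, _ in rob}):
            tps = sorted(tp for s, tp in rob if s == stress)
            fits = {tp: association.fit_all_genes(expr, rob[(stress, tp)])
                    for tp in tps}
            sig = association.strain_signature(
                fits[tps[0]], fits[tps[1]], alpha=cfg.alpha,
                product_threshold=cfg.product_threshold)
            tables.write_tsv(sig, out / f"signature_{strain}_{stress}.tsv",
                             {"strain": strain, "stress": stress,
                              "timepoints_min": f"{tps[0]},{tps[1]}"})
            _log_table(out, "associate", f"signature_{strain}_{stress}.tsv", sig)
            surv = {tp: phen[tables.survival_columns(phen)[(stress, tp)]]
                    for tp in tps}
            sel = phenotype.select_timepoint(surv)
            fit_sel = fits[sel].reset_index()
            tables.write_tsv(fit_sel,
                             out / f"association_{strain}_{stress}_selected.tsv",
                             {"strain": strain, "stress": stress,
                              "timepoint_min": sel})
        de = association.parameter_differential_expression(
            expr, design, alpha=cfg.ttest_alpha)
        counts = de.overlap_counts.reset_index(names="parameter")
        pct = de.overlap_pct.reset_index(names="parameter")
        tables.write_tsv(counts, out / f"de_overlap_counts_{strain}.tsv",
                         {"strain": strain, "alpha": cfg.ttest_alpha})
        tables.write_tsv(pct, out / f"de_overlap_pct_{strain}.tsv",
                         {"strain": strain, "alpha": cfg.ttest_alpha})


def run_generic(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    og_map, _ = tables.read_tsv(out / "og_map.tsv")
    for stress in STRESSES:
        results = {}
        for strain in cfg.strains:
            path = out / f"association_{strain}_{stress}_selected.tsv"
            if not path.exists():
                raise FileNotFoundError(f"{path} missing; run associate first")
            res, _ = tables.read_tsv(path, index_col="gene_id")
            results[strain] = res
        ranked = generic.generic_rank(results, og_map,
                                      p_threshold=cfg.generic_p_threshold,
                                      top_k=cfg.top_k)
        tables.write_tsv(ranked, out / f"generic_{stress}.tsv",
                         {"stress": stress,
                          "p_threshold": cfg.generic_p_threshold})
        _log_table(out, "generic", f"generic_{stress}.tsv", ranked)


_RUNNERS = {"simulate": run_simulate, "phenotype": run_phenotype,
            "preprocess": run_preprocess, "associate": run_associate,
            "generic": run_generic}


def run_pipeline(cfg: PipelineConfig, stages) -> None:
    """Run the requested *stages* in canonical order."""
    if isinstance(stages, str):
        stages = (stages,)
    stages = tuple(stages)
    if stages == ("all",):
        stages = STAGES
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}; choose from {STAGES}")
    out = _out(cfg)
    with open(out / "run.log", "a") as fh:
        fh.write(f"# stages={','.join(stages)} seed={cfg.seed}\n")
    cfg.to_file(out / "config.txt")
    for stage in STAGES:
        if stage in stages:
            logger.info("running stage %s", stage)
            _RUNNERS[stage](cfg)
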