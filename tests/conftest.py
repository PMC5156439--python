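import numpy as np
import pandas as pd
import pytest

import robustsig as rs

STRAINS = ("IL1403", "KF147", "SK11")


@pytest.fixture(scope="session")
def design():
    return rs.generate_design()


@pytest.fixture(scope="session")
def table1():
    """Packaged per-strain phenotype tables (13 fermentations each)."""
    return {s: rs.load_packaged_phenotypes(s) for s in STRAINS}


@pytest.fixture(scope="session")
def loop_design():
    return rs.LoopDesign.two_loops()


def heat_robustness_pair(seed, noise_sd=1.5):
    """True robustness at both heat timepoints, indexed by fermentation."""
    design = rs.generate_design()
    rob, _ = rs.generate_phenotypes(design, seed=seed, noise_sd=noise_sd)
    heat = rob[rob.stress == "heat"]
    r1 = heat[heat.timepoint_min == 10].set_index("fermentation_id")["true_robustness"]
    r2 = heat[heat.timepoint_min == 30].set_index("fermentation_id")["true_robustness"]
    return r1.rename("heat"), r2.rename("heat")


def planted_run(seed, n_genes=1000, n_planted=20, noise_sd_rob=1.5,
                slope_range=(1.5, 3.0), expr_noise=0.5):
    """One planted-signal simulation: returns (signature frame, planted set)."""
    r1, r2 = heat_robustness_pair(seed, noise_sd=noise_sd_rob)
    truth = rs.make_truth(n_genes, {"heat": n_planted} if n_planted else {},
                          slope_range=slope_range, noise_sd=expr_noise,
                          seed=seed)
    expr, _ = rs.generate_expression(r1, n_genes, truth)
    sig = rs.strain_signature(rs.fit_all_genes(expr, r1),
                              rs.fit_all_genes(expr, r2))
    return sig, set(truth.planted_genes.get("heat", set()))
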