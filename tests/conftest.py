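import logging
import warnings

import numpy as np
import pandas as pd
import pytest

import pairrisk as pr
from pairrisk.datasets import simulate_expression, simulate_survival
from pairrisk.pairs import build_pair_matrix

logging.getLogger("pairrisk").setLevel(logging.ERROR)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic synthetic cohort (200 tumor / 20 normal)."""
    truth = pr.default_truth(seed=7)
    expr, ann, clin, maf, truth = pr.simulate_cohort(
        truth=truth, seed=7, n_tumor=200, n_normal=20, n_noise_lncrna=40
    )
    return {"expr": expr, "annotation": ann, "clinical": clin, "maf": maf, "truth": truth}


def make_survival_cohort(seed, n=400, beta=None, n_pairs=5):
    """Pair matrix + clinical table with planted hazard, for survival tests.

    beta=None uses the default truth betas; beta=0 plants an all-null world
    with the same pair structure.
    """
    truth = pr.default_truth(seed=seed)
    if beta is not None:
        # post-init reassignment: lets tests plant uniform or zero hazards
        truth.prognostic_pairs = [
            (a, b, float(beta)) for a, b, _ in truth.prognostic_pairs[:n_pairs]
        ]
    expr, _ = simulate_expression(truth, n_tumor=n, n_normal=2, n_noise_lncrna=0, seed=seed)
    tumor = expr.values[expr.tumor_samples()]
    genes = sorted({g for a, b, _ in truth.prognostic_pairs for g in (a, b)})
    pm = build_pair_matrix(tumor, genes)
    keys = [f"{a}|{b}" for a, b, _ in truth.prognostic_pairs]
    clin = simulate_survival(truth, pm.loc[keys], seed=seed + 1)
    return pm, clin, keys, truth
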