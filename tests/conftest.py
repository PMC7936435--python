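import numpy as np
import pandas as pd
import pytest

from gmdscreen.qc import BetaMatrix
from gmdscreen.synthetic import PanelConfig, PlantedEffect, generate_panel


@pytest.fixture(scope="session")
def chain_panel():
    """600-line panel with a planted GMD -> probe -> drug chain plus a cis
    repression effect, shared across tests that only read it."""
    cfg = PanelConfig(
        n_cell_lines=600,
        n_cancer_categories=2,
        n_gmds=6,
        n_target_genes=25,
        seed=11,
        planted_effects=[
            PlantedEffect("expr_meth_trans", "GMD01", "cg00000300", 0.7),
            PlantedEffect("meth_drug", "cg00000300", "AGENT01@GDSC", -0.6),
            PlantedEffect("expr_meth_cis", "GMD02", "GMD02|TSS200", -0.6),
        ],
    )
    return generate_panel(cfg)


@pytest.fixture(scope="session")
def null_panel():
    """Panel with no planted effects (global null)."""
    cfg = PanelConfig(
        n_cell_lines=200,
        n_cancer_categories=2,
        n_gmds=6,
        n_target_genes=20,
        seed=7,
    )
    return generate_panel(cfg)


def random_beta_matrix(n_probes=50, n_samples=12, seed=0, missing_rate=0.1):
    """Small beta matrix with scattered missing values, for oracle checks."""
    rng = np.random.default_rng(seed)
    beta = rng.random((n_probes, n_samples))
    miss = rng.random(beta.shape) < missing_rate
    beta[miss] = np.nan
    probes = [f"cg{i:08d}" for i in range(1, n_probes + 1)]
    samples = [f"CL{i:04d}" for i in range(1, n_samples + 1)]
    return BetaMatrix(pd.DataFrame(beta, index=probes, columns=samples))


def make_beta(values, detection=None, probes=None, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    probes = probes or [f"cg{i:08d}" for i in range(1, values.shape[0] + 1)]
    samples = samples or [f"CL{i:04d}" for i in range(1, values.shape[1] + 1)]
    beta = pd.DataFrame(values, index=probes, columns=samples)
    detp = None
    if detection is not None:
        detp = pd.DataFrame(
            np.atleast_2d(np.asarray(detection, dtype=float)),
            index=probes,
            columns=samples,
        )
    return BetaMatrix(beta, detp)
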