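import numpy as np
import pytest

from gallop import (
    LongitudinalLMM,
    SimulationConfig,
    fit_variance_components,
    precompute,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated panel: 80 subjects, 4 occasions, 2 covariates, 12 SNPs."""
    cfg = SimulationConfig(n=80, k=4, q=2, n_snps=12, seed=42)
    effects = np.zeros((12, 2))
    effects[0] = (0.4, 0.3)
    effects[1] = (0.8, 0.0)
    data, block, truth = simulate_dataset(cfg, snp_effects=effects)
    return data, block, truth


@pytest.fixture(scope="session")
def small_fit(small_sim):
    data, block, truth = small_sim
    vc, reduced = fit_variance_components(data)
    return data, block, vc, reduced


@pytest.fixture(scope="session")
def small_pc(small_fit):
    data, block, vc, reduced = small_fit
    return precompute(data, vc, reduced)


def dense_full_model_solve(data, vc, dosages):
    """Oracle: dense weighted Henderson solve of the SNP model.

    Returns (beta2, beta3, se2, se3) at the given variance components for
    one SNP's per-subject dosages.
    """
    from gallop.lmm import henderson_solve

    s_row = np.asarray(dosages, float)[data.row_subject]
    X_full = np.column_stack(
        [s_row, s_row * data.t_filled, data.X_star]
    )
    sol = henderson_solve(
        X_full,
        data.Z,
        data.row_subject,
        vc.P_star,
        data.y_filled,
        data.w,
        sigma2=vc.sigma2,
    )
    se = np.sqrt(np.diag(sol.cov_beta))
    return sol.beta[0], sol.beta[1], se[0], se[1]
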