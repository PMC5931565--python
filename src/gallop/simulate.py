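"""Synthetic longitudinal GWAS data with a known generative model.

Generates data from the full mixed model

    y_ij = b0 + b1*t_ij + b2*s_i + b3*t_ij*s_i + C_ij' bcov
           + u0_i + u1_i*t_ij + e_ij,

with per-subject random intercept/slope ``(u0, u1) ~ N(0, D)`` and
i.i.d. measurement error ``e ~ N(0, sigma^2)``.  The defaults mirror a
typical imputed-dosage longitudinal GWAS: n = 2000 subjects measured on
k = 4 occasions at times uniform on (0, 10), 3 time-varying covariates
drawn from N(2, 0.5^2), fixed intercept -2.6 and slope -1.9, covariate
coefficients drawn once per dataset from N(0, 1),
D = [[1, -0.2], [-0.2, 1]], error SD 2.5, and dosages uniform on (0, 2)
(continuous, as for imputed genotypes; a Binomial(2, maf) hard-call law is
available).  SNP effect sizes are supplied per SNP, by default zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data import LongitudinalData, assemble
from .engine import DosageBlock

__all__ = ["SimulationConfig", "simulate_dataset", "inject_missingness", "effect_grid"]


@dataclass
class SimulationConfig:
    """Generative parameters for a synthetic longitudinal GWAS dataset."""

    n: int = 2000  # subjects
    k: int = 4  # measurement occasions per subject
    q: int = 3  # covariates
    t_range: tuple = (0.0, 10.0)  # uniform window for measurement times
    beta0: float = -2.6  # fixed intercept
    beta1: float = -1.9  # fixed time slope
    beta_cov: np.ndarray | None = None  # drawn ~ N(0,1) per dataset if None
    cov_mean: float = 2.0
    cov_scale: float = 0.5
    cov_scale_is_variance: bool = False  # if True, 0.5 is a variance not an SD
    D: np.ndarray = field(
        default_factory=lambda: np.array([[1.0, -0.2], [-0.2, 1.0]])
    )
    sigma: float = 2.5  # measurement-error SD
    n_snps: int = 1
    dosage_law: str = "uniform"  # "uniform" on (0,2) or "binomial" hard calls
    maf: float = 0.3  # used by the binomial law
    seed: int | None = None

    def __post_init__(self):
        self.D = np.asarray(self.D, float)
        if self.D.shape != (2, 2) or not np.allclose(self.D, self.D.T):
            raise ValueError("D must be symmetric 2x2")
        if np.any(np.linalg.eigvalsh(self.D) < 0):
            raise ValueError("D must be positive semidefinite")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.n < 1 or self.k < 1 or self.q < 0 or self.n_snps < 0:
            raise ValueError("n, k >= 1 and q, n_snps >= 0 required")
        if self.dosage_law not in ("uniform", "binomial"):
            raise ValueError(f"unknown dosage_law: {self.dosage_law!r}")
        if not 0 < self.maf < 1:
            raise ValueError("maf must be in (0, 1)")

    @property
    def cov_sd(self) -> float:
        return float(np.sqrt(self.cov_scale)) if self.cov_scale_is_variance else float(self.cov_scale)


def effect_grid(n_points: int = 200, low: float = 0.0, high: float = 1.0) -> np.ndarray:
    """Equally spaced SNP effect sizes, default 200 points on [0, 1]."""
    return np.linspace(low, high, n_points)


def simulate_dataset(
    cfg: SimulationConfig,
    snp_effects=(0.0, 0.0),
    rng: np.random.Generator | None = None,
):
    """Simulate one longitudinal dataset plus a dosage panel.

    Parameters
    ----------
    cfg : SimulationConfig
    snp_effects : pair (beta2, beta3) or array (n_snps, 2)
        Cross-sectional and longitudinal effect of each SNP; a single pair
        applies to SNP 0 with any remaining SNPs null.
    rng : numpy Generator, optional
        Overrides ``cfg.seed``.  A fixed seed reproduces the dataset
        byte-for-byte.

    Returns
    -------
    data : LongitudinalData
    block : DosageBlock
    truth : dict
        All generating values (fixed effects, covariate coefficients, per-
        subject random effects, SNP effects, config echo).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n, k, q, m = cfg.n, cfg.k, cfg.q, cfg.n_snps

    effects = np.zeros((max(m, 1), 2))
    se = np.asarray(snp_effects, float)
    if se.ndim == 1:
        effects[0] = se
    else:
        if se.shape != (m, 2):
            raise ValueError("snp_effects must be a pair or an (n_snps, 2) array")
        effects = se

    t = rng.uniform(cfg.t_range[0], cfg.t_range[1], size=(n, k))
    C = rng.normal(cfg.cov_mean, cfg.cov_sd, size=(n, k, q))
    beta_cov = (
        rng.standard_normal(q)
        if cfg.beta_cov is None
        else np.asarray(cfg.beta_cov, float)
    )
    if beta_cov.shape != (q,):
        raise ValueError("beta_cov must have length q")
    b = (
        rng.multivariate_normal(np.zeros(2), cfg.D, size=n)
        if np.any(cfg.D)
        else np.zeros((n, 2))
    )
    eps = rng.normal(0.0, cfg.sigma, size=(n, k)) if cfg.sigma > 0 else np.zeros((n, k))

    if m > 0:
        if cfg.dosage_law == "uniform":
            dosages = rng.uniform(0.0, 2.0, size=(n, m))
        else:
            dosages = rng.binomial(2, cfg.maf, size=(n, m)).astype(float)
    else:
        dosages = np.empty((n, 0))

    y = (
        cfg.beta0
        + cfg.beta1 * t
        + np.einsum("nkq,q->nk", C, beta_cov)
        + b[:, 0, None]
        + b[:, 1, None] * t
        + eps
    )
    if m > 0:
        # SNP contribution: s_i * (beta2 + beta3 * t_ij) summed over SNPs
        y = y + (dosages @ effects[:m, 0])[:, None]
        y = y + (dosages @ effects[:m, 1])[:, None] * t

    ids = np.repeat(np.arange(1, n + 1), k)
    df = pd.DataFrame(
        {"id": ids, "time": t.ravel(), "y": y.ravel()}
    )
    cov_names = [f"cov{j + 1}" for j in range(q)]
    for j, name in enumerate(cov_names):
        df[name] = C[:, :, j].ravel()

    data = assemble(df)
    snp_ids = [f"snp{j + 1}" for j in range(m)]
    block = DosageBlock(
        dosages=dosages, snp_ids=snp_ids, subject_ids=data.subject_ids
    )
    truth = {
        "beta0": cfg.beta0,
        "beta1": cfg.beta1,
        "beta_cov": beta_cov,
        "snp_effects": effects[:m],
        "D": cfg.D,
        "sigma": cfg.sigma,
        "random_effects": b,
        "config": asdict(cfg) | {"beta_cov": beta_cov.tolist()},
    }
    return data, block, truth


def inject_missingness(
    data: LongitudinalData,
    rate: float,
    rng: np.random.Generator | None = None,
    mechanism: str = "MCAR",
    missing_policy: str = "zero_weight",
) -> LongitudinalData:
    """Set outcomes missing completely at random at the given per-row rate.

    Returns a freshly assembled dataset; under the default policy the
    affected rows get weight 0 (and subjects losing every row are
    dropped), which is exactly equivalent to deleting those rows.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if mechanism != "MCAR":
        raise ValueError("only MCAR missingness is implemented")
    if rng is None:
        rng = np.random.default_rng()
    df = data.to_frame()
    if rate > 0:
        mask = rng.random(len(df)) < rate
        df.loc[mask, "y"] = np.nan
    return assemble(
        df, covariate_cols=data.covariate_names, missing_policy=missing_policy
    )
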