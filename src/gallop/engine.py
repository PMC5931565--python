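"""Per-SNP scoring via the bordered penalized least-squares system.

Adding a SNP to the reduced model appends two fixed-effect columns,
``[s, s*t]``; because the SNP value is constant over time those columns are
``s_i * Z_i`` per subject, so the border of the Henderson system is built
from the same 2x2 per-subject statistics as the core.  Eliminating the core
yields a 2x2 Schur-complement system per SNP:

    C = sum_i s_i^2 F_i  -  a M^-1 a',      a = sum_i s_i E_i,
    beta_snp = C^-1 c,                      c = sum_i s_i g_i,
    se = sigma_hat * sqrt(diag C^-1),

where ``E_i = R_i - K_i' Atil_i``, ``F_i = S_i - K_i' K_i`` and
``g_i = r_i - R_i beta* - K_i' theta_i`` depend only on the reduced model
(``K_i = Phi_i S_i``, ``Atil_i = Phi_i R_i``), and ``M`` is the reduced
model's p x p GLS information matrix, factorized once.  A whole block of m
SNPs is scored with two weighted aggregations (weights ``s`` and ``s^2``)
over an n-row feature table — the per-row SNP vector of length n*k is
never materialized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg, special

from .data import LongitudinalData
from .lmm import (
    LongitudinalLMMResults,
    SubjectBlocks,
    VarianceComponents,
    rotate,
    subject_blocks,
)

__all__ = [
    "DosageBlock",
    "GallopPrecompute",
    "SnpResult",
    "precompute",
    "score_block",
    "wald_pvalues",
    "neglog10_pvalues",
    "predict_variance_inflation",
    "handle_missing_dosage",
]

#: dosage variance below which a SNP is flagged monomorphic and not scored
MONOMORPHIC_VAR = 1e-8
#: condition number above which the 2x2 SNP system is declared singular
MAX_CONDITION = 1e12

STATUS_OK = "ok"
STATUS_MONOMORPHIC = "monomorphic"
STATUS_SINGULAR = "singular"
STATUS_ALL_MISSING = "all_missing"
STATUS_SKIPPED = "skipped_missing"


@dataclass
class DosageBlock:
    """A block of SNP dosages: one value in [0, 2] per subject per SNP."""

    dosages: np.ndarray  # (n_subjects, m), NaN = missing
    snp_ids: list
    subject_ids: np.ndarray | None = None
    imputed: np.ndarray | None = None  # per-SNP count of imputed entries
    unscored: np.ndarray | None = None  # per-SNP status (None/str)

    def __post_init__(self):
        self.dosages = np.atleast_2d(np.asarray(self.dosages, float))
        if self.dosages.shape[1] != len(self.snp_ids):
            raise ValueError("dosage matrix and snp_ids disagree on m")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]


@dataclass
class SnpResult:
    """Estimates for one SNP: main (cross-sectional) and SNP-by-time effects."""

    snp_id: str
    beta2: float  # main SNP effect
    beta3: float  # SNP x time effect
    se2: float
    se3: float
    z2: float
    z3: float
    p2: float
    p3: float
    n_used: int
    mean_dosage: float
    status: str = STATUS_OK
    n_imputed: int = 0

    @property
    def freq(self) -> float:
        """Allele frequency implied by the mean dosage."""
        return self.mean_dosage / 2.0


@dataclass
class GallopPrecompute:
    """Everything reusable across SNPs, computed once from the reduced fit."""

    blocks: SubjectBlocks
    vc: VarianceComponents
    beta_star: np.ndarray  # (p,)
    theta: np.ndarray  # (n, 2)
    Phi: np.ndarray  # (n, 2, 2)
    K: np.ndarray  # (n, 2, 2) = Phi S
    Atil: np.ndarray  # (n, 2, p) = Phi R
    qtil: np.ndarray  # (n, 2) = Phi r
    E: np.ndarray  # (n, 2, p) = R - K' Atil
    F: np.ndarray  # (n, 2, 2) = S - K' K
    g: np.ndarray  # (n, 2) = r - R beta* - K' theta
    M: np.ndarray  # (p, p) = A11 - sum Atil' Atil
    M_cho: tuple = field(repr=False, default=None)
    subject_ids: np.ndarray | None = None

    @property
    def n_subjects(self) -> int:
        return self.E.shape[0]

    @property
    def p(self) -> int:
        return self.E.shape[2]

    @property
    def sigma2(self) -> float:
        return self.vc.sigma2

    def feature_table(self) -> np.ndarray:
        """Stacked per-subject features, shape (n, 2p + 6)."""
        n = self.n_subjects
        return np.concatenate(
            [self.E.reshape(n, -1), self.F.reshape(n, 4), self.g], axis=1
        )


def precompute(
    data: LongitudinalData,
    vc: VarianceComponents,
    reduced: LongitudinalLMMResults | None = None,
    blocks: SubjectBlocks | None = None,
) -> GallopPrecompute:
    """One-time precomputation shared by every SNP.

    Builds the per-subject rotations from ``S_i + P*``, solves the reduced
    (SNP-free) system through the factorized ``M`` (which reproduces the
    dense Henderson solution exactly), and derives the two-numbers-per-
    subject border features ``E_i, F_i, g_i``.

    If ``reduced`` is given, its ``beta*``/``theta`` are recomputed here
    from the same variance components (identical by the transform
    equivalence); only ``vc`` is actually consumed.
    """
    if blocks is None:
        blocks = subject_blocks(data)
    P_star = vc.P_star
    Phi, _, _ = rotate(blocks.S, P_star)
    K = Phi @ blocks.S
    Atil = Phi @ blocks.R
    qtil = np.einsum("nij,nj->ni", Phi, blocks.r)

    M = blocks.A11 - np.einsum("nip,niq->pq", Atil, Atil)
    M = (M + M.T) / 2.0
    try:
        M_cho = linalg.cho_factor(M)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "reduced-model information matrix M is not positive definite "
            "(collinear covariates?)"
        ) from e
    beta_star = linalg.cho_solve(
        M_cho, blocks.q1 - np.einsum("nip,ni->p", Atil, qtil)
    )
    theta = qtil - np.einsum("nip,p->ni", Atil, beta_star)

    E = blocks.R - np.einsum("nji,njp->nip", K, Atil)
    F = blocks.S - np.einsum("nji,njk->nik", K, K)
    g = (
        blocks.r
        - np.einsum("nip,p->ni", blocks.R, beta_star)
        - np.einsum("nji,nj->ni", K, theta)
    )
    return GallopPrecompute(
        blocks=blocks,
        vc=vc,
        beta_star=np.asarray(beta_star),
        theta=theta,
        Phi=Phi,
        K=K,
        Atil=Atil,
        qtil=qtil,
        E=E,
        F=F,
        g=g,
        M=M,
        M_cho=M_cho,
        subject_ids=np.asarray(data.subject_ids),
    )


def wald_pvalues(beta, se):
    """Two-sided Wald test against the standard normal.

    Returns ``(z, p)`` with ``z = beta / se`` and
    ``p = 2 * (1 - Phi(|z|))``, clamped into (0, 1] so extreme statistics
    never report an exact zero.
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if np.any(se[np.isfinite(se)] <= 0):
        raise ValueError("standard errors must be positive")
    z = beta / se
    p = special.erfc(np.abs(z) / np.sqrt(2.0))
    p = np.where(np.isfinite(z), np.maximum(p, np.nextafter(0.0, 1.0)), np.nan)
    return z, p


def neglog10_pvalues(z):
    """-log10 of the two-sided normal p-value, accurate for huge |z|.

    Uses the scaled complementary error function so that statistics far in
    the tail (where the p-value itself underflows) still give a finite
    -log10 p.
    """
    z = np.abs(np.asarray(z, float))
    x = z / np.sqrt(2.0)
    # erfc(x) = erfcx(x) * exp(-x^2)  =>  log p = log(erfcx) - x^2
    with np.errstate(over="ignore"):
        logp = np.log(special.erfcx(x)) - x * x
    return -logp / np.log(10.0)


def predict_variance_inflation(
    D: np.ndarray, beta2: float, beta3: float, var_snp: float
) -> np.ndarray:
    """Random-effect covariance implied by omitting a SNP with given effects.

    When the reduced model leaves out a SNP with main effect ``beta2`` and
    time-interaction ``beta3``, the subject-level intercepts and slopes
    absorb it, inflating their covariance to

        D* = D + var(SNP) * [[beta2^2, beta2*beta3],
                             [beta2*beta3, beta3^2]].

    For null or tiny effects ``D* ~= D``, which is why scoring every SNP at
    the reduced-model variance components is near-exact in the usual GWAS
    effect-size range and (mildly) conservative otherwise.
    """
    D = np.asarray(D, float)
    if var_snp < 0:
        raise ValueError("var_snp must be nonnegative")
    eff = np.array([beta2, beta3], float)
    return D + var_snp * np.outer(eff, eff)


def handle_missing_dosage(block: DosageBlock, policy: str = "mean_impute") -> DosageBlock:
    """Resolve missing genotype dosages before scoring.

    ``mean_impute`` replaces missing entries with the SNP's observed mean
    dosage (flagged per SNP); ``skip`` marks any SNP with missing entries
    as unscored.  SNPs missing for every subject are unscored under either
    policy.
    """
    if policy not in ("mean_impute", "skip"):
        raise ValueError(f"unknown missing-dosage policy: {policy!r}")
    s = block.dosages
    miss = np.isnan(s)
    n_missing = miss.sum(axis=0)
    unscored = np.array(
        [None if c < block.n_subjects else STATUS_ALL_MISSING for c in n_missing],
        dtype=object,
    )
    if not miss.any():
        return replace(
            block,
            imputed=np.zeros(block.m, int),
            unscored=unscored,
        )
    s = s.copy()
    if policy == "mean_impute":
        n_obs = (~miss).sum(axis=0)
        col_mean = np.where(miss, 0.0, s).sum(axis=0) / np.maximum(n_obs, 1)
        s[miss] = np.broadcast_to(col_mean, s.shape)[miss]
        imputed = n_missing.astype(int)
    else:
        for j in range(block.m):
            if 0 < n_missing[j] < block.n_subjects and unscored[j] is None:
                unscored[j] = STATUS_SKIPPED
        s = np.where(miss, 0.0, s)
        imputed = np.zeros(block.m, int)
    return replace(block, dosages=s, imputed=imputed, unscored=unscored)


def _inv2(C):
    """Closed-form inverse, determinant and condition of batched 2x2 PD blocks."""
    det = C[:, 0, 0] * C[:, 1, 1] - C[:, 0, 1] * C[:, 1, 0]
    inv = np.empty_like(C)
    inv[:, 0, 0] = C[:, 1, 1]
    inv[:, 1, 1] = C[:, 0, 0]
    inv[:, 0, 1] = -C[:, 0, 1]
    inv[:, 1, 0] = -C[:, 1, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = inv / det[:, None, None]
    # condition number from the symmetric 2x2 eigenvalues
    tr = C[:, 0, 0] + C[:, 1, 1]
    disc = np.sqrt(np.maximum((C[:, 0, 0] - C[:, 1, 1]) ** 2 + 4 * C[:, 0, 1] ** 2, 0.0))
    lmax = (tr + disc) / 2.0
    lmin = (tr - disc) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(lmin > 0, lmax / lmin, np.inf)
    return inv, det, cond


def score_block(
    pc: GallopPrecompute,
    block: DosageBlock,
    missing_policy: str | None = None,
    method: str = "aggregated",
    monomorphic_var: float = MONOMORPHIC_VAR,
    max_condition: float = MAX_CONDITION,
) -> list[SnpResult]:
    """Score a block of SNPs against the precomputed reduced model.

    For each SNP with per-subject dosages ``s`` the 2x2 bordered system is

        C = Fagg - a M^-1 a',   beta_snp = C^-1 c,
        a = sum_i s_i E_i,  c = sum_i s_i g_i,  Fagg = sum_i s_i^2 F_i,

    and ``se = sigma_hat * sqrt(diag C^-1)``.  With ``method="aggregated"``
    (default) all m SNPs are computed through two weighted aggregations
    (weights ``s`` and ``s^2``) over the stacked feature table; the
    ``"loop"`` method scores one SNP at a time and exists as a slow
    reference path for tests.

    Parameters
    ----------
    missing_policy : {"mean_impute", "skip"}, optional
        If given, missing dosages are resolved here; otherwise the block is
        assumed clean (or already passed through
        :func:`handle_missing_dosage`).
    """
    if block.subject_ids is not None and pc.subject_ids is not None:
        if len(block.subject_ids) != pc.n_subjects or np.any(
            np.asarray(block.subject_ids) != pc.subject_ids
        ):
            raise ValueError("dosage block subject order does not match precompute")
    elif block.n_subjects != pc.n_subjects:
        raise ValueError("dosage block has wrong number of subjects")

    if missing_policy is not None:
        block = handle_missing_dosage(block, missing_policy)
    elif np.isnan(block.dosages).any():
        raise ValueError(
            "block contains missing dosages; pass missing_policy or use "
            "handle_missing_dosage first"
        )
    if block.m == 0:
        return []

    if method == "loop":
        out = []
        for j in range(block.m):
            sub = DosageBlock(
                dosages=block.dosages[:, j : j + 1],
                snp_ids=[block.snp_ids[j]],
                subject_ids=block.subject_ids,
                imputed=None if block.imputed is None else block.imputed[j : j + 1],
                unscored=None if block.unscored is None else block.unscored[j : j + 1],
            )
            out.extend(
                score_block(
                    pc,
                    sub,
                    method="aggregated",
                    monomorphic_var=monomorphic_var,
                    max_condition=max_condition,
                )
            )
        return out
    if method != "aggregated":
        raise ValueError(f"unknown method: {method!r}")

    s = block.dosages
    n, m = s.shape
    p = pc.p
    mean_s = s.mean(axis=0)
    var_s = s.var(axis=0)

    # two weighted aggregations over the per-subject features; transposed
    # matmuls keep every temporary O(n + m * p), apart from one (n, m)
    # buffer for s^2 — never the O(n * k * m) row expansion
    Ef = pc.E.reshape(n, 2 * p)
    Ff = pc.F.reshape(n, 4)
    a = (Ef.T @ s).T.reshape(m, 2, p)  # sum_i s_i E_i
    c = (pc.g.T @ s).T  # (m, 2)
    s2 = s * s
    Fagg = (Ff.T @ s2).T.reshape(m, 2, 2)
    del s2

    # a M^-1 a'
    AM = linalg.cho_solve(pc.M_cho, a.reshape(m * 2, p).T).T.reshape(m, 2, p)
    quad = np.einsum("mip,mjp->mij", a, AM)
    C = Fagg - quad
    C = (C + np.swapaxes(C, 1, 2)) / 2.0

    Cinv, det, cond = _inv2(C)
    ok = (var_s >= monomorphic_var) & (cond <= max_condition) & (det > 0)
    if block.unscored is not None:
        ok &= np.array([u is None for u in block.unscored])

    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.einsum("mij,mj->mi", Cinv, c)
        var_beta = pc.sigma2 * np.stack([Cinv[:, 0, 0], Cinv[:, 1, 1]], axis=1)
        se = np.sqrt(np.where(var_beta > 0, var_beta, np.nan))

    n_imputed = block.imputed if block.imputed is not None else np.zeros(m, int)
    results = []
    for j in range(m):
        if block.unscored is not None and block.unscored[j] is not None:
            status = block.unscored[j]
        elif var_s[j] < monomorphic_var:
            status = STATUS_MONOMORPHIC
        elif not ok[j]:
            status = STATUS_SINGULAR
        else:
            status = STATUS_OK
        if status == STATUS_OK:
            z, pv = wald_pvalues(beta[j], se[j])
            results.append(
                SnpResult(
                    snp_id=str(block.snp_ids[j]),
                    beta2=float(beta[j, 0]),
                    beta3=float(beta[j, 1]),
                    se2=float(se[j, 0]),
                    se3=float(se[j, 1]),
                    z2=float(z[0]),
                    z3=float(z[1]),
                    p2=float(pv[0]),
                    p3=float(pv[1]),
                    n_used=n,
                    mean_dosage=float(mean_s[j]),
                    status=status,
                    n_imputed=int(n_imputed[j]),
                )
            )
        else:
            results.append(
                SnpResult(
                    snp_id=str(block.snp_ids[j]),
                    beta2=np.nan,
                    beta3=np.nan,
                    se2=np.nan,
                    se3=np.nan,
                    z2=np.nan,
                    z3=np.nan,
                    p2=np.nan,
                    p3=np.nan,
                    n_used=0 if status == STATUS_ALL_MISSING else n,
                    mean_dosage=float(mean_s[j]) if status != STATUS_ALL_MISSING else np.nan,
                    status=status,
                    n_imputed=int(n_imputed[j]),
                )
            )
    return results
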