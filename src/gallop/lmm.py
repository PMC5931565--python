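"""Linear mixed-model algebra for the random-intercept-and-slope model.

The model for subject ``i`` with observations ``y_i`` at times ``t_i`` is

    y_i = X_i beta + Z_i b_i + e_i,   b_i ~ N(0, D),   e_i ~ N(0, sigma^2 I)

with ``Z_i = [1, t_i]`` and ``D`` a 2x2 positive-definite covariance of the
random intercept and slope.  At known variance components the joint
estimates of ``beta`` and ``b`` solve the penalized least-squares
(Henderson) system with per-subject penalty ``P* = (D / sigma^2)^-1``.

This module provides:

* per-subject sufficient statistics ``S_i = Z_i' W_i Z_i``,
  ``R_i = Z_i' W_i X_i``, ``r_i = Z_i' W_i y_i`` (``W_i`` a 0/1 diagonal
  encoding missing rows);
* a profiled-REML optimizer for the variance components that works purely
  on those 2x2 statistics, so one fit costs O(n) with tiny constants;
* an exact dense solver for the weighted Henderson system (the oracle the
  fast per-SNP path is validated against);
* the per-subject rotation ``Phi_i`` with ``Phi_i (S_i + P*) Phi_i' = I``
  that turns the random-effect block of the system into the identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .data import LongitudinalData, assemble

__all__ = [
    "VarianceComponents",
    "SubjectBlocks",
    "subject_blocks",
    "rotate",
    "henderson_solve",
    "HendersonSolution",
    "LongitudinalLMM",
    "LongitudinalLMMResults",
    "fit_variance_components",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """REML optimization failed to converge."""


@dataclass
class VarianceComponents:
    """Variance components of the random-intercept-and-slope model.

    ``D`` is the 2x2 covariance of (random intercept, random slope);
    ``sigma2`` the measurement-error variance.  ``P_star = (D/sigma2)^-1``
    is the penalty attached to each subject's random effects in the
    penalized least-squares formulation.
    """

    D: np.ndarray
    sigma2: float

    def __post_init__(self):
        self.D = np.asarray(self.D, float)
        if self.D.shape != (2, 2):
            raise ValueError("D must be 2x2")
        if not np.allclose(self.D, self.D.T):
            raise ValueError("D must be symmetric")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        ev = np.linalg.eigvalsh(self.D)
        if ev[0] <= 0:
            raise ValueError("D must be positive definite")

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.sigma2))

    @property
    def P_star(self) -> np.ndarray:
        P = np.linalg.inv(self.D / self.sigma2)
        return (P + P.T) / 2.0


@dataclass
class SubjectBlocks:
    """Weighted per-subject sufficient statistics and their global sums.

    ``S``: (n,2,2) blocks Z_i'W_iZ_i; ``R``: (n,2,p) blocks Z_i'W_iX_i;
    ``r``: (n,2) vectors Z_i'W_iy_i; ``A11 = sum X_i'W_iX_i``;
    ``q1 = sum X_i'W_iy_i``; ``yy = sum y_i'W_iy_i``; ``n_obs``: total
    weight-1 rows.
    """

    S: np.ndarray
    R: np.ndarray
    r: np.ndarray
    A11: np.ndarray
    q1: np.ndarray
    yy: float
    n_obs: int
    yy_i: np.ndarray | None = None  # per-subject sum of w y^2

    @property
    def n_subjects(self) -> int:
        return self.S.shape[0]

    @property
    def p(self) -> int:
        return self.R.shape[2]


def _segment_sum(values: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Sum `values` (rows) within each subject segment.

    Implemented as cumulative-sum differences: a sequential scan adds 0.0
    exactly, so zero-weighted rows give bit-identical segment sums to
    physically deleted rows (pairwise summation would regroup terms).
    """
    cs = np.cumsum(values, axis=0)
    ends = starts[1:] - 1
    out = cs[ends].copy()
    out[1:] -= cs[ends[:-1]]
    return out


def subject_blocks(data: LongitudinalData) -> SubjectBlocks:
    """Compute weighted per-subject sufficient statistics.

    Zero-weight rows enter every sum multiplied by 0, so the result is
    identical to physically removing those rows first.
    """
    w = data.w
    t = data.t_filled
    y = data.y_filled
    X = data.X_star
    starts = data.starts

    wt = w * t
    # S_i entries: [sum w, sum w t; sum w t, sum w t^2]
    s00 = _segment_sum(w, starts)
    s01 = _segment_sum(wt, starts)
    s11 = _segment_sum(wt * t, starts)
    S = np.empty((data.n_subjects, 2, 2))
    S[:, 0, 0] = s00
    S[:, 0, 1] = S[:, 1, 0] = s01
    S[:, 1, 1] = s11

    wX = w[:, None] * X
    wtX = wt[:, None] * X
    R = np.stack(
        [_segment_sum(wX, starts), _segment_sum(wtX, starts)], axis=1
    )  # (n, 2, p)
    r = np.stack([_segment_sum(w * y, starts), _segment_sum(wt * y, starts)], axis=1)

    # global sums accumulated per subject first so that zero-weighted rows
    # give bit-identical results to deleted rows
    XtX_rows = wX[:, :, None] * X[:, None, :]
    A11 = _segment_sum(XtX_rows, starts).sum(axis=0)
    q1 = _segment_sum(wX * y[:, None], starts).sum(axis=0)
    yy_i = _segment_sum(w * y * y, starts)
    return SubjectBlocks(
        S=S, R=R, r=r, A11=A11, q1=q1, yy=float(yy_i.sum()),
        n_obs=int(w.sum()), yy_i=yy_i,
    )


def rotate(S_i: np.ndarray, P_star: np.ndarray):
    """Per-subject rotation diagonalizing the random-effect block.

    For each subject let ``U_i Omega_i U_i'`` be the eigendecomposition of
    ``S_i + P*`` and set ``Phi_i = Omega_i^{-1/2} U_i'`` so that
    ``Phi_i (S_i + P*) Phi_i' = I``.  Accepts a single 2x2 block or a
    batched (n,2,2) array.

    Returns
    -------
    Phi : ndarray, same leading shape, (…,2,2)
    U : ndarray of eigenvectors (columns)
    omega : ndarray of eigenvalues (ascending)

    Raises
    ------
    ValueError
        If any ``S_i + P*`` is not positive definite.
    """
    S_i = np.asarray(S_i, float)
    A = S_i + P_star
    omega, U = np.linalg.eigh(A)
    if np.min(omega) <= 0:
        raise ValueError(
            "S_i + P* not positive definite (eigenvalue <= 0); "
            "check the variance components"
        )
    # Phi = diag(omega^-1/2) U'
    Phi = np.swapaxes(U, -1, -2) / np.sqrt(omega)[..., None]
    return Phi, U, omega


@dataclass
class HendersonSolution:
    """Exact solution of the weighted penalized least-squares system."""

    beta: np.ndarray  # fixed effects, length p_full
    b: np.ndarray  # random effects, (n, 2)
    cov_beta: np.ndarray  # sigma2 * upper-left block of the system inverse
    sigma2: float


def henderson_solve(
    X: np.ndarray,
    Z: np.ndarray,
    groups: np.ndarray,
    P: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    sigma2: float = 1.0,
) -> HendersonSolution:
    """Dense solve of the weighted Henderson / penalized LS system.

    Solves ``[[X'WX, X'WZ], [Z'WX, Z'WZ + P_blk]] (beta; b) = (X'Wy; Z'Wy)``
    where ``Z`` is block diagonal per subject with blocks ``Z_i = [1, t_i]``
    (passed stacked as an (N,2) array plus a subject index per row) and
    ``P_blk`` repeats the 2x2 penalty ``P`` for every subject.

    This is the exact reference path: it is O((p + 2n)^3) and is used as
    the oracle against which the fast per-SNP solver is validated.

    Parameters
    ----------
    X : (N, p_full) fixed-effect design (may include SNP columns).
    Z : (N, 2) random-effect design rows.
    groups : (N,) int subject index per row, 0..n-1.
    P : (2, 2) positive-definite penalty ``(D/sigma^2)^-1``.
    y : (N,) outcomes.
    weights : (N,) 0/1 weights; ``None`` means all ones.
    sigma2 : scale used for the coefficient covariance
        (``cov_beta = sigma2 * [(system)^-1]_{beta,beta}``).

    Raises
    ------
    np.linalg.LinAlgError
        If the system is singular; the message names the offending
        fixed-effect columns when collinearity is detected.
    """
    X = np.atleast_2d(np.asarray(X, float))
    Z = np.asarray(Z, float)
    y = np.asarray(y, float)
    groups = np.asarray(groups)
    n = int(groups.max()) + 1
    p_full = X.shape[1]
    if weights is None:
        weights = np.ones(len(y))
    w = np.asarray(weights, float)

    Xw = X * w[:, None]
    Zw = Z * w[:, None]
    dim = p_full + 2 * n
    H = np.zeros((dim, dim))
    H[:p_full, :p_full] = Xw.T @ X
    rhs = np.zeros((dim,))
    rhs[:p_full] = Xw.T @ y
    for i in range(n):
        rows = groups == i
        Zi = Z[rows]
        sl = slice(p_full + 2 * i, p_full + 2 * i + 2)
        H[:p_full, sl] = Xw[rows].T @ Zi
        H[sl, :p_full] = H[:p_full, sl].T
        H[sl, sl] = Zw[rows].T @ Zi + P
        rhs[sl] = Zw[rows].T @ y[rows]

    try:
        cf = linalg.cho_factor(H)
    except np.linalg.LinAlgError:
        # name the collinear fixed-effect columns
        _, Rq, piv = linalg.qr(Xw, pivoting=True, mode="economic")
        diag = np.abs(np.diag(Rq))
        tol = diag.max() * max(Xw.shape) * np.finfo(float).eps if diag.size else 0.0
        bad = sorted(piv[diag <= tol].tolist())
        raise np.linalg.LinAlgError(
            f"singular Henderson system; collinear fixed-effect columns: {bad}"
        )
    sol = linalg.cho_solve(cf, rhs)
    eye_p = np.zeros((dim, p_full))
    eye_p[:p_full, :p_full] = np.eye(p_full)
    inv_top = linalg.cho_solve(cf, eye_p)[:p_full, :]
    return HendersonSolution(
        beta=sol[:p_full],
        b=sol[p_full:].reshape(n, 2),
        cov_beta=sigma2 * (inv_top + inv_top.T) / 2.0,
        sigma2=sigma2,
    )


# ---------------------------------------------------------------------------
# Profiled REML on the 2x2 sufficient statistics
# ---------------------------------------------------------------------------


def _reml_neg2loglik(x: np.ndarray, blocks: SubjectBlocks):
    """Profiled REML criterion at log-Cholesky parameters of A = D/sigma^2.

    Both beta and sigma^2 are profiled out; the criterion is
    ``sum_i log|I + S_i A| + log|sum_i X_i' Vtil_i^-1 X_i| + (N-p) log RSS``
    up to an additive constant, with ``Vtil_i = I + Z_i A Z_i'``.
    Returns (criterion, beta, sigma2_reml, B) where ``B`` is the GLS
    information matrix on the unit-error scale.
    """
    l0, c, l2 = x
    L = np.array([[np.exp(l0), 0.0], [c, np.exp(l2)]])
    A = L @ L.T

    S, R, r = blocks.S, blocks.R, blocks.r
    SA = S @ A
    IA = SA + np.eye(2)
    det = IA[:, 0, 0] * IA[:, 1, 1] - IA[:, 0, 1] * IA[:, 1, 0]
    if np.any(det <= 0) or not np.all(np.isfinite(det)):
        return np.inf, None, None, None
    inv = np.empty_like(IA)
    inv[:, 0, 0] = IA[:, 1, 1]
    inv[:, 1, 1] = IA[:, 0, 0]
    inv[:, 0, 1] = -IA[:, 0, 1]
    inv[:, 1, 0] = -IA[:, 1, 0]
    inv /= det[:, None, None]
    # Woodbury middle factor: Vtil^-1 = I - Z Q Z' with Q = A (I + S A)^-1
    Q = A @ inv
    Q = (Q + np.swapaxes(Q, 1, 2)) / 2.0

    QR = Q @ R  # (n, 2, p)
    B = blocks.A11 - np.einsum("nip,niq->pq", R, QR)
    Qr = np.einsum("nij,nj->ni", Q, r)
    cvec = blocks.q1 - np.einsum("nip,ni->p", R, Qr)
    a = blocks.yy - float(np.einsum("ni,ni->", r, Qr))

    sB, ldB = np.linalg.slogdet(B)
    if sB <= 0:
        return np.inf, None, None, None
    try:
        beta = np.linalg.solve(B, cvec)
    except np.linalg.LinAlgError:
        return np.inf, None, None, None
    rss = a - float(cvec @ beta)
    dof = blocks.n_obs - blocks.p
    if rss <= 0 or dof <= 0:
        return np.inf, None, None, None
    crit = float(np.log(det).sum() + ldB + dof * np.log(rss))
    return crit, beta, rss / dof, B


def _log_cholesky(A: np.ndarray) -> np.ndarray:
    c = np.linalg.cholesky(A)
    return np.array([np.log(c[0, 0]), c[1, 0], np.log(c[1, 1])])


def _moment_start(blocks: SubjectBlocks) -> np.ndarray | None:
    """Method-of-moments start for A = D/sigma^2.

    Per-subject OLS lines fitted to the covariate-adjusted outcome give
    intercept/slope estimates whose dispersion, minus its sampling part,
    approximates D; pooled within-subject residuals approximate sigma^2.
    Rough on purpose — this only seeds the optimizer.
    """
    k_i = blocks.S[:, 0, 0]
    det = blocks.S[:, 0, 0] * blocks.S[:, 1, 1] - blocks.S[:, 0, 1] ** 2
    use = (k_i >= 3) & (det > 1e-8 * np.maximum(blocks.S[:, 1, 1], 1.0))
    if use.sum() < 10:
        return None
    beta_ols = np.linalg.solve(blocks.A11, blocks.q1)
    r_e = blocks.r - np.einsum("nip,p->ni", blocks.R, beta_ols)
    Sinv = np.linalg.inv(blocks.S[use])
    coef = np.einsum("nij,nj->ni", Sinv, r_e[use])
    # within-subject residual variance around each subject's own line
    rss = blocks.yy_i[use] - np.einsum(
        "ni,nij,nj->n", blocks.r[use], Sinv, blocks.r[use]
    )
    dof = k_i[use] - 2
    s2_w = float(np.sum(np.maximum(rss, 0.0)) / max(np.sum(dof), 1.0))
    if not np.isfinite(s2_w) or s2_w <= 0:
        return None
    D0 = np.cov(coef.T) - s2_w * Sinv.mean(axis=0)
    A0 = (D0 + D0.T) / (2.0 * s2_w)
    ev, U = np.linalg.eigh(A0)
    A0 = (U * np.clip(ev, 1e-3, None)) @ U.T
    return _log_cholesky(A0)


def _reml_optimize(blocks: SubjectBlocks, x0=None, maxiter=4000):
    obj = lambda x: _reml_neg2loglik(x, blocks)[0]
    mean_t2 = max(
        float(np.mean(blocks.S[:, 1, 1] / np.maximum(blocks.S[:, 0, 0], 1.0))),
        1e-2,
    )
    if x0 is not None:
        starts = [np.asarray(x0, float)]
    else:
        # the REML surface can have a boundary-trapped local optimum, so
        # seed from moments plus small/moderate fallbacks and keep the best
        starts = []
        ms = _moment_start(blocks)
        if ms is not None:
            starts.append(ms)
        for scale in (0.7, 0.05):
            starts.append(
                np.array([np.log(scale) / 2, 0.0, 0.5 * np.log(scale / mean_t2)])
            )
    probes = []
    for s in starts:
        probes.append(
            optimize.minimize(
                obj, s, method="Nelder-Mead",
                options=dict(xatol=1e-4, fatol=1e-5, maxiter=maxiter, maxfev=maxiter),
            )
        )
    best = min(probes, key=lambda r: r.fun)
    # polish with a fresh simplex; the criterion is flat to ~1e-9 near the
    # optimum, so tighter tolerances than this cannot converge
    res2 = optimize.minimize(
        obj, best.x, method="Nelder-Mead",
        options=dict(xatol=1e-8, fatol=1e-9, maxiter=maxiter, maxfev=maxiter),
    )
    return res2 if res2.fun <= best.fun else best


@dataclass
class LongitudinalLMMResults:
    """REML fit of the random-intercept-and-slope mixed model.

    Carries the variance components, fixed-effect estimates with their
    covariance, BLUPs of the per-subject random effects (both in the
    rotated ``theta`` coordinates and backtransformed), fitted values and
    residuals.
    """

    model: "LongitudinalLMM"
    vc: VarianceComponents
    params: pd.Series
    cov_params: pd.DataFrame
    random_effects: np.ndarray  # (n, 2) BLUPs b_i*
    theta: np.ndarray  # (n, 2) rotated random effects
    fitted_values: np.ndarray  # per row, zero-weight rows included
    converged: bool
    n_iter: int
    reml_criterion: float
    boundary: bool = False

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.cov_params.to_numpy())), index=self.params.index
        )

    @property
    def resid(self) -> np.ndarray:
        data = self.model.data
        return np.where(data.w > 0, data.y - self.fitted_values, np.nan)

    @property
    def D(self) -> np.ndarray:
        return self.vc.D

    @property
    def sigma2(self) -> float:
        return self.vc.sigma2

    def r2(self) -> float:
        """Predictive R^2 = 1 - ||y - yhat||^2 / ||y - ybar||^2 on valid rows."""
        from .study import compute_r2

        m = self.model.data.w > 0
        return compute_r2(self.model.data.y[m], self.fitted_values[m])

    def summary(self) -> str:
        d = self.vc.D
        lines = [
            "Longitudinal mixed model (random intercept and slope), REML",
            f"subjects: {self.model.data.n_subjects}   "
            f"observations: {self.model.data.n_obs}   "
            f"fixed effects: {len(self.params)}",
            f"converged: {self.converged}   boundary: {self.boundary}",
            "",
            "Variance components",
            f"  D = [[{d[0, 0]: .6g}, {d[0, 1]: .6g}],",
            f"       [{d[1, 0]: .6g}, {d[1, 1]: .6g}]]",
            f"  sigma^2 = {self.vc.sigma2:.6g}  (sigma = {self.vc.sigma:.6g})",
            "",
            "Fixed effects",
            f"  {'term':<16}{'coef':>12}{'std err':>12}{'z':>10}",
        ]
        bse = self.bse
        for name in self.params.index:
            b, s = self.params[name], bse[name]
            lines.append(f"  {name:<16}{b:>12.5g}{s:>12.5g}{b / s:>10.3f}")
        return "\n".join(lines)


class LongitudinalLMM:
    """Random-intercept-and-slope mixed model for long-format data.

    The statsmodels-style front end to the reduced (SNP-free) model: build
    from a :class:`~gallop.data.LongitudinalData` (or a long-format
    DataFrame via :meth:`from_dataframe`), call :meth:`fit` for REML
    estimates of ``D`` and ``sigma^2`` together with GLS fixed effects and
    BLUPs.

    Examples
    --------
    >>> from gallop import SimulationConfig, simulate_dataset, LongitudinalLMM
    >>> data, _, _ = simulate_dataset(SimulationConfig(n=300, seed=1))
    >>> res = LongitudinalLMM(data).fit()
    >>> res.vc.D.shape
    (2, 2)
    """

    def __init__(self, data: LongitudinalData):
        if data.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if (data.counts[np.add.reduceat(data.w, data.starts[:-1]) >= 2].size) < 2:
            raise ValueError(
                "need at least 2 subjects with >= 2 observations to "
                "identify a random slope"
            )
        if data.p >= data.n_obs:
            raise ValueError("more fixed effects than observations")
        self.data = data
        self.blocks = subject_blocks(data)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **assemble_kwargs) -> "LongitudinalLMM":
        return cls(assemble(df, **assemble_kwargs))

    def fit(
        self,
        start=None,
        maxiter: int = 4000,
        boundary_tol: float = 1e-6,
        on_boundary: str = "warn",
    ) -> LongitudinalLMMResults:
        """Estimate variance components by profiled REML.

        Parameters
        ----------
        start : optional (3,) log-Cholesky start for ``D/sigma^2``.
        on_boundary : {"warn", "raise", "ignore"}
            What to do when ``D`` is estimated at (numerically) the
            boundary of the positive-definite cone; downstream per-SNP
            scoring needs a PD ``D``.
        """
        res = _reml_optimize(self.blocks, x0=start, maxiter=maxiter)
        crit, beta, sigma2, B = _reml_neg2loglik(res.x, self.blocks)
        if not res.success or beta is None:
            raise ConvergenceError(f"REML did not converge: {res.message}")
        l0, c, l2 = res.x
        L = np.array([[np.exp(l0), 0.0], [c, np.exp(l2)]])
        A = L @ L.T
        D = sigma2 * A
        ev = np.linalg.eigvalsh(A)
        boundary = bool(ev[0] < boundary_tol * max(ev[1], 1.0))
        if boundary:
            msg = (
                "estimated D is on (or numerically at) the boundary of the "
                "PD cone; per-SNP scoring requires a PD D"
            )
            if on_boundary == "raise":
                raise ConvergenceError(msg)
            if on_boundary == "warn":
                warnings.warn(msg, RuntimeWarning, stacklevel=2)
            # keep D usable downstream
            D = D + boundary_tol * max(ev[1] * sigma2, sigma2) * np.eye(2)

        vc = VarianceComponents(D=(D + D.T) / 2.0, sigma2=float(sigma2))
        cov = sigma2 * np.linalg.inv(B)
        names = self.data.fixed_effect_names

        # BLUPs from the rotated system (identical to the Henderson solve)
        Phi, U, omega = rotate(self.blocks.S, vc.P_star)
        Atil = Phi @ self.blocks.R
        qtil = np.einsum("nij,nj->ni", Phi, self.blocks.r)
        theta = qtil - np.einsum("nip,p->ni", Atil, beta)
        b_star = np.einsum("nji,nj->ni", Phi, theta)  # Phi' theta

        data = self.data
        fitted = data.X_star @ beta + np.sum(
            data.Z * b_star[data.row_subject], axis=1
        )
        return LongitudinalLMMResults(
            model=self,
            vc=vc,
            params=pd.Series(beta, index=names),
            cov_params=pd.DataFrame((cov + cov.T) / 2.0, index=names, columns=names),
            random_effects=b_star,
            theta=theta,
            fitted_values=fitted,
            converged=bool(res.success),
            n_iter=int(res.nit),
            reml_criterion=float(crit),
            boundary=boundary,
        )


def fit_variance_components(
    data: LongitudinalData, **fit_kwargs
) -> tuple[VarianceComponents, LongitudinalLMMResults]:
    """REML variance components and reduced-model fit for assembled data.

    Functional wrapper around :class:`LongitudinalLMM`; returns
    ``(VarianceComponents, LongitudinalLMMResults)``.
    """
    res = LongitudinalLMM(data).fit(**fit_kwargs)
    return res.vc, res
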