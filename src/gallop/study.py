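"""Accuracy study: fast per-SNP scoring vs exact per-SNP REML refits.

Reproduces the precision experiment for the scoring approximation: many
datasets are simulated from the full model over a grid of SNP effect
sizes; each dataset's SNP is scored both with the fast bordered solver
(variance components fixed at the SNP-free fit) and with a full REML refit
of the SNP model, the exact-but-slow comparator.  From the paired results
the report derives the threshold calibration (the fast scan's -log10 p
needed to capture every refit-significant SNP) and the contribution of the
SNP effects to the predictive R^2.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import add_covariates
from .engine import neglog10_pvalues, precompute, score_block
from .lmm import ConvergenceError, LongitudinalLMM
from .simulate import SimulationConfig, effect_grid, simulate_dataset

__all__ = [
    "AccuracyReport",
    "run_accuracy_study",
    "compute_r2",
    "threshold_calibration",
]


def compute_r2(y, fitted) -> float:
    """Predictive R^2 = 1 - ||y - yhat||^2 / ||y - ybar||^2."""
    y = np.asarray(y, float)
    fitted = np.asarray(fitted, float)
    if y.shape != fitted.shape:
        raise ValueError("y and fitted must have equal length")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("constant outcome: R^2 undefined")
    return 1.0 - float(np.sum((y - fitted) ** 2)) / ss_tot


@dataclass
class AccuracyReport:
    """Paired fast-scan vs REML-refit results over the effect grid.

    ``table`` has one row per replicate with the true effects, both sets
    of estimates/SEs/-log10 p for the cross-sectional and longitudinal
    effects, the full- and reduced-model R^2, and the replicate's
    variance-component estimates.
    """

    table: pd.DataFrame
    config: SimulationConfig
    seed: int | None
    refit_cut: float = 7.3
    comparator: str = "profiled-REML refit of the SNP model (normal Wald)"

    @property
    def n_replicates(self) -> int:
        return len(self.table)

    def paired_neglogp(self) -> pd.DataFrame:
        """Long view: one row per (replicate, effect) with both -log10 p."""
        rows = []
        for eff, g, r in (
            ("cs", "gallop_nlp_cs", "refit_nlp_cs"),
            ("long", "gallop_nlp_long", "refit_nlp_long"),
        ):
            sub = self.table.loc[self.table["refit_ok"], ["rep", g, r]].copy()
            sub.columns = ["rep", "gallop_nlp", "refit_nlp"]
            sub["effect"] = eff
            rows.append(sub)
        return pd.concat(rows, ignore_index=True)

    def threshold_calibration(self, refit_cut: float | None = None) -> float:
        """Fast-scan -log10 p threshold capturing all refit-significant SNPs."""
        return threshold_calibration(self, refit_cut or self.refit_cut)

    def max_r2_contribution(self, marginal: bool = True) -> float:
        """Largest SNP contribution to R^2 (full minus reduced) on the grid.

        ``marginal=True`` (default) compares fixed-effects-only fitted
        values, i.e. the variance the SNP terms explain beyond the other
        fixed effects.  ``marginal=False`` uses fitted values including
        the BLUPs; because a subject-constant SNP effect is absorbed
        almost entirely by the random intercept and slope, that
        difference is near zero by construction.
        """
        d = self.table.loc[self.table["refit_ok"]]
        if marginal:
            return float((d["r2_marg_full"] - d["r2_marg_reduced"]).max())
        return float((d["r2_full"] - d["r2_reduced"]).max())

    def max_abs_beta_diff(self) -> float:
        d = self.table.loc[self.table["refit_ok"]]
        return float(
            np.maximum(
                (d["gallop_beta_cs"] - d["refit_beta_cs"]).abs(),
                (d["gallop_beta_long"] - d["refit_beta_long"]).abs(),
            ).max()
        )

    def se_ratio(self) -> pd.DataFrame:
        """Fast-scan / refit SE ratios (the SE inflation curve)."""
        d = self.table.loc[self.table["refit_ok"]]
        return pd.DataFrame(
            {
                "beta2_true": d["beta2_true"],
                "beta3_true": d["beta3_true"],
                "se_ratio_cs": d["gallop_se_cs"] / d["refit_se_cs"],
                "se_ratio_long": d["gallop_se_long"] / d["refit_se_long"],
            }
        )

    def summary(self) -> dict:
        tau = self.threshold_calibration()
        return {
            "n_replicates": self.n_replicates,
            "n_refit_failed": int((~self.table["refit_ok"]).sum()),
            "refit_cut": self.refit_cut,
            "tau": tau,
            "max_r2_contribution": self.max_r2_contribution(),
            "max_abs_beta_diff": self.max_abs_beta_diff(),
            "comparator": self.comparator,
            "seed": self.seed,
        }

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)

    def plot_accuracy(self, kind: str = "pvalues", ax=None):
        """Scatter fast-scan vs refit (-log10 p or coefficients)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if kind == "pvalues":
            d = self.paired_neglogp()
            for eff, marker in (("cs", "o"), ("long", "s")):
                sub = d[d["effect"] == eff]
                ax.plot(
                    sub["refit_nlp"], sub["gallop_nlp"], marker,
                    ms=3, ls="", label=f"{eff} effect",
                )
            lim = max(d["refit_nlp"].max(), d["gallop_nlp"].max())
            ax.set_xlabel("-log10 p, REML refit")
            ax.set_ylabel("-log10 p, fast scan")
        elif kind == "coefficients":
            d = self.table[self.table["refit_ok"]]
            ax.plot(d["refit_beta_cs"], d["gallop_beta_cs"], "o", ms=3, ls="", label="cs")
            ax.plot(d["refit_beta_long"], d["gallop_beta_long"], "s", ms=3, ls="", label="long")
            lim = max(
                d[["refit_beta_cs", "refit_beta_long"]].abs().max().max(),
                d[["gallop_beta_cs", "gallop_beta_long"]].abs().max().max(),
            )
            ax.set_xlabel("coefficient, REML refit")
            ax.set_ylabel("coefficient, fast scan")
        else:
            raise ValueError(f"unknown kind: {kind!r}")
        ax.plot([0, lim], [0, lim], "k--", lw=1)
        ax.legend()
        return ax


def threshold_calibration(report: AccuracyReport, refit_cut: float = 7.3) -> float:
    """Smallest fast-scan -log10 p among refit-significant grid points.

    Declaring fast-scan hits at ``-log10 p > tau`` then captures every SNP
    the exact refit calls significant at ``refit_cut``.  Returns NaN (with
    a warning) when no grid point exceeds the cut.
    """
    pairs = report.paired_neglogp()
    hit = pairs["refit_nlp"] > refit_cut
    if not hit.any():
        warnings.warn(
            f"no grid point exceeds refit -log10 p > {refit_cut}; "
            "threshold undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return float(pairs.loc[hit, "gallop_nlp"].min())


def _refit_full_model(data, dosages_per_subject):
    """Exact comparator: REML refit of the mixed model including the SNP."""
    s_row = dosages_per_subject[data.row_subject]
    full = add_covariates(data, snp=s_row, snp_time=s_row * data.t_filled)
    res = LongitudinalLMM(full).fit(on_boundary="ignore")
    return res


def run_accuracy_study(
    cfg: SimulationConfig | None = None,
    n_replicates: int = 200,
    seed: int | None = None,
    grid_low: float = 0.0,
    grid_high: float = 1.0,
    refit: bool = True,
    refit_cut: float = 7.3,
) -> AccuracyReport:
    """Simulate over the effect grid and compare fast scan to REML refits.

    One dataset is generated per replicate.  The cross-sectional and
    longitudinal effect sizes each run over ``n_replicates`` equally
    spaced values between ``grid_low`` and ``grid_high``, paired through
    two independent random permutations, so the grid is covered once per
    effect.  Each dataset carries one SNP; it is scored by the fast
    bordered solver at the reduced-model variance components and, if
    ``refit`` is true, by a full REML refit of the SNP model.

    Refit non-convergence is recorded (``refit_ok`` False) and the point
    excluded from summaries.
    """
    if cfg is None:
        cfg = SimulationConfig()
    if cfg.n_snps != 1:
        raise ValueError("the accuracy study uses exactly one SNP per dataset")
    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = ss.spawn(n_replicates)

    grid = effect_grid(n_replicates, grid_low, grid_high)
    beta2s = grid[master.permutation(n_replicates)]
    beta3s = grid[master.permutation(n_replicates)]

    rows = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(child_seeds[rep])
        b2, b3 = float(beta2s[rep]), float(beta3s[rep])
        data, block, truth = simulate_dataset(cfg, snp_effects=(b2, b3), rng=rng)

        reduced = LongitudinalLMM(data).fit(on_boundary="ignore")
        pc = precompute(data, reduced.vc)
        (snp,) = score_block(pc, block)
        m = data.w > 0
        r2_reduced = compute_r2(data.y[m], reduced.fitted_values[m])
        fixed_red = data.X_star @ reduced.params.to_numpy()
        r2_marg_reduced = compute_r2(data.y[m], fixed_red[m])

        row = {
            "rep": rep,
            "beta2_true": b2,
            "beta3_true": b3,
            "gallop_beta_cs": snp.beta2,
            "gallop_beta_long": snp.beta3,
            "gallop_se_cs": snp.se2,
            "gallop_se_long": snp.se3,
            "gallop_nlp_cs": float(neglog10_pvalues(snp.z2)),
            "gallop_nlp_long": float(neglog10_pvalues(snp.z3)),
            "r2_reduced": r2_reduced,
            "r2_marg_reduced": r2_marg_reduced,
            "D00_hat": reduced.vc.D[0, 0],
            "D01_hat": reduced.vc.D[0, 1],
            "D11_hat": reduced.vc.D[1, 1],
            "sigma_hat": reduced.vc.sigma,
            "refit_ok": False,
        }
        if refit:
            try:
                res = _refit_full_model(data, block.dosages[:, 0])
                zc = res.params["snp"] / res.bse["snp"]
                zl = res.params["snp_time"] / res.bse["snp_time"]
                fixed_full = res.model.data.X_star @ res.params.to_numpy()
                row.update(
                    refit_beta_cs=res.params["snp"],
                    refit_beta_long=res.params["snp_time"],
                    refit_se_cs=res.bse["snp"],
                    refit_se_long=res.bse["snp_time"],
                    refit_nlp_cs=float(neglog10_pvalues(zc)),
                    refit_nlp_long=float(neglog10_pvalues(zl)),
                    r2_full=compute_r2(data.y[m], res.fitted_values[m]),
                    r2_marg_full=compute_r2(data.y[m], fixed_full[m]),
                    refit_ok=bool(res.converged),
                )
            except (ConvergenceError, np.linalg.LinAlgError):
                pass
        rows.append(row)

    return AccuracyReport(
        table=pd.DataFrame(rows),
        config=cfg,
        seed=seed,
        refit_cut=refit_cut,
    )
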