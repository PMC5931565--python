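"""Genome-wide scan front end: GallopModel / GallopResults.

``GallopModel`` ties the pieces together the way a practitioner runs them:
align subjects between phenotype and genotypes, fit the reduced mixed model
once (or accept known variance components), precompute the shared
factorization, then stream dosage chunks through the per-SNP solver.
"""

from __future__ import annotations

import logging
from dataclasses import asdict

import numpy as np
import pandas as pd

from .data import LongitudinalData, assemble
from .engine import (
    DosageBlock,
    GallopPrecompute,
    SnpResult,
    precompute,
    score_block,
)
from .lmm import LongitudinalLMM, LongitudinalLMMResults, VarianceComponents

__all__ = ["GallopModel", "GallopResults"]

logger = logging.getLogger("gallop")

RESULT_COLUMNS = [
    "snp",
    "n_used",
    "freq",
    "beta_cs",
    "se_cs",
    "z_cs",
    "p_cs",
    "beta_long",
    "se_long",
    "z_long",
    "p_long",
    "status",
]


def _results_frame(results: list[SnpResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp": [r.snp_id for r in results],
            "n_used": [r.n_used for r in results],
            "freq": [r.freq for r in results],
            "beta_cs": [r.beta2 for r in results],
            "se_cs": [r.se2 for r in results],
            "z_cs": [r.z2 for r in results],
            "p_cs": [r.p2 for r in results],
            "beta_long": [r.beta3 for r in results],
            "se_long": [r.se3 for r in results],
            "z_long": [r.z3 for r in results],
            "p_long": [r.p3 for r in results],
            "status": [r.status for r in results],
        }
    )


class GallopResults:
    """Results of a genome-wide longitudinal scan.

    Attributes
    ----------
    table : DataFrame
        One row per input SNP (``beta_cs``/``p_cs`` the cross-sectional
        main effect, ``beta_long``/``p_long`` the SNP-by-time effect;
        unscored SNPs keep their row with an explanatory ``status``).
    reduced : LongitudinalLMMResults or None
        The SNP-free mixed-model fit whose variance components were reused
        for every SNP.
    """

    def __init__(
        self,
        model: "GallopModel",
        table: pd.DataFrame,
        reduced: LongitudinalLMMResults | None,
        vc: VarianceComponents,
        pc: GallopPrecompute,
    ):
        self.model = model
        self.table = table
        self.reduced = reduced
        self.vc = vc
        self.precompute = pc

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def n_flagged(self) -> int:
        return int((self.table["status"] != "ok").sum())

    def top(self, n: int = 10, effect: str = "long") -> pd.DataFrame:
        col = "p_long" if effect == "long" else "p_cs"
        return self.table.nsmallest(n, col)

    def summary(self) -> str:
        d = self.vc.D
        ok = self.table["status"] == "ok"
        lines = [
            "GALLOP genome-wide longitudinal scan",
            f"subjects: {self.precompute.n_subjects}   SNPs: {self.n_snps} "
            f"(scored: {int(ok.sum())}, flagged: {self.n_flagged})",
            f"variance components: D = [[{d[0,0]:.4g}, {d[0,1]:.4g}], "
            f"[{d[1,0]:.4g}, {d[1,1]:.4g}]], sigma^2 = {self.vc.sigma2:.4g}",
        ]
        if ok.any():
            best_l = self.table.loc[ok, "p_long"].idxmin()
            best_c = self.table.loc[ok, "p_cs"].idxmin()
            rl, rc = self.table.loc[best_l], self.table.loc[best_c]
            lines += [
                f"top SNP-by-time effect: {rl['snp']} "
                f"(beta = {rl['beta_long']:.4g}, p = {rl['p_long']:.3g})",
                f"top main effect:        {rc['snp']} "
                f"(beta = {rc['beta_cs']:.4g}, p = {rc['p_cs']:.3g})",
            ]
        return "\n".join(lines)

    def to_tsv(self, path, raw: bool = False) -> None:
        from .io import write_results

        write_results(self.table, path, raw=raw)

    def plot_qq(self, effect: str = "long", ax=None):
        """QQ plot of observed vs expected -log10 p for one effect."""
        import matplotlib.pyplot as plt

        col = "p_long" if effect == "long" else "p_cs"
        p = np.sort(self.table.loc[self.table["status"] == "ok", col].to_numpy())
        exp = -np.log10((np.arange(1, len(p) + 1) - 0.5) / len(p))
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(exp, -np.log10(p), ".", ms=3)
        lim = max(exp.max(), -np.log10(p.min()))
        ax.plot([0, lim], [0, lim], "k--", lw=1)
        ax.set_xlabel("expected -log10 p")
        ax.set_ylabel("observed -log10 p")
        ax.set_title(f"{'SNP x time' if effect == 'long' else 'main'} effect")
        return ax


class GallopModel:
    """Genome-wide association scan of a longitudinal phenotype.

    Parameters
    ----------
    data : LongitudinalData
        Assembled phenotype data (see :func:`gallop.assemble`).
    genotypes : DosageBlock, ndarray or DosageStore
        Subjects-by-SNPs dosage matrix, or a store from :mod:`gallop.io`
        for chunked access.  Subject identifiers, when present, are
        aligned with the phenotype by intersection; phenotype order wins,
        phenotype subjects absent from the store are dropped (logged),
        duplicate store ids are an error.
    vc : VarianceComponents, optional
        Known variance components; by default REML-estimated from the
        SNP-free model.
    missing_dosage : {"mean_impute", "skip"}
    chunk_size : SNPs per scoring block.

    Examples
    --------
    >>> from gallop import SimulationConfig, simulate_dataset, GallopModel
    >>> cfg = SimulationConfig(n=300, n_snps=20, seed=7)
    >>> data, block, _ = simulate_dataset(cfg)
    >>> res = GallopModel(data, block).fit()
    >>> len(res.table)
    20
    """

    def __init__(
        self,
        data: LongitudinalData,
        genotypes,
        vc: VarianceComponents | None = None,
        missing_dosage: str = "mean_impute",
        chunk_size: int = 1000,
    ):
        self.vc = vc
        self.missing_dosage = missing_dosage
        self.chunk_size = int(chunk_size)
        self._store = None

        if isinstance(genotypes, DosageBlock):
            geno_ids = genotypes.subject_ids
        elif isinstance(genotypes, np.ndarray):
            genotypes = DosageBlock(
                dosages=genotypes,
                snp_ids=[f"snp{j + 1}" for j in range(np.atleast_2d(genotypes).shape[1])],
                subject_ids=data.subject_ids,
            )
            geno_ids = genotypes.subject_ids
        else:  # a DosageStore-like object
            self._store = genotypes
            geno_ids = np.asarray(genotypes.subject_ids)

        self.data, self._geno_index, self.n_dropped = self._align(
            data, geno_ids
        )
        self.genotypes = genotypes

    @staticmethod
    def _align(data: LongitudinalData, geno_ids):
        if geno_ids is None:
            return data, None, 0
        geno_ids = np.asarray(geno_ids)
        if len(np.unique(geno_ids)) != len(geno_ids):
            raise ValueError("duplicate subject ids in the genotype store")
        pos = {sid: i for i, sid in enumerate(geno_ids)}
        keep = np.array([sid in pos for sid in data.subject_ids])
        n_dropped = int((~keep).sum())
        if keep.sum() < 2:
            raise ValueError(
                "fewer than 2 subjects shared between phenotype and genotypes"
            )
        if n_dropped:
            logger.info(
                "dropping %d phenotype subjects absent from the genotype store",
                n_dropped,
            )
            df = data.to_frame()
            keep_ids = set(data.subject_ids[keep])
            df = df[df["id"].isin(keep_ids)]
            data = assemble(df, covariate_cols=data.covariate_names)
        index = np.array([pos[sid] for sid in data.subject_ids])
        return data, index, n_dropped

    @classmethod
    def from_files(
        cls,
        pheno_path,
        geno_path,
        covariates=None,
        missing_policy: str = "zero_weight",
        **kwargs,
    ) -> "GallopModel":
        """Build a model from a phenotype file and a dosage store on disk."""
        from .io import open_dosage, read_phenotype

        df = read_phenotype(pheno_path)
        data = assemble(
            df, covariate_cols=covariates, missing_policy=missing_policy
        )
        store = open_dosage(geno_path)
        return cls(data, store, **kwargs)

    def _iter_blocks(self):
        if self._store is not None:
            from .io import chunk_reader

            for block in chunk_reader(self._store, self.chunk_size):
                yield DosageBlock(
                    dosages=block.dosages[self._geno_index],
                    snp_ids=block.snp_ids,
                    subject_ids=self.data.subject_ids,
                )
        else:
            block = self.genotypes
            dos = block.dosages
            if self._geno_index is not None:
                dos = dos[self._geno_index]
            for j0 in range(0, block.m, self.chunk_size):
                j1 = min(j0 + self.chunk_size, block.m)
                yield DosageBlock(
                    dosages=dos[:, j0:j1],
                    snp_ids=list(block.snp_ids[j0:j1]),
                    subject_ids=self.data.subject_ids,
                )

    def fit(self, progress: bool = False) -> GallopResults:
        """Run the scan: reduced REML fit (if needed), precompute, score."""
        reduced = None
        vc = self.vc
        if vc is None:
            reduced = LongitudinalLMM(self.data).fit()
            vc = reduced.vc
            d = vc.D
            logger.info(
                "reduced model: D = [[%.5g, %.5g], [%.5g, %.5g]], sigma^2 = %.5g",
                d[0, 0], d[0, 1], d[1, 0], d[1, 1], vc.sigma2,
            )
        pc = precompute(self.data, vc)
        results: list[SnpResult] = []
        n_flagged = 0
        for i, block in enumerate(self._iter_blocks()):
            rs = score_block(pc, block, missing_policy=self.missing_dosage)
            n_flagged += sum(r.status != "ok" for r in rs)
            results.extend(rs)
            if progress or logger.isEnabledFor(logging.INFO):
                logger.info(
                    "chunk %d: %d SNPs scored (%d flagged so far)",
                    i + 1, len(rs), n_flagged,
                )
        table = _results_frame(results)
        return GallopResults(self, table, reduced, vc, pc)
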