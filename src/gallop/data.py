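"""Long-format longitudinal phenotype data and missing-value weighting.

The container groups rows by subject (order of first appearance), keeps an
explicit 0/1 observation weight per row, and exposes the design pieces the
mixed-model algebra needs: per-row time ``t``, outcome ``y``, covariates
``C`` and the fixed-effect design ``X* = [1, t, C]``.  Rows with a missing
outcome, time or covariate get weight 0, which is algebraically equivalent
to deleting them (their design rows enter every sum multiplied by zero);
subjects with no valid rows are dropped entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LongitudinalData", "assemble", "add_covariates"]


@dataclass
class LongitudinalData:
    """Assembled longitudinal phenotype data, grouped by subject.

    Attributes
    ----------
    subject_ids : ndarray, shape (n,)
        Unique subject identifiers in order of first appearance.
    t, y : ndarray, shape (N,)
        Measurement times and outcomes, all subjects stacked.  ``y`` (and
        covariates) may contain NaN only on zero-weight rows.
    C : ndarray, shape (N, q)
        Covariate matrix (possibly time-varying); q may be 0.
    w : ndarray, shape (N,)
        0/1 observation weights (0 = row excluded from every sum).
    starts : ndarray, shape (n + 1,)
        Row offsets: subject ``i`` owns rows ``starts[i]:starts[i+1]``.
    covariate_names : list of str
    dropped_subjects : list
        Subjects removed because all their rows had weight 0.
    """

    subject_ids: np.ndarray
    t: np.ndarray
    y: np.ndarray
    C: np.ndarray
    w: np.ndarray
    starts: np.ndarray
    covariate_names: list = field(default_factory=list)
    dropped_subjects: list = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_rows(self) -> int:
        return len(self.t)

    @property
    def n_obs(self) -> int:
        """Number of rows contributing to the fit (weight 1)."""
        return int(self.w.sum())

    @property
    def q(self) -> int:
        return self.C.shape[1]

    @property
    def p(self) -> int:
        """Fixed-effect dimension of the SNP-free model: 1, t, covariates."""
        return 2 + self.q

    @property
    def counts(self) -> np.ndarray:
        """Rows per subject (including zero-weight rows)."""
        return np.diff(self.starts)

    @property
    def row_subject(self) -> np.ndarray:
        """Subject index (0..n-1) of each row."""
        return np.repeat(np.arange(self.n_subjects), self.counts)

    # -- filled views: zero-weight rows replaced by 0 so that w * value is
    #    always finite (NaN * 0 would poison every sum) --------------------
    @property
    def t_filled(self) -> np.ndarray:
        return np.where(self.w > 0, self.t, 0.0)

    @property
    def y_filled(self) -> np.ndarray:
        return np.where(self.w > 0, self.y, 0.0)

    @property
    def C_filled(self) -> np.ndarray:
        if self.q == 0:
            return self.C
        return np.where(self.w[:, None] > 0, self.C, 0.0)

    @property
    def Z(self) -> np.ndarray:
        """Random-effect design ``[1, t]`` per row, shape (N, 2)."""
        return np.column_stack([np.ones(self.n_rows), self.t_filled])

    @property
    def X_star(self) -> np.ndarray:
        """Fixed-effect design of the reduced model ``[1, t, C]``, (N, p)."""
        return np.column_stack(
            [np.ones(self.n_rows), self.t_filled, self.C_filled]
        )

    @property
    def fixed_effect_names(self) -> list:
        return ["const", "time", *self.covariate_names]

    def to_frame(self) -> pd.DataFrame:
        """Reconstruct the long-format table (NaN on zero-weight rows)."""
        df = pd.DataFrame(
            {
                "id": np.repeat(self.subject_ids, self.counts),
                "time": self.t,
                "y": np.where(self.w > 0, self.y, np.nan),
            }
        )
        for j, name in enumerate(self.covariate_names):
            df[name] = np.where(self.w > 0, self.C[:, j], np.nan)
        return df


def assemble(
    table: pd.DataFrame,
    subject_col: str = "id",
    time_col: str = "time",
    outcome_col: str = "y",
    covariate_cols=None,
    missing_policy: str = "zero_weight",
) -> LongitudinalData:
    """Build a :class:`LongitudinalData` from a long-format table.

    Parameters
    ----------
    table : DataFrame
        One row per measurement occasion.
    covariate_cols : sequence of str, optional
        Columns to use as covariates; by default every column other than
        subject, time and outcome.
    missing_policy : {"zero_weight", "strict"}
        ``zero_weight`` gives rows with a missing outcome, time or covariate
        weight 0 (the weighted system is identical to dropping them);
        ``strict`` raises on any missing value.

    Raises
    ------
    ValueError
        On an empty table, missing required columns, non-numeric time, a
        missing value under ``strict``, or (strict only) a subject losing
        all rows.
    """
    if missing_policy not in ("zero_weight", "strict"):
        raise ValueError(f"unknown missing_policy: {missing_policy!r}")
    for col in (subject_col, time_col, outcome_col):
        if col not in table.columns:
            raise ValueError(f"required column {col!r} not in table")
    if len(table) == 0:
        raise ValueError("empty phenotype table")

    if covariate_cols is None:
        covariate_cols = [
            c
            for c in table.columns
            if c not in (subject_col, time_col, outcome_col)
        ]
    covariate_cols = list(covariate_cols)

    t = pd.to_numeric(table[time_col], errors="coerce").to_numpy(float)
    if np.isnan(t).any() and not table[time_col].isna().to_numpy().any():
        raise ValueError(f"non-numeric values in time column {time_col!r}")
    y = pd.to_numeric(table[outcome_col], errors="coerce").to_numpy(float)
    C = (
        table[covariate_cols].apply(pd.to_numeric, errors="coerce").to_numpy(float)
        if covariate_cols
        else np.empty((len(table), 0))
    )

    bad = np.isnan(t) | np.isnan(y)
    if C.shape[1]:
        bad |= np.isnan(C).any(axis=1)
    if missing_policy == "strict" and bad.any():
        raise ValueError(
            f"{int(bad.sum())} rows with missing values under strict policy"
        )
    w = (~bad).astype(float)

    # group rows by subject in order of first appearance, stable within
    codes, uniques = pd.factorize(table[subject_col], use_na_sentinel=False)
    order = np.argsort(codes, kind="stable")
    codes = codes[order]
    t, y, C, w = t[order], y[order], C[order], w[order]

    counts = np.bincount(codes, minlength=len(uniques))
    valid_per_subject = np.bincount(
        codes, weights=w, minlength=len(uniques)
    )
    keep = valid_per_subject > 0
    dropped = [uniques[i] for i in np.nonzero(~keep)[0]]
    if not keep.any():
        raise ValueError("no subject has a valid observation")

    if not keep.all():
        row_keep = keep[codes]
        codes = codes[row_keep]
        t, y, C, w = t[row_keep], y[row_keep], C[row_keep], w[row_keep]
        # re-index the retained subjects compactly, preserving order
        remap = np.cumsum(keep) - 1
        codes = remap[codes]
        counts = counts[keep]

    starts = np.concatenate([[0], np.cumsum(counts)])
    subject_ids = np.asarray(uniques)[keep] if not keep.all() else np.asarray(uniques)
    return LongitudinalData(
        subject_ids=subject_ids,
        t=t,
        y=y,
        C=C,
        w=w,
        starts=starts,
        covariate_names=covariate_cols,
        dropped_subjects=dropped,
    )


def add_covariates(data: LongitudinalData, **columns) -> LongitudinalData:
    """Return a copy of ``data`` with extra per-row covariate columns.

    Used e.g. to append SNP and SNP-by-time columns when refitting the full
    mixed model for a single variant.  New columns must be fully observed on
    weight-1 rows.
    """
    extra = []
    names = []
    for name, col in columns.items():
        col = np.asarray(col, float)
        if col.shape != (data.n_rows,):
            raise ValueError(f"column {name!r} has wrong length")
        if np.isnan(col[data.w > 0]).any():
            raise ValueError(f"column {name!r} has missing values on valid rows")
        extra.append(col)
        names.append(name)
    C = np.column_stack([data.C, *extra]) if extra else data.C.copy()
    return LongitudinalData(
        subject_ids=data.subject_ids,
        t=data.t,
        y=data.y,
        C=C,
        w=data.w,
        starts=data.starts,
        covariate_names=[*data.covariate_names, *names],
        dropped_subjects=list(data.dropped_subjects),
    )
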