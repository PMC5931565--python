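"""File formats: phenotype tables, dosage stores, results files.

Phenotypes are delimited text (header row; ``id``, ``time``, ``y`` plus
numeric covariate columns).  Dosages come either as delimited text
(first column subject id, one column per SNP) or as a chunked flat-binary
container — a row-major (subjects x SNPs) array of float64 with a JSON
sidecar recording dimensions, ids, the missing-value sentinel and the
chunk geometry — which is the fast path for genome-wide panels: a scan
only ever touches ``chunk_size`` SNP columns at a time.

VCF/BGEN ingestion is out of scope: convert upstream (e.g. extract the DS
dosage field per subject with bcftools/cyvcf2) and write the matrix with
:func:`write_binary_dosage`.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .engine import DosageBlock

__all__ = [
    "read_phenotype",
    "write_phenotype",
    "TextDosageStore",
    "BinaryDosageStore",
    "write_text_dosage",
    "write_binary_dosage",
    "open_dosage",
    "chunk_reader",
    "write_results",
    "read_results",
]

DEFAULT_SENTINEL = -9.0


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    for cand in ("\t", ",", ";"):
        if cand in header:
            return cand
    return r"\s+"


def _read_kwargs(path, sep, na_token):
    """Always parse with the correctly-rounded float converter so that
    read -> write -> read is bit-lossless; the delimiter is sniffed from
    the header when not given."""
    if sep is None:
        sep = _sniff_sep(path)
    return dict(sep=sep, na_values=[na_token], float_precision="round_trip")


def read_phenotype(
    path, sep: str | None = None, na_token: str = "NA"
) -> pd.DataFrame:
    """Read a long-format phenotype table (delimiter sniffed by default)."""
    try:
        df = pd.read_csv(path, **_read_kwargs(path, sep, na_token))
    except pd.errors.ParserError as e:
        raise ValueError(f"malformed phenotype file {path}: {e}") from e
    if len(df.columns) < 3:
        raise ValueError(
            f"phenotype file {path} needs at least id, time and outcome columns"
        )
    return df


def write_phenotype(df: pd.DataFrame, path, sep: str = "\t", na_token: str = "NA") -> None:
    # repr keeps the round trip bit-lossless for float columns
    df.to_csv(path, sep=sep, index=False, na_rep=na_token, float_format=lambda x: repr(float(x)))


class TextDosageStore:
    """Delimited-text dosage panel: rows = subjects, columns = SNPs."""

    def __init__(self, path, sep: str | None = None, na_token: str = "NA"):
        self.path = os.fspath(path)
        try:
            df = pd.read_csv(self.path, **_read_kwargs(path, sep, na_token))
        except pd.errors.ParserError as e:
            raise ValueError(f"malformed dosage file {path}: {e}") from e
        self.subject_ids = df.iloc[:, 0].to_numpy()
        self.snp_ids = list(df.columns[1:])
        self._matrix = df.iloc[:, 1:].to_numpy(float)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def read(self, start: int = 0, stop: int | None = None) -> np.ndarray:
        stop = self.n_snps if stop is None else stop
        return self._matrix[:, start:stop].copy()


class BinaryDosageStore:
    """Chunked flat-binary dosage container with a JSON sidecar.

    The payload is a row-major float64 array (subjects x SNPs); the
    sidecar (``<payload>.json``) holds dimensions, subject and SNP ids,
    the missing-value sentinel and a chunk-size hint.  Chunk reads are
    memory-mapped column slices and bit-identical to a whole-file read.
    """

    def __init__(self, path):
        path = os.fspath(path)
        if path.endswith(".json"):
            self.sidecar_path, self.bin_path = path, path[: -len(".json")]
        else:
            self.sidecar_path, self.bin_path = path + ".json", path
        with open(self.sidecar_path) as fh:
            meta = json.load(fh)
        self.meta = meta
        self.subject_ids = np.asarray(meta["subject_ids"])
        self.snp_ids = list(meta["snp_ids"])
        self.sentinel = float(meta.get("missing_value", DEFAULT_SENTINEL))
        self.chunk_size = int(meta.get("chunk_size", 1000))
        self._dtype = np.dtype(meta.get("dtype", "float64"))
        n, m = int(meta["n_subjects"]), int(meta["n_snps"])
        if n != len(self.subject_ids) or m != len(self.snp_ids):
            raise ValueError(f"sidecar {self.sidecar_path} is inconsistent")
        expected = n * m * self._dtype.itemsize
        actual = os.path.getsize(self.bin_path)
        if actual != expected:
            raise ValueError(
                f"binary payload {self.bin_path} has {actual} bytes, "
                f"sidecar promises {expected} ({n} x {m} {self._dtype})"
            )
        self._mm = np.memmap(self.bin_path, dtype=self._dtype, mode="r", shape=(n, m))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def read(self, start: int = 0, stop: int | None = None) -> np.ndarray:
        stop = self.n_snps if stop is None else stop
        out = np.array(self._mm[:, start:stop], dtype=float)
        out[out == self.sentinel] = np.nan
        return out


def write_text_dosage(
    path, dosages, subject_ids, snp_ids, sep: str = "\t", na_token: str = "NA"
) -> None:
    df = pd.DataFrame(np.asarray(dosages, float), columns=list(snp_ids))
    df.insert(0, "id", subject_ids)
    df.to_csv(path, sep=sep, index=False, na_rep=na_token, float_format=lambda x: repr(float(x)))


def write_binary_dosage(
    path,
    dosages,
    subject_ids,
    snp_ids,
    missing_value: float = DEFAULT_SENTINEL,
    chunk_size: int = 1000,
) -> str:
    """Write the flat-binary container; returns the payload path."""
    path = os.fspath(path)
    arr = np.ascontiguousarray(np.asarray(dosages, float))
    arr = np.where(np.isnan(arr), missing_value, arr)
    n, m = arr.shape
    if len(subject_ids) != n or len(snp_ids) != m:
        raise ValueError("ids do not match the dosage matrix shape")
    arr.astype("<f8").tofile(path)
    meta = {
        "format": "gallop-dosage",
        "version": 1,
        "n_subjects": n,
        "n_snps": m,
        "dtype": "<f8",
        "order": "row-major (subjects x SNPs)",
        "subject_ids": np.asarray(subject_ids).tolist(),
        "snp_ids": list(map(str, snp_ids)),
        "missing_value": missing_value,
        "chunk_size": int(chunk_size),
    }
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh)
    return path


def open_dosage(path):
    """Open a dosage store, dispatching on the sidecar's presence."""
    path = os.fspath(path)
    if path.endswith(".json") or os.path.exists(path + ".json"):
        return BinaryDosageStore(path)
    return TextDosageStore(path)


def chunk_reader(store, chunk_size: int | None = None):
    """Yield consecutive :class:`DosageBlock` chunks of at most chunk_size."""
    if chunk_size is None:
        chunk_size = getattr(store, "chunk_size", 1000)
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    for start in range(0, store.n_snps, chunk_size):
        stop = min(start + chunk_size, store.n_snps)
        yield DosageBlock(
            dosages=store.read(start, stop),
            snp_ids=list(store.snp_ids[start:stop]),
            subject_ids=np.asarray(store.subject_ids),
        )


def _format_float(x, raw: bool) -> str:
    if isinstance(x, float) and np.isnan(x):
        return "NA"
    if isinstance(x, float):
        return repr(x) if raw else f"{x:.6g}"
    return str(x)


def write_results(table: pd.DataFrame, path, raw: bool = False) -> None:
    """Write the per-SNP results table as TSV (floats at 6 significant
    digits unless ``raw``)."""
    out = table.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = [_format_float(float(v), raw) for v in out[col]]
    out.to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
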