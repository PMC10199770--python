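"""Count-matrix and metadata I/O plus library-size (CPM) normalization.

The universal carrier is :class:`CountMatrix`, a miRNA x sample table of
non-negative values with an explicit ``scale`` — raw counts or counts per
million.  The scale is declared, never guessed: differential testing needs
raw counts while the deconvolution operates on CPM, and silently mixing the
two is a classic source of wrong answers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RAW_COUNTS = "raw_counts"
CPM = "cpm"
_SCALES = (RAW_COUNTS, CPM)
_DELIMS = {"tsv": "\t", "csv": ","}

GROUPS = ("cancer", "healthy")


def _check_unique(ids, axis_name: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = sorted(seen[seen.duplicated()].unique())
        raise ValueError(f"duplicate {axis_name} id(s): {', '.join(map(str, dups))}")


@dataclass
class CountMatrix:
    """miRNA x sample expression table with an explicit scale.

    Parameters
    ----------
    values
        DataFrame indexed by miRNA id with one column per sample.  All
        entries must be finite and non-negative; missing cells are an
        error, not imputed.
    scale
        Either ``"raw_counts"`` or ``"cpm"``.
    """

    values: pd.DataFrame
    scale: str = RAW_COUNTS

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        _check_unique(self.values.index, "miRNA")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = np.where(~self.values.map(lambda v: isinstance(v, (int, float, np.number))))
            r, c = bad[0][0], bad[1][0]
            raise ValueError(
                f"non-numeric value at miRNA {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise ValueError(
                f"missing value at miRNA {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative value {arr[r, c]} at miRNA {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_mirna(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.values[list(sample_ids)], scale=self.scale)

    def subset_mirnas(self, mirna_ids) -> "CountMatrix":
        return CountMatrix(self.values.loc[list(mirna_ids)], scale=self.scale)


def read_counts(path, dialect: str = "tsv", scale: str = RAW_COUNTS) -> CountMatrix:
    """Read a count matrix whose first column holds miRNA ids.

    Row and column order of the file are preserved.  Duplicated ids,
    negative cells and non-numeric cells raise ``ValueError`` naming the
    offending coordinate.
    """
    if dialect not in _DELIMS:
        raise ValueError(f"dialect must be one of {tuple(_DELIMS)}, got {dialect!r}")
    df = pd.read_csv(path, sep=_DELIMS[dialect], comment="#", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected an id column plus at least one sample")
    ids = df.iloc[:, 0]
    table = df.iloc[:, 1:]
    for col in table.columns:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            row = ids[bad].iloc[0]
            raise ValueError(
                f"{path}: non-numeric value {table[col][bad].iloc[0]!r} "
                f"at miRNA {row!r}, sample {col!r}"
            )
        table[col] = coerced
    table.index = pd.Index(ids, name=df.columns[0])
    return CountMatrix(table, scale=scale)


def write_counts(counts: CountMatrix, path, dialect: str = "tsv") -> None:
    """Write a count matrix with miRNA ids in the first column."""
    sep = _DELIMS[dialect]
    df = counts.values.copy()
    df.index.name = df.index.name or "mirna_id"
    df.to_csv(path, sep=sep, float_format="%.12g")


def read_metadata(path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a sample-metadata table (``sample_id``, ``group``, optional ``cancer_type``)."""
    meta = pd.read_csv(path, sep=_DELIMS[dialect], comment="#", dtype=str)
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "group"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing column(s): {sorted(missing)}")
    _check_unique(meta["sample_id"], "sample")
    if meta["group"].isna().any():
        bad = meta.loc[meta["group"].isna(), "sample_id"].iloc[0]
        raise ValueError(f"sample {bad!r} has no group assignment")
    unknown = set(meta["group"]) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group label(s) {sorted(unknown)}; expected {GROUPS}")
    if "cancer_type" not in meta.columns:
        meta = meta.assign(cancer_type=None)
    return meta.reset_index(drop=True)


def check_samples_match(counts: CountMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Align metadata to a count matrix; every sample must have exactly one row."""
    meta = validate_metadata(meta)
    idx = meta.set_index("sample_id")
    missing = [s for s in counts.sample_ids if s not in idx.index]
    if missing:
        raise ValueError(f"sample(s) without metadata: {missing}")
    return idx.loc[counts.sample_ids].reset_index()


def cpm_normalize(counts: CountMatrix) -> CountMatrix:
    """Counts-per-million normalization: cell / column total x 1e6.

    The library size is the per-column total of the provided matrix.  A
    zero-total column cannot be normalized and raises an error naming the
    sample.  No pseudocount is added; log transforms are owned by callers.
    """
    if counts.scale != RAW_COUNTS:
        raise ValueError(f"cpm_normalize expects raw counts, got scale={counts.scale!r}")
    totals = counts.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total counts")
    return CountMatrix(counts.values / totals * 1e6, scale=CPM)


# ---------------------------------------------------------------------------
# Commented-TSV result tables (signatures, purity tables, DE tables)

def write_table(df: pd.DataFrame, path, params: dict | None = None) -> None:
    """Write a result table as TSV with a one-line ``#`` provenance header."""
    from exopurity import __version__

    items = " ".join(f"{k}={v}" for k, v in (params or {}).items())
    header = f"# exopurity {__version__}" + (f" | {items}" if items else "")
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format="%.12g")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        fh.write(buf.getvalue())


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
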