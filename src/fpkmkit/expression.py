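"""Reading, validation and elementary transforms of FPKM expression matrices.

The :class:`ExpressionMatrix` is the data backbone of the package: a dense
non-negative genes-by-samples array with ordered, unique identifiers on both
axes.  Sample annotations (group, acquisition batch, optional sex/age) travel
separately in a :class:`SampleTable` keyed by sample identifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError, ParseError, ValidationError

GROUPS = ("control", "AD", "PD")
BATCHES = ("session1", "session2")


def _find_duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups


class ExpressionMatrix:
    """Non-negative FPKM values over genes (rows) and samples (columns).

    Parameters
    ----------
    values:
        2-D array-like of shape ``(n_genes, n_samples)``; finite, ``>= 0``.
    gene_ids, sample_ids:
        Ordered unique identifiers for the two axes.  Identifiers are opaque
        case-sensitive strings; no symbol/alias resolution is attempted.
    allow_negative:
        Relaxes the non-negativity invariant; set automatically on
        log-transformed matrices, whose values may dip below zero.
    """

    def __init__(
        self,
        values: np.ndarray,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        allow_negative: bool = False,
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        gene_ids = [str(g) for g in gene_ids]
        sample_ids = [str(s) for s in sample_ids]
        if values.shape != (len(gene_ids), len(sample_ids)):
            raise ValidationError(
                f"shape {values.shape} inconsistent with "
                f"{len(gene_ids)} genes x {len(sample_ids)} samples"
            )
        dup_g = _find_duplicates(gene_ids)
        if dup_g:
            raise ValidationError(f"duplicate gene identifiers: {dup_g}")
        dup_s = _find_duplicates(sample_ids)
        if dup_s:
            raise ValidationError(f"duplicate sample identifiers: {dup_s}")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at gene {gene_ids[bad[0]]!r}, "
                f"sample {sample_ids[bad[1]]!r}"
            )
        if not allow_negative and np.any(values < 0):
            bad = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative value at gene {gene_ids[bad[0]]!r}, "
                f"sample {sample_ids[bad[1]]!r}"
            )
        self.allow_negative = allow_negative
        self.values = values
        self.gene_ids = list(gene_ids)
        self.sample_ids = list(sample_ids)

    # -- basic properties -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"

    # -- conversions ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))

    # -- subsetting -------------------------------------------------------
    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.sample_ids]
        if missing:
            raise ArgumentError(f"unknown samples: {missing}")
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            self.values[:, idx], self.gene_ids, list(sample_ids), self.allow_negative
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.gene_ids]
        if missing:
            raise ArgumentError(f"unknown genes: {missing}")
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        return ExpressionMatrix(
            self.values[idx, :], list(gene_ids), self.sample_ids, self.allow_negative
        )


@dataclass(frozen=True)
class GenePanel:
    """Named ordered list of gene identifiers (a figure panel's gene set)."""

    name: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValidationError(f"panel {self.name!r} is empty")
        dups = _find_duplicates(self.gene_ids)
        if dups:
            raise ValidationError(f"panel {self.name!r} has duplicates: {dups}")


class SampleTable:
    """Per-sample metadata: group, acquisition batch, optional sex and age."""

    REQUIRED = ("sample_id", "group", "batch")

    def __init__(self, frame: pd.DataFrame) -> None:
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        frame = frame.copy()
        frame["sample_id"] = frame["sample_id"].astype(str)
        dups = _find_duplicates(list(frame["sample_id"]))
        if dups:
            raise ValidationError(f"duplicate sample_id in metadata: {dups}")
        bad_groups = sorted(set(frame["group"]) - set(GROUPS))
        if bad_groups:
            raise ValidationError(
                f"unknown groups {bad_groups}; expected one of {list(GROUPS)}"
            )
        bad_batches = sorted(set(frame["batch"]) - set(BATCHES))
        if bad_batches:
            raise ValidationError(
                f"unknown batches {bad_batches}; expected one of {list(BATCHES)}"
            )
        if "age_years" in frame.columns:
            ages = pd.to_numeric(frame["age_years"], errors="coerce")
            if (ages.dropna() < 0).any():
                raise ValidationError("negative age_years in metadata")
        self.frame = frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def group_of(self, sample_id: str) -> str:
        row = self.frame.loc[self.frame["sample_id"] == sample_id]
        if row.empty:
            raise ArgumentError(f"sample {sample_id!r} not in metadata")
        return str(row["group"].iloc[0])

    def samples_in_group(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise ArgumentError(f"unknown group {group!r}")
        return list(self.frame.loc[self.frame["group"] == group, "sample_id"])

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Every matrix sample must have exactly one metadata record."""
        missing = [s for s in matrix.sample_ids if s not in set(self.sample_ids)]
        if missing:
            raise ValidationError(f"samples without metadata: {missing}")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_fpkm_table(path: str | Path, sep: str = "\t") -> ExpressionMatrix:
    """Read a gene-by-sample FPKM table.

    The first column holds gene identifiers; every remaining column is one
    sample of numeric FPKM values.  Missing cells are rejected, not imputed.
    Input gene order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        frame = pd.read_csv(path, sep=sep, header=0, index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"empty expression table: {path}") from exc
    if frame.shape[1] == 0:
        raise ParseError(f"expression table has no sample columns: {path}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | frame.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric or missing cell at row {frame.index[r]!r}, "
            f"column {frame.columns[c]!r} in {path}"
        )
    return ExpressionMatrix.from_frame(numeric)


def write_fpkm_table(matrix: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    frame = matrix.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep=sep)


def read_sample_table(path: str | Path, sep: str = "\t") -> SampleTable:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        frame = pd.read_csv(path, sep=sep, header=0)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"empty metadata table: {path}") from exc
    return SampleTable(frame)


def write_sample_table(table: SampleTable, path: str | Path, sep: str = "\t") -> None:
    table.frame.to_csv(path, sep=sep, index=False)


def read_gene_panel(path: str | Path, name: str | None = None) -> GenePanel:
    """One identifier per line; blank lines and ``#`` comments ignored."""
    path = Path(path)
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ParseError(f"empty gene panel file: {path}")
    return GenePanel(name=name or path.stem, gene_ids=tuple(lines))


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def filter_expressed(matrix: ExpressionMatrix, min_samples_nonzero: int) -> ExpressionMatrix:
    """Keep genes with FPKM > 0 in at least ``min_samples_nonzero`` samples.

    ``min_samples_nonzero = 0`` is the identity.  Order is preserved; the
    result may be empty.
    """
    if not 0 <= min_samples_nonzero <= matrix.n_samples:
        raise ArgumentError(
            f"min_samples_nonzero must be in [0, {matrix.n_samples}], "
            f"got {min_samples_nonzero}"
        )
    keep = (matrix.values > 0).sum(axis=1) >= min_samples_nonzero
    return ExpressionMatrix(
        matrix.values[keep, :],
        [g for g, k in zip(matrix.gene_ids, keep) if k],
        matrix.sample_ids,
        matrix.allow_negative,
    )


def log_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Replace every value ``v`` with ``log2(v + pseudocount)``."""
    if not pseudocount > 0:
        raise ArgumentError(f"pseudocount must be > 0, got {pseudocount}")
    return ExpressionMatrix(
        np.log2(matrix.values + pseudocount),
        matrix.gene_ids,
        matrix.sample_ids,
        allow_negative=True,
    )
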