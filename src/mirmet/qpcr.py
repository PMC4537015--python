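"""Cq-level primitives for RT-qPCR miRNA profiling.

Quantification-cycle (Cq) matrices are stored miRNA x sample together with a
parallel boolean grid of detection flags.  Lower Cq means higher abundance.
An undetected well carries no Cq until it is imputed at the detection
ceiling (40 cycles by default).  Normalisation is single-reference:

    dCq(m, s) = Cq(m, s) - Cq(reference, s)

with the small nuclear RNA U6 as the canonical endogenous reference, so a
*higher* dCq means *lower* relative expression.  Relative expression on the
log10 scale is ``-dCq * log10(2)`` (perfect doubling per cycle assumed).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_REFERENCE = "U6"
DEFAULT_CEILING = 40.0

METADATA_COLUMNS = ("sample_id", "group", "set", "pair_id", "mycn")

LOG10_2 = math.log10(2.0)


class CqParseError(ValueError):
    """Raised when a Cq table or its metadata cannot be interpreted."""


@dataclass
class CqMatrix:
    """Raw or imputed Cq values with parallel detection flags.

    ``values`` and ``detected`` are miRNA x sample DataFrames sharing index
    and columns.  Cells that were never detected hold NaN before imputation
    and the ceiling afterwards; ``detected`` is False for them either way.
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    reference_id: str = DEFAULT_REFERENCE

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.detected.index) or not self.values.columns.equals(
            self.detected.columns
        ):
            raise ValueError("values and detected grids must share index and columns")
        if self.values.index.has_duplicates:
            raise CqParseError("duplicate miRNA ids in Cq matrix")
        if self.values.columns.has_duplicates:
            raise CqParseError("duplicate sample ids in Cq matrix")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "CqMatrix":
        return CqMatrix(self.values.copy(), self.detected.copy(), self.reference_id)


@dataclass
class DeltaCqMatrix:
    """Reference-normalised Cq values (dCq), reference row removed.

    Detection flags are carried through from the source matrix so that
    downstream filters can reason about missingness on the dCq scale.
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    reference_id: str = DEFAULT_REFERENCE

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def read_cq_table(
    path: str | Path,
    metadata_path: str | Path,
    reference_id: str = DEFAULT_REFERENCE,
) -> tuple[CqMatrix, pd.DataFrame]:
    """Read a Cq TSV (first column ``mirna_id``, empty cell = undetected)
    plus a sample-metadata TSV covering every sample column.

    Returns the matrix (values NaN where undetected) and the metadata frame
    indexed by ``sample_id``.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.columns[0] != "mirna_id":
        raise CqParseError(f"first column of {path} must be 'mirna_id', got {raw.columns[0]!r}")
    raw = raw.set_index("mirna_id")
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise CqParseError(f"duplicate miRNA ids: {dups}")
    if raw.columns.has_duplicates:
        raise CqParseError("duplicate sample columns")

    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        for row, cell in raw[col].items():
            cell = cell.strip()
            if cell == "":
                values.loc[row, col] = np.nan
                continue
            try:
                values.loc[row, col] = float(cell)
            except ValueError:
                raise CqParseError(
                    f"non-numeric Cq {cell!r} at miRNA {row!r}, sample {col!r}"
                ) from None
    detected = values.notna()

    if reference_id not in values.index:
        raise CqParseError(f"reference row {reference_id!r} missing from Cq table")
    if not detected.loc[reference_id].all():
        bad = detected.columns[~detected.loc[reference_id]].tolist()
        raise CqParseError(f"reference {reference_id!r} undetected in samples {bad}")

    metadata = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in metadata.columns:
        raise CqParseError("metadata must have a 'sample_id' column")
    metadata = metadata.set_index("sample_id")
    if metadata.index.has_duplicates:
        raise CqParseError("duplicate sample ids in metadata")
    missing = [s for s in values.columns if s not in metadata.index]
    if missing:
        raise CqParseError(f"samples missing from metadata: {missing}")

    return CqMatrix(values, detected, reference_id), metadata


def write_cq_table(matrix: CqMatrix, path: str | Path) -> None:
    """Write a Cq matrix as TSV; undetected cells become empty strings."""
    out = matrix.values.where(matrix.detected, np.nan)
    out.index.name = "mirna_id"
    out.to_csv(path, sep="\t", na_rep="")


def impute_undetected(matrix: CqMatrix, ceiling: float = DEFAULT_CEILING) -> CqMatrix:
    """Assign the detection ceiling to every undetected well.

    The ceiling defaults to 40 cycles, the last cycle of the amplification
    run.  Detection flags are preserved so that "not expressed" remains a
    flag-based notion independent of the numeric ceiling.
    """
    detected_values = matrix.values.to_numpy()[matrix.detected.to_numpy()]
    if detected_values.size and ceiling <= np.nanmax(detected_values):
        warnings.warn(
            f"imputation ceiling {ceiling} does not exceed the largest detected Cq "
            f"({np.nanmax(detected_values):.3f})",
            stacklevel=2,
        )
    values = matrix.values.where(matrix.detected, ceiling)
    return CqMatrix(values, matrix.detected.copy(), matrix.reference_id)


def aggregate_replicates(
    matrix: CqMatrix, replicate_map: Mapping[str, Sequence[str]]
) -> CqMatrix:
    """Collapse replicate wells to one column per sample.

    ``replicate_map`` maps each output sample id to its well columns.  The
    aggregate Cq is the median over *detected* wells; a sample whose wells
    are all undetected stays undetected.
    """
    values = {}
    detected = {}
    for sample, wells in replicate_map.items():
        wells = list(wells)
        if not wells:
            raise ValueError(f"replicate group {sample!r} is empty")
        missing = [w for w in wells if w not in matrix.values.columns]
        if missing:
            raise KeyError(f"unknown wells for {sample!r}: {missing}")
        sub = matrix.values[wells].where(matrix.detected[wells])
        med = sub.median(axis=1, skipna=True)
        values[sample] = med
        detected[sample] = matrix.detected[wells].any(axis=1)
    return CqMatrix(pd.DataFrame(values), pd.DataFrame(detected), matrix.reference_id)


def delta_cq(matrix: CqMatrix) -> DeltaCqMatrix:
    """Subtract the reference row (U6) from every miRNA, per sample.

    Requires imputation to have been applied (no NaN cells) and the
    reference to be detected in every sample; normalisation is undefined
    otherwise and raises rather than imputing the reference.
    """
    if matrix.reference_id not in matrix.values.index:
        raise CqParseError(f"reference row {matrix.reference_id!r} missing")
    if not matrix.detected.loc[matrix.reference_id].all():
        bad = matrix.detected.columns[~matrix.detected.loc[matrix.reference_id]].tolist()
        raise ValueError(f"reference undetected in samples {bad}; cannot normalise")
    if matrix.values.isna().any().any():
        raise ValueError("Cq matrix contains undetected cells; impute before delta_cq")
    ref = matrix.values.loc[matrix.reference_id]
    values = matrix.values.drop(index=matrix.reference_id).sub(ref, axis=1)
    detected = matrix.detected.drop(index=matrix.reference_id)
    return DeltaCqMatrix(values, detected.copy(), matrix.reference_id)


def relative_expression(delta_cq_value):
    """log10 relative expression for a dCq value: log10(2**-dCq).

    Accepts scalars or arrays; strictly decreasing in dCq, 0 at dCq = 0.
    """
    arr = np.asarray(delta_cq_value, dtype=float)
    out = -arr * LOG10_2
    if np.ndim(delta_cq_value) == 0:
        return float(out)
    return out
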