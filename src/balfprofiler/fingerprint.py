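"""Ligand-binding fingerprints: data model, binding index, table I/O.

A fingerprint is the 10-vector of binding indices for five carbohydrate
fluorescent ligands (L1..L5) measured natively and again under mannan
competition (ML1..ML5). Each index is the percent of fluorescent ligand
depleted from solution by cell binding and lives on the 0-100 scale.

L1/L2/L5 are mannose-type ligands (linear, cyclic, branched trimannose);
L3/L4 are galactose-type. Mannan competition blocks the mannose-recognising
receptors (CD206/CD209), so the native-minus-competed drop on the mannose
ligands reports receptor specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import BasisError, ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Fixed ligand order shared by every table in the pipeline.
NATIVE_NAMES: tuple[str, ...] = ("L1", "L2", "L3", "L4", "L5")
COMPETED_NAMES: tuple[str, ...] = ("ML1", "ML2", "ML3", "ML4", "ML5")
INDEX_NAMES: tuple[str, ...] = NATIVE_NAMES + COMPETED_NAMES
FINGERPRINT_COLUMNS: tuple[str, ...] = ("sample_id",) + INDEX_NAMES

#: Positions (within L1..L5) of mannose-type vs galactose-type ligands.
MANNOSE_POSITIONS: tuple[int, ...] = (0, 1, 4)
GALACTOSE_POSITIONS: tuple[int, ...] = (2, 3)

#: Number of significant digits used when writing tables (round-trip precision).
TABLE_PRECISION = 6


@dataclass(frozen=True)
class FluorescenceReading:
    """One well: fluorescence before and after incubation with cells.

    ``f_initial`` must be positive; ``f_final`` may exceed ``f_initial`` on a
    noisy plate, in which case the derived binding index is clipped to 0.
    """

    f_initial: float
    f_final: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.f_initial) or self.f_initial <= 0:
            raise ValidationError(
                f"invalid reading: f_initial must be finite and > 0, got {self.f_initial!r}"
            )
        if not np.isfinite(self.f_final) or self.f_final < 0:
            raise ValidationError(
                f"invalid reading: f_final must be finite and >= 0, got {self.f_final!r}"
            )


def compute_binding_index(reading: FluorescenceReading) -> float:
    """Percent of ligand bound: 100 * (F_initial - F_final) / F_initial.

    The result is clipped to [0, 100]; a negative raw value (final signal above
    initial, i.e. plate noise) is logged as a warning before clipping.
    """
    raw = 100.0 * (reading.f_initial - reading.f_final) / reading.f_initial
    if raw < 0:
        logger.warning(
            "negative binding index %.4g (f_final %.4g > f_initial %.4g); clipping to 0",
            raw, reading.f_final, reading.f_initial,
        )
    return float(min(max(raw, 0.0), 100.0))


@dataclass(frozen=True)
class FingerprintVector:
    """A sample's 10 binding indices in fixed ligand order L1..L5, ML1..ML5."""

    sample_id: str
    native: tuple[float, ...]
    competed: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, values in (("native", self.native), ("competed", self.competed)):
            if len(values) != 5:
                raise ValidationError(
                    f"sample {self.sample_id!r}: {name} must have exactly 5 indices, "
                    f"got {len(values)}"
                )
        labels = INDEX_NAMES
        for label, value in zip(labels, tuple(self.native) + tuple(self.competed)):
            if not np.isfinite(value) or not (0.0 <= value <= 100.0):
                raise ValidationError(
                    f"sample {self.sample_id!r}: index {label} = {value!r} "
                    f"is not a finite percent in [0, 100]"
                )
        object.__setattr__(self, "native", tuple(float(v) for v in self.native))
        object.__setattr__(self, "competed", tuple(float(v) for v in self.competed))

    @property
    def values(self) -> np.ndarray:
        """The 10 indices as a float array (L1..L5 then ML1..ML5)."""
        return np.asarray(self.native + self.competed, dtype=float)

    @classmethod
    def from_values(cls, sample_id: str, values: Sequence[float]) -> "FingerprintVector":
        values = tuple(float(v) for v in values)
        if len(values) != 10:
            raise ValidationError(
                f"sample {sample_id!r}: expected 10 indices, got {len(values)}"
            )
        return cls(sample_id=sample_id, native=values[:5], competed=values[5:])


def assemble_fingerprint(
    sample_id: str, native: Sequence[float], competed: Sequence[float]
) -> FingerprintVector:
    """Validate and assemble a fingerprint from its native and competed halves."""
    return FingerprintVector(
        sample_id=sample_id, native=tuple(native), competed=tuple(competed)
    )


@dataclass(frozen=True)
class ReferenceBasis:
    """Binding signatures of the polarised reference populations M0, M1, M2a.

    The three 10-vectors serve as the basis of the mixture model
    ``S = c1 V(M0) + c2 V(M1) + c3 V(M2a) + eps`` and must be linearly
    independent (rank 3); a rank-deficient basis is rejected at construction.
    """

    m0: FingerprintVector
    m1: FingerprintVector
    m2a: FingerprintVector

    #: Numerical rank tolerance, relative to the default of matrix_rank.
    _rank_tol: float | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        mat = self.matrix
        vecs = [self.m0.values, self.m1.values, self.m2a.values]
        for i in range(3):
            for j in range(i + 1, 3):
                if np.array_equal(vecs[i], vecs[j]):
                    raise BasisError("reference basis vectors must be pairwise distinct")
        if np.linalg.matrix_rank(mat, tol=self._rank_tol) < 3:
            raise BasisError(
                "reference basis is rank-deficient: M0/M1/M2a signatures must be "
                "linearly independent"
            )

    @property
    def matrix(self) -> np.ndarray:
        """(3, 10) array with rows V(M0), V(M1), V(M2a)."""
        return np.vstack([self.m0.values, self.m1.values, self.m2a.values])

    @property
    def labels(self) -> tuple[str, str, str]:
        return ("M0", "M1", "M2a")


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def _format_value(x: float) -> str:
    return f"{x:.{TABLE_PRECISION}g}"


def write_fingerprint_table(vectors: Iterable[FingerprintVector], path: str | Path) -> None:
    """Write a comma-delimited fingerprint table (6 significant digits)."""
    vectors = list(vectors)
    lines = [",".join(FINGERPRINT_COLUMNS)]
    for v in vectors:
        lines.append(v.sample_id + "," + ",".join(_format_value(x) for x in v.values))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_fingerprint_table(path: str | Path) -> list[FingerprintVector]:
    """Read a fingerprint table; header names and order are enforced.

    Raises :class:`ParseError` on a missing/misnamed column, a duplicate
    sample_id or a non-numeric cell, naming the offending row/column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"sample_id": str})
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file, expected a header row") from exc
    if tuple(df.columns) != FINGERPRINT_COLUMNS:
        raise ParseError(
            f"{path}: header mismatch; expected {','.join(FINGERPRINT_COLUMNS)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ParseError(f"{path}: duplicate sample_id {dup.iloc[0]!r}")
    vectors: list[FingerprintVector] = []
    for row_idx, row in df.iterrows():
        values = []
        for col in INDEX_NAMES:
            try:
                values.append(float(row[col]))
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"{path}: non-numeric cell at row {row_idx + 2}, column {col}: "
                    f"{row[col]!r}"
                ) from exc
        try:
            vectors.append(FingerprintVector.from_values(str(row["sample_id"]), values))
        except ValidationError as exc:
            raise ParseError(f"{path}: row {row_idx + 2}: {exc}") from exc
    return vectors


def write_reference_basis(basis: ReferenceBasis, path: str | Path) -> None:
    write_fingerprint_table([basis.m0, basis.m1, basis.m2a], path)


def read_reference_basis(path: str | Path) -> ReferenceBasis:
    """Read a reference-basis table: exactly three rows labelled M0, M1, M2a."""
    vectors = read_fingerprint_table(path)
    by_id = {v.sample_id: v for v in vectors}
    if len(vectors) != 3 or set(by_id) != {"M0", "M1", "M2a"}:
        raise BasisError(
            f"{path}: reference basis must contain exactly the rows M0, M1, M2a; "
            f"got {[v.sample_id for v in vectors]}"
        )
    return ReferenceBasis(m0=by_id["M0"], m1=by_id["M1"], m2a=by_id["M2a"])
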