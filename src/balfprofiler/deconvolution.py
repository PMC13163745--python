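"""Phenotype deconvolution by non-negative least squares.

A patient fingerprint S is modelled as a non-negative mixture of the three
reference signatures,

    S = c1 V(M0) + c2 V(M1) + c3 V(M2a) + eps,   c_i >= 0,

solved by NNLS (Lawson-Hanson, via scipy). The unexplained part eps is
reported as a "residual" fraction: it absorbs atypical or transitional
macrophage states (M2b/M2c/M2d and intermediates) that the tripartite basis
deliberately does not model. The residual fraction is defined as
100 * ||eps||_2 / ||S||_2 (capped at 100) and the remaining mass is split
proportionally to the coefficients, so the four reported percentages always
sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .exceptions import DegenerateSampleError, ValidationError
from .fingerprint import FingerprintVector, ReferenceBasis

PHENOTYPE_LABELS = ("M0", "M1", "M2a")
COMPOSITION_COLUMNS = ("sample_id", "m0_pct", "m1_pct", "m2a_pct", "residual_pct")


@dataclass(frozen=True)
class DeconvolutionSolution:
    """NNLS solution for one sample: coefficients, residual vector and norms."""

    coefficients: np.ndarray  # (3,) c1, c2, c3 for M0, M1, M2a
    residual_vector: np.ndarray  # (10,) eps = S - sum(c_i V_i)
    residual_norm: float  # ||eps||_2
    objective: float  # ||eps||_2^2


@dataclass(frozen=True)
class PhenotypeComposition:
    """Percent contributions of M0/M1/M2a plus the residual; sums to 100."""

    sample_id: str
    m0_pct: float
    m1_pct: float
    m2a_pct: float
    residual_pct: float

    def __post_init__(self) -> None:
        parts = self.as_array()
        if np.any(parts < -1e-9) or np.any(parts > 100 + 1e-9):
            raise ValidationError(
                f"sample {self.sample_id!r}: composition percents out of [0, 100]: {parts}"
            )
        if abs(parts.sum() - 100.0) > 1e-6:
            raise ValidationError(
                f"sample {self.sample_id!r}: composition sums to {parts.sum()!r}, not 100"
            )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.m0_pct, self.m1_pct, self.m2a_pct, self.residual_pct], dtype=float
        )


def solve_nnls(s: FingerprintVector, basis: ReferenceBasis) -> DeconvolutionSolution:
    """Globally minimise ||S - sum(c_i V_i)||^2 subject to c_i >= 0.

    The problem is convex and, with a rank-3 basis, the minimiser is unique.
    """
    A = basis.matrix.T  # (10, 3)
    b = s.values
    coef, _ = scipy.optimize.nnls(A, b)
    residual = b - A @ coef
    norm = float(np.linalg.norm(residual))
    return DeconvolutionSolution(
        coefficients=coef,
        residual_vector=residual,
        residual_norm=norm,
        objective=norm**2,
    )


def compose_fractions(
    solution: DeconvolutionSolution, s: FingerprintVector
) -> PhenotypeComposition:
    """Convert an NNLS solution to percentages.

    residual_pct = 100 * ||eps|| / ||S|| (capped at 100); the remaining
    (100 - residual_pct) is allocated proportionally to the coefficients.
    If all coefficients are zero, the whole sample is residual.
    """
    s_norm = float(np.linalg.norm(s.values))
    if s_norm == 0.0:
        raise DegenerateSampleError(
            f"sample {s.sample_id!r}: zero-norm fingerprint cannot be decomposed"
        )
    residual_pct = min(100.0 * solution.residual_norm / s_norm, 100.0)
    total = float(solution.coefficients.sum())
    if total == 0.0:
        shares = np.zeros(3)
        residual_pct = 100.0
    else:
        shares = solution.coefficients / total * (100.0 - residual_pct)
    return PhenotypeComposition(
        sample_id=s.sample_id,
        m0_pct=float(shares[0]),
        m1_pct=float(shares[1]),
        m2a_pct=float(shares[2]),
        residual_pct=float(residual_pct),
    )


def deconvolve(s: FingerprintVector, basis: ReferenceBasis) -> PhenotypeComposition:
    """NNLS-decompose one fingerprint and return its phenotype composition."""
    return compose_fractions(solve_nnls(s, basis), s)


def deconvolve_dataset(
    samples: Iterable[FingerprintVector], basis: ReferenceBasis
) -> pd.DataFrame:
    """Deconvolve each sample; returns a composition table (one row per sample).

    Per-sample errors are re-raised with the sample_id attached.
    """
    rows = []
    for s in samples:
        try:
            comp = deconvolve(s, basis)
        except DegenerateSampleError:
            raise
        except Exception as exc:  # attach context for batch debugging
            raise type(exc)(f"sample {s.sample_id!r}: {exc}") from exc
        rows.append(
            {
                "sample_id": comp.sample_id,
                "m0_pct": comp.m0_pct,
                "m1_pct": comp.m1_pct,
                "m2a_pct": comp.m2a_pct,
                "residual_pct": comp.residual_pct,
            }
        )
    return pd.DataFrame(rows, columns=COMPOSITION_COLUMNS)


def composition_from_row(row: Sequence) -> PhenotypeComposition:
    """Rebuild a PhenotypeComposition from a composition-table row."""
    sample_id, m0, m1, m2a, res = row
    return PhenotypeComposition(
        sample_id=str(sample_id),
        m0_pct=float(m0),
        m1_pct=float(m1),
        m2a_pct=float(m2a),
        residual_pct=float(res),
    )
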