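"""Drug-induced remodeling of macrophage phenotype profiles.

Ex vivo treatment of a BALF sample yields a paired (intact, treated)
fingerprint. Remodeling is quantified three ways:

* the phenotype delta: treated-minus-intact change of the deconvolved
  M0/M1/M2a/residual percentages (the four deltas sum to zero because each
  composition sums to 100);
* the therapeutic vector: the displacement of the sample's canonical LDA
  coordinates from intact to treated state (negative delta-LD1 = movement
  toward the favourable cluster);
* centroid correlation: the Pearson correlation of the treated fingerprint
  against averaged Good-prognosis and Poor-prognosis reference profiles.

Cohort-level shifts are tested with a one-sample t-test on the paired
deltas (algebraically identical to a paired t-test on intact vs treated);
two-sided p-values are reported, with an optional Benjamini-Hochberg
correction for cohort-wide screens.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .deconvolution import PhenotypeComposition, deconvolve
from .discriminant import DiscriminantModel, project
from .exceptions import NumericalError, ValidationError
from .fingerprint import FingerprintVector, ReferenceBasis


@dataclass(frozen=True)
class TreatmentPair:
    """Intact and drug-treated fingerprints of the same patient sample."""

    patient_id: str
    agent: str
    intact: FingerprintVector
    treated: FingerprintVector
    concentration_ug_ml: float | None = None  # metadata only

    def __post_init__(self) -> None:
        if self.intact.values.shape != self.treated.values.shape:
            raise ValidationError("intact and treated fingerprints differ in arity")


@dataclass(frozen=True)
class RemodelingDelta:
    """Signed percent shifts of each phenotype fraction; sums to 0."""

    d_m0: float
    d_m1: float
    d_m2a: float
    d_residual: float

    def as_array(self) -> np.ndarray:
        return np.array([self.d_m0, self.d_m1, self.d_m2a, self.d_residual])


@dataclass(frozen=True)
class TherapeuticVector:
    """Canonical-space displacement from intact (start) to treated (end)."""

    patient_id: str
    agent: str
    start: np.ndarray
    end: np.ndarray

    @property
    def delta_ld1(self) -> float:
        return float(self.end[0] - self.start[0])

    @property
    def displacement(self) -> np.ndarray:
        return self.end - self.start


@dataclass(frozen=True)
class CentroidCorrelation:
    r_good: float
    r_poor: float

    @property
    def preference(self) -> int:
        """sign(r_good - r_poor): +1 leans Good, -1 leans Poor, 0 tied."""
        return int(np.sign(self.r_good - self.r_poor))


@dataclass(frozen=True)
class ShiftTest:
    t_statistic: float
    p_value: float
    n: int


def remodeling_delta(
    intact: PhenotypeComposition, treated: PhenotypeComposition
) -> RemodelingDelta:
    """Componentwise treated - intact phenotype percentages."""
    d = treated.as_array() - intact.as_array()
    return RemodelingDelta(
        d_m0=float(d[0]), d_m1=float(d[1]), d_m2a=float(d[2]), d_residual=float(d[3])
    )


def therapeutic_vector(model: DiscriminantModel, pair: TreatmentPair) -> TherapeuticVector:
    """Project both states of a pair into canonical space."""
    return TherapeuticVector(
        patient_id=pair.patient_id,
        agent=pair.agent,
        start=project(model, pair.intact),
        end=project(model, pair.treated),
    )


def mean_fingerprint(fingerprints: Iterable[FingerprintVector]) -> np.ndarray:
    """Unweighted mean 10-index profile of a set of fingerprints."""
    mat = np.vstack([f.values for f in fingerprints])
    return mat.mean(axis=0)


def centroid_correlation(
    fingerprint, good_centroid_profile: Sequence[float],
    poor_centroid_profile: Sequence[float],
) -> CentroidCorrelation:
    """Pearson correlation of a sample's 10 indices against each stratum profile."""
    x = (
        fingerprint.values
        if isinstance(fingerprint, FingerprintVector)
        else np.asarray(fingerprint, dtype=float)
    )
    good = np.asarray(good_centroid_profile, dtype=float)
    poor = np.asarray(poor_centroid_profile, dtype=float)
    for name, v in (("sample", x), ("good centroid", good), ("poor centroid", poor)):
        if v.shape != (10,):
            raise ValidationError(f"{name} profile must be 10-dimensional, got {v.shape}")
        if np.ptp(v) == 0:
            raise NumericalError(f"correlation undefined: {name} profile is constant")
    r_good, _ = scipy.stats.pearsonr(x, good)
    r_poor, _ = scipy.stats.pearsonr(x, poor)
    return CentroidCorrelation(r_good=float(r_good), r_poor=float(r_poor))


def cohort_shift_test(deltas: Sequence[float]) -> ShiftTest:
    """One-sample t-test of the paired deltas against zero (two-sided)."""
    d = np.asarray(deltas, dtype=float)
    if d.ndim != 1 or len(d) < 2:
        raise ValidationError(f"need >= 2 paired deltas, got {d.shape}")
    if np.ptp(d) == 0:
        raise NumericalError("zero-variance deltas: paired t-test is degenerate")
    res = scipy.stats.ttest_1samp(d, 0.0)
    return ShiftTest(
        t_statistic=float(res.statistic), p_value=float(res.pvalue), n=len(d)
    )


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values."""
    m = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adjusted, 0.0, 1.0)
    return out


def analyze_treatments(
    pairs: Iterable[TreatmentPair],
    basis: ReferenceBasis,
    model: DiscriminantModel | None = None,
    good_profile: Sequence[float] | None = None,
    poor_profile: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Per-pair remodeling table: deltas, optional vectors and centroid correlations."""
    rows = []
    for pair in pairs:
        intact_c = deconvolve(pair.intact, basis)
        treated_c = deconvolve(pair.treated, basis)
        delta = remodeling_delta(intact_c, treated_c)
        row = {
            "patient_id": pair.patient_id,
            "agent": pair.agent,
            "concentration_ug_ml": pair.concentration_ug_ml,
            "d_m0": delta.d_m0,
            "d_m1": delta.d_m1,
            "d_m2a": delta.d_m2a,
            "d_residual": delta.d_residual,
        }
        if model is not None:
            vec = therapeutic_vector(model, pair)
            row["ld1_intact"] = float(vec.start[0])
            row["ld1_treated"] = float(vec.end[0])
            row["delta_ld1"] = vec.delta_ld1
            if model.n_axes > 1:
                row["ld2_intact"] = float(vec.start[1])
                row["ld2_treated"] = float(vec.end[1])
        if good_profile is not None and poor_profile is not None:
            cc = centroid_correlation(pair.treated, good_profile, poor_profile)
            row["r_good"] = cc.r_good
            row["r_poor"] = cc.r_poor
            row["preference"] = cc.preference
        rows.append(row)
    return pd.DataFrame(rows)


def per_agent_tests(
    remodeling_table: pd.DataFrame,
    components: Sequence[str] = ("d_m1", "d_m2a"),
    adjust: bool = False,
) -> pd.DataFrame:
    """Cohort-level paired t-tests per agent and phenotype component.

    ``adjust=True`` applies Benjamini-Hochberg across all reported tests
    (off by default: per-agent p-values are reported unadjusted).
    """
    rows = []
    for agent, grp in remodeling_table.groupby("agent", sort=True):
        for comp in components:
            try:
                test = cohort_shift_test(grp[comp].to_numpy())
            except (ValidationError, NumericalError):
                rows.append(
                    {"agent": agent, "component": comp, "t_statistic": np.nan,
                     "p_value": np.nan, "n": len(grp)}
                )
                continue
            rows.append(
                {"agent": agent, "component": comp, "t_statistic": test.t_statistic,
                 "p_value": test.p_value, "n": test.n}
            )
    out = pd.DataFrame(rows)
    if adjust and not out.empty:
        mask = out["p_value"].notna().to_numpy()
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask] = _benjamini_hochberg(out.loc[mask, "p_value"].to_numpy())
        out["p_adjusted"] = adj
    return out
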