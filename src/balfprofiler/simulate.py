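"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the study design end to end so every pipeline stage is
testable without clinical data:

* a reference basis obeying the qualitative receptor logic — M2a binds the
  mannose-type ligands strongly and is strongly suppressed by mannan; M1
  binds low-to-moderate with little mannan suppression (few mannose
  receptors); M0 is uniformly low;
* patient fingerprints S = sum(w_i V_i) + a A + eta, where A is a fixed
  "atypical" direction orthogonal to the basis span (one degree of freedom
  standing in for the aggregated M2b/M2c/M2d states), and eta is additive
  Gaussian measurement noise on the percent scale, clipped to [0, 100];
* severity-linked classes: each prognostic class has a mixture-weight recipe
  (Poor: M1-dominant with elevated atypical weight; Good: balanced with
  moderate residual, i.e. preserved plasticity) and blood panels are drawn so
  the binary rubric reproduces the intended class exactly;
* named treatment effects as maps on the true mixture weights (e.g. a
  doxycycline-like M1 -> M2a repolarisation), after which the fingerprint is
  regenerated under the same noise model.

All randomness flows from one seed through numpy SeedSequence spawn keys, so
each stream is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .fingerprint import (
    FingerprintVector,
    MANNOSE_POSITIONS,
    ReferenceBasis,
    assemble_fingerprint,
)
from .severity import BloodPanel, ReferenceIntervals, PARAMETERS

#: Cohort split mirroring the 72-patient study population (Good/Neutral/Poor).
DEFAULT_CLASS_PROPORTIONS = {"Good": 22 / 72, "Neutral": 39 / 72, "Poor": 11 / 72}

#: Mixture-weight recipes (m0, m1, m2a, atypical) per prognostic class.
#: Good keeps a balanced profile with a sizeable uncommitted (atypical)
#: share — preserved plasticity; Poor is M1-dominant and rigid.
CLASS_RECIPES: dict[str, np.ndarray] = {
    "Good": np.array([0.40, 0.15, 0.20, 0.25]),
    "Neutral": np.array([0.28, 0.40, 0.20, 0.12]),
    "Poor": np.array([0.08, 0.68, 0.06, 0.18]),
}

#: Per-patient Gaussian jitter of the weight vector (weight units).
WEIGHT_JITTER_SD = 0.03

Weights = tuple[float, float, float]  # (m0, m1, m2a)

# -- treatment effects: maps (m0, m1, m2a, atypical) -> same ---------------


def _doxycycline(w: np.ndarray) -> np.ndarray:
    """M1 -> M2a repolarisation with residual depletion and some M0 gain."""
    m0, m1, m2a, a = w
    return np.array([m0 + 0.1 * m1 + 0.6 * a, 0.1 * m1, m2a + 0.8 * m1, 0.4 * a])


def _mumb(w: np.ndarray) -> np.ndarray:
    """Coumarin-like immunostimulant: activates dormant M0 into M1."""
    m0, m1, m2a, a = w
    return np.array([0.2 * m0, m1 + 0.8 * m0, m2a, a])


def _paclitaxel(w: np.ndarray) -> np.ndarray:
    """Deactivation toward the marker-negative M0 state."""
    m0, m1, m2a, a = w
    return np.array([m0 + 0.6 * m1 + 0.6 * m2a, 0.4 * m1, 0.4 * m2a, a])


def _identity(w: np.ndarray) -> np.ndarray:
    return w.copy()


DEFAULT_TREATMENT_EFFECTS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": _identity,
    "doxycycline": _doxycycline,
    "mumb": _mumb,
    "paclitaxel": _paclitaxel,
}

#: Working ex vivo concentrations (ug/mL), recorded as pair metadata.
AGENT_CONCENTRATIONS = {"doxycycline": 25.0, "mumb": 100.0, "paclitaxel": 2.0}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort (defaults mirror the study)."""

    seed: int = 0
    n_patients: int = 72
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    noise_sd: float = 2.0  # percent-scale sd of fingerprint measurement noise
    atypical_weight_range: tuple[float, float] = (0.02, 0.40)
    separation: float = 4.0  # standardized distance between class centroids
    treatment_effects: Mapping[str, Callable[[np.ndarray], np.ndarray]] = field(
        default_factory=lambda: dict(DEFAULT_TREATMENT_EFFECTS)
    )

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be positive")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"class proportions sum to {total}, not 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        lo, hi = self.atypical_weight_range
        if not (0 <= lo <= hi <= 1):
            raise ValidationError("atypical_weight_range must be within [0, 1]")


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort with its ground truth."""

    fingerprints: tuple[FingerprintVector, ...]
    panels: tuple[BloodPanel, ...]
    labels: tuple[str, ...]
    severity: tuple[int, ...]
    ground_truth: pd.DataFrame  # patient_id, w_m0, w_m1, w_m2a, atypical, label
    basis: ReferenceBasis
    config: GeneratorConfig


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Counter-split generator: independent stream per (seed, key...)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


# ---------------------------------------------------------------------------
# Reference basis
# ---------------------------------------------------------------------------

#: Template native / competed indices per phenotype and ligand position.
#: Mannose ligands: positions 0, 1, 4 (linear < cyclic < branched avidity);
#: galactose ligands: positions 2, 3.
_BASIS_TEMPLATES = {
    # (native L1..L5), (competed ML1..ML5)
    # M0: uniformly low binding, mild suppression (few mannose receptors).
    # M1: low-to-moderate, galactose-leaning, binding persists under mannan
    #     (near-zero suppression: mannose receptors scarcely expressed).
    # M2a: strong binding across the panel, profoundly mannan-suppressed on
    #     the mannose ligands (CD206/CD209-rich).
    "M0": ((34.0, 38.0, 16.0, 18.0, 42.0), (23.0, 26.0, 12.0, 14.0, 29.0)),
    "M1": ((46.0, 40.0, 50.0, 55.0, 44.0), (44.0, 38.0, 46.0, 52.0, 42.0)),
    "M2a": ((62.0, 72.0, 52.0, 62.0, 85.0), (18.0, 20.0, 38.0, 46.0, 24.0)),
}
_BASIS_JITTER_SD = 2.5


def generate_reference_basis(seed: int = 0) -> ReferenceBasis:
    """Draw a rank-3 reference basis obeying the qualitative receptor logic.

    M2a has the highest native mannose-ligand binding and the largest
    mannan suppression; M1 is low-to-moderate with small suppression; M0 is
    uniformly low. Jitter is resampled (up to 100 tries) if it ever breaks
    the ordering rules or the rank-3 requirement.
    """
    rng = _rng(seed, 0)
    for _ in range(100):
        vectors = {}
        for label, (native, competed) in _BASIS_TEMPLATES.items():
            nat = np.clip(np.asarray(native) + rng.normal(0, _BASIS_JITTER_SD, 5), 0, 100)
            com = np.clip(np.asarray(competed) + rng.normal(0, _BASIS_JITTER_SD, 5), 0, 100)
            # competition can only remove binding
            com = np.minimum(com, nat)
            vectors[label] = assemble_fingerprint(label, nat, com)
        basis_ok = True
        man = list(MANNOSE_POSITIONS)
        m0, m1, m2a = (vectors[k] for k in ("M0", "M1", "M2a"))
        nat = {k: np.asarray(v.native) for k, v in vectors.items()}
        sup = {k: np.asarray(v.native) - np.asarray(v.competed) for k, v in vectors.items()}
        if not nat["M2a"][man].mean() > nat["M1"][man].mean() > nat["M0"][man].mean():
            basis_ok = False
        if not sup["M2a"][man].mean() > sup["M1"][man].mean():
            basis_ok = False
        if basis_ok:
            try:
                return ReferenceBasis(m0=m0, m1=m1, m2a=m2a)
            except ValidationError:
                basis_ok = False
    raise ValidationError("could not draw a valid rank-3 reference basis in 100 tries")


def atypical_vector(basis: ReferenceBasis) -> np.ndarray:
    """The fixed out-of-span 'atypical' direction, scaled to basis magnitude.

    A deterministic seed vector is orthogonalised against the three basis
    rows and scaled so that unit atypical weight contributes a signal of the
    same order as a unit mixture weight (0.6 x mean basis row norm). One
    direction stands in for all aggregated atypical states.
    """
    seed_vec = np.array([1.0, -1.0, 2.0, -2.0, 1.5, -1.5, 0.5, -0.5, 2.5, -2.5])
    Q, _ = np.linalg.qr(basis.matrix.T)  # (10, 3) orthonormal span
    u = seed_vec - Q @ (Q.T @ seed_vec)
    norm = np.linalg.norm(u)
    if norm < 1e-9:  # pragma: no cover - seed vector chosen off-span
        raise ValidationError("atypical seed vector lies in the basis span")
    scale = 0.6 * float(np.mean(np.linalg.norm(basis.matrix, axis=1)))
    return u / norm * scale


def generate_patient(
    weights: Sequence[float],
    atypical_weight: float,
    noise_sd: float,
    basis: ReferenceBasis,
    seed: int,
    sample_id: str = "S1",
) -> tuple[FingerprintVector, dict]:
    """One fingerprint S = sum(w_i V_i) + a A + eta, clipped to [0, 100].

    Returns the fingerprint and its ground-truth record.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,) or np.any(w < 0):
        raise ValidationError("weights must be 3 non-negative numbers (M0, M1, M2a)")
    if atypical_weight < 0:
        raise ValidationError("atypical weight must be >= 0")
    rng = _rng(seed, 1)
    signal = w @ basis.matrix + atypical_weight * atypical_vector(basis)
    noise = rng.normal(0.0, noise_sd, 10) if noise_sd > 0 else np.zeros(10)
    values = np.clip(signal + noise, 0.0, 100.0)
    fp = FingerprintVector.from_values(sample_id, values)
    truth = {
        "patient_id": sample_id,
        "w_m0": float(w[0]),
        "w_m1": float(w[1]),
        "w_m2a": float(w[2]),
        "atypical": float(atypical_weight),
    }
    return fp, truth


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def largest_remainder_counts(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Integer class counts by largest-remainder rounding (exact for 22/39/11)."""
    items = list(proportions.items())
    raw = np.array([n * p for _, p in items])
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in range(remainder):
        counts[order[i]] += 1
    return {label: int(c) for (label, _), c in zip(items, counts)}


def _class_weight_profiles(
    config: GeneratorConfig, basis: ReferenceBasis
) -> dict[str, np.ndarray]:
    """Recipes rescaled so the closest pair of class fingerprint centroids
    sits ``separation`` standardised units apart.

    The standardisation unit is the within-class standard deviation along the
    closest-pair direction, combining measurement noise with the propagated
    per-patient weight jitter; this makes the separation knob an honest
    effect size regardless of the noise settings.
    """
    labels = list(config.class_proportions)
    props = np.array([config.class_proportions[c] for c in labels])
    recipes = np.vstack([CLASS_RECIPES[c] for c in labels])
    mean_recipe = props @ recipes
    B = np.vstack([basis.matrix, atypical_vector(basis)])  # (4, 10)
    offsets = (recipes - mean_recipe) @ B
    min_std_sep = np.inf
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            diff = offsets[i] - offsets[j]
            d0 = float(np.linalg.norm(diff))
            if d0 == 0:
                continue
            u = diff / d0
            within_sd = np.sqrt(
                config.noise_sd**2 + float(np.sum((WEIGHT_JITTER_SD * (B @ u)) ** 2))
            )
            min_std_sep = min(min_std_sep, d0 / within_sd)
    scale = config.separation / min_std_sep if np.isfinite(min_std_sep) else 1.0
    profiles = {}
    for i, label in enumerate(labels):
        profiles[label] = np.clip(mean_recipe + scale * (recipes[i] - mean_recipe), 0, None)
    return profiles


def _draw_panel(
    label: str, patient_id: str, rng: np.random.Generator,
    intervals: ReferenceIntervals,
) -> BloodPanel:
    """Draw a blood panel whose rubric score lands in the intended class."""
    n_flags = {"Good": 0, "Neutral": int(rng.integers(1, 3)),
               "Poor": int(rng.integers(3, 6))}[label]
    flagged = set(rng.choice(len(PARAMETERS), size=n_flags, replace=False).tolist())
    values = {}
    iv = intervals.as_dict()
    # in-range and out-of-range sampling windows per parameter
    inside = {
        "wbc": (5.0, 11.5), "neutrophils_pct": (38.0, 59.0),
        "eosinophils_pct": (1.2, 4.8), "monocytes_pct": (2.5, 9.5),
        "crp": (0.2, 4.5),
    }
    below = {
        "wbc": (1.5, 4.2), "neutrophils_pct": (25.0, 36.5),
        "eosinophils_pct": (0.0, 0.9), "monocytes_pct": (0.0, 1.8),
    }
    above = {
        "wbc": (12.5, 20.0), "neutrophils_pct": (61.0, 78.0),
        "eosinophils_pct": (5.2, 12.0), "monocytes_pct": (10.5, 16.0),
        "crp": (6.0, 60.0),
    }
    for i, p in enumerate(PARAMETERS):
        if i in flagged:
            if p == "crp" or rng.random() < 0.5:
                lo, hi = above[p]
            else:
                lo, hi = below[p]
        else:
            lo, hi = inside[p]
        values[p] = float(rng.uniform(lo, hi))
        assert (i in flagged) != iv[p].contains(values[p])
    fever = bool(label == "Poor" and rng.random() < 0.5)
    return BloodPanel(patient_id=patient_id, fever=fever, **values)


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate fingerprints, blood panels, labels and ground truth.

    Class counts follow largest-remainder rounding of the configured
    proportions; blood panels are drawn so the severity rubric reproduces
    the intended class for every patient.
    """
    basis = generate_reference_basis(config.seed)
    profiles = _class_weight_profiles(config, basis)
    counts = largest_remainder_counts(config.n_patients, config.class_proportions)
    intervals = ReferenceIntervals()

    labels: list[str] = []
    for label in config.class_proportions:
        labels.extend([label] * counts[label])

    weight_rng = _rng(config.seed, 2)
    panel_rng = _rng(config.seed, 3)
    lo, hi = config.atypical_weight_range
    fingerprints, panels, truths, severities = [], [], [], []
    for i, label in enumerate(labels):
        pid = f"SP{i + 1:03d}"
        w4 = profiles[label] + weight_rng.normal(0, WEIGHT_JITTER_SD, 4)
        w4 = np.clip(w4, 0.0, None)
        a = float(np.clip(w4[3], lo, hi))
        noise_seed = int(_rng(config.seed, 4, i).integers(2**31))
        fp, truth = generate_patient(
            weights=w4[:3], atypical_weight=a, noise_sd=config.noise_sd,
            basis=basis, seed=noise_seed, sample_id=pid,
        )
        panel = _draw_panel(label, pid, panel_rng, intervals)
        truth["label"] = label
        truth["noise_seed"] = noise_seed
        fingerprints.append(fp)
        panels.append(panel)
        truths.append(truth)
        severities.append(
            sum(
                0 if iv.contains(getattr(panel, p)) else 1
                for p, iv in intervals.as_dict().items()
            )
        )
    return SyntheticCohort(
        fingerprints=tuple(fingerprints),
        panels=tuple(panels),
        labels=tuple(labels),
        severity=tuple(severities),
        ground_truth=pd.DataFrame(truths),
        basis=basis,
        config=config,
    )


# ---------------------------------------------------------------------------
# Treatment effects
# ---------------------------------------------------------------------------

def apply_treatment_effect(
    truth: Mapping[str, float],
    effect_name: str,
    basis: ReferenceBasis,
    noise_sd: float,
    seed: int,
    effects: Mapping[str, Callable[[np.ndarray], np.ndarray]] | None = None,
) -> tuple[FingerprintVector, dict]:
    """Transform a patient's true weights by a named effect and regenerate.

    The treated fingerprint uses the same noise model; passing the same seed
    as the intact draw makes the identity effect reproduce it exactly.
    """
    effects = effects or DEFAULT_TREATMENT_EFFECTS
    if effect_name not in effects:
        raise ValidationError(
            f"unknown treatment effect {effect_name!r}; "
            f"available: {sorted(effects)}"
        )
    w4 = np.array(
        [truth["w_m0"], truth["w_m1"], truth["w_m2a"], truth["atypical"]], dtype=float
    )
    new = np.clip(effects[effect_name](w4), 0.0, None)
    return generate_patient(
        weights=new[:3], atypical_weight=float(new[3]), noise_sd=noise_sd,
        basis=basis, seed=seed, sample_id=str(truth["patient_id"]),
    )


def make_treatment_pairs(
    cohort: SyntheticCohort, effect_name: str, treatment_seed: int | None = None
):
    """Pair every cohort patient's intact fingerprint with its treated state.

    The treated fingerprint is regenerated with an independent noise draw
    (stream keyed off ``treatment_seed``, default the cohort seed) — two
    plate readings of the same well are independent measurements.
    Returns a list of :class:`~balfprofiler.remodeling.TreatmentPair`.
    """
    from .remodeling import TreatmentPair  # local import avoids a cycle

    base = cohort.config.seed if treatment_seed is None else treatment_seed
    pairs = []
    for i, (fp, (_, truth)) in enumerate(
        zip(cohort.fingerprints, cohort.ground_truth.iterrows())
    ):
        treated, _ = apply_treatment_effect(
            truth, effect_name, cohort.basis, cohort.config.noise_sd,
            seed=int(_rng(base, 5, i).integers(2**31)),
        )
        pairs.append(
            TreatmentPair(
                patient_id=fp.sample_id,
                agent=effect_name,
                intact=fp,
                treated=treated,
                concentration_ug_ml=AGENT_CONCENTRATIONS.get(effect_name),
            )
        )
    return pairs
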