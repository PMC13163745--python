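"""Fisher linear discriminant analysis of 10-feature binding fingerprints.

The model separates Good/Neutral/Poor prognostic cohorts by maximising the
ratio of between-class to within-class variance. Features are z-standardised
with training statistics, the within-class scatter S_W is shrunk toward its
diagonal, (1-gamma) S_W + gamma diag(S_W), and the canonical axes are the
leading eigenvectors of the generalised eigenproblem S_B v = lambda S_W v.

Conventions:

* axes have unit Euclidean norm;
* LD1 is oriented so the worst prognostic class present has the higher mean
  LD1 ("higher = worse"); negative shifts along LD1 therefore signify
  movement toward the favourable immune state;
* classification is prior-free nearest-centroid in canonical space, with
  ties broken toward the worse prognosis (conservative triage);
* leave-one-out cross-validation refits the model per fold at the patient
  level; folds that would empty a class are skipped and counted.

The LD1 score doubles as a continuous severity biomarker: its relation to
the clinical severity index is summarised by a Pearson correlation and a
nonlinear exponential fit ``severity ~ a * exp(b * LD1)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.stats

from .exceptions import DegenerateModelError, NumericalError, ValidationError
from .fingerprint import FingerprintVector

logger = logging.getLogger(__name__)

#: Clinical ordering used for LD1 orientation and conservative tie-breaking.
PROGNOSIS_RANK = {"Good": 0, "Neutral": 1, "Poor": 2}

_EIG_TIE_RTOL = 1e-12


def _class_rank(label: str) -> tuple[int, str]:
    """Order classes best -> worst; unknown labels fall back to lexicographic."""
    return (PROGNOSIS_RANK.get(label, 1), label)


@dataclass(frozen=True)
class LabeledCohort:
    """Fingerprints with prognosis labels (and optional severity scores)."""

    fingerprints: tuple[FingerprintVector, ...]
    labels: tuple[str, ...]
    severity: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "fingerprints", tuple(self.fingerprints))
        object.__setattr__(self, "labels", tuple(self.labels))
        if self.severity is not None:
            object.__setattr__(self, "severity", tuple(self.severity))
        if len(self.fingerprints) != len(self.labels):
            raise ValidationError("fingerprints and labels differ in length")
        if self.severity is not None and len(self.severity) != len(self.labels):
            raise ValidationError("severity and labels differ in length")
        counts = self.class_counts()
        if len(counts) < 2:
            raise ValidationError("cohort must contain at least 2 classes")
        small = [c for c, n in counts.items() if n < 2]
        if small:
            raise ValidationError(
                f"every class needs >= 2 members for within-class scatter; "
                f"too small: {small}"
            )

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for lab in self.labels:
            counts[lab] = counts.get(lab, 0) + 1
        return counts

    @property
    def feature_matrix(self) -> np.ndarray:
        return np.vstack([f.values for f in self.fingerprints])

    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.labels), key=_class_rank))


@dataclass
class DiscriminantModel:
    """A fitted canonical discriminant model (see module docstring)."""

    classes: tuple[str, ...]  # ordered best -> worst prognosis
    feature_means: np.ndarray  # (10,)
    feature_scales: np.ndarray  # (10,)
    class_means: np.ndarray  # (k, 10) in standardized space
    axes: np.ndarray  # (n_axes, 10), unit rows
    eigenvalues: np.ndarray  # (n_axes,)
    explained_variance_ratio: np.ndarray  # (n_axes,)
    centroids: np.ndarray  # (k, n_axes) class means in canonical space
    gamma: float
    degenerate: bool = False

    @property
    def n_axes(self) -> int:
        return self.axes.shape[0]

    # -- serialization (plain text, exact round trip via float repr) --------

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "feature_means": self.feature_means.tolist(),
            "feature_scales": self.feature_scales.tolist(),
            "class_means": self.class_means.tolist(),
            "axes": self.axes.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "centroids": self.centroids.tolist(),
            "gamma": self.gamma,
            "degenerate": self.degenerate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscriminantModel":
        return cls(
            classes=tuple(d["classes"]),
            feature_means=np.asarray(d["feature_means"], dtype=float),
            feature_scales=np.asarray(d["feature_scales"], dtype=float),
            class_means=np.asarray(d["class_means"], dtype=float),
            axes=np.asarray(d["axes"], dtype=float),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            explained_variance_ratio=np.asarray(
                d["explained_variance_ratio"], dtype=float
            ),
            centroids=np.asarray(d["centroids"], dtype=float),
            gamma=float(d["gamma"]),
            degenerate=bool(d["degenerate"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "DiscriminantModel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Class-by-class prediction counts (rows = true class) plus fold metadata."""

    classes: tuple[str, ...]
    counts: np.ndarray  # (k, k) ints, rows true / columns predicted
    skipped_folds: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        """Percent correct, reported to 2 decimals."""
        if self.total == 0:
            raise NumericalError("empty confusion matrix has no accuracy")
        return round(100.0 * float(np.trace(self.counts)) / self.total, 2)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _standardize_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=0)
    # Constant features carry no information; unit scale keeps them inert.
    scales = np.where(scales == 0.0, 1.0, scales)
    return means, scales


def fit_lda(
    cohort: LabeledCohort, n_axes: int = 2, gamma: float = 0.1
) -> DiscriminantModel:
    """Fit the shrunken Fisher discriminant (see module docstring).

    ``gamma`` in [0, 1] shrinks S_W toward its diagonal; with 10 features and
    small classes the pooled scatter is often ill-conditioned, and the default
    0.1 is a mild regulariser.
    """
    if not (0.0 <= gamma <= 1.0):
        raise ValidationError(f"gamma must be in [0, 1], got {gamma}")
    classes = cohort.classes()
    max_axes = min(len(classes) - 1, 10)
    if n_axes not in (1, 2):
        raise ValidationError(f"n_axes must be 1 or 2, got {n_axes}")
    n_axes = min(n_axes, max_axes)

    X = cohort.feature_matrix
    means, scales = _standardize_stats(X)
    Z = (X - means) / scales
    labels = np.asarray(cohort.labels)

    grand = Z.mean(axis=0)
    p = Z.shape[1]
    S_W = np.zeros((p, p))
    S_B = np.zeros((p, p))
    class_means = np.zeros((len(classes), p))
    for k, cls in enumerate(classes):
        Zk = Z[labels == cls]
        mu = Zk.mean(axis=0)
        class_means[k] = mu
        centered = Zk - mu
        S_W += centered.T @ centered
        d = (mu - grand)[:, None]
        S_B += len(Zk) * (d @ d.T)

    S_Wr = (1.0 - gamma) * S_W + gamma * np.diag(np.diag(S_W))
    try:
        eigvals, eigvecs = scipy.linalg.eigh(S_B, S_Wr)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError):
        # Zero within-class variance (e.g. point-mass classes) defeats the
        # diagonal shrinkage target; a tiny absolute ridge restores a
        # well-posed problem without perturbing non-degenerate fits.
        ridge = 1e-8 * max(float(np.trace(S_Wr)) / p, 1.0)
        try:
            eigvals, eigvecs = scipy.linalg.eigh(S_B, S_Wr + ridge * np.eye(p))
        except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as exc:
            raise NumericalError(
                "within-class scatter is singular even after ridging; "
                "increase gamma"
            ) from exc

    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]

    degenerate = bool(eigvals[0] <= 1e-10)
    if degenerate:
        logger.warning("degenerate discriminant model: no between-class variance")
    total = eigvals[:max_axes].sum()
    kept_vals = eigvals[:n_axes]
    evr = kept_vals / total if total > 0 else np.full(n_axes, np.nan)

    axes = eigvecs[:, :n_axes].T
    norms = np.linalg.norm(axes, axis=1)
    norms = np.where(norms == 0.0, 1.0, norms)
    axes = axes / norms[:, None]

    # Deterministic signs: LD1 oriented worse > better; further axes by
    # making their largest-magnitude loading positive.
    centroids = class_means @ axes.T
    if not degenerate:
        best, worst = 0, len(classes) - 1
        if centroids[worst, 0] < centroids[best, 0]:
            axes[0] = -axes[0]
    for j in range(1, axes.shape[0]):
        lead = np.argmax(np.abs(axes[j]))
        if axes[j, lead] < 0:
            axes[j] = -axes[j]
    centroids = class_means @ axes.T

    return DiscriminantModel(
        classes=classes,
        feature_means=means,
        feature_scales=scales,
        class_means=class_means,
        axes=axes,
        eigenvalues=kept_vals,
        explained_variance_ratio=np.asarray(evr, dtype=float),
        centroids=centroids,
        gamma=gamma,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Projection and classification
# ---------------------------------------------------------------------------

def _as_feature_vector(fingerprint) -> np.ndarray:
    x = fingerprint.values if isinstance(fingerprint, FingerprintVector) else np.asarray(
        fingerprint, dtype=float
    )
    if x.shape != (10,):
        raise ValidationError(f"expected a 10-feature fingerprint, got shape {x.shape}")
    return x


def project(model: DiscriminantModel, fingerprint) -> np.ndarray:
    """Canonical coordinates (LD1[, LD2]) of a fingerprint."""
    if model.degenerate:
        raise DegenerateModelError("cannot project with a degenerate model")
    x = _as_feature_vector(fingerprint)
    z = (x - model.feature_means) / model.feature_scales
    return model.axes @ z


def classify(model: DiscriminantModel, fingerprint) -> str:
    """Nearest class centroid in canonical space; ties go to the worse class."""
    if model.degenerate:
        raise DegenerateModelError("cannot classify with a degenerate model")
    coords = project(model, fingerprint)
    d = np.linalg.norm(model.centroids - coords, axis=1)
    dmin = d.min()
    tol = _EIG_TIE_RTOL * max(dmin, 1.0)
    # classes are ordered best -> worst; the last tied index is the worst.
    tied = np.flatnonzero(d <= dmin + tol)
    return model.classes[int(tied[-1])]


def loocv(cohort: LabeledCohort, n_axes: int = 2, gamma: float = 0.1) -> ConfusionMatrix:
    """Leave-one-out cross-validation at the patient level.

    Each sample is predicted by a model refit on all others. Folds whose
    removal leaves a class with fewer than 2 members are skipped and counted
    in ``skipped_folds`` rather than silently imputed.
    """
    n = len(cohort.fingerprints)
    if n < 3:
        raise ValidationError(f"LOOCV needs at least 3 samples, got {n}")
    classes = cohort.classes()
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    skipped = 0
    for i in range(n):
        rest_fp = cohort.fingerprints[:i] + cohort.fingerprints[i + 1:]
        rest_lab = cohort.labels[:i] + cohort.labels[i + 1:]
        try:
            sub = LabeledCohort(fingerprints=rest_fp, labels=rest_lab)
            model = fit_lda(sub, n_axes=n_axes, gamma=gamma)
            pred = classify(model, cohort.fingerprints[i])
        except (ValidationError, NumericalError):
            skipped += 1
            continue
        counts[idx[cohort.labels[i]], idx.get(pred, idx[cohort.labels[i]])] += 1
    if counts.sum() == 0:
        raise NumericalError(
            f"all {n} LOOCV folds were degenerate (a left-out sample empties a class)"
        )
    return ConfusionMatrix(classes=classes, counts=counts, skipped_folds=skipped)


# ---------------------------------------------------------------------------
# LD1 as a continuous severity biomarker
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ld1SeverityFit:
    pearson_r: float
    p_value: float
    a: float
    b: float
    r_squared: float


def correlate_ld1_severity(
    ld1_scores: Sequence[float], severity_scores: Sequence[float]
) -> Ld1SeverityFit:
    """Pearson correlation plus an exponential fit severity ~ a*exp(b*LD1).

    The nonlinear least-squares fit is initialised from a log-linear
    regression on the strictly positive severity values; R^2 is computed as
    1 - SS_res/SS_tot on the original scale.
    """
    x = np.asarray(ld1_scores, dtype=float)
    y = np.asarray(severity_scores, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("need >= 3 paired (LD1, severity) observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise NumericalError("correlation undefined for a constant input vector")
    r, p = scipy.stats.pearsonr(x, y)

    pos = y > 0
    if pos.sum() >= 2 and np.ptp(x[pos]) > 0:
        b0, log_a0 = np.polyfit(x[pos], np.log(y[pos]), 1)
        p0 = (float(np.exp(log_a0)), float(b0))
    else:
        p0 = (max(float(y.mean()), 1e-6), 0.0)

    def _model(xx, a, b):
        return a * np.exp(b * xx)

    try:
        (a, b), _ = scipy.optimize.curve_fit(_model, x, y, p0=p0, maxfev=10000)
    except RuntimeError:
        a, b = p0
    ss_res = float(np.sum((y - _model(x, a, b)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return Ld1SeverityFit(
        pearson_r=float(r),
        p_value=float(p),
        a=float(a),
        b=float(b),
        r_squared=1.0 - ss_res / ss_tot,
    )


def decision_mesh(
    model: DiscriminantModel,
    bounds: tuple[float, float, float, float],
    resolution: int = 200,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grid of predicted classes over the 2D canonical plane.

    Returns (xx, yy, labels) where labels is an object array of class names.
    Requires a 2-axis model; nearest-centroid geometry makes the regions
    convex polygons bounded by perpendicular bisectors.
    """
    if model.n_axes != 2:
        raise ValidationError("decision mesh requires a 2-axis model")
    if model.degenerate:
        raise DegenerateModelError("cannot mesh a degenerate model")
    x0, x1, y0, y1 = bounds
    xs = np.linspace(x0, x1, resolution)
    ys = np.linspace(y0, y1, resolution)
    xx, yy = np.meshgrid(xs, ys)
    pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
    d = np.linalg.norm(pts[:, None, :] - model.centroids[None, :, :], axis=2)
    dmin = d.min(axis=1, keepdims=True)
    tol = _EIG_TIE_RTOL * np.maximum(dmin, 1.0)
    tied = d <= dmin + tol
    # last tied class index = worst prognosis among ties
    k = tied.shape[1]
    choice = (tied * np.arange(1, k + 1)).argmax(axis=1)
    labels = np.asarray(model.classes, dtype=object)[choice].reshape(xx.shape)
    return xx, yy, labels
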