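"""Clinical severity scoring from peripheral-blood panels.

An unweighted binary rubric: each of five systemic biomarkers (WBC,
neutrophil %, eosinophil %, monocyte %, CRP) contributes 1 to a cumulative
0-5 Severity Score when it falls outside the laboratory reference interval.
Fever is recorded but never enters the numeric score. Scores stratify into
prognostic classes: 0 -> Good, 1-2 -> Neutral, >=3 -> Poor.

Reference intervals are closed on both ends except CRP, whose upper bound is
exclusive (a CRP of exactly 5.0 mg/L is flagged). Clinical judgement that
departs from the rubric (e.g. escalating a febrile patient with a marked CRP
elevation) is only possible through an explicit, note-carrying override so
the audit trail stays intact.

Eosinophil fractions >= 5.0% additionally flag the allergic (Type 2) airway
endotype, independent of the severity score.

A de-identified 10-patient pediatric blood-panel cohort ships with the
package (``load_packaged_cohort``) together with its single override record.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError

PROGNOSIS_CLASSES = ("Good", "Neutral", "Poor")
PARAMETERS = ("wbc", "neutrophils_pct", "eosinophils_pct", "monocytes_pct", "crp")
PANEL_COLUMNS = (
    "patient_id", "age", "sex", "diagnosis", "fever",
    "wbc", "neutrophils_pct", "eosinophils_pct", "monocytes_pct", "crp",
)

ALLERGIC_EOSINOPHIL_THRESHOLD = 5.0  # percent


@dataclass(frozen=True)
class Interval:
    """A reference interval [low, high]; ``high_inclusive=False`` makes it [low, high)."""

    low: float
    high: float
    high_inclusive: bool = True

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValidationError(f"invalid interval: low {self.low} > high {self.high}")

    def contains(self, value: float) -> bool:
        if value < self.low:
            return False
        return value <= self.high if self.high_inclusive else value < self.high


@dataclass(frozen=True)
class ReferenceIntervals:
    """Laboratory reference intervals for the five rubric parameters."""

    wbc: Interval = Interval(4.5, 12.0)  # 10^9 cells/L
    neutrophils_pct: Interval = Interval(37.0, 60.0)
    eosinophils_pct: Interval = Interval(1.0, 5.0)
    monocytes_pct: Interval = Interval(2.0, 10.0)
    crp: Interval = Interval(0.0, 5.0, high_inclusive=False)  # mg/L, < 5.0 is normal

    def as_dict(self) -> dict[str, Interval]:
        return {p: getattr(self, p) for p in PARAMETERS}


@dataclass(frozen=True)
class BloodPanel:
    """One patient's systemic biomarkers plus the (score-excluded) fever flag."""

    patient_id: str
    wbc: float
    neutrophils_pct: float
    eosinophils_pct: float
    monocytes_pct: float
    crp: float
    fever: bool = False
    age: float | None = None
    sex: str | None = None
    diagnosis: str | None = None

    def __post_init__(self) -> None:
        for p in PARAMETERS:
            v = getattr(self, p)
            if v is None or not np.isfinite(v) or v < 0:
                raise ValidationError(
                    f"patient {self.patient_id!r}: {p} = {v!r} must be a finite "
                    f"non-negative number"
                )
        for p in ("neutrophils_pct", "eosinophils_pct", "monocytes_pct"):
            if getattr(self, p) > 100:
                raise ValidationError(
                    f"patient {self.patient_id!r}: {p} = {getattr(self, p)} exceeds 100%"
                )


@dataclass(frozen=True)
class Override:
    """An explicit, logged replacement of a rubric score (audit trail required)."""

    score: int
    note: str

    def __post_init__(self) -> None:
        if not (0 <= self.score <= 5):
            raise ValidationError(f"override score {self.score} outside 0-5")
        if not self.note or not self.note.strip():
            raise ValidationError("an override requires a non-empty note")


@dataclass(frozen=True)
class SeverityResult:
    """The 0-5 score, per-parameter flags, prognosis class and override state."""

    patient_id: str
    score: int
    flags: Mapping[str, int]
    prognosis: str
    override_applied: bool = False
    override_note: str = ""
    rubric_score: int | None = None  # pre-override score, when overridden


def flag_deviation(value: float, interval: Interval) -> int:
    """1 iff the value lies strictly outside the reference interval, else 0."""
    return 0 if interval.contains(value) else 1


def stratify_prognosis(score: int, override: Override | None = None) -> str:
    """Map a 0-5 score to Good (0), Neutral (1-2) or Poor (>=3).

    An override replaces the score before stratification.
    """
    effective = override.score if override is not None else score
    if not (0 <= effective <= 5):
        raise ValidationError(f"severity score {effective} outside 0-5")
    if effective == 0:
        return "Good"
    if effective <= 2:
        return "Neutral"
    return "Poor"


def compute_severity_score(
    panel: BloodPanel,
    intervals: ReferenceIntervals | None = None,
    override: Override | None = None,
) -> SeverityResult:
    """Apply the binary rubric: one point per out-of-range parameter.

    Fever never contributes. If ``override`` is given, the prognosis is
    stratified from the override score and the result is marked accordingly;
    the raw rubric score is preserved in ``rubric_score``.
    """
    intervals = intervals or ReferenceIntervals()
    flags = {
        p: flag_deviation(getattr(panel, p), iv) for p, iv in intervals.as_dict().items()
    }
    rubric = int(sum(flags.values()))
    if override is None:
        return SeverityResult(
            patient_id=panel.patient_id,
            score=rubric,
            flags=flags,
            prognosis=stratify_prognosis(rubric),
        )
    return SeverityResult(
        patient_id=panel.patient_id,
        score=override.score,
        flags=flags,
        prognosis=stratify_prognosis(rubric, override),
        override_applied=True,
        override_note=override.note,
        rubric_score=rubric,
    )


def flag_allergic_endotype(eosinophils_pct: float) -> bool:
    """True iff the eosinophil fraction is >= 5.0% (Type 2 allergic endotype)."""
    if not (0 <= eosinophils_pct <= 100):
        raise ValidationError(f"eosinophil fraction {eosinophils_pct} outside [0, 100]")
    return eosinophils_pct >= ALLERGIC_EOSINOPHIL_THRESHOLD


def score_cohort(
    panels: Iterable[BloodPanel],
    intervals: ReferenceIntervals | None = None,
    overrides: Mapping[str, Override] | None = None,
) -> pd.DataFrame:
    """Score every panel; returns a table with score, prognosis, endotype flag."""
    overrides = overrides or {}
    rows = []
    for panel in panels:
        res = compute_severity_score(panel, intervals, overrides.get(panel.patient_id))
        rows.append(
            {
                "patient_id": panel.patient_id,
                "score": res.score,
                "prognosis": res.prognosis,
                "allergic_endotype": flag_allergic_endotype(panel.eosinophils_pct),
                "override_applied": res.override_applied,
                "override_note": res.override_note,
                **{f"flag_{p}": res.flags[p] for p in PARAMETERS},
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Table I/O and the packaged cohort
# ---------------------------------------------------------------------------

_TRUE = {"yes", "true", "1", "y"}
_FALSE = {"no", "false", "0", "n"}


def _parse_fever(value, path, row_idx) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ParseError(f"{path}: row {row_idx + 2}: unrecognised fever flag {value!r}")


def read_blood_panel_table(path: str | Path) -> list[BloodPanel]:
    """Read a comma-delimited blood-panel table with the standard header."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str})
    if tuple(df.columns) != PANEL_COLUMNS:
        raise ParseError(
            f"{path}: header mismatch; expected {','.join(PANEL_COLUMNS)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    dup = df["patient_id"][df["patient_id"].duplicated()]
    if not dup.empty:
        raise ParseError(f"{path}: duplicate patient_id {dup.iloc[0]!r}")
    panels = []
    for row_idx, row in df.iterrows():
        try:
            panels.append(
                BloodPanel(
                    patient_id=str(row["patient_id"]),
                    age=float(row["age"]),
                    sex=str(row["sex"]),
                    diagnosis=str(row["diagnosis"]),
                    fever=_parse_fever(row["fever"], path, row_idx),
                    wbc=float(row["wbc"]),
                    neutrophils_pct=float(row["neutrophils_pct"]),
                    eosinophils_pct=float(row["eosinophils_pct"]),
                    monocytes_pct=float(row["monocytes_pct"]),
                    crp=float(row["crp"]),
                )
            )
        except ValidationError as exc:
            raise ParseError(f"{path}: row {row_idx + 2}: {exc}") from exc
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: row {row_idx + 2}: non-numeric cell: {exc}") from exc
    return panels


def write_blood_panel_table(panels: Iterable[BloodPanel], path: str | Path) -> None:
    lines = [",".join(PANEL_COLUMNS)]
    for p in panels:
        lines.append(
            ",".join(
                [
                    p.patient_id,
                    "" if p.age is None else f"{p.age:g}",
                    p.sex or "",
                    p.diagnosis or "",
                    "yes" if p.fever else "no",
                    f"{p.wbc:.6g}",
                    f"{p.neutrophils_pct:.6g}",
                    f"{p.eosinophils_pct:.6g}",
                    f"{p.monocytes_pct:.6g}",
                    f"{p.crp:.6g}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_overrides_table(path: str | Path) -> dict[str, Override]:
    """Read an overrides table: patient_id,override_score,note."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str, "note": str})
    if tuple(df.columns) != ("patient_id", "override_score", "note"):
        raise ParseError(f"{path}: expected header patient_id,override_score,note")
    out: dict[str, Override] = {}
    for _, row in df.iterrows():
        out[str(row["patient_id"])] = Override(
            score=int(row["override_score"]), note=str(row["note"])
        )
    return out


def _packaged(name: str) -> Path:
    return Path(str(resources.files("balfprofiler").joinpath("data", name)))


def load_packaged_cohort() -> tuple[list[BloodPanel], dict[str, Override]]:
    """The packaged 10-patient pediatric cohort and its override record."""
    panels = read_blood_panel_table(_packaged("pediatric_cohort_panels.csv"))
    overrides = read_overrides_table(_packaged("pediatric_cohort_overrides.csv"))
    return panels, overrides
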