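"""Time-to-event endpoint derivation from graded toxicity follow-up.

Four genitourinary endpoints are analysed: dysuria, haematuria, incontinence
and urinary frequency.  An event is the first follow-up visit, strictly later
than the late window start (3 months), at which the recorded grade reaches
the endpoint threshold (grade >= 2 by convention; grade >= 1 for haematuria,
where grade >= 2 events are rare).  Patients without such a visit are
censored at their last visit.  Patients with baseline toxicity of grade >= 1
for the endpoint, patients not treated with external-beam radiotherapy
alone, and patients with no usable post-window follow-up are excluded before
analysis, with a per-patient reason log.

The time origin is months since end of radiotherapy by default; cohorts
whose follow-up clock starts at the beginning of radiotherapy can declare so
via ``ClinicalRecord.clock`` — derivation itself is clock-agnostic, the flag
is carried through for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

LATE_WINDOW_MONTHS = 3.0


@dataclass
class ToxicityEndpoint:
    """An endpoint definition: name, grade threshold, late-window start."""

    name: str
    grade_threshold: int = 2
    late_window_start: float = LATE_WINDOW_MONTHS

    def __post_init__(self) -> None:
        if not 1 <= self.grade_threshold <= 4:
            raise ValueError("grade_threshold must be in 1..4")
        if self.late_window_start < 0:
            raise ValueError("late_window_start must be >= 0")


#: Default endpoint set; haematuria uses grade >= 1.
DEFAULT_ENDPOINTS = {
    "dysuria": ToxicityEndpoint("dysuria", 2),
    "haematuria": ToxicityEndpoint("haematuria", 1),
    "incontinence": ToxicityEndpoint("incontinence", 2),
    "frequency": ToxicityEndpoint("frequency", 2),
}


@dataclass
class ClinicalRecord:
    """One patient's baseline covariates and graded follow-up series.

    ``follow_up_grades`` maps endpoint name -> {visit month: grade 0..4};
    ``baseline_grades`` maps endpoint name -> grade at baseline.
    """

    patient_id: str
    age: float
    prescribed_dose_group: float
    disease_risk: int
    cancer_stage: int
    baseline_psa: float
    n_beams: int
    follow_up_grades: dict[str, dict[float, int]] = field(default_factory=dict)
    baseline_grades: dict[str, int] = field(default_factory=dict)
    ebrt_only: bool = True
    source_cohort: str = "synthetic"
    clock: str = "post_treatment"

    def covariate_dict(self) -> dict[str, float]:
        return {
            "age": self.age,
            "prescribed_dose_group": self.prescribed_dose_group,
            "disease_risk": self.disease_risk,
            "cancer_stage": self.cancer_stage,
            "baseline_psa": self.baseline_psa,
            "n_beams": self.n_beams,
        }


CANDIDATE_COVARIATES = (
    "age",
    "prescribed_dose_group",
    "disease_risk",
    "cancer_stage",
    "baseline_psa",
    "n_beams",
)


def derive_event(record: ClinicalRecord, endpoint: ToxicityEndpoint) -> tuple[bool, float]:
    """First-crossing event time on the visit grid.

    Returns ``(event, time_months)``: the first visit strictly after the late
    window where grade >= threshold, else censoring at the last visit.
    Visit ordering in the input encoding is irrelevant (visits are sorted).
    """
    grades = record.follow_up_grades.get(endpoint.name, {})
    visits = sorted((float(m), int(g)) for m, g in grades.items())
    post_window = [(m, g) for m, g in visits if m > endpoint.late_window_start]
    if not post_window:
        raise ValueError(
            f"patient {record.patient_id}: no follow-up visits after "
            f"{endpoint.late_window_start} months for endpoint {endpoint.name}"
        )
    for month, grade in post_window:
        if grade >= endpoint.grade_threshold:
            return True, month
    return False, post_window[-1][0]


def apply_exclusions(
    cohort: Sequence[ClinicalRecord], endpoint: ToxicityEndpoint
) -> tuple[list[ClinicalRecord], pd.DataFrame]:
    """Build the analysis set for an endpoint and log every exclusion.

    Exclusion reasons, checked in order: non-EBRT treatment, baseline
    toxicity grade >= 1 for the endpoint, no usable post-window follow-up.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    included: list[ClinicalRecord] = []
    log_rows = []
    for rec in cohort:
        reason = None
        if not rec.ebrt_only:
            reason = "non-EBRT treatment"
        elif rec.baseline_grades.get(endpoint.name, 0) >= 1:
            reason = "baseline toxicity"
        else:
            grades = rec.follow_up_grades.get(endpoint.name, {})
            if not any(float(m) > endpoint.late_window_start for m in grades):
                reason = "no post-window follow-up"
        if reason is None:
            included.append(rec)
        log_rows.append({"patient_id": rec.patient_id, "included": reason is None,
                         "exclusion_reason": reason})
    log = pd.DataFrame(log_rows, columns=["patient_id", "included", "exclusion_reason"])
    if not included:
        raise ValueError(f"empty analysis set for endpoint {endpoint.name}")
    return included, log


def outcome_table(
    cohort: Sequence[ClinicalRecord], endpoint: ToxicityEndpoint
) -> pd.DataFrame:
    """Analysis-ready table: one row per included patient.

    Columns: patient_id, the six candidate covariates, event (0/1) and
    time_months, plus source_cohort for pooled analyses.
    """
    included, _ = apply_exclusions(cohort, endpoint)
    rows = []
    for rec in included:
        event, time = derive_event(rec, endpoint)
        row = {"patient_id": rec.patient_id, **rec.covariate_dict(),
               "event": int(event), "time_months": float(time),
               "source_cohort": rec.source_cohort}
        rows.append(row)
    return pd.DataFrame(rows)
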