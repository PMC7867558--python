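"""Published worked-example data of the fibromyalgia tailored-tACS crossover
trial: per-participant demographics and stimulation assignments, and the
enrolment flow counts.

These small printed tables serve as fixtures: they let the stimulation
decision rule and simple demographic summaries be checked against the
trial's own reported numbers without any recorded EEG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import SLOW_BANDS

__all__ = [
    "StudySubject",
    "STUDY_SUBJECTS",
    "ENROLMENT_FLOW",
    "age_summary",
    "slow_excess_count",
    "completers_both_arms",
]


@dataclass(frozen=True)
class StudySubject:
    """One row of the trial's demographic/assignment table."""

    subject: int
    age: int
    sex: str
    education_years: int
    prevailing_band: str      # canonical band name
    site: str                 # printed stimulation site (may be a pair)
    frequency_hz: float       # printed stimulation frequency

    @property
    def anode(self) -> str:
        """Primary (first-listed) electrode of the printed site."""
        return self.site.replace("-", "/").split("/")[0]


# subject, age, sex, education, prevailing band, site, stimulation frequency
STUDY_SUBJECTS: tuple[StudySubject, ...] = (
    StudySubject(1, 51, "F", 16, "theta", "F3", 30.0),
    StudySubject(2, 49, "F", 12, "theta", "C3", 30.0),
    StudySubject(3, 51, "F", 13, "theta", "Cp5", 30.0),
    StudySubject(4, 56, "F", 13, "alpha1", "C4/Cp2", 30.0),
    StudySubject(5, 55, "F", 16, "theta", "C3/Cp5", 30.0),
    StudySubject(6, 49, "F", 9, "theta", "Cz-Fz", 30.0),
    StudySubject(7, 55, "F", 8, "theta", "Cp5", 30.0),
    StudySubject(8, 50, "M", 11, "alpha2", "Cz-Pz", 4.0),
    StudySubject(9, 50, "F", 13, "alpha2", "Pz", 4.0),
    StudySubject(10, 50, "F", 16, "theta", "F4", 30.0),
    StudySubject(11, 65, "F", 9, "delta", "C3", 30.0),
    StudySubject(12, 53, "F", 11, "theta", "Cp5", 30.0),
    StudySubject(13, 57, "F", 13, "theta", "Cp5", 30.0),
    StudySubject(14, 52, "F", 8, "beta", "C3", 4.0),
    StudySubject(15, 53, "M", 17, "beta", "Pz", 4.0),
)

#: enrolment flow: recruited minus exclusions and per-arm losses
ENROLMENT_FLOW = {
    "recruited": 24,
    "excluded_at_screening": {
        "contraindication_to_stimulation": 2,
        "psychiatric_disease": 3,
        "recent_drug_change": 2,
    },
    "lost_first_arm": {"drop_out": 1, "drug_change": 1},
    "lost_second_arm": {"drug_change": 1, "stroke": 1, "drop_out_personal": 2},
}


def age_summary() -> tuple[float, float]:
    """Mean and sample SD (n-1) of the participants' ages in years."""
    ages = np.array([s.age for s in STUDY_SUBJECTS], dtype=float)
    return float(ages.mean()), float(ages.std(ddof=1))


def slow_excess_count() -> int:
    """Participants whose prevailing rhythm is a slow band (delta, theta,
    alpha1), i.e. those assigned 30 Hz stimulation by the decision rule."""
    return sum(1 for s in STUDY_SUBJECTS if s.prevailing_band in SLOW_BANDS)


def completers_both_arms() -> int:
    """Participants completing both crossover arms, from the flow counts."""
    flow = ENROLMENT_FLOW
    entered = flow["recruited"] - sum(flow["excluded_at_screening"].values())
    first = entered - sum(flow["lost_first_arm"].values())
    return first - sum(flow["lost_second_arm"].values())
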