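"""Four-patient cohort fixtures: the published per-patient measurements.

Each :class:`PatientRecord` holds one patient's printed values — stent-graft
dimensions, pre/post-operative branch flows (L/min), branch cross-sectional
areas (cm^2), maximum flow velocities (cm/s) and ascending-aortic pressures
(mmHg). ``PRINTED_MEANS`` carries the published column means so downstream
summaries can flag any cell where exact recomputation disagrees with print.

Vessel keys: AAo ascending aorta, BCT brachiocephalic trunk, LCCA left
common carotid, LSA left subclavian, DAo descending aorta. Post-operative
rows have no LSA entry: its origin is covered by the graft and the left arm
is supplied through the carotid-subclavian bypass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["PatientRecord", "GraftComponent", "cohort_fixture", "PRINTED_MEANS"]

PRE_VESSELS = ("AAo", "BCT", "LCCA", "LSA", "DAo")
POST_VESSELS = ("AAo", "BCT", "LCCA", "DAo")


@dataclass(frozen=True)
class GraftComponent:
    """One stent-graft component: proximal/distal diameter and length, mm."""

    proximal_mm: float
    distal_mm: float
    length_mm: float


@dataclass(frozen=True)
class PatientRecord:
    """One patient's printed measurements across all tables."""

    patient_id: int
    age: int
    sex: str
    disease: str
    graft: tuple[GraftComponent, ...]
    flow_pre: dict[str, float]
    flow_post: dict[str, float]
    area_pre: dict[str, float]
    area_post: dict[str, float]
    velocity_pre: dict[str, float]
    velocity_post: dict[str, float]
    pressure_pre: dict[str, float]
    pressure_post: dict[str, float]

    def __post_init__(self) -> None:
        if not 1 <= self.patient_id <= 4:
            raise ValueError(f"patient_id must be 1..4, got {self.patient_id}")
        for group in (self.flow_pre, self.flow_post, self.area_pre, self.area_post,
                      self.velocity_pre, self.velocity_post,
                      self.pressure_pre, self.pressure_post):
            for key, v in group.items():
                if v < 0:
                    raise ValueError(f"negative value {v} for {key}")

    def flows(self, phase: str) -> dict[str, float]:
        if phase == "pre":
            return dict(self.flow_pre)
        if phase == "post":
            return dict(self.flow_post)
        raise ValueError(f"phase must be 'pre' or 'post', got {phase!r}")


def _rec(pid, age, disease, graft, fpre, fpost, apre, apost, vpre, vpost, ppre, ppost):
    return PatientRecord(
        patient_id=pid, age=age, sex="M", disease=disease,
        graft=tuple(GraftComponent(*g) for g in graft),
        flow_pre=dict(zip(PRE_VESSELS, fpre)),
        flow_post=dict(zip(POST_VESSELS, fpost)),
        area_pre=dict(zip(("BCT", "LCCA", "LSA"), apre)),
        area_post=dict(zip(("BCT", "LCCA"), apost)),
        velocity_pre=dict(zip(("BCT", "LCCA", "LSA"), vpre)),
        velocity_post=dict(zip(("BCT", "LCCA"), vpost)),
        pressure_pre=dict(zip(("systolic", "diastolic", "mean"), ppre)),
        pressure_post=dict(zip(("systolic", "diastolic", "mean"), ppost)),
    )


_COHORT = (
    _rec(1, 48, "TAA", [(28, 24, 150)],
         (6.31, 0.54, 0.19, 0.33, 5.26), (6.64, 1.21, 1.08, 4.35),
         (0.95, 0.39, 0.75), (1.05, 0.57),
         (104.4, 89.3, 105.3), (106.7, 134.9),
         (131, 58, 82), (127, 66, 87)),
    _rec(2, 65, "PAU", [(42, 42, 100)],
         (5.98, 0.67, 0.12, 0.17, 5.01), (4.61, 0.57, 0.24, 3.81),
         (2.22, 0.67, 0.82), (2.10, 0.76),
         (36.6, 27.0, 25.8), (33.7, 40.8),
         (110, 49, 80), (108, 56, 80)),
    _rec(3, 74, "TAA", [(44, 44, 200), (46, 46, 200), (46, 46, 150)],
         (4.74, 0.54, 0.12, 0.24, 3.85), (4.53, 0.72, 0.76, 3.05),
         (3.40, 1.27, 1.95), (3.53, 1.30),
         (35.9, 33.8, 45.9), (28.3, 71.4),
         (117, 61, 89), (114, 65, 88)),
    _rec(4, 81, "TAA", [(42, 42, 200), (46, 46, 200), (46, 46, 150)],
         (3.69, 0.75, 0.41, 0.28, 2.26), (2.62, 0.30, 0.37, 1.95),
         (6.09, 1.44, 2.90), (6.06, 1.46),
         (14.1, 29.3, 13.3), (8.9, 43.2),
         (94, 62, 77), (106, 55, 77)),
)

#: published column means, as printed (one decimal for velocities, two for
#: flows/areas, integers for pressures)
PRINTED_MEANS = {
    "flow_pre": {"AAo": 5.18, "BCT": 0.62, "LCCA": 0.21, "LSA": 0.25, "DAo": 4.10},
    "flow_post": {"AAo": 4.60, "BCT": 0.70, "LCCA": 0.61, "DAo": 3.29},
    "area_pre": {"BCT": 3.16, "LCCA": 0.94, "LSA": 1.61},
    "area_post": {"BCT": 3.19, "LCCA": 1.02},
    "velocity_pre": {"BCT": 47.8, "LCCA": 44.9, "LSA": 47.6},
    "velocity_post": {"BCT": 44.5, "LCCA": 72.6},
    "pressure_pre": {"systolic": 113, "diastolic": 58, "mean": 82},
    "pressure_post": {"systolic": 114, "diastolic": 61, "mean": 83},
}


def cohort_fixture() -> list[PatientRecord]:
    """The four-patient cohort, exactly as printed."""
    return list(_COHORT)
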