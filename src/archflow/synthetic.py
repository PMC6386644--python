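"""Synthetic patients with known ground-truth Windkessel parameters.

A synthetic patient stands in for one subject's PC-MRI + cuff-pressure
dataset: an ascending-aortic inflow waveform, four outlets (BCT, LCCA, LSA,
DAo) with cross-sectional areas, per-outlet target mean flows that sum
exactly to the inflow mean, cuff systolic/diastolic targets, and a
ground-truth RCR parameter set per outlet. Because the truth is known,
calibration and flow-redistribution routines can be tested for recovery
rather than merely for plausibility.

Sampling ranges are physiologic resting values: cardiac output 3.5-6.5
L/min with a peak-to-mean ratio of 3-4.5, supra-aortic branch fractions
summing to 20-30% of cardiac output, brachial pressures 100-140 over 50-80
mmHg, and distal-bed time constants R_dist*C of 0.5-1.8 s (log-uniform).
All draws come from one integer-seeded generator; the same seed reproduces
the patient bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ArchModel, OutletBranch
from .waveform import FlowWaveform, gen_inflow_waveform
from .windkessel import WindkesselParams

__all__ = ["OutletSpec", "SyntheticPatient", "gen_synthetic_patient", "build_arch_model"]

#: default proximal share of total resistance (characteristic impedance)
PROX_FRACTION = 0.09
#: log-uniform range for the distal time constant R_dist * C, seconds
TAU_RANGE = (0.5, 1.8)

_AREA_RANGES = {  # cm^2, just distal to each origin
    "BCT": (1.0, 4.0),
    "LCCA": (0.4, 1.5),
    "LSA": (0.7, 3.0),
    "DAo": (2.5, 5.0),
}
_FLOW_FRACTIONS = {"BCT": (0.10, 0.15), "LCCA": (0.03, 0.08), "LSA": (0.04, 0.07)}


@dataclass(frozen=True)
class OutletSpec:
    """One outlet's area, target mean flow and ground-truth RCR set."""

    name: str
    area_cm2: float
    wk_true: WindkesselParams
    target_mean_flow_l_min: float


@dataclass(frozen=True)
class SyntheticPatient:
    """Ground-truth dataset for one synthetic subject."""

    inflow: FlowWaveform
    outlets: tuple[OutletSpec, ...]
    target_sys: float
    target_dia: float
    seed: int

    @property
    def map_mmhg(self) -> float:
        """Cuff mean arterial pressure estimate (sys + 2 dia)/3."""
        return (self.target_sys + 2.0 * self.target_dia) / 3.0

    def outlet(self, name: str) -> OutletSpec:
        for o in self.outlets:
            if o.name == name:
                return o
        raise KeyError(name)


def gen_synthetic_patient(seed: int) -> SyntheticPatient:
    """Draw one internally consistent synthetic patient.

    The four outlet target flows sum exactly to the inflow mean (DAo takes
    the remainder); each outlet's ground-truth total resistance is
    MAP / target flow, so the arch model built from the truth reproduces
    the target flow split and mean pressure by construction.
    """
    rng = np.random.default_rng(seed)
    mean_flow = float(rng.uniform(3.5, 6.5))  # L/min
    peak_flow = mean_flow * float(rng.uniform(3.0, 4.5))
    period = float(rng.uniform(0.85, 1.1))
    map_mmhg = float(rng.uniform(75.0, 100.0))

    inflow = gen_inflow_waveform(
        mean_flow, peak_flow, period=period, n_samples=256,
        seed=int(rng.integers(0, 2**31 - 1)),
    )

    # Cuff targets must be producible by the patient's own circulation: the
    # pulse flow through the proximal resistance alone already generates
    # prox_fraction * MAP * (Qmax - Qmin)/Qmean of pulse pressure (a
    # scale-invariant floor), so the drawn pulse pressure sits above it.
    swing = float((inflow.flows.max() - inflow.flows.min()) / inflow.mean)
    pp_floor = PROX_FRACTION * map_mmhg * swing
    pulse = pp_floor + 5.0 + float(rng.uniform(0.0, 20.0))
    target_sys = map_mmhg + 2.0 * pulse / 3.0
    target_dia = map_mmhg - pulse / 3.0

    flows = {
        name: mean_flow * float(rng.uniform(*frac))
        for name, frac in _FLOW_FRACTIONS.items()
    }
    flows["DAo"] = mean_flow - sum(flows.values())  # exact closure

    outlets = []
    for name in ("BCT", "LCCA", "LSA", "DAo"):
        q_ml_s = flows[name] * 1000.0 / 60.0
        r_total = map_mmhg / q_ml_s
        r_prox = PROX_FRACTION * r_total
        r_dist = r_total - r_prox
        tau = float(np.exp(rng.uniform(np.log(TAU_RANGE[0]), np.log(TAU_RANGE[1]))))
        wk = WindkesselParams(r_prox=r_prox, c=tau / r_dist, r_dist=r_dist)
        area = float(rng.uniform(*_AREA_RANGES[name]))
        outlets.append(OutletSpec(name, area, wk, flows[name]))

    return SyntheticPatient(inflow, tuple(outlets), target_sys, target_dia, seed)


def build_arch_model(
    patient: SyntheticPatient,
    params: dict[str, WindkesselParams] | None = None,
) -> ArchModel:
    """Pre-TEVAR arch model from a synthetic patient.

    Uses the ground-truth Windkessel sets unless per-outlet ``params``
    (e.g. freshly calibrated ones) are supplied.
    """
    branches = tuple(
        OutletBranch.single(
            o.name, o.area_cm2, params[o.name] if params is not None else o.wk_true
        )
        for o in patient.outlets
    )
    return ArchModel(patient.inflow, branches, topology="pre_tevar")
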