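"""Pulsatile volumetric flow waveforms.

A :class:`FlowWaveform` carries one closed cardiac cycle of volumetric flow
Q(t) — the kind of signal phase-contrast MRI yields at the ascending aorta
or a supra-aortic branch. Times span exactly one period with the endpoint
sample repeating the start (periodicity), and flows are stored in m^3/s.

The generator synthesises a PC-MRI-like inflow: a half-sine systolic bump
occupying the first ~35% of the cycle plus a small seeded 4-harmonic
Fourier perturbation, affinely rescaled so the trapezoidal cycle mean and
the cycle maximum hit the requested values to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units

__all__ = ["FlowWaveform", "InvalidWaveformError", "gen_inflow_waveform", "mean_flow"]

#: fraction of the cycle occupied by the systolic ejection bump
SYSTOLE_FRACTION = 0.35
#: number of Fourier perturbation harmonics
N_HARMONICS = 4
#: amplitude ceiling for each harmonic, relative to the unit systolic bump
HARMONIC_SCALE = 0.02


class InvalidWaveformError(ValueError):
    """Raised when waveform samples violate the one-cycle contract."""


@dataclass(frozen=True)
class FlowWaveform:
    """One closed cycle of volumetric flow.

    Parameters
    ----------
    times :
        Sample times in seconds, strictly increasing, ``times[0] == 0`` and
        ``times[-1] == period``.
    flows :
        Volumetric flow in m^3/s at each sample; the endpoint must repeat
        the start value (relative tolerance 1e-9).
    period :
        Cycle duration in seconds.
    """

    times: np.ndarray
    flows: np.ndarray
    period: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        flows = np.asarray(self.flows, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "flows", flows)
        if times.ndim != 1 or flows.shape != times.shape:
            raise InvalidWaveformError("times and flows must be matching 1-D arrays")
        if self.period <= 0:
            raise InvalidWaveformError(f"period must be positive, got {self.period}")
        if np.any(np.diff(times) <= 0):
            raise InvalidWaveformError("times must be strictly increasing")
        if times[0] != 0.0 or not np.isclose(times[-1], self.period, rtol=1e-12, atol=0.0):
            raise InvalidWaveformError("times must span exactly [0, period]")
        scale = max(abs(flows[0]), abs(flows[-1]), np.max(np.abs(flows)))
        if scale > 0 and abs(flows[0] - flows[-1]) > 1e-9 * scale:
            raise InvalidWaveformError("endpoint flow must equal start flow (periodicity)")

    @property
    def mean(self) -> float:
        """Trapezoidal cycle-average flow, m^3/s."""
        return float(np.trapezoid(self.flows, self.times) / self.period)

    @property
    def peak(self) -> float:
        """Cycle maximum flow, m^3/s."""
        return float(np.max(self.flows))

    @property
    def mean_l_min(self) -> float:
        return units.m3_s_to_l_per_min(self.mean)

    @property
    def peak_l_min(self) -> float:
        return units.m3_s_to_l_per_min(self.peak)

    @property
    def flows_ml_s(self) -> np.ndarray:
        return self.flows * units.M3_S_TO_ML_S

    @property
    def flows_l_min(self) -> np.ndarray:
        return self.flows * units.M3_S_TO_L_PER_MIN

    def sample(self, t: np.ndarray | float) -> np.ndarray:
        """Flow (m^3/s) at arbitrary times, periodic extension, linear interp."""
        tt = np.mod(np.asarray(t, dtype=float), self.period)
        return np.interp(tt, self.times, self.flows)

    def scaled_to_mean(self, mean_l_min: float) -> "FlowWaveform":
        """Uniformly rescale so the cycle mean equals ``mean_l_min``."""
        target = units.l_per_min_to_m3_s(mean_l_min)
        if self.mean == 0:
            raise InvalidWaveformError("cannot rescale a zero-mean waveform")
        return FlowWaveform(self.times.copy(), self.flows * (target / self.mean), self.period)


def gen_inflow_waveform(
    mean_flow_l_min: float,
    peak_flow_l_min: float,
    period: float = 1.0,
    n_samples: int = 256,
    seed: int = 0,
) -> FlowWaveform:
    """Synthesise a PC-MRI-like inflow waveform.

    The shape is a half-sine systolic bump over the first ``SYSTOLE_FRACTION``
    of the cycle plus a small seeded Fourier perturbation, affinely rescaled
    so that the trapezoidal mean equals ``mean_flow_l_min`` and the maximum
    equals ``peak_flow_l_min`` exactly (machine precision). ``peak == mean``
    degenerates to a constant waveform.

    Raises
    ------
    InvalidWaveformError
        If ``peak_flow_l_min < mean_flow_l_min``, the mean is not positive,
        or fewer than 32 samples are requested.
    """
    if mean_flow_l_min <= 0:
        raise InvalidWaveformError(f"mean flow must be positive, got {mean_flow_l_min}")
    if peak_flow_l_min < mean_flow_l_min:
        raise InvalidWaveformError(
            f"peak flow ({peak_flow_l_min}) must be >= mean flow ({mean_flow_l_min})"
        )
    if n_samples < 32:
        raise InvalidWaveformError(f"need at least 32 samples, got {n_samples}")
    if period <= 0:
        raise InvalidWaveformError(f"period must be positive, got {period}")

    t = np.linspace(0.0, period, n_samples)
    if peak_flow_l_min == mean_flow_l_min:
        flows = np.full_like(t, units.l_per_min_to_m3_s(mean_flow_l_min))
        return FlowWaveform(t, flows, period)

    t_sys = SYSTOLE_FRACTION * period
    shape = np.where(t <= t_sys, np.sin(np.pi * np.minimum(t, t_sys) / t_sys), 0.0)

    rng = np.random.default_rng(seed)
    amps = rng.uniform(0.2, 1.0, N_HARMONICS) * HARMONIC_SCALE
    phases = rng.uniform(0.0, 2.0 * np.pi, N_HARMONICS)
    for k in range(N_HARMONICS):
        shape = shape + amps[k] * np.sin(2.0 * np.pi * (k + 1) * t / period + phases[k])
    # periodic by construction: bump vanishes at both endpoints, harmonics wrap
    shape[-1] = shape[0]

    shape_mean = float(np.trapezoid(shape, t) / period)
    shape_max = float(np.max(shape))
    # affine map a + b*shape hitting mean and max exactly (b > 0 keeps argmax)
    b = (peak_flow_l_min - mean_flow_l_min) / (shape_max - shape_mean)
    a = mean_flow_l_min - b * shape_mean
    flows_l_min = a + b * shape
    return FlowWaveform(t, flows_l_min * units.L_PER_MIN_TO_M3_S, period)


def mean_flow(w: FlowWaveform) -> float:
    """Trapezoidal cycle-average flow in L/min."""
    return w.mean_l_min
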