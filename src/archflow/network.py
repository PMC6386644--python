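"""Lumped (0D) aortic-arch network: one inflow, Windkessel outlets.

The arch is reduced to a single pressure node fed by the ascending-aortic
inflow Q_in(t) and drained by the supra-aortic branches and the descending
aorta, each terminated by a three-element Windkessel. At every instant the
node pressure P solves the algebraic balance

    sum_i (P - P_d,i) / R_prox,i = Q_in(t)

and each distal pressure P_d,i advances by its RCR ordinary differential
equation. Both are discretised together with the trapezoidal rule, so flow
is conserved at the node to machine precision at every step.

Zone-2 TEVAR is a topology transform: the left subclavian (LSA) outlet is
removed from the arch and its distal bed is re-attached in parallel with
the left-carotid (LCCA) bed through a carotid-subclavian bypass resistance
in series. With zero bypass resistance the combined branch conductance is
exactly the sum of the two original branch conductances, which is what
produces the observed post-operative LCCA flow increase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import units
from .waveform import FlowWaveform
from .windkessel import ConvergenceWarning, ParameterError, PressureTrace, WindkesselParams

__all__ = [
    "WKElement",
    "OutletBranch",
    "ArchModel",
    "NetworkResult",
    "ModelError",
    "TopologyError",
    "PRE_TEVAR_OUTLETS",
    "POST_TEVAR_OUTLETS",
    "simulate_network",
    "apply_tevar",
    "max_velocity",
    "mean_flow",
]

PRE_TEVAR_OUTLETS = ("BCT", "LCCA", "LSA", "DAo")
POST_TEVAR_OUTLETS = ("BCT", "LCCA", "DAo")


class ModelError(ValueError):
    """Raised for structurally invalid arch models."""


class TopologyError(ModelError):
    """Raised when a topology transform is applied to the wrong state."""


@dataclass(frozen=True)
class WKElement:
    """One RCR termination, optionally reached through a series resistance.

    ``series_r`` models a conduit between the arch node and the Windkessel
    inlet — the carotid-subclavian bypass in the post-TEVAR LCCA branch.
    The effective proximal resistance is ``params.r_prox + series_r``.
    """

    params: WindkesselParams
    series_r: float = 0.0

    def __post_init__(self) -> None:
        if self.series_r < 0 or np.isnan(self.series_r):
            raise ParameterError(f"series_r must be >= 0, got {self.series_r}")

    @property
    def r_prox_eff(self) -> float:
        return self.params.r_prox + self.series_r

    @property
    def steady_conductance(self) -> float:
        """1 / (R_prox_eff + R_dist), mL/(mmHg.s)."""
        denom = self.r_prox_eff + self.params.r_dist
        return 0.0 if np.isinf(denom) else 1.0 / denom


@dataclass(frozen=True)
class OutletBranch:
    """Named arch outlet: one or more Windkessel elements sharing the node.

    A branch usually holds a single element; the post-TEVAR LCCA holds two
    (its own bed plus the bypassed subclavian bed). ``area_cm2`` is the
    vessel cross-section just distal to its origin, used for velocity
    estimates.
    """

    name: str
    area_cm2: float
    elements: tuple[WKElement, ...]

    def __post_init__(self) -> None:
        if self.area_cm2 <= 0:
            raise ModelError(f"outlet {self.name}: area must be positive, got {self.area_cm2}")
        if not self.elements:
            raise ModelError(f"outlet {self.name}: needs at least one Windkessel element")

    @classmethod
    def single(cls, name: str, area_cm2: float, wk: WindkesselParams) -> "OutletBranch":
        return cls(name, area_cm2, (WKElement(wk),))

    @property
    def steady_conductance(self) -> float:
        return sum(e.steady_conductance for e in self.elements)


@dataclass(frozen=True)
class ArchModel:
    """Arch inflow plus outlet set, tagged pre or post TEVAR."""

    inflow: FlowWaveform
    outlets: tuple[OutletBranch, ...]
    topology: str = "pre_tevar"
    bypass_resistance: float = 0.0

    def __post_init__(self) -> None:
        if not self.outlets:
            raise ModelError("model needs at least one outlet")
        names = [o.name for o in self.outlets]
        if len(set(names)) != len(names):
            raise ModelError(f"duplicate outlet names: {names}")
        if self.topology not in ("pre_tevar", "post_tevar"):
            raise ModelError(f"unknown topology {self.topology!r}")
        if self.bypass_resistance < 0:
            raise ModelError("bypass_resistance must be >= 0")

    def outlet(self, name: str) -> OutletBranch:
        for o in self.outlets:
            if o.name == name:
                return o
        raise ModelError(f"no outlet named {name!r}")


@dataclass(frozen=True)
class NetworkResult:
    """Last-cycle network solution in clinical units.

    ``outlet_flows`` holds one closed-cycle flow waveform per outlet;
    ``mean_flows``/``peak_flows`` are their trapezoidal means and maxima in
    L/min. ``pressure`` is the full multi-cycle node pressure (mmHg) and
    ``max_conservation_residual`` the largest relative violation of
    sum(outlet flows) = inflow over every time step of every cycle.
    """

    pressure: PressureTrace
    outlet_flows: dict[str, FlowWaveform]
    mean_flows: dict[str, float]
    peak_flows: dict[str, float]
    max_conservation_residual: float


def simulate_network(
    model: ArchModel,
    n_cycles: int = 6,
    steps_per_cycle: int = 1000,
    init: str = "periodic",
) -> NetworkResult:
    """Solve the single-node arch network over ``n_cycles`` cardiac cycles.

    Implicit trapezoidal step: each element's next distal pressure is an
    affine function of the unknown node pressure, so the node balance
    reduces to one scalar equation per step. The network is linear, so the
    one-cycle map on the distal-pressure vector is affine; with
    ``init="periodic"`` (default) that map is identified from a handful of
    spin-up sweeps and integration starts from its exact fixed point.
    ``init="steady"`` warm-starts at the steady solution for the mean
    inflow instead. The last cycle is reported.
    """
    if n_cycles < 2:
        raise ModelError(f"n_cycles must be >= 2, got {n_cycles}")
    if steps_per_cycle < 100:
        raise ModelError(f"steps_per_cycle must be >= 100, got {steps_per_cycle}")
    if init not in ("periodic", "steady"):
        raise ModelError(f"init must be 'periodic' or 'steady', got {init!r}")

    elements = [(o.name, e) for o in model.outlets for e in o.elements]
    period = model.inflow.period
    dt = period / steps_per_cycle
    n_steps = n_cycles * steps_per_cycle
    t = np.arange(n_steps + 1) * dt
    q_in = model.inflow.sample(t) * units.M3_S_TO_ML_S  # mL/s

    # steady solution at mean inflow: node pressure from total conductance
    q_mean = model.inflow.mean * units.M3_S_TO_ML_S
    g_total = sum(e.steady_conductance for _, e in elements)
    if g_total <= 0:
        raise ModelError("total branch conductance must be positive")
    p_node_steady = q_mean / g_total

    n_el = len(elements)
    r = np.array([e.r_prox_eff for _, e in elements])
    rd = np.array([e.params.r_dist for _, e in elements])
    c = np.array([e.params.c for _, e in elements])
    finite = np.isfinite(r)

    p_steady = np.where(
        finite,
        p_node_steady * rd / np.where(finite, r + rd, 1.0),
        p_node_steady,  # disconnected element: rests at node pressure
    )

    alpha = c / dt
    beta = 1.0 / (2.0 * rd)
    inv_r = np.where(finite, 1.0 / r, 0.0)
    d_coef = alpha + beta + 0.5 * inv_r
    b_coef = 0.5 * inv_r / d_coef
    gain = (alpha - beta) / d_coef
    node_den = float(np.sum(inv_r * (1.0 - b_coef)))

    def node_solve(qin_now: float, p_d_now: np.ndarray) -> tuple[float, np.ndarray]:
        """Algebraic node balance at the current instant."""
        p = (qin_now + float(np.sum(inv_r * p_d_now))) / float(np.sum(inv_r))
        return p, inv_r * (p - p_d_now)

    def sweep(p_d0: np.ndarray, q_series: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Advance the coupled system over q_series; returns (p_node, flows, p_d)."""
        steps = len(q_series) - 1
        p_nodes = np.empty(steps + 1)
        flows = np.empty((steps + 1, n_el))
        p_d = p_d0.copy()
        p_nodes[0], flows[0] = node_solve(q_series[0], p_d)
        for n in range(steps):
            a_coef = ((alpha - beta) * p_d + 0.5 * flows[n]) / d_coef
            p_new = (q_series[n + 1] + float(np.sum(inv_r * a_coef))) / node_den
            p_d = a_coef + b_coef * p_new
            p_nodes[n + 1] = p_new
            flows[n + 1] = inv_r * (p_new - p_d)
        return p_nodes, flows, p_d

    p_d0 = p_steady
    if init == "periodic":
        # identify the affine one-cycle map p_d(T) = A p_d(0) + b and start
        # at its fixed point; A columns come from homogeneous (zero-inflow)
        # sweeps, b from one forced sweep from the zero state
        q_one = q_in[: steps_per_cycle + 1]
        _, _, b_vec = sweep(np.zeros(n_el), q_one)
        a_mat = np.empty((n_el, n_el))
        q_zero = np.zeros(steps_per_cycle + 1)
        for j in range(n_el):
            e_j = np.zeros(n_el)
            e_j[j] = 1.0
            _, _, a_mat[:, j] = sweep(e_j, q_zero)
        p_d0 = np.linalg.solve(np.eye(n_el) - a_mat, b_vec)

    p_node, flows, _ = sweep(p_d0, q_in)
    scale = np.maximum(np.abs(q_in), q_mean)
    residual = float(np.max(np.abs(flows.sum(axis=1) - q_in) / scale))

    bounds = np.arange(n_cycles + 1) * steps_per_cycle
    pressure = PressureTrace(t, p_node, bounds)
    if pressure.drift >= 1e-3:
        warnings.warn(
            f"network not converged: last-two-cycle mean drift {pressure.drift:.2e}",
            ConvergenceWarning,
            stacklevel=2,
        )

    sl = slice((n_cycles - 1) * steps_per_cycle, n_steps + 1)
    t_last = t[sl] - t[sl][0]
    outlet_flows: dict[str, FlowWaveform] = {}
    mean_flows: dict[str, float] = {}
    peak_flows: dict[str, float] = {}
    for outlet in model.outlets:
        idx = [i for i, (name, _) in enumerate(elements) if name == outlet.name]
        q_branch_ml = flows[sl][:, idx].sum(axis=1)
        q_branch = q_branch_ml / units.M3_S_TO_ML_S
        # close the cycle: residual transient leaves a sub-convergence-level
        # endpoint mismatch; snap it when below the drift warning threshold
        if abs(q_branch[-1] - q_branch[0]) <= 1e-3 * max(abs(q_branch).max(), 1e-300):
            q_branch[-1] = q_branch[0]
        wf = FlowWaveform(t_last, q_branch, period)
        outlet_flows[outlet.name] = wf
        mean_flows[outlet.name] = wf.mean_l_min
        peak_flows[outlet.name] = wf.peak_l_min

    return NetworkResult(pressure, outlet_flows, mean_flows, peak_flows, residual)


def apply_tevar(
    model: ArchModel,
    bypass_resistance: float = 0.0,
    new_inflow: FlowWaveform | None = None,
) -> ArchModel:
    """Transform a pre-TEVAR arch into the post-TEVAR topology.

    The LSA outlet is removed; its distal bed is re-attached in parallel
    with the LCCA bed through ``bypass_resistance`` (mmHg.s/mL) in series —
    the carotid-subclavian bypass. Distal beds are otherwise unchanged.
    The post-operative ascending-aortic inflow is an input, not a
    prediction; pass ``new_inflow`` to replace it, else the pre-operative
    inflow is kept.
    """
    if model.topology != "pre_tevar":
        raise TopologyError(f"apply_tevar requires a pre_tevar model, got {model.topology}")
    if bypass_resistance < 0 or np.isnan(bypass_resistance):
        raise ModelError(f"bypass_resistance must be >= 0, got {bypass_resistance}")
    names = {o.name for o in model.outlets}
    if not {"LCCA", "LSA"}.issubset(names):
        raise ModelError("pre_tevar model must contain LCCA and LSA outlets")

    lcca = model.outlet("LCCA")
    lsa = model.outlet("LSA")
    bypassed = tuple(
        replace(e, series_r=e.series_r + bypass_resistance) for e in lsa.elements
    )
    merged = OutletBranch("LCCA", lcca.area_cm2, lcca.elements + bypassed)
    outlets = tuple(
        merged if o.name == "LCCA" else o for o in model.outlets if o.name != "LSA"
    )
    return ArchModel(
        inflow=new_inflow if new_inflow is not None else model.inflow,
        outlets=outlets,
        topology="post_tevar",
        bypass_resistance=bypass_resistance,
    )


def max_velocity(peak_flow_l_min: float, area_cm2: float, profile_factor: float = 2.0) -> float:
    """Peak point velocity (cm/s) from peak flow and lumen area.

    ``profile_factor`` maps the cross-section average to the point maximum:
    2 for a parabolic (Poiseuille) profile, 1 for plug flow.
    """
    if area_cm2 <= 0:
        raise ModelError(f"area must be positive, got {area_cm2}")
    if profile_factor < 1:
        raise ModelError(f"profile_factor must be >= 1, got {profile_factor}")
    q_cm3_s = peak_flow_l_min * 1000.0 / 60.0
    return profile_factor * q_cm3_s / area_cm2


def mean_flow(w: FlowWaveform) -> float:
    """Trapezoidal cycle-average flow, L/min."""
    return w.mean_l_min
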