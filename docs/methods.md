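# Methods

## Scope and model reduction

The package studies the hemodynamic consequences of zone-2 TEVAR — coverage
of the left subclavian artery (LSA) origin by an arch stent graft with a
carotid–subclavian bypass — at the level of a lumped-parameter (0D)
circulation. The 3D geometry of a patient's arch is deliberately out of
scope: the arch is reduced to a single pressure node, each outflow vessel
(brachiocephalic trunk, left common carotid, left subclavian, descending
aorta) to a three-element Windkessel, and the stent graft to a triangulated
surface carrying per-face pressure and wall-shear fields. The 0D reduction
keeps exactly the mechanism that drives post-operative supra-aortic flow
redistribution — conductance competition at a shared pressure node — while
discarding wave travel, secondary flow and geometric detail.

## Windkessel outlets

Each distal bed is the classic RCR circuit: proximal resistance `R_p`
(characteristic impedance of the feeding artery) in series with compliance
`C` parallel to distal resistance `R_d`, in clinical units (mmHg·s/mL,
mL/mmHg). With prescribed inflow `Q(t)`:

    C dP_d/dt = Q(t) − P_d/R_d,        P(t) = P_d(t) + R_p Q(t).

**Integration.** Fixed-step trapezoidal update, default 1000 steps per
cycle, six cycles retained with the last cycle reported. The scheme is
second-order; a Richardson test against a 10×-finer reference confirms the
order empirically.

**Initialization.** Because the circuit is linear, the one-cycle update map
`P_d(T) = a·P_d(0) + b` is affine with `|a| < 1`. One spin-up sweep
identifies `(a, b)` and the simulation starts from the fixed point
`b/(1−a)`, so every reported cycle is already periodic and the cycle-5 →
cycle-6 mean drift is at machine precision. A mean-value warm start
(`P_d(0) = R_d·Q̄`) is retained as an option (`init="mean"`); with it,
physiologic time constants `R_d·C` of 1–2 s leave a residual drift of
0.2–0.5% after six cycles, which is why the periodic start is the default.

**Calibration.** Targets are a brachial cuff pair (systolic, diastolic).
The total resistance starts at the standard cuff estimate
`R_tot = MAP/Q̄`, `MAP = (SBP + 2·DBP)/3`, split `R_p = 0.09·R_tot`
(characteristic-impedance heuristic; configurable). The inner loop bisects
`C` (log-space, bracket 1e-3–10 mL/mmHg) on the last-cycle pulse pressure,
which decreases strictly with `C`; tolerance 0.25 mmHg. Matching the mean
and the pulse does not by itself pin both extremes — the trace's form
factor `(max−mean)/pulse` is waveform-dependent and generally not the 2/3
the cuff formula assumes — so an outer fixed-point step shifts `R_tot` by
`−offset/Q̄` (the periodic mean responds exactly one-to-one) until both
extremes sit within tolerance. Two to four outer iterations suffice; the
fitted `R_tot` stays within a few percent of the cuff estimate and both
cuff targets are reproduced within 0.5 mmHg on re-simulation. A constant
inflow cannot produce pulse pressure; calibration then raises an error
reporting the achieved pair.

## Arch network and the TEVAR transform

All outlets share one pressure node. At each instant the node pressure
solves the algebraic balance `Σ_i (P − P_d,i)/R_p,i = Q_in(t)`; each distal
pressure then advances by its own ODE. Both are discretized together
(trapezoidal, each element's next distal pressure affine in the unknown
node pressure), so the node balance — and hence flow conservation — holds
to machine precision at every step. The same affine-map argument as for a
single outlet gives the exact periodic start, now with a small linear solve
over the distal-pressure vector.

`apply_tevar` removes the LSA outlet and re-attaches its distal bed in
parallel with the LCCA bed through a series bypass resistance. With zero
bypass resistance the merged branch conductance is the sum of the two
original conductances, so the steady node pressure is unchanged and the
post-operative LCCA flow equals pre-operative LCCA + LSA exactly; the
pulsatile means inherit the identity to rounding. Increasing the bypass
resistance strictly decreases the merged flow. In the limit of a
disconnected bypass the LCCA flow does *not* return to its pre-operative
value: with the LSA bed gone from a flow-driven node, the remaining three
outlets share the full inflow and the LCCA flow sits above pre-op by about
the LSA's conductance share (~6%). The post-operative ascending-aortic
inflow is an input, not a model prediction — measured post-op inflows
differ from pre-op and the 0D model has no heart.

Point velocity estimates use `v_max = k·Q_peak/A` with the vessel
cross-section `A` just distal to the branch origin and profile factor
`k = 2` (parabolic centreline) by default, `k = 1` for plug flow.

## Displacement force

The load on the graft is the traction integral at the systolic peak,

    DF = Σ_f ( p_f n̂_f A_f + τ_f A_f ),

piecewise-constant per face, normals outward from the lumen, pressure and
viscous parts reported separately. Accuracy is controlled by mesh
refinement, not quadrature order; the bend-tube oracle converges at second
order in element size. "Systolic peak" means the instant of maximum node
pressure within the last cycle (ties to the earliest sample; a peak-inflow
definition is available in the configuration). Only the graft's lateral
(wetted) surface is integrated — no end caps, matching a stent graft.
Orientation is validated structurally: every shared edge must be traversed
once in each direction, and closed surfaces must enclose positive signed
volume.

Anatomical frame: +z cranial, +x ventral, +y patient-left. Direction labels
come from the (x, z) sign pair — dorsocranial means x < 0, z > 0 — with
vectors within 5° of a separating plane flagged as boundary cases.

Three closed forms anchor the integral: uniform pressure on a closed
surface yields zero net force (divergence theorem); a 90° bend under
uniform `p` yields `√2·p·πr²` (the lateral integral equals minus the two
end-cap contributions); Poiseuille wall shear `4μQ/(πr³)` over a straight
tube sums to the drag `8μLQ/r²`.

## Synthetic data

The waveform generator emulates a PC-MRI aortic flow curve: a half-sine
systolic bump over the first 35% of the cycle plus a small seeded
4-harmonic Fourier perturbation, affinely rescaled to hit the requested
trapezoidal mean and peak exactly. It reproduces the gross structure of an
ejection waveform (single systolic peak, mild diastolic undulation,
possibly slightly negative end-systolic flow) but no specific patient's
curve, no Womersley profile shape, and no beat-to-beat variability.

Synthetic patients draw cardiac output 3.5–6.5 L/min, peak-to-mean ratio
3–4.5, period 0.85–1.1 s, MAP 75–100 mmHg, branch flow fractions (BCT
10–15%, LCCA 3–8%, LSA 4–7% of cardiac output, descending aorta the exact
remainder) and per-outlet distal time constants `R_d·C` log-uniform in
0.5–1.8 s. Ground-truth total resistances are `MAP/q̄_i`, so the assembled
arch model reproduces the drawn flow split and mean pressure by
construction — which is what makes parameter-recovery tests well posed.
The cuff pulse pressure is drawn *above* the model's reachability floor
`0.09·MAP·ΔQ/Q̄` (the pulse generated by the proximal resistor alone), so
every patient's targets are attainable by its own circuit. All draws come
from a single integer-seeded generator; a seed reproduces the patient
bit-identically.

What passing these tests shows — and does not show: the pipeline's
arithmetic, conservation, calibration and integration are correct on data
whose generating process is known. They say nothing about image
segmentation, 3D flow features, wall motion (the rigid-wall limitation of
the underlying CFD approach), or beds not modelled (coronaries, distal
carotid territory).

## Cohort arithmetic

The embedded four-patient tables (flows in L/min, branch areas in cm²,
peak velocities in cm/s, pressures in mmHg) are processed in exact decimal
arithmetic with half-away-from-zero rounding, because binary floating
point misrounds ties such as 4.095 or 44.85 that the printed means
require. Ranges are column extrema; percent changes are integers computed
from the printed (rounded) column means by default, with unrounded means
as an option. Four printed means are exact .5 ties rounded the other way
in print (the source data were evidently averaged unrounded); these are
flagged as printed-vs-recomputed discrepancies rather than silently
matched, as is the published +294% LCCA flow change, which is not
derivable from the printed cells (the ratio of printed means gives +190%).
The Pearson test uses `t = r·√((n−2)/(1−r²))` with `n−2` degrees of
freedom, two-sided.

## Numerical defaults

| parameter | default | meaning |
|---|---|---|
| steps_per_cycle | 1000 | trapezoidal steps per cardiac cycle |
| n_cycles | 6 | cycles simulated; last reported |
| prox_fraction | 0.09 | proximal share of total resistance |
| c_bracket | 1e-3–10 mL/mmHg | compliance search bracket |
| pp_tol | 0.25 mmHg | pulse-pressure bisection tolerance |
| profile_factor | 2 | peak-velocity profile factor |
| convergence drift | 0.1% | last-two-cycle mean warning threshold |

Problem sizes in the validation studies (mesh resolutions 16–128 per
direction, 20 synthetic patients, 50 random parameter sets) keep the whole
suite and the acceptance run within a few seconds each while leaving the
convergence slopes and worst-case errors well resolved.

## Known limitations

- Single-node arch: no inter-branch impedances, no wave propagation, no
  inertance; the redistribution mechanism is conductance competition only.
- Rigid surfaces; no fluid–structure interaction.
- The post-TEVAR ascending inflow must be supplied, not predicted.
- Printed-table ties make four published column means unrecoverable from
  the published per-patient values; they are flagged, not forced.
- The published stent-graft surface areas behind the force–area
  correlation are not tabulated, so that regression can only be
  demonstrated on synthetic grafts, not recomputed from published data.
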