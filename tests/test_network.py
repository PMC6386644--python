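import numpy as np
import pytest

from archflow.network import (
    ArchModel,
    ModelError,
    OutletBranch,
    TopologyError,
    apply_tevar,
    max_velocity,
    mean_flow,
    simulate_network,
)
from archflow.synthetic import build_arch_model, gen_synthetic_patient
from archflow.waveform import FlowWaveform
from archflow.windkessel import WindkesselParams, simulate_wk3
from conftest import constant_waveform


def two_outlet_model(inflow):
    # total branch resistances 1.0 and 3.0 mmHg.s/mL -> conductance split 3:1
    return ArchModel(
        inflow,
        (
            OutletBranch.single("BCT", 1.0, WindkesselParams(0.1, 0.5, 0.9)),
            OutletBranch.single("DAo", 3.0, WindkesselParams(0.3, 0.5, 2.7)),
        ),
    )


def test_steady_conductance_split():
    inflow = constant_waveform(4.8)  # 80 mL/s
    res = simulate_network(two_outlet_model(inflow), 6, 1000)
    assert res.mean_flows["BCT"] == pytest.approx(3.6, rel=1e-9)   # 60 mL/s
    assert res.mean_flows["DAo"] == pytest.approx(1.2, rel=1e-9)   # 20 mL/s


def test_flow_conservation_every_step(inflow):
    res = simulate_network(two_outlet_model(inflow), 6, 500)
    assert res.max_conservation_residual <= 1e-9


def test_single_outlet_matches_windkessel(inflow):
    """One-outlet network degenerates to the standalone RCR simulation."""
    params = WindkesselParams(0.09, 1.2, 0.91)
    model = ArchModel(inflow, (OutletBranch.single("DAo", 3.0, params),))
    res = simulate_network(model, 6, 500)
    ref = simulate_wk3(params, inflow, 6, 500)
    assert np.max(np.abs(res.pressure.pressures - ref.pressures)) < 1e-8


def test_model_validation(inflow):
    with pytest.raises(ModelError):
        ArchModel(inflow, ())
    with pytest.raises(ModelError):
        ArchModel(
            inflow,
            (
                OutletBranch.single("BCT", 1.0, WindkesselParams(0.1, 1.0, 1.0)),
                OutletBranch.single("BCT", 1.0, WindkesselParams(0.1, 1.0, 1.0)),
            ),
        )
    with pytest.raises(ModelError):
        OutletBranch.single("BCT", -1.0, WindkesselParams(0.1, 1.0, 1.0))


class TestApplyTevar:
    def test_outlet_count_drops(self):
        pre = build_arch_model(gen_synthetic_patient(3))
        post = apply_tevar(pre, 0.5)
        assert len(pre.outlets) == 4 and len(post.outlets) == 3
        assert {o.name for o in post.outlets} == {"BCT", "LCCA", "DAo"}
        assert post.topology == "post_tevar"

    def test_zero_bypass_steady_flows_add_exactly(self):
        """Unchanged beds + zero bypass: post LCCA flow = pre LCCA + LSA."""
        for seed in range(20):
            pat = gen_synthetic_patient(seed)
            pre = build_arch_model(pat)
            steady = ArchModel(
                constant_waveform(pat.inflow.mean_l_min, pat.inflow.period),
                pre.outlets,
            )
            r_pre = simulate_network(steady, 2, 200)
            r_post = simulate_network(apply_tevar(steady, 0.0), 2, 200)
            expected = r_pre.mean_flows["LCCA"] + r_pre.mean_flows["LSA"]
            assert r_post.mean_flows["LCCA"] == pytest.approx(expected, rel=1e-9)

    def test_zero_bypass_pulsatile_means_add(self):
        pre = build_arch_model(gen_synthetic_patient(5))
        r_pre = simulate_network(pre, 6, 500)
        r_post = simulate_network(apply_tevar(pre, 0.0), 6, 500)
        expected = r_pre.mean_flows["LCCA"] + r_pre.mean_flows["LSA"]
        assert r_post.mean_flows["LCCA"] == pytest.approx(expected, rel=5e-3)

    def test_lcca_flow_decreases_with_bypass_resistance(self):
        pre = build_arch_model(gen_synthetic_patient(8))
        flows = [
            simulate_network(apply_tevar(pre, rb), 4, 500).mean_flows["LCCA"]
            for rb in (0.0, 0.2, 1.0, 5.0, 25.0)
        ]
        assert all(a > b for a, b in zip(flows, flows[1:]))

    def test_infinite_bypass_recovers_isolated_lcca(self):
        pre = build_arch_model(gen_synthetic_patient(8))
        r_pre = simulate_network(pre, 6, 500)
        r_inf = simulate_network(apply_tevar(pre, np.inf), 6, 500)
        # disconnecting the bypass leaves LCCA slightly above its pre-op flow
        # (the LSA no longer competes for the node) but close to it
        assert r_inf.mean_flows["LCCA"] == pytest.approx(
            r_pre.mean_flows["LCCA"], rel=0.15
        )
        assert r_inf.mean_flows["LCCA"] > r_pre.mean_flows["LCCA"]

    def test_post_model_rejects_second_transform(self):
        pre = build_arch_model(gen_synthetic_patient(1))
        post = apply_tevar(pre, 0.0)
        with pytest.raises(TopologyError):
            apply_tevar(post, 0.0)


class TestVelocityAndMeanFlow:
    def test_max_velocity_parabolic(self):
        # 1.2 L/min = 20 mL/s through 1 cm^2, parabolic centreline factor 2
        assert max_velocity(1.2, 1.0, 2.0) == pytest.approx(40.0)

    def test_max_velocity_plug(self):
        assert max_velocity(1.2, 1.0, 1.0) == pytest.approx(20.0)

    def test_max_velocity_rejects_bad_area(self):
        with pytest.raises(ModelError):
            max_velocity(1.2, 0.0)

    def test_mean_flow_constant(self, const_inflow):
        assert mean_flow(const_inflow) == pytest.approx(5.0, rel=1e-12)

    def test_mean_flow_generator_contract(self, inflow):
        assert mean_flow(inflow) == pytest.approx(5.0, rel=1e-6)

    def test_mean_flow_sinusoid_averages_out(self):
        t = np.linspace(0, 1, 201)
        flows = (4.0 + 2.0 * np.sin(2 * np.pi * t)) / 60000.0
        w = FlowWaveform(t, flows, 1.0)
        assert mean_flow(w) == pytest.approx(4.0, rel=1e-6)
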