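"""Protocol simulations: clamps, fixed schedules, IVGTT, flux windows."""

import numpy as np
import pytest

from glucostore.model import ModelParameters, basal_steady_state
from glucostore.protocols import (
    IVGTT_GRID,
    FluxDecomposition,
    InfusionProtocol,
    Trajectory,
    decompose_fluxes,
    initial_state,
    run_clamp,
    simulate_fixed,
    simulate_infusion,
    simulate_ivgtt,
)


def ref(**over):
    base = dict(k1=3.0, k2=0.01, k3=1.25e-4, k4=0.015, k5=3e-4, k6=1e-3,
                k7=600.0, k8=3e-3, G0=120.0, I0=0.5)
    base.update(over)
    return ModelParameters(**base)


class TestSimulateFixed:
    def test_basal_steady_state_stays_fixed_without_infusion(self):
        p = ref()
        ss = basal_steady_state(p)
        protocol = InfusionProtocol(
            mode="fixed_schedule", body_weight=25.0,
            schedule_times=[0.0], schedule_rates=[0.0],
        )
        traj = simulate_fixed(p, protocol, init=ss)
        assert np.max(np.abs(traj.G / ss.G - 1)) < 1e-6
        assert np.max(np.abs(traj.I / ss.I - 1)) < 1e-6
        assert np.max(np.abs(traj.stG / ss.stG - 1)) < 1e-6

    def test_negligible_store_capacity_silences_flux5(self):
        p = ref(k7=1e-9)
        protocol = InfusionProtocol(
            mode="fixed_schedule", body_weight=25.0,
            schedule_times=[0.0, 30.0], schedule_rates=[0.2, 0.0],
        )
        traj = simulate_fixed(p, protocol)
        assert np.max(traj.fluxes[:, 4]) < 1e-6
        assert np.max(traj.stG) <= p.k7 * (1 + 1e-8)

    def test_mass_balance_against_independent_quadrature(self):
        # infused mass must equal circulating rise plus cumulative uptake
        p = ref()
        protocol = InfusionProtocol(
            mode="fixed_schedule", body_weight=25.0,
            schedule_times=[0.0, 20.0, 60.0, 120.0],
            schedule_rates=[0.3, 0.05, 0.15, 0.0],
        )
        traj = simulate_fixed(p, protocol)
        assert traj.mass_balance_residual() < 1e-6
        # independent oracle: trapezoidal quadrature of flux2 - flux1 + flux5
        dagdt = traj.fluxes[:, 1] - traj.fluxes[:, 0] + traj.fluxes[:, 4]
        ag_quad = np.concatenate(
            [[0.0], np.cumsum(np.diff(traj.times) * 0.5 * (dagdt[1:] + dagdt[:-1]))]
        )
        assert np.max(np.abs(ag_quad - traj.AG)) < 1e-3 * max(1.0, traj.AG[-1])

    @pytest.mark.parametrize("draw", range(5))
    def test_positivity_and_store_cap_along_trajectory(self, draw):
        # random-but-reproducible parameter sets around the reference decades
        rng = np.random.default_rng(1000 + draw)
        base = ref()
        scale = {n: float(10 ** rng.uniform(-0.7, 0.7)) for n in
                 ("k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8")}
        p = ModelParameters.from_dict(
            {**{n: getattr(base, n) * s for n, s in scale.items()},
             "G0": float(rng.uniform(80, 250)), "I0": float(rng.uniform(0.2, 5))}
        )
        protocol = InfusionProtocol(
            mode="fixed_schedule", body_weight=25.0,
            schedule_times=[0.0, 10.0, 40.0],
            schedule_rates=[float(rng.uniform(0, 2)), 0.0,
                            float(rng.uniform(0, 0.5))],
        )
        traj = simulate_fixed(p, protocol)
        assert traj.G.min() >= -1e-8 and traj.I.min() >= -1e-8
        assert traj.stG.min() >= -1e-8
        assert traj.stG.max() <= p.k7 * (1 + 1e-8)

    def test_refinement_stability_under_tighter_tolerances(self):
        p = ref()
        protocol = InfusionProtocol(
            mode="fixed_schedule", body_weight=25.0,
            schedule_times=[0.0, 30.0], schedule_rates=[0.25, 0.1],
        )
        t1 = simulate_fixed(p, protocol, rtol=1e-8, atol=1e-10)
        t2 = simulate_fixed(p, protocol, rtol=5e-9, atol=5e-11)
        for attr in ("G", "I", "stG"):
            a, b = getattr(t1, attr), getattr(t2, attr)
            assert np.max(np.abs(a - b) / np.maximum(np.abs(a), 1.0)) < 1e-4


class TestRunClamp:
    def test_tracks_target_within_five_percent_after_attainment(self, cd_clamp_traj):
        traj = cd_clamp_traj
        target = traj.metadata["target"]
        att = traj.metadata["attained_time"]
        assert att is not None
        adj = traj.dose_times[traj.dose_times > att]
        err = np.abs(traj.sample(adj, "G") - target) / target
        assert err.max() < 0.05

    def test_mass_balance_holds_in_closed_loop(self, cd_clamp_traj):
        assert cd_clamp_traj.mass_balance_residual() < 1e-6

    def test_faster_priming_reaches_target_sooner(self, reference_params,
                                                  cd_clamp_traj):
        fast = InfusionProtocol(mode="clamp", body_weight=27.0, initial_rate=4.0)
        tf = run_clamp(reference_params, fast)
        assert tf.metadata["attained_time"] < cd_clamp_traj.metadata["attained_time"]

    def test_dose_series_is_biphasic_for_chow_fed_reference(self, cd_clamp_traj):
        d, t = cd_clamp_traj.doses_mg, cd_clamp_traj.dose_times
        mid = (t > 20) & (t < 70)
        dip = d[mid].min()
        assert 20 < t[mid][np.argmin(d[mid])] < 70
        assert np.all(d[t > 120] > dip)

    def test_insulin_relaxes_toward_clamped_equilibrium(self, reference_params,
                                                        cd_clamp_traj):
        # under a held glucose level, I(t) follows a single-exponential
        # relaxation to k3*G/k4; the clamp's G wobble perturbs it only mildly
        p = reference_params
        traj = cd_clamp_traj
        att = traj.metadata["attained_time"]
        target = traj.metadata["target"]
        tt = traj.times[traj.times >= att]
        i_obs = traj.I[traj.times >= att]
        i_att = i_obs[0]
        i_inf = p.k3 * target / p.k4
        i_closed = i_inf + (i_att - i_inf) * np.exp(-p.k4 * (tt - att))
        assert np.all(np.diff(i_obs) > -1e-9)
        assert np.max(np.abs(i_obs - i_closed)) / i_inf < 0.06

    def test_unattainable_target_warns_instead_of_raising(self):
        p = ref()
        protocol = InfusionProtocol(
            mode="clamp", body_weight=27.0, initial_rate=1e-6
        )
        with pytest.warns(UserWarning, match="never attained"):
            traj = run_clamp(p, protocol)
        assert "warning" in traj.metadata

    def test_doses_match_exact_rate_integrals(self, cd_clamp_traj):
        traj = cd_clamp_traj
        edges = np.concatenate([[0.0], traj.dose_times])
        expect = np.diff(traj.cumulative_infused_mg(edges))
        np.testing.assert_allclose(traj.doses_mg, expect, rtol=1e-12, atol=1e-12)


class TestIVGTT:
    def protocol(self, dose=0.75):
        return InfusionProtocol(
            mode="ivgtt_bolus", body_weight=25.0, bolus_dose=dose,
            bolus_duration=3.0, glucose_solution_concentration=0.15,
            total_duration=90.0,
        )

    def test_zero_bolus_equals_basal_run(self, reference_params):
        p = reference_params
        ss = basal_steady_state(p)
        pz = ModelParameters.from_dict(
            {**p.to_dict(), "G0": ss.G, "I0": ss.I}
        )
        traj = simulate_ivgtt(pz, self.protocol(dose=1e-15),
                              stg0_mode="conditional_ss")
        assert np.max(np.abs(traj.G / ss.G - 1)) < 1e-6

    def test_peak_timing_and_monotone_return(self, reference_params):
        traj = simulate_ivgtt(reference_params, self.protocol())
        ipk = int(np.argmax(traj.G))
        assert 2.0 <= traj.times[ipk] <= 6.0
        after = traj.G[traj.times >= traj.times[ipk]]
        assert np.all(np.diff(after) <= 1e-9)

    def test_doubling_bolus_doubles_infused_mass(self, reference_params):
        t1 = simulate_ivgtt(reference_params, self.protocol(0.75))
        t2 = simulate_ivgtt(reference_params, self.protocol(1.5))
        m1 = t1.cumulative_infused_mg(t1.times[-1:])[0]
        m2 = t2.cumulative_infused_mg(t2.times[-1:])[0]
        assert m2 == pytest.approx(2 * m1, rel=1e-12)
        assert t1.mass_balance_residual() < 1e-6


class TestDecomposeFluxes:
    def test_constant_flux_windows_integrate_to_width_times_level(self):
        # synthetic trajectory with all fluxes pinned at a constant c
        c = 2.5
        t = np.linspace(0.0, 180.0, 721)
        traj = Trajectory(
            times=t, G=np.full_like(t, 300.0), I=np.ones_like(t),
            stG=np.zeros_like(t), AG=np.zeros_like(t),
            fluxes=np.full((t.size, 7), c),
            infusion_breaks=np.array([0.0]), infusion_rates=np.array([0.0]),
            body_weight=25.0, params=ref(),
        )
        dec = decompose_fluxes(traj)
        np.testing.assert_allclose(dec.flux5_integrals, 10.0 * c, rtol=1e-12)
        np.testing.assert_allclose(dec.flux2_integrals, 10.0 * c, rtol=1e-12)

    def test_reference_clamp_matches_reported_shape(self, cd_clamp_traj):
        dec = decompose_fluxes(cd_clamp_traj)
        f5, f2 = dec.flux5_integrals, dec.flux2_integrals
        assert f5[0] > f5[-1]  # early insulin-independent burst dominates
        assert np.all(np.diff(f2) >= 0)  # insulin-dependent uptake keeps rising

    def test_out_of_span_window_raises(self, cd_clamp_traj):
        with pytest.raises(ValueError, match="outside"):
            decompose_fluxes(cd_clamp_traj, window_ends=[5.0])
        with pytest.raises(ValueError, match="outside"):
            decompose_fluxes(cd_clamp_traj, window_ends=[240.0])


class TestProtocolValidation:
    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            InfusionProtocol(mode="sprint", body_weight=25.0)

    def test_decreasing_adjustment_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            InfusionProtocol(mode="clamp", body_weight=25.0,
                             adjustment_times=[0.0, 10.0, 5.0])

    def test_negative_schedule_rate_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            InfusionProtocol(mode="fixed_schedule", body_weight=25.0,
                             schedule_times=[0.0], schedule_rates=[-1.0])

    def test_initial_state_modes(self):
        p = ref()
        assert initial_state(p, "fasted").stG == 0.0
        cond = initial_state(p, "conditional_ss").stG
        assert 0.0 < cond < p.k7
        with pytest.raises(ValueError):
            initial_state(p, "warm")
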