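"""DANTE and binomial-MT pulse-train propagation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mtvaper as mv
from mtvaper.physiology import COMPARTMENTS, VoxelState
from mtvaper.prep_trains import (
    dante_fixed_point,
    dante_propagate,
    dante_steady_state_pulses,
    dante_velocity_response,
    mt_frequency_response,
    mt_propagate,
    ramped_flip_schedule,
)


def closed_form_flowing(n, flip_deg, interval, T1):
    """Independent oracle: M_ss + (M0 - M_ss)(E1 cos a)^n."""
    e1 = math.exp(-interval / T1)
    a = e1 * math.cos(math.radians(flip_deg))
    m_ss = (1.0 - e1) / (1.0 - a)
    return m_ss + (1.0 - m_ss) * a ** n


class TestDantePropagate:
    def test_matches_closed_form_oracle(self, model, dante_train):
        res = dante_propagate(VoxelState(), model, dante_train, 300)
        T1 = model.compartment("arteriole").T1
        for n in (1, 10, 100, 300):
            expected = closed_form_flowing(n, 9.0, 1e-3, T1)
            assert res.trajectory[n].mz["arteriole"] == pytest.approx(
                expected, abs=1e-9
            )

    def test_no_relaxation_limit_is_pure_cosine_power(self, model, dante_train):
        # T1 -> infinity: per-pulse product cos(9 deg)^n, brute-force oracle
        comps = [c.model_copy(update={"T1": math.inf, "T2": math.inf,
                                      "T2star": math.inf})
                 for c in model.compartments]
        m = model.model_copy(update={"compartments": comps})
        res = dante_propagate(VoxelState(), m, dante_train, 200)
        brute = 1.0
        for _ in range(200):
            brute *= math.cos(math.radians(9.0))
        assert res.final.mz["arteriole"] == pytest.approx(brute, rel=1e-12)
        assert res.final.mz["arteriole"] == pytest.approx(0.0839, abs=5e-5)

    def test_zero_flip_keeps_equilibrium(self, model):
        train = mv.default_dante_train(flip_deg=1e-12)
        res = dante_propagate(VoxelState(), model, train, 50)
        for name in COMPARTMENTS:
            assert res.final.mz[name] == pytest.approx(1.0, abs=1e-9)

    def test_tissue_ideal_preservation_with_no_relaxation(self, model, dante_train):
        comps = [c.model_copy(update={"T1": math.inf, "T2": math.inf,
                                      "T2star": math.inf})
                 for c in model.compartments]
        tp = model.two_pool.model_copy(update={"permeability_rate": 0.0})
        m = model.model_copy(update={"compartments": comps, "two_pool": tp})
        res = dante_propagate(VoxelState(), m, dante_train, 1780)
        assert res.final.mz["tissue"] == pytest.approx(1.0, abs=1e-9)

    def test_trajectory_length_and_errors(self, model, dante_train):
        res = dante_propagate(VoxelState(), model, dante_train, 7)
        assert len(res.trajectory) == 8
        with pytest.raises(ValueError):
            dante_propagate(VoxelState(), model, dante_train, -1)
        with pytest.raises(ValueError):
            dante_propagate(VoxelState(), model, mv.default_mt_train(), 1)

    def test_capillary_diluted_by_arteriolar_inflow(self, model, dante_train):
        res = dante_propagate(VoxelState(), model, dante_train, 1780)
        mz = res.final.mz
        # capillary intermediate between crushed arteriole and preserved tissue
        assert mz["arteriole"] < mz["capillary"] < mz["tissue"]


class TestDanteSteadyState:
    def test_default_count_in_paper_range(self, model, dante_train):
        n = dante_steady_state_pulses(model, dante_train)
        assert 200 <= n <= 300

    def test_count_matches_closed_form_oracle(self, model, dante_train):
        n = dante_steady_state_pulses(model, dante_train, tol_fraction=0.05)
        T1 = model.compartment("arteriole").T1
        m_ss = dante_fixed_point(T1, 1e-3, math.cos(math.radians(9.0)))
        assert abs(closed_form_flowing(n, 9.0, 1e-3, T1) - m_ss) < 0.05
        assert abs(closed_form_flowing(n - 1, 9.0, 1e-3, T1) - m_ss) >= 0.05

    def test_monotone_in_tolerance(self, model, dante_train):
        loose = dante_steady_state_pulses(model, dante_train, tol_fraction=0.5)
        tight = dante_steady_state_pulses(model, dante_train, tol_fraction=0.05)
        assert loose < tight

    def test_large_flip_is_order_of_magnitude_faster(self, model):
        fast = dante_steady_state_pulses(model, mv.default_dante_train(flip_deg=89.0))
        slow = dante_steady_state_pulses(model, mv.default_dante_train())
        assert fast <= slow / 10

    def test_non_flowing_compartment_rejected(self, model, dante_train):
        with pytest.raises(ValueError, match="not flowing"):
            dante_steady_state_pulses(model, dante_train, compartment="tissue")


class TestVelocityResponse:
    def test_static_spin_untouched(self, model, dante_train):
        assert dante_velocity_response(0.0, model, dante_train) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_cutoff_velocity_mostly_suppressed(self, model, dante_train):
        assert dante_velocity_response(2.0, model, dante_train) > 0.9

    def test_monotone_in_velocity_and_gradient(self, model, dante_train):
        v = np.linspace(0.0, 5.0, 21)
        att = [dante_velocity_response(x, model, dante_train) for x in v]
        assert np.all(np.diff(att) >= 0)
        weak = mv.default_dante_train(gradient_amplitude=10.0)
        for x in (0.5, 1.0, 1.5):
            assert (dante_velocity_response(x, model, weak)
                    <= dante_velocity_response(x, model, dante_train))

    def test_invalid_arguments(self, model, dante_train):
        with pytest.raises(ValueError):
            dante_velocity_response(-1.0, model, dante_train)
        with pytest.raises(ValueError):
            dante_velocity_response(1.0, model,
                                    mv.default_dante_train(gradient_amplitude=0.0))


class TestMtPropagate:
    def test_no_exchange_means_no_transfer_path(self, model, mt_train):
        tp = model.two_pool.model_copy(update={"exchange_rate_k": 0.0})
        m = model.model_copy(update={"two_pool": tp})
        res = mt_propagate(VoxelState(), m, mt_train, 500)
        # tissue starts at equilibrium; with no transfer path only T1 acts,
        # and at equilibrium T1 changes nothing
        assert res.final.mz["tissue"] == pytest.approx(1.0, abs=1e-9)

    def test_tissue_suppression_is_monotone(self, model, mt_train):
        res = mt_propagate(VoxelState(), model, mt_train, 3060)
        tissue = np.array([s.mz["tissue"] for s in res.trajectory])
        assert np.all(np.diff(tissue) <= 1e-12)
        assert res.final.mz["tissue"] < 0.95

    def test_matches_fine_step_ode_oracle(self, model, mt_train):
        """Exact matrix-exponential intervals vs brute-force ODE integration."""
        from scipy.integrate import solve_ivp

        from mtvaper._bloch import free_generator, mt_pulse_event

        n = 120
        A, b = free_generator(model)
        pulse = np.diag(mt_pulse_event(model, mt_train))[:5]
        y = np.ones(5)
        for _ in range(n):
            y = y * pulse
            sol = solve_ivp(lambda t, yy: A @ yy + b, (0, mt_train.pulse_interval),
                            y, rtol=1e-10, atol=1e-12)
            y = sol.y[:, -1]
        res = mt_propagate(VoxelState(), model, mt_train, n)
        np.testing.assert_allclose(res.final.as_vector(), y, atol=1e-8)

    def test_full_inflow_refresh_retains_arteriole(self, model, mt_train):
        fl = model.flow.model_copy(update={"arteriole_refresh_rate": 500.0})
        m = model.model_copy(update={"flow": fl})
        res = mt_propagate(VoxelState(), m, mt_train, 3060, arteriole_refresh=True)
        assert res.final.mz["arteriole"] > 0.99

    def test_unit_saturation_is_identity_at_equilibrium(self, model, mt_train):
        tp = model.two_pool.model_copy(
            update={"mp_sat_per_pulse": 1.0, "venule_sat_scale": 0.0}
        )
        m = model.model_copy(update={"two_pool": tp})
        res = mt_propagate(VoxelState(), m, mt_train, 500)
        vec = res.final.as_vector()
        np.testing.assert_allclose(vec, np.ones(5), atol=1e-9)

    def test_venule_declines_faster_than_other_vessels(self, model, mt_train):
        res = mt_propagate(VoxelState(), model, mt_train, 3060)
        assert res.final.mz["venule"] < res.final.mz["arteriole"]
        assert res.final.mz["venule"] < res.final.mz["capillary"]


class TestRampedSchedule:
    def test_no_ramp_is_constant_alternating(self):
        sched = ramped_flip_schedule(10, 11.0, 0)
        assert np.all(np.abs(sched) == 11.0)
        assert np.all(sched[::2] > 0) and np.all(sched[1::2] < 0)

    def test_ramp_magnitudes_increase_then_plateau(self):
        sched = ramped_flip_schedule(36, 11.0, 8)
        mags = np.abs(sched)
        assert np.all(np.diff(mags[:8]) > 0)
        assert np.all(mags[8:28] == 11.0)
        assert np.all(np.diff(mags[28:]) < 0)

    def test_signed_sum_cancels_for_even_length(self):
        assert ramped_flip_schedule(36, 11.0, 8).sum() == pytest.approx(0, abs=1e-12)
        assert ramped_flip_schedule(20, 9.0, 0).sum() == pytest.approx(0, abs=1e-12)

    def test_ramp_too_long_rejected(self):
        with pytest.raises(ValueError):
            ramped_flip_schedule(10, 11.0, 6)


class TestFrequencyResponse:
    def test_on_resonance_attenuation_negligible(self, mt_train):
        assert mt_frequency_response(0.0, mt_train) <= 1e-3

    def test_argmax_at_half_inverse_interval(self, mt_train):
        offsets = np.arange(0.0, 5000.0, 10.0)
        att = mt_frequency_response(offsets, mt_train)
        assert offsets[np.argmax(att)] == pytest.approx(2500.0)

    def test_periodicity_at_inverse_interval(self, mt_train):
        assert mt_frequency_response(5000.0, mt_train) == pytest.approx(
            mt_frequency_response(0.0, mt_train), abs=1e-6
        )


class TestStateBoundsProperty:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        flip=st.floats(1.0, 89.0),
        t1_blood=st.floats(0.3, 4.0),
        mp_sat=st.floats(0.9, 1.0),
        k=st.floats(0.0, 5.0),
        n=st.integers(0, 400),
    )
    def test_mz_stays_in_unit_interval(self, flip, t1_blood, mp_sat, k, n):
        comps = []
        for c in mv.default_model().compartments:
            if c.name != "tissue":
                t2 = min(c.T2, t1_blood)
                comps.append(c.model_copy(update={
                    "T1": t1_blood, "T2": t2, "T2star": min(c.T2star, t2)}))
            else:
                comps.append(c)
        model = mv.default_model().model_copy(update={
            "compartments": comps,
            "two_pool": mv.TwoPoolParams(mp_sat_per_pulse=mp_sat,
                                         exchange_rate_k=k),
        })
        res_d = dante_propagate(VoxelState(), model,
                                mv.default_dante_train(flip_deg=flip), n)
        res_m = mt_propagate(VoxelState(), model,
                             mv.default_mt_train(flip_deg=flip), n)
        for res in (res_d, res_m):
            for s in res.trajectory:
                assert all(-1.0 <= v <= 1.0 for v in s.mz.values())
                assert 0.0 <= s.mz_mp <= 1.0
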