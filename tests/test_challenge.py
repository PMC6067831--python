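"""Challenge-test protocols: DST, cosyntropin stimulation, two-stage test."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hpaxis as hx
from hpaxis import InputSignal, percentage_suppression
from hpaxis.challenge import (
    acth_protocol,
    adrenal_reactivity_params,
    dex_protocol,
    equilibrate_on_attractor,
    run_acth_test,
    run_dex_test,
    run_two_stage_test,
    stress_transition,
)


class TestPercentageSuppression:
    @pytest.mark.parametrize("pre,post,expected", [
        (1.0, 1.0, 0.0),
        (1.0, 0.0, 100.0),
        (1.0, 0.26, 74.0),
    ])
    def test_definition(self, pre, post, expected):
        assert percentage_suppression(pre, post) == pytest.approx(expected)

    def test_zero_pre_dose_undefined(self):
        with pytest.raises(ValueError):
            percentage_suppression(0.0, 0.1)

    @given(pre=st.floats(min_value=0.1, max_value=10),
           post=st.floats(min_value=0.0, max_value=10),
           lam=st.floats(min_value=0.01, max_value=100))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, pre, post, lam):
        a = percentage_suppression(pre, post)
        b = percentage_suppression(lam * pre, lam * post)
        assert a == pytest.approx(b, rel=1e-9, abs=1e-9)


class TestDexSuppression:
    def test_diseased_suppression_exceeds_normal(self, dst_results):
        """Same parameters, different basin: the low-cortisol state shows the
        larger percentage suppression in both measurement conventions."""
        assert (dst_results[("diseased", "period_averaged")].s
                > dst_results[("normal", "period_averaged")].s)
        assert (dst_results[("diseased", "instantaneous")].s
                > dst_results[("normal", "instantaneous")].s)

    def test_peak_phase_measurement_raises_suppression(self, dst_results):
        for basin in ("normal", "diseased"):
            assert (dst_results[(basin, "instantaneous")].s
                    > dst_results[(basin, "period_averaged")].s)

    def test_oscillations_cease_under_suppression(self, dst_results):
        for basin in ("normal", "diseased"):
            r = dst_results[(basin, "period_averaged")]
            assert r.post_oscillation_amplitude < 0.01 * r.pre_oscillation_amplitude

    def test_feedback_drop_larger_in_diseased_state(self, dst_results):
        rn = dst_results[("normal", "period_averaged")]
        rd = dst_results[("diseased", "period_averaged")]
        assert rd.delta_fa > rn.delta_fa > 0

    def test_suppression_is_genuinely_suppressive(self, ref, ref_fixed_points):
        """Post-dose endogenous ACTH and cortisol never exceed their undosed
        counterparts at the same times."""
        eq = equilibrate_on_attractor(ref, "normal", ref_fixed_points)
        dosed = run_dex_test(ref, "normal", fixed_points=ref_fixed_points,
                             equilibrium=eq)
        undosed = run_dex_test(ref, "normal",
                               protocol=dex_protocol(height=1e-12),
                               fixed_points=ref_fixed_points, equilibrium=eq)
        td, tu = dosed.trajectory, undosed.trajectory
        assert np.all(td.o <= tu.o + 1e-9)
        # the undosed baseline oscillates, so ACTH is compared on rolling
        # one-period averages rather than pointwise against the trough
        T = dosed.period
        for t_mid in np.linspace(T, td.t[-1], 25):
            grid = np.linspace(t_mid - T, t_mid, 64)
            assert (td.values_at(grid, "a").mean()
                    <= tu.values_at(grid, "a").mean() + 1e-6)

    def test_monostable_set_has_no_diseased_basin(self, ref):
        with pytest.raises(ValueError, match="bistab"):
            run_dex_test(ref.replace(n=4.0), "diseased")


class TestActhStimulation:
    def test_hyporeactive_baseline_is_higher(self, acth_sweeps):
        """10% adrenal hyporeactivity mildly raises basal cortisol, the
        counterintuitive signature of the feedback loop."""
        assert (acth_sweeps[0.9][0].baseline_mean_o
                > acth_sweeps[1.0][0].baseline_mean_o)

    def test_phase_curve_is_periodic(self, acth_sweeps):
        for lam, results in acth_sweeps.items():
            assert results[0].peak_o == pytest.approx(results[-1].peak_o, abs=1e-9)

    def test_peak_exceeds_undosed_maximum(self, acth_sweeps):
        for results in acth_sweeps.values():
            for r in results:
                assert r.peak_o >= r.baseline_max_o - 1e-9

    def test_null_dose_recovers_baseline_maximum(self, ref):
        res = run_acth_test(ref, 1.0, 0.0, protocol=acth_protocol(height=1e-12))
        assert res.peak_o == pytest.approx(res.baseline_max_o, rel=5e-3)

    def test_response_maximal_near_rising_nadir(self, acth_sweeps):
        """Dosing in the rising phase near the cortisol nadir (theta ~ pi)
        yields a larger peak than dosing at the cortisol peak (theta = 0)."""
        for results in acth_sweeps.values():
            phases = np.array([r.phase_at_dose for r in results[:-1]])
            peaks = np.array([r.peak_o for r in results[:-1]])
            best = phases[int(np.argmax(peaks))]
            assert abs(best - math.pi) < math.pi / 2
            assert peaks[int(np.argmin(np.abs(phases - math.pi)))] > peaks[0]

    def test_repeat_run_is_bit_identical(self, ref):
        a = run_acth_test(ref, 0.9, 1.0)
        b = run_acth_test(ref, 0.9, 1.0)
        assert a.peak_o == b.peak_o
        assert np.array_equal(a.trajectory.states, b.trajectory.states)

    def test_invalid_reactivity(self, ref):
        with pytest.raises(ValueError):
            adrenal_reactivity_params(ref, 0.0)
        with pytest.raises(ValueError):
            adrenal_reactivity_params(ref, 1.5)

    def test_phase_sweep_requires_resolution(self, ref):
        with pytest.raises(ValueError):
            hx.phase_sweep_acth(ref, 1.0, n_phases=4)


class TestTwoStage:
    def test_diseased_response_exceeds_normal(self, two_stage_results):
        """During the stressor the low-cortisol state both rises more and
        peaks higher than the normal state, despite its stronger DEX
        suppression -- the discriminating signature of bistability."""
        rn, rd = two_stage_results["normal"], two_stage_results["diseased"]
        assert rd.peak_o_during_stress > rn.peak_o_during_stress
        assert rd.rise > rn.rise
        assert rd.dex.s > rn.dex.s

    def test_null_stressor_reduces_to_plain_dst(self, ref, ref_fixed_points):
        eq = equilibrate_on_attractor(ref, "normal", ref_fixed_points)
        plain = run_dex_test(ref, "normal", fixed_points=ref_fixed_points,
                             equilibrium=eq)
        null = run_two_stage_test(ref, "normal", stressor_amplitude=0.0,
                                  fixed_points=ref_fixed_points, equilibrium=eq)
        t_common = plain.trajectory.t
        o_null = null.trajectory.values_at(t_common, "o")
        np.testing.assert_allclose(o_null, plain.trajectory.o, rtol=0, atol=1e-12)
        assert null.dex.s == pytest.approx(plain.s, abs=1e-9)


class TestStressTransition:
    def test_null_input_preserves_basin(self, ref, ref_fixed_points):
        sig = InputSignal(baseline=ref.I0)
        final = stress_transition(ref, "diseased", sig, horizon=30.0,
                                  relax=4.0 * ref.t_c, fixed_points=ref_fixed_points)
        assert final == "diseased"

    def test_strong_prolonged_stressor_escapes_diseased_basin(self, ref, ref_fixed_points):
        sig = InputSignal(baseline=ref.I0, steps=((0.0, 60.0, 1.0),))
        final = stress_transition(ref, "diseased", sig, horizon=70.0,
                                  relax=6.0 * ref.t_c, fixed_points=ref_fixed_points)
        assert final == "normal"

    def test_escape_is_monotone_in_amplitude(self, ref, ref_fixed_points):
        """If amplitude A escapes the diseased basin, every larger amplitude
        (same duration) does too."""
        outcomes = []
        for amp in (0.05, 0.5, 1.0):
            sig = InputSignal(baseline=ref.I0, steps=((0.0, 60.0, amp),))
            final = stress_transition(ref, "diseased", sig, horizon=70.0,
                                      relax=6.0 * ref.t_c,
                                      fixed_points=ref_fixed_points)
            outcomes.append(final == "normal")
        first_escape = outcomes.index(True) if True in outcomes else len(outcomes)
        assert all(outcomes[first_escape:])
        assert outcomes[-1]  # the largest amplitude must escape
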