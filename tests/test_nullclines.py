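"""Nullcline construction, fixed points, and the qualitative parameter ledger."""
import math

import numpy as np
import pytest
from scipy.optimize import brentq

import hpaxis as hx
from hpaxis import c_nullcline, cs_nullcline, find_fixed_points, sweep
from hpaxis.model import autocrine_upregulation, release_fraction
from hpaxis.nullclines import c_nullcline_cs_of_c, curve_summary
from hpaxis.pa import oscillatory_c_range


def eq6_residual(cs, c, p):
    """Residual of the circulating-CRH balance at a candidate point."""
    return p.q0 * p.I0 * release_fraction(cs, p.k) + autocrine_upregulation(c, p) - p.q2 * c


class TestCNullcline:
    def test_origin_on_curve(self, ref):
        crv = c_nullcline(ref)
        assert crv.c[0] == 0.0
        assert crv.cs[0] == 0.0

    def test_samples_satisfy_defining_relation(self, ref):
        crv = c_nullcline(ref)
        res = np.array([eq6_residual(cs, c, ref) for cs, c in zip(crv.cs, crv.c)])
        assert np.max(np.abs(res)) < 1e-8

    def test_closed_form_equals_bisection_oracle(self, ref):
        """The closed form must agree with a bisection root-finder on the
        stored-CRH release balance across a randomized parameter suite."""
        rng = np.random.default_rng(20180201)
        for _ in range(25):
            p = ref.replace(
                q0=rng.uniform(20, 36), q1=rng.uniform(0.03, 0.05),
                q2=rng.uniform(1.4, 2.2), gc_max=rng.uniform(30, 50),
                n=float(rng.integers(2, 8)), k=rng.uniform(2.0, 3.5),
            )
            c = float(rng.uniform(0.5, 12.0))
            cs_closed = c_nullcline_cs_of_c(c, p)
            if not np.isfinite(cs_closed):
                continue
            f = lambda cs: eq6_residual(cs, c, p)
            cs_root = brentq(f, 0.0, 200.0, xtol=1e-14, rtol=8.9e-16)
            assert abs(cs_closed - cs_root) < 1e-10
            assert abs(eq6_residual(cs_closed, c, p)) < 1e-10

    def test_fold_onset_in_hill_coefficient(self, ref):
        """The curve is monotone at n = 4 and S-shaped (two knees) at n = 5."""
        assert not c_nullcline(ref.replace(n=4.0)).folded
        crv5 = c_nullcline(ref.replace(n=5.0))
        assert crv5.folded and len(crv5.knees) == 2

    def test_branch_labels_partition_fold(self, ref):
        crv = c_nullcline(ref)
        labels = set(crv.branch_labels)
        assert labels == {"lower", "middle", "upper"}

    def test_empty_curve_is_explicit(self, ref):
        crv = c_nullcline(ref, c_grid=np.array([1000.0, 2000.0]))
        assert crv.is_empty

    def test_bistability_invariant_under_q0_I_rescaling(self, ref):
        """Only the product q0*I enters the release balance."""
        lam = 1.7
        p_scaled = ref.replace(q0=lam * ref.q0, I0=ref.I0 / lam)
        a = c_nullcline(ref)
        b = c_nullcline(p_scaled, c_grid=a.c)
        np.testing.assert_array_equal(a.cs, b.cs)
        assert a.knees == b.knees


class TestCsNullcline:
    GRID = np.linspace(2.0, 33.0, 16)

    def test_weak_feedback_limit(self, ref):
        """b -> 0: the synthesis target saturates at c_inf_bar + 1 per c."""
        p = ref.replace(b=1e-12)
        crv = cs_nullcline(p, c_grid=np.array([2.0, 10.0, 20.0, 30.0]))
        np.testing.assert_allclose(crv.cs, p.c_inf_bar + 1.0, atol=1e-10)

    def test_stronger_feedback_shifts_left(self, ref):
        a = cs_nullcline(ref, c_grid=self.GRID)
        b = cs_nullcline(ref.replace(b=1.2 * ref.b), c_grid=self.GRID)
        assert np.all(b.cs < a.cs)

    def test_oscillatory_samples_flagged(self, ref):
        crv = cs_nullcline(ref, c_grid=self.GRID)
        assert crv.oscillatory is not None
        assert crv.oscillatory.any() and (~crv.oscillatory).any()
        # oscillation onset is interior: quiescent at low c, cycling at high c
        assert not crv.oscillatory[0] and crv.oscillatory[-1]


class TestFixedPoints:
    def test_reference_set_is_bistable(self, ref, ref_fixed_points):
        fps = ref_fixed_points
        assert len(fps) == 3
        stab = [f.stability for f in fps]
        assert stab == ["stable", "unstable", "stable"]
        regimes = {f.regime for f in fps if f.stability == "stable"}
        assert regimes == {"normal", "diseased"}

    def test_regime_labels_follow_cortisol_average(self, ref_fixed_points):
        by_regime = {f.regime: f for f in ref_fixed_points if f.stability == "stable"}
        assert by_regime["normal"].mean_o > by_regime["diseased"].mean_o

    def test_both_attractors_oscillate(self, ref_fixed_points):
        assert all(f.oscillatory for f in ref_fixed_points)

    def test_intersections_lie_on_both_curves(self, ref, ref_fixed_points):
        for f in ref_fixed_points:
            assert abs(eq6_residual(f.cs, f.c, ref)) < 1e-6
            # stored-CRH balance: cs equals the averaged synthesis target
            target = hx.averaged_crh_target(f.c, ref)
            assert f.cs == pytest.approx(target, abs=2e-3)

    def test_monotone_curve_single_stable_point(self, ref):
        p = ref.replace(n=4.0)
        fps = find_fixed_points(p)
        assert len(fps) == 1
        assert fps[0].stability == "stable"
        assert fps[0].regime == "normal"

    def test_raised_drive_raises_all_intersections(self, ref, ref_fixed_points):
        """A 20% stronger basal CRH release pushes every intersection to
        larger circulating CRH and larger attractor cortisol."""
        fps_hi = find_fixed_points(ref.replace(q0=1.2 * ref.q0))
        assert len(fps_hi) >= 1
        c_ref = sorted(f.c for f in ref_fixed_points)
        c_hi = sorted(f.c for f in fps_hi)
        assert c_hi[0] > c_ref[0]
        assert c_hi[-1] > c_ref[-1]
        o_ref = sorted(f.mean_o for f in ref_fixed_points)
        o_hi = sorted(f.mean_o for f in fps_hi)
        assert o_hi[0] > o_ref[0]
        assert o_hi[-1] > o_ref[-1]


class TestSweep:
    def test_unknown_parameter_listed(self, ref):
        with pytest.raises(ValueError, match="q0"):
            sweep(ref, "nonsense", [1.0])

    def test_release_coupling_shifts_window_not_fold_heights(self, ref):
        """Raising k compresses the curve toward smaller stored CRH while
        the fold's circulating-CRH locations are exactly unchanged (k does
        not enter the fold condition)."""
        curves, summaries = sweep(ref, "k", [2.26, 3.40], curve="c")
        lo, hi = curves
        k_lo_knee_c = sorted(kc[1] for kc in lo.knees)
        k_hi_knee_c = sorted(kc[1] for kc in hi.knees)
        np.testing.assert_allclose(k_lo_knee_c, k_hi_knee_c, rtol=1e-6)
        assert all(kh[0] < kl[0] for kh, kl in
                   zip(sorted(hi.knees), sorted(lo.knees)))


# ---------------------------------------------------------------------------
# the 13-row qualitative ledger: each +20% perturbation must reproduce the
# documented direction of nullcline deformation
# ---------------------------------------------------------------------------

def _c_curve_knees(p):
    crv = c_nullcline(p)
    ks = sorted(crv.knees, key=lambda kc: kc[1])  # by c: (low-c knee, high-c knee)
    return crv, ks


@pytest.fixture(scope="module")
def ref_c_curve(ref):
    return _c_curve_knees(ref)


@pytest.fixture(scope="module")
def ref_osc_range(ref):
    return oscillatory_c_range(ref)


@pytest.fixture(scope="module")
def ref_cs_mean(ref):
    crv = cs_nullcline(ref, c_grid=np.linspace(16.0, 33.0, 10))
    return float(crv.cs.mean())


def _cs_mean(p):
    crv = cs_nullcline(p, c_grid=np.linspace(16.0, 33.0, 10))
    return float(crv.cs.mean())


class TestParameterLedgerCNullcline:
    """Directional effects of +20% perturbations on the c-nullcline."""

    def test_q0_upper_branch_up_knees_left(self, ref, ref_c_curve):
        crv0, ks0 = ref_c_curve
        crv, ks = _c_curve_knees(ref.replace(q0=1.2 * ref.q0))
        assert crv.c.max() > crv0.c.max()           # upper branch reaches higher c
        assert ks[0][0] < ks0[0][0] and ks[1][0] < ks0[1][0]  # both knees leftward

    def test_q1_upper_branch_up_knees_left(self, ref, ref_c_curve):
        crv0, ks0 = ref_c_curve
        crv, ks = _c_curve_knees(ref.replace(q1=1.2 * ref.q1))
        assert crv.c.max() > crv0.c.max()
        assert ks[0][0] < ks0[0][0] and ks[1][0] < ks0[1][0]

    def test_q2_upper_branch_down_knees_right(self, ref, ref_c_curve):
        crv0, ks0 = ref_c_curve
        # +20% pushes the fold out through the admissible window's right edge,
        # so the knee displacement is read at a +5% perturbation
        crv, ks = _c_curve_knees(ref.replace(q2=1.05 * ref.q2))
        assert len(ks) == 2
        assert ks[0][0] > ks0[0][0] and ks[1][0] > ks0[1][0]  # knees rightward
        crv20 = c_nullcline(ref.replace(q2=1.2 * ref.q2))
        assert crv20.c.max() < crv0.c.max()          # upper branch pulled down
        assert c_nullcline_cs_of_c(10.0, ref.replace(q2=1.2 * ref.q2)) \
            > c_nullcline_cs_of_c(10.0, ref)

    def test_gc_max_upper_branch_up_fold_toward_lower_cs(self, ref, ref_c_curve):
        crv0, ks0 = ref_c_curve
        crv, ks = _c_curve_knees(ref.replace(gc_max=1.2 * ref.gc_max))
        assert crv.c.max() > crv0.c.max()
        assert ks[0][0] < ks0[0][0] and ks[1][0] < ks0[1][0]

    def test_n_elongates_bistable_window(self, ref, ref_c_curve):
        _, ks0 = ref_c_curve
        _, ks = _c_curve_knees(ref.replace(n=1.2 * ref.n))
        # low-c knee climbs to larger cs, high-c knee drops to smaller cs:
        # the bistable cs-window widens on both sides
        assert ks[0][0] > ks0[0][0]
        assert ks[1][0] < ks0[1][0]

    def test_k_shifts_curve_toward_lower_cs(self, ref):
        c_probe = np.array([5.0, 10.0, 15.0, 20.0])
        cs0 = c_nullcline_cs_of_c(c_probe, ref)
        cs1 = c_nullcline_cs_of_c(c_probe, ref.replace(k=1.2 * ref.k))
        assert np.all(cs1 < cs0)


class TestParameterLedgerCsNullcline:
    """Directional effects of +20% perturbations on the cs-nullcline."""

    def test_b_shifts_left_without_changing_oscillatory_window(self, ref, ref_osc_range, ref_cs_mean):
        p = ref.replace(b=1.2 * ref.b)
        assert _cs_mean(p) < ref_cs_mean                       # leftward in cs
        lo, hi = oscillatory_c_range(p)
        assert lo == pytest.approx(ref_osc_range[0], abs=0.2)  # b is outside the PA loop
        assert hi == pytest.approx(ref_osc_range[1], abs=0.2)

    def test_p2_elongates_and_shifts_right(self, ref, ref_osc_range, ref_cs_mean):
        p = ref.replace(p2=1.2 * ref.p2)
        lo, hi = oscillatory_c_range(p)
        assert hi - lo > ref_osc_range[1] - ref_osc_range[0]
        assert _cs_mean(p) > ref_cs_mean

    def test_p3_elongates_and_shifts_right(self, ref, ref_osc_range, ref_cs_mean):
        p = ref.replace(p3=1.2 * ref.p3)
        lo, hi = oscillatory_c_range(p)
        assert hi - lo > ref_osc_range[1] - ref_osc_range[0]
        assert _cs_mean(p) > ref_cs_mean

    def test_p4_elongates(self, ref, ref_osc_range):
        lo, hi = oscillatory_c_range(ref.replace(p4=1.2 * ref.p4))
        assert hi - lo > ref_osc_range[1] - ref_osc_range[0]

    def test_p5_shortens(self, ref, ref_osc_range):
        lo, hi = oscillatory_c_range(ref.replace(p5=1.2 * ref.p5))
        assert hi - lo < ref_osc_range[1] - ref_osc_range[0]

    def test_p6_raises_upper_limit_and_shifts_left(self, ref, ref_osc_range, ref_cs_mean):
        p = ref.replace(p6=1.2 * ref.p6)
        lo, hi = oscillatory_c_range(p)
        assert hi > ref_osc_range[1]          # upper end of the cycling branch climbs
        assert _cs_mean(p) < ref_cs_mean      # and the curve moves to smaller cs

    def test_t_d_elongates(self, ref, ref_osc_range):
        lo, hi = oscillatory_c_range(ref.replace(t_d=1.2 * ref.t_d))
        assert hi - lo > ref_osc_range[1] - ref_osc_range[0]
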