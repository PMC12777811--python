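"""NCA engine: BLQ policy, trapezoidal AUC, terminal-slope selection,
extrapolation, and IV disposition parameters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from lymphpk import (
    ConcentrationProfile,
    auc_trapezoid,
    clearance_l_per_h,
    estimate_lambda_z,
    handle_blq,
    nca_extravascular,
    nca_intravenous,
    simulate_oral_experiment,
)
from lymphpk.nca import ProfileError
from lymphpk.simulate import (
    DEFAULT_ORAL_SCHEDULE,
    LymphFlowModel,
    PKParameters,
)


def profile(times, concs, blq=None, **kw):
    return ConcentrationProfile(
        times=np.asarray(times, float), concentrations=np.asarray(concs, float),
        blq=blq, **kw,
    )


class TestHandleBlq:
    def test_leading_blq_becomes_zero(self):
        p = profile([0.0, 1, 2, 3], [0.0, 0.5, 10, 20])
        out = handle_blq(p, lloq=1.0)
        assert out.times.tolist() == [0, 1, 2, 3]
        assert out.concentrations.tolist() == [0, 0, 10, 20]
        assert not out.blq.any()
        assert any("leading BLQ" in e for e in out.edits)

    def test_fully_quantifiable_profile_unchanged(self):
        p = profile([1, 2, 3], [5, 10, 4])
        out = handle_blq(p, lloq=1.0)
        np.testing.assert_array_equal(out.concentrations, p.concentrations)
        assert out.edits == ()

    def test_trailing_blq_excluded_from_auc_and_tail(self):
        """A 24 h BLQ after a quantifiable 12 h point is dropped: the AUC
        equals the hand trapezoid over the remaining 4-point profile."""
        p = profile([2, 6, 12, 24], [10, 20, 8, 0.4])
        out = handle_blq(p, lloq=1.0)
        assert out.times.tolist() == [2, 6, 12, 24][:3]
        # hand trapezoid: (10+20)/2*4 + (20+8)/2*6 = 60 + 84
        assert auc_trapezoid(out) == pytest.approx(144.0)

    def test_embedded_blq_dropped(self):
        p = profile([1, 2, 3, 4], [10, 0.2, 8, 4])
        out = handle_blq(p, lloq=1.0)
        assert out.times.tolist() == [1, 3, 4]
        assert any("embedded" in e for e in out.edits)

    def test_all_blq_is_an_error(self):
        with pytest.raises(ProfileError, match="below the limit"):
            handle_blq(profile([1, 2, 3], [0.1, 0.2, 0.3]), lloq=1.0)


class TestAucTrapezoid:
    def test_rectangle(self):
        assert auc_trapezoid(profile([0, 2, 4], [10, 10, 10])) == pytest.approx(40.0)

    def test_hand_trapezoid(self):
        assert auc_trapezoid(profile([0, 1, 2], [0, 10, 5])) == pytest.approx(12.5)

    def test_interpolated_boundary(self):
        # C interpolates to 7.5 at t=1.5; area over [1.5, 2] is (7.5+5)/2*0.5
        assert auc_trapezoid(profile([0, 1, 2], [0, 10, 5]), 1.5, 2.0) == pytest.approx(
            3.125
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_additivity_over_subintervals(self, data):
        n = data.draw(st.integers(3, 10))
        times = np.cumsum(data.draw(
            st.lists(st.floats(0.1, 5), min_size=n, max_size=n)
        ))
        concs = data.draw(st.lists(st.floats(0, 100), min_size=n, max_size=n))
        p = profile(times, concs)
        mid = data.draw(st.floats(float(times[0]), float(times[-1])))
        if not times[0] < mid < times[-1]:
            return
        total = auc_trapezoid(p)
        parts = auc_trapezoid(p, times[0], mid) + auc_trapezoid(p, mid, times[-1])
        assert parts == pytest.approx(total, abs=1e-9 * max(1, total))

    def test_split_at_a_sample_is_exact(self):
        p = profile([0, 2, 8, 24], [0, 10, 6, 1])
        assert auc_trapezoid(p, 0, 8) + auc_trapezoid(p, 8, 24) == pytest.approx(
            auc_trapezoid(p), abs=1e-12
        )

    def test_span_outside_data_is_an_error(self):
        with pytest.raises(ProfileError, match="outside"):
            auc_trapezoid(profile([1, 2, 3], [1, 2, 3]), 0.0, 3.0)


class TestLambdaZ:
    def test_exact_mono_exponential(self):
        t = np.array([1, 2, 4, 8, 12, 24], float)
        p = profile(t, 100 * np.exp(-0.1 * t))
        fit = estimate_lambda_z(p)
        assert fit.lambda_z == pytest.approx(0.1, rel=1e-9)
        assert fit.t_half == pytest.approx(6.93, abs=0.005)
        assert fit.r2_adj == pytest.approx(1.0, abs=1e-9)
        assert fit.n_points == 5  # all post-Tmax points on an exact exponential

    def test_no_decaying_tail_gives_absent_fit(self):
        p = profile([1, 2, 3, 4, 5], [1, 5, 10, 10, 10])
        assert estimate_lambda_z(p) is None
        res = nca_extravascular(p)
        assert res.auc_inf is None
        assert any("terminal" in w for w in res.warnings)

    def test_biexponential_slow_phase_recovered(self, exact_flow):
        """lambda_z estimated at the 13-sample oral schedule is within 5%
        of the slow hybrid rate of the two-compartment disposition."""
        p = PKParameters(
            fa=0.5, phi_lymph=0.05, eh=0.3, ka=1.5, klt=1.0,
            cl=33.6, vc=40.0, k12=1.7, k21=0.25,
        )
        rec = simulate_oral_experiment(p, 200.0, DEFAULT_ORAL_SCHEDULE, exact_flow)
        fit = estimate_lambda_z(rec.serum)
        assert fit.lambda_z == pytest.approx(oracles.slow_hybrid_rate(p), rel=0.05)


class TestExtravascular:
    def test_tmax_tie_breaks_to_earliest(self):
        res = nca_extravascular(profile([1, 4, 5, 8], [3, 10, 10, 2]))
        assert res.tmax == 4.0
        assert res.cmax == 10.0

    def test_extrapolated_tail_is_clast_over_lambda(self):
        t = np.array([1, 2, 4, 8, 12, 24], float)
        res = nca_extravascular(profile(t, 100 * np.exp(-0.1 * t)))
        c_last = 100 * np.exp(-0.1 * 24)
        assert res.auc_inf - res.auc_last == pytest.approx(c_last / 0.1, rel=1e-9)

    def test_high_extrapolation_warns(self):
        t = np.array([1, 2, 3, 4, 5], float)
        res = nca_extravascular(profile(t, 100 * np.exp(-0.01 * t)))
        assert res.pct_extrapolated > 20
        assert any("extrapolated" in w for w in res.warnings)

    def test_simulated_oral_auc_inf_near_analytic(self, oil_params, exact_flow):
        """At the sparse 13-sample schedule, the oral AUC_inf is within 3%
        of the analytic systemic exposure fa(1-phi)(1-eh)*D/CL."""
        rec = simulate_oral_experiment(
            oil_params, 200.0, DEFAULT_ORAL_SCHEDULE, exact_flow
        )
        res = nca_extravascular(rec.serum)
        assert res.auc_inf == pytest.approx(
            oracles.oral_auc_inf(oil_params, 200.0), rel=0.03
        )


class TestIntravenous:
    def _dense_1cpt(self, cl=2.0, vc=10.0, dose=20.0):
        p = PKParameters(fa=0.5, phi_lymph=0.1, eh=0.5, ka=1.0, klt=1.0, cl=cl, vc=vc)
        t = np.linspace(0.05, 60, 600)
        return profile(
            t, oracles.iv_serum_conc_1cpt(p, dose, t), route="iv", dose_mg=dose
        )

    def test_clearance_identity_at_reported_exposure(self):
        """A 20 mg bolus with AUC_inf of 594.4 ng*h/ml implies CL of
        33.6 l/h at one decimal."""
        assert round(clearance_l_per_h(20.0, 594.4), 1) == 33.6

    def test_cl_times_auc_equals_dose(self):
        res = nca_intravenous(self._dense_1cpt())
        assert res.cl * res.auc_inf == pytest.approx(
            20.0 * 1e6 / 1e3, rel=1e-12
        )

    def test_one_compartment_recovery(self):
        res = nca_intravenous(self._dense_1cpt(cl=2.0, vc=10.0), bodyweight=50.0)
        assert res.cl == pytest.approx(2.0, rel=0.01)
        assert res.vss == pytest.approx(10.0, rel=0.02)
        assert res.mrt == pytest.approx(5.0, rel=0.02)
        assert res.cl_per_kg == pytest.approx(2.0 / 50, rel=0.01)
        assert res.terminal.t_half == pytest.approx(np.log(2) / 0.2, rel=0.01)

    def test_scaling_concentrations_halves_clearance(self):
        base = self._dense_1cpt()
        doubled = profile(
            base.times, 2 * base.concentrations, route="iv", dose_mg=base.dose_mg
        )
        assert nca_intravenous(doubled).cl == pytest.approx(
            nca_intravenous(base).cl / 2, rel=1e-12
        )

    def test_trapezoid_error_shrinks_second_order(self):
        """Halving the sampling interval cuts the AUC error ~4-fold."""
        p = PKParameters(fa=0.5, phi_lymph=0.1, eh=0.5, ka=1.0, klt=1.0, cl=2, vc=10)
        analytic = oracles.iv_auc_inf(p, 20.0)

        def err(n):
            t = np.linspace(0, 30, n)
            c = oracles.iv_serum_conc_1cpt(p, 20.0, t)
            tail = c[-1] / 0.2
            return abs(np.trapezoid(c, t) + tail - analytic)

        ratios = [err(n) / err(2 * n) for n in (30, 60, 120)]
        assert all(3.5 < r < 4.5 for r in ratios)


class TestProfileValidation:
    def test_non_increasing_times_rejected(self):
        with pytest.raises(ProfileError, match="increasing"):
            profile([1, 1, 2], [1, 2, 3])

    def test_negative_quantifiable_concentration_rejected(self):
        with pytest.raises(ProfileError, match="negative"):
            profile([1, 2, 3], [1, -2, 3])

    def test_fewer_than_three_points_rejected_for_nca(self):
        with pytest.raises(ProfileError, match="3 quantifiable"):
            nca_extravascular(profile([1, 2], [5, 3]))
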