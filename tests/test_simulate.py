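"""Simulator correctness: closed-form oracles, mass balance, truth
identities, noise model and the cross-over study generator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from lymphpk import (
    NoiseModel,
    PKParameters,
    SamplingSchedule,
    apply_measurement_noise,
    generate_crossover_study,
    simulate_iv_experiment,
    simulate_oral_experiment,
    true_transport_fractions,
)
from lymphpk.simulate import (
    DEFAULT_IV_SCHEDULE,
    DEFAULT_ORAL_SCHEDULE,
    LymphFlowModel,
)

DENSE = SamplingSchedule(
    serum_times=tuple(np.linspace(0.25, 48, 192)),
    lymph_interval_bounds=tuple(np.linspace(0.0, 48, 97)),
)


class TestClosedFormEquivalence:
    def test_oral_serum_matches_one_compartment_solution(
        self, one_cpt_params, exact_flow
    ):
        rec = simulate_oral_experiment(one_cpt_params, 200.0, DENSE, exact_flow)
        expected = oracles.oral_serum_conc_1cpt(one_cpt_params, 200.0, rec.serum.times)
        np.testing.assert_allclose(rec.serum.concentrations, expected, rtol=1e-6)

    def test_collected_lymph_matches_closed_form(self, one_cpt_params, exact_flow):
        rec = simulate_oral_experiment(one_cpt_params, 200.0, DENSE, exact_flow)
        ends = np.array([r.t_end for r in rec.lymph])
        collected = np.cumsum([r.conc_ng_ml * r.volume_ml for r in rec.lymph])
        np.testing.assert_allclose(
            collected, oracles.collected_lymph_ng(one_cpt_params, 200.0, ends),
            rtol=1e-6,
        )

    def test_iv_serum_is_mono_exponential(self, one_cpt_params):
        rec = simulate_iv_experiment(one_cpt_params, 20.0, DEFAULT_IV_SCHEDULE)
        expected = oracles.iv_serum_conc_1cpt(one_cpt_params, 20.0, rec.serum.times)
        np.testing.assert_allclose(rec.serum.concentrations, expected, rtol=1e-6)
        # log-concentration vs time is exactly linear with slope -cl/vc
        slope = np.polyfit(rec.serum.times, np.log(rec.serum.concentrations), 1)[0]
        assert slope == pytest.approx(-one_cpt_params.cl / one_cpt_params.vc, rel=1e-9)

    def test_dense_trapezoid_auc_matches_analytic(self, one_cpt_params, exact_flow):
        """Trapezoidal serum AUC on dense sampling is within 0.5% of the
        analytic AUC of the closed-form bi-exponential."""
        rec = simulate_oral_experiment(one_cpt_params, 200.0, DENSE, exact_flow)
        t = np.concatenate(([0.0], rec.serum.times))  # C(0) = 0 pre-dose
        c = np.concatenate(([0.0], rec.serum.concentrations))
        auc = np.trapezoid(c, t)
        analytic = oracles.oral_auc_inf(one_cpt_params, 200.0)
        assert auc == pytest.approx(analytic, rel=5e-3)

    def test_iv_analytic_auc_identity(self):
        p = PKParameters(
            fa=0.5, phi_lymph=0.1, eh=0.5, ka=0.5, klt=0.5, cl=33.6, vc=40.0
        )
        assert oracles.iv_auc_inf(p, 20.0) == pytest.approx(595.2, abs=0.05)


class TestTransportTruth:
    def test_symmetric_split(self):
        p = PKParameters(fa=1.0, phi_lymph=0.5, eh=0.0, ka=1.0, klt=1.0, cl=10, vc=10)
        t = true_transport_fractions(p)
        assert (t.f_al_true, t.f_ap_true, t.f_true, t.f_rl_true) == (50, 50, 100, 50)

    def test_hand_arithmetic(self):
        p = PKParameters(fa=0.1, phi_lymph=0.2, eh=0.5, ka=1.0, klt=1.0, cl=10, vc=10)
        t = true_transport_fractions(p)
        assert t.f_al_true == pytest.approx(2.0)
        assert t.f_ap_true == pytest.approx(4.0)
        assert t.f_true == pytest.approx(6.0)
        assert t.f_rl_true == pytest.approx(100 * 2 / 6)

    def test_no_absorption_gives_all_zero(self):
        p = PKParameters(fa=0.0, phi_lymph=0.2, eh=0.5, ka=1.0, klt=1.0, cl=10, vc=10)
        t = true_transport_fractions(p)
        assert (t.f_al_true, t.f_ap_true, t.f_true, t.f_rl_true) == (0, 0, 0, 0)

    def test_complete_first_pass_extraction_makes_lymph_exclusive(self):
        p = PKParameters(fa=0.5, phi_lymph=0.3, eh=1.0, ka=1.0, klt=1.0, cl=10, vc=10)
        t = true_transport_fractions(p)
        assert t.f_ap_true == 0
        assert t.f_rl_true == 100


class TestSimulationInvariants:
    def test_lymph_route_off(self, exact_flow):
        p = PKParameters(fa=0.5, phi_lymph=0.0, eh=0.5, ka=0.5, klt=0.5, cl=20, vc=30)
        rec = simulate_oral_experiment(p, 200.0, DEFAULT_ORAL_SCHEDULE, exact_flow)
        assert all(r.conc_ng_ml == 0 for r in rec.lymph)
        assert rec.truth.f_al_true == 0

    def test_dose_linearity(self, oil_params, exact_flow):
        r1 = simulate_oral_experiment(oil_params, 100.0, DEFAULT_ORAL_SCHEDULE, exact_flow)
        r2 = simulate_oral_experiment(oil_params, 200.0, DEFAULT_ORAL_SCHEDULE, exact_flow)
        np.testing.assert_allclose(
            r2.serum.concentrations, 2 * r1.serum.concentrations, rtol=1e-9
        )
        iv1 = simulate_iv_experiment(oil_params, 10.0)
        iv2 = simulate_iv_experiment(oil_params, 20.0)
        np.testing.assert_allclose(
            iv2.serum.concentrations, 2 * iv1.serum.concentrations, rtol=1e-9
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        fa=st.floats(0.05, 1.0),
        phi=st.floats(0.0, 1.0),
        eh=st.floats(0.0, 1.0),
        ka=st.floats(0.05, 5.0),
        klt=st.floats(0.05, 5.0),
        cl=st.floats(1.0, 100.0),
        vc=st.floats(5.0, 500.0),
        k12=st.floats(0.0, 3.0),
        k21=st.floats(0.05, 3.0),
    )
    def test_cumulative_collection_is_monotone_and_converges(
        self, fa, phi, eh, ka, klt, cl, vc, k12, k21
    ):
        """Across random parameter sets the simulation satisfies mass
        balance (asserted internally), collected lymph is non-decreasing
        and converges to fa*phi*dose as t grows."""
        p = PKParameters(
            fa=fa, phi_lymph=phi, eh=eh, ka=ka, klt=klt, cl=cl, vc=vc,
            k12=k12, k21=k21,
        )
        sched = SamplingSchedule(
            serum_times=(1.0, 4.0, 12.0, 400.0),
            lymph_interval_bounds=(0.0, 1.0, 4.0, 12.0, 400.0),
        )
        rec = simulate_oral_experiment(p, 200.0, sched, LymphFlowModel(70.0, 0.0))
        masses = np.array([r.conc_ng_ml * r.volume_ml for r in rec.lymph])
        assert np.all(masses >= -1e-6)
        total = masses.sum() / oracles.NG_PER_MG
        assert total == pytest.approx(fa * phi * 200.0, abs=200 * 1e-6 + fa * phi * 200 * 1e-3)


class TestMeasurementNoise:
    def test_zero_cv_only_flags(self, oil_params, exact_flow):
        rec = simulate_oral_experiment(oil_params, 200.0, DEFAULT_ORAL_SCHEDULE, exact_flow)
        noisy = apply_measurement_noise(rec, NoiseModel(0.0, 0.0, lloq=1.0), seed=1)
        np.testing.assert_array_equal(
            noisy.serum.concentrations, rec.serum.concentrations
        )
        assert noisy.serum.blq.tolist() == (rec.serum.concentrations < 1.0).tolist()

    def test_same_seed_reproduces(self, oil_params, exact_flow):
        rec = simulate_oral_experiment(oil_params, 200.0, DEFAULT_ORAL_SCHEDULE, exact_flow)
        noise = NoiseModel(0.2, 0.0, lloq=1.0)
        a = apply_measurement_noise(rec, noise, seed=7)
        b = apply_measurement_noise(rec, noise, seed=7)
        np.testing.assert_array_equal(a.serum.concentrations, b.serum.concentrations)
        assert [r.conc_ng_ml for r in a.lymph] == [r.conc_ng_ml for r in b.lymph]

    def test_noise_cv_recovers_nominal(self):
        """10^4 noisy replicates of a true concentration of 100 show a
        sample CV within 0.02 of the nominal 0.2."""
        rng = np.random.default_rng(0)
        sigma = np.sqrt(np.log1p(0.2**2))
        draws = 100.0 * rng.lognormal(-0.5 * sigma**2, sigma, size=10_000)
        cv = draws.std(ddof=1) / draws.mean()
        assert abs(cv - 0.2) < 0.02

    def test_seed_is_required(self, oil_params, exact_flow):
        rec = simulate_oral_experiment(oil_params, 200.0, DEFAULT_ORAL_SCHEDULE, exact_flow)
        with pytest.raises(ValueError, match="seed"):
            apply_measurement_noise(rec, NoiseModel(0.1, 0.0, 1.0), seed=None)


class TestCrossoverGenerator:
    def test_default_schedule_counts(self, oil_params, nano_params):
        ds = generate_crossover_study(
            3, {"oil": oil_params, "nano": nano_params}, seed=5
        )
        assert len(ds.oral_records) == 6
        assert len(ds.iv_records) == 1
        for rec in ds.oral_records:
            assert len(rec.serum.times) == 13
            assert len(rec.lymph) == 13
        assert ds.iv_records[0].lymph == ()

    def test_no_variability_makes_animals_identical(
        self, oil_params, nano_params, no_noise, exact_flow
    ):
        ds = generate_crossover_study(
            3, {"oil": oil_params, "nano": nano_params}, no_noise, exact_flow, seed=5
        )
        oil = [r for r in ds.oral_records if r.formulation == "oil"]
        for rec in oil[1:]:
            np.testing.assert_array_equal(
                rec.serum.concentrations, oil[0].serum.concentrations
            )

    def test_seeded_run_reproduces_end_to_end(self, oil_params, nano_params):
        from lymphpk.pipeline import run_study

        kwargs = dict(seed=11)
        d1 = generate_crossover_study(3, {"a": oil_params, "b": nano_params}, **kwargs)
        d2 = generate_crossover_study(3, {"a": oil_params, "b": nano_params}, **kwargs)
        t1 = run_study(d1)["transport_full"]
        t2 = run_study(d2)["transport_full"]
        assert t1.equals(t2)

    def test_single_animal_warns_but_produces(self, oil_params, nano_params):
        with pytest.warns(UserWarning, match="paired"):
            ds = generate_crossover_study(
                1, {"a": oil_params, "b": nano_params}, seed=3
            )
        assert len(ds.oral_records) == 2
        assert ds.warnings
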