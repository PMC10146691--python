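"""Inverse-pipeline tests: steady viscometry, transient fit, inversion."""

import numpy as np
import pytest

from coflow import (
    CorrectionFactorModel,
    GroundTruth,
    InterfaceSeries,
    analytic_beta,
    analyze_experiment,
    complete_parameter_set,
    compliances_from_eigenvalues,
    eigenvalues_forward,
    select_steady_window,
    simulate_measurement,
    steady_viscosity,
    two_exponential_fit,
)
from coflow.errors import (
    InsufficientDataError,
    InvalidInputError,
    NonIdentifiableError,
    PipelineStageError,
    RepeatedRootError,
    ValidityWarning,
)
from coflow.synthetic import generate_flow_program

from conftest import random_circuit

PRINTED_LAMBDAS = (0.1945, 0.0127)
PRINTED_COMPLIANCES = (53.3, 1398.2)


class TestSteadyWindow:
    def test_window_covers_last_25_seconds(self):
        program = generate_flow_program(cycles=1)
        t = program.times()
        series = InterfaceSeries(t, np.full(t.size, 0.6), program=program)
        (idx,) = select_steady_window(series, program, n=50)
        assert series.times[idx[0]] == 95.0
        assert series.times[idx[-1]] == 119.5
        assert idx.size == 50

    def test_pure_off_phase_rejected(self):
        program = generate_flow_program(cycles=1)
        t = np.arange(120.0, 240.0, 0.5)
        series = InterfaceSeries(t, np.full(t.size, 0.5))
        with pytest.raises(InsufficientDataError):
            select_steady_window(series, program)

    def test_constant_series_mean(self):
        program = generate_flow_program(cycles=1)
        t = program.times()
        series = InterfaceSeries(t, np.full(t.size, 0.4321), program=program)
        (idx,) = select_steady_window(series, program)
        assert series.alpha[idx].mean() == pytest.approx(0.4321)

    def test_short_on_phase_rejected(self):
        program = generate_flow_program(T_s=160.0, cycles=1)  # 80 s on
        t = program.times()
        series = InterfaceSeries(t, np.full(t.size, 0.5), program=program)
        with pytest.raises(InsufficientDataError):
            select_steady_window(series, program, n=50, settle_s=70.0)


class TestSteadyViscosity:
    def test_symmetric_identity(self):
        unit = CorrectionFactorModel.constant(1.0)
        assert steady_viscosity(0.5, 1.0, 1.0, 1.0, unit) == pytest.approx(1.0)

    def test_three_quarters(self):
        unit = CorrectionFactorModel.constant(1.0)
        assert steady_viscosity(0.75, 1.0, 1.0, 1.0, unit) == pytest.approx(3.0)

    def test_h20_polynomial_value(self, cf20):
        assert steady_viscosity(0.61, 1.0, 1.0, 1.0, cf20) == pytest.approx(
            1.629, abs=1e-3
        )

    def test_out_of_range_warns(self, cf20):
        with pytest.warns(ValidityWarning):
            steady_viscosity(0.95, 1.0, 1.0, 1.0, cf20)


def _series_from_modes(d1, d2, lam1, lam2, n=240, dt=0.5,
                       sigma=0.0, seed=None):
    t = np.arange(n) * dt
    beta = analytic_beta(d1, d2, lam1, lam2, t)
    alpha = 1.0 - 1.0 / beta
    if sigma > 0:
        rng = np.random.default_rng(seed)
        alpha = np.clip(alpha + rng.normal(0, sigma, alpha.size),
                        1e-3, 1 - 1e-3)
    return InterfaceSeries(t, alpha)


class TestTwoExponentialFit:
    def test_noiseless_exact_recovery(self):
        series = _series_from_modes(-0.12, 1.3, 0.19, 0.013)
        fit = two_exponential_fit(series, 0.0)
        assert fit.converged and not fit.degenerate
        assert fit.d1 == pytest.approx(-0.12, rel=1e-6)
        assert fit.d2 == pytest.approx(1.3, rel=1e-6)
        assert fit.lambda1 == pytest.approx(0.19, rel=1e-6)
        assert fit.lambda2 == pytest.approx(0.013, rel=1e-6)

    def test_noisy_recovery_seed42(self):
        # pixel-scale α noise: the slow mode is sharply determined while
        # the small-amplitude fast mode carries most of the uncertainty
        # (tolerances frozen from a seeded run of this estimator)
        series = _series_from_modes(-0.12, 1.3, 0.19, 0.013,
                                    sigma=0.005, seed=42)
        fit = two_exponential_fit(series, 0.0)
        assert fit.lambda2 == pytest.approx(0.013, rel=0.01)
        assert fit.lambda1 == pytest.approx(0.19, rel=0.20)

    def test_single_exponential_flagged_degenerate(self):
        series = _series_from_modes(0.0, 1.3, 0.19, 0.013)
        fit = two_exponential_fit(series, 0.0)
        assert fit.degenerate

    def test_too_few_samples(self):
        series = _series_from_modes(-0.12, 1.3, 0.19, 0.013, n=20)
        with pytest.raises(InsufficientDataError):
            two_exponential_fit(series, 0.0)

    def test_canonical_ordering(self):
        series = _series_from_modes(-0.12, 1.3, 0.19, 0.013)
        fit = two_exponential_fit(series, 0.0)
        assert fit.lambda1 >= fit.lambda2 > 0


class TestComplianceInversion:
    def test_printed_worked_example(self, geom_h20):
        # printed eigenvalues + the demonstration viscosity reproduce the
        # printed compliance pair to printed-rounding accuracy
        c1, c2 = compliances_from_eigenvalues(
            *PRINTED_LAMBDAS, 2.2266, geom_h20, 1.0, 1.183
        )
        assert c1 == pytest.approx(PRINTED_COMPLIANCES[0], rel=0.015)
        assert c2 == pytest.approx(PRINTED_COMPLIANCES[1], rel=0.015)

    def test_forward_inverse_roundtrip(self, geom_h20):
        rng = np.random.default_rng(99)
        for _ in range(100):
            p = random_circuit(rng, geom_h20)
            lam1, lam2 = eigenvalues_forward(p)
            c1, c2 = compliances_from_eigenvalues(
                lam1, lam2, p.fluids.mu_b, geom_h20, 1.0, p.CF0
            )
            assert c1 == pytest.approx(p.C1, rel=1e-9)
            assert c2 == pytest.approx(p.C2, rel=1e-9)

    def test_equal_rates_rejected(self, geom_h20):
        with pytest.raises(RepeatedRootError):
            compliances_from_eigenvalues(0.1, 0.1, 2.0, geom_h20, 1.0, 1.183)


class TestCompleteParameterSet:
    def test_known_c1_completes_mu_and_c2(self, geom_h20):
        res = complete_parameter_set(
            *PRINTED_LAMBDAS, geom_h20, 1.0, 1.183, C1=53.3
        )
        assert res["mu_b"] == pytest.approx(2.23, abs=0.01)
        assert res["C2"] == pytest.approx(1392.1, rel=1e-3)
        # the rejected candidate root has C2 < C1
        rejected = [r for r in res["diagnostics"]["roots"]
                    if r["C2"] != pytest.approx(res["C2"])]
        assert rejected and rejected[0]["C2"] < rejected[0]["C1"]

    def test_known_c2_completes_mu_and_c1(self, geom_h20):
        res = complete_parameter_set(
            *PRINTED_LAMBDAS, geom_h20, 1.0, 1.183, C2=1398.2
        )
        assert res["mu_b"] == pytest.approx(2.22, abs=0.01)
        assert res["C1"] == pytest.approx(53.53, rel=1e-3)

    def test_known_mu_roundtrip(self, geom_h20):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = random_circuit(rng, geom_h20)
            lam1, lam2 = eigenvalues_forward(p)
            res = complete_parameter_set(
                lam1, lam2, geom_h20, 1.0, p.CF0, mu_b=p.fluids.mu_b
            )
            assert res["C1"] == pytest.approx(p.C1, rel=1e-9)
            assert res["C2"] == pytest.approx(p.C2, rel=1e-9)

    def test_close_rates_not_identifiable(self, geom_h20):
        # known C2: infeasibility manifests as a negative discriminant when
        # the two rates are too close (an ordering-violating root pair
        # cannot arise in this case — see the inversion module docstring)
        with pytest.raises(NonIdentifiableError):
            complete_parameter_set(
                0.013, 0.0127, geom_h20, 1.0, 1.183, C2=1398.2
            )

    def test_exactly_one_known_required(self, geom_h20):
        with pytest.raises(InvalidInputError):
            complete_parameter_set(
                *PRINTED_LAMBDAS, geom_h20, 1.0, 1.183, C1=50.0, C2=1400.0
            )

    def test_root_selection_unique_in_identifiable_regime(self, geom_h20):
        # for C2 > k²·C1 (k = 1 + (l1/l2)·CF0) exactly one candidate root
        # obeys C1 < C2; closer compliance pairs admit a second ordered
        # root (the companion pair (C2/k, k·C1)) and are genuinely
        # ambiguous given only (λ1, λ2, µ_b)
        rng = np.random.default_rng(17)
        for _ in range(100):
            p = random_circuit(rng, geom_h20, identifiable_only=True)
            lam1, lam2 = eigenvalues_forward(p)
            res = complete_parameter_set(
                lam1, lam2, geom_h20, 1.0, p.CF0, mu_b=p.fluids.mu_b
            )
            physical = [
                r for r in res["diagnostics"]["roots"]
                if r["mu_b"] > 0 and 0 < r["C1"] < r["C2"] < np.inf
            ]
            assert len(physical) == 1

    def test_ambiguous_companion_root_reported(self, geom_h20):
        # a compliance pair with C2 < k²·C1 yields two ordered roots; both
        # must be reported in diagnostics rather than silently dropped
        from coflow import CircuitParameters, FluidPair

        p = CircuitParameters(
            geometry=geom_h20,
            fluids=FluidPair(mu_r=1.0, mu_b=2.0),
            C1=150.0,
            C2=600.0,  # ratio 4 < k² ≈ 8.1
            CF0=1.183,
        )
        lam1, lam2 = eigenvalues_forward(p)
        res = complete_parameter_set(
            lam1, lam2, geom_h20, 1.0, p.CF0, mu_b=2.0
        )
        physical = [
            r for r in res["diagnostics"]["roots"]
            if r["mu_b"] > 0 and 0 < r["C1"] < r["C2"] < np.inf
        ]
        assert len(physical) == 2
        assert res["diagnostics"]["n_physical"] == 2


class TestAnalyzeExperiment:
    def test_noiseless_self_consistency(self):
        truth = GroundTruth(mu_b=2.2, C1=50.0, C2=1400.0,
                            sigma_alpha=0.0, seed=0)
        series = simulate_measurement(truth)
        res = analyze_experiment(series, truth.analysis_setup())
        assert res.mu_b == pytest.approx(2.2, rel=1e-4)
        assert res.C1 == pytest.approx(50.0, rel=1e-4)
        assert res.C2 == pytest.approx(1400.0, rel=1e-4)

    def test_noisy_recovery_within_tolerance(self):
        truth = GroundTruth(mu_b=2.2, C1=50.0, C2=1400.0,
                            sigma_alpha=0.005, seed=7)
        series = simulate_measurement(truth)
        res = analyze_experiment(series, truth.analysis_setup())
        assert res.mu_b == pytest.approx(2.2, rel=0.02)
        assert res.C1 == pytest.approx(50.0, rel=0.10)
        assert res.C2 == pytest.approx(1400.0, rel=0.10)

    def test_viscosity_exact_on_inverted_steady_window(self, cf20):
        # windows generated by inverting the steady-state law give back the
        # viscosity to machine precision
        from coflow import steady_interface

        program = generate_flow_program(cycles=1)
        t = program.times()
        for mu_true in (1.3, 2.0, 3.5):
            alpha = steady_interface(mu_true, 1.0, 1.0, cf20)
            series = InterfaceSeries(t, np.full(t.size, alpha),
                                     program=program)
            (idx,) = select_steady_window(series, program)
            mu = steady_viscosity(series.alpha[idx].mean(), 1.0, 1.0, 1.0,
                                  cf20)
            assert mu == pytest.approx(mu_true, rel=1e-12)

    def test_missing_off_phase_raises_stage_error(self):
        program = generate_flow_program(cycles=1)
        t = np.arange(0.0, 120.0, 0.5)
        truth = GroundTruth(sigma_alpha=0.0)
        series = InterfaceSeries(t, np.full(t.size, 0.65), program=program)
        with pytest.raises(PipelineStageError) as err:
            analyze_experiment(series, truth.analysis_setup())
        assert err.value.stage == "two_exponential_fit"

    def test_multi_cycle_aggregation(self):
        truth = GroundTruth(mu_b=2.2, C1=50.0, C2=1400.0, sigma_alpha=0.003,
                            seed=3,
                            program=generate_flow_program(cycles=2))
        series = simulate_measurement(truth)
        res = analyze_experiment(series, truth.analysis_setup())
        assert res.n_cycles == 2
        assert len(res.cycles) == 2
        assert res.mu_b_sd >= 0
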