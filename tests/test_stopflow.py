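"""Stopped-flow simulation and analysis: relaxation, association, fitting."""

import math

import numpy as np
import pytest

from tfdimer import (
    BindingModel,
    DimerKinetics,
    KineticTrace,
    NoiseSpec,
    SelfAssociationModel,
    attribute_phases,
    fit_dilution_relaxation,
    fit_exponentials,
    make_stopflow_trace,
    regress_kobs,
    residence_time,
    select_model,
    simulate_association,
    simulate_dilution_relaxation,
    solve_speciation,
)


class TestDilutionRelaxation:
    def test_no_dilution_gives_flat_trace(self, kinetics, t_grid):
        trace = simulate_dilution_relaxation(1.0, 1.0, kinetics, t_grid)
        assert np.ptp(trace.signal) <= 1e-8 * abs(trace.signal[0])

    def test_final_state_reaches_diluted_equilibrium(self, kinetics, t_grid):
        trace = simulate_dilution_relaxation(1.0, 10.0, kinetics, t_grid)
        aM, aD = trace.meta["signal_coeffs"]
        eq = solve_speciation(0.1, kinetics.model)
        expected = aM * eq.m + aD * 2 * eq.d
        assert trace.signal[-1] == pytest.approx(expected, rel=1e-6)
        # free monomer after 10-fold dilution of 1 µM at Kd = 2 µM
        assert eq.m == pytest.approx(0.0916, abs=1e-4)

    def test_single_exponential_rate_near_linearization_eigenvalue(
        self, kinetics, t_grid
    ):
        """The relaxation is not exactly exponential, but its fitted rate must
        stay within 25% of kdiss + 4 kass m_eq (and hence of kdiss itself)."""
        trace = simulate_dilution_relaxation(1.0, 10.0, kinetics, t_grid)
        fit = fit_exponentials(trace, n_phases=1)
        m_eq = solve_speciation(0.1, kinetics.model).m
        eigenvalue = kinetics.kdiss + 4 * kinetics.kass * m_eq
        assert eigenvalue == pytest.approx(11.83, abs=0.01)
        assert abs(fit.rates[0] - eigenvalue) / eigenvalue < 0.25

    def test_ode_fit_recovers_kdiss(self, kinetics, t_grid):
        trace = simulate_dilution_relaxation(1.0, 10.0, kinetics, t_grid)
        out = fit_dilution_relaxation(trace, kinetics.model)
        assert out["kdiss"] == pytest.approx(10.0, rel=1e-6)
        assert out["kass"] == pytest.approx(5.0, rel=1e-6)

    def test_invalid_protocol_rejected(self, kinetics, t_grid):
        with pytest.raises(ValueError):
            simulate_dilution_relaxation(0.0, 10.0, kinetics, t_grid)
        with pytest.raises(ValueError):
            simulate_dilution_relaxation(1.0, 0.5, kinetics, t_grid)


class TestAssociationSimulation:
    def test_no_chaperone_gives_flat_zero_signal(self, binding, kinetics, t_grid):
        trace = simulate_association(2.0, 0.0, binding, kinetics, t_grid)
        assert np.all(trace.signal == 0)

    def test_monomer_only_pseudo_first_order_rate(self, t_grid):
        """10 µM pure monomer, kon 0.5 µM⁻¹s⁻¹, koff 6 s⁻¹ -> kobs 11 s⁻¹."""
        kin = DimerKinetics(kdiss=10.0, model=SelfAssociationModel(Kd_dim=1e6))
        bm = BindingModel(kon_m=0.5, koff_m=6.0, kon_d=0.0, koff_d=0.0)
        trace = simulate_association(2.0, 10.0, bm, kin, t_grid)
        fit = fit_exponentials(trace, n_phases=1)
        assert fit.rates[0] == pytest.approx(11.0, rel=1e-2)

    def test_mixed_population_gives_per_species_eigenvalues(
        self, binding, kinetics, t_grid
    ):
        """Decoupled trace at 40 µM total: rates kon_d d + koff_d and
        kon_m m + koff_m with d = 17.08, m = 5.84 µM."""
        trace = simulate_association(2.0, 40.0, binding, kinetics, t_grid)
        fit = fit_exponentials(trace, n_phases=2)
        spec = solve_speciation(40.0, kinetics.model)
        k_fast = binding.kon_d * spec.d + binding.koff_d
        k_slow = binding.kon_m * spec.m + binding.koff_m
        assert k_fast == pytest.approx(48.8, abs=0.1)
        assert k_slow == pytest.approx(8.92, abs=0.01)
        assert fit.rates[0] == pytest.approx(k_fast, rel=1e-2)
        assert fit.rates[1] == pytest.approx(k_slow, rel=1e-2)

    def test_decoupled_final_state_matches_binding_equilibrium(
        self, binding, kinetics, t_grid
    ):
        trace = simulate_association(2.0, 40.0, binding, kinetics, t_grid)
        spec = solve_speciation(40.0, kinetics.model)
        expected = 0.0
        for frac, kon, koff, C in (
            (spec.monomer_mass_fraction, binding.kon_m, binding.koff_m, spec.m),
            (spec.dimer_mass_fraction, binding.kon_d, binding.koff_d, spec.d),
        ):
            expected += 2.0 * frac * kon * C / (kon * C + koff)
        assert trace.signal[-1] == pytest.approx(expected, rel=1e-6)

    def test_coupled_mode_conserves_mass_and_equilibrates(self, kinetics):
        bm = BindingModel(coupling="coupled")
        t = np.linspace(0.0, 5.0, 500)
        spec = solve_speciation(40.0, kinetics.model)
        from scipy.integrate import solve_ivp

        def rhs(_t, y):
            m, d, S, MS, DS = y
            v_ex = kinetics.kass * m * m - kinetics.kdiss * d
            v_m = bm.kon_m * m * S - bm.koff_m * MS
            v_d = bm.kon_d * d * S - bm.koff_d * DS
            return [-2 * v_ex - v_m, v_ex - v_d, -v_m - v_d, v_m, v_d]

        sol = solve_ivp(rhs, (0, 5.0), [spec.m, spec.d, 2.0, 0.0, 0.0],
                        t_eval=t, rtol=1e-10, atol=1e-13)
        m, d, S, MS, DS = sol.y
        chap_total = m + 2 * d + MS + 2 * DS
        sub_total = S + MS + DS
        assert np.allclose(chap_total, 40.0, rtol=1e-8)
        assert np.allclose(sub_total, 2.0, rtol=1e-8)
        # final state at detailed balance for every reaction
        assert kinetics.kass * m[-1] ** 2 == pytest.approx(
            kinetics.kdiss * d[-1], rel=1e-5
        )
        assert bm.kon_m * m[-1] * S[-1] == pytest.approx(
            bm.koff_m * MS[-1], rel=1e-5
        )
        assert bm.kon_d * d[-1] * S[-1] == pytest.approx(
            bm.koff_d * DS[-1], rel=1e-5
        )
        # and the production coupled simulation reproduces this independent
        # integration's bound-substrate signal
        trace = simulate_association(2.0, 40.0, bm, kinetics, t)
        assert np.allclose(trace.signal, MS + DS, rtol=1e-6, atol=1e-9)

    def test_sub_pseudo_first_order_warns(self, binding, kinetics, t_grid):
        with pytest.warns(RuntimeWarning, match="pseudo-first-order"):
            simulate_association(2.0, 3.0, binding, kinetics, t_grid)

    def test_negative_concentration_rejected(self, binding, kinetics, t_grid):
        with pytest.raises(ValueError):
            simulate_association(-1.0, 10.0, binding, kinetics, t_grid)


def synthetic_exponential(t, amplitudes, rates, offset=0.0):
    y = np.full_like(t, offset)
    for a, r in zip(amplitudes, rates):
        y = y + a * np.exp(-r * t)
    return KineticTrace(t=t, signal=y)


class TestExponentialFitting:
    def test_single_exponential_exact_recovery(self, t_grid):
        trace = synthetic_exponential(t_grid, [1.0], [10.0], offset=0.3)
        fit = fit_exponentials(trace, 1)
        assert fit.rates[0] == pytest.approx(10.0, rel=1e-6)
        assert fit.converged

    def test_double_exponential_recovery_within_1pct(self, t_grid):
        trace = synthetic_exponential(t_grid, [0.85, 0.15], [48.8, 8.9])
        fit = fit_exponentials(trace, 2)
        assert fit.rates[0] == pytest.approx(48.8, rel=1e-2)
        assert fit.rates[1] == pytest.approx(8.9, rel=1e-2)
        assert fit.fast_amplitude_fraction == pytest.approx(0.85, abs=1e-3)

    def test_photobleach_baseline_recovery_within_5pct(self, t_grid):
        kinetic = synthetic_exponential(t_grid, [0.85, 0.15], [48.8, 8.9], offset=2.0)
        bleach = 0.5 * np.exp(-0.3 * t_grid)
        trace = KineticTrace(t=t_grid, signal=kinetic.signal + bleach)
        fit = fit_exponentials(trace, 2, baseline_policy="photobleach")
        assert fit.baseline is not None
        assert fit.rates[0] == pytest.approx(48.8, rel=5e-2)
        assert fit.rates[1] == pytest.approx(8.9, rel=5e-2)

    def test_rates_sorted_descending(self, t_grid):
        trace = synthetic_exponential(t_grid, [0.2, 0.8], [3.0, 30.0])
        fit = fit_exponentials(trace, 2)
        assert fit.rates[0] > fit.rates[1]

    def test_insufficient_points_rejected(self):
        t = np.linspace(0, 1, 8)
        with pytest.raises(ValueError):
            fit_exponentials(KineticTrace(t=t, signal=np.exp(-t)), 1)

    def test_missing_tail_rejected_for_photobleach_policy(self):
        t = np.linspace(0.0, 0.5, 100)
        trace = KineticTrace(t=t, signal=np.exp(-10 * t))
        with pytest.raises(ValueError, match="photobleach"):
            fit_exponentials(trace, 1, baseline_policy="photobleach")


class TestModelSelection:
    """Phase counting on traces with realistic (0.5% of amplitude) noise;
    on strictly noiseless data any extra phase trivially improves the fit."""

    NOISE = 0.005

    def noisy(self, t_grid, amplitudes, rates, seed=0):
        trace = synthetic_exponential(t_grid, amplitudes, rates)
        rng = np.random.default_rng(seed)
        return KineticTrace(
            t=trace.t,
            signal=trace.signal + rng.normal(0, self.NOISE, size=trace.t.shape),
        )

    def test_pure_single_exponential_selects_one_phase(self, t_grid):
        assert select_model(self.noisy(t_grid, [1.0], [10.0])) == 1

    def test_well_separated_phases_select_two(self, t_grid):
        assert select_model(self.noisy(t_grid, [0.5, 0.5], [50.0, 10.0])) == 2

    def test_indistinguishable_rates_collapse_to_one_phase(self, t_grid):
        assert select_model(self.noisy(t_grid, [0.5, 0.5], [10.5, 10.0])) == 1


class TestPhaseAttribution:
    def test_fast_fraction_tracks_dimer_fraction_at_40uM(
        self, binding, kinetics, t_grid
    ):
        trace = simulate_association(2.0, 40.0, binding, kinetics, t_grid)
        fit = fit_exponentials(trace, 2)
        spec = solve_speciation(40.0, kinetics.model)
        attr = attribute_phases(fit, spec)
        assert attr.fast_species == "dimer"
        assert attr.fast_amplitude_fraction > 0.80
        assert attr.agreement < 0.05

    def test_single_phase_fit_rejected(self, t_grid, kinetics):
        fit = fit_exponentials(synthetic_exponential(t_grid, [1.0], [10.0]), 1)
        with pytest.raises(ValueError):
            attribute_phases(fit, solve_speciation(40.0, kinetics.model))


class TestKobsRegression:
    def test_exact_round_trip(self):
        concs = [2.0, 5.0, 10.0, 20.0, 40.0]
        pts = [(c, 0.5 * c + 6.0) for c in concs]
        rc = regress_kobs(pts, species="monomer")
        assert rc.kon == pytest.approx(0.5e6, rel=1e-10)
        assert rc.koff == pytest.approx(6.0, rel=1e-10)
        assert rc.species == "monomer"

    def test_concentration_independent_kobs_gives_zero_slope(self):
        rc = regress_kobs([(1.0, 7.0), (5.0, 7.0), (20.0, 7.0)])
        assert rc.kon == pytest.approx(0.0, abs=1e-8)
        assert rc.koff == pytest.approx(7.0)

    def test_negative_intercept_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clipped"):
            rc = regress_kobs([(1.0, 0.5), (2.0, 1.6), (3.0, 2.7)])
        assert rc.koff == 0.0

    def test_too_few_distinct_concentrations_rejected(self):
        with pytest.raises(ValueError):
            regress_kobs([(1.0, 2.0), (1.0, 2.1), (1.0, 1.9)])


class TestResidenceTime:
    @pytest.mark.parametrize("kdiss, expected", [(10.0, 0.1), (1.0, 1.0), (20.0, 0.05)])
    def test_inverse_of_dissociation_rate(self, kdiss, expected):
        kin = DimerKinetics(kdiss=kdiss)
        assert residence_time(kin) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            DimerKinetics(kdiss=0.0)


class TestEndToEndRecovery:
    CONCS = (5.0, 10.0, 20.0, 30.0, 40.0)

    def run_pipeline(self, kinetics, noise_sigma=0.0, seed=0):
        fast, slow = [], []
        for c in self.CONCS:
            trace, _ = make_stopflow_trace(
                "association",
                {"S0_uM": 2.0, "chap_CT_uM": c},
                noise=NoiseSpec("multiplicative_gaussian", noise_sigma,
                                seed * 1000 + int(c)),
                n_points=500,
            )
            fit = fit_exponentials(trace, 2)
            spec = solve_speciation(c, kinetics.model)
            fast.append((spec.d, fit.rates[0]))
            slow.append((spec.m, fit.rates[1]))
        return regress_kobs(fast, "dimer"), regress_kobs(slow, "monomer")

    def test_noiseless_recovery_within_5pct(self, kinetics):
        rd, rm = self.run_pipeline(kinetics)
        assert rd.kon == pytest.approx(1.1e6, rel=0.05)
        assert rd.koff == pytest.approx(30.0, rel=0.05)
        assert rm.kon == pytest.approx(0.5e6, rel=0.05)
        assert rm.koff == pytest.approx(6.0, rel=0.05)

    def test_noisy_recovery_medians_within_20pct(self, kinetics):
        """2% multiplicative noise, 50 seeds: median of each constant within 20%."""
        results = []
        for seed in range(50):
            rd, rm = self.run_pipeline(kinetics, 0.02, seed)
            results.append((rd.kon, rd.koff, rm.kon, rm.koff))
        medians = np.median(np.array(results), axis=0)
        truth = np.array([1.1e6, 30.0, 0.5e6, 6.0])
        assert np.all(np.abs(medians / truth - 1.0) < 0.20)
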