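"""Transfer-matrix model: closed forms, enumeration oracle, fits, energies."""

import math
from fractions import Fraction
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gqstack.helix_coil import (
    DEFAULT_TEMPERATURE_K,
    KB_KCAL,
    HelixCoilParams,
    StackedFractionSeries,
    coupling_free_energy,
    delta_g_stack,
    eigenvalues,
    fit_params,
    partition_function,
    partition_function_bruteforce,
    specific_heat_curve,
    stacked_fraction,
    stacked_fraction_bruteforce,
    transfer_matrix,
    unstacked_multiplet_fraction,
)

FITTED = HelixCoilParams(s=0.455, sigma=0.76)

weights = st.floats(0.05, 5.0, allow_nan=False, allow_infinity=False)


class TestTransferMatrix:
    def test_matrix_entries(self):
        G = transfer_matrix(FITTED)
        assert np.allclose(G, [[0.76, 1.0], [0.455, 0.455]])
        ones = transfer_matrix(HelixCoilParams(s=1.0, sigma=1.0))
        assert np.allclose(ones, np.ones((2, 2)))

    @given(weights, weights)
    @settings(max_examples=50, deadline=None)
    def test_determinant_closed_form(self, s, sig):
        G = transfer_matrix(HelixCoilParams(s=s, sigma=sig))
        assert np.linalg.det(G) == pytest.approx(s * (sig - 1.0), rel=1e-9, abs=1e-12)

    def test_eigenvalues_special_cases(self):
        lam0, lam1 = eigenvalues(HelixCoilParams(s=1.0, sigma=1.0))
        assert (lam0, lam1) == pytest.approx((2.0, 0.0), abs=1e-14)
        # sigma -> 0 limit: golden-ratio pair (1 +- sqrt(5))/2
        lam0, lam1 = eigenvalues(HelixCoilParams(s=1.0, sigma=1e-300))
        assert lam0 == pytest.approx((1 + math.sqrt(5)) / 2, rel=1e-12)
        assert lam1 == pytest.approx((1 - math.sqrt(5)) / 2, rel=1e-12)

    @given(weights, weights)
    @settings(max_examples=50, deadline=None)
    def test_eigenvalues_match_numeric_eigensolver(self, s, sig):
        p = HelixCoilParams(s=s, sigma=sig)
        lam = sorted(np.linalg.eigvals(transfer_matrix(p)), reverse=True)
        lam0, lam1 = eigenvalues(p)
        assert lam0 == pytest.approx(float(np.real(lam[0])), abs=1e-12)
        assert lam1 == pytest.approx(float(np.real(lam[1])), abs=1e-12)


class TestPartitionFunction:
    def test_small_n_closed_forms(self):
        s, sig = Fraction(455, 1000), Fraction(76, 100)
        assert partition_function_bruteforce(2, s, sig) == 1 + s
        assert partition_function_bruteforce(3, s, sig) == sig + 2 * s + s * s

    def test_all_weights_one_counts_states(self):
        p = HelixCoilParams(s=1.0, sigma=1.0)
        for n in range(2, 12):
            assert partition_function(n, p) == pytest.approx(2.0 ** (n - 1), rel=1e-12)

    def test_closed_form_equals_enumeration_on_grid(self):
        grid = np.linspace(0.1, 3.0, 5)
        for s, sig in product(grid, grid):
            p = HelixCoilParams(s=float(s), sigma=float(sig))
            for n in (2, 3, 5, 8, 12):
                qa = partition_function(n, p)
                qb = partition_function_bruteforce(n, p)
                assert abs(qa - qb) / qb < 1e-12

    def test_outside_fitted_regime(self):
        p = HelixCoilParams(s=2.0, sigma=0.5)
        assert partition_function(5, p) == pytest.approx(
            partition_function_bruteforce(5, p), rel=1e-12)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            partition_function(1, FITTED)
        with pytest.raises(ValueError):
            partition_function_bruteforce(21, FITTED)


class TestStackedFraction:
    def test_dimer_closed_form(self):
        assert stacked_fraction(2, FITTED) == pytest.approx(0.455 / 1.455, rel=1e-12)

    def test_matches_enumeration_expectation(self):
        for s, sig in product((0.2, 0.455, 1.7), (0.3, 0.76, 2.5)):
            p = HelixCoilParams(s=s, sigma=sig)
            for n in range(2, 9):
                assert stacked_fraction(n, p) == pytest.approx(
                    stacked_fraction_bruteforce(n, p), abs=1e-12)

    def test_trimer_value(self):
        # enumeration over the 4 states of (unit2, unit3)
        assert stacked_fraction(3, FITTED) == pytest.approx(0.3527, abs=5e-5)

    @given(weights, weights)
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_s_and_bounded(self, s, sig):
        p1 = HelixCoilParams(s=s, sigma=sig)
        p2 = HelixCoilParams(s=s * 1.05, sigma=sig)
        for n in (2, 4, 7):
            f1 = stacked_fraction(n, p1)
            assert 0.0 < f1 < 1.0
            assert stacked_fraction(n, p2) > f1

    def test_sigma_one_reduces_to_independent_junctions(self):
        # sigma = 1 removes the second-neighbour coupling: f_n = s/(1+s) for all n
        for s in (0.2, 0.455, 1.3):
            p = HelixCoilParams(s=s, sigma=1.0)
            for n in range(2, 12):
                assert stacked_fraction(n, p) == pytest.approx(s / (1 + s), rel=1e-10)

    def test_vanishing_s_limit(self):
        p = HelixCoilParams(s=1e-12, sigma=0.76)
        for n in (2, 5, 9):
            assert stacked_fraction(n, p) < 1e-10


class TestFit:
    def test_fit_reference_fractions(self):
        """The simulated 2-4-mer stacked fractions pin (s, sigma) near
        (0.455, 0.76)."""
        series = StackedFractionSeries((2, 3, 4), (0.315, 0.350, 0.369))
        params, info = fit_params(series)
        assert params.s == pytest.approx(0.455, abs=0.01)
        assert params.sigma == pytest.approx(0.76, abs=0.03)
        assert info["s_err"] < 0.05 and info["sigma_err"] < 0.1

    def test_noiseless_self_consistency(self):
        truth = HelixCoilParams(s=0.6, sigma=1.4)
        ns = (2, 3, 4, 5, 6)
        series = StackedFractionSeries(
            ns, tuple(stacked_fraction(n, truth) for n in ns))
        params, _ = fit_params(series)
        assert params.s == pytest.approx(truth.s, abs=1e-6)
        assert params.sigma == pytest.approx(truth.sigma, abs=1e-6)

    def test_noise_propagates_to_parameter_spread(self):
        truth = HelixCoilParams(s=0.455, sigma=0.76)
        ns = (2, 3, 4)
        clean = np.array([stacked_fraction(n, truth) for n in ns])
        rng = np.random.default_rng(5)
        s_fit, sig_fit = [], []
        for _ in range(100):
            noisy = clean + 0.001 * rng.standard_normal(3)
            p, _ = fit_params(StackedFractionSeries(ns, tuple(noisy),
                                                    (0.001,) * 3))
            s_fit.append(p.s)
            sig_fit.append(p.sigma)
        # spread comparable to the +-0.008 / +-0.02 scale of the reference fit
        assert 0.001 < np.std(s_fit) < 0.02
        assert 0.003 < np.std(sig_fit) < 0.06

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError):
            fit_params(StackedFractionSeries((3, 3), (0.3, 0.31)))


class TestFreeEnergies:
    @pytest.mark.parametrize("n, fn, expected, tol", [
        (2, 0.315, 0.452, 0.005),
        (3, 0.350, 0.719, 0.01),
        (4, 0.369, 0.94, 0.01),
    ])
    def test_stacking_free_energy_table(self, n, fn, expected, tol):
        """dGs from the simulated fractions at 293 K, in kcal/mol."""
        assert delta_g_stack(n, fn) == pytest.approx(expected, abs=tol)

    def test_symmetry_point(self):
        assert delta_g_stack(3, 0.5) == 0.0

    def test_s_equals_boltzmann_factor_of_dimer_dG(self):
        # algebraic identity: Q2 = 1 + s forces s = exp(-dGs(2)/kBT)
        for s in (0.2, 0.455, 2.0):
            p = HelixCoilParams(s=s, sigma=0.76)
            f2 = stacked_fraction(2, p)
            assert math.exp(-delta_g_stack(2, f2, p) / p.kBT) == pytest.approx(
                s, rel=1e-12)

    def test_per_junction_free_energy_decreases_with_n(self):
        vals = [delta_g_stack(n, stacked_fraction(n, FITTED), FITTED) / (n - 1)
                for n in range(2, 8)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        fns = [stacked_fraction(n, FITTED) for n in range(2, 8)]
        assert all(a < b for a, b in zip(fns, fns[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            delta_g_stack(2, 0.0)
        with pytest.raises(ValueError):
            delta_g_stack(2, 1.0)

    @pytest.mark.parametrize("dgn, dg1, n, expected", [
        (-12.0, -6.0, 2, 0.0),
        (-10.0, -6.0, 2, 2.0),
        (-6.0, -6.0, 1, 0.0),
    ])
    def test_coupling_free_energy_arithmetic(self, dgn, dg1, n, expected):
        assert coupling_free_energy(dgn, dg1, n) == pytest.approx(expected)


def _multiplet_oracle(n, m, s, sig, mode):
    """Independent enumeration with explicit state tuples (itertools)."""
    total = 0.0
    acc = 0.0
    for states in product((0, 1), repeat=n - 1):
        full = (0,) + states
        w = 1.0
        for i in range(1, n):
            if full[i] == 1:
                w *= s
            elif i >= 2 and full[i - 1] == 0:
                w *= sig
        total += w
        hits = sum(1 for start in range(n - m + 1)
                   if all(v == 0 for v in full[start:start + m]))
        if mode == "window_fraction":
            acc += w * hits / (n - m + 1)
        else:
            acc += w * (hits > 0)
    return acc / total


class TestMultiplets:
    @pytest.mark.parametrize("mode", ["window_fraction", "any_run"])
    @pytest.mark.parametrize("n, m", [(4, 3), (5, 3), (6, 4), (4, 2)])
    def test_against_independent_enumeration(self, n, m, mode):
        got = unstacked_multiplet_fraction(n, m, FITTED, mode=mode)
        ref = _multiplet_oracle(n, m, FITTED.s, FITTED.sigma, mode)
        assert got == pytest.approx(ref, rel=1e-12)

    def test_limits(self):
        nearly_zero_s = HelixCoilParams(s=1e-9, sigma=0.76)
        huge_s = HelixCoilParams(s=9.99, sigma=0.76)
        for n, m in [(4, 2), (6, 3), (8, 5)]:
            assert unstacked_multiplet_fraction(n, m, nearly_zero_s) > 1 - 1e-6
        # the s -> inf limit is slowest for windows containing the first
        # unit (always unstacked), so test it on m >= 3 windows
        for n, m in [(4, 3), (6, 3), (8, 5)]:
            assert unstacked_multiplet_fraction(n, m, huge_s) < 0.02

    def test_domain(self):
        with pytest.raises(ValueError):
            unstacked_multiplet_fraction(3, 4, FITTED)
        with pytest.raises(ValueError):
            unstacked_multiplet_fraction(4, 3, FITTED, mode="bogus")


class TestSpecificHeat:
    def test_constant_mapping_gives_zero(self):
        T = np.linspace(200, 320, 61)
        C = specific_heat_curve(T, 6, lambda t: 0.455, lambda t: 0.76)
        assert np.max(np.abs(C)) < 1e-12

    def test_two_state_mapping_single_peak(self):
        # s = exp(-dG/kBT) with dG(T) = eps*(1 - T/T0): a single stacking
        # enthalpy eps < 0 gives one crossover (s = 1) at T0 and one C peak
        eps = -20.0  # kcal/mol
        T0 = 250.0

        def s_map(t):
            return math.exp((eps / KB_KCAL) * (1.0 / T0 - 1.0 / t))

        T = np.linspace(150, 350, 801)
        C = specific_heat_curve(T, 8, s_map, lambda t: 0.76)
        peaks = np.where((C[1:-1] > C[:-2]) & (C[1:-1] > C[2:])
                         & (C[1:-1] > 0.2 * C.max()))[0]
        assert len(peaks) == 1
        # the peak sits near the crossover temperature
        assert abs(T[peaks[0] + 1] - T0) < 15.0
        # numeric cross-check of U on a coarser grid (independent stencil)
        Tc = np.linspace(200, 300, 101)
        lnQ = np.array([math.log(partition_function(
            8, HelixCoilParams(s=s_map(t), sigma=0.76, temperature_K=t)))
            for t in Tc])
        U = KB_KCAL * Tc**2 * np.gradient(lnQ, Tc)
        C2 = np.gradient(U, Tc)
        C_interp = np.interp(Tc[5:-5], T, C)
        assert np.allclose(C2[5:-5], C_interp, rtol=0.05, atol=0.02 * C.max())

    def test_requires_mapping(self):
        with pytest.raises(ValueError):
            specific_heat_curve(np.linspace(200, 300, 11), 4, None, None)
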