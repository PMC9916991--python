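"""Core three-state kinetics: rates, propagation, steady states, eigenmodes."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cyblink import (
    EffectiveRates,
    ExcitationField,
    PhotokineticParameters,
    StatePopulations,
    effective_rates,
    photon_flux,
    populations_vs_time,
    rate_matrix,
    relaxation_modes,
    steady_state,
)
from cyblink.photokinetics import InvalidParametersError

from conftest import random_parameter_sets


class TestPhotonFlux:
    def test_zero_intensity(self):
        assert photon_flux(0.0, 638.0) == 0.0

    def test_hand_value_at_638nm(self):
        # E = h c / lambda = 3.114e-19 J; 1 kW/cm2 = 1000 W/cm2
        assert photon_flux(1.0, 638.0) == pytest.approx(3.21e21, rel=2e-3)

    def test_linearity(self):
        assert photon_flux(21.0, 638.0) == pytest.approx(
            21.0 * photon_flux(1.0, 638.0), rel=1e-14)

    @pytest.mark.parametrize("inten,wl", [(-1.0, 638.0), (1.0, 0.0),
                                          (1.0, -5.0)])
    def test_domain_errors(self, inten, wl):
        with pytest.raises(ValueError):
            photon_flux(inten, wl)


class TestEffectiveRates:
    def test_dark_limit(self, fcs_params):
        p = fcs_params.replace(k_th1=0.015, k_th2=0.08)
        r = effective_rates(p, 0.0)
        assert r.kiso1p == 0.0 and r.kiso2p == 0.0
        assert r.kbiso1p == p.k_th1 and r.kbiso2p == p.k_th2

    def test_printed_cross_sections_at_21kw(self, fcs_params):
        # hand oracle: sigma * photon_flux(21, 638) in us^-1,
        # kiso1' additionally scaled by kiso/k10N with k10N = 1/1ns - 36/us
        phi = photon_flux(21.0, 638.0)
        r = effective_rates(fcs_params, 21.0)
        assert r.kiso1p == pytest.approx(
            36.0 * 6.2e-16 * phi * 1e-6 / (1e3 - 36.0), rel=1e-12)
        assert r.kiso2p == pytest.approx(0.31e-16 * phi * 1e-6, rel=1e-12)
        assert r.kbiso1p == pytest.approx(0.25e-16 * phi * 1e-6, rel=1e-12)
        # magnitudes as expected: ~1.56, 2.09, 1.69 us^-1
        assert r.kiso1p == pytest.approx(1.56, abs=0.01)
        assert r.kiso2p == pytest.approx(2.09, abs=0.01)
        assert r.kbiso1p == pytest.approx(1.69, abs=0.01)

    def test_linearity_in_intensity(self, fcs_params):
        r1 = effective_rates(fcs_params, 10.0)
        r2 = effective_rates(fcs_params, 20.0)
        assert r2.kiso1p == pytest.approx(2 * r1.kiso1p, rel=1e-12)
        assert r2.kiso2p == pytest.approx(2 * r1.kiso2p, rel=1e-12)

    def test_saturation_reduces_pumping(self, fcs_params):
        lin = effective_rates(fcs_params, 100.0, saturation=False)
        sat = effective_rates(fcs_params, 100.0, saturation=True)
        assert sat.kiso1p < lin.kiso1p
        # identical in the weak-excitation limit
        lin0 = effective_rates(fcs_params, 0.1, saturation=False)
        sat0 = effective_rates(fcs_params, 0.1, saturation=True)
        assert sat0.kiso1p == pytest.approx(lin0.kiso1p, rel=0.05)

    def test_invalid_k10N_rejected(self):
        with pytest.raises(InvalidParametersError):
            PhotokineticParameters(kiso=1100.0, sigma_N=6e-16,
                                   sigma_biso1=0, sigma_iso2=0,
                                   sigma_biso2=0, tau_f=1.0)


class TestRateMatrix:
    def test_zero_rates(self):
        M = rate_matrix(EffectiveRates(0, 0, 0, 0))
        assert np.all(M == 0)

    def test_conservation_and_topology(self, fcs_params):
        M = rate_matrix(effective_rates(fcs_params, 21.0))
        assert np.allclose(M.sum(axis=0), 0.0, atol=1e-14)
        assert M[0, 2] == 0.0 and M[2, 0] == 0.0
        off = M[~np.eye(3, dtype=bool)]
        assert np.all(off >= 0)

    def test_eigenvalues_at_21kw(self, fcs_params):
        # characteristic-polynomial oracle: nonzero eigenvalues are roots
        # of x^2 + a x + b with a = k1+kb1+k2+kb2, b = k1k2+k1kb2+kb1kb2
        r = effective_rates(fcs_params, 21.0)
        a = r.kiso1p + r.kbiso1p + r.kiso2p + r.kbiso2p
        b = (r.kiso1p * r.kiso2p + r.kiso1p * r.kbiso2p
             + r.kbiso1p * r.kbiso2p)
        roots = np.roots([1.0, a, b])
        lam2, lam3, _ = relaxation_modes(fcs_params, 21.0)
        assert sorted([lam2, lam3]) == pytest.approx(sorted(roots), rel=1e-10)
        assert lam2 == pytest.approx(-1.62, abs=0.01)
        assert lam3 == pytest.approx(-5.41, abs=0.01)


class TestPopulationsVsTime:
    def test_initial_value(self, fcs_params):
        init = StatePopulations(0.5, 0.3, 0.2)
        p = populations_vs_time(fcs_params, 21.0, init, [0.0, 1.0])
        assert p[0] == pytest.approx(init.as_array(), abs=1e-14)

    def test_long_time_reaches_steady_state(self, fcs_params):
        lam2, _, _ = relaxation_modes(fcs_params, 21.0)
        t_long = 25.0 / abs(lam2)
        p = populations_vs_time(fcs_params, 21.0,
                                StatePopulations(1, 0, 0), [t_long])
        ss = steady_state(fcs_params, 21.0)
        assert p[0] == pytest.approx(ss.as_array(), abs=1e-8)

    def test_conservation_everywhere(self, fcs_params):
        t = np.logspace(-3, 3, 200)
        p = populations_vs_time(fcs_params, 21.0,
                                StatePopulations(1, 0, 0), t)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)

    def test_eigen_solution_matches_ode_oracle(self):
        """Eigen-decomposition equals adaptive RK integration to 1e-8."""
        t = np.logspace(-3, 2, 200)
        for i, params in enumerate(random_parameter_sets(100, seed=42)):
            inten = 0.5 + (i % 10) * 5.0
            M = rate_matrix(effective_rates(params, inten))
            p = populations_vs_time(params, inten,
                                    StatePopulations(1, 0, 0), t)
            sol = solve_ivp(lambda _t, y: M @ y, (0, t[-1]), [1.0, 0, 0],
                            t_eval=t, rtol=1e-10, atol=1e-12)
            assert np.max(np.abs(p - sol.y.T)) < 1e-8

    def test_two_state_reduction_closed_form(self, fcs_params):
        """With P2 decoupled, pN relaxes mono-exponentially."""
        p2off = fcs_params.replace(sigma_iso2=0.0, sigma_biso2=0.0,
                                   k_th2=0.0)
        r = effective_rates(p2off, 21.0)
        lam = r.kiso1p + r.kbiso1p
        pbar = r.kbiso1p / lam
        t = np.logspace(-3, 2, 100)
        p = populations_vs_time(p2off, 21.0, StatePopulations(1, 0, 0), t)
        expect = pbar + (1 - pbar) * np.exp(-lam * t)
        assert np.max(np.abs(p[:, 0] - expect)) < 1e-10
        assert np.all(p[:, 2] == pytest.approx(0.0, abs=1e-12))


class TestSteadyState:
    def test_dark_returns_all_trans(self, fcs_params):
        assert steady_state(fcs_params, 0.0).as_array() == pytest.approx(
            [1.0, 0.0, 0.0])

    def test_chain_ratio_oracle_at_21kw(self, fcs_params):
        r = effective_rates(fcs_params, 21.0)
        raw = np.array([1.0, r.kiso1p / r.kbiso1p,
                        (r.kiso1p / r.kbiso1p) * (r.kiso2p / r.kbiso2p)])
        ss = steady_state(fcs_params, 21.0)
        assert ss.as_array() == pytest.approx(raw / raw.sum(), rel=1e-12)
        assert ss.as_array() == pytest.approx([0.33, 0.30, 0.37], abs=0.01)

    def test_intensity_scale_invariance_without_thermal_rates(self,
                                                              fcs_params):
        a = steady_state(fcs_params, 3.0).as_array()
        b = steady_state(fcs_params, 90.0).as_array()
        assert a == pytest.approx(b, rel=1e-12)

    def test_thermal_rates_break_invariance(self, trast_params):
        a = steady_state(trast_params, 1.2).as_array()
        b = steady_state(trast_params, 4.7).as_array()
        assert abs(a[0] - b[0]) > 0.01


class TestRelaxationModes:
    def test_slow_time_near_0p6_us(self, fcs_params):
        lam2, lam3, _ = relaxation_modes(fcs_params, 21.0)
        assert abs(lam2) <= abs(lam3)
        assert lam2 < 0 and lam3 < 0
        assert 1.0 / abs(lam2) == pytest.approx(0.6, abs=0.05)

    def test_two_state_limit_single_mode(self, fcs_params):
        p2off = fcs_params.replace(sigma_iso2=0.0, sigma_biso2=0.0,
                                   k_th2=0.0)
        r = effective_rates(p2off, 21.0)
        lam2, lam3, _ = relaxation_modes(p2off, 21.0)
        lams = sorted([lam2, lam3], key=abs)
        # one vanishing mode (decoupled P2), one at -(k1+kb1)
        assert min(abs(lam2), abs(lam3)) < 1e-12
        assert max(abs(lam2), abs(lam3)) == pytest.approx(
            r.kiso1p + r.kbiso1p, rel=1e-10)

    def test_independent_of_Q(self, fcs_params):
        lam_a = relaxation_modes(fcs_params.replace(Q=0.0), 21.0)[:2]
        lam_b = relaxation_modes(fcs_params.replace(Q=0.9), 21.0)[:2]
        assert lam_a == pytest.approx(lam_b, rel=1e-14)


class TestSerialization:
    def test_json_round_trip(self, tmp_path, trast_params):
        f = tmp_path / "params.json"
        trast_params.to_json(f)
        back = PhotokineticParameters.from_json(f)
        assert back == trast_params


class TestExcitationField:
    def test_uniform_single_node(self):
        f = ExcitationField(mode="uniform", intensity=4.2, grid=64)
        intens, w = f.quadrature()
        assert intens.tolist() == [4.2] and w.tolist() == [1.0]

    def test_gaussian3d_single_node_equals_uniform(self, fcs_params):
        from cyblink import blinking_term_three_state
        lags = np.logspace(-3, 2, 50)
        g1 = blinking_term_three_state(
            fcs_params, ExcitationField(mode="gaussian3d", intensity=21.0,
                                        omega0=0.3, omegaz=2.0, grid=1),
            0.0, lags)
        g2 = blinking_term_three_state(
            fcs_params, ExcitationField(mode="uniform", intensity=21.0),
            0.0, lags)
        assert np.array_equal(g1, g2)

    def test_widefield_mean_below_peak(self):
        f = ExcitationField(mode="gaussian2d_widefield", intensity=4.7,
                            omega0=20.0, roi_radius=20.0, grid=64)
        intens, w = f.quadrature()
        mean = np.sum(intens * w) / np.sum(w)
        assert 0 < mean < 4.7
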