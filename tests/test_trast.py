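"""TRAST pulse response, pulse averaging, normalization, bleach correction,
and the global fit."""

import warnings

import numpy as np
import pytest
from scipy.integrate import quad

from cyblink import (
    ExcitationField,
    PulseTrain,
    bleach_correct,
    default_width_grid,
    effective_rates,
    fit_trast_global,
    pulse_average,
    pulse_fluorescence,
    steady_state,
    trast_curve,
)
from cyblink.synthetic import gen_trast_dataset
from cyblink.trast import DEFAULT_FIELD


@pytest.fixture(scope="module")
def uniform_47():
    return ExcitationField(mode="uniform", intensity=4.7)


class TestPulseTrain:
    def test_duty_cycle_guard_warns(self):
        with pytest.warns(UserWarning, match="duty"):
            PulseTrain(w=1.0, duty=0.5, n_pulses=10)

    def test_exposure_time(self):
        pt = PulseTrain(w=10.0, duty=0.01, n_pulses=100, t_ill=1.0)
        assert pt.t_exp == pytest.approx(100.0)  # ms

    def test_inconsistent_t_ill_rejected(self):
        with pytest.raises(ValueError):
            PulseTrain(w=10.0, duty=0.01, n_pulses=100, t_ill=5.0)


class TestPulseFluorescence:
    def test_starts_at_unity(self, trast_params, uniform_47):
        F = pulse_fluorescence(trast_params, uniform_47, 0.0, [0.0])
        assert F[0] == pytest.approx(1.0, abs=1e-12)

    def test_plateau_equals_steady_state_brightness(self, trast_params,
                                                    uniform_47):
        ss = steady_state(trast_params, 4.7)
        for q in (0.0, 0.28):
            F = pulse_fluorescence(trast_params, uniform_47, q, [1e5])
            assert F[0] == pytest.approx(ss.pN + q * ss.pP2, rel=1e-9)

    def test_monotone_decay_uniform(self, trast_params, uniform_47):
        t = np.logspace(-2, 3, 100)
        F = pulse_fluorescence(trast_params, uniform_47, 0.0, t)
        assert np.all(np.diff(F) < 1e-12)


class TestPulseAverage:
    def test_short_window_limit(self, trast_params, uniform_47):
        assert pulse_average(trast_params, uniform_47, 0.0,
                             1e-6) == pytest.approx(1.0, abs=1e-5)

    def test_long_window_limit(self, trast_params, uniform_47):
        ss = steady_state(trast_params, 4.7)
        assert pulse_average(trast_params, uniform_47, 0.0,
                             1e7) == pytest.approx(ss.pN, rel=1e-4)

    def test_closed_form_vs_numeric_quadrature(self, trast_params,
                                               uniform_47):
        """Eigen-expansion integral equals adaptive quadrature of F(t)."""
        for w in (0.5, 7.3, 120.0):
            cf = pulse_average(trast_params, uniform_47, 0.28, w)
            nq = quad(lambda t: pulse_fluorescence(
                trast_params, uniform_47, 0.28, [t])[0], 0, w,
                limit=300)[0] / w
            assert cf == pytest.approx(nq, abs=1e-9)

    def test_two_state_closed_form(self, trast_params, uniform_47):
        p = trast_params.replace(sigma_iso2=0.0, sigma_biso2=0.0, k_th2=0.0)
        r = effective_rates(p, 4.7)
        lam = r.kiso1p + r.kbiso1p
        nbar = r.kbiso1p / lam
        for w in (0.3, 3.0, 30.0):
            expect = nbar + (1 - nbar) * (1 - np.exp(-lam * w)) / (lam * w)
            assert pulse_average(p, uniform_47, 0.0, w) == pytest.approx(
                expect, rel=1e-10)


class TestTrastCurve:
    def test_normalized_at_w0(self, trast_params):
        widths = default_width_grid(20)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c = trast_curve(trast_params, DEFAULT_FIELD.at_intensity(4.7),
                            0.0, widths, w0=widths[0])
        assert c.f_norm[0] == pytest.approx(1.0, abs=1e-14)

    def test_flat_without_photodynamics(self):
        from cyblink import PhotokineticParameters
        dead = PhotokineticParameters(kiso=0.0, sigma_N=6.2e-16,
                                      sigma_biso1=0.0, sigma_iso2=0.0,
                                      sigma_biso2=0.0)
        c = trast_curve(dead, DEFAULT_FIELD.at_intensity(4.7), 0.0,
                        default_width_grid(15))
        assert c.f_norm == pytest.approx(np.ones(15), abs=1e-12)

    def test_monotone_decay(self, trast_params):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c = trast_curve(trast_params, DEFAULT_FIELD.at_intensity(4.7),
                            0.0, default_width_grid())
        assert np.all(np.diff(c.f_norm) < 1e-12)

    def test_amplitude_decreases_with_filter_q(self, trast_params):
        amps = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for q in (0.0, 0.28, 0.6, 1.0):
                c = trast_curve(trast_params,
                                DEFAULT_FIELD.at_intensity(4.7), q,
                                default_width_grid(15))
                amps.append(1.0 - c.f_norm[-1])
        assert np.all(np.diff(amps) < 0)

    def test_thermal_rates_reduce_amplitude_at_low_intensity(self,
                                                             trast_params):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            amp = [1.0 - trast_curve(trast_params,
                                     DEFAULT_FIELD.at_intensity(i), 0.0,
                                     default_width_grid(15)).f_norm[-1]
                   for i in (4.7, 1.2)]
        assert amp[1] < amp[0]

    def test_w0_exceeding_min_width_rejected(self, trast_params):
        with pytest.raises(ValueError):
            trast_curve(trast_params, DEFAULT_FIELD.at_intensity(4.7), 0.0,
                        [1.0, 10.0], w0=2.0)

    def test_buildup_warning_recorded(self, trast_params):
        with pytest.warns(UserWarning, match="build-up"):
            c = trast_curve(trast_params, DEFAULT_FIELD.at_intensity(50.0),
                            0.0, [10.0, 100.0], w0=10.0)
        assert c.meta


class TestBleachCorrect:
    def test_constant_references_identity(self):
        frames = np.array([3.0, 2.0, 1.5])
        out = bleach_correct(frames, [5.0, 5.0], [1, 2, 3], [0, 4])
        assert out == pytest.approx(frames)

    def test_linear_decay_recovered(self):
        # constant true signal bleached linearly by 8% end to end
        ref_pos = np.array([0.0, 10.0])
        refs = np.array([1.0, 0.92])
        frame_pos = np.linspace(1, 9, 5)
        bleach = np.interp(frame_pos, ref_pos, refs)
        frames = 7.0 * bleach
        out = bleach_correct(frames, refs, frame_pos, ref_pos)
        assert out == pytest.approx(7.0 * np.ones(5), abs=1e-9)

    def test_randomized_trace_within_interpolation_error(self):
        rng = np.random.default_rng(7)
        ref_pos = np.arange(0, 41, 4)
        true_bleach = np.exp(-0.002 * np.arange(41))
        refs = true_bleach[ref_pos]
        frame_pos = np.arange(41)
        frames = 5.0 * true_bleach * (1 + 0.0 * rng.standard_normal(41))
        out = bleach_correct(frames, refs, frame_pos, ref_pos)
        # piecewise-linear interp of a smooth exponential: tiny residual
        assert np.max(np.abs(out / 5.0 - 1.0)) < 1e-4

    def test_excessive_bleaching_warns(self):
        with pytest.warns(UserWarning, match="bleach"):
            bleach_correct([1.0], [1.0, 0.7], [1], [0, 2])

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            bleach_correct([1.0], [1.0, 0.0], [1], [0, 2])


class TestFitTrastGlobal:
    def test_noiseless_self_consistency(self, trast_params):
        curves, _ = gen_trast_dataset(trast_params, noise_scale=0.0, seed=0)
        res = fit_trast_global(curves, seed=0)
        assert res.success
        truth = {"kiso": 33.0, "sigma_biso1": 0.26e-16,
                 "sigma_iso2": 0.30e-16, "sigma_biso2": 0.25e-16,
                 "k_th1": 0.015, "k_th2": 0.08, "Q": 0.28}
        for k, v in truth.items():
            assert res.params[k] == pytest.approx(v, rel=1e-3), k
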