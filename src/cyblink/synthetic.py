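"""Seeded synthetic datasets with recorded ground truth.

Every generator is a pure function of its configuration and an integer
seed: the same call reproduces the same dataset bit for bit.  Per-curve
randomness is drawn from independent child generators keyed by
``(seed, curve index)``, so adding or reordering curves does not perturb
the others.  Each generator returns the dataset together with a
:class:`GroundTruthBundle` holding the kinetic parameters and all nuisance
values needed to reproduce or score a recovery experiment.

Noise models (the package's own conventions, stated in docs/methods.md):

* FCS: heteroscedastic Gaussian noise with standard deviation
  ``noise_scale * (G - 1 + 1/Nm) / sqrt(dtau * T)`` (dtau the local lag-bin
  width, T a fixed 60 s acquisition proxy) — the standard shape in which
  FCS noise shrinks with lag-bin averaging;
* TRAST: additive Gaussian noise, SD = ``noise_scale * f_norm``, plus an
  optional exponential bleaching trace correctable by
  :func:`~cyblink.trast.bleach_correct`;
* spectra and decays: Poisson shot noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .fcs import (
    FcsCurve,
    FcsDiffusionParams,
    default_lag_grid,
    fcs_curve_three_state,
)
from .photokinetics import (
    ExcitationField,
    PhotokineticParameters,
    effective_rates,
    rate_matrix,
)
from .spectral import EmissionSpectrumSet
from .tcspc import (
    DEFAULT_BIN_NS,
    DEFAULT_WINDOW_NS,
    DecayHistogram,
    DecayModel,
    decay_model_counts,
)
from .trast import DEFAULT_FIELD, TrastCurve, default_width_grid, trast_curve

__all__ = [
    "GroundTruthBundle",
    "FCS_DEFAULT_INTENSITIES",
    "TRAST_DEFAULT_INTENSITIES",
    "gen_fcs_dataset",
    "gen_trast_dataset",
    "gen_spectra_dataset",
    "gen_decay_dataset",
    "nbar_basis",
    "p2_basis",
]

#: Irradiance ladder for synthetic FCS sets, kW/cm^2: a doubling ladder
#: around the printed 21 kW/cm^2 mean, inside the >= 4 kW/cm^2 regime where
#: thermal back-isomerization is negligible.
FCS_DEFAULT_INTENSITIES = (5.25, 10.5, 21.0, 42.0)

#: Irradiance ladder for synthetic TRAST sets, kW/cm^2 (the calculated
#: population-evolution series).
TRAST_DEFAULT_INTENSITIES = (1.2, 2.4, 3.6, 4.7)

#: Acquisition-time proxy entering the FCS noise shape, us.
FCS_DURATION_PROXY_US = 6e7


@dataclass(frozen=True)
class GroundTruthBundle:
    """Everything needed to reproduce and score a synthetic dataset."""

    params: PhotokineticParameters
    nuisance: dict = dc_field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        def clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, dict):
                return {k: clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [clean(x) for x in v]
            return v
        return {"params": self.params.to_dict(),
                "nuisance": clean(self.nuisance), "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthBundle":
        return cls(PhotokineticParameters.from_dict(d["params"]),
                   d.get("nuisance", {}), d.get("seed", 0))


def _child_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, index)))


def gen_fcs_dataset(truth: PhotokineticParameters,
                    intensities=FCS_DEFAULT_INTENSITIES,
                    filters: dict | None = None, noise_scale: float = 1.0,
                    seed: int = 0, n_mean: float = 1.0,
                    tau_d: float = 100.0, lags=None):
    """Two-filter, multi-irradiance synthetic FCS curve set.

    ``filters`` maps filter id to the P2 relative brightness in that band
    (default ``{"B": 0.0, "R": truth.Q}``).  Returns ``(curves, bundle)``.
    """
    if filters is None:
        filters = {"B": 0.0, "R": truth.Q}
    lags = default_lag_grid() if lags is None else np.asarray(lags, float)
    dtau = np.gradient(lags)
    diff = FcsDiffusionParams(n_mean, tau_d)
    curves = []
    idx = 0
    for fid, fq in filters.items():
        for inten in intensities:
            field = ExcitationField(mode="uniform", intensity=float(inten))
            clean = fcs_curve_three_state(truth, field, fq, diff, lags,
                                          filter_id=fid)
            sd = noise_scale * (clean.g - 1.0 + 1.0 / n_mean) / np.sqrt(
                dtau * FCS_DURATION_PROXY_US)
            g = clean.g + _child_rng(seed, idx).normal(0.0, 1.0,
                                                       lags.size) * sd
            curves.append(FcsCurve(lags=lags, g=g, intensity=float(inten),
                                   filter_id=fid, sd=sd,
                                   n_molecules_hint=n_mean))
            idx += 1
    bundle = GroundTruthBundle(truth, {
        "n_mean": n_mean, "tau_d": tau_d, "noise_scale": noise_scale,
        "intensities": list(intensities), "filters": dict(filters)}, seed)
    return curves, bundle


def gen_trast_dataset(truth: PhotokineticParameters,
                      intensities=TRAST_DEFAULT_INTENSITIES,
                      filters: dict | None = None, noise_scale: float = 0.01,
                      seed: int = 0, widths=None, w0: float = 0.1,
                      field: ExcitationField | None = None,
                      bleach_loss: float = 0.0):
    """Two-filter, multi-irradiance synthetic TRAST curve set.

    Forward curves use the wide-field disc-averaged geometry by default.
    ``bleach_loss`` > 0 additionally applies an exponential bleaching trace
    of that total relative loss across the acquisition sequence (stored in
    the bundle so tests can undo it with ``bleach_correct``).
    Returns ``(curves, bundle)``.
    """
    if filters is None:
        filters = {"B": 0.0, "R": truth.Q}
    widths = default_width_grid() if widths is None else np.asarray(
        widths, float)
    base = DEFAULT_FIELD if field is None else field
    curves = []
    idx = 0
    import warnings as _w
    for fid, fq in filters.items():
        for inten in intensities:
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                clean = trast_curve(truth, base.at_intensity(float(inten)),
                                    fq, widths, w0=w0)
            f = clean.f_norm.copy()
            if bleach_loss > 0:
                decay = np.exp(np.log(1 - bleach_loss) *
                               np.arange(widths.size) / (widths.size - 1))
                f = f * decay
            sd = noise_scale * clean.f_norm
            f = f + _child_rng(seed, idx).normal(0.0, 1.0, widths.size) * sd
            curves.append(TrastCurve(widths=widths, f_norm=f,
                                     intensity=float(inten), filter_id=fid,
                                     w0=w0, sd=sd))
            idx += 1
    bundle = GroundTruthBundle(truth, {
        "noise_scale": noise_scale, "intensities": list(intensities),
        "filters": dict(filters), "w0": w0, "bleach_loss": bleach_loss,
        "field_mode": base.mode}, seed)
    return curves, bundle


def nbar_basis(wavelengths, peak: float = 670.0,
               width: float = 0.04) -> np.ndarray:
    """Log-normal emission basis of the all-trans state N (peak 670 nm).

    The width (sigma of log-wavelength, default 0.04 ~ 63 nm FWHM) stands
    in for the full asymmetric Cy5 emission band including its red
    vibronic shoulder, so that the 690-750 nm window retains a dominant N
    contribution as it does experimentally.
    """
    wl = np.asarray(wavelengths, dtype=float)
    return np.exp(-np.log(wl / peak) ** 2 / (2 * width**2))


def p2_basis(wavelengths, peak: float = 710.0,
             width: float = 0.044) -> np.ndarray:
    """Red-shifted emission basis of P2 (default +40 nm, 10% broader)."""
    return nbar_basis(wavelengths, peak, width)


def _average_populations(params, intensity, widths):
    """Pulse-averaged populations <p>_w, shape (n_widths, 3); p(0)=(1,0,0)."""
    M = rate_matrix(effective_rates(params, intensity))
    ev, V = np.linalg.eig(M)
    c = np.linalg.solve(V, np.array([1.0, 0.0, 0.0], dtype=complex))
    x = np.outer(np.asarray(widths, float), ev)
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(np.abs(x) < 1e-12, 1.0,
                       np.expm1(x) / np.where(x == 0, 1.0, x))
    return np.real(avg * c[None, :] @ V.T)


def gen_spectra_dataset(truth: PhotokineticParameters, widths=None,
                        seed: int = 0, intensity: float = 3.9,
                        duty: float = 0.002, wavelengths=None,
                        q_scale: float | None = None,
                        peak_counts: float = 1e5):
    """Pulse-width-resolved emission spectra with Poisson shot noise.

    The noiseless spectrum is a two-component mixture
    ``S(lambda, w) = <pN>_w B_N(lambda) + q_scale <pP2>_w B_P2(lambda)``
    with log-normal bases peaking at 670 nm (N) and 710 nm (P2) and
    ``q_scale`` the relative P2 brightness (default ``truth.Q``).  Scaled
    so the shortest-width spectrum peaks at ``peak_counts`` expected
    counts.  Returns ``(EmissionSpectrumSet, bundle)``.
    """
    widths = (default_width_grid(12) if widths is None
              else np.asarray(widths, float))
    wavelengths = (np.arange(630.0, 800.0 + 1e-9, 1.0) if wavelengths is None
                   else np.asarray(wavelengths, float))
    if q_scale is None:
        q_scale = truth.Q
    pops = _average_populations(truth, intensity, widths)
    bn, bp = nbar_basis(wavelengths), p2_basis(wavelengths)
    clean = pops[:, [0]] * bn[None, :] + q_scale * pops[:, [2]] * bp[None, :]
    scale = peak_counts / clean[np.argmin(widths)].max()
    rng = _child_rng(seed, 0)
    spectra = rng.poisson(clean * scale).astype(float)
    sset = EmissionSpectrumSet(wavelengths=wavelengths, spectra=spectra,
                               widths=widths, intensity=intensity, duty=duty)
    bundle = GroundTruthBundle(truth, {
        "q_scale": q_scale, "intensity": intensity, "duty": duty,
        "peak_counts": peak_counts, "clean_scaled": clean * scale}, seed)
    return sset, bundle


def gen_decay_dataset(model: DecayModel, irf_fwhm: float = 0.2,
                      total_counts: float = 1e6, seed: int = 0,
                      bin_ns: float = DEFAULT_BIN_NS,
                      window_ns: float = DEFAULT_WINDOW_NS,
                      irf_t0: float = 2.0, background_rate: float = 0.0):
    """Poisson-sampled reconvolved decay histogram.

    The IRF is a noise-free Gaussian of FWHM ``irf_fwhm`` ns centered at
    ``irf_t0`` ns, scaled to 1e6 counts.  Expected decay counts are the
    IRF-convolved model scaled to ``total_counts`` plus a flat background
    of ``background_rate`` counts/bin, then Poisson sampled.
    Returns ``(DecayHistogram, bundle)``.
    """
    t = np.arange(0.0, window_ns, bin_ns)
    s = irf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    irf = np.exp(-0.5 * ((t - irf_t0) / s) ** 2)
    irf = irf / irf.sum() * 1e6
    base = DecayModel(model.lifetimes, model.amplitudes, 0.0,
                      background_rate)
    expected = decay_model_counts(t, irf, base, 1.0)
    expected *= (total_counts - background_rate * t.size) / (
        expected.sum() - background_rate * t.size)
    rng = _child_rng(seed, 0)
    counts = rng.poisson(np.maximum(expected, 0.0)).astype(float)
    h = DecayHistogram(bin_times=t, counts=counts, irf=irf)
    bundle = GroundTruthBundle(
        PhotokineticParameters(kiso=0.0, sigma_N=0.0, sigma_biso1=0.0,
                               sigma_iso2=0.0, sigma_biso2=0.0,
                               tau_f=model.lifetimes[0]),
        {"model": {"lifetimes": list(model.lifetimes),
                   "amplitudes": list(model.amplitudes)},
         "irf_fwhm": irf_fwhm, "total_counts": total_counts,
         "background_rate": background_rate}, seed)
    return h, bundle
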