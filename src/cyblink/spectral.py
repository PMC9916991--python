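"""Spectral-TRAST: pulse-width-resolved emission spectra and band analysis.

Recording an emission spectrum for each pulse width w of a TRAST-style
pulse train turns one spectrofluorometric series into many wavelength-
resolved TRAST curves.  With a red-shifted second emissive state (P2), the
spectrum red-shifts as w grows: the N contribution decays with dark-state
build-up while P2 partially replaces it at longer wavelengths.  Band-
integrated intensities, normalized to the shortest pulse, then show decay
amplitudes that shrink with the redness of the band.

Operations: correction for the wavelength-dependent detector/grating
efficiency, the two normalization conventions used for display (all
spectra against the shortest-w peak, or each against its own peak), and
trapezoidal band integration into per-band :class:`~cyblink.trast.TrastCurve`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .trast import TrastCurve

__all__ = [
    "EmissionSpectrumSet",
    "detector_correct",
    "normalize_modes",
    "band_trast_curves",
]


@dataclass(frozen=True)
class EmissionSpectrumSet:
    """Emission spectra indexed by excitation pulse width.

    ``spectra[i]`` is the intensity vector on ``wavelengths`` recorded with
    pulse width ``widths[i]`` (us).  ``intensity`` is the in-pulse
    irradiance (kW/cm^2) and ``duty`` the pulse-train duty cycle.
    """

    wavelengths: np.ndarray     # nm, strictly increasing
    spectra: np.ndarray         # (n_widths, n_wavelengths)
    widths: np.ndarray          # us
    intensity: float = 0.0
    duty: float = 0.002

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        sp = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        w = np.asarray(self.widths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "spectra", sp)
        object.__setattr__(self, "widths", w)
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if sp.shape != (w.size, wl.size):
            raise ValueError("spectra must have shape (n_widths, n_wavelengths)")

    def with_spectra(self, spectra) -> "EmissionSpectrumSet":
        return replace(self, spectra=np.asarray(spectra, dtype=float))


def detector_correct(raw: EmissionSpectrumSet, response) -> EmissionSpectrumSet:
    """Divide out the wavelength detection-efficiency function.

    ``response`` is a callable (nm -> efficiency) or a vector on the set's
    wavelength grid; it must be strictly positive on the support.
    """
    if callable(response):
        resp = np.asarray(response(raw.wavelengths), dtype=float)
    else:
        resp = np.asarray(response, dtype=float)
    if resp.shape != raw.wavelengths.shape:
        raise ValueError("response must match the wavelength grid")
    if np.any(resp <= 0):
        raise ValueError("detector response must be > 0 on the support")
    return raw.with_spectra(raw.spectra / resp[None, :])


def normalize_modes(sset: EmissionSpectrumSet,
                    mode: str = "global_ref") -> EmissionSpectrumSet:
    """Normalize spectra for display.

    ``global_ref``: divide every spectrum by the maximum of the shortest-w
    spectrum (absolute bleed-off visible).  ``per_curve_peak``: divide each
    spectrum by its own maximum (shape changes visible; every peak = 1).
    """
    sp = sset.spectra
    order = np.argsort(sset.widths)
    if mode == "global_ref":
        ref = sp[order[0]].max()
        if ref <= 0:
            raise ValueError("reference spectrum has non-positive maximum")
        return sset.with_spectra(sp / ref)
    if mode == "per_curve_peak":
        peaks = sp.max(axis=1, keepdims=True)
        if np.any(peaks <= 0):
            raise ValueError("all-zero spectrum cannot be peak-normalized")
        return sset.with_spectra(sp / peaks)
    raise ValueError(f"unknown normalization mode {mode!r}")


def _band_integral(wl, spectrum, lo, hi):
    """Trapezoidal integral over the grid points in [lo, hi].

    Both edges are inclusive, so adjacent bands sharing an edge point are
    exactly additive (the shared node contributes area to neither side
    twice).  A degenerate single-point band returns the pointwise value.
    """
    mask = (wl >= lo) & (wl <= hi)
    if not np.any(mask):
        raise ValueError(f"empty band [{lo}, {hi}] nm")
    if mask.sum() == 1:
        return float(spectrum[mask][0])
    return float(np.trapezoid(spectrum[mask], wl[mask]))


def band_trast_curves(sset: EmissionSpectrumSet, bands) -> list[TrastCurve]:
    """Integrate each spectral band into a TRAST curve over pulse width.

    ``bands`` is a list of (lambda_lo, lambda_hi) in nm.  For each band the
    trapezoidal integral per width is divided by the integral at the
    shortest width, so f_norm(min w) = 1.  The input must be detector-
    corrected but *not* peak-normalized.
    """
    order = np.argsort(sset.widths)
    widths = sset.widths[order]
    out = []
    for lo, hi in bands:
        vals = np.array([_band_integral(sset.wavelengths, sset.spectra[i],
                                        lo, hi) for i in order])
        if vals[0] <= 0:
            raise ValueError(f"non-positive reference integral in band "
                             f"[{lo}, {hi}) nm")
        out.append(TrastCurve(widths=widths, f_norm=vals / vals[0],
                              intensity=sset.intensity, w0=float(widths[0]),
                              filter_id=f"{lo:g}-{hi:g}nm"))
    return out
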