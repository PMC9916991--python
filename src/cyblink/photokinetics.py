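"""Three-state trans/cis photoisomerization kinetics of Cy5.

The model lumps the dye into three conformers: the all-trans ground form N
(emissive), a mono-cis form P1 (dark) and a double-cis form P2 (emissive,
red-shifted).  Transitions follow the chain N <-> P1 <-> P2; there is no
direct N <-> P2 pathway.  Because the singlet ground/excited equilibration
within each conformer is orders of magnitude faster (ns) than isomerization
(us), each conformer is treated as a single lumped state driven by
*effective* rates:

    k_iso1' = kiso * sigmaN * Phi / k10N      (N  -> P1, photo-driven)
    k_biso1' = sigma_biso1 * Phi + k_th1      (P1 -> N)
    k_iso2' = sigma_iso2 * Phi                (P1 -> P2)
    k_biso2' = sigma_biso2 * Phi + k_th2      (P2 -> P1)

where Phi is the excitation photon flux (photons cm^-2 s^-1), kiso the
excited-state isomerization rate of N, k10N = 1/tau_f - kiso the remaining
S1 deactivation rate of N, and k_th1/k_th2 thermal back-isomerization rates
active without light.

Internal unit convention: times in microseconds, rates in us^-1, cross
sections in cm^2, irradiance in kW/cm^2, wavelengths in nm.  Conversion to
photon flux happens only in :func:`photon_flux`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
import json

import numpy as np
from scipy.linalg import expm

__all__ = [
    "PLANCK_J_S",
    "SPEED_OF_LIGHT_M_S",
    "PhotokineticParameters",
    "ExcitationField",
    "StatePopulations",
    "EffectiveRates",
    "FCS_FIT_PARAMS",
    "TRAST_FIT_PARAMS",
    "photon_flux",
    "effective_rates",
    "rate_matrix",
    "populations_vs_time",
    "steady_state",
    "relaxation_modes",
]

PLANCK_J_S = 6.62607015e-34
SPEED_OF_LIGHT_M_S = 2.99792458e8

# Relative gap below which the two relaxation eigenvalues are treated as
# degenerate and propagation falls back to a dense matrix exponential.
_DEGENERACY_RTOL = 1e-9


class InvalidParametersError(ValueError):
    """Raised when a kinetic parameter set violates its physical invariants."""


@dataclass(frozen=True)
class PhotokineticParameters:
    """Rate/cross-section set of the three-state isomerization model.

    Parameters
    ----------
    kiso : float
        S1 isomerization rate of N, us^-1.
    sigma_N : float
        Excitation cross section of N at ``wavelength``, cm^2.
    sigma_biso1 : float
        P1 -> N back-isomerization cross section, cm^2.
    sigma_iso2 : float
        P1 -> P2 isomerization cross section, cm^2.
    sigma_biso2 : float
        P2 -> P1 back-isomerization cross section, cm^2.
    k_th1, k_th2 : float
        Thermal back-isomerization rates P1->N and P2->P1, us^-1.
    tau_f : float
        Excited-state lifetime of N, ns.
    Q : float
        Detected brightness of P2 relative to N (band dependent);
        Q = 0 encodes a detection band in which P2 is invisible.
    wavelength : float
        Excitation wavelength, nm.
    """

    kiso: float
    sigma_N: float
    sigma_biso1: float
    sigma_iso2: float
    sigma_biso2: float
    k_th1: float = 0.0
    k_th2: float = 0.0
    tau_f: float = 1.0
    Q: float = 0.0
    wavelength: float = 638.0

    def __post_init__(self) -> None:
        for name in ("kiso", "sigma_N", "sigma_biso1", "sigma_iso2",
                     "sigma_biso2", "k_th1", "k_th2", "Q"):
            if getattr(self, name) < 0:
                raise InvalidParametersError(f"{name} must be >= 0")
        if self.tau_f <= 0:
            raise InvalidParametersError("tau_f must be > 0")
        if self.wavelength <= 0:
            raise InvalidParametersError("wavelength must be > 0")
        if self.k10N <= 0:
            raise InvalidParametersError(
                "k10N = 1/tau_f - kiso must be > 0 "
                f"(got {self.k10N:g} us^-1)")

    @property
    def k10N(self) -> float:
        """S1 deactivation rate of N excluding isomerization, us^-1."""
        return 1e3 / self.tau_f - self.kiso

    def replace(self, **changes) -> "PhotokineticParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhotokineticParameters":
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PhotokineticParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


#: Global FCS-fit parameter set (638 nm, thermal rates fixed to zero).
FCS_FIT_PARAMS = PhotokineticParameters(
    kiso=36.0, sigma_N=6.2e-16, sigma_biso1=0.25e-16, sigma_iso2=0.31e-16,
    sigma_biso2=0.25e-16, k_th1=0.0, k_th2=0.0, tau_f=1.0, Q=0.46,
    wavelength=638.0)

#: Global TRAST-fit parameter set (638 nm, thermal rates free).
TRAST_FIT_PARAMS = PhotokineticParameters(
    kiso=33.0, sigma_N=6.2e-16, sigma_biso1=0.26e-16, sigma_iso2=0.30e-16,
    sigma_biso2=0.25e-16, k_th1=0.015, k_th2=0.08, tau_f=1.0, Q=0.28,
    wavelength=638.0)


@dataclass(frozen=True)
class StatePopulations:
    """Occupation probabilities of N, P1, P2 (each lumping S0+S1)."""

    pN: float
    pP1: float
    pP2: float

    def __post_init__(self) -> None:
        vec = self.as_array()
        if np.any(vec < -1e-12) or np.any(vec > 1 + 1e-12):
            raise ValueError(f"populations outside [0,1]: {vec}")
        if abs(vec.sum() - 1.0) > 1e-9:
            raise ValueError(f"populations must sum to 1, got {vec.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.pN, self.pP1, self.pP2], dtype=float)

    @classmethod
    def from_array(cls, v) -> "StatePopulations":
        v = np.asarray(v, dtype=float)
        return cls(float(v[0]), float(v[1]), float(v[2]))


@dataclass(frozen=True)
class EffectiveRates:
    """Effective light-driven rates of the N <-> P1 <-> P2 chain, us^-1."""

    kiso1p: float
    kbiso1p: float
    kiso2p: float
    kbiso2p: float

    def __post_init__(self) -> None:
        for name in ("kiso1p", "kbiso1p", "kiso2p", "kbiso2p"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ExcitationField:
    """Spatial excitation profile with a quadrature over the detection region.

    ``uniform`` is a single node at ``intensity``.  ``gaussian3d`` is the
    confocal 3-D Gaussian profile with lateral/axial 1/e^2 radii
    ``omega0``/``omegaz`` sampled on a Gauss-Legendre grid in cylindrical
    coordinates.  ``gaussian2d_widefield`` is a 2-D Gaussian beam in the
    sample plane averaged over a detection disc of radius ``roi_radius``.
    """

    mode: str = "uniform"
    intensity: float = 1.0          # kW/cm^2 (peak for gaussian modes)
    omega0: float = 20.0            # um
    omegaz: float = 136.0           # um (gaussian3d only)
    roi_radius: float = 20.0        # um (widefield only)
    grid: int = 32

    def __post_init__(self) -> None:
        if self.mode not in ("uniform", "gaussian3d", "gaussian2d_widefield"):
            raise ValueError(f"unknown field mode {self.mode!r}")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        if self.omega0 <= 0 or self.omegaz <= 0 or self.roi_radius <= 0:
            raise ValueError("field radii must be > 0")
        if self.grid < 1:
            raise ValueError("grid must be >= 1")

    def quadrature(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (local irradiances kW/cm^2, volume weights).

        Weights are plain quadrature volume elements; any brightness
        weighting (linear or squared in the local excitation rate) is
        applied by the caller.  ``uniform`` returns exactly one node so
        that uniform-field results are bit-reproducible closed forms.
        """
        if self.mode == "uniform" or self.grid == 1:
            return (np.array([self.intensity]), np.array([1.0]))
        if self.mode == "gaussian3d":
            xr, wr = np.polynomial.legendre.leggauss(self.grid)
            r = 0.5 * 3 * self.omega0 * (xr + 1.0)
            wr = wr * 0.5 * 3 * self.omega0
            xz, wz = np.polynomial.legendre.leggauss(self.grid)
            z = 0.5 * 3 * self.omegaz * (xz + 1.0)
            wz = wz * 0.5 * 3 * self.omegaz
            rr, zz = np.meshgrid(r, z, indexing="ij")
            ww = np.outer(wr * r, wz)   # cylindrical volume element r dr dz
            intens = self.intensity * np.exp(
                -2 * (rr / self.omega0) ** 2 - 2 * (zz / self.omegaz) ** 2)
            return intens.ravel(), ww.ravel()
        # gaussian2d_widefield: radial quadrature over the detection disc
        xr, wr = np.polynomial.legendre.leggauss(self.grid)
        r = 0.5 * self.roi_radius * (xr + 1.0)
        wr = wr * 0.5 * self.roi_radius * r      # area element r dr
        intens = self.intensity * np.exp(-2 * (r / self.omega0) ** 2)
        return intens, wr

    def at_intensity(self, intensity: float) -> "ExcitationField":
        return replace(self, intensity=intensity)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def photon_flux(intensity: float, wavelength: float) -> float:
    """Convert irradiance (kW/cm^2) to photon flux (photons cm^-2 s^-1).

    ``flux = I / (h*c/lambda)`` with I in W/cm^2.
    """
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity < 0):
        raise ValueError("intensity must be >= 0")
    if wavelength <= 0:
        raise ValueError("wavelength must be > 0")
    photon_energy = PLANCK_J_S * SPEED_OF_LIGHT_M_S / (wavelength * 1e-9)
    out = intensity * 1e3 / photon_energy
    return float(out) if out.ndim == 0 else out


def effective_rates(params: PhotokineticParameters, intensity: float,
                    saturation: bool = False) -> EffectiveRates:
    """Effective chain rates at an irradiance (kW/cm^2), us^-1.

    With ``saturation=False`` the N->P1 rate is linear in the excitation
    rate, kiso * sigmaN*Phi / k10N; with ``saturation=True`` the excitation
    factor saturates as sigmaN*Phi / (sigmaN*Phi + k10N), relevant above
    ~100 kW/cm^2 where the S1 population of N is no longer negligible.
    """
    phi = photon_flux(intensity, params.wavelength)
    k_exc = params.sigma_N * phi * 1e-6          # us^-1
    k10N = params.k10N
    if saturation:
        factor = k_exc / (k_exc + k10N)
    else:
        factor = k_exc / k10N
    return EffectiveRates(
        kiso1p=params.kiso * factor,
        kbiso1p=params.sigma_biso1 * phi * 1e-6 + params.k_th1,
        kiso2p=params.sigma_iso2 * phi * 1e-6,
        kbiso2p=params.sigma_biso2 * phi * 1e-6 + params.k_th2,
    )


def rate_matrix(rates: EffectiveRates) -> np.ndarray:
    """3x3 generator M of dp/dt = M p for state order (N, P1, P2).

    Columns sum to zero (probability conservation) and the N<->P2 entries
    are structurally zero (no direct pathway).
    """
    k1, kb1 = rates.kiso1p, rates.kbiso1p
    k2, kb2 = rates.kiso2p, rates.kbiso2p
    return np.array([
        [-k1,        kb1,        0.0],
        [k1,  -(kb1 + k2),       kb2],
        [0.0,         k2,       -kb2],
    ])


def _rate_matrices(params, intensities, saturation=False) -> np.ndarray:
    """Stack of rate matrices for an array of irradiances, shape (n,3,3)."""
    intensities = np.atleast_1d(np.asarray(intensities, dtype=float))
    out = np.empty((intensities.size, 3, 3))
    for i, inten in enumerate(intensities):
        out[i] = rate_matrix(effective_rates(params, inten, saturation))
    return out


def _propagate(M: np.ndarray, p0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Solve dp/dt = M p by eigen-decomposition; batched over leading axis.

    M : (n,3,3), p0 : (n,3), times : (m,) in us  ->  populations (n,m,3).
    Falls back to scaling-and-squaring expm when the two relaxation
    eigenvalues are (near-)degenerate.
    """
    times = np.asarray(times, dtype=float)
    evals, evecs = np.linalg.eig(M)
    # a conservative generator has one exactly-zero eigenvalue and none
    # with positive real part; snap numerical +/-eps to 0 so exp(lam*t)
    # neither overflows nor spuriously kills the stationary mode at
    # asymptotic times
    scale = np.max(np.abs(evals), axis=1, keepdims=True)
    evals = np.where(np.abs(evals) < 1e-10 * np.maximum(scale, 1e-300),
                     0.0, evals)
    evals = np.where(evals.real > 0, 1j * evals.imag, evals)
    out = np.empty((M.shape[0], times.size, 3))
    for i in range(M.shape[0]):
        w, V = evals[i], evecs[i]
        nz = np.sort(np.abs(w))
        degenerate = nz[2] > 0 and (nz[2] - nz[1]) < _DEGENERACY_RTOL * nz[2]
        if degenerate or np.linalg.cond(V) > 1e12:
            for j, t in enumerate(times):
                out[i, j] = expm(M[i] * t) @ p0[i]
            continue
        c = np.linalg.solve(V, p0[i].astype(complex))
        ph = np.exp(np.outer(times, w))              # (m,3)
        out[i] = np.real(ph * c[None, :] @ V.T)
    return out


def populations_vs_time(params: PhotokineticParameters, intensity: float,
                        init: StatePopulations, times,
                        saturation: bool = False) -> np.ndarray:
    """Populations (pN, pP1, pP2) on a time grid (us) after excitation onset.

    Returns an array of shape ``(len(times), 3)``; row sums are 1 to
    numerical precision and the row at t=0 equals ``init``.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    M = _rate_matrices(params, intensity, saturation)
    p0 = init.as_array()[None, :]
    pops = _propagate(M, p0, times)[0]
    return np.clip(pops, 0.0, 1.0) / np.clip(pops, 0.0, 1.0).sum(
        axis=1, keepdims=True)


def steady_state(params: PhotokineticParameters, intensity: float,
                 saturation: bool = False) -> StatePopulations:
    """CW steady-state populations at an irradiance.

    The chain topology obeys detailed balance, so the stationary vector
    follows from the flux-balance ratios pP1/pN = kiso1'/kbiso1' and
    pP2/pP1 = kiso2'/kbiso2'.  Without excitation the dye relaxes fully
    to N: (1, 0, 0).
    """
    r = effective_rates(params, intensity, saturation)
    if r.kiso1p == 0.0:
        return StatePopulations(1.0, 0.0, 0.0)
    if r.kbiso1p == 0.0:
        raise InvalidParametersError(
            "no return path from P1 (kbiso1' = 0 with kiso1' > 0)")
    if r.kiso2p > 0 and r.kbiso2p == 0.0:
        raise InvalidParametersError(
            "no return path from P2 (kbiso2' = 0 with kiso2' > 0)")
    ratio1 = r.kiso1p / r.kbiso1p
    ratio2 = (r.kiso2p / r.kbiso2p) if r.kiso2p > 0 else 0.0
    raw = np.array([1.0, ratio1, ratio1 * ratio2])
    return StatePopulations.from_array(raw / raw.sum())


def relaxation_modes(params: PhotokineticParameters, intensity: float,
                     saturation: bool = False):
    """Non-zero eigenvalues of the rate matrix and their mode vectors.

    Returns ``(lam2, lam3, modes)`` with |lam2| <= |lam3| (us^-1, both
    real and <= 0 for valid chains) and ``modes`` the corresponding right
    eigenvectors as columns of a (3,2) array.
    """
    M = rate_matrix(effective_rates(params, intensity, saturation))
    w, V = np.linalg.eig(M)
    if np.max(np.abs(w.imag)) > 1e-9 * max(np.max(np.abs(w.real)), 1e-300):
        raise RuntimeError("unexpected complex relaxation eigenvalues")
    w = w.real
    order = np.argsort(np.abs(w))
    lam2, lam3 = w[order[1]], w[order[2]]
    modes = np.real(V[:, order[1:]])
    return lam2, lam3, modes
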