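"""FCS forward models and fitting for diffusing Cy5 undergoing isomerization.

The normalized fluorescence autocorrelation factorizes into translational
diffusion and photophysical blinking,

    G(tau) = G_D(tau) * G_T(tau) + 1,

with the 3-D Gaussian diffusion term

    G_D(tau) = (1/Nm) (1 + tau/tauD)^-1 (1 + (tau/tauD)/S^2)^-1/2,

S = omega_z/omega_0 the detection-volume aspect ratio (fixed to 6.8 by
default).  Two blinking models are provided:

* the classic two-state trans/cis model with a single exponential
  relaxation of amplitude ``Aiso`` and time ``tau_iso``;
* the three-state model (N, P1 dark, P2 emissive with relative brightness
  Q), in which the blinking factor is computed from the kinetic populations,

      G_T(tau) = sum_r w^2(r) [pN(r,tau) + Q^2 pP2(r,tau)]
               / sum_r w^2(r) [pN_ss(r) + Q^2 pP2_ss(r)],

  a brightness-squared-weighted average over the detection volume.  The
  initial populations encode which state emitted the photon detected at
  lag zero: with Q = 0 only N emits and p(0) = (1,0,0); with Q > 0 the
  steady-state populations are brightness-weighted (pN, 0, pP2)(0)
  proportional to (pN_ss, 0, Q*pP2_ss).

Global fitting shares the kinetic parameters {kiso, sigma_biso1,
sigma_iso2, sigma_biso2, Q} across curves recorded at several irradiances
and in two detection bands (a blue band where Q is fixed to 0 and a red
band where Q is free), with per-curve diffusion nuisances {Nm, tauD}.
Because Q enters the lag-zero initial condition, it is updated in an outer
iteration until self-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import FitResult, multistart_least_squares
from .photokinetics import (
    ExcitationField,
    PhotokineticParameters,
    StatePopulations,
    _propagate,
    _rate_matrices,
    steady_state,
)

__all__ = [
    "FcsCurve",
    "FcsDiffusionParams",
    "TwoStateFcsParams",
    "default_lag_grid",
    "diffusion_term",
    "two_state_curve",
    "fcs_initial_state",
    "blinking_term_three_state",
    "fcs_curve_three_state",
    "fit_two_state",
    "fit_three_state_global",
]

#: Detection-volume aspect ratio omega_z/omega_0 used unless freed.
DEFAULT_S_RATIO = 6.8

#: Validity floor of the blinking term: lags must exceed the anti-bunching
#: regime (~ns), enforced as tau >= 1e-3 us.
MIN_LAG_US = 1e-3


@dataclass(frozen=True)
class FcsCurve:
    """A normalized FCS curve G(tau) with acquisition metadata."""

    lags: np.ndarray            # us, strictly increasing, > 0
    g: np.ndarray
    intensity: float = 0.0      # mean irradiance, kW/cm^2
    filter_id: str = "full"
    sd: np.ndarray | None = None
    n_molecules_hint: float | None = None

    def __post_init__(self):
        lags = np.asarray(self.lags, dtype=float)
        g = np.asarray(self.g, dtype=float)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "g", g)
        if self.sd is not None:
            object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if lags.ndim != 1 or g.shape != lags.shape:
            raise ValueError("lags and g must be matching 1-D arrays")
        if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing and > 0")
        if not np.all(np.isfinite(g)):
            raise ValueError("g must be finite")


@dataclass(frozen=True)
class FcsDiffusionParams:
    """Diffusion part of the model: mean occupancy, diffusion time, aspect."""

    n_mean: float               # Nm
    tau_d: float                # us
    s_ratio: float = DEFAULT_S_RATIO

    def __post_init__(self):
        if self.n_mean <= 0 or self.tau_d <= 0 or self.s_ratio <= 0:
            raise ValueError("diffusion parameters must be > 0")


@dataclass(frozen=True)
class TwoStateFcsParams:
    """Two-state isomerization model: amplitude, relaxation time, diffusion."""

    a_iso: float
    tau_iso: float              # us
    diffusion: FcsDiffusionParams

    def __post_init__(self):
        if not 0.0 <= self.a_iso < 1.0:
            raise ValueError("a_iso must be in [0, 1)")
        if self.tau_iso <= 0:
            raise ValueError("tau_iso must be > 0")


def default_lag_grid(n: int = 200, lo: float = MIN_LAG_US,
                     hi: float = 1e4) -> np.ndarray:
    """Log-spaced lag grid in us covering blinking and diffusion decades."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


def diffusion_term(p: FcsDiffusionParams, lags) -> np.ndarray:
    """3-D Gaussian-volume diffusion autocorrelation G_D(tau)."""
    tau = np.asarray(lags, dtype=float)
    if np.any(tau < 0):
        raise ValueError("lags must be >= 0")
    x = tau / p.tau_d
    return (1.0 / p.n_mean) / (1.0 + x) / np.sqrt(1.0 + x / p.s_ratio**2)


def two_state_curve(p: TwoStateFcsParams, lags, intensity: float = 0.0,
                    filter_id: str = "full") -> FcsCurve:
    """Two-state isomerization FCS model.

    G(tau) = G_D(tau) [1 - Aiso + Aiso e^(-tau/tau_iso)] / (1 - Aiso) + 1.
    """
    tau = np.asarray(lags, dtype=float)
    gd = diffusion_term(p.diffusion, tau)
    blink = (1.0 - p.a_iso + p.a_iso * np.exp(-tau / p.tau_iso)) / (1.0 - p.a_iso)
    return FcsCurve(lags=tau, g=gd * blink + 1.0, intensity=intensity,
                    filter_id=filter_id)


def fcs_initial_state(params: PhotokineticParameters, intensity: float,
                      filter_q: float,
                      saturation: bool = False) -> StatePopulations:
    """Populations at lag zero, conditioned on having detected a photon.

    With ``filter_q = 0`` only N emits in the detection band and the
    initial state is (1, 0, 0).  Otherwise the detected photon came from N
    or P2 in proportion to their steady-state brightness:
    p(0) = (pN_ss, 0, q*pP2_ss) / (pN_ss + q*pP2_ss).
    """
    if filter_q < 0:
        raise ValueError("filter_q must be >= 0")
    if filter_q == 0:
        return StatePopulations(1.0, 0.0, 0.0)
    ss = steady_state(params, intensity, saturation)
    denom = ss.pN + filter_q * ss.pP2
    if denom <= 0:
        raise ValueError("no detectable emission: pN + q*pP2 = 0")
    return StatePopulations(ss.pN / denom, 0.0, filter_q * ss.pP2 / denom)


def _blinking_nodes(params, intensities, filter_q, lags, saturation=False):
    """Per-node populations and steady states for the blinking term.

    Returns ``(pops (n,m,3), ss (n,3))`` for n quadrature nodes, m lags.
    """
    intensities = np.atleast_1d(np.asarray(intensities, dtype=float))
    M = _rate_matrices(params, intensities, saturation)
    p0 = np.empty((intensities.size, 3))
    for i, inten in enumerate(intensities):
        p0[i] = fcs_initial_state(params, inten, filter_q,
                                  saturation).as_array()
    # evaluate the steady state as the t->inf limit of the same eigen
    # solution so that G_T(inf) = 1 holds to machine precision
    times = np.append(np.asarray(lags, dtype=float), 1e30)
    pops = _propagate(M, p0, times)
    return pops[:, :-1, :], pops[:, -1, :]


def blinking_term_three_state(params: PhotokineticParameters,
                              field: ExcitationField, filter_q: float,
                              lags, init_q: float | None = None,
                              saturation: bool = False) -> np.ndarray:
    """Brightness-squared-weighted blinking factor G_T(tau) of the 3-state model.

    Each quadrature node of ``field`` contributes with weight
    w^2 = (CEF * local irradiance)^2 (uniform CEF); ``filter_q``^2 weights
    the P2 population.  ``init_q`` sets the brightness ratio used in the
    lag-zero initial condition (defaults to ``filter_q``; the iterative-Q
    global fit holds it at the previous outer iterate).  Normalized so
    that G_T(inf) = 1.
    """
    tau = np.asarray(lags, dtype=float)
    if np.any(tau < MIN_LAG_US * (1 - 1e-12)):
        raise ValueError(f"lags must be >= {MIN_LAG_US} us "
                         "(anti-bunching regime excluded)")
    intens, volw = field.quadrature()
    if intens.size == 0:
        raise ValueError("empty quadrature")
    if init_q is None:
        init_q = filter_q
    q2 = filter_q**2
    pops, ss = _blinking_nodes(params, intens, init_q, tau, saturation)
    w2 = volw * intens**2
    num = np.einsum("n,nm->m", w2, pops[:, :, 0] + q2 * pops[:, :, 2])
    den = float(np.dot(w2, ss[:, 0] + q2 * ss[:, 2]))
    return num / den


def fcs_curve_three_state(params: PhotokineticParameters,
                          field: ExcitationField, filter_q: float,
                          diffusion: FcsDiffusionParams, lags,
                          filter_id: str = "full",
                          saturation: bool = False) -> FcsCurve:
    """Full three-state FCS curve G(tau) = G_D(tau) G_T(tau) + 1."""
    tau = np.asarray(lags, dtype=float)
    gt = blinking_term_three_state(params, field, filter_q, tau,
                                   saturation=saturation)
    gd = diffusion_term(diffusion, tau)
    return FcsCurve(lags=tau, g=gd * gt + 1.0, intensity=field.intensity,
                    filter_id=filter_id)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_two_state(curve: FcsCurve, init_guess: TwoStateFcsParams | None = None,
                  free_s: bool = False, weights: bool = False) -> FitResult:
    """Fit the two-state model to a single FCS curve.

    Fitted parameters: Nm, Aiso, tau_iso, tauD (and S if ``free_s``).
    Returns a flagged :class:`~cyblink.fitting.FitResult`; the fitted
    :class:`TwoStateFcsParams` is available as ``result.params['model']``.
    """
    tau, g = curve.lags, curve.g
    if tau.size < 30 or tau[-1] / tau[0] < 1e3:
        raise ValueError("need >= 30 lags spanning >= 3 decades")
    sd = curve.sd if (weights and curve.sd is not None
                      and np.all(curve.sd > 0)) else None

    if init_guess is None:
        g0 = max(g[0] - 1.0, 1e-3)
        nm0 = curve.n_molecules_hint or 1.0 / g0
        # crude split: half-decay lag of (g-1) for tauD, amplitude 0.3
        half = tau[np.searchsorted(-(g - 1.0), -(g0 / 2.0))] \
            if np.any(g - 1.0 < g0 / 2.0) else tau[-1] / 10
        init_guess = TwoStateFcsParams(
            0.3, 1.0, FcsDiffusionParams(nm0, float(half)))

    fixed_s = init_guess.diffusion.s_ratio
    x0 = [init_guess.diffusion.n_mean, init_guess.a_iso,
          init_guess.tau_iso, init_guess.diffusion.tau_d]
    lo, hi = [1e-6, 0.0, 1e-4, 1e-2], [1e6, 0.999, 1e5, 1e8]
    if free_s:
        x0.append(fixed_s)
        lo.append(0.5)
        hi.append(100.0)

    def resid(x):
        s = x[4] if free_s else fixed_s
        p = TwoStateFcsParams(x[1], x[2], FcsDiffusionParams(x[0], x[3], s))
        model = two_state_curve(p, tau).g
        r = model - g
        return r / sd if sd is not None else r

    res, cov = multistart_least_squares(resid, x0, (lo, hi), n_starts=3,
                                        seed=12345, x_scale="jac")
    names = ["n_mean", "a_iso", "tau_iso", "tau_d"] + (["s_ratio"] if free_s else [])
    params = dict(zip(names, res.x))
    s = params.get("s_ratio", fixed_s)
    model = TwoStateFcsParams(params["a_iso"], params["tau_iso"],
                              FcsDiffusionParams(params["n_mean"],
                                                 params["tau_d"], s))
    unc = {}
    if cov is not None:
        unc = {n: float(np.sqrt(max(cov[i, i], 0)))
               for i, n in enumerate(names)}
    dof = max(tau.size - len(x0), 1)
    return FitResult(params={**params, "model": model},
                     residuals=res.fun, cost=float(res.cost),
                     success=bool(res.success), message=res.status and str(res.message) or "",
                     uncertainties=unc, redchi=float(2 * res.cost / dof))


def _group_curves(curves):
    """Split curves into the Q=0 group ('B') and the Q-fitted group ('R')."""
    b_idx = [i for i, c in enumerate(curves) if c.filter_id.upper().startswith("B")]
    r_idx = [i for i, c in enumerate(curves) if i not in b_idx]
    return b_idx, r_idx


def fit_three_state_global(curves, fixed: dict | None = None,
                           init_guess: dict | None = None,
                           q_tol: float = 1e-4, max_outer: int = 50,
                           n_starts: int = 3, seed: int = 0,
                           thermal_free: bool = False,
                           weights: bool = False,
                           saturation: bool = False) -> FitResult:
    """Globally fit the three-state model to a two-band, multi-irradiance set.

    Shared parameters: kiso, sigma_biso1, sigma_iso2, sigma_biso2, Q
    (plus k_th1/k_th2 when ``thermal_free``; by default the thermal rates
    are fixed to 0, justified at the high irradiances of FCS where
    photo-driven back-isomerization dominates).  Per-curve: Nm, tauD.
    sigma_N and tau_f are fixed inputs (``fixed`` dict).

    Because Q also sets the lag-zero state of the red-band curves, an
    outer loop re-fits with the initial condition evaluated at the current
    Q until |dQ| < ``q_tol``; the Q trace is recorded in ``trace``.
    """
    fixed = {"sigma_N": 6.2e-16, "tau_f": 1.0, "wavelength": 638.0,
             **(fixed or {})}
    b_idx, r_idx = _group_curves(curves)
    if not r_idx:
        raise ValueError("need at least one red-band (Q-fitted) curve")
    guess = {"kiso": 20.0, "sigma_biso1": 0.2e-16, "sigma_iso2": 0.2e-16,
             "sigma_biso2": 0.2e-16, "Q": 0.3, "k_th1": 0.01, "k_th2": 0.05,
             **(init_guess or {})}

    glob_names = ["kiso", "sigma_biso1", "sigma_iso2", "sigma_biso2", "Q"]
    if thermal_free:
        glob_names += ["k_th1", "k_th2"]
    # scale cross sections to ~1 by expressing them in 1e-16 cm^2
    scales = {n: (1e-16 if n.startswith("sigma") else 1.0) for n in glob_names}

    def make_params(gvals, k_th_override=None):
        kw = {n: gvals[n] for n in glob_names if n != "Q"}
        if not thermal_free:
            kw.setdefault("k_th1", 0.0)
            kw.setdefault("k_th2", 0.0)
        return PhotokineticParameters(
            sigma_N=fixed["sigma_N"], tau_f=fixed["tau_f"],
            wavelength=fixed["wavelength"], Q=gvals["Q"], **kw)

    nglob = len(glob_names)
    x0 = [guess[n] / scales[n] for n in glob_names]
    lo = [0.0] * nglob
    hi = [np.inf] * nglob
    hi[0] = 0.999e3 / fixed["tau_f"]        # keep k10N > 0
    hi[glob_names.index("Q")] = 5.0
    for c in curves:
        g0 = max(c.g[0] - 1.0, 1e-3)
        nm0 = c.n_molecules_hint or 2.0 / g0
        x0 += [nm0, 100.0]
        lo += [1e-6, 1e-2]
        hi += [1e6, 1e8]
    x0, lo, hi = map(np.asarray, (x0, lo, hi))

    fields = [ExcitationField(mode="uniform", intensity=c.intensity)
              for c in curves]
    lag_list = [c.lags for c in curves]
    sd_list = [c.sd if (weights and c.sd is not None and np.all(c.sd > 0))
               else None for c in curves]

    def residual_factory(q_ic):
        def resid(x):
            gvals = {n: x[i] * scales[n] for i, n in enumerate(glob_names)}
            try:
                params = make_params(gvals)
            except ValueError:
                return np.full(sum(l.size for l in lag_list), 1e3)
            out = []
            b_set = set(b_idx)
            for j, c in enumerate(curves):
                nm, td = x[nglob + 2 * j], x[nglob + 2 * j + 1]
                in_b = j in b_set
                diff = FcsDiffusionParams(nm, td)
                gt = blinking_term_three_state(
                    params, fields[j],
                    filter_q=0.0 if in_b else gvals["Q"],
                    lags=lag_list[j],
                    init_q=0.0 if in_b else q_ic,
                    saturation=saturation)
                model = diffusion_term(diff, lag_list[j]) * gt + 1.0
                r = model - c.g
                out.append(r / sd_list[j] if sd_list[j] is not None else r)
            return np.concatenate(out)
        return resid

    q_ic = guess["Q"]
    trace = []
    res = cov = None
    x_start = x0
    converged = False
    # The fixed-point map Q_ic -> Q_fit can have slope < -1 (the weighting-Q
    # over-compensates a frozen initial condition), so plain iteration
    # oscillates; a half-step damped update keeps it contractive.
    damping = 0.5
    for outer in range(max_outer):
        res, cov = multistart_least_squares(
            residual_factory(q_ic), x_start, (lo, hi),
            n_starts=(n_starts if outer == 0 else 1), seed=seed,
            x_scale="jac", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        q_fit = float(res.x[glob_names.index("Q")])
        trace.append({"outer": outer, "Q_ic": q_ic, "Q_fit": q_fit,
                      "cost": float(res.cost)})
        if abs(q_fit - q_ic) < q_tol:
            converged = True
            q_ic = q_fit
            break
        q_ic = q_ic + damping * (q_fit - q_ic)
        x_start = res.x.copy()
        x_start[glob_names.index("Q")] = q_ic
    gvals = {n: float(res.x[i] * scales[n]) for i, n in enumerate(glob_names)}
    locs = [{"n_mean": float(res.x[nglob + 2 * j]),
             "tau_d": float(res.x[nglob + 2 * j + 1])}
            for j in range(len(curves))]
    unc = {}
    if cov is not None:
        unc = {n: float(np.sqrt(max(cov[i, i], 0)) * scales[n])
               for i, n in enumerate(glob_names)}
    ndata = sum(l.size for l in lag_list)
    dof = max(ndata - res.x.size, 1)
    return FitResult(params=gvals, locals=locs, residuals=res.fun,
                     cost=float(res.cost),
                     success=bool(res.success) and converged,
                     message="" if converged else
                     f"Q iteration not converged after {max_outer} loops",
                     n_outer_iterations=len(trace), trace=trace,
                     uncertainties=unc, redchi=float(2 * res.cost / dof))
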