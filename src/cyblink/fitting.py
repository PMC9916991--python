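"""Shared least-squares machinery: bounded trust-region fits with multistart.

All model fitting in the package goes through :func:`multistart_least_squares`,
a thin wrapper around ``scipy.optimize.least_squares`` (TRF, bounds) that
re-runs the solver from a few deterministically perturbed starting points
and keeps the lowest-cost solution.  Randomness is confined to a seeded
``numpy`` generator so fits are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = ["FitResult", "multistart_least_squares"]


@dataclass
class FitResult:
    """Outcome of a (possibly global) nonlinear least-squares fit.

    ``params`` holds the shared/global parameters by name, ``locals`` one
    dict per curve for individually fitted nuisance parameters.  A failed
    fit is *flagged* (``success=False``), never raised.
    """

    params: dict
    locals: list = field(default_factory=list)
    residuals: np.ndarray | None = None
    cost: float = np.inf
    success: bool = False
    message: str = ""
    n_outer_iterations: int = 0
    trace: list = field(default_factory=list)
    uncertainties: dict = field(default_factory=dict)
    redchi: float | None = None

    def summary(self) -> str:
        lines = [f"converged: {self.success}  cost: {self.cost:.6g}"]
        for k, v in self.params.items():
            err = self.uncertainties.get(k)
            lines.append(f"  {k} = {v:.6g}" +
                         (f" +/- {err:.2g}" if err is not None else ""))
        return "\n".join(lines)


def _covariance(res) -> np.ndarray | None:
    """1-sigma covariance from the Jacobian at the solution."""
    try:
        J = res.jac
        dof = max(J.shape[0] - J.shape[1], 1)
        s2 = 2.0 * res.cost / dof
        JTJ = J.T @ J
        return s2 * np.linalg.pinv(JTJ)
    except Exception:
        return None


def multistart_least_squares(residual_fn, x0, bounds, n_starts=3, seed=0,
                             perturb=0.3, **ls_kwargs):
    """Run bounded least squares from ``n_starts`` perturbed starts.

    The first start is ``x0`` itself; later starts multiply each free
    parameter by a log-normal factor exp(perturb * N(0,1)) clipped to the
    bounds.  Returns ``(scipy result, covariance or None)`` of the best run.
    """
    rng = np.random.default_rng(seed)
    lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    x0 = np.asarray(x0, dtype=float)
    best = None
    for start in range(max(n_starts, 1)):
        if start == 0:
            xs = x0
        else:
            xs = x0 * np.exp(perturb * rng.standard_normal(x0.size))
        xs = np.clip(xs, lo + 1e-12 * np.maximum(np.abs(lo), 1),
                     np.where(np.isfinite(hi), hi * (1 - 1e-12), np.inf))
        xs = np.where(np.isfinite(xs), xs, x0)
        try:
            res = least_squares(residual_fn, xs, bounds=(lo, hi),
                                method="trf", **ls_kwargs)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all least-squares starts failed")
    return best, _covariance(best)
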