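"""Per-cell likelihood and maximum-likelihood initialization.

The measurement model is multiplicative Gaussian: an observed fluorescence
y_t is Normal with mean [gluc]_t (the ODE solution at t) and standard
deviation sigma_t = max(cv_error * [gluc]_t, sigma_floor).  The MLE step fits
the forward model to one trace by Levenberg-Marquardt least squares in
(ln u, ln d) coordinates, mirroring the initialization stage of the
hierarchical sampler.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .model import (
    CellTrace,
    CompiledGrid,
    ExternalProfile,
    KineticParams,
    cell_volume,
    compile_grid,
    eval_profile,
)

__all__ = ["NonIdentifiableError", "loglik_trace", "mle_fit", "init_hyperpriors"]

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)


class NonIdentifiableError(ValueError):
    """Raised when a trace carries no information about (u_gluc, d_gluc)."""


def gaussian_loglik(y: np.ndarray, mean: np.ndarray, cv_error: float,
                    sigma_floor: float) -> float:
    """Sum of Normal log-densities with sd = max(cv_error*mean, sigma_floor)."""
    if not np.all(np.isfinite(mean)):
        return -np.inf
    sd = np.maximum(cv_error * np.abs(mean), sigma_floor)
    z = (y - mean) / sd
    return float(-0.5 * np.sum(z * z) - np.sum(np.log(sd)) - 0.5 * _LOG_2PI * y.size)


def loglik_trace(
    params: KineticParams,
    trace: CellTrace,
    profile: ExternalProfile,
    cv_error: float,
    sigma_floor: float,
    grid: CompiledGrid | None = None,
) -> float:
    """Log-likelihood of one cell's trace under the forward model.

    Returns -inf (with a debug log) if the model output is non-finite, e.g.
    under an overflowing proposal.
    """
    if grid is None:
        grid = compile_grid(profile, trace.times)
    V_c = cell_volume(trace.geometry)
    mean = grid.propagate(params.u_gluc / V_c, params.d_gluc)
    ll = gaussian_loglik(trace.values, mean, cv_error, sigma_floor)
    if not np.isfinite(ll) and ll != -np.inf:
        logger.debug("non-finite log-likelihood for cell %s", trace.cell_id)
        return -np.inf
    return ll


def _initial_guess(trace: CellTrace, profile: ExternalProfile, V_c: float) -> np.ndarray:
    """Heuristic (ln u, ln d) start: plateau level sets u/(d V_c), the
    post-washout decay (or the rise half-time) sets d."""
    t, y = trace.times, trace.values
    g_max = float(np.max(profile.conc))
    if g_max <= 0:
        raise NonIdentifiableError("profile carries no 2-NBDG")
    washout = profile.washout_time
    if washout is None:
        washout = t[0] + 0.6 * (t[-1] - t[0])
    pre = (t > 0.5 * washout) & (t <= washout)
    y_ss = float(np.mean(y[pre])) if np.any(pre) else float(np.max(y))
    if not np.isfinite(y_ss) or y_ss <= 0 or float(np.max(np.abs(y))) == 0.0:
        raise NonIdentifiableError("trace has no signal above zero")

    d0 = None
    tail = t > washout
    if np.count_nonzero(tail) >= 4:
        tt, yy = t[tail], y[tail]
        pos = yy > 0.02 * y_ss
        if np.count_nonzero(pos) >= 3:
            slope = np.polyfit(tt[pos], np.log(yy[pos]), 1)[0]
            if slope < 0:
                d0 = -slope
    if d0 is None:
        # time to half the plateau during accumulation
        rise = t <= washout
        above = y[rise] >= 0.5 * y_ss
        t_half = t[rise][np.argmax(above)] if np.any(above) else washout / 4
        d0 = math.log(2.0) / max(t_half, t[1] - t[0])
    d0 = min(max(d0, 1e-5), 1.0)
    u0 = max(y_ss * d0 * V_c / g_max, 1e-12)
    return np.array([math.log(u0), math.log(d0)])


def mle_fit(
    trace: CellTrace,
    profile: ExternalProfile,
    max_iter: int = 15,
    x0: np.ndarray | None = None,
) -> KineticParams:
    """Levenberg-Marquardt least-squares fit of the forward model to a trace.

    Optimizes in (ln u, ln d) so positivity is automatic.  ``max_iter`` caps
    the optimizer's iterations (function-evaluation budget of
    max_iter * 3, two parameters plus the objective per iteration).
    """
    V_c = cell_volume(trace.geometry)
    grid = compile_grid(profile, trace.times)
    if x0 is None:
        x0 = _initial_guess(trace, profile, V_c)

    y = trace.values

    def residuals(x):
        mean = grid.propagate(math.exp(x[0]) / V_c, math.exp(x[1]))
        return mean - y

    res = least_squares(residuals, x0, method="lm", max_nfev=max_iter * 3)
    x = res.x
    if not np.all(np.isfinite(x)):
        raise NonIdentifiableError(f"cell {trace.cell_id}: optimizer diverged")
    return KineticParams.from_log(x)


def init_hyperpriors(
    mle_params: np.ndarray, ridge: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical hyperprior moments from per-cell MLEs.

    Returns (mu, Sigma): the sample mean and ridge-regularized sample
    covariance of the (ln u, ln d) point estimates, used as the fixed
    hyper-mean and hyper-covariance of the population model.
    """
    x = np.asarray(mle_params, dtype=float).reshape(-1, 2)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 cells to set hyperpriors")
    mu = x.mean(axis=0)
    sigma = np.cov(x, rowvar=False, ddof=1) + ridge * np.eye(2)
    return mu, sigma
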