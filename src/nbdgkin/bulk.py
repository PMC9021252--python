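"""Bulk-population assay computations.

One-phase exponential decay fits (time constant Tau) for extracellular-
glucose disappearance and inhibitor-competition fluorescence series, and the
colorimetric glucose assay: a blank-subtracted linear standard curve plus the
concentration formula C = S_a / S_v.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DecayFitError",
    "DecayFitResult",
    "fit_one_phase_decay",
    "StandardCurve",
    "build_standard_curve",
    "glucose_concentration",
]


class DecayFitError(ValueError):
    """Raised when a decay fit is impossible or meaningless on the data."""


@dataclass(frozen=True)
class DecayFitResult:
    """One-phase decay fit y(t) = (Y0 - plateau) exp(-t/Tau) + plateau.

    Standard errors come from the Jacobian at the optimum (the usual
    nonlinear-least-squares covariance); across-replicate spread, when
    replicates exist, is a separate quantity the caller computes from the
    per-replicate Tau values.
    """

    Y0: float
    plateau: float
    Tau: float
    se_Y0: float
    se_plateau: float
    se_Tau: float
    rss: float

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return (self.Y0 - self.plateau) * np.exp(-t / self.Tau) + self.plateau


def _decay(t, y0, plateau, tau):
    return (y0 - plateau) * np.exp(-t / tau) + plateau


def fit_one_phase_decay(
    t, y, fix_plateau: float | None = None, sigma=None
) -> DecayFitResult:
    """Nonlinear least-squares one-phase decay fit.

    Initialization: Y0 from the earliest samples, plateau from the latest,
    Tau from the log-linear slope of the plateau-subtracted early decay.
    ``fix_plateau`` pins the asymptote (e.g. 0 for complete disappearance);
    ``sigma`` forwards known per-point noise SDs for a weighted fit.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size != y.size:
        raise ValueError("t and y must have equal length")
    if t.size < 4:
        raise DecayFitError("need at least 4 points for a decay fit")
    if np.ptp(y) == 0:
        raise DecayFitError("constant data: no decay to fit")

    order = np.argsort(t)
    t, y = t[order], y[order]
    n_edge = max(2, t.size // 5)
    y0_guess = float(np.mean(y[:n_edge]))
    plat_guess = fix_plateau if fix_plateau is not None else float(np.mean(y[-n_edge:]))
    if y0_guess <= plat_guess:
        raise DecayFitError(
            "data do not decay: early mean does not exceed late mean"
        )
    resid = y - plat_guess
    pos = resid > 0.05 * (y0_guess - plat_guess)
    if np.count_nonzero(pos) >= 3:
        slope = np.polyfit(t[pos], np.log(resid[pos]), 1)[0]
        tau_guess = -1.0 / slope if slope < 0 else (t[-1] - t[0]) / 3.0
    else:
        tau_guess = (t[-1] - t[0]) / 3.0
    tau_guess = max(tau_guess, 1e-9)

    sig = None if sigma is None else np.asarray(sigma, dtype=float)
    try:
        if fix_plateau is not None:
            popt, pcov = curve_fit(
                lambda tt, y0, tau: _decay(tt, y0, fix_plateau, tau),
                t, y, p0=[y0_guess, tau_guess], sigma=sig,
                absolute_sigma=sig is not None, maxfev=10000,
            )
            y0, tau = popt
            plateau = float(fix_plateau)
            se = np.sqrt(np.diag(pcov))
            se_y0, se_tau, se_plat = se[0], se[1], 0.0
        else:
            popt, pcov = curve_fit(
                _decay, t, y, p0=[y0_guess, plat_guess, tau_guess], sigma=sig,
                absolute_sigma=sig is not None, maxfev=10000,
            )
            y0, plateau, tau = popt
            se_y0, se_plat, se_tau = np.sqrt(np.diag(pcov))
    except RuntimeError as exc:
        raise DecayFitError(f"decay fit did not converge: {exc}") from exc
    if not (tau > 0 and np.isfinite(tau)):
        raise DecayFitError(f"fit returned a non-positive time constant ({tau})")
    rss = float(np.sum((_decay(t, y0, plateau, tau) - y) ** 2))
    return DecayFitResult(
        Y0=float(y0), plateau=float(plateau), Tau=float(tau),
        se_Y0=float(se_y0), se_plateau=float(se_plat), se_Tau=float(se_tau),
        rss=rss,
    )


@dataclass(frozen=True)
class StandardCurve:
    """Blank-subtracted linear calibration: absorbance = slope*amount + intercept."""

    slope: float
    intercept: float
    blank: float

    def to_absorbance(self, amount):
        return self.slope * np.asarray(amount, dtype=float) + self.intercept

    def to_amount(self, absorbance):
        """Invert a raw absorbance (blank is subtracted internally) to nmole."""
        a = np.asarray(absorbance, dtype=float) - self.blank
        out = (a - self.intercept) / self.slope
        return float(out) if out.ndim == 0 else out


def build_standard_curve(standard_amounts, absorbances) -> StandardCurve:
    """Least-squares line through the blank-subtracted glucose standards.

    The 0-nmole standard is the assay blank; its absorbance is subtracted
    from every well before the straight-line fit.
    """
    amounts = np.asarray(standard_amounts, dtype=float)
    absorb = np.asarray(absorbances, dtype=float)
    if amounts.size != absorb.size:
        raise ValueError("standards and absorbances must have equal length")
    if amounts.size < 2 or np.unique(amounts).size < 2:
        raise ValueError("need at least 2 distinct standard amounts")
    if not np.any(amounts == 0):
        raise ValueError("standards must include the 0-amount assay blank")
    blank = float(np.mean(absorb[amounts == 0]))
    corrected = absorb - blank
    slope, intercept = np.polyfit(amounts, corrected, 1)
    if slope == 0:
        raise ValueError("degenerate standards: zero slope")
    return StandardCurve(slope=float(slope), intercept=float(intercept), blank=blank)


def glucose_concentration(S_a: float, S_v: float) -> float:
    """Glucose concentration C = S_a / S_v (nmole / µL)."""
    if not S_v > 0:
        raise ValueError(f"sample volume must be > 0, got {S_v}")
    return S_a / S_v
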