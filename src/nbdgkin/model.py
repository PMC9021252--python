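"""Deterministic forward model for single-cell 2-NBDG kinetics.

Intracellular concentration of the fluorescent glucose analogue 2-NBDG in a
rod-shaped bacterium follows first-order uptake/degradation kinetics

    d[gluc]_in/dt = -d_gluc * [gluc]_in + (u_gluc / V_c) * [gluc]_ex(t)

where ``u_gluc`` (µm³/s) is the uptake rate constant, ``d_gluc`` (1/s) the
degradation rate constant, ``V_c`` (µm³) the cell volume, and ``[gluc]_ex(t)``
the extracellular concentration, represented as a piecewise-linear function of
time.  Because the forcing is piecewise linear the ODE is solved exactly,
segment by segment, with the closed-form solution for linear forcing; no
generic numeric integrator is needed.

Fluorescence (a.u.) is treated as proportional to concentration with unit
proportionality, so ``u_gluc`` is identified in a.u.-consistent units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InvalidGeometryError",
    "CellGeometry",
    "KineticParams",
    "ExternalProfile",
    "CellTrace",
    "ConcentrationSeries",
    "cell_volume",
    "eval_profile",
    "propagate_segment",
    "CompiledGrid",
    "compile_grid",
    "solve_trace",
    "analytic_step_solution",
]


class InvalidGeometryError(ValueError):
    """Raised when a cell geometry violates width > 0 or length >= width."""


@dataclass(frozen=True)
class CellGeometry:
    """Rod-shaped cell geometry: ``width`` is the diameter, ``length`` the
    pole-to-pole extent, both in µm."""

    width: float
    length: float

    def __post_init__(self) -> None:
        if not (self.width > 0):
            raise InvalidGeometryError(f"width must be > 0, got {self.width}")
        if self.length < self.width:
            raise InvalidGeometryError(
                f"length ({self.length}) must be >= width ({self.width})"
            )


@dataclass(frozen=True)
class KineticParams:
    """Per-cell kinetic parameters: uptake ``u_gluc`` (µm³/s) and degradation
    ``d_gluc`` (1/s).  Both strictly positive so log-transforms are defined."""

    u_gluc: float
    d_gluc: float

    def __post_init__(self) -> None:
        if not (self.u_gluc > 0 and self.d_gluc > 0):
            raise ValueError(
                f"u_gluc and d_gluc must be > 0, got ({self.u_gluc}, {self.d_gluc})"
            )

    @property
    def log(self) -> np.ndarray:
        """(ln u_gluc, ln d_gluc) as an array — the inference coordinates."""
        return np.array([math.log(self.u_gluc), math.log(self.d_gluc)])

    @classmethod
    def from_log(cls, x) -> "KineticParams":
        return cls(u_gluc=float(np.exp(x[0])), d_gluc=float(np.exp(x[1])))


@dataclass(frozen=True)
class ExternalProfile:
    """Piecewise-linear extracellular 2-NBDG concentration [gluc]_ex(t).

    Knot times are non-decreasing; a repeated time encodes an instantaneous
    step (the paper's idealized addition/washout), evaluated right-
    continuously.  Outside the knot range the profile clamps to the first/last
    knot value.
    """

    times: np.ndarray
    conc: np.ndarray
    washout_time: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.conc, dtype=float)
        if t.size == 0:
            raise ValueError("profile needs at least one knot")
        if t.size != c.size:
            raise ValueError("times and conc must have equal length")
        if np.any(np.diff(t) < 0):
            raise ValueError("knot times must be non-decreasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "conc", c)

    @classmethod
    def from_knots(cls, knots, washout_time: float | None = None) -> "ExternalProfile":
        """Build from an ordered list of (time, concentration) pairs."""
        if len(knots) == 0:
            raise ValueError("profile needs at least one knot")
        t, c = zip(*knots)
        return cls(times=np.asarray(t, float), conc=np.asarray(c, float),
                   washout_time=washout_time)

    def __call__(self, t):
        return eval_profile(self, t)


def eval_profile(profile: ExternalProfile, t):
    """Evaluate [gluc]_ex at time(s) ``t`` by linear interpolation between
    knots, clamped to the first/last knot value outside the knot range."""
    return np.interp(t, profile.times, profile.conc)


@dataclass(frozen=True)
class CellTrace:
    """One cell's background-subtracted mean-fluorescence time series (a.u.)
    with its geometry — the observed data for inference."""

    cell_id: str
    times: np.ndarray
    values: np.ndarray
    geometry: CellGeometry

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size != v.size:
            raise ValueError(f"cell {self.cell_id}: times and values length mismatch")
        if t.size < 3:
            raise ValueError(f"cell {self.cell_id}: need at least 3 time points")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"cell {self.cell_id}: times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"cell {self.cell_id}: non-finite fluorescence values")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class ConcentrationSeries:
    """Intracellular concentration [gluc]_in sampled on a time grid."""

    times: np.ndarray
    conc: np.ndarray


def cell_volume(geometry: CellGeometry, shape: str = "spherocylinder") -> float:
    """Cell volume in µm³ from width (diameter) and length.

    The default is a spherocylinder — a cylinder of length (l - w) capped by
    two hemispheres of diameter w, the standard idealization of E. coli:

        V = pi (w/2)^2 (l - w) + (4/3) pi (w/2)^3

    ``shape="cylinder"`` gives the plain cylinder pi (w/2)^2 l for sensitivity
    checks.
    """
    w, l = geometry.width, geometry.length
    r = w / 2.0
    if shape == "spherocylinder":
        return math.pi * r * r * (l - w) + (4.0 / 3.0) * math.pi * r**3
    if shape == "cylinder":
        return math.pi * r * r * l
    raise ValueError(f"unknown shape {shape!r}")


def propagate_segment(
    y0: float, d_gluc: float, u_over_V: float, a: float, b: float, dt: float
) -> float:
    """Exact solution of  y' = -d_gluc*y + u_over_V*(a + b*tau)  at tau=dt.

    ``a`` and ``b`` describe the linear extracellular forcing on the segment
    (value at the segment start and slope).  Uses expm1 so the small-d_gluc*dt
    limit is accurate.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if not d_gluc > 0:
        raise ValueError("d_gluc must be > 0")
    E = math.exp(-d_gluc * dt)
    P = -math.expm1(-d_gluc * dt) / d_gluc        # (1 - E)/d
    Q = (dt - P) / d_gluc                          # dt/d - (1 - E)/d^2
    return y0 * E + u_over_V * (a * P + b * Q)


class CompiledGrid:
    """A profile/time-grid pair pre-processed for fast repeated propagation.

    Compiling merges the output grid with the profile knots so every
    propagation segment carries exactly linear forcing; ``propagate`` then
    walks the segments with the closed-form step.  Reused heavily in the
    likelihood loop, where only (u_gluc/V_c, d_gluc) change between calls.
    """

    def __init__(self, times: np.ndarray, h: np.ndarray, g0: np.ndarray,
                 slope: np.ndarray, out_idx: np.ndarray):
        self.times = times
        self._h = h
        self._g0 = g0
        self._slope = slope
        self._out_idx = out_idx

    def propagate(self, u_over_V: float, d_gluc: float, y0: float = 0.0) -> np.ndarray:
        """Concentration at the original output grid for one parameter set."""
        h = self._h
        E = np.exp(-d_gluc * h)
        P = -np.expm1(-d_gluc * h) / d_gluc
        Q = (h - P) / d_gluc
        F = u_over_V * (self._g0 * P + self._slope * Q)
        y = np.empty(h.size + 1)
        y[0] = y0
        acc = y0
        # plain-float scan: the recurrence is inherently sequential
        El = E.tolist()
        Fl = F.tolist()
        for k in range(len(El)):
            acc = acc * El[k] + Fl[k]
            y[k + 1] = acc
        return y[self._out_idx]


def compile_grid(profile: ExternalProfile, t_grid) -> CompiledGrid:
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size < 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be non-empty and strictly increasing")
    interior = profile.times[(profile.times > t_grid[0]) & (profile.times < t_grid[-1])]
    union = np.unique(np.concatenate([t_grid, interior]))
    h = np.diff(union)
    # sample strictly inside each segment so jump knots at the endpoints
    # cannot contaminate the linear coefficients
    m1 = union[:-1] + 0.25 * h
    m2 = union[:-1] + 0.75 * h
    f1 = eval_profile(profile, m1)
    f2 = eval_profile(profile, m2)
    with np.errstate(invalid="ignore"):
        slope = np.where(h > 0, (f2 - f1) / np.maximum(0.5 * h, 1e-300), 0.0)
    g0 = f1 - slope * 0.25 * h
    out_idx = np.searchsorted(union, t_grid)
    return CompiledGrid(union, h, g0, slope, out_idx)


def solve_trace(
    params: KineticParams,
    V_c: float,
    profile: ExternalProfile,
    t_grid,
    y0: float = 0.0,
) -> ConcentrationSeries:
    """Solve the uptake/degradation ODE exactly on ``t_grid``.

    The initial condition defaults to [gluc]_in = 0 at the first grid point
    (cells are 2-NBDG-naive before addition).
    """
    if not V_c > 0:
        raise ValueError("V_c must be > 0")
    grid = compile_grid(profile, t_grid)
    conc = grid.propagate(params.u_gluc / V_c, params.d_gluc, y0=y0)
    return ConcentrationSeries(times=np.asarray(t_grid, float), conc=conc)


def analytic_step_solution(
    params: KineticParams, V_c: float, g_ex: float, t, t1: float
):
    """Closed-form [gluc]_in for an idealized step profile: extracellular
    concentration jumps 0 -> g_ex at t=0 and back to 0 at t=t1.

        0 <= t <= t1 :  (u g_ex)/(d V_c) (1 - exp(-d t))
        t >= t1      :  (u g_ex)/(d V_c) (exp(-d (t - t1)) - exp(-d t))
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if not t1 > 0:
        raise ValueError("t1 must be > 0")
    u, d = params.u_gluc, params.d_gluc
    amp = u * g_ex / (d * V_c)
    rising = amp * -np.expm1(-d * t)
    falling = amp * (np.exp(-d * (t - t1)) - np.exp(-d * t))
    out = np.where(t <= t1, rising, falling)
    return float(out) if out.ndim == 0 else out
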