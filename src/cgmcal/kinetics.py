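"""Interstitial-glucose kinetics driven by a blood-glucose forcing function.

A CGM sensor sits in the interstitial fluid, so its signal tracks blood
glucose (BG) only after a first-order exchange between the blood and
interstitial compartments.  Working on the scale of *normalised*
interstitial glucose NIG (scaled so that NIG equals BG at steady state),
the kinetics reduce to a single linear ODE with one rate constant:

    dNIG/dt = p1 * (BG(t) - NIG(t)),        NIG(t0) = nig0,

where ``BG(t)`` is the piecewise-linear interpolant of the observed
blood-glucose series (the *forcing function*) and ``1/p1`` is the
physiological time delay, in minutes, between glucose appearing in blood
and on the sensor.

Two solvers are provided:

* :func:`solve_nig_exact` — the default.  Because the forcing is linear in
  time between breakpoints, the ODE has a closed-form solution on each
  segment; the solution is assembled segment by segment over the merged
  grid of forcing knots and evaluation times, so it is exact up to
  round-off.
* :func:`solve_nig_rk4` — a classical fixed-step 4th-order Runge-Kutta
  integrator, retained as an independent numerical cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


__all__ = [
    "ForcingFunction",
    "KineticState",
    "interpolate_bg",
    "solve_nig_exact",
    "solve_nig_rk4",
]


@dataclass(frozen=True)
class ForcingFunction:
    """Piecewise-linear blood-glucose curve built from observed knots.

    Parameters
    ----------
    knot_times
        Observation times in minutes from study start, strictly increasing,
        at least two.
    knot_values
        BG concentrations (mmol/L) at the knots, strictly positive.

    Evaluation at a knot returns that knot's value exactly; between knots
    the linear interpolant is used; outside the knot range the nearest
    boundary value is returned (clamped extrapolation).
    """

    knot_times: np.ndarray
    knot_values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.knot_times, dtype=float)
        v = np.asarray(self.knot_values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise ValueError("knot_times and knot_values must be 1-D and equal length")
        if t.size < 2:
            raise ValueError("a forcing function needs at least two knots")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(v)):
            raise ValueError("forcing knots must be finite")
        if np.any(np.diff(t) <= 0):
            raise ValueError("knot_times must be strictly increasing")
        if np.any(v <= 0):
            raise ValueError("BG concentrations must be strictly positive")
        object.__setattr__(self, "knot_times", t)
        object.__setattr__(self, "knot_values", v)

    def __call__(self, t):
        return interpolate_bg(self, t)


@dataclass(frozen=True)
class KineticState:
    """Rate constant and initial condition of the NIG compartment.

    ``p1`` is the exchange rate in 1/min (so ``1/p1`` is the blood-to-sensor
    delay in minutes) and ``nig0`` the NIG concentration (mmol/L) at the
    first evaluation time.
    """

    p1: float
    nig0: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.p1) or self.p1 <= 0:
            raise ValueError("p1 must be positive and finite")
        if not np.isfinite(self.nig0) or self.nig0 <= 0:
            raise ValueError("nig0 must be positive and finite")

    @property
    def delay(self) -> float:
        """Implied blood-to-interstitium time delay 1/p1, minutes."""
        return 1.0 / self.p1


def interpolate_bg(f: ForcingFunction, t):
    """Evaluate the forcing function at time(s) ``t`` (minutes).

    Returns the exact linear interpolant, clamped to the boundary values
    outside the knot range.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("evaluation times must be finite")
    out = np.interp(t, f.knot_times, f.knot_values)
    return float(out) if out.ndim == 0 else out


@njit(cache=True)
def _exact_kernel(tau, bg, p1, nig0):
    # Per-segment closed form for dy/dt = p1*(a + b*(t - t_m) - y); written
    # with expm1 so that small p1*dt does not lose precision to cancellation.
    out = np.empty(tau.shape[0])
    out[0] = nig0
    for m in range(tau.shape[0] - 1):
        dt = tau[m + 1] - tau[m]
        if dt <= 0.0:
            out[m + 1] = out[m]
            continue
        b = (bg[m + 1] - bg[m]) / dt
        em1 = -np.expm1(-p1 * dt)  # 1 - exp(-p1*dt)
        out[m + 1] = out[m] + em1 * (bg[m] - out[m]) + b * (dt - em1 / p1)
    return out


@njit(cache=True)
def _rk4_kernel(tau, kt, kv, p1, nig0, step):
    out = np.empty(tau.shape[0])
    out[0] = nig0
    y = nig0
    for m in range(tau.shape[0] - 1):
        a = tau[m]
        gap = tau[m + 1] - a
        if gap <= 0.0:
            out[m + 1] = y
            continue
        ns = int(np.ceil(gap / step))
        h = gap / ns
        t = a
        for _ in range(ns):
            k1 = p1 * (np.interp(t, kt, kv) - y)
            k2 = p1 * (np.interp(t + 0.5 * h, kt, kv) - (y + 0.5 * h * k1))
            k3 = p1 * (np.interp(t + 0.5 * h, kt, kv) - (y + 0.5 * h * k2))
            k4 = p1 * (np.interp(t + h, kt, kv) - (y + h * k3))
            y = y + h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            t += h
        out[m + 1] = y
    return out


def _merged_grid(f: ForcingFunction, eval_times: np.ndarray, t0: float):
    """Union of t0, evaluation times and interior forcing knots.

    Including the knots as breakpoints means the forcing is linear on every
    segment of the merged grid, which is what both solvers assume.
    """
    interior = f.knot_times[(f.knot_times > t0) & (f.knot_times < eval_times[-1])]
    tau = np.union1d(np.concatenate((np.array([t0]), eval_times)), interior)
    idx = np.searchsorted(tau, eval_times)
    return tau, idx


def _check_eval_times(eval_times, t0: float) -> np.ndarray:
    eval_times = np.asarray(eval_times, dtype=float)
    if eval_times.ndim != 1 or eval_times.size == 0:
        raise ValueError("eval_times must be a non-empty 1-D array")
    if not np.all(np.isfinite(eval_times)) or not np.isfinite(t0):
        raise ValueError("eval_times and t0 must be finite")
    if np.any(np.diff(eval_times) < 0):
        raise ValueError("eval_times must be ascending")
    if eval_times[0] < t0:
        raise ValueError("eval_times must not precede t0")
    return eval_times


def solve_nig_exact(k: KineticState, f: ForcingFunction, eval_times, t0: float):
    """NIG series at ``eval_times``, solved segment-wise in closed form.

    The first-order linear ODE with a forcing that is linear in time on
    each segment has an analytic solution; stitching these together across
    the merged breakpoint grid gives the continuous exact solution.
    """
    eval_times = _check_eval_times(eval_times, t0)
    tau, idx = _merged_grid(f, eval_times, t0)
    bg_tau = np.interp(tau, f.knot_times, f.knot_values)
    return _exact_kernel(tau, bg_tau, k.p1, k.nig0)[idx]


def solve_nig_rk4(k: KineticState, f: ForcingFunction, eval_times, t0: float, step: float):
    """NIG series via classical fixed-step RK4 with forcing interpolation.

    ``step`` (minutes) must be positive and no larger than the smallest gap
    between consecutive evaluation times.  Stage values of the forcing are
    obtained with :func:`interpolate_bg`'s convention (numpy linear
    interpolation with clamping).
    """
    eval_times = _check_eval_times(eval_times, t0)
    if step <= 0:
        raise ValueError("step must be positive")
    gaps = np.diff(np.concatenate(([t0], eval_times)))
    gaps = gaps[gaps > 0]
    if gaps.size and step > gaps.min():
        raise ValueError("step larger than the smallest inter-evaluation gap")
    tau, idx = _merged_grid(f, eval_times, t0)
    return _rk4_kernel(tau, f.knot_times, f.knot_values, k.p1, k.nig0, step)[idx]
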