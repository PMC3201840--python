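"""Sensor-glucose observation model: calibration periods and residuals.

The CGM device reports sensor glucose SG, which relates to normalised
interstitial glucose NIG through an affine map whose coefficients change
each time the sensor is recalibrated.  Within calibration period ``k``,

    CIG_j = F_k * NIG_j + B_k,

where ``F_k`` is the calibration scale factor (dimensionless) and ``B_k``
the calibration shift (mmol/L).  The *calibrated interstitial glucose*
CIG is the model's mean for SG before residual noise.

Residuals SG - CIG are modelled either as iid Gaussian (per individual in
the basic model, per calibration period otherwise) or as an AR(1) process

    eta_j = (F_{P[j]} / F_{P[j-1]}) * rho * eta_{j-1} + gamma_j,

whose ratio term adjusts the process across calibration boundaries and is
one elsewhere.  Under the AR variant the one-step-ahead conditional mean is

    phi_j = CIG_j + (F_{P[j]}/F_{P[j-1]}) * rho * (SG_{j-1} - CIG_{j-1}),

and the first reading carries no data term: it determines the ODE initial
condition through the initial residual eta_1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .kinetics import ForcingFunction, _exact_kernel, _merged_grid

__all__ = [
    "CalibrationSchedule",
    "IndividualParams",
    "IndividualData",
    "Dataset",
    "assign_periods",
    "compute_cig",
    "initial_nig_from_eta1",
    "ar_conditional_means",
    "loglik_individual",
    "simulate_sg",
    "predict_series",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

VARIANTS = ("basic", "calibrated", "calibrated_ar")


def _norm_logpdf(x, mean, sd):
    z = (np.asarray(x) - mean) / sd
    return -0.5 * _LOG_2PI - np.log(sd) - 0.5 * z * z


@dataclass(frozen=True)
class CalibrationSchedule:
    """Calibration event times splitting the study into K+1 periods."""

    psi: np.ndarray
    study_start: float = 0.0
    study_end: float = 1140.0

    def __post_init__(self) -> None:
        psi = np.asarray(self.psi, dtype=float)
        if psi.ndim != 1 or psi.size == 0:
            raise ValueError("psi must be a non-empty 1-D array")
        if np.any(np.diff(psi) <= 0):
            raise ValueError("calibration times must be strictly increasing")
        if psi[0] <= self.study_start or psi[-1] >= self.study_end:
            raise ValueError("calibration times must lie strictly inside the study window")
        object.__setattr__(self, "psi", psi)

    @property
    def n_periods(self) -> int:
        return self.psi.size + 1


def assign_periods(sg_times, schedule: CalibrationSchedule) -> np.ndarray:
    """1-based calibration-period index for each SG time.

    A reading taken exactly at a calibration instant belongs to the *new*
    period (the calibration resets the sensor from that instant), i.e.
    periods are half-open intervals, left-closed at each calibration time.
    """
    t = np.asarray(sg_times, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("sg_times must be sorted ascending")
    if t.size and (t[0] < schedule.study_start or t[-1] > schedule.study_end):
        raise ValueError("sg_times must lie within the study window")
    return np.searchsorted(schedule.psi, t, side="right") + 1


@dataclass
class IndividualParams:
    """One individual's kinetic, calibration and residual parameters.

    ``B``/``logF``/``sigma`` hold one entry per calibration period in the
    calibrated variants; in the basic model ``sigma`` is a scalar and the
    calibration arrays are ``None``.  ``rho`` and ``eta1`` belong to the
    AR variant; ``nig0`` to the variants with an explicit initial state.
    """

    p1: float
    B: Optional[np.ndarray] = None
    logF: Optional[np.ndarray] = None
    sigma: np.ndarray | float = 1.0
    rho: float = 0.0
    eta1: float = 0.0
    nig0: Optional[float] = None

    @property
    def F(self) -> np.ndarray:
        return np.exp(np.asarray(self.logF, dtype=float))

    def validate(self) -> None:
        if not np.isfinite(self.p1) or self.p1 <= 0:
            raise ValueError("p1 must be positive")
        if np.any(np.asarray(self.sigma) <= 0):
            raise ValueError("sigma must be positive")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")


@dataclass
class IndividualData:
    """One individual's SG/BG series and calibration schedule.

    ``sg`` may contain NaN where readings are missing; the ``sg_missing``
    mask flags those entries.  BG values must be complete and positive.
    """

    sg_times: np.ndarray
    sg: np.ndarray
    bg_times: np.ndarray
    bg: np.ndarray
    schedule: CalibrationSchedule
    sg_missing: Optional[np.ndarray] = None
    individual_id: str = "0"
    _periods: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.sg_times = np.asarray(self.sg_times, dtype=float)
        self.sg = np.asarray(self.sg, dtype=float)
        self.bg_times = np.asarray(self.bg_times, dtype=float)
        self.bg = np.asarray(self.bg, dtype=float)
        if self.sg_missing is None:
            self.sg_missing = np.isnan(self.sg)
        self.sg_missing = np.asarray(self.sg_missing, dtype=bool)
        if self.sg_times.shape != self.sg.shape or self.bg_times.shape != self.bg.shape:
            raise ValueError("time and value arrays must have matching shapes")
        if np.any(np.diff(self.sg_times) <= 0) or np.any(np.diff(self.bg_times) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if np.any(self.bg <= 0) or np.any(self.sg[~self.sg_missing] <= 0):
            raise ValueError("observed glucose values must be positive")

    @property
    def n(self) -> int:
        return self.sg_times.size

    @property
    def m(self) -> int:
        return self.bg_times.size

    @property
    def periods(self) -> np.ndarray:
        if self._periods is None:
            self._periods = assign_periods(self.sg_times, self.schedule)
        return self._periods

    def forcing(self) -> ForcingFunction:
        return ForcingFunction(self.bg_times, self.bg)


@dataclass
class Dataset:
    """A study: several individuals sharing one calibration design."""

    individuals: list
    schedule: "object" = None  # StudySchedule-like, optional

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)


def compute_cig(nig_series, params: IndividualParams, periods) -> np.ndarray:
    """Calibrated interstitial glucose: CIG_j = F_{P[j]} NIG_j + B_{P[j]}."""
    k = np.asarray(periods) - 1
    return params.F[k] * np.asarray(nig_series) + np.asarray(params.B)[k]


def initial_nig_from_eta1(sg1: float, eta1: float, B1: float, F1: float) -> float:
    """Initial NIG implied by the first reading and its residual.

    Choosing the ODE's reference time as the first sensor reading lets the
    initial condition be expressed deterministically as
    (SG_1 - eta_1 - B_1)/F_1, so the AR variant needs no separate NIG0
    parameter.
    """
    if F1 <= 0:
        raise ValueError("F1 must be positive")
    nig0 = (sg1 - eta1 - B1) / F1
    if nig0 <= 0:
        raise ValueError("implied initial NIG is non-positive (implausible state)")
    return nig0


def _f_ratio(params: IndividualParams, periods: np.ndarray) -> np.ndarray:
    """F_{P[j]}/F_{P[j-1]} for j>=2; equals one except across calibrations."""
    f = params.F[np.asarray(periods) - 1]
    return f[1:] / f[:-1]


def ar_conditional_means(cig_series, sg_series, rho, params: IndividualParams, periods):
    """One-step conditional means phi of the AR(1) residual model.

    ``phi_1 = CIG_1 + eta_1``; for later readings the previous *observed*
    residual is carried forward, scaled by rho and the calibration-boundary
    F-ratio.  Missing SG values must have been imputed beforehand.
    """
    cig = np.asarray(cig_series, dtype=float)
    sg = np.asarray(sg_series, dtype=float)
    if np.any(np.isnan(sg[:-1])):
        raise ValueError("missing SG values must be imputed before computing phi")
    phi = np.empty_like(cig)
    phi[0] = cig[0] + params.eta1
    phi[1:] = cig[1:] + _f_ratio(params, periods) * rho * (sg[:-1] - cig[:-1])
    return phi


def _nig_for(data: IndividualData, params: IndividualParams, variant: str) -> np.ndarray:
    if variant == "calibrated_ar":
        nig0 = initial_nig_from_eta1(
            data.sg[0], params.eta1, params.B[0], params.F[0]
        )
    else:
        if params.nig0 is None:
            raise ValueError("variant %r requires nig0" % variant)
        nig0 = params.nig0
    f = data.forcing()
    tau, idx = _merged_grid(f, data.sg_times, data.sg_times[0])
    bg_tau = np.interp(tau, f.knot_times, f.knot_values)
    return _exact_kernel(tau, bg_tau, params.p1, nig0)[idx]


def loglik_individual(
    data: IndividualData,
    params: IndividualParams,
    variant: str = "calibrated_ar",
    nig_series=None,
) -> float:
    """Gaussian log-likelihood of one individual's SG series.

    basic          sum_j N(SG_j | NIG_j, sigma_i^2)
    calibrated     sum_j N(SG_j | CIG_j, sigma_{P[j]}^2)
    calibrated_ar  sum_{j>=2} N(SG_j | phi_j, sigma_{P[j]}^2); the first
                   reading is absorbed into the eta_1 construction.
    """
    if variant not in VARIANTS:
        raise ValueError("unknown variant %r" % variant)
    sg = data.sg
    if np.any(np.isnan(sg)):
        raise ValueError("SG contains NaN; impute missing values first")
    nig = _nig_for(data, params, variant) if nig_series is None else np.asarray(nig_series)
    if variant == "basic":
        return float(np.sum(_norm_logpdf(sg, nig, float(np.asarray(params.sigma)))))
    periods = data.periods
    cig = compute_cig(nig, params, periods)
    sd = np.asarray(params.sigma)[periods - 1]
    if variant == "calibrated":
        return float(np.sum(_norm_logpdf(sg, cig, sd)))
    phi = ar_conditional_means(cig, sg, params.rho, params, periods)
    return float(np.sum(_norm_logpdf(sg[1:], phi[1:], sd[1:])))


def simulate_sg(nig_series, params: IndividualParams, periods, rng: np.random.Generator):
    """Forward-simulate an SG series from the AR(1) observation model.

    ``SG_1 = CIG_1 + eta_1``; subsequent residuals follow the AR recursion
    with period-specific innovation SDs.  Returns ``(sg, eta)`` with the
    realised residual series.  The simulator never emits NaN; a warning is
    logged if noise pushes a simulated reading negative.
    """
    periods = np.asarray(periods)
    cig = compute_cig(nig_series, params, periods)
    sd = np.asarray(params.sigma)[periods - 1] * np.ones_like(cig)
    ratio = np.concatenate(([1.0], _f_ratio(params, periods)))
    n = cig.size
    eta = np.empty(n)
    eta[0] = params.eta1
    gamma = rng.normal(0.0, 1.0, size=n) * sd
    for j in range(1, n):
        eta[j] = ratio[j] * params.rho * eta[j - 1] + gamma[j]
    sg = cig + eta
    if np.any(sg <= 0):
        warnings.warn("simulated SG contains non-positive values", RuntimeWarning)
    return sg, eta


def predict_series(data: IndividualData, params: IndividualParams, variant: str = "calibrated_ar"):
    """Model-implied series for diagnostics: NIG, CIG and (AR) phi."""
    nig = _nig_for(data, params, variant)
    out = {"nig": nig}
    if variant != "basic":
        cig = compute_cig(nig, params, data.periods)
        out["cig"] = cig
        if variant == "calibrated_ar":
            out["phi"] = ar_conditional_means(cig, data.sg, params.rho, params, data.periods)
    return out
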