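"""Population model: transforms, priors and summaries.

Individual-level parameters are modelled on transformed scales on which
normal population distributions are sensible:

* calibration vectors ``C_k = (B_k, log F_k)`` are bivariate normal with
  mean ``mu`` and inter-individual covariance ``Sigma`` (three-level
  hierarchy); optionally each individual has its own mean ``omega_i`` with
  intra-individual covariance ``Omega`` (four-level);
* ``log p1`` and ``log sigma`` are normal with unknown means and unknown
  log-standard-deviations;
* the initial residual ``eta_1`` is ``N(0, sd_eta1^2)`` with ``sd_eta1``
  given an informative uniform prior on (0, 0.5), which keeps initial
  residuals above one unlikely;
* the residual autocorrelation is bounded by ``rho_max``; when free,
  ``logit(rho/rho_max)`` carries a vague normal prior.  An individual-
  specific variant (``logit(rho_i/rho_max)`` normal across individuals)
  is retained as an option.

Hyperpriors are vague but proper: normal with SD 100 for location
parameters and log-SDs, inverse-Wishart with degrees of freedom equal to
the dimension (two) for the covariance matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit, logit, multigammaln

from .observation_model import IndividualParams

__all__ = [
    "PopulationParams",
    "HyperPriors",
    "REFERENCE_FITS",
    "default_population",
    "log_prior",
    "sample_individual",
    "population_summaries",
    "delay_prediction_interval",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class PopulationParams:
    """Means, spreads and correlations of the individual-level parameters.

    Defaults are the posterior medians estimated for the Guardian RT
    sensor in the clinical study this package models (calibrated + AR
    model), so that a :class:`PopulationParams` constructed with no
    arguments describes that study population.
    """

    mu: np.ndarray = field(default_factory=lambda: np.array([1.63, -0.202]))  # (B, logF)
    Sigma: np.ndarray = field(
        default_factory=lambda: np.diag([1.37**2, 0.298**2])
    )
    mean_log_p1: float = -2.82
    sd_log_p1: float = 0.166
    mean_log_sigma: float = -2.14
    sd_log_sigma: float = 0.445
    sd_eta1: float = 0.374
    rho: float = 0.8
    rho_max: float = 0.8
    mean_log_nig0: Optional[float] = None
    sd_log_nig0: Optional[float] = None
    # four-level option: intra-individual covariance and per-individual means
    Omega: Optional[np.ndarray] = None
    omega: Optional[np.ndarray] = None
    # individual-specific rho option: logit(rho_i/rho_max) ~ N(mean, sd)
    mean_logit_rho: Optional[float] = None
    sd_logit_rho: Optional[float] = None
    # free shared rho: transformed value logit(rho/rho_max)
    logit_rho_raw: Optional[float] = None

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if self.Sigma.shape != (2, 2) or not np.allclose(self.Sigma, self.Sigma.T):
            raise ValueError("Sigma must be a symmetric 2x2 matrix")
        if np.any(np.linalg.eigvalsh(self.Sigma) <= 0):
            raise ValueError("Sigma must be positive definite")
        if not (0.0 < self.rho_max <= 1.0):
            raise ValueError("rho_max must lie in (0, 1]")
        if not (0.0 < self.sd_eta1 < 0.5):
            raise ValueError("sd_eta1 must lie in (0, 0.5)")


#: Posterior-median population parameters reported for the Guardian RT
#: study under each model variant; used as reference inputs for worked
#: transforms and as the synthetic-data generator's study conditions.
REFERENCE_FITS = {
    "basic": dict(
        mean_log_p1=-3.58,
        sd_log_p1=0.889,
        mean_log_sigma=-0.130,
        sd_log_sigma=0.320,
        mean_log_nig0=2.31,
        sd_log_nig0=0.458,
    ),
    "calibrated": dict(
        mean_log_p1=-2.79,
        sd_log_p1=0.164,
        mu=np.array([1.52, -0.198]),
        Sigma=np.diag([1.76**2, 0.316**2]),
        mean_log_sigma=-1.42,
        sd_log_sigma=0.615,
        mean_log_nig0=2.20,
        sd_log_nig0=0.588,
    ),
    "calibrated_ar": dict(
        mean_log_p1=-2.82,
        sd_log_p1=0.166,
        mu=np.array([1.63, -0.202]),
        Sigma=np.diag([1.37**2, 0.298**2]),
        mean_log_sigma=-2.14,
        sd_log_sigma=0.445,
        sd_eta1=0.374,
        rho=0.8,
        rho_max=0.8,
    ),
}


def default_population(variant: str = "calibrated_ar") -> PopulationParams:
    """Reference study population for the given model variant."""
    return PopulationParams(**REFERENCE_FITS[variant])


@dataclass
class HyperPriors:
    """Vague-but-proper hyperprior settings.

    ``vague_sd`` is the prior SD for every location hyperparameter and for
    the log-SD parameters; covariance matrices get inverse-Wishart priors
    with ``wishart_df`` degrees of freedom (the dimension, for maximal
    vagueness) and scale ``wishart_scale``.  The centres are the analyst's
    best a-priori guesses and are all overridable.
    """

    vague_sd: float = 100.0
    wishart_df: float = 2.0
    wishart_scale: np.ndarray = field(default_factory=lambda: np.eye(2))
    mu_center: np.ndarray = field(default_factory=lambda: np.zeros(2))
    log_p1_center: float = -2.8  # ~16-minute delay
    log_sigma_center: float = -1.0
    log_nig0_center: float = 2.2
    log_sd_center: float = 0.0
    eta1_sd_bound: float = 0.5

    def __post_init__(self) -> None:
        self.wishart_scale = np.asarray(self.wishart_scale, dtype=float)
        self.mu_center = np.asarray(self.mu_center, dtype=float)
        if self.wishart_df < 2:
            raise ValueError("Wishart degrees of freedom must be >= dimension (2)")


def _norm_lpdf(x, mean, sd) -> float:
    z = (x - mean) / sd
    return float(np.sum(-0.5 * _LOG_2PI - np.log(sd) - 0.5 * z * z))


def _invwishart_lpdf(X: np.ndarray, df: float, scale: np.ndarray) -> float:
    d = X.shape[0]
    sign, logdet_x = np.linalg.slogdet(X)
    if sign <= 0:
        return -np.inf
    _, logdet_s = np.linalg.slogdet(scale)
    tr = float(np.trace(scale @ np.linalg.inv(X)))
    return (
        0.5 * df * logdet_s
        - 0.5 * df * d * np.log(2.0)
        - multigammaln(0.5 * df, d)
        - 0.5 * (df + d + 1) * logdet_x
        - 0.5 * tr
    )


def _mvn_lpdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    d = mean.size
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        return -np.inf
    r = np.atleast_2d(np.asarray(x) - mean)
    sol = np.linalg.solve(cov, r.T)
    quad = np.sum(r.T * sol)
    return float(-0.5 * (r.shape[0] * (d * _LOG_2PI + logdet) + quad))


def log_prior(
    pop: PopulationParams,
    hp: HyperPriors,
    variant: str = "calibrated_ar",
    hierarchy_variant: str = "three_level",
) -> float:
    """Joint log prior density of the population-level parameters.

    The sum of independent component densities: vague normals on the
    location parameters and log-SDs, inverse-Wishart on the covariance(s),
    Unif(0, 0.5) on ``sd_eta1`` and, when the shared autocorrelation is a
    free parameter, a vague normal on ``logit(rho/rho_max)``.  Returns
    ``-inf`` outside the support.
    """
    lp = 0.0
    lp += _norm_lpdf(pop.mean_log_p1, hp.log_p1_center, hp.vague_sd)
    lp += _norm_lpdf(np.log(pop.sd_log_p1), hp.log_sd_center, hp.vague_sd)
    lp += _norm_lpdf(pop.mean_log_sigma, hp.log_sigma_center, hp.vague_sd)
    lp += _norm_lpdf(np.log(pop.sd_log_sigma), hp.log_sd_center, hp.vague_sd)
    if variant != "basic":
        lp += _norm_lpdf(pop.mu, hp.mu_center, hp.vague_sd)
        lp += _invwishart_lpdf(pop.Sigma, hp.wishart_df, hp.wishart_scale)
        if hierarchy_variant == "four_level":
            if pop.Omega is None or pop.omega is None:
                raise ValueError("four-level hierarchy requires Omega and omega")
            lp += _invwishart_lpdf(pop.Omega, hp.wishart_df, hp.wishart_scale)
            lp += _mvn_lpdf(pop.omega, pop.mu, pop.Sigma)
    if variant != "calibrated_ar":
        if pop.mean_log_nig0 is None or pop.sd_log_nig0 is None:
            raise ValueError("variant %r requires NIG0 population parameters" % variant)
        lp += _norm_lpdf(pop.mean_log_nig0, hp.log_nig0_center, hp.vague_sd)
        lp += _norm_lpdf(np.log(pop.sd_log_nig0), hp.log_sd_center, hp.vague_sd)
    if variant == "calibrated_ar":
        if not (0.0 < pop.sd_eta1 < hp.eta1_sd_bound):
            return -np.inf
        lp += -np.log(hp.eta1_sd_bound)  # Unif(0, bound)
        if pop.logit_rho_raw is not None:
            lp += _norm_lpdf(pop.logit_rho_raw, 0.0, hp.vague_sd)
        if pop.mean_logit_rho is not None:
            lp += _norm_lpdf(pop.mean_logit_rho, 0.0, hp.vague_sd)
            lp += _norm_lpdf(np.log(pop.sd_logit_rho), hp.log_sd_center, hp.vague_sd)
    return float(lp)


def sample_individual(
    pop: PopulationParams,
    rng: np.random.Generator,
    variant: str = "calibrated_ar",
    n_periods: int = 5,
) -> IndividualParams:
    """Draw one individual's parameters from the population distributions.

    Calibration vectors are MVN2 draws (via ``omega_i`` in the four-level
    variant); ``p1`` and the residual SDs are log-normal; ``eta_1`` is
    centred normal; ``rho_i`` is a bounded logistic-normal draw when
    individual-specific, otherwise the shared value is used.
    """
    p1 = float(np.exp(rng.normal(pop.mean_log_p1, pop.sd_log_p1)))
    if variant == "basic":
        sigma = float(np.exp(rng.normal(pop.mean_log_sigma, pop.sd_log_sigma)))
        nig0 = float(np.exp(rng.normal(pop.mean_log_nig0, pop.sd_log_nig0)))
        return IndividualParams(p1=p1, sigma=sigma, nig0=nig0)
    chol_S = np.linalg.cholesky(pop.Sigma)
    if pop.Omega is not None:
        omega_i = pop.mu + chol_S @ rng.normal(size=2)
        chol_O = np.linalg.cholesky(pop.Omega)
        C = omega_i[None, :] + rng.normal(size=(n_periods, 2)) @ chol_O.T
    else:
        C = pop.mu[None, :] + rng.normal(size=(n_periods, 2)) @ chol_S.T
    sigma = np.exp(rng.normal(pop.mean_log_sigma, pop.sd_log_sigma, size=n_periods))
    if variant == "calibrated":
        nig0 = float(np.exp(rng.normal(pop.mean_log_nig0, pop.sd_log_nig0)))
        return IndividualParams(p1=p1, B=C[:, 0], logF=C[:, 1], sigma=sigma, nig0=nig0)
    eta1 = float(rng.normal(0.0, pop.sd_eta1))
    if pop.mean_logit_rho is not None:
        rho = float(pop.rho_max * expit(rng.normal(pop.mean_logit_rho, pop.sd_logit_rho)))
    else:
        rho = float(pop.rho)
    return IndividualParams(
        p1=p1, B=C[:, 0], logF=C[:, 1], sigma=sigma, rho=rho, eta1=eta1
    )


def _lognormal_summary(mean: float, sd: float, negate: bool = False) -> dict:
    m = -mean if negate else mean
    lo, hi = np.exp(m - 1.96 * sd), np.exp(m + 1.96 * sd)
    if negate:
        lo, hi = min(lo, hi), max(lo, hi)
    return {
        "median": float(np.exp(m)),
        "cv": float(np.sqrt(np.expm1(sd**2))),
        "lower95": float(lo),
        "upper95": float(hi),
    }


def population_summaries(pop: PopulationParams, variant: str = "calibrated_ar") -> dict:
    """Natural-scale medians, CVs and plug-in 95% ranges.

    For a log-normally distributed quantity the median is the exponential
    of its log-scale population mean; the blood-to-sensor delay is
    ``exp(-mean log p1)`` minutes.  The plug-in 95% range ignores
    hyperparameter uncertainty (contrast the posterior-predictive interval
    of :func:`delay_prediction_interval`).
    """
    out = {
        "delay_min": _lognormal_summary(pop.mean_log_p1, pop.sd_log_p1, negate=True),
        "p1_per_min": _lognormal_summary(pop.mean_log_p1, pop.sd_log_p1),
        "sigma_mmol": _lognormal_summary(pop.mean_log_sigma, pop.sd_log_sigma),
    }
    if variant != "basic":
        sdB = float(np.sqrt(pop.Sigma[0, 0]))
        sdF = float(np.sqrt(pop.Sigma[1, 1]))
        out["shift_mmol"] = {
            "median": float(pop.mu[0]),
            "lower95": float(pop.mu[0] - 1.96 * sdB),
            "upper95": float(pop.mu[0] + 1.96 * sdB),
        }
        out["scale_factor"] = _lognormal_summary(float(pop.mu[1]), sdF)
    if variant != "calibrated_ar" and pop.mean_log_nig0 is not None:
        out["nig0_mmol"] = _lognormal_summary(pop.mean_log_nig0, pop.sd_log_nig0)
    return out


def delay_prediction_interval(
    mean_log_p1_draws,
    sd_log_p1_draws,
    rng: np.random.Generator,
    level: float = 0.95,
) -> tuple:
    """Posterior-predictive delay interval for a new individual, minutes.

    Mixes over posterior draws of the population mean and SD of ``log p1``
    (one new-individual draw per posterior draw), so hyperparameter
    uncertainty widens the interval relative to the plug-in range.
    """
    m = np.asarray(mean_log_p1_draws, dtype=float)
    s = np.asarray(sd_log_p1_draws, dtype=float)
    draws = rng.normal(m, s)
    delays = np.exp(-draws)
    a = 0.5 * (1.0 - level)
    return tuple(np.quantile(delays, [a, 1.0 - a]))


def rho_from_raw(logit_rho_raw: float, rho_max: float) -> float:
    """Map the unconstrained shared-autocorrelation parameter to (0, rho_max)."""
    return float(rho_max * expit(logit_rho_raw))


def raw_from_rho(rho: float, rho_max: float) -> float:
    """Inverse of :func:`rho_from_raw`."""
    return float(logit(rho / rho_max))
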