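"""Study-structured synthetic data: schedules, BG curves, virtual patients.

The generator emulates a 19-hour inpatient CGM validation study: the study
window runs from 17:00 (t = 0 min) to 12:00 the next day (t = 1140 min),
with venous blood glucose drawn every 15 min (77 readings), sensor glucose
reported every 5 min starting at minute 5 (228 readings), sensor
calibration shortly after the start and every 6 h thereafter (four events,
hence five calibration periods), and two meals (18:00 and 08:00) whose
carbohydrate content drives BG excursions.

The BG curve model is deliberately statistical, not physiological: a
baseline plus gamma-shaped meal excursions plus a mean-reverting smooth
noise process, clamped to a plausible glycaemic range.  It provides a
forcing input with realistic scale and smoothness; it does not model
insulin action or meal absorption mechanistically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .hierarchy import PopulationParams, default_population, sample_individual
from .kinetics import ForcingFunction, solve_nig_exact, KineticState
from .observation_model import (
    CalibrationSchedule,
    Dataset,
    IndividualData,
    IndividualParams,
    assign_periods,
    simulate_sg,
)

__all__ = [
    "StudySchedule",
    "BgSimConfig",
    "make_schedule",
    "simulate_bg",
    "simulate_study",
    "virtual_patients",
]


@dataclass(frozen=True)
class StudySchedule:
    """Observation and calibration time grids of the study design.

    Times are minutes from study start (17:00).  The SG grid starts one
    sampling interval after the window opens while the BG grid starts at
    zero; this is the only grid convention consistent with 77 BG and 228
    SG readings over the 1140-minute window.
    """

    study_start: float = 0.0
    study_end: float = 1140.0
    bg_interval: float = 15.0
    sg_interval: float = 5.0
    psi: tuple = (20.0, 380.0, 740.0, 1100.0)
    meal_times: tuple = (60.0, 900.0)

    @property
    def bg_times(self) -> np.ndarray:
        return np.arange(self.study_start, self.study_end + 0.5 * self.bg_interval, self.bg_interval)

    @property
    def sg_times(self) -> np.ndarray:
        return np.arange(
            self.study_start + self.sg_interval,
            self.study_end + 0.5 * self.sg_interval,
            self.sg_interval,
        )

    @property
    def n_bg(self) -> int:
        return self.bg_times.size

    @property
    def n_sg(self) -> int:
        return self.sg_times.size

    @property
    def calibration(self) -> CalibrationSchedule:
        return CalibrationSchedule(
            np.asarray(self.psi, dtype=float), self.study_start, self.study_end
        )

    @property
    def n_periods(self) -> int:
        return len(self.psi) + 1


def make_schedule(
    study_start: float = 0.0,
    study_end: float = 1140.0,
    bg_interval: float = 15.0,
    sg_interval: float = 5.0,
    psi: tuple = (20.0, 380.0, 740.0, 1100.0),
    meal_times: tuple = (60.0, 900.0),
) -> StudySchedule:
    """Build and validate a study schedule (defaults: the reference design)."""
    window = study_end - study_start
    if window <= 0:
        raise ValueError("study_end must exceed study_start")
    for name, interval in (("bg_interval", bg_interval), ("sg_interval", sg_interval)):
        if interval <= 0 or abs(round(window / interval) - window / interval) > 1e-9:
            raise ValueError(f"{name} must be positive and divide the study window")
    sched = StudySchedule(study_start, study_end, bg_interval, sg_interval, tuple(psi), tuple(meal_times))
    sched.calibration  # validates psi
    return sched


@dataclass
class BgSimConfig:
    """Settings of the blood-glucose curve generator.

    ``carb_to_peak`` converts grams of carbohydrate to the peak height of
    a meal excursion (mmol/L per g); it is invented plumbing with a
    defensible scale, not an estimate from data.  The smooth-noise process
    is a discretised Ornstein-Uhlenbeck process.
    """

    baseline_mean: float = 8.0  # mmol/L
    baseline_sd: float = 1.5
    carb_mean: float = 87.0  # g, per meal
    carb_sd: float = 23.0
    carb_to_peak: float = 0.05  # mmol/L per g
    excursion_tau: float = 40.0  # minutes to excursion peak
    noise_sd: float = 0.5  # stationary SD of smooth noise, mmol/L
    noise_corr_time: float = 45.0  # minutes
    clamp: tuple = (2.5, 20.0)  # physiological range, mmol/L


def _meal_bump(t: np.ndarray, t_meal: float, peak: float, tau: float) -> np.ndarray:
    """Gamma-shaped excursion peaking ``tau`` minutes after the meal."""
    x = np.clip(t - t_meal, 0.0, None) / tau
    return peak * x * np.exp(1.0 - x)


def simulate_bg(
    schedule: StudySchedule,
    cfg: Optional[BgSimConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Simulate a BG series on the schedule's BG grid (mmol/L)."""
    cfg = cfg or BgSimConfig()
    rng = rng if rng is not None else np.random.default_rng()
    t = schedule.bg_times
    bg = np.full(t.shape, rng.normal(cfg.baseline_mean, cfg.baseline_sd))
    for t_meal in schedule.meal_times:
        carbs = max(rng.normal(cfg.carb_mean, cfg.carb_sd), 0.0)
        bg += _meal_bump(t, t_meal, carbs * cfg.carb_to_peak, cfg.excursion_tau)
    # mean-reverting smooth noise: stationary AR(1) on the BG grid
    dt = schedule.bg_interval
    a = np.exp(-dt / cfg.noise_corr_time)
    innov_sd = cfg.noise_sd * np.sqrt(1.0 - a * a)
    noise = np.empty(t.shape)
    noise[0] = rng.normal(0.0, cfg.noise_sd)
    for i in range(1, t.size):
        noise[i] = a * noise[i - 1] + rng.normal(0.0, innov_sd)
    return np.clip(bg + noise, *cfg.clamp)


def _simulate_individual(
    params: IndividualParams,
    schedule: StudySchedule,
    bg_cfg: BgSimConfig,
    rng: np.random.Generator,
    individual_id: str,
    missing_rate: float,
) -> IndividualData:
    bg = simulate_bg(schedule, bg_cfg, rng)
    forcing = ForcingFunction(schedule.bg_times, bg)
    sg_times = schedule.sg_times
    # the eta1-implied initial state: start the sensor at the forcing level,
    # so SG_1 = F_1*NIG_1 + B_1 + eta_1 is consistent with
    # NIG_1 = (SG_1 - eta_1 - B_1)/F_1
    nig0 = float(forcing(sg_times[0]))
    nig = solve_nig_exact(KineticState(params.p1, nig0), forcing, sg_times, sg_times[0])
    periods = assign_periods(sg_times, schedule.calibration)
    sg, _ = simulate_sg(nig, params, periods, rng)
    sg = sg.copy()
    mask = rng.random(sg.size) < missing_rate
    sg[mask] = np.nan
    return IndividualData(
        sg_times=sg_times,
        sg=sg,
        bg_times=schedule.bg_times,
        bg=bg,
        schedule=schedule.calibration,
        sg_missing=mask,
        individual_id=individual_id,
    )


def simulate_study(
    pop: Optional[PopulationParams] = None,
    n_individuals: int = 12,
    schedule: Optional[StudySchedule] = None,
    missing_rate: float = 0.01,
    rng: Optional[np.random.Generator] = None,
    bg_config: Optional[BgSimConfig] = None,
    variant: str = "calibrated_ar",
):
    """Simulate a full study and return ``(dataset, truths)``.

    Each individual gets parameters drawn from ``pop`` (default: the
    reference study population), a fresh BG curve, the exact ODE solution
    as the latent NIG series, calibration-period affine mapping, AR(1)
    sensor noise, and missing-completely-at-random SG masking.  ``truths``
    records the generating parameters so fits can be checked blind.
    """
    pop = pop or default_population()
    schedule = schedule or make_schedule()
    rng = rng if rng is not None else np.random.default_rng()
    bg_config = bg_config or BgSimConfig()
    individuals = []
    truths_ind = []
    for i in range(n_individuals):
        params = sample_individual(pop, rng, variant=variant, n_periods=schedule.n_periods)
        data = _simulate_individual(params, schedule, bg_config, rng, str(i + 1), missing_rate)
        individuals.append(data)
        truths_ind.append(
            {
                "individual_id": str(i + 1),
                "p1": params.p1,
                "delay_min": 1.0 / params.p1,
                "B": None if params.B is None else list(map(float, params.B)),
                "logF": None if params.logF is None else list(map(float, params.logF)),
                "sigma": np.asarray(params.sigma).tolist(),
                "rho": params.rho,
                "eta1": params.eta1,
            }
        )
    truths = {
        "population": {
            "mu": pop.mu.tolist(),
            "Sigma": pop.Sigma.tolist(),
            "mean_log_p1": pop.mean_log_p1,
            "sd_log_p1": pop.sd_log_p1,
            "mean_log_sigma": pop.mean_log_sigma,
            "sd_log_sigma": pop.sd_log_sigma,
            "sd_eta1": pop.sd_eta1,
            "rho": pop.rho,
        },
        "individuals": truths_ind,
        "variant": variant,
        "missing_rate": missing_rate,
    }
    return Dataset(individuals=individuals, schedule=schedule), truths


def virtual_patients(
    source,
    n_patients: int,
    schedule: Optional[StudySchedule] = None,
    bg_inputs=None,
    rng: Optional[np.random.Generator] = None,
    bg_config: Optional[BgSimConfig] = None,
):
    """Simulate SG traces for new 'virtual patients'.

    ``source`` is either a :class:`PopulationParams` (plug-in values) or a
    fitted MCMC trace, in which case one posterior draw of the population
    hyperparameters is used per patient so that hyperparameter uncertainty
    propagates into the simulated cohort.  ``bg_inputs`` may supply
    observed BG forcing functions; by default BG curves are simulated.
    """
    schedule = schedule or make_schedule()
    rng = rng if rng is not None else np.random.default_rng()
    bg_config = bg_config or BgSimConfig()
    out = []
    for i in range(n_patients):
        pop = _pop_from_source(source, rng)
        params = sample_individual(pop, rng, variant="calibrated_ar", n_periods=schedule.n_periods)
        if bg_inputs is not None:
            forcing = bg_inputs[i % len(bg_inputs)]
            bg = forcing(schedule.bg_times)
        else:
            bg = simulate_bg(schedule, bg_config, rng)
            forcing = ForcingFunction(schedule.bg_times, bg)
        sg_times = schedule.sg_times
        nig0 = float(forcing(sg_times[0]))
        nig = solve_nig_exact(KineticState(params.p1, nig0), forcing, sg_times, sg_times[0])
        periods = assign_periods(sg_times, schedule.calibration)
        sg, eta = simulate_sg(nig, params, periods, rng)
        out.append(
            {
                "sg_times": sg_times,
                "sg": sg,
                "bg_times": schedule.bg_times,
                "bg": bg,
                "nig": nig,
                "eta": eta,
                "params": params,
            }
        )
    return out


def _pop_from_source(source, rng: np.random.Generator) -> PopulationParams:
    if isinstance(source, PopulationParams):
        return source
    samples = source.samples  # fitted-trace duck type
    n_chain, n_draw = samples["mean_log_p1"].shape[:2]
    c = int(rng.integers(n_chain))
    d = int(rng.integers(n_draw))
    rho = samples["rho"][c, d] if "rho" in samples else 0.8
    return PopulationParams(
        mu=samples["mu"][c, d],
        Sigma=samples["Sigma"][c, d],
        mean_log_p1=float(samples["mean_log_p1"][c, d]),
        sd_log_p1=float(samples["sd_log_p1"][c, d]),
        mean_log_sigma=float(samples["mean_log_sigma"][c, d]),
        sd_log_sigma=float(samples["sd_log_sigma"][c, d]),
        sd_eta1=float(samples.get("sd_eta1", np.full((n_chain, n_draw), 0.374))[c, d]),
        rho=float(np.asarray(rho).reshape(-1)[0]),
    )
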