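"""MCMC inference for the calibration models.

The sampler is an adaptive random-walk Metropolis-within-Gibbs scheme over
all unknowns: individual-level transformed parameters (``log p1``,
calibration vectors ``C_ik = (B_ik, log F_ik)`` updated as 2-blocks,
``log sigma_ik``, initial residuals ``eta_i1``), missing SG readings
(latent variables), the shared or individual residual autocorrelation, and
the population hyperparameters.  Conjugate Gibbs steps are used where
available — the multivariate-normal mean(s) and inverse-Wishart
covariance(s) of the calibration vectors and the normal population means —
which markedly improves mixing of the calibration blocks; everything else
is Metropolis with per-parameter step sizes tuned during burn-in toward
0.44 acceptance for scalar updates and 0.23 for blocks, then frozen.

Four treatments of the autocorrelation ``rho`` are supported:

* ``free_bounded`` — ``logit(rho/rho_max)`` is a free parameter with a
  vague normal prior, so ``rho`` cannot exceed the bound ``rho_max``;
* ``fixed`` — ``rho`` held at a constant;
* ``distributional_constant`` — ``rho`` is resampled each iteration from
  Unif(0.75, 0.85) with the likelihood prevented from updating it (cut
  feedback: information flows prior -> likelihood only);
* the duplicated-data cut of :func:`fit_duplicated` — the SG data are
  duplicated, a homoscedastic calibrated likelihood drives ``B``, ``F``,
  ``p1`` and their hyperparameters, and an AR(1) likelihood built on the
  resulting CIG series drives only ``rho`` (now unconstrained) and its
  innovation SDs, with a valve blocking information flow back to
  ``B``/``F``/``p1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import invwishart

from .hierarchy import HyperPriors
from .kinetics import _exact_kernel, _merged_grid
from .observation_model import (
    Dataset,
    IndividualData,
    IndividualParams,
    loglik_individual,
)

__all__ = [
    "McmcConfig",
    "McmcTrace",
    "fit",
    "fit_duplicated",
    "rho_update",
    "dic",
    "dic_from_deviance",
    "DicResult",
    "diagnostics_report",
    "summary_table",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def _exp(x: float) -> float:
    """exp that saturates to inf instead of raising on overflow."""
    return float(np.exp(x))


RHO_MODES = ("free_bounded", "fixed", "distributional_constant", "duplicated_cut")


@dataclass
class McmcConfig:
    """Run-length, seeding, adaptation and rho-treatment settings.

    Defaults are a scaled-down run (20k iterations, half burn-in, thinning
    by five) suitable for the reference study size on a single CPU; longer
    runs are a matter of raising ``n_iter``.
    """

    n_iter: int = 20_000
    burn_in: int = 10_000
    thin: int = 5
    seed: int = 0
    n_chains: int = 1
    rho_mode: str = "free_bounded"
    rho_value: float = 0.8
    rho_max: float = 0.8
    rho_shared: bool = True
    rho_cut_low: float = 0.75
    rho_cut_high: float = 0.85
    target_accept_scalar: float = 0.44
    target_accept_block: float = 0.23
    adapt: bool = True
    progress_every: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.rho_mode not in RHO_MODES:
            raise ValueError("unknown rho_mode %r" % self.rho_mode)


@dataclass
class McmcTrace:
    """Thinned posterior samples with chain metadata.

    ``samples`` maps parameter names to arrays shaped
    ``(n_chains, n_draws, ...)``; ``missing_map`` lists the
    ``(individual_index, sg_index)`` coordinates of the imputed readings in
    the ``sg_missing`` sample array.
    """

    samples: dict
    variant: str
    hierarchy_variant: str
    config: McmcConfig
    acceptance: dict = field(default_factory=dict)
    missing_map: list = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return next(iter(self.samples.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.samples.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Samples of ``name`` with chains concatenated along axis 0."""
        a = self.samples[name]
        return a.reshape((-1,) + a.shape[2:])

    def to_inference_data(self):
        import arviz as az

        return az.from_dict({k: v for k, v in self.samples.items()})


def _norm_lpdf_scalar(x: float, mean: float, sd: float) -> float:
    z = (x - mean) / sd
    return -0.5 * _LOG_2PI - math.log(sd) - 0.5 * z * z


class _ChainSampler:
    """Single-chain state and update steps; see module docstring."""

    def __init__(
        self,
        dataset: Dataset,
        variant: str,
        hierarchy_variant: str,
        config: McmcConfig,
        hp: HyperPriors,
        rng: np.random.Generator,
        extra_ll: Optional[Callable] = None,
    ):
        self.variant = variant
        self.hier = hierarchy_variant
        self.cfg = config
        self.hp = hp
        self.rng = rng
        self.extra_ll = extra_ll
        self.individuals = list(dataset.individuals)
        self.N = len(self.individuals)
        sched = None
        if self.N:
            sched = self.individuals[0].schedule
        elif dataset.schedule is not None:
            sched = dataset.schedule.calibration
        self.P = 1 if variant == "basic" else (sched.n_periods if sched is not None else 5)

        # per-individual fixed structures
        self.sg = []
        self.miss = []
        self.pidx = []
        self.grid = []  # (tau, bg_tau, eval_idx)
        for d in self.individuals:
            sg = d.sg.copy()
            miss = np.flatnonzero(d.sg_missing)
            if miss.size:
                obs = np.flatnonzero(~d.sg_missing)
                sg[miss] = np.interp(d.sg_times[miss], d.sg_times[obs], sg[obs])
            self.sg.append(sg)
            self.miss.append(miss)
            self.pidx.append(d.periods - 1 if variant != "basic" else np.zeros(d.n, dtype=int))
            f = d.forcing()
            tau, idx = _merged_grid(f, d.sg_times, d.sg_times[0])
            self.grid.append((tau, np.interp(tau, f.knot_times, f.knot_values), idx))

        self._init_state()
        self.block_stats: dict = {}
        self.logstep: dict = {}
        self.acount: dict = {}
        self.acc_accum: dict = {}
        self.adapting = False
        self.nig = [None] * self.N
        self.nig0 = np.zeros(self.N)
        self.ll = np.zeros(self.N)
        for i in range(self.N):
            self._refresh_individual(i)
            if not np.isfinite(self.ll[i]):
                raise RuntimeError(
                    f"non-finite initial log-likelihood for individual "
                    f"{self.individuals[i].individual_id!r}"
                )

    # ------------------------------------------------------------------ init

    def _init_state(self) -> None:
        rng, hp, N, P = self.rng, self.hp, self.N, self.P
        jit = 0.1
        self.log_p1 = hp.log_p1_center + jit * rng.normal(size=N)
        self.m_lp1 = hp.log_p1_center
        self.lsd_lp1 = math.log(0.3)
        self.m_lsig = hp.log_sigma_center
        self.lsd_lsig = math.log(0.3)
        if self.variant == "basic":
            self.log_sig = hp.log_sigma_center + jit * rng.normal(size=N)
        else:
            self.log_sig = hp.log_sigma_center + jit * rng.normal(size=(N, P))
            self.C = np.tile(hp.mu_center, (N, P, 1)) + jit * rng.normal(size=(N, P, 2))
            self.mu = hp.mu_center.astype(float).copy()
            self.Sigma = np.eye(2) * 0.5
            self._sync_cov()
            if self.hier == "four_level":
                self.Omega = np.eye(2) * 0.5
                self.Omega_inv = np.linalg.inv(self.Omega)
                self.omega = self.C.mean(axis=1) if N else np.zeros((0, 2))
        if self.variant == "calibrated_ar":
            self.eta1 = np.zeros(N)
            self.sd_eta1 = 0.25
            mode = self.cfg.rho_mode
            if mode == "fixed":
                self.rho = float(self.cfg.rho_value)
            elif mode == "distributional_constant":
                self.rho = 0.5 * (self.cfg.rho_cut_low + self.cfg.rho_cut_high)
            elif mode == "duplicated_cut":
                self.rho = 0.5
            elif self.cfg.rho_shared:
                self.z_rho = 0.0
                self.rho = self.cfg.rho_max * 0.5
            else:
                self.z_rho_i = np.zeros(N)
                self.rho_i = np.full(N, self.cfg.rho_max * 0.5)
                self.m_zrho = 0.0
                self.lsd_zrho = math.log(0.3)
        else:
            self.log_nig0 = np.array(
                [math.log(max(sg[0], 1e-2)) for sg in self.sg] if self.N else [],
                dtype=float,
            )
            self.log_nig0 += jit * rng.normal(size=N)
            self.m_lnig0 = hp.log_nig0_center
            self.lsd_lnig0 = math.log(0.3)

    def _sync_cov(self) -> None:
        self.Sigma_inv = np.linalg.inv(self.Sigma)
        self.Sigma_chol = np.linalg.cholesky(self.Sigma)

    # ------------------------------------------------------- likelihood bits

    def _rho_for(self, i: int):
        if self.variant != "calibrated_ar":
            return 0.0
        if self.cfg.rho_mode == "free_bounded" and not self.cfg.rho_shared:
            return self.rho_i[i]
        return self.rho

    def _solve_nig(self, i: int, p1: float, nig0: float) -> np.ndarray:
        tau, bg_tau, idx = self.grid[i]
        return _exact_kernel(tau, bg_tau, p1, nig0)[idx]

    def _implied_nig0(self, i: int, eta1: float, C_i: np.ndarray, sg0: Optional[float] = None):
        sg0 = self.sg[i][0] if sg0 is None else sg0
        return (sg0 - eta1 - C_i[0, 0]) / math.exp(C_i[0, 1])

    def _ll_calc(self, i, nig, C_i, log_sig_i, eta1_i, rho_i, sg=None) -> float:
        sg = self.sg[i] if sg is None else sg
        pidx = self.pidx[i]
        if self.variant == "basic":
            sd = math.exp(float(log_sig_i))
            r = (sg - nig) / sd
            ll = -sg.size * (0.5 * _LOG_2PI + math.log(sd)) - 0.5 * float(r @ r)
        else:
            F = np.exp(C_i[:, 1])
            Fp = F[pidx]
            cig = Fp * nig + C_i[pidx, 0]
            sd = np.exp(log_sig_i)[pidx]
            if self.variant == "calibrated":
                r = (sg - cig) / sd
                ll = float(np.sum(-0.5 * _LOG_2PI - np.log(sd) - 0.5 * r * r))
            else:
                ratio = Fp[1:] / Fp[:-1]
                phi = cig[1:] + ratio * rho_i * (sg[:-1] - cig[:-1])
                r = (sg[1:] - phi) / sd[1:]
                ll = float(np.sum(-0.5 * _LOG_2PI - np.log(sd[1:]) - 0.5 * r * r))
        if not np.isfinite(ll):
            return -np.inf
        if self.extra_ll is not None:
            ll += self.extra_ll(i, nig, C_i)
        return ll

    def _ll_current(self, i: int) -> float:
        return self._ll_calc(
            i,
            self.nig[i],
            self.C[i] if self.variant != "basic" else None,
            self.log_sig[i],
            self.eta1[i] if self.variant == "calibrated_ar" else 0.0,
            self._rho_for(i),
        )

    def _refresh_individual(self, i: int) -> None:
        if self.variant == "calibrated_ar":
            self.nig0[i] = self._implied_nig0(i, self.eta1[i], self.C[i])
        else:
            self.nig0[i] = math.exp(self.log_nig0[i])
        self.nig[i] = self._solve_nig(i, math.exp(self.log_p1[i]), self.nig0[i])
        self.ll[i] = self._ll_current(i)

    # --------------------------------------------------------- MH machinery

    def _step(self, key, init=-1.0) -> float:
        return self.logstep.setdefault(key, init)

    def _adapt(self, key, acc: float, target: float) -> None:
        if not self.adapting:
            return
        n = self.acount[key] = self.acount.get(key, 0) + 1
        self.logstep[key] += min(0.5, 1.5 * n ** -0.6) * (acc - target)

    def _track(self, key, accepted: bool) -> None:
        if self.adapting:
            return
        fam = key[0] if isinstance(key, tuple) else key
        s, c = self.acc_accum.get(fam, (0, 0))
        self.acc_accum[fam] = (s + int(accepted), c + 1)

    def _accept(self, la: float) -> tuple:
        acc = 0.0 if la == -np.inf else min(1.0, math.exp(min(la, 0.0)))
        return math.log(self.rng.random()) < la, acc

    # ------------------------------------------------------ individual steps

    def _upd_log_p1(self, i: int) -> None:
        key = ("log_p1", i)
        prop = self.log_p1[i] + math.exp(self._step(key)) * self.rng.normal()
        nigp = self._solve_nig(i, math.exp(prop), self.nig0[i])
        llp = self._ll_calc(
            i,
            nigp,
            self.C[i] if self.variant != "basic" else None,
            self.log_sig[i],
            self.eta1[i] if self.variant == "calibrated_ar" else 0.0,
            self._rho_for(i),
        )
        sd = _exp(self.lsd_lp1)
        la = (
            llp
            - self.ll[i]
            + _norm_lpdf_scalar(prop, self.m_lp1, sd)
            - _norm_lpdf_scalar(self.log_p1[i], self.m_lp1, sd)
        )
        ok, acc = self._accept(la)
        if ok:
            self.log_p1[i] = prop
            self.nig[i] = nigp
            self.ll[i] = llp
        self._adapt(key, acc, self.cfg.target_accept_scalar)
        self._track(key, ok)

    def _upd_log_nig0(self, i: int) -> None:
        key = ("log_nig0", i)
        prop = self.log_nig0[i] + math.exp(self._step(key)) * self.rng.normal()
        nigp = self._solve_nig(i, math.exp(self.log_p1[i]), math.exp(prop))
        llp = self._ll_calc(
            i, nigp, self.C[i] if self.variant != "basic" else None, self.log_sig[i], 0.0, 0.0
        )
        sd = _exp(self.lsd_lnig0)
        la = (
            llp
            - self.ll[i]
            + _norm_lpdf_scalar(prop, self.m_lnig0, sd)
            - _norm_lpdf_scalar(self.log_nig0[i], self.m_lnig0, sd)
        )
        ok, acc = self._accept(la)
        if ok:
            self.log_nig0[i] = prop
            self.nig0[i] = math.exp(prop)
            self.nig[i] = nigp
            self.ll[i] = llp
        self._adapt(key, acc, self.cfg.target_accept_scalar)
        self._track(key, ok)

    def _c_prior_quad(self, i: int, c: np.ndarray, k: int) -> float:
        if self.hier == "four_level":
            d = c - self.omega[i]
            return -0.5 * float(d @ self.Omega_inv @ d)
        d = c - self.mu
        return -0.5 * float(d @ self.Sigma_inv @ d)

    def _block_chol(self, key, cur: np.ndarray) -> np.ndarray:
        """Adaptive proposal shape for 2-blocks (Haario-style).

        The empirical covariance of the block's trajectory is accumulated
        during burn-in (Welford updates) and its Cholesky factor shapes the
        random-walk proposal, which lets the chain travel along the strong
        B / log F ridge of the calibration posterior.  Frozen, like the
        step sizes, once burn-in ends.
        """
        st = self.block_stats.setdefault(
            key, [0, np.zeros(2), np.zeros((2, 2)), np.eye(2)]
        )
        if self.adapting:
            n = st[0] = st[0] + 1
            delta = cur - st[1]
            st[1] = st[1] + delta / n
            st[2] = st[2] + np.outer(delta, cur - st[1])
            if n >= 100 and n % 25 == 0:
                cov = st[2] / (n - 1) + 1e-9 * np.eye(2)
                try:
                    st[3] = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    pass
        return st[3]

    def _upd_C(self, i: int, k: int) -> None:
        key = ("C", i, k)
        L = self._block_chol(key, self.C[i, k])
        prop = self.C[i, k] + math.exp(self._step(key, init=-2.0)) * (
            L @ self.rng.normal(size=2)
        )
        Cp = self.C[i].copy()
        Cp[k] = prop
        nigp, nig0p = self.nig[i], self.nig0[i]
        la = None
        if self.variant == "calibrated_ar" and k == 0:
            nig0p = self._implied_nig0(i, self.eta1[i], Cp)
            if nig0p <= 0:
                la = -np.inf
            else:
                nigp = self._solve_nig(i, math.exp(self.log_p1[i]), nig0p)
        if la is None:
            llp = self._ll_calc(
                i,
                nigp,
                Cp,
                self.log_sig[i],
                self.eta1[i] if self.variant == "calibrated_ar" else 0.0,
                self._rho_for(i),
            )
            la = (
                llp
                - self.ll[i]
                + self._c_prior_quad(i, prop, k)
                - self._c_prior_quad(i, self.C[i, k], k)
            )
        ok, acc = self._accept(la)
        if ok:
            self.C[i, k] = prop
            self.nig[i] = nigp
            self.nig0[i] = nig0p
            self.ll[i] = llp
        self._adapt(key, acc, self.cfg.target_accept_block)
        self._track(key, ok)

    def _upd_log_sig(self, i: int, k: Optional[int]) -> None:
        key = ("log_sig", i, -1 if k is None else k)
        cur = self.log_sig[i] if k is None else self.log_sig[i, k]
        prop = cur + math.exp(self._step(key)) * self.rng.normal()
        if k is None:
            lsp = prop
        else:
            lsp = self.log_sig[i].copy()
            lsp[k] = prop
        llp = self._ll_calc(
            i,
            self.nig[i],
            self.C[i] if self.variant != "basic" else None,
            lsp,
            self.eta1[i] if self.variant == "calibrated_ar" else 0.0,
            self._rho_for(i),
        )
        sd = _exp(self.lsd_lsig)
        la = (
            llp
            - self.ll[i]
            + _norm_lpdf_scalar(prop, self.m_lsig, sd)
            - _norm_lpdf_scalar(cur, self.m_lsig, sd)
        )
        ok, acc = self._accept(la)
        if ok:
            if k is None:
                self.log_sig[i] = prop
            else:
                self.log_sig[i, k] = prop
            self.ll[i] = llp
        self._adapt(key, acc, self.cfg.target_accept_scalar)
        self._track(key, ok)

    def _upd_eta1(self, i: int) -> None:
        key = ("eta1", i)
        prop = self.eta1[i] + math.exp(self._step(key)) * self.rng.normal()
        nig0p = self._implied_nig0(i, prop, self.C[i])
        if nig0p <= 0:
            la = -np.inf
        else:
            nigp = self._solve_nig(i, math.exp(self.log_p1[i]), nig0p)
            llp = self._ll_calc(i, nigp, self.C[i], self.log_sig[i], prop, self._rho_for(i))
            la = (
                llp
                - self.ll[i]
                + _norm_lpdf_scalar(prop, 0.0, self.sd_eta1)
                - _norm_lpdf_scalar(self.eta1[i], 0.0, self.sd_eta1)
            )
        ok, acc = self._accept(la)
        if ok:
            self.eta1[i] = prop
            self.nig0[i] = nig0p
            self.nig[i] = nigp
            self.ll[i] = llp
        self._adapt(key, acc, self.cfg.target_accept_scalar)
        self._track(key, ok)

    def _upd_missing(self, i: int) -> None:
        miss = self.miss[i]
        if miss.size == 0:
            return
        sg = self.sg[i]
        pidx = self.pidx[i]
        if self.variant == "basic":
            sd = math.exp(float(self.log_sig[i]))
            for j in miss:
                sg[j] = self.nig[i][j] + sd * self.rng.normal()
            self.ll[i] = self._ll_current(i)
            return
        F = np.exp(self.C[i][:, 1])
        Fp = F[pidx]
        cig = Fp * self.nig[i] + self.C[i][pidx, 0]
        sd = np.exp(self.log_sig[i])[pidx]
        if self.variant == "calibrated":
            for j in miss:
                sg[j] = cig[j] + sd[j] * self.rng.normal()
            self.ll[i] = self._ll_current(i)
            return
        rho = self._rho_for(i)
        n = sg.size
        for j in miss:
            if j == 0:
                # SG_1 sets the initial condition; Metropolis step
                key = ("sg0", i)
                prop = sg[0] + math.exp(self._step(key)) * self.rng.normal()
                nig0p = self._implied_nig0(i, self.eta1[i], self.C[i], sg0=prop)
                if nig0p <= 0 or prop <= 0:
                    la = -np.inf
                else:
                    nigp = self._solve_nig(i, math.exp(self.log_p1[i]), nig0p)
                    sgp = sg.copy()
                    sgp[0] = prop
                    llp = self._ll_calc(
                        i, nigp, self.C[i], self.log_sig[i], self.eta1[i], rho, sg=sgp
                    )
                    la = llp - self.ll[i]
                ok, acc = self._accept(la)
                if ok:
                    sg[0] = prop
                    self.nig0[i] = nig0p
                    self.nig[i] = nigp
                    self.ll[i] = llp
                    F = np.exp(self.C[i][:, 1])
                    Fp = F[pidx]
                    cig = Fp * self.nig[i] + self.C[i][pidx, 0]
                self._adapt(key, acc, self.cfg.target_accept_scalar)
                self._track(key, ok)
            else:
                r_j = Fp[j] / Fp[j - 1]
                phi_j = cig[j] + r_j * rho * (sg[j - 1] - cig[j - 1])
                prec = 1.0 / sd[j] ** 2
                num = phi_j / sd[j] ** 2
                if j + 1 < n:
                    a = (Fp[j + 1] / Fp[j]) * rho
                    prec += a * a / sd[j + 1] ** 2
                    num += a * (sg[j + 1] - cig[j + 1] + a * cig[j]) / sd[j + 1] ** 2
                sg[j] = num / prec + math.sqrt(1.0 / prec) * self.rng.normal()
        self.ll[i] = self._ll_current(i)

    # ------------------------------------------------------------- rho step

    def _upd_rho(self) -> None:
        mode = self.cfg.rho_mode
        if self.variant != "calibrated_ar" or mode in ("fixed", "duplicated_cut"):
            return
        if mode == "distributional_constant":
            # cut feedback: a fresh prior draw, likelihood ignored
            self.rho = float(self.rng.uniform(self.cfg.rho_cut_low, self.cfg.rho_cut_high))
            for i in range(self.N):
                self.ll[i] = self._ll_current(i)
            return
        if self.cfg.rho_shared:
            key = "z_rho"
            prop = self.z_rho + math.exp(self._step(key)) * self.rng.normal()
            rhop = self.cfg.rho_max * float(expit(prop))
            llp = np.array(
                [
                    self._ll_calc(i, self.nig[i], self.C[i], self.log_sig[i], self.eta1[i], rhop)
                    for i in range(self.N)
                ]
            )
            la = (
                float(np.sum(llp) - np.sum(self.ll))
                + _norm_lpdf_scalar(prop, 0.0, self.hp.vague_sd)
                - _norm_lpdf_scalar(self.z_rho, 0.0, self.hp.vague_sd)
            )
            ok, acc = self._accept(la)
            if ok:
                self.z_rho = prop
                self.rho = rhop
                self.ll = llp
            self._adapt(key, acc, self.cfg.target_accept_scalar)
            self._track(key, ok)
        else:
            sd = _exp(self.lsd_zrho)
            for i in range(self.N):
                key = ("z_rho_i", i)
                prop = self.z_rho_i[i] + math.exp(self._step(key)) * self.rng.normal()
                rhop = self.cfg.rho_max * float(expit(prop))
                llp = self._ll_calc(
                    i, self.nig[i], self.C[i], self.log_sig[i], self.eta1[i], rhop
                )
                la = (
                    llp
                    - self.ll[i]
                    + _norm_lpdf_scalar(prop, self.m_zrho, sd)
                    - _norm_lpdf_scalar(self.z_rho_i[i], self.m_zrho, sd)
                )
                ok, acc = self._accept(la)
                if ok:
                    self.z_rho_i[i] = prop
                    self.rho_i[i] = rhop
                    self.ll[i] = llp
                self._adapt(key, acc, self.cfg.target_accept_scalar)
                self._track(key, ok)

    # ----------------------------------------------------------- hyper steps

    def _gibbs_mean(self, values: np.ndarray, sd: float, center: float) -> float:
        v0 = self.hp.vague_sd
        var = sd * sd  # may saturate to inf or 0 under a prior-only walk
        if values.size == 0 or not np.isfinite(var):
            # no data term, or an infinitely diffuse population: the prior
            prec = 1.0 / v0**2
            num = center / v0**2
        elif var <= 0.0:
            # degenerate population: the mean is pinned at the sample mean
            return float(values.mean()) + 0.0 * self.rng.normal()
        else:
            prec = 1.0 / v0**2 + values.size / var
            num = center / v0**2 + values.sum() / var
        return num / prec + math.sqrt(1.0 / prec) * self.rng.normal()

    def _mh_lsd(self, key: str, cur: float, values: np.ndarray, mean: float) -> float:
        prop = cur + math.exp(self._step(key)) * self.rng.normal()
        sdp, sdc = _exp(prop), _exp(cur)
        ll = 0.0
        if values.size:
            zc = (values - mean) / sdc
            zp = (values - mean) / sdp
            ll = values.size * (cur - prop) - 0.5 * float(zp @ zp - zc @ zc)
        la = (
            ll
            + _norm_lpdf_scalar(prop, self.hp.log_sd_center, self.hp.vague_sd)
            - _norm_lpdf_scalar(cur, self.hp.log_sd_center, self.hp.vague_sd)
        )
        ok, acc = self._accept(la)
        self._adapt(key, acc, self.cfg.target_accept_scalar)
        self._track(key, ok)
        return prop if ok else cur

    def _gibbs_mvn_mean(self, vectors: np.ndarray, cov_inv: np.ndarray, center: np.ndarray):
        v0 = self.hp.vague_sd
        prec = np.eye(2) / v0**2 + vectors.shape[0] * cov_inv
        cov = np.linalg.inv(prec)
        mean = cov @ (center / v0**2 + cov_inv @ vectors.sum(axis=0))
        return mean + np.linalg.cholesky(cov) @ self.rng.normal(size=2)

    def _gibbs_invwishart(self, resid: np.ndarray) -> np.ndarray:
        df = self.hp.wishart_df + resid.shape[0]
        scale = self.hp.wishart_scale + resid.T @ resid
        return invwishart.rvs(df=df, scale=scale, random_state=self.rng)

    def _upd_hypers(self) -> None:
        if self.variant != "basic":
            if self.hier == "four_level":
                for i in range(self.N):
                    prec = self.Sigma_inv + self.P * self.Omega_inv
                    cov = np.linalg.inv(prec)
                    mean = cov @ (self.Sigma_inv @ self.mu + self.Omega_inv @ self.C[i].sum(0))
                    self.omega[i] = mean + np.linalg.cholesky(cov) @ self.rng.normal(size=2)
                resid_c = (self.C - self.omega[:, None, :]).reshape(-1, 2)
                self.Omega = self._gibbs_invwishart(resid_c)
                self.Omega_inv = np.linalg.inv(self.Omega)
                level2 = self.omega
            else:
                level2 = self.C.reshape(-1, 2) if self.N else np.zeros((0, 2))
            self.mu = self._gibbs_mvn_mean(level2, self.Sigma_inv, self.hp.mu_center)
            self.Sigma = self._gibbs_invwishart(level2 - self.mu)
            self._sync_cov()
        self.m_lp1 = self._gibbs_mean(self.log_p1, _exp(self.lsd_lp1), self.hp.log_p1_center)
        self.lsd_lp1 = self._mh_lsd("lsd_lp1", self.lsd_lp1, self.log_p1, self.m_lp1)
        lsig = np.ravel(self.log_sig)
        self.m_lsig = self._gibbs_mean(lsig, _exp(self.lsd_lsig), self.hp.log_sigma_center)
        self.lsd_lsig = self._mh_lsd("lsd_lsig", self.lsd_lsig, lsig, self.m_lsig)
        if self.variant != "calibrated_ar":
            self.m_lnig0 = self._gibbs_mean(
                self.log_nig0, _exp(self.lsd_lnig0), self.hp.log_nig0_center
            )
            self.lsd_lnig0 = self._mh_lsd("lsd_lnig0", self.lsd_lnig0, self.log_nig0, self.m_lnig0)
        else:
            # sd_eta1 ~ Unif(0, bound); random walk with rejection outside
            key = "sd_eta1"
            prop = self.sd_eta1 + math.exp(self._step(key, init=-2.0)) * self.rng.normal()
            if not (0.0 < prop < self.hp.eta1_sd_bound):
                la = -np.inf
            else:
                la = float(
                    np.sum(_norm_lpdf_scalar(self.eta1, 0.0, prop))
                    - np.sum(_norm_lpdf_scalar(self.eta1, 0.0, self.sd_eta1))
                ) if self.N else 0.0
            ok, acc = self._accept(la)
            if ok:
                self.sd_eta1 = prop
            self._adapt(key, acc, self.cfg.target_accept_scalar)
            self._track(key, ok)
            if self.cfg.rho_mode == "free_bounded" and not self.cfg.rho_shared:
                self.m_zrho = self._gibbs_mean(self.z_rho_i, _exp(self.lsd_zrho), 0.0)
                self.lsd_zrho = self._mh_lsd("lsd_zrho", self.lsd_zrho, self.z_rho_i, self.m_zrho)

    # -------------------------------------------------------------- iterate

    def iterate(self, it: int) -> None:
        self.adapting = self.cfg.adapt and it < self.cfg.burn_in
        for i in range(self.N):
            self._upd_log_p1(i)
            if self.variant != "calibrated_ar":
                self._upd_log_nig0(i)
            if self.variant == "basic":
                self._upd_log_sig(i, None)
            else:
                for k in range(self.P):
                    self._upd_C(i, k)
                for k in range(self.P):
                    self._upd_log_sig(i, k)
            if self.variant == "calibrated_ar":
                self._upd_eta1(i)
            self._upd_missing(i)
        self._upd_rho()
        self._upd_hypers()

    # ------------------------------------------------------------ recording

    def record_keys(self) -> dict:
        N, P = self.N, self.P
        keys = {
            "log_p1": (N,),
            "mean_log_p1": (),
            "sd_log_p1": (),
            "mean_log_sigma": (),
            "sd_log_sigma": (),
            "deviance": (),
        }
        keys["log_sigma"] = (N,) if self.variant == "basic" else (N, P)
        if self.variant != "basic":
            keys.update({"C": (N, P, 2), "mu": (2,), "Sigma": (2, 2)})
            if self.hier == "four_level":
                keys.update({"omega": (N, 2), "Omega": (2, 2)})
        if self.variant == "calibrated_ar":
            keys.update({"eta1": (N,), "sd_eta1": ()})
            if self.cfg.rho_mode == "free_bounded" and not self.cfg.rho_shared:
                keys["rho"] = (N,)
            else:
                keys["rho"] = ()
        else:
            keys.update({"log_nig0": (N,), "mean_log_nig0": (), "sd_log_nig0": ()})
        n_missing = int(sum(m.size for m in self.miss))
        keys["sg_missing"] = (n_missing,)
        return keys

    def snapshot(self) -> dict:
        out = {
            "log_p1": self.log_p1.copy(),
            "mean_log_p1": self.m_lp1,
            "sd_log_p1": _exp(self.lsd_lp1),
            "mean_log_sigma": self.m_lsig,
            "sd_log_sigma": _exp(self.lsd_lsig),
            "log_sigma": np.copy(self.log_sig),
            "deviance": -2.0 * float(np.sum(self.ll)),
        }
        if self.variant != "basic":
            out.update({"C": self.C.copy(), "mu": self.mu.copy(), "Sigma": self.Sigma.copy()})
            if self.hier == "four_level":
                out.update({"omega": self.omega.copy(), "Omega": self.Omega.copy()})
        if self.variant == "calibrated_ar":
            out.update({"eta1": self.eta1.copy(), "sd_eta1": self.sd_eta1})
            if self.cfg.rho_mode == "free_bounded" and not self.cfg.rho_shared:
                out["rho"] = self.rho_i.copy()
            else:
                out["rho"] = self.rho
        else:
            out.update(
                {
                    "log_nig0": self.log_nig0.copy(),
                    "mean_log_nig0": self.m_lnig0,
                    "sd_log_nig0": _exp(self.lsd_lnig0),
                }
            )
        out["sg_missing"] = np.concatenate(
            [self.sg[i][self.miss[i]] for i in range(self.N)]
        ) if any(m.size for m in self.miss) else np.zeros(0)
        return out

    def missing_map(self) -> list:
        return [(i, int(j)) for i in range(self.N) for j in self.miss[i]]

    def acceptance_rates(self) -> dict:
        return {fam: s / c for fam, (s, c) in self.acc_accum.items() if c}


def rho_update(sampler: _ChainSampler, config: McmcConfig) -> float:
    """Advance the autocorrelation parameter one step under ``config``.

    Exposed mainly for testing; :func:`fit` calls the same update inside
    its Gibbs sweep.  Returns the current rho after the update.
    """
    sampler._upd_rho()
    return sampler.rho if config.rho_shared else sampler.rho_i


def _run_chain(sampler: _ChainSampler, config: McmcConfig, extra=None) -> dict:
    n_keep = (config.n_iter - config.burn_in + config.thin - 1) // config.thin
    keys = sampler.record_keys()
    if extra is not None:
        keys.update(extra.record_keys())
    store = {k: np.zeros((n_keep,) + shape) for k, shape in keys.items()}
    kept = 0
    for it in range(config.n_iter):
        sampler.iterate(it)
        if extra is not None:
            extra.update(it)
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            snap = sampler.snapshot()
            if extra is not None:
                snap.update(extra.snapshot())
            for k, v in snap.items():
                store[k][kept] = v
            kept += 1
    return store


def fit(
    dataset: Dataset,
    variant: str = "calibrated_ar",
    hierarchy_variant: str = "three_level",
    config: Optional[McmcConfig] = None,
    hyperpriors: Optional[HyperPriors] = None,
) -> McmcTrace:
    """Fit a model variant by adaptive Metropolis-within-Gibbs MCMC.

    Deterministic given ``config.seed``; chains are run sequentially with
    per-chain substreams.  Missing SG readings are treated as latent
    variables and sampled alongside the parameters.
    """
    config = config or McmcConfig()
    hp = hyperpriors or HyperPriors()
    chains = []
    acc = {}
    mmap = []
    for c in range(config.n_chains):
        rng = np.random.default_rng([config.seed, c])
        sampler = _ChainSampler(dataset, variant, hierarchy_variant, config, hp, rng)
        chains.append(_run_chain(sampler, config))
        acc = sampler.acceptance_rates()
        mmap = sampler.missing_map()
    samples = {k: np.stack([ch[k] for ch in chains]) for k in chains[0]}
    return McmcTrace(
        samples=samples,
        variant=variant,
        hierarchy_variant=hierarchy_variant,
        config=config,
        acceptance=acc,
        missing_map=mmap,
    )


class _ArBlock:
    """AR(1) module of the duplicated-data cut.

    Operates on residuals ``e = SG - CIG`` computed from the calibrated
    sampler's current parameters; drives only the unconstrained
    autocorrelation ``rho = expit(z)`` and its innovation SDs (with their
    own hierarchical mean/log-SD), using an independent random stream so
    the calibrated module's trajectory is untouched when the valve is in
    place.
    """

    def __init__(self, sampler: _ChainSampler, config: McmcConfig, hp: HyperPriors, rng):
        self.s = sampler
        self.cfg = config
        self.hp = hp
        self.rng = rng
        N, P = sampler.N, sampler.P
        self.log_sig2 = np.full((N, P), hp.log_sigma_center)
        self.m_lsig2 = hp.log_sigma_center
        self.lsd_lsig2 = math.log(0.3)
        self.z_rho = 0.0
        self.rho = 0.5
        self.logstep = {}
        self.acount = {}
        self.adapting = False
        self.ll = np.array([self._ll_i(i, self.log_sig2[i], self.rho) for i in range(N)])

    def _resid(self, i: int):
        s = self.s
        pidx = s.pidx[i]
        F = np.exp(s.C[i][:, 1])
        Fp = F[pidx]
        cig = Fp * s.nig[i] + s.C[i][pidx, 0]
        return s.sg[i] - cig, Fp

    def _ll_i(self, i: int, log_sig2_i, rho: float, resid=None) -> float:
        e, Fp = self._resid(i) if resid is None else resid
        ratio = Fp[1:] / Fp[:-1]
        gam = e[1:] - ratio * rho * e[:-1]
        sd = np.exp(log_sig2_i)[self.s.pidx[i][1:]]
        ll = float(np.sum(-0.5 * _LOG_2PI - np.log(sd) - 0.5 * (gam / sd) ** 2))
        return ll if np.isfinite(ll) else -np.inf

    def extra_ll(self, i: int, nig: np.ndarray, C_i: np.ndarray) -> float:
        """AR-copy likelihood as a function of candidate calibrated params.

        Only used when the valve is removed (``cut=False``): it feeds the
        duplicated data's AR likelihood back into the B/F/p1 updates.
        """
        pidx = self.s.pidx[i]
        F = np.exp(C_i[:, 1])
        Fp = F[pidx]
        cig = Fp * nig + C_i[pidx, 0]
        e = self.s.sg[i] - cig
        return self._ll_i(i, self.log_sig2[i], self.rho, resid=(e, Fp))

    def _step(self, key, init=-1.0):
        return self.logstep.setdefault(key, init)

    def _adapt(self, key, acc):
        if not self.adapting:
            return
        n = self.acount[key] = self.acount.get(key, 0) + 1
        self.logstep[key] += min(0.5, 1.5 * n ** -0.6) * (acc - self.cfg.target_accept_scalar)

    def update(self, it: int) -> None:
        self.adapting = self.cfg.adapt and it < self.cfg.burn_in
        # calibrated params moved this iteration: refresh residual likelihoods
        self.ll = np.array(
            [self._ll_i(i, self.log_sig2[i], self.rho) for i in range(self.s.N)]
        )
        for i in range(self.s.N):
            for k in range(self.s.P):
                key = ("log_sig2", i, k)
                prop = self.log_sig2[i, k] + math.exp(self._step(key)) * self.rng.normal()
                lsp = self.log_sig2[i].copy()
                lsp[k] = prop
                llp = self._ll_i(i, lsp, self.rho)
                sd = math.exp(self.lsd_lsig2)
                la = (
                    llp
                    - self.ll[i]
                    + _norm_lpdf_scalar(prop, self.m_lsig2, sd)
                    - _norm_lpdf_scalar(self.log_sig2[i, k], self.m_lsig2, sd)
                )
                if math.log(self.rng.random()) < la:
                    self.log_sig2[i, k] = prop
                    self.ll[i] = llp
                    self._adapt(key, 1.0)
                else:
                    self._adapt(key, 0.0 if la == -np.inf else min(1.0, math.exp(min(la, 0.0))))
        key = "z_rho2"
        prop = self.z_rho + math.exp(self._step(key)) * self.rng.normal()
        rhop = float(expit(prop))
        llp = np.array([self._ll_i(i, self.log_sig2[i], rhop) for i in range(self.s.N)])
        la = (
            float(np.sum(llp) - np.sum(self.ll))
            + _norm_lpdf_scalar(prop, 0.0, self.hp.vague_sd)
            - _norm_lpdf_scalar(self.z_rho, 0.0, self.hp.vague_sd)
        )
        if math.log(self.rng.random()) < la:
            self.z_rho = prop
            self.rho = rhop
            self.ll = llp
            self._adapt(key, 1.0)
        else:
            self._adapt(key, 0.0 if la == -np.inf else min(1.0, math.exp(min(la, 0.0))))
        lsig = self.log_sig2.ravel()
        v0 = self.hp.vague_sd
        tau = math.exp(self.lsd_lsig2)
        prec = 1.0 / v0**2 + lsig.size / tau**2
        mean = (self.hp.log_sigma_center / v0**2 + lsig.sum() / tau**2) / prec
        self.m_lsig2 = mean + math.sqrt(1.0 / prec) * self.rng.normal()
        key = "lsd_lsig2"
        prop = self.lsd_lsig2 + math.exp(self._step(key)) * self.rng.normal()
        sdp, sdc = math.exp(prop), math.exp(self.lsd_lsig2)
        zc = (lsig - self.m_lsig2) / sdc
        zp = (lsig - self.m_lsig2) / sdp
        la = (
            lsig.size * (self.lsd_lsig2 - prop)
            - 0.5 * float(zp @ zp - zc @ zc)
            + _norm_lpdf_scalar(prop, self.hp.log_sd_center, v0)
            - _norm_lpdf_scalar(self.lsd_lsig2, self.hp.log_sd_center, v0)
        )
        if math.log(self.rng.random()) < la:
            self.lsd_lsig2 = prop
            self._adapt(key, 1.0)
        else:
            self._adapt(key, min(1.0, math.exp(min(la, 0.0))))

    def record_keys(self) -> dict:
        N, P = self.s.N, self.s.P
        return {
            "rho": (),
            "log_sigma2": (N, P),
            "mean_log_sigma2": (),
            "sd_log_sigma2": (),
        }

    def snapshot(self) -> dict:
        return {
            "rho": self.rho,
            "log_sigma2": self.log_sig2.copy(),
            "mean_log_sigma2": self.m_lsig2,
            "sd_log_sigma2": math.exp(self.lsd_lsig2),
        }


def fit_duplicated(
    dataset: Dataset,
    config: Optional[McmcConfig] = None,
    hierarchy_variant: str = "three_level",
    hyperpriors: Optional[HyperPriors] = None,
    cut: bool = True,
) -> McmcTrace:
    """Duplicated-data cut-feedback fit.

    The SG data are used twice: a homoscedastic calibrated likelihood
    drives ``B``, ``F``, ``p1``, the period SDs and all hyperparameters
    (identically to :func:`fit` with ``variant='calibrated'`` at the same
    seed), while an AR(1) likelihood on the implied residuals drives an
    *unconstrained* ``rho`` and its own innovation SDs.  With ``cut=True``
    (the valve in place) no information flows from the AR module back to
    the calibrated parameters; ``cut=False`` removes the valve, double-
    using the data — provided as a negative control.
    """
    config = config or McmcConfig()
    hp = hyperpriors or HyperPriors()
    chains = []
    acc = {}
    mmap = []
    for c in range(config.n_chains):
        rng1 = np.random.default_rng([config.seed, c])
        rng2 = np.random.default_rng([config.seed, c, 1])
        sampler = _ChainSampler(dataset, "calibrated", hierarchy_variant, config, hp, rng1)
        block = _ArBlock(sampler, config, hp, rng2)
        if not cut:
            sampler.extra_ll = block.extra_ll
            for i in range(sampler.N):
                sampler.ll[i] = sampler._ll_current(i)
        chains.append(_run_chain(sampler, config, extra=block))
        acc = sampler.acceptance_rates()
        mmap = sampler.missing_map()
    samples = {k: np.stack([ch[k] for ch in chains]) for k in chains[0]}
    return McmcTrace(
        samples=samples,
        variant="duplicated_cut" if cut else "duplicated_nocut",
        hierarchy_variant=hierarchy_variant,
        config=config,
        acceptance=acc,
        missing_map=mmap,
    )


class DicResult(NamedTuple):
    Dbar: float
    pD: float
    DIC: float


def dic_from_deviance(deviance_samples, deviance_at_mean: float) -> DicResult:
    """DIC from a deviance series and the deviance at the posterior means.

    ``pD = Dbar - D(theta_bar)`` is the effective number of parameters;
    ``DIC = Dbar + pD`` penalises the mean deviance by model complexity.
    """
    dev = np.asarray(deviance_samples, dtype=float)
    if dev.size < 100:
        raise ValueError("need at least 100 deviance samples for a stable DIC")
    dbar = float(dev.mean())
    pd_ = dbar - float(deviance_at_mean)
    return DicResult(dbar, pd_, dbar + pd_)


def _params_at_posterior_means(trace: McmcTrace, i: int, n_periods: int) -> IndividualParams:
    s = trace.samples
    p1 = float(np.exp(trace.stacked("log_p1").mean(axis=0)[i]))
    if trace.variant == "basic":
        sigma = float(np.exp(trace.stacked("log_sigma").mean(axis=0)[i]))
        nig0 = float(np.exp(trace.stacked("log_nig0").mean(axis=0)[i]))
        return IndividualParams(p1=p1, sigma=sigma, nig0=nig0)
    C = trace.stacked("C").mean(axis=0)[i]
    sigma = np.exp(trace.stacked("log_sigma").mean(axis=0)[i])
    if trace.variant == "calibrated":
        nig0 = float(np.exp(trace.stacked("log_nig0").mean(axis=0)[i]))
        return IndividualParams(p1=p1, B=C[:, 0], logF=C[:, 1], sigma=sigma, nig0=nig0)
    rho = trace.stacked("rho").mean(axis=0)
    rho_i = float(rho[i]) if np.ndim(rho) else float(rho)
    eta1 = float(trace.stacked("eta1").mean(axis=0)[i])
    return IndividualParams(
        p1=p1, B=C[:, 0], logF=C[:, 1], sigma=sigma, rho=rho_i, eta1=eta1
    )


def dic(trace: McmcTrace, dataset: Dataset, variant: Optional[str] = None) -> DicResult:
    """Deviance information criterion of a fitted model.

    ``Dbar`` is the posterior mean deviance recorded during sampling;
    ``D(theta_bar)`` evaluates the deviance at the posterior means of the
    likelihood-level parameters (on their sampled, transformed scales)
    with missing readings set to their posterior mean imputations.
    """
    variant = variant or trace.variant
    if variant not in ("basic", "calibrated", "calibrated_ar"):
        raise ValueError("DIC is defined here for the single-likelihood variants")
    miss_mean = (
        trace.stacked("sg_missing").mean(axis=0) if trace.missing_map else np.zeros(0)
    )
    d_at_mean = 0.0
    for i, d in enumerate(dataset.individuals):
        sg = d.sg.copy()
        for pos, (ii, jj) in enumerate(trace.missing_map):
            if ii == i:
                sg[jj] = miss_mean[pos]
        filled = IndividualData(
            sg_times=d.sg_times,
            sg=sg,
            bg_times=d.bg_times,
            bg=d.bg,
            schedule=d.schedule,
            sg_missing=np.zeros(d.n, dtype=bool),
            individual_id=d.individual_id,
        )
        params = _params_at_posterior_means(trace, i, d.schedule.n_periods)
        d_at_mean += -2.0 * loglik_individual(filled, params, variant)
    return dic_from_deviance(trace.stacked("deviance"), d_at_mean)


def _flat_names(name: str, shape: tuple):
    if not shape:
        yield name, ()
    else:
        for idx in np.ndindex(shape):
            yield name + "[" + ",".join(map(str, idx)) + "]", idx


def diagnostics_report(trace: McmcTrace) -> pd.DataFrame:
    """Posterior medians, 95% credible intervals, ESS and split-R-hat.

    R-hat requires at least two chains and is NaN otherwise.  One row per
    scalar component of every sampled quantity.
    """
    import arviz as az

    idata = trace.to_inference_data()
    ess = az.ess(idata)
    rhat = az.rhat(idata) if trace.n_chains >= 2 else None
    rows = []
    for name, arr in trace.samples.items():
        flat = arr.reshape((-1,) + arr.shape[2:])
        for label, idx in _flat_names(name, arr.shape[2:]):
            x = flat[(slice(None),) + idx]
            med, lo, hi = np.quantile(x, [0.5, 0.025, 0.975])
            e = float(np.asarray(ess[name])[idx]) if name in ess else np.nan
            r = (
                float(np.asarray(rhat[name])[idx])
                if rhat is not None and name in rhat
                else np.nan
            )
            rows.append(
                {
                    "parameter": label,
                    "median": med,
                    "lower95": lo,
                    "upper95": hi,
                    "ess_bulk": e,
                    "rhat": r,
                }
            )
    return pd.DataFrame(rows)


def _median_ci(x: np.ndarray) -> str:
    med, lo, hi = np.quantile(x, [0.5, 0.025, 0.975])
    return f"{med:.3g} ({lo:.3g}, {hi:.3g})"


def summary_table(trace: McmcTrace) -> pd.DataFrame:
    """Population-parameter summary in the study's reporting layout.

    One row per population parameter, with posterior medians and 95%
    credible intervals of the population mean and population SD.
    """
    s = trace.samples
    rows = []

    def row(name, mean_x, sd_x):
        rows.append(
            {
                "parameter": name,
                "pop_mean (95% CI)": _median_ci(mean_x) if mean_x is not None else "-",
                "pop_sd (95% CI)": _median_ci(sd_x) if sd_x is not None else "-",
            }
        )

    row("log p1", trace.stacked("mean_log_p1"), trace.stacked("sd_log_p1"))
    if "mu" in s:
        mu = trace.stacked("mu")
        Sg = trace.stacked("Sigma")
        row("log F", mu[:, 1], np.sqrt(Sg[:, 1, 1]))
        row("B", mu[:, 0], np.sqrt(Sg[:, 0, 0]))
    row("log sigma", trace.stacked("mean_log_sigma"), trace.stacked("sd_log_sigma"))
    if "mean_log_nig0" in s:
        row("log NIG0", trace.stacked("mean_log_nig0"), trace.stacked("sd_log_nig0"))
    if "sd_eta1" in s:
        row("eta.1", None, trace.stacked("sd_eta1"))
    if "rho" in s:
        rho = trace.stacked("rho")
        row("rho", rho if rho.ndim == 1 else rho.mean(axis=1), None)
    return pd.DataFrame(rows)
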