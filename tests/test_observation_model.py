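"""Calibration mapping, AR(1) residual structure and likelihoods."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from cgmcal import (
    CalibrationSchedule,
    IndividualData,
    IndividualParams,
    ar_conditional_means,
    assign_periods,
    compute_cig,
    initial_nig_from_eta1,
    loglik_individual,
    simulate_sg,
)
from cgmcal.observation_model import _nig_for

PSI = np.array([20.0, 380.0, 740.0, 1100.0])


def _params(P=5, **kw):
    defaults = dict(
        p1=0.06,
        B=np.full(P, 1.5),
        logF=np.log(np.full(P, 0.8)),
        sigma=np.full(P, 0.2),
        rho=0.0,
        eta1=0.0,
    )
    defaults.update(kw)
    return IndividualParams(**defaults)


class TestPeriods:
    def test_boundaries(self):
        sched = CalibrationSchedule(PSI)
        # a calibration resets the sensor from that instant
        assert assign_periods([5.0], sched)[0] == 1
        assert assign_periods([380.0], sched)[0] == 3
        assert assign_periods([1140.0], sched)[0] == 5

    def test_every_time_covered_once(self):
        sched = CalibrationSchedule(PSI)
        t = np.arange(5.0, 1141.0, 5.0)
        p = assign_periods(t, sched)
        assert p.min() == 1 and p.max() == 5
        assert np.all(np.diff(p) >= 0)
        assert set(np.unique(p)) == {1, 2, 3, 4, 5}

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            assign_periods([10.0, 5.0], CalibrationSchedule(PSI))


class TestCig:
    def test_identity_and_affine(self):
        p_id = _params(B=np.zeros(5), logF=np.zeros(5))
        nig = np.array([4.0, 10.0])
        assert np.allclose(compute_cig(nig, p_id, np.array([1, 3])), nig)
        p = _params()
        assert compute_cig(np.array([10.0]), p, np.array([2]))[0] == pytest.approx(9.5)

    def test_piecewise_jump_at_calibration(self):
        p = _params(B=np.array([0.0, 1.0, 0, 0, 0]), logF=np.log([1.0, 1.2, 1, 1, 1]))
        nig = np.array([10.0, 10.0])
        cig = compute_cig(nig, p, np.array([1, 2]))
        assert cig[0] == pytest.approx(10.0) and cig[1] == pytest.approx(13.0)


def test_initial_nig_from_eta1():
    assert initial_nig_from_eta1(8.0, 0.0, 0.0, 1.0) == pytest.approx(8.0)
    assert initial_nig_from_eta1(8.0, 0.4, 1.5, 0.8) == pytest.approx(7.625)
    with pytest.raises(ValueError):
        initial_nig_from_eta1(8.0, 0.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        initial_nig_from_eta1(1.0, 0.0, 2.0, 1.0)  # implied NIG < 0


class TestArConditionalMeans:
    def test_rho_zero_collapses_to_cig(self):
        p = _params(eta1=0.3)
        cig = np.array([10.0, 10.2, 9.8])
        sg = cig + np.array([0.5, -0.2, 0.1])
        phi = ar_conditional_means(cig, sg, 0.0, p, np.array([1, 1, 1]))
        assert phi[0] == pytest.approx(10.3)
        assert np.allclose(phi[1:], cig[1:])

    def test_within_and_across_period(self):
        p = _params(logF=np.log([1.0, 1.1, 1, 1, 1]))
        cig = np.array([10.0, 10.2])
        sg = np.array([10.5, 11.0])
        same = ar_conditional_means(cig, sg, 0.8, p, np.array([1, 1]))
        assert same[1] == pytest.approx(10.6)
        cross = ar_conditional_means(cig, sg, 0.8, p, np.array([1, 2]))
        assert cross[1] == pytest.approx(10.64)


def _make_data(n=20, seed=0, P=3):
    rng = np.random.default_rng(seed)
    end = 5.0 * (n + 2)
    psi = np.linspace(end / P, end * (P - 1) / P, P - 1)
    sched = CalibrationSchedule(psi, 0.0, end)
    sg_times = np.arange(5.0, 5.0 * (n + 1), 5.0)
    bg_times = np.arange(0.0, end + 1, 15.0)
    bg = 7.0 + np.cumsum(rng.normal(0, 0.2, bg_times.size))
    bg = np.clip(bg, 3.0, 15.0)
    sg = np.clip(7.0 + rng.normal(0, 0.5, n), 2.0, None)
    return IndividualData(sg_times, sg, bg_times, bg, sched)


def test_loglik_perfect_fit_matches_closed_form():
    d = _make_data()
    P = d.schedule.n_periods
    params = _params(P=P, sigma=np.full(P, 0.3), nig0=7.0)
    nig = _nig_for(d, params, "calibrated")
    cig = compute_cig(nig, params, d.periods)
    d.sg = np.clip(cig, 1e-3, None)  # make the fit exact where CIG > 0
    assert np.allclose(d.sg, cig)
    ll = loglik_individual(d, params, "calibrated")
    expected = d.n * (-np.log(0.3 * np.sqrt(2 * np.pi)))
    assert ll == pytest.approx(expected)


def test_ar_loglik_nests_calibrated_at_rho_zero():
    d = _make_data(seed=3)
    P = d.schedule.n_periods
    params = _params(P=P, rho=0.0, eta1=0.15)
    nig0 = initial_nig_from_eta1(d.sg[0], params.eta1, params.B[0], params.F[0])
    params_cal = _params(P=P, nig0=nig0)
    ll_ar = loglik_individual(d, params, "calibrated_ar")
    # same NIG path, iid likelihood restricted to j >= 2
    nig = _nig_for(d, params_cal, "calibrated")
    cig = compute_cig(nig, params_cal, d.periods)
    sd = np.asarray(params_cal.sigma)[d.periods - 1]
    manual = np.sum(
        -np.log(sd[1:] * np.sqrt(2 * np.pi)) - 0.5 * ((d.sg[1:] - cig[1:]) / sd[1:]) ** 2
    )
    assert ll_ar == pytest.approx(manual, abs=1e-10)


def test_ar_loglik_matches_dense_covariance_oracle():
    """The sequential AR likelihood equals the joint Gaussian density of
    (SG_2..SG_n | SG_1) computed from the full AR covariance matrix."""
    d = _make_data(n=20, seed=5)
    P = d.schedule.n_periods
    rng = np.random.default_rng(8)
    params = _params(
        P=P,
        B=rng.normal(1.5, 0.5, P),
        logF=rng.normal(-0.2, 0.1, P),
        sigma=np.abs(rng.normal(0.2, 0.05, P)) + 0.05,
        rho=0.8,
        eta1=0.2,
    )
    ll = loglik_individual(d, params, "calibrated_ar")

    nig = _nig_for(d, params, "calibrated_ar")
    cig = compute_cig(nig, params, d.periods)
    n = d.n
    F = params.F[d.periods - 1]
    sd = np.asarray(params.sigma)[d.periods - 1]
    a = np.concatenate(([np.nan], (F[1:] / F[:-1]) * params.rho))  # transition coeffs
    # eta_j = (prod_{q=2..j} a_q) * eta_1 + sum_{q=2..j} (prod_{u=q+1..j} a_u) gamma_q
    A = np.zeros((n - 1, n - 1))  # maps gamma_2..n to eta_2..n
    det = np.zeros(n - 1)  # deterministic eta_1 propagation
    eta1_obs = d.sg[0] - cig[0]
    for j in range(1, n):
        prod = 1.0
        for q in range(j, 0, -1):
            if q == j:
                A[j - 1, q - 1] = 1.0
            else:
                prod_u = np.prod(a[q + 1 : j + 1])
                A[j - 1, q - 1] = prod_u
        det[j - 1] = np.prod(a[1 : j + 1]) * eta1_obs
    cov = A @ np.diag(sd[1:] ** 2) @ A.T
    mean = cig[1:] + det
    oracle = multivariate_normal.logpdf(d.sg[1:], mean=mean, cov=cov)
    assert ll == pytest.approx(oracle, abs=1e-8)


class TestSimulateSg:
    def test_noiseless_limit_and_determinism(self):
        d = _make_data(n=30, seed=1)
        P = d.schedule.n_periods
        params = _params(P=P, sigma=np.full(P, 1e-12), rho=0.0, eta1=0.0, nig0=7.0)
        nig = _nig_for(d, params, "calibrated")
        cig = compute_cig(nig, params, d.periods)
        sg, _ = simulate_sg(nig, params, d.periods, np.random.default_rng(0))
        assert np.allclose(sg, cig, atol=1e-9)
        params2 = _params(P=P, sigma=np.full(P, 0.2), rho=0.7, eta1=0.1, nig0=7.0)
        sg_a, _ = simulate_sg(nig, params2, d.periods, np.random.default_rng(5))
        sg_b, _ = simulate_sg(nig, params2, d.periods, np.random.default_rng(5))
        assert np.array_equal(sg_a, sg_b)

    def test_lag1_autocorrelation_matches_rho(self):
        rho, sigma = 0.6, 0.3
        n = 100_000
        params = IndividualParams(
            p1=0.06,
            B=np.zeros(1),
            logF=np.zeros(1),
            sigma=np.array([sigma]),
            rho=rho,
            eta1=0.0,
        )
        nig = np.full(n, 8.0)
        periods = np.ones(n, dtype=int)
        sg, eta = simulate_sg(nig, params, periods, np.random.default_rng(9))
        resid = sg - 8.0
        r1 = np.corrcoef(resid[:-1], resid[1:])[0, 1]
        assert r1 == pytest.approx(rho, abs=0.01)
        # stationary variance sigma^2/(1-rho^2)
        assert np.var(resid[100:]) == pytest.approx(sigma**2 / (1 - rho**2), rel=0.03)
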