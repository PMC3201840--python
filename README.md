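# cgmcal

Hierarchical Bayesian calibration of continuous glucose monitoring (CGM)
sensor data against blood glucose.

## The problem

CGM devices report *sensor glucose* (SG) from an electrode in the
interstitial fluid, while clinical decisions — and the control algorithm
of an artificial pancreas — care about *blood glucose* (BG).  The two
differ in three ways: a physiological delay while glucose equilibrates
between blood and interstitium, a drifting affine calibration that is
reset every time the sensor is recalibrated, and serially correlated
measurement noise.  `cgmcal` characterises all three at the population
level from a standard inpatient validation study (frequent venous BG
alongside CGM traces), so that realistic *virtual patients* — parameter
sets plus simulated sensor noise — can be generated for in-silico testing
of closed-loop insulin-delivery algorithms.  It is aimed at
biostatisticians and diabetes-technology researchers.

## The model

For individual *i*, normalised interstitial glucose NIG follows first-order
exchange with blood glucose, driven by the piecewise-linear interpolant of
the observed BG series (a *forcing function*):

    dNIG/dt = p1_i (BG_i(t) − NIG),        delay = 1/p1_i  [min]

Within calibration period *k* (periods are delimited by the sensor's
calibration events) the expected sensor reading is the *calibrated
interstitial glucose*

    CIG_ij = F_ik · NIG_ij + B_ik

with scale factor `F_ik` and shift `B_ik` (mmol/L).  Residuals
`η_ij = SG_ij − CIG_ij` are AR(1),

    η_ij = (F_iP[j] / F_iP[j−1]) ρ η_i,j−1 + γ_ij,    γ_ij ~ N(0, σ²_iP[j]),

the F-ratio adjusting the process across calibration boundaries.  The
first reading defines the ODE initial state through the initial residual,
`NIG_i1 = (SG_i1 − η_i1 − B_i1)/F_i1`.  Individual-level parameters get
normal population distributions on transformed scales (`log p1`,
`C_ik = (B_ik, log F_ik)` bivariate normal, `log σ_ik`, `η_i1`), with
vague-but-proper hyperpriors.  Because ρ is confounded with the model fit,
it is either bounded (`logit(ρ/ρ_max)` free, ρ_max = 0.8), treated as a
*distributional constant* (resampled from Unif(0.75, 0.85) with feedback
from the likelihood cut), or released entirely under a duplicated-data cut.
Inference is adaptive Metropolis-within-Gibbs with conjugate updates for
the calibration-vector mean and covariance; missing SG readings are
sampled as latent variables.

## Worked example

Simulate a study with the reference design (12 individuals, BG every
15 min, SG every 5 min over 19 h, calibrations at minutes 20/380/740/1100),
fit the calibrated + AR model, and summarise:

```python
import numpy as np
from cgmcal import (simulate_study, fit, McmcConfig, summary_table,
                    population_summaries, default_population)

dataset, truths = simulate_study(rng=np.random.default_rng(101))
cfg = McmcConfig(n_iter=20_000, burn_in=10_000, thin=5, seed=11,
                 rho_mode="fixed", rho_value=0.8)
trace = fit(dataset, "calibrated_ar", config=cfg)
m = np.median(trace.stacked("mean_log_p1"))
print(f"population median delay: {np.exp(-m):.1f} min")
print(summary_table(trace).to_string(index=False))
```

which prints (about two minutes on one CPU):

```
population median delay: 17.7 min
parameter      pop_mean (95% CI)       pop_sd (95% CI)
   log p1   -2.87 (-2.98, -2.74) 0.152 (0.0564, 0.304)
    log F -0.258 (-0.354, -0.16)  0.315 (0.258, 0.395)
        B      1.82 (1.36, 2.29)     1.32 (1.03, 1.73)
log sigma    -2.08 (-2.2, -1.95)  0.429 (0.349, 0.545)
    eta.1                      - 0.272 (0.0233, 0.489)
      rho         0.8 (0.8, 0.8)                     -
```

The generating population here had mean log p1 = −2.82 (median delay
≈ 16.8 min), mean log F = −0.202, mean B = 1.63 and mean log σ = −2.14;
each 95% interval covers its generating value.  The same pipeline is available from the shell:

```sh
cgmcal simulate --seed 1 --out study.csv
cgmcal fit --data study.csv --rho-mode fixed --out-dir run/
cgmcal diagnose --data study.csv --truths study.truths.json --out-dir diag/
cgmcal compare --data study.csv --out dic.csv
cgmcal predict --n-patients 100 --seed 2 --out virtual.csv
```

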