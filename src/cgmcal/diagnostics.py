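"""Model-checking computations: lagged correlation and residual summaries.

These are the checks used to judge the calibration model on real studies:
a crude lag-correlation analysis of BG against time-shifted SG (a
model-free estimate of the blood-to-sensor delay), relative residuals on
the percentage scale, and residual summaries stratified by glycaemic
range (hypo-, eu- and hyperglycaemia).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "lag_correlation",
    "relative_residuals",
    "residuals_by_range",
    "cig_plausibility",
    "plot_residual_panels",
]

#: Glycaemic-range boundaries, mmol/L: hypo <= 3.9 < eu <= 10 < hyper.
HYPO_BOUND = 3.9
HYPER_BOUND = 10.0


def lag_correlation(dataset, lags: Sequence[float]):
    """Pooled Pearson correlation of BG with SG lagged by each offset.

    For lag L, BG at time s is paired with the SG reading at time s + L
    (the sensor lags the blood, so the best alignment shifts SG back in
    time).  Pairs are pooled over all individuals; missing SG readings and
    times without an exact SG match are dropped.  Returns ``(corrs,
    best_lag)`` where ``corrs`` maps each lag to its correlation and
    ``best_lag`` maximises it.
    """
    lags = [float(l) for l in lags]
    corrs = {}
    for lag in lags:
        xs, ys = [], []
        for d in dataset.individuals:
            target = d.bg_times + lag
            j = np.searchsorted(d.sg_times, target)
            ok = (j < d.sg_times.size) & np.isclose(
                d.sg_times[np.minimum(j, d.sg_times.size - 1)], target
            )
            jj = j[ok]
            keep = ~d.sg_missing[jj]
            xs.append(d.bg[ok][keep])
            ys.append(d.sg[jj][keep])
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        if x.size < 3:
            raise ValueError(f"no usable BG/SG overlap at lag {lag}")
        corrs[lag] = float(np.corrcoef(x, y)[0, 1])
    best = max(corrs, key=corrs.get)
    return corrs, best


def relative_residuals(sg, phi) -> np.ndarray:
    """Relative residuals in per cent: 100 * (SG - phi) / phi."""
    sg = np.asarray(sg, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(phi <= 0):
        raise ValueError("phi must be strictly positive")
    return 100.0 * (sg - phi) / phi


def residuals_by_range(residuals, glucose) -> pd.DataFrame:
    """Absolute-residual summaries per glycaemic range.

    Residuals (mmol/L) are grouped by the accompanying glucose level:
    hypoglycaemic (<= 3.9), euglycaemic (> 3.9, <= 10) and hyperglycaemic
    (> 10 mmol/L).  Returns the count, median and inter-quartile interval
    of |residual| for each non-empty group.
    """
    residuals = np.asarray(residuals, dtype=float)
    glucose = np.asarray(glucose, dtype=float)
    if residuals.shape != glucose.shape:
        raise ValueError("residuals and glucose must be aligned")
    labels = pd.cut(
        glucose,
        bins=[-np.inf, HYPO_BOUND, HYPER_BOUND, np.inf],
        labels=["hypoglycaemic", "euglycaemic", "hyperglycaemic"],
    )
    df = pd.DataFrame({"group": labels, "abs_residual": np.abs(residuals)})
    out = (
        df.groupby("group", observed=True)["abs_residual"]
        .agg(count="size", median="median", q25=lambda s: s.quantile(0.25), q75=lambda s: s.quantile(0.75))
        .reset_index()
    )
    return out


def cig_plausibility(dataset, params_by_individual) -> pd.DataFrame:
    """Mean |SG - CIG| per individual (mmol/L).

    The underlying CIG series should track the data; when the AR process
    absorbs the systematic fit (too-large rho), this distance blows up.
    Choosing the autocorrelation bound rho_max is a user decision guided by
    this diagnostic rather than an automated selection.
    """
    from .observation_model import predict_series

    rows = []
    for d, params in zip(dataset.individuals, params_by_individual):
        cig = predict_series(d, params, "calibrated_ar")["cig"]
        keep = ~d.sg_missing
        rows.append(
            {
                "individual_id": d.individual_id,
                "mean_abs_sg_minus_cig": float(np.mean(np.abs(d.sg[keep] - cig[keep]))),
            }
        )
    return pd.DataFrame(rows)


def plot_residual_panels(residuals_by_individual: dict, path=None):
    """Time-ordered relative-residual panels, one per individual."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(residuals_by_individual)
    ncol = min(4, max(1, n))
    nrow = (n + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2 * nrow), squeeze=False)
    for ax, (label, res) in zip(axes.ravel(), residuals_by_individual.items()):
        ax.plot(res, ".", ms=2)
        ax.axhline(0.0, lw=0.5, color="k")
        ax.set_title(str(label), fontsize=8)
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
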