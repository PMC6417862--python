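"""Inference procedures for the treadmilling-network analyses.

Three estimators mirror how the measurements are analysed:

* initial binding slopes — ordinary least squares on the early part of each
  material path through a bound-cofilin kymograph; under local depletion the
  slopes decrease with the path's starting time, without depletion they are
  flat;
* the binding-rate correlation — Pearson correlation of the initial slope
  with the product C0 * A, the signature of the diffusion-limited binding
  rate kB * C0 * A;
* power-law exponent fitting — the length law L = c * V * A0**alpha /
  CB**beta is linear in logs, so log(L/V) is regressed on log A0 and log CB;
  a fixed-exponent mode scores user-supplied (alpha, beta) by the R² of
  predicted vs observed lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .synthetic_data import Kymograph

__all__ = [
    "SlopeEstimate",
    "ExponentFit",
    "estimate_initial_slopes",
    "correlate_binding_rate",
    "fit_exponents",
    "fixed_exponent_r2",
]


@dataclass(frozen=True)
class SlopeEstimate:
    """OLS slope of bound cofilin along one material path's initial window."""

    start_time: float
    slope: float
    stderr: float
    n_samples: int


@dataclass(frozen=True)
class ExponentFit:
    """Result of the log-space power-law regression.

    ``alpha_hat`` multiplies log A0, ``beta_hat`` is the negated log CB
    coefficient, so the fitted law reads L = c * V * A0**alpha / CB**beta.
    ``r_squared`` scores predicted vs observed log-lengths.
    """

    alpha_hat: float
    beta_hat: float
    alpha_ci: tuple[float, float]
    beta_ci: tuple[float, float]
    r_squared: float
    p_value: float
    log_prefactor: float
    condition_number: float


def estimate_initial_slopes(kymo: Kymograph, start_times, window_frac: float = 0.2,
                            window_seconds: float | None = None,
                            normalize: bool = False) -> list[SlopeEstimate]:
    """Initial loading slope of CB along material paths starting at given times.

    Each path y = V (t - t0) is sampled at the kymograph frames; the initial
    window is either ``window_seconds`` or the first ``window_frac`` of the
    path's duration, and must contain at least 3 samples.  With
    ``normalize=True`` the slopes are divided by their mean (mean-one
    normalization), making them comparable across intensity scales.
    """
    out = []
    for t0 in start_times:
        ts, vals = kymo.material_path(float(t0))
        if ts.size == 0:
            raise ValueError(f"path starting at t0={t0} lies outside the kymograph")
        span = window_seconds if window_seconds is not None \
            else window_frac * (ts[-1] - ts[0])
        sel = ts - ts[0] <= span + 1e-9
        if sel.sum() < 3:
            raise ValueError(
                f"initial window for t0={t0} holds {int(sel.sum())} samples; need >= 3")
        res = stats.linregress(ts[sel], vals[sel])
        out.append(SlopeEstimate(start_time=float(t0), slope=float(res.slope),
                                 stderr=float(res.stderr), n_samples=int(sel.sum())))
    if normalize:
        mean_slope = np.mean([s.slope for s in out])
        if mean_slope == 0:
            raise ValueError("cannot normalize: mean slope is zero")
        out = [SlopeEstimate(s.start_time, s.slope / mean_slope,
                             s.stderr / abs(mean_slope), s.n_samples) for s in out]
    return out


def correlate_binding_rate(table: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation (R, two-sided p) of the initial slope with C0 * A.

    Expects columns ``slope_uM_per_s``, ``C0_uM``, ``A_uM`` as produced by
    :func:`treadnet.synthetic_data.gen_binding_table`.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows")
    x = table["C0_uM"].to_numpy() * table["A_uM"].to_numpy()
    ys = table["slope_uM_per_s"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(ys) == 0:
        raise ValueError("zero-variance inputs; correlation undefined")
    r, p = stats.pearsonr(x, ys)
    return float(r), float(p)


def fit_exponents(table: pd.DataFrame) -> ExponentFit:
    """Fit alpha and beta of L = c * V * A0**alpha / CB**beta by log-space OLS.

    Regresses log(L/V) on log A0 and log CB; the power law is linear there.
    A condition number above ~30 for the design matrix signals collinear
    predictors (e.g. A0 and CB varying in lockstep) and raises.
    """
    if len(table) < 5:
        raise ValueError("need at least 5 records")
    for col in ("L_um", "V_um_per_s", "A0_uM", "CB_uM"):
        if (table[col] <= 0).any():
            raise ValueError(f"column {col} must be strictly positive")
    z = np.log(table["L_um"].to_numpy() / table["V_um_per_s"].to_numpy())
    P = np.column_stack([np.log(table["A0_uM"].to_numpy()),
                         np.log(table["CB_uM"].to_numpy())])
    sd = P.std(axis=0)
    if (sd == 0).any():
        raise ValueError("a predictor has zero variance; cannot fit exponents")
    cond = float(np.linalg.cond((P - P.mean(axis=0)) / sd))
    if not np.isfinite(cond) or cond > 1e6:
        raise ValueError(f"collinear predictors (condition number {cond:.3g}); "
                         "cannot separate alpha and beta")
    model = sm.OLS(z, sm.add_constant(P)).fit()
    ci = model.conf_int()
    return ExponentFit(
        alpha_hat=float(model.params[1]),
        beta_hat=float(-model.params[2]),
        alpha_ci=(float(ci[1, 0]), float(ci[1, 1])),
        beta_ci=(float(-ci[2, 1]), float(-ci[2, 0])),
        r_squared=float(model.rsquared),
        p_value=float(model.f_pvalue),
        log_prefactor=float(model.params[0]),
        condition_number=cond,
    )


def fixed_exponent_r2(table: pd.DataFrame, alpha: float, beta: float) -> float:
    """R² of predicted vs observed log-lengths at fixed exponents.

    The prediction is log L = const + log V + alpha log A0 - beta log CB with
    the constant fitted; R² = 1 - SS_res / SS_tot in log-length space.  This
    is how a whole (alpha, beta) grid can be scored against one dataset.
    """
    z = np.log(table["L_um"].to_numpy())
    pred = (np.log(table["V_um_per_s"].to_numpy())
            + alpha * np.log(table["A0_uM"].to_numpy())
            - beta * np.log(table["CB_uM"].to_numpy()))
    resid = z - pred
    resid = resid - resid.mean()  # fitted prefactor
    ss_tot = float(((z - z.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("observed lengths have zero variance")
    return 1.0 - float((resid**2).sum()) / ss_tot
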