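"""Headline outputs from a posterior fit.

Time-dependent hazard-ratio curves against the reference treatment,
extrapolated survival curves, fixed-time survival predictions with credible
intervals, and treatment rankings by predicted survival.

Point summaries are posterior means of the per-draw HR(t) and S(t) curves
(so parameter uncertainty propagates into the summaries), with pointwise
posterior-quantile credible bands; a plug-in variant at the posterior-mean
parameters is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .families import log_pdf, log_sf
from .fit import FitResult

__all__ = [
    "EffectSurface",
    "RankingTable",
    "hr_curve",
    "survival_at_times",
    "extrapolate_curves",
    "rank_treatments",
]

DEFAULT_TIMES = (12.0, 24.0, 36.0, 60.0)


@dataclass(frozen=True)
class EffectSurface:
    """Per-treatment survival and hazard-ratio surfaces over a time grid.

    ``survival`` columns: treatment, time_months, mean, lo, hi, extrapolated.
    ``hazard_ratio`` has the same shape for the non-reference treatments.
    """

    endpoint: str
    horizon: float
    survival: pd.DataFrame
    hazard_ratio: pd.DataFrame


@dataclass(frozen=True)
class RankingTable:
    """Treatments ordered by posterior-mean predicted survival at one time."""

    time_months: float
    table: pd.DataFrame  # rank, treatment, mean, lo, hi, tied


def _draw_arrays(fit: FitResult, treatment: str):
    loc = fit.location_draws(treatment)[:, None]  # (D, 1)
    anc = fit.ancillary_draws()
    return loc, (anc[:, None] if anc is not None else None)


def _hazard_draws(fit: FitResult, treatment: str, grid: np.ndarray) -> np.ndarray:
    loc, anc = _draw_arrays(fit, treatment)
    return np.exp(
        log_pdf(fit.family, grid, loc, anc) - log_sf(fit.family, grid, loc, anc)
    )


def _survival_draws(fit: FitResult, treatment: str, grid: np.ndarray) -> np.ndarray:
    loc, anc = _draw_arrays(fit, treatment)
    s = np.exp(log_sf(fit.family, np.maximum(grid, 1e-6), loc, anc))
    return np.where(grid == 0, 1.0, s)


def _band(draws: np.ndarray, level: float):
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha], axis=0)
    return draws.mean(axis=0), lo, hi


def hr_curve(
    fit: FitResult,
    treatment: str,
    grid,
    level: float = 0.95,
    plug_in: bool = False,
) -> pd.DataFrame:
    """Time-dependent hazard ratio of a treatment vs the reference.

    Per posterior draw, HR(t) = h(t; treatment) / h(t; reference); the band
    is the pointwise posterior quantile interval.  With ``plug_in`` the point
    estimate is instead evaluated at the posterior-mean parameters.
    """
    if treatment == fit.reference:
        raise ValueError("hazard ratio of the reference against itself is 1")
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("HR grid times must be positive")
    hr = _hazard_draws(fit, treatment, grid) / _hazard_draws(
        fit, fit.reference, grid
    )
    mean, lo, hi = _band(hr, level)
    if plug_in:
        from .families import hazard as _hz

        params = fit.posterior_mean_params()
        mean = np.asarray(_hz(fit.family, params, treatment, grid)) / np.asarray(
            _hz(fit.family, params, fit.reference, grid)
        )
    return pd.DataFrame(
        {
            "treatment": treatment,
            "time_months": grid,
            "mean": mean,
            "lo": lo,
            "hi": hi,
        }
    )


def survival_at_times(
    fit: FitResult,
    times=DEFAULT_TIMES,
    level: float = 0.95,
    treatments=None,
) -> pd.DataFrame:
    """Predicted survival probabilities at fixed times for every treatment.

    Per draw, the plug-in S(t) is evaluated for each treatment; reported are
    the posterior mean and the central credible interval.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("prediction times must be non-negative")
    all_treatments = (
        list(treatments)
        if treatments is not None
        else [fit.reference, *fit.treatments]
    )
    rows = []
    for trt in all_treatments:
        s = _survival_draws(fit, trt, times)
        mean, lo, hi = _band(s, level)
        rows.append(
            pd.DataFrame(
                {
                    "treatment": trt,
                    "time_months": times,
                    "mean": mean,
                    "lo": lo,
                    "hi": hi,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def extrapolate_curves(
    fit: FitResult,
    horizon: float = 60.0,
    step: float = 0.1,
    level: float = 0.95,
) -> EffectSurface:
    """Survival and HR surfaces on a grid up to the horizon.

    Grid points beyond the last observed time in the fitted data are flagged
    ``extrapolated``.  The HR grid starts at ``step`` (never 0, where
    log-time hazards are singular); the survival grid starts at 0.
    """
    if horizon < fit.max_time:
        raise ValueError(
            f"horizon {horizon} is before the last observed time {fit.max_time:.2f}"
        )
    grid = np.round(np.arange(0.0, horizon + step / 2, step), 10)
    hr_grid = grid[grid > 0]
    surv_frames = []
    for trt in [fit.reference, *fit.treatments]:
        s = _survival_draws(fit, trt, grid)
        mean, lo, hi = _band(s, level)
        surv_frames.append(
            pd.DataFrame(
                {
                    "treatment": trt,
                    "time_months": grid,
                    "mean": mean,
                    "lo": lo,
                    "hi": hi,
                    "extrapolated": grid > fit.max_time,
                }
            )
        )
    hr_frames = []
    for trt in fit.treatments:
        df = hr_curve(fit, trt, hr_grid, level=level)
        df["extrapolated"] = hr_grid > fit.max_time
        hr_frames.append(df)
    return EffectSurface(
        endpoint=fit.endpoint,
        horizon=float(horizon),
        survival=pd.concat(surv_frames, ignore_index=True),
        hazard_ratio=(
            pd.concat(hr_frames, ignore_index=True)
            if hr_frames
            else pd.DataFrame(
                columns=["treatment", "time_months", "mean", "lo", "hi", "extrapolated"]
            )
        ),
    )


def rank_treatments(predictions: pd.DataFrame, time_point: float) -> RankingTable:
    """Rank treatments by posterior-mean predicted survival at one time.

    Descending order; exact ties are broken lexicographically by treatment
    label and flagged.  The time point must be present in ``predictions``.
    """
    sel = predictions[np.isclose(predictions["time_months"], time_point)]
    if len(sel) == 0:
        known = sorted(predictions["time_months"].unique())
        raise ValueError(f"no predictions at t={time_point}; available: {known}")
    sel = sel.sort_values(
        ["mean", "treatment"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    tied = sel["mean"].duplicated(keep=False)
    table = pd.DataFrame(
        {
            "rank": np.arange(1, len(sel) + 1),
            "treatment": sel["treatment"],
            "mean": sel["mean"],
            "lo": sel["lo"],
            "hi": sel["hi"],
            "tied": tied,
        }
    )
    return RankingTable(time_months=float(time_point), table=table)
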