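"""Back-calculated probability-of-treatment-seeking surfaces.

From posterior draws of the 3PL and ability parameters, these operations
evaluate the response probability draw-by-draw — at a grid of travel times,
at fixed thresholds (10/30/60/120 minutes), or over a travel-time raster —
and summarise with the posterior median and central 95% credible interval.

Evaluation is draw-wise: the curve and its band are quantiles, per grid
point, of the probability evaluated at every retained draw. A plug-in mode
(evaluating once at the parameter medians) is available for comparison but
does not yield valid credible bands.

All functions take a "draw frame": a DataFrame with one row per retained
draw and columns ``alpha, beta_time, beta_urban, a, b, c`` (produced by
``FeverTreatmentResults.draw_frame``; fixed parameters appear as constant
columns).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .raster import Raster, assert_coregistered
from .travel import TravelTimeRaster

__all__ = [
    "TreatmentCurve",
    "treatment_curve",
    "summarize_at_thresholds",
    "threshold_floor",
    "probability_raster",
    "predict_probability",
]

_DRAW_COLS = ["alpha", "beta_time", "beta_urban", "a", "b", "c"]


@dataclass
class TreatmentCurve:
    """Posterior treatment-seeking probability by travel time."""

    time_grid: np.ndarray  # minutes
    median: np.ndarray
    lower: np.ndarray  # 2.5% quantile
    upper: np.ndarray  # 97.5% quantile
    residence: str
    item: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_min": self.time_grid,
                "median": self.median,
                "lo95": self.lower,
                "hi95": self.upper,
                "stratum": self.residence,
                "item": self.item,
            }
        )


def _draw_matrix(draws: pd.DataFrame) -> tuple[np.ndarray, ...]:
    missing = [c for c in _DRAW_COLS if c not in draws.columns]
    if missing:
        raise ValueError(f"draw frame missing columns {missing}")
    return tuple(draws[c].to_numpy(dtype=float) for c in _DRAW_COLS)


def _probability_draws(draws: pd.DataFrame, t_min: np.ndarray,
                       urban: np.ndarray) -> np.ndarray:
    """(n_draws, n_points) matrix of 3PL probabilities."""
    alpha, bt, bu, a, b, c = _draw_matrix(draws)
    theta = (
        alpha[:, None]
        + bt[:, None] * t_min[None, :]
        + bu[:, None] * urban[None, :]
    )
    lin = a[:, None] * theta - b[:, None]
    return c[:, None] + (1.0 - c[:, None]) * expit(lin)


def treatment_curve(draws: pd.DataFrame, time_grid, residence: str = "rural",
                    item: str = "public", plug_in: bool = False) -> TreatmentCurve:
    """Probability-of-treatment curve over a travel-time grid.

    Per grid point, the posterior median and central 95% interval of the 3PL
    probability across draws (linear-interpolation quantiles). With
    ``plug_in=True`` the curve is a single evaluation at the parameter
    medians and the band collapses onto it.
    """
    grid = np.asarray(time_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty travel-time grid")
    urb = np.full(grid.shape, float(residence == "urban"))
    if plug_in:
        med_draws = draws.median(axis=0).to_frame().T
        p = _probability_draws(med_draws, grid, urb)[0]
        return TreatmentCurve(grid, p, p.copy(), p.copy(), residence, item)
    p = _probability_draws(draws, grid, urb)
    lo, med, hi = np.quantile(p, [0.025, 0.5, 0.975], axis=0)
    return TreatmentCurve(grid, med, lo, hi, residence, item)


def summarize_at_thresholds(curve: TreatmentCurve,
                            thresholds=(10, 30, 60, 120)) -> pd.DataFrame:
    """Median (95% CrI) at fixed travel-time thresholds.

    One row per threshold with the values and a ``median (lo-hi)`` string to
    two decimals. Thresholds must lie within the curve's grid range; values
    between grid points are linearly interpolated.
    """
    thresholds = list(thresholds)
    rows = []
    g = curve.time_grid
    for t in thresholds:
        if not g.min() <= t <= g.max():
            raise ValueError(f"threshold {t} min outside curve grid "
                             f"[{g.min()}, {g.max()}]")
        med = float(np.interp(t, g, curve.median))
        lo = float(np.interp(t, g, curve.lower))
        hi = float(np.interp(t, g, curve.upper))
        rows.append(
            {
                "t_min": float(t),
                "median": med,
                "lo95": lo,
                "hi95": hi,
                "formatted": f"{med:.2f} ({lo:.2f}–{hi:.2f})",
            }
        )
    return pd.DataFrame(rows, columns=["t_min", "median", "lo95", "hi95",
                                       "formatted"])


def threshold_floor(draws: pd.DataFrame, level: float = 0.95):
    """Posterior median and central credible interval of the threshold c.

    c is the asymptotic floor of the treatment-seeking curve: the minimum
    probability of seeking treatment reached at large travel time.
    """
    c = draws["c"].to_numpy(dtype=float)
    lo = (1.0 - level) / 2.0
    return float(np.median(c)), (float(np.quantile(c, lo)),
                                 float(np.quantile(c, 1.0 - lo)))


def probability_raster(draws: pd.DataFrame, travel: TravelTimeRaster,
                       urban_raster: Raster) -> Raster:
    """Gridded posterior-median probability of seeking treatment.

    Draw-wise evaluation at each cell's travel time and residence, then the
    per-cell median; nodata travel-time cells propagate to nodata.
    """
    tt = travel.minutes
    assert_coregistered(tt, urban_raster)
    t = tt.data.ravel()
    u = urban_raster.data.ravel()
    out = np.full(t.shape, np.nan)
    valid = np.isfinite(t) & np.isfinite(u)
    if valid.any():
        p = _probability_draws(draws, t[valid], u[valid])
        out[valid] = np.median(p, axis=0)
    return Raster(out.reshape(tt.data.shape), tt.cell_size)


def predict_probability(draws: pd.DataFrame, travel_time_min, urban,
                        mode: str = "median") -> np.ndarray:
    """Per-observation posterior probability (draw-wise median or mean)."""
    t = np.atleast_1d(np.asarray(travel_time_min, dtype=float))
    u = np.atleast_1d(np.asarray(urban, dtype=float))
    if np.isnan(t).any() or np.isnan(u).any():
        bad = np.nonzero(np.isnan(t) | np.isnan(u))[0]
        raise ValueError(f"missing covariates at positions {bad[:10].tolist()}")
    p = _probability_draws(draws, t, u)
    if mode == "median":
        return np.median(p, axis=0)
    if mode == "mean":
        return p.mean(axis=0)
    raise ValueError(f"unknown mode {mode!r}")
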