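"""Age-detrended residual size and residual growth.

Pipeline: fit per-age mean radii over a pooled cohort (equivalent to OLS on
age as a factor), subtract to get residual size-at-age, first-difference to
get residual growth, optionally pass increments through a settlement
correction hook, then per-fish z-score and 3-day centered rolling mean.

The settlement-correction hook defaults to the identity: the published
correction it stands in for is defined elsewhere and is deliberately NOT
reproduced here; supply your own callable to apply one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .simulate import IncrementSeries

__all__ = [
    "AgeDetrendModel",
    "ResidualSeries",
    "fit_age_detrend",
    "residual_size",
    "to_growth",
    "normalize",
    "smooth",
    "process",
]

# correction hook signature: (growth values, ages of each growth value,
# settlement_index or None) -> adjusted growth values
CorrectionHook = Callable[[np.ndarray, np.ndarray, "int | None"], np.ndarray]


@dataclass(frozen=True)
class AgeDetrendModel:
    """Per-age mean radius fitted on a pooled training cohort."""

    ages: np.ndarray
    mean_radius_at_age: np.ndarray
    n_obs_at_age: np.ndarray

    def __post_init__(self):
        if self.ages.size == 0:
            raise ValueError("detrend model has no ages")

    def mean_at(self, ages: np.ndarray) -> np.ndarray:
        """Fitted mean radius at each requested age; unseen age is an error."""
        idx = np.searchsorted(self.ages, ages)
        bad = (idx >= self.ages.size) | (self.ages[np.minimum(idx, self.ages.size - 1)] != ages)
        if np.any(bad):
            missing = np.asarray(ages)[bad]
            raise ValueError(f"ages not in detrend model: {missing.tolist()}")
        return self.mean_radius_at_age[idx]


@dataclass
class ResidualSeries:
    """De-trended size-at-age and its day-to-day change for one fish."""

    fish_id: int
    ages: np.ndarray                      # ages of residual_size entries
    residual_size: np.ndarray             # um
    residual_growth: np.ndarray | None = None   # um/day, at ages[1:]
    settlement_index: int | None = None
    normalized: bool = False
    smoothed: bool = False

    @property
    def growth_ages(self) -> np.ndarray:
        """Age assigned to each growth value: the later day of the difference."""
        return self.ages[1:]


def fit_age_detrend(pool: Sequence[IncrementSeries]) -> AgeDetrendModel:
    """Mean radius per age over all fish-age observations in the pool.

    With age modelled as a factor, OLS fitted values are exactly these
    per-age means, so residuals at each age sum to zero over the pool.
    """
    if not pool:
        raise ValueError("cannot fit detrend model on an empty pool")
    frames = pd.concat(
        [pd.DataFrame({"age": s.ages, "radius": s.radii}) for s in pool],
        ignore_index=True,
    )
    g = frames.groupby("age")["radius"].agg(["mean", "count"])
    return AgeDetrendModel(
        ages=g.index.to_numpy(),
        mean_radius_at_age=g["mean"].to_numpy(),
        n_obs_at_age=g["count"].to_numpy(),
    )


def residual_size(series: IncrementSeries, model: AgeDetrendModel) -> ResidualSeries:
    """Residual size-at-age: observed radius minus the fitted per-age mean."""
    ages = series.ages
    resid = series.radii - model.mean_at(ages)
    return ResidualSeries(
        fish_id=series.fish_id,
        ages=ages,
        residual_size=resid,
        settlement_index=series.settlement_index,
    )


def to_growth(rs: ResidualSeries, correction: CorrectionHook | None = None) -> ResidualSeries:
    """First-difference residual size into residual growth.

    ``correction`` may adjust increments spanning the settlement check;
    the default (None) applies no adjustment.
    """
    if rs.residual_size.size < 2:
        raise ValueError(f"fish {rs.fish_id}: need >= 2 residual sizes to difference")
    growth = np.diff(rs.residual_size)
    if correction is not None:
        growth = np.asarray(
            correction(growth, rs.growth_ages, rs.settlement_index), dtype=float
        )
        if growth.shape != rs.growth_ages.shape:
            raise ValueError("correction hook changed the series length")
    return replace(rs, residual_growth=growth, normalized=False, smoothed=False)


def normalize(rs: ResidualSeries) -> ResidualSeries:
    """Per-fish z-score of residual growth (sample sd, ddof=1)."""
    g = rs.residual_growth
    if g is None:
        raise ValueError("call to_growth before normalize")
    sd = np.std(g, ddof=1)
    if not sd > 0:
        raise ValueError(f"fish {rs.fish_id}: zero-variance growth series cannot be normalized")
    return replace(rs, residual_growth=(g - np.mean(g)) / sd, normalized=True)


def smooth(rs: ResidualSeries, window: int = 3) -> ResidualSeries:
    """Centered rolling mean of residual growth.

    Edges keep shrunken (partial) windows rather than being trimmed, so the
    late age windows retain support on short records.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    g = rs.residual_growth
    if g is None:
        raise ValueError("call to_growth before smooth")
    if window > g.size:
        raise ValueError(f"window {window} exceeds series length {g.size}")
    sm = (
        pd.Series(g)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return replace(rs, residual_growth=sm, smoothed=True)


def process(
    series: IncrementSeries,
    model: AgeDetrendModel,
    *,
    correction: CorrectionHook | None = None,
    do_normalize: bool = True,
    do_smooth: bool = True,
    window: int = 3,
) -> ResidualSeries:
    """detrend -> difference -> (normalize) -> (smooth), in that order."""
    rs = to_growth(residual_size(series, model), correction=correction)
    if do_normalize:
        rs = normalize(rs)
    if do_smooth:
        rs = smooth(rs, window=window)
    return rs


def residuals_frame(
    pool: Sequence[IncrementSeries],
    model: AgeDetrendModel | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Long-format residuals table for a cohort (CLI backend)."""
    if model is None:
        model = fit_age_detrend(pool)
    rows = []
    for s in pool:
        rs = process(s, model, **kwargs)
        size_by_age = dict(zip(rs.ages, rs.residual_size))
        growth_by_age = dict(zip(rs.growth_ages, rs.residual_growth))
        for age in rs.ages:
            rows.append(
                {
                    "fish_id": s.fish_id,
                    "age_dph": int(age),
                    "residual_size_um": size_by_age[age],
                    "residual_growth": growth_by_age.get(age, np.nan),
                    "normalized": rs.normalized,
                    "smoothed": rs.smoothed,
                }
            )
    return pd.DataFrame(rows)
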