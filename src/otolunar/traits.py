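"""Growth-history trait extraction.

Twelve features per fish, computed from residual growth:

1-3   trend, linearity, curvature of the normalized + smoothed series
      (loess trend strength; orthogonal quadratic regression coefficients)
4-9   OLS slope and intercept of normalized + smoothed residual growth on
      three age windows (28-34, 35-41, 42-48 days post-hatch, inclusive)
10-11 amplitude ``a`` and offset ``d`` of a lunar-periodic sinusoid fitted
      to the RAW (not normalized, not smoothed) residual growth restricted
      to ages 25-47; the phase parameter is estimated but not a trait
12    pelagic larval duration (settlement-check age, days)
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .lunar import LunarCalendar, theta
from .residuals import AgeDetrendModel, CorrectionHook, process, residual_size, to_growth
from .simulate import IncrementSeries

__all__ = [
    "TRAIT_NAMES",
    "AGE_WINDOWS",
    "SINUSOID_AGE_RANGE",
    "SinusoidFit",
    "TraitVector",
    "stl_traits",
    "window_fits",
    "fit_sinusoid",
    "fit_sinusoid_nls",
    "pld",
    "extract_traits",
    "traits_frame",
    "birthdate_error_days",
]

AGE_WINDOWS: tuple[tuple[int, int], ...] = ((28, 34), (35, 41), (42, 48))
SINUSOID_AGE_RANGE: tuple[int, int] = (25, 47)

TRAIT_NAMES: tuple[str, ...] = (
    "trend",
    "linearity",
    "curvature",
    "slope_28_34",
    "intercept_28_34",
    "slope_35_41",
    "intercept_35_41",
    "slope_42_48",
    "intercept_42_48",
    "sin_a",
    "sin_d",
    "pld_days",
)


@dataclass(frozen=True)
class SinusoidFit:
    """Canonical parameters of ``a*sin(theta*pi/180 + c) + d`` (a >= 0, c in [0, 2pi))."""

    a: float
    c: float
    d: float
    sse: float
    converged: bool = True

    def __post_init__(self):
        if self.a < 0 or not (0.0 <= self.c < 2 * np.pi):
            raise ValueError(f"non-canonical sinusoid parameters a={self.a}, c={self.c}")


@dataclass(frozen=True)
class TraitVector:
    """The 12 growth-history features for one fish."""

    fish_id: int
    trend: float
    linearity: float
    curvature: float
    slope_28_34: float
    intercept_28_34: float
    slope_35_41: float
    intercept_35_41: float
    slope_42_48: float
    intercept_42_48: float
    sin_a: float
    sin_d: float
    pld_days: float
    # bookkeeping, not traits
    missing_windows: tuple[str, ...] = ()
    stage: str = "unknown"

    def __post_init__(self):
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            bad = [n for n, v in zip(TRAIT_NAMES, vals) if not np.isfinite(v)]
            raise ValueError(f"fish {self.fish_id}: non-finite traits {bad}")
        if not (20.0 <= self.pld_days <= 80.0):
            raise ValueError(f"fish {self.fish_id}: implausible PLD {self.pld_days}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in TRAIT_NAMES], dtype=float)

    @classmethod
    def names(cls) -> tuple[str, ...]:
        return TRAIT_NAMES


def _orthonormal_quadratic(n: int) -> np.ndarray:
    """Orthonormal degree-1 and degree-2 polynomial contrasts on 1..n.

    Columns are unit-norm, orthogonal to the intercept and to each other;
    signs fixed so the linear column increases with index and the quadratic
    column is positive at the endpoints (convex upward).
    """
    t = np.arange(1, n + 1, dtype=float)
    X = np.column_stack([np.ones(n), t, t**2])
    Q, _ = np.linalg.qr(X)
    lin, quad = Q[:, 1], Q[:, 2]
    if lin[-1] < lin[0]:
        lin = -lin
    if quad[0] + quad[-1] < 0:
        quad = -quad
    return np.column_stack([lin, quad])


def stl_traits(values: np.ndarray, *, loess_frac: float = 0.75) -> tuple[float, float, float]:
    """Trend strength plus linearity/curvature of the trend component.

    A loess smoother plays the role of the trend extractor (no seasonal
    component is identifiable at lunar period on records this short);
    trend strength is ``max(0, 1 - Var(remainder)/Var(series))``;
    linearity and curvature are the first- and second-order coefficients
    of an orthogonal quadratic regression of the trend on time index.
    """
    y = np.asarray(values, dtype=float)
    n = y.size
    if n < 5:
        raise ValueError(f"need >= 5 points for trend decomposition, got {n}")
    t = np.arange(1, n + 1, dtype=float)
    trend_comp = lowess(y, t, frac=loess_frac, return_sorted=False)
    remainder = y - trend_comp
    var_y = np.var(y, ddof=1)
    trend = 0.0 if var_y == 0 else max(0.0, 1.0 - np.var(remainder, ddof=1) / var_y)
    C = _orthonormal_quadratic(n)
    linearity, curvature = C.T @ trend_comp
    return float(trend), float(linearity), float(curvature)


def window_fits(
    ages: np.ndarray,
    values: np.ndarray,
    windows: Sequence[tuple[int, int]] = AGE_WINDOWS,
    *,
    min_points: int = 3,
) -> tuple[dict[str, float], list[str]]:
    """OLS slope and intercept of ``values`` on age within each window.

    Windows with fewer than ``min_points`` available ages yield slope and
    intercept of 0.0 (mean imputation in downstream standardized space) and
    are reported in the missing list. Intercepts are at age 0 (raw OLS).
    """
    ages = np.asarray(ages)
    values = np.asarray(values, dtype=float)
    out: dict[str, float] = {}
    missing: list[str] = []
    any_fit = False
    for lo, hi in windows:
        key = f"{lo}_{hi}"
        m = (ages >= lo) & (ages <= hi)
        if m.sum() >= min_points:
            slope, intercept = np.polyfit(ages[m].astype(float), values[m], 1)
            out[f"slope_{key}"], out[f"intercept_{key}"] = float(slope), float(intercept)
            any_fit = True
        else:
            out[f"slope_{key}"], out[f"intercept_{key}"] = 0.0, 0.0
            missing.append(key)
    if not any_fit:
        raise ValueError("no age window has enough points for a fit")
    return out, missing


def fit_sinusoid(
    ages: np.ndarray,
    growth: np.ndarray,
    *,
    birth_angle: float = 0.0,
    cal: LunarCalendar | None = None,
    age_range: tuple[int, int] = SINUSOID_AGE_RANGE,
) -> SinusoidFit:
    """Least-squares fit of ``growth = a*sin(theta*pi/180 + c) + d``.

    ``theta`` is the lunar phase angle at each age. The model is linear in
    ``(a cos c, a sin c, d)`` via ``a sin(x + c) = (a cos c) sin x +
    (a sin c) cos x``, so the global optimum is found exactly by linear
    algebra; no iteration, no convergence concerns.

    ``birth_angle`` defaults to 0: an unknown hatch phase only shifts the
    phase parameter, which is not a trait, leaving ``a`` and ``d`` intact —
    this is what makes the fit applicable to fish of unknown birthdate.
    """
    cal = cal or LunarCalendar()
    ages = np.asarray(ages)
    growth = np.asarray(growth, dtype=float)
    m = (ages >= age_range[0]) & (ages <= age_range[1])
    if m.sum() < 6:
        raise ValueError(
            f"need >= 6 points in ages {age_range[0]}-{age_range[1]}, got {int(m.sum())}"
        )
    x = np.radians(theta(ages[m].astype(float), birth_angle, cal))
    y = growth[m]
    X = np.column_stack([np.sin(x), np.cos(x), np.ones_like(x)])
    (A, B, d), *_ = np.linalg.lstsq(X, y, rcond=None)
    a = float(np.hypot(A, B))
    c = float(np.mod(np.arctan2(B, A), 2 * np.pi))
    resid = y - X @ np.array([A, B, d])
    return SinusoidFit(a=a, c=c, d=float(d), sse=float(resid @ resid), converged=True)


def fit_sinusoid_nls(
    ages: np.ndarray,
    growth: np.ndarray,
    *,
    birth_angle: float = 0.0,
    cal: LunarCalendar | None = None,
    age_range: tuple[int, int] = SINUSOID_AGE_RANGE,
    n_starts: int = 8,
) -> SinusoidFit:
    """Multi-start nonlinear least-squares fit of the same sinusoid.

    Retained for workflows where a correction hook makes the model
    nonlinear in practice; for the plain model :func:`fit_sinusoid` is
    exact and should be preferred.
    """
    from scipy.optimize import least_squares

    cal = cal or LunarCalendar()
    ages = np.asarray(ages)
    growth = np.asarray(growth, dtype=float)
    m = (ages >= age_range[0]) & (ages <= age_range[1])
    if m.sum() < 6:
        raise ValueError(f"need >= 6 points in ages {age_range}, got {int(m.sum())}")
    x = np.radians(theta(ages[m].astype(float), birth_angle, cal))
    y = growth[m]

    def resid(p):
        a, c, d = p
        return a * np.sin(x + c) + d - y

    best = None
    any_success = False
    a0 = max(np.std(y) * np.sqrt(2), 1e-6)
    for c0 in np.linspace(0, 2 * np.pi, n_starts, endpoint=False):
        sol = least_squares(resid, x0=[a0, c0, float(np.mean(y))])
        sse = 2 * sol.cost
        any_success = any_success or sol.success
        if best is None or sse < best[0]:
            best = (sse, sol.x)
    sse, (a, c, d) = best
    if a < 0:
        a, c = -a, c + np.pi
    return SinusoidFit(
        a=float(a), c=float(np.mod(c, 2 * np.pi)), d=float(d),
        sse=float(sse), converged=bool(any_success),
    )


def pld(series: IncrementSeries) -> int:
    """Pelagic larval duration: the settlement-check age in days post-hatch."""
    if series.settlement_index is None:
        raise ValueError(f"fish {series.fish_id}: no settlement check recorded")
    return int(series.settlement_index)


def extract_traits(
    series: IncrementSeries,
    model: AgeDetrendModel,
    cal: LunarCalendar | None = None,
    *,
    birth_angle: float = 0.0,
    correction: CorrectionHook | None = None,
    smooth_window: int = 3,
) -> TraitVector:
    """Run the residual pipeline and compute all 12 traits for one fish.

    The sinusoid's phase parameter is estimated but deliberately excluded
    from the trait vector.
    """
    cal = cal or LunarCalendar()
    rs_proc = process(
        series, model, correction=correction, do_normalize=True,
        do_smooth=True, window=smooth_window,
    )
    trend, linearity, curvature = stl_traits(rs_proc.residual_growth)
    wins, missing = window_fits(rs_proc.growth_ages, rs_proc.residual_growth)

    rs_raw = to_growth(residual_size(series, model), correction=correction)
    sfit = fit_sinusoid(
        rs_raw.growth_ages, rs_raw.residual_growth, birth_angle=birth_angle, cal=cal
    )
    return TraitVector(
        fish_id=series.fish_id,
        trend=trend,
        linearity=linearity,
        curvature=curvature,
        sin_a=sfit.a,
        sin_d=sfit.d,
        pld_days=float(pld(series)),
        missing_windows=tuple(missing),
        stage=series.stage,
        **wins,
    )


def traits_frame(
    pool: Sequence[IncrementSeries],
    model: AgeDetrendModel | None = None,
    cal: LunarCalendar | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Trait table for a cohort; detrend model fitted on the pool if absent."""
    from .residuals import fit_age_detrend

    if model is None:
        model = fit_age_detrend(pool)
    rows = []
    for s in pool:
        tv = extract_traits(s, model, cal, **kwargs)
        row = {"fish_id": tv.fish_id, "stage": tv.stage}
        row.update({n: getattr(tv, n) for n in TRAIT_NAMES})
        row["missing_windows"] = ";".join(tv.missing_windows)
        rows.append(row)
    return pd.DataFrame(rows)


def birthdate_error_days(
    count_error_rate: float, age_years: float, days_per_year: float = 365.25
) -> int:
    """Birthdate error range (whole days) implied by a relative
    increment-counting error applied over a fish's age.

    A 1% error rate on an 8-year-old fish gives 29 days — a full lunar
    cycle, which is why adult birthdates cannot be counted directly.
    """
    if count_error_rate < 0 or age_years < 0:
        raise ValueError("error rate and age must be non-negative")
    return int(round(count_error_rate * age_years * days_per_year))
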