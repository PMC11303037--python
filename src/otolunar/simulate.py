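"""Synthetic otolith cohort generator with known ground truth.

Produces daily-increment radius series whose residual growth carries a
lunar-periodic signal phased by birth quarter, plus a truth table covering
birth timing, pelagic larval duration (PLD), settlement environment,
quarter-dependent survival through life stages, and an environmentally
driven primary-male determination rule.

Randomness is split per fish: fish ``i`` draws from
``default_rng([seed, i])`` (growth) and ``default_rng([seed, i, 1])``
(life history), so generating a larger cohort never changes earlier fish.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .lunar import (
    LunarCalendar,
    LunarQuarter,
    days_from_new_moon,
    nearest_quarter,
    theta,
)

__all__ = [
    "SimParams",
    "TruthRecord",
    "IncrementSeries",
    "default_params",
    "default_base_growth",
    "simulate_cohort",
    "apply_life_history",
    "simulate",
    "write_cohort",
    "read_cohort",
]

STAGES = ("egg", "settler", "juvenile", "adult")
SEX_PATHS = ("none", "female", "primary_male", "terminal_phase_male")

# quarter order used for all per-quarter parameter vectors
_QUARTERS = (LunarQuarter.NEW, LunarQuarter.WAXING, LunarQuarter.FULL, LunarQuarter.WANING)


def default_base_growth(max_age: int = 120) -> np.ndarray:
    """Mean daily increment width (um/day) for ages 1..max_age, decreasing with age."""
    ages = np.arange(1, max_age + 1, dtype=float)
    return 9.0 * np.exp(-(ages - 1.0) / 35.0) + 3.0


@dataclass
class SimParams:
    """Parameters of the synthetic data-generating process.

    Per-quarter vectors are ordered (NEW, WAXING, FULL, WANING).
    """

    n_spawned: int = 400
    # spawning timing
    spawn_concentration: float = 1.0      # von Mises kappa around spawn mode
    spawn_mode_deg: float = 0.0           # 0 = new moon
    n_cycles: int = 6                     # birth cycles the cohort spans
    # pelagic larval duration (days)
    pld_mean: float = 46.0
    pld_sd: float = 4.0
    pld_min: float = 37.0
    pld_max: float = 61.0
    # pull of settlement toward the nearest feasible new moon, in [0, 1];
    # delaying (waiting for a later new moon) is weaker than advancing
    # (settling at an imminent one), which keeps mean PLD near pld_mean
    settle_snap: float = 0.15             # strength when the target new moon is later
    settle_snap_advance: float = 0.6      # strength when the target new moon is earlier
    # growth model
    base_growth_curve: np.ndarray = field(default_factory=default_base_growth)
    moon_amp: float = 0.6                 # um/day amplitude of lunar growth modulation
    moon_phase_offset: float = 0.0        # radians, added inside the sine
    noise_sd: float = 0.3                 # um/day iid daily noise
    post_settlement_days_max: int = 24    # record extends 0..this many days past settlement
    max_record_days: int = 70
    # life history (per-quarter survival probabilities)
    survival_by_quarter: tuple = (0.15, 0.45, 0.50, 0.12)           # egg -> settler
    juvenile_survival_by_quarter: tuple = (0.55, 0.60, 0.60, 0.45)  # settler -> juvenile
    adult_survival_by_quarter: tuple = (0.75, 0.40, 0.40, 0.70)     # juvenile -> adult
    # settlement environment
    p_offshore_given_quarter: tuple = (0.70, 0.35, 0.50, 0.30)
    p_group_given_quarter: tuple = (0.50, 0.50, 0.25, 0.25)
    group_size_mean_extra: float = 1.2    # Poisson mean of group members beyond 2
    # sex determination: logistic coefficients on (1, largest-in-group, grouped, offshore)
    sex_logit_coefs: tuple = (-4.0, 2.5, 3.5, 1.5)
    tp_fraction: float = 0.3              # fraction of adults progressing to terminal phase male
    # lunar clock
    synodic_length: float = 29.53
    epoch_new_moon: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        errors = []
        if self.n_spawned <= 0:
            errors.append(f"n_spawned must be > 0, got {self.n_spawned}")
        if not (self.pld_min <= self.pld_mean <= self.pld_max):
            errors.append(
                f"require pld_min <= pld_mean <= pld_max, got "
                f"({self.pld_min}, {self.pld_mean}, {self.pld_max})"
            )
        if self.pld_sd <= 0:
            errors.append(f"pld_sd must be > 0, got {self.pld_sd}")
        if not (0.0 <= self.settle_snap <= 1.0):
            errors.append(f"settle_snap must be in [0, 1], got {self.settle_snap}")
        if not (0.0 <= self.settle_snap_advance <= 1.0):
            errors.append(
                f"settle_snap_advance must be in [0, 1], got {self.settle_snap_advance}"
            )
        for name in (
            "survival_by_quarter",
            "juvenile_survival_by_quarter",
            "adult_survival_by_quarter",
            "p_offshore_given_quarter",
            "p_group_given_quarter",
        ):
            vec = getattr(self, name)
            if len(vec) != 4 or any(not (0.0 <= p <= 1.0) for p in vec):
                errors.append(f"{name} must be 4 probabilities in [0, 1], got {vec}")
        if not (0.0 <= self.tp_fraction <= 1.0):
            errors.append(f"tp_fraction must be in [0, 1], got {self.tp_fraction}")
        base = np.asarray(self.base_growth_curve, dtype=float)
        if base.ndim != 1 or base.size == 0 or np.any(base <= 0):
            errors.append("base_growth_curve must be a non-empty 1-D array of positive increments")
        if self.noise_sd < 0 or self.moon_amp < 0:
            errors.append("noise_sd and moon_amp must be >= 0")
        if errors:
            raise ValueError("invalid SimParams: " + "; ".join(errors))

    @property
    def calendar(self) -> LunarCalendar:
        return LunarCalendar(self.epoch_new_moon, self.synodic_length)


def default_params(**overrides) -> SimParams:
    """Documented default parameters: PLD mean 46 d on [37, 61], spawning
    mode at the new moon, pre-settlement survival favouring FULL/WAXING
    births and post-juvenile survival favouring NEW/WANING births."""
    return replace(SimParams(), **overrides) if overrides else SimParams()


@dataclass
class TruthRecord:
    """Simulator ground truth for one spawned fish."""

    fish_id: int
    birth_day: float
    birth_angle: float
    birth_quarter: LunarQuarter
    pld: int
    settle_day_rel_new_moon: float
    settle_radius_um: float
    offshore: bool = False
    grouped: bool = False
    group_size: int = 1
    stage_reached: str = "egg"
    sex_path: str = "none"

    def __post_init__(self) -> None:
        if self.stage_reached not in STAGES:
            raise ValueError(f"unknown stage {self.stage_reached!r}")
        if self.sex_path not in SEX_PATHS:
            raise ValueError(f"unknown sex path {self.sex_path!r}")
        if self.sex_path != "none" and self.stage_reached != "adult":
            raise ValueError("sex_path is defined only for adults")


@dataclass
class IncrementSeries:
    """One fish's cumulative otolith radius at each daily age 1..n."""

    fish_id: int
    radii: np.ndarray
    settlement_index: int | None = None
    stage: str = "unknown"
    capture_day: float = float("nan")

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        if self.radii.ndim != 1 or self.radii.size == 0:
            raise ValueError(f"fish {self.fish_id}: radii must be a non-empty 1-D array")
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError(f"fish {self.fish_id}: radii must be strictly increasing")
        if self.settlement_index is not None and not (
            1 <= self.settlement_index <= self.radii.size
        ):
            raise ValueError(
                f"fish {self.fish_id}: settlement_index {self.settlement_index} "
                f"outside 1..{self.radii.size}"
            )

    @property
    def ages(self) -> np.ndarray:
        """Days post-hatch of each increment (1-based)."""
        return np.arange(1, self.radii.size + 1)

    @property
    def n_days(self) -> int:
        return self.radii.size


def _base_increment(base: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """base growth at each age; ages beyond the table reuse the last value."""
    idx = np.minimum(ages - 1, base.size - 1)
    return base[idx]


def _simulate_one(fish_id: int, params: SimParams, cal: LunarCalendar):
    rng = np.random.default_rng([params.seed, fish_id])

    # birth timing: von Mises phase around the spawn mode, in one of n_cycles cycles
    if params.spawn_concentration > 0:
        vm = rng.vonmises(0.0, params.spawn_concentration)
    else:
        vm = rng.uniform(-np.pi, np.pi)
    birth_angle = float(np.mod(np.degrees(vm) + params.spawn_mode_deg, 360.0))
    cycle = int(rng.integers(0, params.n_cycles))
    birth_day = (
        params.epoch_new_moon
        + cycle * params.synodic_length
        + birth_angle / 360.0 * params.synodic_length
    )

    # PLD: truncated normal, settlement then pulled toward the nearest new
    # moon REACHABLE within the PLD bounds. Feasibility matters: a fish born
    # at the new moon cannot settle at its nearest new moon (that would need
    # a PLD of ~29.5 d, below the competency window), so it delays toward the
    # following one -- which is what makes new-moon-born fish settle older,
    # larger, and earlier relative to the new moon than other quarters.
    a = (params.pld_min - params.pld_mean) / params.pld_sd
    b = (params.pld_max - params.pld_mean) / params.pld_sd
    pld_raw = float(
        truncnorm.rvs(a, b, loc=params.pld_mean, scale=params.pld_sd, random_state=rng)
    )
    settle = birth_day + pld_raw
    k0 = round((settle - params.epoch_new_moon) / params.synodic_length)
    candidates = [
        params.epoch_new_moon + k * params.synodic_length for k in (k0 - 1, k0, k0 + 1)
    ]
    # 2-day slack: a near-feasible new moon still attracts; rounding clamps later
    feasible = [
        c for c in candidates
        if params.pld_min - 2.0 <= c - birth_day <= params.pld_max + 2.0
    ]
    if feasible:
        target = min(feasible, key=lambda c: abs(c - settle))
        snap = params.settle_snap if target > settle else params.settle_snap_advance
        settle += snap * (target - settle)
    pld = int(np.clip(round(settle - birth_day), params.pld_min, params.pld_max))

    # daily increments: base curve + lunar modulation + noise
    extra = int(rng.integers(0, params.post_settlement_days_max + 1))
    n_days = min(pld + extra, params.max_record_days)
    ages = np.arange(1, n_days + 1)
    incr = _base_increment(np.asarray(params.base_growth_curve, dtype=float), ages)
    if params.moon_amp > 0:
        ang = theta(ages.astype(float), birth_angle, cal)
        incr = incr + params.moon_amp * np.sin(np.radians(ang) + params.moon_phase_offset)
    if params.noise_sd > 0:
        incr = incr + rng.normal(0.0, params.noise_sd, size=n_days)
    incr = np.maximum(incr, 0.05)  # otolith increments cannot be negative
    radii = np.cumsum(incr)

    series = IncrementSeries(
        fish_id=fish_id,
        radii=radii,
        settlement_index=pld,
        stage="unknown",
        capture_day=birth_day + n_days,
    )
    truth = TruthRecord(
        fish_id=fish_id,
        birth_day=birth_day,
        birth_angle=birth_angle,
        birth_quarter=nearest_quarter(birth_angle),
        pld=pld,
        settle_day_rel_new_moon=float(days_from_new_moon(birth_day + pld, cal)),
        settle_radius_um=float(radii[pld - 1]),
    )
    return series, truth


def simulate_cohort(params: SimParams) -> tuple[list[IncrementSeries], list[TruthRecord]]:
    """Generate growth histories and birth-timing truth for ``n_spawned`` fish.

    Life-history outcomes (survival, environment, sex) are filled in by
    :func:`apply_life_history`; here every fish is at stage ``egg``.
    """
    params.validate()
    cal = params.calendar
    out = [_simulate_one(i, params, cal) for i in range(params.n_spawned)]
    series = [s for s, _ in out]
    truth = [t for _, t in out]
    return series, truth


def apply_life_history(truth: Sequence[TruthRecord], params: SimParams) -> list[TruthRecord]:
    """Draw survival through egg -> settler -> juvenile -> adult, settlement
    environment, and the primary-male determination outcome.

    The primary-male rule is logistic on (largest-in-group, grouped,
    offshore); the probability of being largest in a group of size g is the
    fish's settle-radius quantile (within the cohort) raised to g - 1.
    """
    params.validate()
    radii = np.array([t.settle_radius_um for t in truth])
    # empirical quantile of settle size within the spawned cohort
    quantile = {t.fish_id: q for t, q in zip(truth, (np.argsort(np.argsort(radii)) + 0.5) / len(radii))}

    updated: list[TruthRecord] = []
    for t in truth:
        rng = np.random.default_rng([params.seed, t.fish_id, 1])
        qi = _QUARTERS.index(t.birth_quarter)
        rec = replace(t, stage_reached="egg", sex_path="none",
                      offshore=False, grouped=False, group_size=1)

        if rng.random() < params.survival_by_quarter[qi]:
            rec.stage_reached = "settler"
            rec.offshore = bool(rng.random() < params.p_offshore_given_quarter[qi])
            rec.grouped = bool(rng.random() < params.p_group_given_quarter[qi])
            rec.group_size = (
                2 + int(rng.poisson(params.group_size_mean_extra)) if rec.grouped else 1
            )
            if rng.random() < params.juvenile_survival_by_quarter[qi]:
                rec.stage_reached = "juvenile"
                if rng.random() < params.adult_survival_by_quarter[qi]:
                    rec.stage_reached = "adult"
                    p_top = quantile[t.fish_id] ** (rec.group_size - 1)
                    is_top = rng.random() < p_top
                    b0, b_top, b_grp, b_off = params.sex_logit_coefs
                    logit = b0 + b_top * is_top + b_grp * rec.grouped + b_off * rec.offshore
                    if rng.random() < expit(logit):
                        rec.sex_path = "primary_male"
                    else:
                        rec.sex_path = "female"
                    if rng.random() < params.tp_fraction:
                        rec.sex_path = "terminal_phase_male"
        updated.append(rec)
    return updated


def simulate(params: SimParams) -> tuple[list[IncrementSeries], list[TruthRecord]]:
    """Full generator: growth histories plus life-history outcomes, with
    series stage labels synchronized to the truth table."""
    series, truth = simulate_cohort(params)
    truth = apply_life_history(truth, params)
    stage_of = {t.fish_id: t.stage_reached for t in truth}
    for s in series:
        s.stage = stage_of[s.fish_id]
    return series, truth


# ---------------------------------------------------------------------------
# CSV round trip


_TRUTH_COLUMNS = [
    "fish_id", "birth_day", "birth_angle", "birth_quarter", "pld",
    "settle_day_rel_new_moon", "settle_radius_um", "offshore", "grouped",
    "group_size", "stage_reached", "sex_path",
]


def _truth_to_frame(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    rows = []
    for t in truth:
        d = asdict(t)
        d["birth_quarter"] = t.birth_quarter.name
        rows.append(d)
    return pd.DataFrame(rows, columns=_TRUTH_COLUMNS)


def write_cohort(series: Sequence[IncrementSeries], truth: Sequence[TruthRecord],
                 path: str | Path) -> tuple[Path, Path]:
    """Write increments.csv (long format) and truth.csv under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    inc_rows = []
    for s in series:
        for age, r in zip(s.ages, s.radii):
            inc_rows.append(
                {
                    "fish_id": s.fish_id,
                    "age_dph": int(age),
                    "radius_um": float(r),
                    "settlement_index": s.settlement_index,
                    "stage": s.stage,
                    "capture_day": s.capture_day,
                }
            )
    inc_cols = ["fish_id", "age_dph", "radius_um", "settlement_index", "stage", "capture_day"]
    inc = pd.DataFrame(inc_rows, columns=inc_cols)
    inc_path = path / "increments.csv"
    # %.17g guarantees exact float round trips through the text format
    inc.to_csv(inc_path, index=False, float_format="%.17g")

    truth_path = path / "truth.csv"
    _truth_to_frame(truth).to_csv(truth_path, index=False, float_format="%.17g")
    return inc_path, truth_path


class CohortParseError(ValueError):
    """Malformed cohort file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


def read_cohort(path: str | Path) -> tuple[list[IncrementSeries], list[TruthRecord]]:
    """Read a cohort written by :func:`write_cohort`, validating invariants.

    An empty cohort (header-only files) round-trips to empty lists.
    """
    path = Path(path)
    inc = pd.read_csv(path / "increments.csv", float_precision="round_trip")
    required = {"fish_id", "age_dph", "radius_um", "settlement_index", "stage", "capture_day"}
    missing = required - set(inc.columns)
    if missing:
        raise CohortParseError(f"increments.csv missing columns {sorted(missing)}")

    series: list[IncrementSeries] = []
    if len(inc):
        # preserve original line numbers (header is line 1) for error reporting
        inc = inc.assign(_line=np.arange(2, len(inc) + 2))
        for fid, g in inc.groupby("fish_id", sort=True):
            g = g.sort_values("age_dph")
            ages = g["age_dph"].to_numpy()
            if not np.array_equal(ages, np.arange(1, len(ages) + 1)):
                raise CohortParseError(
                    f"fish {fid}: ages must be consecutive 1..n", int(g["_line"].iloc[0])
                )
            radii = g["radius_um"].to_numpy(dtype=float)
            bad = np.nonzero(np.diff(radii) <= 0)[0]
            if bad.size:
                raise CohortParseError(
                    f"fish {fid}: radii not strictly increasing at age {ages[bad[0] + 1]}",
                    int(g["_line"].iloc[bad[0] + 1]),
                )
            sidx = g["settlement_index"].iloc[0]
            series.append(
                IncrementSeries(
                    fish_id=int(fid),
                    radii=radii,
                    settlement_index=None if pd.isna(sidx) else int(sidx),
                    stage=str(g["stage"].iloc[0]),
                    capture_day=float(g["capture_day"].iloc[0]),
                )
            )

    tdf = pd.read_csv(path / "truth.csv", float_precision="round_trip")
    truth: list[TruthRecord] = []
    for i, row in tdf.iterrows():
        try:
            truth.append(
                TruthRecord(
                    fish_id=int(row["fish_id"]),
                    birth_day=float(row["birth_day"]),
                    birth_angle=float(row["birth_angle"]),
                    birth_quarter=LunarQuarter[row["birth_quarter"]],
                    pld=int(row["pld"]),
                    settle_day_rel_new_moon=float(row["settle_day_rel_new_moon"]),
                    settle_radius_um=float(row["settle_radius_um"]),
                    offshore=bool(row["offshore"]),
                    grouped=bool(row["grouped"]),
                    group_size=int(row["group_size"]),
                    stage_reached=str(row["stage_reached"]),
                    sex_path=str(row["sex_path"]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise CohortParseError(str(exc), int(i) + 2) from exc
    return series, truth
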