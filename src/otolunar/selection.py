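"""Birth-quarter distributions by life stage and log-ratio selection indices.

Selection on a stage transition is ``log10(P_to / P_from)`` per quarter,
where ``P`` is the proportion of that stage's fish born in the quarter:
positive values mean that quarter's fish survived the transition relatively
well. The stage graph is

    egg -> settler -> juvenile -> {female, primary_male} -> tp_male

and the full matrix covers every ordered pair connected by a path (14 pairs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .lunar import QUARTER_ORDER, LunarQuarter
from .simulate import TruthRecord

__all__ = [
    "SELECTION_STAGES",
    "STAGE_PAIRS",
    "StageCohort",
    "SelectionEstimate",
    "stage_distribution",
    "selection_index",
    "selection_matrix",
    "settler_summary",
    "stage_cohorts_from_truth",
]

SELECTION_STAGES = ("egg", "settler", "juvenile", "female", "primary_male", "tp_male")

# stage graph: direct successors
_SUCCESSORS = {
    "egg": ("settler",),
    "settler": ("juvenile",),
    "juvenile": ("female", "primary_male"),
    "female": ("tp_male",),
    "primary_male": ("tp_male",),
    "tp_male": (),
}


def _reachable(stage: str) -> list[str]:
    out, frontier = [], list(_SUCCESSORS[stage])
    while frontier:
        s = frontier.pop(0)
        if s not in out:
            out.append(s)
            frontier.extend(_SUCCESSORS[s])
    return out


#: All ordered stage pairs connected by a path, in panel order.
STAGE_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (a, b) for a in SELECTION_STAGES for b in _reachable(a)
)


@dataclass(frozen=True)
class StageCohort:
    """Birth-quarter distribution of one life stage."""

    stage: str
    n: int
    P: np.ndarray  # proportions, ordered NEW, WAXING, FULL, WANING

    def __post_init__(self):
        P = np.asarray(self.P, dtype=float)
        if P.shape != (4,) or np.any(P < 0) or abs(P.sum() - 1.0) > 1e-9:
            raise ValueError(f"stage {self.stage}: P must be 4 proportions summing to 1")
        object.__setattr__(self, "P", P)


@dataclass(frozen=True)
class SelectionEstimate:
    """log10 proportion ratio for one quarter across one stage transition."""

    from_stage: str
    to_stage: str
    quarter: LunarQuarter
    value: float
    finite: bool


def stage_distribution(quarters: Sequence[LunarQuarter], stage: str = "") -> StageCohort:
    """Birth-quarter proportions over one stage's fish, with exact counts."""
    quarters = list(quarters)
    if not quarters:
        raise ValueError(f"stage {stage!r}: empty assignment set")
    counts = np.array([sum(q == lq for q in quarters) for lq in QUARTER_ORDER], dtype=float)
    return StageCohort(stage=stage, n=len(quarters), P=counts / counts.sum())


def selection_index(
    to: StageCohort, frm: StageCohort, *, smooth: bool = False
) -> list[SelectionEstimate]:
    """Per-quarter ``log10(P_to / P_from)``.

    Zero proportions give non-finite estimates flagged ``finite=False``
    unless ``smooth`` adds 0.5 pseudo-counts per quarter to both cohorts.
    """
    p_to, p_frm = to.P, frm.P
    if smooth:
        p_to = (to.P * to.n + 0.5) / (to.n + 2.0)
        p_frm = (frm.P * frm.n + 0.5) / (frm.n + 2.0)
    out = []
    for i, q in enumerate(QUARTER_ORDER):
        with np.errstate(divide="ignore", invalid="ignore"):
            v = float(np.log10(p_to[i] / p_frm[i])) if p_frm[i] != 0 or p_to[i] != 0 else float("nan")
        out.append(
            SelectionEstimate(
                from_stage=frm.stage, to_stage=to.stage, quarter=q,
                value=v, finite=bool(np.isfinite(v)),
            )
        )
    return out


def selection_matrix(
    cohorts: Iterable[StageCohort], *, smooth: bool = False
) -> list[SelectionEstimate]:
    """Selection estimates for every stage pair connected by a path.

    Only pairs whose both stages are present in ``cohorts`` are returned;
    with all six stages this is the full 14-transition matrix.
    """
    by_stage = {c.stage: c for c in cohorts}
    unknown = set(by_stage) - set(SELECTION_STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; expected {SELECTION_STAGES}")
    if len(by_stage) < 2:
        raise ValueError("need at least two stage cohorts")
    out = []
    for a, b in STAGE_PAIRS:
        if a in by_stage and b in by_stage:
            out.extend(selection_index(by_stage[b], by_stage[a], smooth=smooth))
    return out


def selection_frame(estimates: Sequence[SelectionEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "from_stage": [e.from_stage for e in estimates],
            "to_stage": [e.to_stage for e in estimates],
            "quarter": [e.quarter.name for e in estimates],
            "log10_ratio": [e.value for e in estimates],
            "finite": [e.finite for e in estimates],
        }
    )


def stage_cohorts_from_truth(truth: Sequence[TruthRecord]) -> list[StageCohort]:
    """Build the six stage cohorts from simulator ground truth.

    Stage membership is cumulative upstream (an adult was also a settler and
    a juvenile) and exclusive at the sex stages (current phenotype).
    """
    stage_rank = {"egg": 0, "settler": 1, "juvenile": 2, "adult": 3}
    cohorts = []
    for stage, rank in (("egg", 0), ("settler", 1), ("juvenile", 2)):
        qs = [t.birth_quarter for t in truth if stage_rank[t.stage_reached] >= rank]
        if qs:
            cohorts.append(stage_distribution(qs, stage))
    for stage, path in (
        ("female", "female"),
        ("primary_male", "primary_male"),
        ("tp_male", "terminal_phase_male"),
    ):
        qs = [t.birth_quarter for t in truth if t.sex_path == path]
        if qs:
            cohorts.append(stage_distribution(qs, stage))
    return cohorts


def settler_summary(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    """Per-birth-quarter settlement environment summary (one row per quarter):
    mean settlement day relative to the new moon, mean otolith radius and age
    at settlement, and the proportions settling offshore and in groups.

    Quarters with no settlers get NaN cells and ``n = 0``.
    """
    settlers = [t for t in truth if t.stage_reached in ("settler", "juvenile", "adult")]
    if not settlers:
        raise ValueError("no settler records")
    rows = []
    for q in QUARTER_ORDER:
        sub = [t for t in settlers if t.birth_quarter == q]
        if sub:
            rows.append(
                {
                    "birth_quarter": q.name,
                    "n": len(sub),
                    "mean_settle_day_rel_new_moon": np.mean(
                        [t.settle_day_rel_new_moon for t in sub]
                    ),
                    "mean_settle_radius_um": np.mean([t.settle_radius_um for t in sub]),
                    "mean_age_at_settlement": np.mean([t.pld for t in sub]),
                    "prop_offshore": np.mean([t.offshore for t in sub]),
                    "prop_grouped": np.mean([t.grouped for t in sub]),
                }
            )
        else:
            rows.append(
                {
                    "birth_quarter": q.name, "n": 0,
                    "mean_settle_day_rel_new_moon": np.nan,
                    "mean_settle_radius_um": np.nan,
                    "mean_age_at_settlement": np.nan,
                    "prop_offshore": np.nan, "prop_grouped": np.nan,
                }
            )
    return pd.DataFrame(rows)
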