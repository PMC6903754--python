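"""Burst detection on agonistic onset series.

Implements the two-parameter infinite-state burst automaton on inter-onset
gaps: state *i* emits gaps from an exponential with rate ``alpha_i =
(n / T) * s**i`` (``n`` gaps spanning ``T`` seconds), moving up ``j - i``
states costs ``gamma * (j - i) * ln(n)``, moving down is free.  The
formally infinite state ladder is capped at the first state whose expected
gap falls below the smallest observed gap (plus one spare state): higher
states can never be optimal.  The minimum-cost state sequence is found by
dynamic programming with ties broken toward the lower state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import events_io
from .events_io import Ethogram, EventLog, OnsetSeries
from .exceptions import PreconditionError

__all__ = [
    "KleinbergParams",
    "BurstInterval",
    "BurstSummary",
    "n_states_for",
    "kleinberg_state_sequence",
    "state_sequence_cost",
    "extract_bursts",
    "detect_dyad_bursts",
    "burst_summary",
]


@dataclass(frozen=True)
class KleinbergParams:
    gamma: float = 0.3
    s: float = 2.0
    level: int = 2

    def __post_init__(self):
        if not self.gamma > 0:
            raise PreconditionError("gamma must be > 0")
        if not self.s > 1:
            raise PreconditionError("s must be > 1")
        if self.level < 1:
            raise PreconditionError("level must be >= 1")


@dataclass(frozen=True)
class BurstInterval:
    dyad_id: object
    day: int
    start: float
    end: float
    level: int
    index: int  # cumulative within dyad, 1-based, ordered by (day, start)

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t <= self.end


def n_states_for(gaps: np.ndarray, s: float) -> int:
    """Number of automaton states 0..k for the capped ladder."""
    n = gaps.size
    T = float(gaps.sum())
    dmin = float(gaps.min())
    base_gap = T / n  # expected gap in state 0
    k = 1
    while base_gap / s**k >= dmin:
        k += 1
    return k + 2  # states 0..k+1 (one spare above the cap)


def _costs(gaps: np.ndarray, params: KleinbergParams) -> tuple[np.ndarray, float]:
    """Emission cost matrix (n_gaps x n_states) and the up-move unit cost."""
    n = gaps.size
    T = float(gaps.sum())
    n_states = n_states_for(gaps, params.s)
    alpha = (n / T) * params.s ** np.arange(n_states)
    # -ln(alpha * exp(-alpha x)) = -ln(alpha) + alpha * x
    emit = -np.log(alpha)[None, :] + alpha[None, :] * gaps[:, None]
    return emit, params.gamma * np.log(n)


def kleinberg_state_sequence(series: OnsetSeries, params: KleinbergParams) -> np.ndarray:
    """Minimum-cost automaton state per inter-onset gap.

    Returns an integer array aligned with ``diff(times)``; empty when the
    series has fewer than two onsets.  The automaton starts in state 0.
    """
    if len(series) < 2:
        return np.empty(0, dtype=int)
    t = series.strictly_increasing().times
    gaps = np.diff(t)
    if np.any(gaps <= 0):
        raise PreconditionError("onset times must be strictly increasing")
    emit, up_unit = _costs(gaps, params)
    n_gaps, n_states = emit.shape
    states = np.arange(n_states)
    # up-move cost matrix tau[i, j]
    delta = states[None, :] - states[:, None]
    tau = np.where(delta > 0, up_unit * delta, 0.0)

    cost = np.full(n_states, np.inf)
    cost[0] = 0.0
    back = np.zeros((n_gaps, n_states), dtype=int)
    for g in range(n_gaps):
        cand = cost[:, None] + tau  # predecessor i -> state j
        # argmin with ties toward the lower predecessor state
        back[g] = np.argmin(cand, axis=0)
        cost = cand[back[g], states] + emit[g]
    # final state: ties toward the lower state
    q = np.empty(n_gaps, dtype=int)
    q[-1] = int(np.argmin(cost))
    for g in range(n_gaps - 1, 0, -1):
        q[g - 1] = back[g, q[g]]
    return q


def state_sequence_cost(gaps: np.ndarray, q: np.ndarray, params: KleinbergParams) -> float:
    """Total automaton cost of an arbitrary state sequence (for auditing)."""
    gaps = np.asarray(gaps, dtype=float)
    q = np.asarray(q, dtype=int)
    emit, up_unit = _costs(gaps, params)
    total = emit[np.arange(gaps.size), q].sum()
    prev = np.concatenate([[0], q[:-1]])
    ups = np.clip(q - prev, 0, None)
    return float(total + up_unit * ups.sum())


def extract_bursts(
    states: np.ndarray,
    series: OnsetSeries,
    level: int,
    dyad_id=None,
    day: int = 0,
) -> list[BurstInterval]:
    """Maximal runs of gaps at or above ``level`` as time intervals.

    A run of qualifying gaps from gap *i* to gap *j* spans the onsets
    bounding it: ``[t_i, t_{j+1}]``.  Indices are assigned later by
    :func:`detect_dyad_bursts`; here they are 1-based within the series.
    """
    states = np.asarray(states, dtype=int)
    t = series.strictly_increasing().times
    if states.size != max(0, t.size - 1):
        raise PreconditionError("state sequence not aligned with series gaps")
    out: list[BurstInterval] = []
    g = 0
    while g < states.size:
        if states[g] >= level:
            h = g
            while h + 1 < states.size and states[h + 1] >= level:
                h += 1
            out.append(
                BurstInterval(
                    dyad_id=dyad_id,
                    day=day,
                    start=float(t[g]),
                    end=float(t[h + 1]),
                    level=level,
                    index=len(out) + 1,
                )
            )
            g = h + 1
        else:
            g += 1
    return out


def detect_dyad_bursts(
    log: EventLog,
    dyad,
    eth: Ethogram,
    params: KleinbergParams | None = None,
) -> list[BurstInterval]:
    """Per-day burst detection on the dyad's pooled agonistic onsets.

    Both subjects' aggressive and subordinate onsets are pooled per day;
    days with fewer than two agonistic onsets contribute no bursts.  Burst
    indices run cumulatively across days in (day, start) order.
    """
    params = params or KleinbergParams()
    agonistic = eth.agonistic_behaviors()
    out: list[BurstInterval] = []
    for day in sorted(log.for_dyad(dyad)["day"].unique()):
        series = events_io.extract_onsets(log, dyad, behaviors=agonistic, day=int(day))
        if len(series) < 2:
            continue
        states = kleinberg_state_sequence(series, params)
        for b in extract_bursts(states, series, params.level, dyad_id=dyad, day=int(day)):
            out.append(b)
    out.sort(key=lambda b: (b.day, b.start))
    return [
        BurstInterval(b.dyad_id, b.day, b.start, b.end, b.level, i + 1)
        for i, b in enumerate(out)
    ]


def bursts_to_frame(bursts: list[BurstInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "dyad_id": b.dyad_id,
                "day": b.day,
                "index": b.index,
                "start_s": b.start,
                "end_s": b.end,
                "level": b.level,
            }
            for b in bursts
        ],
        columns=["dyad_id", "day", "index", "start_s", "end_s", "level"],
    )


def bursts_from_frame(df: pd.DataFrame) -> list[BurstInterval]:
    return [
        BurstInterval(
            dyad_id=r.dyad_id,
            day=int(r.day),
            start=float(r.start_s),
            end=float(r.end_s),
            level=int(r.level),
            index=int(r.index),
        )
        for r in df.itertuples(index=False)
    ]


@dataclass
class BurstSummary:
    """Descriptive burst statistics: raw per dyad-day rows plus per-day medians."""

    per_dyad_day: pd.DataFrame = field(default_factory=pd.DataFrame)
    by_day: pd.DataFrame = field(default_factory=pd.DataFrame)


def _median_iqr(x: pd.Series) -> tuple[float, float, float]:
    x = x.dropna()
    if x.empty:
        return (np.nan, np.nan, np.nan)
    return (float(x.median()), float(x.quantile(0.25)), float(x.quantile(0.75)))


def burst_summary(log: EventLog, bursts: list[BurstInterval], eth: Ethogram) -> BurstSummary:
    """Burst frequency, duration, and in-burst agonistic proportions per day.

    Proportions count state onsets with ``start <= t <= end`` for some
    burst, over all state onsets that day; undefined (no onsets) stays NaN.
    """
    by_dyad_day: dict[tuple, list[BurstInterval]] = {}
    for b in bursts:
        by_dyad_day.setdefault((b.dyad_id, b.day), []).append(b)

    rows = []
    agg = eth.behaviors_in_state(events_io.AGGRESSIVE)
    sub = eth.behaviors_in_state(events_io.SUBORDINATE)
    for dyad in log.dyads:
        for day in sorted(log.for_dyad(dyad)["day"].unique()):
            day = int(day)
            dbursts = by_dyad_day.get((dyad, day), [])
            row: dict = {
                "dyad_id": dyad,
                "day": day,
                "n_bursts": len(dbursts),
                "median_duration_s": (
                    float(np.median([b.duration for b in dbursts])) if dbursts else np.nan
                ),
            }
            for name, behaviors in (("aggressive", agg), ("subordinate", sub)):
                series = events_io.extract_onsets(log, dyad, behaviors=behaviors, day=day)
                if len(series) == 0:
                    row[f"prop_{name}_in_bursts"] = np.nan
                    continue
                inside = sum(
                    1 for t in series.times if any(b.contains(t) for b in dbursts)
                )
                row[f"prop_{name}_in_bursts"] = inside / len(series)
            rows.append(row)
    per = pd.DataFrame(rows)

    day_rows = []
    for day, grp in per.groupby("day"):
        entry: dict = {"day": day}
        for col in ("n_bursts", "median_duration_s", "prop_aggressive_in_bursts",
                    "prop_subordinate_in_bursts"):
            med, q1, q3 = _median_iqr(grp[col])
            entry[f"{col}_median"] = med
            entry[f"{col}_q1"] = q1
            entry[f"{col}_q3"] = q3
        day_rows.append(entry)
    return BurstSummary(per_dyad_day=per, by_day=pd.DataFrame(day_rows))
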