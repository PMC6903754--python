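"""Directional timed-window cross-correlation between partners' event trains.

For actor onsets A and responder onsets B observed over shared windows, the
forward tiling coefficient is

    FSTTC = 1/2 * ((P - T_B) / (1 - P * T_B) + (P - T_A) / (1 - P * T_A))

where P is the fraction of B onsets falling within dt after some A onset
(closed window, b - a in [0, dt]) and T_X is the fraction of observation
time covered by the union of (t, t + dt] tiles after X's onsets, clipped
to the windows.  Sessions on different days never interact: components are
accumulated per segment and combined.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import events_io, intervals
from .events_io import Ethogram, EventLog, OnsetSeries
from .exceptions import PreconditionError
from .resolution import PhaseSegmentation
from .stats_util import paired_wilcoxon

__all__ = [
    "FsttcResult",
    "tiled_time",
    "forward_hits",
    "forward_proportion",
    "forward_sttc",
    "forward_sttc_from_components",
    "symmetric_sttc",
    "default_groupings",
    "dyad_fsttc_table",
    "compare_directions",
]

DIRECTIONS = ("DOM->SUB", "SUB->DOM")


@dataclass(frozen=True)
class FsttcResult:
    value: float | None
    P: float | None
    T_A: float | None
    T_B: float | None
    n_A: int
    n_B: int
    total_time: float

    @property
    def defined(self) -> bool:
        return self.value is not None


def tile_union(times: np.ndarray, windows, dt: float) -> list[tuple[float, float]]:
    """Merged union of (t, t + dt] tiles clipped to the observation windows."""
    tiles = [(float(t), float(t) + dt) for t in np.asarray(times, dtype=float)]
    return intervals.intersect(intervals.merge(tiles), intervals.validate_windows(windows))


def tiled_time(series: OnsetSeries, dt: float) -> float:
    """Proportion of observation time within dt after any onset."""
    total = series.total_time
    if total <= 0:
        raise PreconditionError("total observation time is zero")
    return intervals.total_length(tile_union(series.times, series.windows, dt)) / total


def forward_hits(a_times: np.ndarray, b_times: np.ndarray, dt: float) -> int:
    """Number of B onsets with some A onset at lag in [0, dt]."""
    a = np.sort(np.asarray(a_times, dtype=float))
    b = np.asarray(b_times, dtype=float)
    if a.size == 0 or b.size == 0:
        return 0
    # nearest A onset at or before each b (lag >= 0)
    idx = np.searchsorted(a, b, side="right") - 1
    ok = idx >= 0
    lags = np.where(ok, b - a[np.clip(idx, 0, None)], np.inf)
    return int(np.count_nonzero(lags <= dt))


def forward_proportion(A: OnsetSeries, B: OnsetSeries, dt: float) -> float:
    """Fraction of B onsets within dt after any A onset (closed bounds)."""
    if len(B) == 0:
        raise PreconditionError("forward proportion undefined for empty target series")
    return forward_hits(A.times, B.times, dt) / len(B)


def _combine(p: float, t: float) -> float | None:
    denom = 1.0 - p * t
    if denom == 0.0:
        return None
    return (p - t) / denom


def forward_sttc_from_components(
    hit_count: int,
    n_A: int,
    n_B: int,
    tiled_A: float,
    tiled_B: float,
    total_time: float,
) -> FsttcResult:
    """Assemble the coefficient from per-segment accumulated components."""
    if n_A == 0 or n_B == 0 or total_time <= 0:
        return FsttcResult(None, None, None, None, n_A, n_B, total_time)
    P = hit_count / n_B
    T_A = tiled_A / total_time
    T_B = tiled_B / total_time
    term_b = _combine(P, T_B)
    term_a = _combine(P, T_A)
    if term_a is None or term_b is None:
        return FsttcResult(None, P, T_A, T_B, n_A, n_B, total_time)
    return FsttcResult(0.5 * (term_b + term_a), P, T_A, T_B, n_A, n_B, total_time)


def forward_sttc(
    segments: Sequence[tuple[OnsetSeries, OnsetSeries]],
    dt: float = 2.0,
) -> FsttcResult:
    """Forward tiling coefficient over one or more (A, B) segments.

    Each segment pairs the actor and responder series over the same
    windows (e.g. one day's phase windows); onsets and time in different
    segments never interact.
    """
    if dt <= 0:
        raise PreconditionError("dt must be positive")
    hits = n_A = n_B = 0
    tiled_A = tiled_B = total = 0.0
    for A, B in segments:
        if A.windows != B.windows:
            raise PreconditionError("A and B must share observation windows")
        hits += forward_hits(A.times, B.times, dt)
        n_A += len(A)
        n_B += len(B)
        tiled_A += intervals.total_length(tile_union(A.times, A.windows, dt))
        tiled_B += intervals.total_length(tile_union(B.times, B.windows, dt))
        total += A.total_time
    return forward_sttc_from_components(hits, n_A, n_B, tiled_A, tiled_B, total)


def symmetric_sttc(
    segments: Sequence[tuple[OnsetSeries, OnsetSeries]],
    dt: float = 2.0,
) -> float | None:
    """Classic symmetric tiling coefficient (+-dt windows), as a cross-check."""
    pa = pb = n_A = n_B = 0
    tiled_A = tiled_B = total = 0.0
    for A, B in segments:
        a, b = A.times, B.times
        pa += sum(1 for t in a if b.size and np.min(np.abs(b - t)) <= dt)
        pb += sum(1 for t in b if a.size and np.min(np.abs(a - t)) <= dt)
        n_A += len(A)
        n_B += len(B)
        two_sided_a = [(t - dt, t + dt) for t in a]
        two_sided_b = [(t - dt, t + dt) for t in b]
        tiled_A += intervals.total_length(
            intervals.intersect(intervals.merge(two_sided_a), A.windows)
        )
        tiled_B += intervals.total_length(
            intervals.intersect(intervals.merge(two_sided_b), B.windows)
        )
        total += A.total_time
    if n_A == 0 or n_B == 0 or total <= 0:
        return None
    P_A, P_B = pa / n_A, pb / n_B
    T_A, T_B = tiled_A / total, tiled_B / total
    term1 = _combine(P_A, T_B)
    term2 = _combine(P_B, T_A)
    if term1 is None or term2 is None:
        return None
    return 0.5 * (term1 + term2)


# ---------------------------------------------------------------------------
# Dyad-level tables


def default_groupings(eth: Ethogram) -> dict[str, frozenset[str]]:
    """Behavior groups studied by default: pooled lunge/bite, tail rattle
    alone, pooled subordinate behaviors, plus every ethogram state."""
    groups = {
        "lunge-bite": frozenset({"lunge", "bite"}),
        "tail-rattle": frozenset({"tail-rattle"}),
        "subordinate": eth.behaviors_in_state(events_io.SUBORDINATE),
    }
    for state in events_io.STATES:
        groups.setdefault(state.lower(), eth.behaviors_in_state(state))
    return groups


def _phase_segments(
    log: EventLog,
    dyad,
    phases: PhaseSegmentation,
    phase: str,
    actor,
    responder,
    given: frozenset[str],
    target: frozenset[str],
) -> list[tuple[OnsetSeries, OnsetSeries]]:
    segs = []
    days = sorted({d for (d, _, _) in phases.windows.get(phase, [])})
    for day in days:
        wins = phases.day_windows(phase, day)
        A = events_io.extract_onsets(log, dyad, subjects=[actor], behaviors=given,
                                     windows=wins, day=day)
        B = events_io.extract_onsets(log, dyad, subjects=[responder], behaviors=target,
                                     windows=wins, day=day)
        segs.append((A, B))
    return segs


def dyad_fsttc_table(
    log: EventLog,
    dyad,
    phases: PhaseSegmentation,
    roles: dict,
    eth: Ethogram,
    groupings: dict[str, frozenset[str]] | None = None,
    dt: float = 2.0,
    which_phases: Sequence[str] = ("pre", "post"),
) -> pd.DataFrame:
    """FSTTC per (phase, given group, target group, direction) for one dyad.

    Undefined cells (empty series, degenerate denominators, absent phase)
    are recorded with a missing value, never imputed as 0.
    """
    groupings = groupings or default_groupings(eth)
    dom = [s for s, r in roles.items() if r == "dom"][0]
    sub = [s for s, r in roles.items() if r == "sub"][0]
    rows = []
    for phase in which_phases:
        for gname, gset in groupings.items():
            for tname, tset in groupings.items():
                for direction, actor, responder in (
                    ("DOM->SUB", dom, sub),
                    ("SUB->DOM", sub, dom),
                ):
                    if phases.duration(phase) <= 0:
                        res = FsttcResult(None, None, None, None, 0, 0, 0.0)
                    else:
                        segs = _phase_segments(
                            log, dyad, phases, phase, actor, responder, gset, tset
                        )
                        res = forward_sttc(segs, dt=dt)
                    rows.append(
                        {
                            "dyad_id": dyad,
                            "phase": phase,
                            "direction": direction,
                            "given_group": gname,
                            "target_group": tname,
                            "P": res.P,
                            "T_A": res.T_A,
                            "T_B": res.T_B,
                            "fsttc": res.value,
                            "n_A": res.n_A,
                            "n_B": res.n_B,
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=["dyad_id", "phase", "direction", "given_group", "target_group",
                 "P", "T_A", "T_B", "fsttc", "n_A", "n_B"],
    )


def compare_directions(table: pd.DataFrame) -> pd.DataFrame:
    """Paired Wilcoxon tests of DOM->SUB vs SUB->DOM values across dyads.

    One row per (given group, target group, phase); dyads with either
    direction undefined are dropped pairwise, and cells with no complete
    pair are marked untestable.
    """
    rows = []
    for (gname, tname, phase), grp in table.groupby(
        ["given_group", "target_group", "phase"]
    ):
        fwd, rev = [], []
        for dyad, dgrp in grp.groupby("dyad_id"):
            vals = dict(zip(dgrp["direction"], dgrp["fsttc"]))
            v1, v2 = vals.get("DOM->SUB"), vals.get("SUB->DOM")
            if v1 is not None and v2 is not None and not (pd.isna(v1) or pd.isna(v2)):
                fwd.append(float(v1))
                rev.append(float(v2))
        row = {
            "given_group": gname,
            "target_group": tname,
            "phase": phase,
            "n_dyads": len(fwd),
        }
        if fwd:
            res = paired_wilcoxon(np.asarray(fwd), np.asarray(rev))
            row.update(
                median_dom_sub=float(np.median(fwd)),
                median_sub_dom=float(np.median(rev)),
                statistic=res.statistic,
                v=res.v,
                p=res.p,
                testable=True,
            )
        else:
            row.update(
                median_dom_sub=np.nan,
                median_sub_dom=np.nan,
                statistic=np.nan,
                v=np.nan,
                p=np.nan,
                testable=False,
            )
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["given_group", "target_group", "phase", "n_dyads", "median_dom_sub",
                 "median_sub_dom", "statistic", "v", "p", "testable"],
    )
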