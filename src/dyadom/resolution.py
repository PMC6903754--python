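"""Relationship-resolution criteria and phase-wise behavioral comparison.

Each burst yields a 2x2 agonistic matrix (aggressive/subordinate counts by
eventual role).  Two criteria locate the burst at which the relationship
resolves: a stringent phi-coefficient rule (phi > 0 with chi-square p <
alpha for the burst and every later informative burst) and a lenient
difference rule ((a - c) >= (b - d) from the burst onward).  Combining the
two segments each dyad's timeline into pre / middle / post phases.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import events_io, intervals
from .bursts import BurstInterval
from .events_io import AGGRESSIVE, SUBORDINATE, Ethogram, EventLog
from .exceptions import AmbiguousRolesError, PhaseOrderingError, PreconditionError
from .stats_util import paired_wilcoxon

__all__ = [
    "AgonisticMatrix",
    "PhiResult",
    "ResolutionResult",
    "PhaseSegmentation",
    "PHASES",
    "agonistic_matrix",
    "dyad_matrices",
    "phi_coefficient",
    "assign_eventual_dominant",
    "resolve_phi",
    "resolve_difference",
    "segment_phases",
    "phase_proportions",
    "compare_phase_behaviors",
]

PHASES = ("pre", "middle", "post")


@dataclass(frozen=True)
class AgonisticMatrix:
    """Per-burst 2x2 table of agonistic counts by eventual role.

    a/b: aggressive/subordinate onsets by the eventual dominant;
    c/d: aggressive/subordinate onsets by the eventual subordinate.
    """

    burst_index: int
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise PreconditionError("agonistic counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class PhiResult:
    burst_index: int
    phi: float | None
    chi_sq: float | None
    p: float | None
    excluded: bool
    n: int


@dataclass(frozen=True)
class ResolutionResult:
    method: str  # "phi" | "difference"
    resolved: bool
    resolution_burst_index: int | None = None
    resolution_day: int | None = None
    cumulative_interaction_s: float | None = None
    reason: str = ""


@dataclass
class PhaseSegmentation:
    """Disjoint labeled windows per day, partitioning each session exactly.

    ``windows[phase]`` is a list of (day, start, end) spans; a phase may be
    empty (e.g. no post phase when the phi criterion never resolves).
    """

    windows: dict[str, list[tuple[int, float, float]]]
    session_length: float = 1200.0

    def day_windows(self, phase: str, day: int) -> list[tuple[float, float]]:
        return [(s, e) for (d, s, e) in self.windows.get(phase, []) if d == day]

    def duration(self, phase: str) -> float:
        return float(sum(e - s for (_, s, e) in self.windows.get(phase, [])))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"phase": ph, "day": d, "start_s": s, "end_s": e}
            for ph, wins in self.windows.items()
            for (d, s, e) in wins
        ]
        return pd.DataFrame(rows, columns=["phase", "day", "start_s", "end_s"])


def agonistic_matrix(
    log: EventLog,
    burst: BurstInterval,
    roles: dict,
    eth: Ethogram,
) -> AgonisticMatrix:
    """Counts of aggressive/subordinate onsets inside the burst, by role."""
    dom = [s for s, r in roles.items() if r == "dom"]
    sub = [s for s, r in roles.items() if r == "sub"]
    if len(dom) != 1 or len(sub) != 1:
        raise PreconditionError("roles must assign exactly one dom and one sub")
    counts = {}
    for key, subject, state in (
        ("a", dom[0], AGGRESSIVE),
        ("b", dom[0], SUBORDINATE),
        ("c", sub[0], AGGRESSIVE),
        ("d", sub[0], SUBORDINATE),
    ):
        series = events_io.extract_onsets(
            log,
            burst.dyad_id,
            subjects=[subject],
            behaviors=eth.behaviors_in_state(state),
            windows=[(burst.start, burst.end)],
            day=burst.day,
        )
        counts[key] = len(series)
    return AgonisticMatrix(burst_index=burst.index, **counts)


def _burst_agonistic_counts(log: EventLog, burst: BurstInterval, eth: Ethogram) -> dict:
    """Per-subject (aggressive, subordinate) counts inside one burst."""
    out = {}
    dyad = burst.dyad_id
    for subject in log.subjects(dyad):
        row = []
        for state in (AGGRESSIVE, SUBORDINATE):
            series = events_io.extract_onsets(
                log,
                dyad,
                subjects=[subject],
                behaviors=eth.behaviors_in_state(state),
                windows=[(burst.start, burst.end)],
                day=burst.day,
            )
            row.append(len(series))
        out[subject] = tuple(row)
    return out


def assign_eventual_dominant(
    log: EventLog,
    bursts: Sequence[BurstInterval],
    eth: Ethogram,
) -> dict:
    """Roles from the pooled last two bursts (last one if only one exists).

    The subject with strictly more aggressive and strictly fewer
    subordinate onsets is the eventual dominant; a tie on either count, or
    the two conditions disagreeing, raises :class:`AmbiguousRolesError`.
    """
    if not bursts:
        raise PreconditionError("at least one burst is required to assign roles")
    tail = sorted(bursts, key=lambda b: b.index)[-2:]
    pooled: dict = {}
    for b in tail:
        for subject, (agg, sub) in _burst_agonistic_counts(log, b, eth).items():
            prev = pooled.get(subject, (0, 0))
            pooled[subject] = (prev[0] + agg, prev[1] + sub)
    if len(pooled) != 2:
        raise PreconditionError("dyad must have exactly two subjects")
    (sx, (ax, bx)), (sy, (ay, by)) = sorted(pooled.items(), key=lambda kv: str(kv[0]))
    if ax > ay and bx < by:
        return {sx: "dom", sy: "sub"}
    if ay > ax and by < bx:
        return {sy: "dom", sx: "sub"}
    raise AmbiguousRolesError(
        f"cannot assign roles from last bursts: {sx}=(agg {ax}, sub {bx}), "
        f"{sy}=(agg {ay}, sub {by})"
    )


def dyad_matrices(
    log: EventLog,
    bursts: Sequence[BurstInterval],
    roles: dict,
    eth: Ethogram,
) -> list[AgonisticMatrix]:
    return [agonistic_matrix(log, b, roles, eth) for b in sorted(bursts, key=lambda b: b.index)]


def phi_coefficient(m: AgonisticMatrix, min_n: int = 6) -> PhiResult:
    """Phi association of the 2x2 matrix with chi-square significance.

    phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)); X2 = N * phi**2 on 1 df.
    The burst is excluded (phi undefined) when N < min_n or any margin is
    zero.
    """
    if m.n < min_n or 0 in m.margins:
        return PhiResult(m.burst_index, None, None, None, excluded=True, n=m.n)
    r1, r2, c1, c2 = m.margins
    phi = (m.a * m.d - m.b * m.c) / np.sqrt(float(r1) * r2 * c1 * c2)
    chi_sq = m.n * phi**2
    p = float(stats.chi2.sf(chi_sq, df=1))
    return PhiResult(m.burst_index, float(phi), float(chi_sq), p, excluded=False, n=m.n)


def _resolution_scan(passes: Sequence[tuple[int, bool]]) -> int | None:
    """Earliest index k such that burst k and every later listed burst pass."""
    result = None
    for idx, ok in reversed(passes):
        if not ok:
            break
        result = idx
    return result


def _finish(
    method: str,
    idx: int | None,
    bursts_by_index: dict[int, BurstInterval] | None,
    session_length: float,
    reason: str = "",
) -> ResolutionResult:
    if idx is None:
        return ResolutionResult(method=method, resolved=False, reason=reason)
    day = cumulative = None
    if bursts_by_index is not None and idx in bursts_by_index:
        b = bursts_by_index[idx]
        day = b.day
        cumulative = (b.day - 1) * session_length + b.end
    return ResolutionResult(
        method=method,
        resolved=True,
        resolution_burst_index=idx,
        resolution_day=day,
        cumulative_interaction_s=cumulative,
    )


def resolve_phi(
    ms: Sequence[AgonisticMatrix],
    alpha: float = 0.1,
    min_n: int = 6,
    bursts: Sequence[BurstInterval] | None = None,
    session_length: float = 1200.0,
    excluded_veto: bool = False,
) -> ResolutionResult:
    """Stringent criterion: phi > 0 and p < alpha from a burst onward.

    Excluded bursts (N < min_n or undefined phi) are skipped when
    evaluating the run, unless ``excluded_veto`` makes them count as
    failures.  Unresolved when no informative burst starts a passing run.
    """
    by_index = {b.index: b for b in bursts} if bursts else None
    passes: list[tuple[int, bool]] = []
    for m in sorted(ms, key=lambda m: m.burst_index):
        r = phi_coefficient(m, min_n=min_n)
        if r.excluded:
            if excluded_veto:
                passes.append((m.burst_index, False))
            continue
        passes.append((m.burst_index, r.phi > 0 and r.p < alpha))
    if not passes:
        return ResolutionResult("phi", resolved=False, reason="no informative bursts")
    idx = _resolution_scan(passes)
    return _finish("phi", idx, by_index, session_length,
                   reason="" if idx is not None else "final informative burst fails criterion")


def resolve_difference(
    ms: Sequence[AgonisticMatrix],
    bursts: Sequence[BurstInterval] | None = None,
    session_length: float = 1200.0,
) -> ResolutionResult:
    """Lenient criterion: (a - c) >= (b - d) from a burst onward (no exclusions)."""
    by_index = {b.index: b for b in bursts} if bursts else None
    passes = [
        (m.burst_index, (m.a - m.c) >= (m.b - m.d))
        for m in sorted(ms, key=lambda m: m.burst_index)
    ]
    if not passes:
        return ResolutionResult("difference", resolved=False, reason="no bursts")
    idx = _resolution_scan(passes)
    return _finish("difference", idx, by_index, session_length,
                   reason="" if idx is not None else "final burst fails criterion")


def segment_phases(
    log: EventLog,
    bursts: Sequence[BurstInterval],
    res_diff: ResolutionResult,
    res_phi: ResolutionResult,
    days: Sequence[int] | None = None,
) -> PhaseSegmentation:
    """Pre / middle / post windows from the two resolution results.

    Pre is all session time strictly before the start of the difference
    burst; post is all time strictly after the end of the phi burst; middle
    is the remainder (both boundary bursts included).  An unresolved phi
    criterion leaves the post phase empty.
    """
    if not res_diff.resolved:
        raise PreconditionError("difference criterion must be resolved to segment phases")
    by_index = {b.index: b for b in bursts}
    diff_b = by_index[res_diff.resolution_burst_index]
    L = log.session_length
    if days is None:
        days = log.days
    phi_b = None
    if res_phi.resolved:
        phi_b = by_index[res_phi.resolution_burst_index]
        if (phi_b.day, phi_b.end) < (diff_b.day, diff_b.start):
            raise PhaseOrderingError(
                "phi-criterion burst ends before difference-criterion burst starts"
            )

    windows: dict[str, list[tuple[int, float, float]]] = {p: [] for p in PHASES}
    for day in sorted(int(d) for d in days):
        cuts = []  # [(phase, start, end)] for this day
        pre_end = L if day < diff_b.day else (diff_b.start if day == diff_b.day else 0.0)
        if day > diff_b.day:
            pre_end = 0.0
        if phi_b is None:
            post_start = L  # no post phase
        elif day < phi_b.day:
            post_start = L
        elif day == phi_b.day:
            post_start = phi_b.end
        else:
            post_start = 0.0
        pre_end = min(pre_end, L)
        post_start = max(post_start, pre_end)
        if pre_end > 0:
            cuts.append(("pre", 0.0, pre_end))
        if post_start > pre_end:
            cuts.append(("middle", pre_end, post_start))
        if post_start < L:
            cuts.append(("post", post_start, L))
        for phase, s, e in cuts:
            if e > s:
                windows[phase].append((day, s, e))
    return PhaseSegmentation(windows=windows, session_length=L)


def phase_proportions(
    log: EventLog,
    dyad,
    phases: PhaseSegmentation,
    eth: Ethogram,
) -> pd.DataFrame:
    """Proportion of each phase's time spent in each behavior, per subject.

    Bout durations are clipped to the phase windows; rows cover the full
    ethogram so absent behaviors appear as 0.  Phases with zero total
    duration are omitted.
    """
    df = log.for_dyad(dyad)
    rows = []
    for phase in PHASES:
        total = phases.duration(phase)
        if total <= 0:
            continue
        for subject in log.subjects(dyad):
            sdf = df[df["subject_id"] == subject]
            sums = {b: 0.0 for b in eth.behaviors}
            for (day, s, e) in phases.windows.get(phase, []):
                ddf = sdf[sdf["day"] == day]
                for r in ddf.itertuples(index=False):
                    if r.behavior not in sums:
                        continue
                    sums[r.behavior] += intervals.overlap_length(
                        r.onset_s, r.offset_s, [(s, e)]
                    )
            for behavior, dur in sums.items():
                rows.append(
                    {
                        "dyad_id": dyad,
                        "subject_id": subject,
                        "phase": phase,
                        "behavior": behavior,
                        "proportion": dur / total,
                        "phase_duration_s": total,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["dyad_id", "subject_id", "phase", "behavior", "proportion", "phase_duration_s"],
    )


def compare_phase_behaviors(
    table: pd.DataFrame,
    roles_by_dyad: dict,
) -> pd.DataFrame:
    """Paired Wilcoxon tests of dominant vs subordinate proportions.

    ``table`` is the concatenation of per-dyad :func:`phase_proportions`
    frames; ``roles_by_dyad[dyad][subject]`` gives "dom"/"sub".  Dyads
    missing a phase are dropped pairwise.  Returns one row per (phase,
    behavior) with medians per role, the signed-rank statistic and p.
    """
    rows = []
    for (phase, behavior), grp in table.groupby(["phase", "behavior"]):
        dom_vals, sub_vals = [], []
        for dyad, dgrp in grp.groupby("dyad_id"):
            roles = roles_by_dyad.get(dyad)
            if roles is None:
                continue
            vals = {}
            for r in dgrp.itertuples(index=False):
                vals[roles.get(r.subject_id)] = r.proportion
            if "dom" in vals and "sub" in vals:
                dom_vals.append(vals["dom"])
                sub_vals.append(vals["sub"])
        if not dom_vals:
            continue
        res = paired_wilcoxon(np.asarray(dom_vals), np.asarray(sub_vals))
        rows.append(
            {
                "phase": phase,
                "behavior": behavior,
                "n_dyads": len(dom_vals),
                "median_dom": float(np.median(dom_vals)),
                "median_sub": float(np.median(sub_vals)),
                "statistic": res.statistic,
                "p": res.p,
                "note": res.note,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["phase", "behavior", "n_dyads", "median_dom", "median_sub",
                 "statistic", "p", "note"],
    )
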