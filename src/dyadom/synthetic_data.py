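"""Synthetic dyadic event logs with known ground truth.

Each dyad-day session (default 1200 s) contains: planted agonistic bursts
(dense pooled aggressive/subordinate events) over a quiescent background,
a role switch at a planted cumulative burst index k* (symmetric before,
role-faithful after), continuous non-agonistic filler behavior per subject
driven by role/phase-specific no-repeat transition kernels, and optional
forward contingencies: a partner response onset planted within a short lag
after a given behavior with probability theta.

Every generated log satisfies the event-log invariants, and identical
seeds reproduce identical logs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import events_io
from .events_io import EventLog
from .exceptions import ConfigError

__all__ = ["Contingency", "SyntheticConfig", "GroundTruth", "simulate_dyad", "simulate_cohort"]

AGGRESSIVE_BEHAVIORS = ("lunge", "bite", "tail-rattle")
SUBORDINATE_BEHAVIORS = ("flee", "freeze", "subordinate-posture")
FILLER_BEHAVIORS = (
    "sniff-head", "sniff-body", "sniff-anogenital", "sniff-follow",
    "pursue", "allogroom", "side-by-side",
    "digging", "self-grooming",
    "active-moving", "rearing", "jumping", "idle",
)


@dataclass(frozen=True)
class Contingency:
    """Forward dependency: after each ``given`` onset by ``direction``'s
    actor, a ``target`` response by the partner is planted with
    probability ``theta`` at a lag uniform in [min_lag, dt]."""

    direction: str  # "DOM->SUB" or "SUB->DOM"
    given: tuple[str, ...]
    target: str
    theta: float
    min_lag: float = 0.1
    dt: float = 2.0


@dataclass
class SyntheticConfig:
    n_dyads: int = 21
    n_days: int = 5
    session_length: float = 1200.0
    #: non-agonistic filler bouts per second per subject
    baseline_event_rate: float = 0.2
    #: planted agonistic bursts per day (decreasing across days)
    bursts_per_day: tuple[int, ...] = (6, 5, 4, 3, 2)
    burst_duration_range: tuple[float, float] = (15.0, 25.0)
    #: pooled agonistic onsets per second inside / outside bursts
    burst_agonistic_rate: float = 1.2
    quiescent_agonistic_rate: float = 0.002
    #: cumulative burst index at which roles differentiate (1-based)
    resolution_burst: int = 8
    #: P(agonistic act is aggressive) before k*, for either subject
    pre_mix: float = 0.5
    #: pre-k* handicap: the eventual dominant is slightly less aggressive
    pre_contest_bias: float = 0.1
    post_dom_aggressive: float = 0.95
    post_sub_subordinate: float = 0.95
    #: multiplicative boosts on filler-kernel cells, per (role, phase)
    boosted_pairs: dict = field(default_factory=dict)
    # e.g. {("dom", "post"): [("sniff-body", "sniff-head", 5.0)]}
    contingencies: tuple[Contingency, ...] = ()
    bout_duration_median: float = 1.0
    bout_duration_sigma: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if self.n_dyads < 1 or self.n_days < 1:
            raise ConfigError("need at least one dyad and one day")
        if len(self.bursts_per_day) < self.n_days:
            raise ConfigError("bursts_per_day must cover every day")
        if self.burst_agonistic_rate <= 0 or self.baseline_event_rate <= 0:
            raise ConfigError("rates must be positive")
        lo, hi = self.burst_duration_range
        if not (0 < lo <= hi):
            raise ConfigError("bad burst duration range")
        n_slots = max(self.bursts_per_day[: self.n_days])
        if n_slots * hi * 2 > self.session_length:
            raise ConfigError("burst schedule cannot fit in the session")
        for p in (self.pre_mix, self.post_dom_aggressive, self.post_sub_subordinate):
            if not 0 <= p <= 1:
                raise ConfigError("probabilities must lie in [0, 1]")
        for c in self.contingencies:
            if not 0 <= c.theta <= 1:
                raise ConfigError("theta must lie in [0, 1]")


@dataclass
class GroundTruth:
    dyad_id: object
    roles: dict  # subject -> "dom" | "sub"
    resolution_burst: int
    planted_bursts: list[dict]  # {day, start, end, index}
    theta: dict  # str(direction, given, target) -> theta

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _default_filler_kernel(rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Structured no-repeat kernel over the filler behaviors.

    Clusters (sniffing chain, activity pair, rest) transition mostly within
    themselves, echoing the stereotyped structure of rodent interaction.
    """
    k = len(FILLER_BEHAVIORS)
    idx = {b: i for i, b in enumerate(FILLER_BEHAVIORS)}
    M = np.ones((k, k))
    clusters = [
        ("sniff-head", "sniff-body", "sniff-anogenital", "sniff-follow"),
        ("active-moving", "rearing", "jumping"),
        ("digging", "self-grooming", "idle"),
        ("pursue", "allogroom", "side-by-side"),
    ]
    for cluster in clusters:
        for a in cluster:
            for b in cluster:
                if a != b:
                    M[idx[a], idx[b]] = 6.0
    # a couple of strong stereotyped arcs
    M[idx["active-moving"], idx["rearing"]] = 12.0
    M[idx["rearing"], idx["active-moving"]] = 12.0
    M[idx["sniff-body"], idx["sniff-anogenital"]] = 10.0
    np.fill_diagonal(M, 0.0)
    M = M / M.sum(axis=1, keepdims=True)
    return pd.DataFrame(M, index=FILLER_BEHAVIORS, columns=FILLER_BEHAVIORS)


def _boost_kernel(kernel: pd.DataFrame, boosts) -> pd.DataFrame:
    K = kernel.to_numpy().copy()
    idx = {b: i for i, b in enumerate(kernel.index)}
    for a, b, factor in boosts:
        K[idx[a], idx[b]] *= factor
    K = K / K.sum(axis=1, keepdims=True)
    return pd.DataFrame(K, index=kernel.index, columns=kernel.columns)


def _schedule_bursts(
    cfg: SyntheticConfig, day: int, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Non-overlapping burst windows with generous quiescent margins."""
    n = cfg.bursts_per_day[day - 1]
    if n == 0:
        return []
    lo, hi = cfg.burst_duration_range
    durations = rng.uniform(lo, hi, size=n)
    margin = 30.0
    free = cfg.session_length - durations.sum() - margin * (n + 1)
    if free < 0:
        raise ConfigError("burst schedule cannot fit in the session")
    gaps = rng.dirichlet(np.ones(n + 1)) * free
    out = []
    cursor = 0.0
    for i in range(n):
        cursor += gaps[i] + margin
        out.append((cursor, cursor + durations[i]))
        cursor += durations[i]
    return out


def _agonistic_label(rng: np.random.Generator, aggressive: bool) -> str:
    pool = AGGRESSIVE_BEHAVIORS if aggressive else SUBORDINATE_BEHAVIORS
    return pool[rng.integers(len(pool))]


def _bout_duration(cfg: SyntheticConfig, rng: np.random.Generator) -> float:
    return float(
        np.exp(np.log(cfg.bout_duration_median) + cfg.bout_duration_sigma * rng.standard_normal())
    )


def simulate_dyad(
    cfg: SyntheticConfig,
    dyad_id,
    rng: np.random.Generator | int | None = None,
) -> tuple[EventLog, GroundTruth]:
    """One dyad's event log over ``cfg.n_days`` sessions, plus ground truth."""
    cfg.validate()
    rng = np.random.default_rng(rng if rng is not None else cfg.seed)
    subjects = (f"{dyad_id}-1", f"{dyad_id}-2")
    roles = {subjects[0]: "dom", subjects[1]: "sub"}
    dom, sub = subjects
    rows: list[dict] = []
    planted: list[dict] = []
    burst_counter = 0
    kernels = {
        (role, phase): _boost_kernel(
            _default_filler_kernel(), cfg.boosted_pairs.get((role, phase), [])
        )
        for role in ("dom", "sub")
        for phase in ("pre", "post")
    }

    for day in range(1, cfg.n_days + 1):
        bursts = _schedule_bursts(cfg, day, rng)
        burst_windows = []
        for (s, e) in bursts:
            burst_counter += 1
            planted.append({"day": day, "start": s, "end": e, "index": burst_counter})
            burst_windows.append((s, e, burst_counter))

        # --- agonistic events: dense inside bursts, sparse outside
        agonistic: list[tuple[float, str, str]] = []  # (onset, subject, behavior)
        for (s, e, index) in burst_windows:
            n_ev = rng.poisson(cfg.burst_agonistic_rate * (e - s))
            times = np.sort(rng.uniform(s, e, size=n_ev))
            post = index >= cfg.resolution_burst
            for t in times:
                actor = subjects[rng.integers(2)]
                if post:
                    if actor == dom:
                        aggressive = rng.random() < cfg.post_dom_aggressive
                    else:
                        aggressive = rng.random() >= cfg.post_sub_subordinate
                else:
                    p_agg = cfg.pre_mix + (
                        -cfg.pre_contest_bias if actor == dom else cfg.pre_contest_bias
                    )
                    aggressive = rng.random() < p_agg
                agonistic.append((float(t), actor, _agonistic_label(rng, aggressive)))
        outside = rng.poisson(cfg.quiescent_agonistic_rate * cfg.session_length)
        for t in rng.uniform(0, cfg.session_length, size=outside):
            actor = subjects[rng.integers(2)]
            agonistic.append((float(t), actor, _agonistic_label(rng, rng.random() < 0.5)))
        agonistic.sort()

        # --- planted forward contingencies
        responses: list[tuple[float, str, str]] = []
        for c in cfg.contingencies:
            actor, responder = (dom, sub) if c.direction == "DOM->SUB" else (sub, dom)
            given = {events_io.normalize_label(g) for g in c.given}
            for (t, who, behavior) in agonistic:
                if who == actor and behavior in given and rng.random() < c.theta:
                    lag = rng.uniform(c.min_lag, c.dt)
                    if t + lag < cfg.session_length:
                        responses.append((t + lag, responder, c.target))
        agonistic.extend(responses)
        agonistic.sort()

        for (t, who, behavior) in agonistic:
            dur = min(_bout_duration(cfg, rng), 2.0)
            rows.append(
                {
                    "dyad_id": dyad_id,
                    "day": day,
                    "subject_id": who,
                    "behavior": behavior,
                    "onset_s": round(t, 4),
                    "offset_s": round(min(t + dur, cfg.session_length), 4),
                }
            )

        # --- filler behavior: per-subject renewal chain
        for subject in subjects:
            role = roles[subject]
            phase = "pre" if burst_counter < cfg.resolution_burst else "post"
            kernel = kernels[(role, phase)]
            K = kernel.to_numpy()
            labels = list(kernel.index)
            state = int(rng.integers(len(labels)))
            t = float(rng.exponential(1.0 / cfg.baseline_event_rate))
            while t < cfg.session_length:
                dur = _bout_duration(cfg, rng)
                rows.append(
                    {
                        "dyad_id": dyad_id,
                        "day": day,
                        "subject_id": subject,
                        "behavior": labels[state],
                        "onset_s": round(t, 4),
                        "offset_s": round(min(t + dur, cfg.session_length), 4),
                    }
                )
                state = int(rng.choice(len(labels), p=K[state]))
                t += dur * 0.5 + float(rng.exponential(1.0 / cfg.baseline_event_rate))

    log = EventLog(pd.DataFrame(rows), session_length=cfg.session_length)
    truth = GroundTruth(
        dyad_id=dyad_id,
        roles=roles,
        resolution_burst=cfg.resolution_burst,
        planted_bursts=planted,
        theta={
            f"{c.direction}|{'+'.join(c.given)}|{c.target}": c.theta
            for c in cfg.contingencies
        },
    )
    return log, truth


def simulate_cohort(
    cfg: SyntheticConfig,
    seed: int | None = None,
) -> tuple[EventLog, list[GroundTruth]]:
    """Independent dyads A, B, C, ... with per-dyad derived seeds.

    Each dyad's stream is derived from (seed, dyad position), so a dyad's
    log does not depend on how many other dyads are simulated.
    """
    cfg.validate()
    seed = cfg.seed if seed is None else seed
    logs, truths = [], []
    for i in range(cfg.n_dyads):
        dyad_id = _dyad_name(i)
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        log, truth = simulate_dyad(cfg, dyad_id, rng)
        logs.append(log.df)
        truths.append(truth)
    df = pd.concat(logs, ignore_index=True)
    return EventLog(df, session_length=cfg.session_length), truths


def _dyad_name(i: int) -> str:
    name = ""
    i0 = i
    while True:
        name = chr(ord("A") + i0 % 26) + name
        i0 = i0 // 26 - 1
        if i0 < 0:
            break
    return name


def write_ground_truth(truths: list[GroundTruth], path) -> None:
    with open(path, "w") as fh:
        json.dump([t.to_dict() for t in truths], fh, indent=2, default=str)
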