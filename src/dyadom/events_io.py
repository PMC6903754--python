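"""Data model and I/O for dyadic behavioral event logs.

An event log is a tidy long table with one row per coded behavior bout:
``dyad_id, day, subject_id, behavior, onset_s, offset_s``.  Onsets and
offsets are seconds within a session (default 20 min = 1200 s); sessions on
different days are separate clocks and are never concatenated.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import intervals
from .exceptions import FormatError, RowParseError, ValidationError

__all__ = [
    "AGGRESSIVE",
    "SUBORDINATE",
    "INVESTIGATIVE",
    "SOCIAL",
    "REPETITIVE",
    "ACTIVITY",
    "INACTIVITY",
    "STATES",
    "Ethogram",
    "EventLog",
    "OnsetSeries",
    "BehaviorSequence",
    "ValidationReport",
    "normalize_label",
    "read_event_log",
    "write_event_log",
    "validate_events",
    "extract_onsets",
    "collapse_to_sequence",
]

AGGRESSIVE = "Aggressive"
SUBORDINATE = "Subordinate"
INVESTIGATIVE = "Investigative"
SOCIAL = "Social"
REPETITIVE = "Repetitive"
ACTIVITY = "Activity"
INACTIVITY = "Inactivity"
STATES = (AGGRESSIVE, SUBORDINATE, INVESTIGATIVE, SOCIAL, REPETITIVE, ACTIVITY, INACTIVITY)

COLUMNS = ("dyad_id", "day", "subject_id", "behavior", "onset_s", "offset_s")

#: Default 19-behavior ethogram with state assignments.
_DEFAULT_STATE_OF = {
    "lunge": AGGRESSIVE,
    "bite": AGGRESSIVE,
    "tail-rattle": AGGRESSIVE,
    "flee": SUBORDINATE,
    "freeze": SUBORDINATE,
    "subordinate-posture": SUBORDINATE,
    "sniff-head": INVESTIGATIVE,
    "sniff-body": INVESTIGATIVE,
    "sniff-anogenital": INVESTIGATIVE,
    "sniff-follow": INVESTIGATIVE,
    "pursue": SOCIAL,
    "allogroom": SOCIAL,
    "side-by-side": SOCIAL,
    "digging": REPETITIVE,
    "self-grooming": REPETITIVE,
    "active-moving": ACTIVITY,
    "rearing": ACTIVITY,
    "jumping": ACTIVITY,
    "idle": INACTIVITY,
}


def normalize_label(label: str) -> str:
    """Case-fold a behavior label; spaces and underscores become hyphens."""
    return str(label).strip().lower().replace("_", "-").replace(" ", "-")


@dataclass(frozen=True)
class Ethogram:
    """Registry mapping behavior labels to behavioral states."""

    state_of: dict[str, str]

    def __post_init__(self):
        norm = {normalize_label(b): s for b, s in self.state_of.items()}
        object.__setattr__(self, "state_of", norm)
        for b, s in norm.items():
            if s not in STATES:
                raise ValidationError(f"behavior {b!r} mapped to unknown state {s!r}")

    @classmethod
    def default(cls) -> "Ethogram":
        return cls(dict(_DEFAULT_STATE_OF))

    @property
    def behaviors(self) -> frozenset[str]:
        return frozenset(self.state_of)

    def behaviors_in_state(self, *states: str) -> frozenset[str]:
        return frozenset(b for b, s in self.state_of.items() if s in states)

    def agonistic_behaviors(self) -> frozenset[str]:
        """Aggressive plus subordinate behaviors — the substrate of contests."""
        return self.behaviors_in_state(AGGRESSIVE, SUBORDINATE)

    def __contains__(self, behavior: str) -> bool:
        return normalize_label(behavior) in self.state_of


@dataclass
class EventLog:
    """Validated, sorted collection of behavior bouts.

    Thin wrapper over a :class:`pandas.DataFrame` with the canonical column
    set; all analysis modules consume this type.
    """

    df: pd.DataFrame
    session_length: float = 1200.0

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"event table missing column(s): {', '.join(missing)}")
        df = self.df.loc[:, list(COLUMNS)].copy()
        df["behavior"] = df["behavior"].map(normalize_label)
        df["day"] = df["day"].astype(int)
        df["onset_s"] = df["onset_s"].astype(float)
        df["offset_s"] = df["offset_s"].astype(float)
        bad = df.index[df["offset_s"] < df["onset_s"]]
        if len(bad):
            raise ValidationError(
                f"offset before onset in row(s): {', '.join(map(str, bad.tolist()[:10]))}"
            )
        df = df.sort_values(["dyad_id", "day", "onset_s"], kind="stable").reset_index(drop=True)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def dyads(self) -> list:
        return sorted(self.df["dyad_id"].unique().tolist())

    @property
    def days(self) -> list[int]:
        return sorted(self.df["day"].unique().tolist())

    def subjects(self, dyad) -> list:
        return sorted(self.df.loc[self.df["dyad_id"] == dyad, "subject_id"].unique().tolist())

    def for_dyad(self, dyad) -> pd.DataFrame:
        return self.df[self.df["dyad_id"] == dyad]


@dataclass(frozen=True)
class OnsetSeries:
    """Onset times within a set of disjoint observation windows.

    Times are sorted (ties kept, stable order); callers needing strictly
    increasing times use :meth:`strictly_increasing`.
    """

    times: np.ndarray
    windows: tuple[tuple[float, float], ...]
    _TIE_JITTER = 1e-6

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        windows = tuple(intervals.validate_windows(self.windows))
        if np.any(np.diff(times) < 0):
            raise ValidationError("onset times must be sorted")
        if times.size and not intervals.clip_point_mask(times, windows).all():
            raise ValidationError("onset time outside all observation windows")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "windows", windows)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def total_time(self) -> float:
        return intervals.total_length(self.windows)

    def strictly_increasing(self) -> "OnsetSeries":
        """Resolve exact ties by adding 1e-6 s to each later duplicate."""
        t = self.times.copy()
        for i in range(1, t.size):
            if t[i] <= t[i - 1]:
                t[i] = t[i - 1] + self._TIE_JITTER
        return OnsetSeries(t, self.windows)


@dataclass(frozen=True)
class BehaviorSequence:
    """Ordered behavior labels with consecutive duplicates collapsed."""

    subject_id: object
    label: str  # phase or day tag
    labels: tuple[str, ...]

    def __post_init__(self):
        labels = tuple(self.labels)
        for x, y in zip(labels, labels[1:]):
            if x == y:
                raise ValidationError("behavior sequence contains adjacent duplicates")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class ValidationReport:
    unknown_behaviors: list[str] = field(default_factory=list)
    out_of_session: list[int] = field(default_factory=list)  # row indices
    malformed_dyads: list = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not (self.unknown_behaviors or self.out_of_session or self.malformed_dyads)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["clean"] = self.clean
        return json.dumps(d, indent=2, default=str)


# ---------------------------------------------------------------------------
# Readers / writers

#: Header aliases accepted out of the box (e.g. Observer XT style exports).
_DEFAULT_ALIASES = {
    "dyad_id": ("dyad_id", "dyad", "pair_id", "pair"),
    "day": ("day", "session", "trial_day"),
    "subject_id": ("subject_id", "subject", "animal_id", "animal", "mouse_id"),
    "behavior": ("behavior", "behaviour", "behavior_label", "action"),
    "onset_s": ("onset_s", "onset", "start_s", "start", "start_time"),
    "offset_s": ("offset_s", "offset", "stop_s", "stop", "end_s", "end", "stop_time"),
}


def _resolve_columns(header: Sequence[str], dialect: dict | None) -> dict[str, str]:
    dialect = dialect or {}
    explicit = dialect.get("columns", {})
    lower = {h.lower(): h for h in header}
    mapping = {}
    for canon in COLUMNS:
        if canon in explicit:
            src = explicit[canon]
            if src not in header:
                raise FormatError(f"dialect maps {canon!r} to missing column {src!r}")
            mapping[canon] = src
            continue
        for alias in _DEFAULT_ALIASES[canon]:
            if alias in lower:
                mapping[canon] = lower[alias]
                break
        else:
            raise FormatError(f"no column found for {canon!r} (header: {list(header)})")
    return mapping


def read_event_log(
    path: str | Path,
    dialect: dict | None = None,
    session_length: float = 1200.0,
) -> EventLog:
    """Read a tidy CSV/TSV event log.

    ``dialect`` may carry ``{"columns": {canonical: actual}, "sep": ","}``.
    Raises :class:`FormatError` for missing columns, :class:`RowParseError`
    (with line number) for unparseable times, and :class:`ValidationError`
    when an offset precedes its onset.
    """
    path = Path(path)
    sep = (dialect or {}).get("sep")
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    raw = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    mapping = _resolve_columns(raw.columns, dialect)
    df = raw.rename(columns={v: k for k, v in mapping.items()})[list(COLUMNS)]
    for col in ("day", "onset_s", "offset_s"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.index[parsed.isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise RowParseError(
                f"cannot parse {col!r} value {df.loc[bad[0], col]!r} at line {bad[0] + 2}",
                line=int(bad[0]) + 2,
            )
        df[col] = parsed
    return EventLog(df, session_length=session_length)


def write_event_log(log: EventLog, path: str | Path) -> None:
    """Write the canonical tidy CSV (or TSV by extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    log.df.to_csv(path, sep=sep, index=False)


def validate_events(log: EventLog, eth: Ethogram) -> ValidationReport:
    """Report unknown labels, out-of-session times, and malformed dyads."""
    report = ValidationReport()
    known = eth.behaviors
    unknown = sorted(set(log.df["behavior"]) - known)
    report.unknown_behaviors = unknown
    in_session = (
        (log.df["onset_s"] >= 0)
        & (log.df["onset_s"] <= log.session_length)
        & (log.df["offset_s"] <= log.session_length)
    )
    report.out_of_session = log.df.index[~in_session].tolist()
    for dyad, grp in log.df.groupby("dyad_id"):
        if grp["subject_id"].nunique() != 2:
            report.malformed_dyads.append(dyad)
    return report


# ---------------------------------------------------------------------------
# Derivations consumed downstream


def extract_onsets(
    log: EventLog,
    dyad,
    subjects: Iterable | None = None,
    behaviors: Iterable[str] | None = None,
    windows: Sequence[tuple[float, float]] | None = None,
    day: int | None = None,
) -> OnsetSeries:
    """Pooled onset series of selected behaviors by selected subjects.

    ``windows`` defaults to the full session.  Selection arguments of
    ``None`` mean "all"; empty iterables select nothing.  Times are clipped
    to the windows; exact ties are kept in stable input order.
    """
    if windows is None:
        windows = [(0.0, log.session_length)]
    windows = intervals.validate_windows(windows)
    df = log.for_dyad(dyad)
    if day is not None:
        df = df[df["day"] == day]
    if subjects is not None:
        df = df[df["subject_id"].isin(set(subjects))]
    if behaviors is not None:
        wanted = {normalize_label(b) for b in behaviors}
        df = df[df["behavior"].isin(wanted)]
    times = df["onset_s"].to_numpy(dtype=float)
    times = times[intervals.clip_point_mask(times, windows)]
    times = np.sort(times, kind="stable")
    return OnsetSeries(times, tuple(windows))


def collapse_to_sequence(
    log: EventLog,
    dyad,
    subject,
    windows: dict[int, Sequence[tuple[float, float]]] | None = None,
    label: str = "",
) -> BehaviorSequence:
    """No-repeat behavior sequence for one subject across days.

    ``windows`` maps day → list of (start, end) windows; ``None`` selects
    every recorded day in full.  Behaviors are ordered by (day, onset) and
    consecutive duplicates collapsed.
    """
    df = log.for_dyad(dyad)
    df = df[df["subject_id"] == subject]
    out: list[str] = []
    for d in sorted(df["day"].unique()):
        sub = df[df["day"] == d]
        if windows is not None:
            if d not in windows:
                continue
            wins = intervals.validate_windows(windows[d])
            mask = intervals.clip_point_mask(sub["onset_s"].to_numpy(dtype=float), wins)
            sub = sub[mask]
        for b in sub.sort_values("onset_s", kind="stable")["behavior"]:
            if not out or out[-1] != b:
                out.append(b)
    return BehaviorSequence(subject_id=subject, label=label, labels=tuple(out))
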