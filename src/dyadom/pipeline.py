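"""End-to-end orchestration: events -> bursts -> resolution -> phases ->
phase statistics, Markov transition analysis, and FSTTC tables.

Each stage writes a standalone CSV so any step can be re-run from the
previous stage's files; a JSON manifest records the configuration, seed,
and per-stage counts.  Per-dyad failures (ambiguous roles, unresolved
criteria, short sequences) are recorded as flags, not crashes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import bursts as bursts_mod
from . import events_io, fsttc, markov, resolution
from .bursts import KleinbergParams
from .events_io import Ethogram, EventLog
from .exceptions import AmbiguousRolesError, SequenceTooShortError
from .stats_util import paired_wilcoxon

logger = logging.getLogger("dyadom")

__all__ = ["PipelineConfig", "run_pipeline", "summarize_resolution", "analyze_dyads"]


@dataclass
class PipelineConfig:
    input: str
    out_dir: str
    session_length: float = 1200.0
    kleinberg: KleinbergParams = field(default_factory=KleinbergParams)
    alpha: float = 0.1
    min_events: int = 6
    n_perm: int = 1000
    p_thresh: float = 0.01
    prob_thresh: float = 0.075
    min_transitions: int = 10
    dt: float = 2.0
    binomial_p0: float = 0.5
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class DyadResult:
    dyad_id: object
    bursts: list
    roles: dict | None
    matrices: list
    res_phi: resolution.ResolutionResult | None
    res_diff: resolution.ResolutionResult | None
    phases: resolution.PhaseSegmentation | None
    flags: list[str] = field(default_factory=list)


def analyze_dyads(
    log: EventLog,
    eth: Ethogram,
    params: KleinbergParams,
    alpha: float = 0.1,
    min_events: int = 6,
) -> dict:
    """Bursts, roles, both resolution criteria and phases for every dyad."""
    out: dict = {}
    for dyad in log.dyads:
        flags: list[str] = []
        dyad_bursts = bursts_mod.detect_dyad_bursts(log, dyad, eth, params)
        roles = matrices = None
        res_phi = res_diff = phases = None
        if not dyad_bursts:
            flags.append("no-bursts")
        else:
            try:
                roles = resolution.assign_eventual_dominant(log, dyad_bursts, eth)
            except AmbiguousRolesError as err:
                flags.append(f"ambiguous-roles: {err}")
        if roles is not None:
            matrices = resolution.dyad_matrices(log, dyad_bursts, roles, eth)
            res_phi = resolution.resolve_phi(
                matrices, alpha=alpha, min_n=min_events,
                bursts=dyad_bursts, session_length=log.session_length,
            )
            res_diff = resolution.resolve_difference(
                matrices, bursts=dyad_bursts, session_length=log.session_length
            )
            if not res_phi.resolved:
                flags.append("phi-unresolved")
            if res_diff.resolved:
                phases = resolution.segment_phases(
                    log, dyad_bursts, res_diff, res_phi, days=log.days
                )
            else:
                flags.append("difference-unresolved")
        out[dyad] = DyadResult(
            dyad_id=dyad,
            bursts=dyad_bursts,
            roles=roles,
            matrices=matrices or [],
            res_phi=res_phi,
            res_diff=res_diff,
            phases=phases,
            flags=flags,
        )
    return out


def summarize_resolution(
    results: dict,
    binomial_p0: float = 0.5,
) -> dict:
    """Cohort-level resolution summary.

    Counts resolved dyads per method and day, tests the resolution success
    rate with an exact binomial test, and tests first-burst phi against 0
    with a Wilcoxon signed-rank test.
    """
    summary: dict = {"n_dyads": len(results)}
    for method in ("phi", "difference"):
        resolved_days, cumulative = [], []
        n_resolved = 0
        for r in results.values():
            res = r.res_phi if method == "phi" else r.res_diff
            if res is not None and res.resolved:
                n_resolved += 1
                resolved_days.append(res.resolution_day)
                cumulative.append(res.cumulative_interaction_s)
        entry = {
            "n_resolved": n_resolved,
            "by_day": {
                int(d): int(sum(1 for x in resolved_days if x == d))
                for d in sorted(set(resolved_days))
            },
            "median_cumulative_s": float(np.median(cumulative)) if cumulative else None,
        }
        n = len(results)
        if n:
            entry["binomial_p"] = float(
                stats.binomtest(n_resolved, n, binomial_p0).pvalue
            )
        summary[method] = entry
    first_phis = []
    for r in results.values():
        if r.matrices:
            pr = resolution.phi_coefficient(r.matrices[0])
            if not pr.excluded:
                first_phis.append(pr.phi)
    if first_phis:
        res = paired_wilcoxon(np.asarray(first_phis), np.zeros(len(first_phis)))
        summary["first_burst_phi"] = {
            "n": len(first_phis),
            "median": float(np.median(first_phis)),
            "p": res.p,
        }
    return summary


def _resolution_frame(results: dict) -> pd.DataFrame:
    rows = []
    for dyad, r in results.items():
        for res in (r.res_phi, r.res_diff):
            if res is None:
                continue
            rows.append(
                {
                    "dyad_id": dyad,
                    "method": res.method,
                    "resolved": res.resolved,
                    "resolution_burst_index": res.resolution_burst_index,
                    "resolution_day": res.resolution_day,
                    "cumulative_interaction_s": res.cumulative_interaction_s,
                    "flags": ";".join(r.flags),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["dyad_id", "method", "resolved", "resolution_burst_index",
                 "resolution_day", "cumulative_interaction_s", "flags"],
    )


def _phases_frame(results: dict) -> pd.DataFrame:
    frames = []
    for dyad, r in results.items():
        if r.phases is None:
            continue
        f = r.phases.to_frame()
        f.insert(0, "dyad_id", dyad)
        frames.append(f)
    if not frames:
        return pd.DataFrame(columns=["dyad_id", "phase", "day", "start_s", "end_s"])
    return pd.concat(frames, ignore_index=True)


def _roles_frame(results: dict) -> pd.DataFrame:
    rows = [
        {"dyad_id": dyad, "subject_id": s, "role": role}
        for dyad, r in results.items()
        if r.roles
        for s, role in r.roles.items()
    ]
    return pd.DataFrame(rows, columns=["dyad_id", "subject_id", "role"])


def run_markov_stage(
    log: EventLog,
    results: dict,
    eth: Ethogram,
    n_perm: int,
    seed: int,
    p_thresh: float,
    prob_thresh: float,
    min_transitions: int,
) -> dict:
    """Per-individual permutation tests and group summaries (pre/post x role)."""
    per_individual: dict = {}
    groups: dict[str, list] = {}
    freqs: dict[str, list] = {}
    excluded: list[dict] = []
    root = np.random.SeedSequence([seed, 1])
    streams = iter(root.spawn(4 * len(results) + 8))
    for dyad, r in sorted(results.items(), key=lambda kv: str(kv[0])):
        if r.phases is None or r.roles is None:
            continue
        for subject, role in sorted(r.roles.items()):
            for phase in ("pre", "post"):
                windows = {
                    d: [(s, e)]
                    for (d, s, e) in r.phases.windows.get(phase, [])
                }
                # merge multi-window days
                windows = {}
                for (d, s, e) in r.phases.windows.get(phase, []):
                    windows.setdefault(d, []).append((s, e))
                seq = events_io.collapse_to_sequence(
                    log, dyad, subject, windows=windows, label=phase
                )
                rng = np.random.default_rng(next(streams))
                key = (dyad, subject, role, phase)
                try:
                    res = markov.permutation_transition_test(
                        seq, n_perm=n_perm, rng=rng, min_transitions=min_transitions
                    )
                except SequenceTooShortError as err:
                    excluded.append(
                        {"dyad_id": dyad, "subject_id": subject, "phase": phase,
                         "reason": str(err)}
                    )
                    continue
                per_individual[key] = res
                gname = f"{role}-{phase}"
                groups.setdefault(gname, []).append(res)
                counts: dict[str, float] = {}
                for b in seq.labels:
                    counts[b] = counts.get(b, 0.0) + 1.0
                total = sum(counts.values()) or 1.0
                freqs.setdefault(gname, []).append({b: c / total for b, c in counts.items()})
    summaries = {
        g: markov.group_transition_summary(
            rs, group=g, p_thresh=p_thresh, prob_thresh=prob_thresh,
            frequencies=freqs.get(g),
        )
        for g, rs in groups.items()
    }
    return {"per_individual": per_individual, "summaries": summaries, "excluded": excluded}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write the results bundle to ``cfg.out_dir``."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    eth = Ethogram.default()
    log = events_io.read_event_log(cfg.input, session_length=cfg.session_length)
    report = events_io.validate_events(log, eth)
    if not report.clean:
        logger.warning("input validation issues: %s", report.to_json())

    logger.info("detecting bursts for %d dyads", len(log.dyads))
    results = analyze_dyads(
        log, eth, cfg.kleinberg, alpha=cfg.alpha, min_events=cfg.min_events
    )

    all_bursts = [b for r in results.values() for b in r.bursts]
    bursts_mod.bursts_to_frame(all_bursts).to_csv(out / "bursts.csv", index=False)
    summary = bursts_mod.burst_summary(log, all_bursts, eth)
    summary.by_day.to_csv(out / "burst_summary.csv", index=False)
    _resolution_frame(results).to_csv(out / "resolution.csv", index=False)
    _phases_frame(results).to_csv(out / "phases.csv", index=False)
    _roles_frame(results).to_csv(out / "roles.csv", index=False)

    # phase behavior statistics
    tables = [
        resolution.phase_proportions(log, dyad, r.phases, eth)
        for dyad, r in results.items()
        if r.phases is not None
    ]
    roles_by_dyad = {d: r.roles for d, r in results.items() if r.roles}
    if tables:
        table = pd.concat(tables, ignore_index=True)
        table.to_csv(out / "phase_proportions.csv", index=False)
        resolution.compare_phase_behaviors(table, roles_by_dyad).to_csv(
            out / "phase_stats.csv", index=False
        )

    # Markov stage
    logger.info("running Markov permutation tests (n_perm=%d)", cfg.n_perm)
    mk = run_markov_stage(
        log, results, eth,
        n_perm=cfg.n_perm, seed=cfg.seed,
        p_thresh=cfg.p_thresh, prob_thresh=cfg.prob_thresh,
        min_transitions=cfg.min_transitions,
    )
    mdir = out / "markov"
    mdir.mkdir(exist_ok=True)
    indiv_frames = []
    for (dyad, subject, role, phase), res in mk["per_individual"].items():
        f = res.to_frame()
        f.insert(0, "phase", phase)
        f.insert(0, "role", role)
        f.insert(0, "subject_id", subject)
        f.insert(0, "dyad_id", dyad)
        indiv_frames.append(f)
    if indiv_frames:
        pd.concat(indiv_frames, ignore_index=True).to_csv(
            mdir / "transitions_individual.csv", index=False
        )
    group_frames = []
    for g, s in mk["summaries"].items():
        f = s.table.copy()
        f.insert(0, "group", g)
        group_frames.append(f)
        markov.export_kinetogram(s, mdir / f"kinetogram_{g}")
    if group_frames:
        pd.concat(group_frames, ignore_index=True).to_csv(
            mdir / "transitions_group.csv", index=False
        )
    pd.DataFrame(mk["excluded"]).to_csv(mdir / "excluded_sequences.csv", index=False)

    # FSTTC stage
    logger.info("computing FSTTC tables (dt=%.1f)", cfg.dt)
    fsttc_frames = []
    for dyad, r in results.items():
        if r.phases is None or r.roles is None:
            continue
        fsttc_frames.append(
            fsttc.dyad_fsttc_table(log, dyad, r.phases, r.roles, eth, dt=cfg.dt)
        )
    if fsttc_frames:
        ftable = pd.concat(fsttc_frames, ignore_index=True)
        ftable.to_csv(out / "fsttc.csv", index=False)
        fsttc.compare_directions(ftable).to_csv(out / "fsttc_tests.csv", index=False)

    res_summary = summarize_resolution(results, binomial_p0=cfg.binomial_p0)
    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "n_events": len(log),
        "n_dyads": len(log.dyads),
        "n_bursts": len(all_bursts),
        "flags": {str(d): r.flags for d, r in results.items() if r.flags},
        "resolution_summary": res_summary,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return {"results": results, "manifest": manifest, "markov": mk}
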