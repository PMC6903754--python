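"""Within-individual first-order transition analysis.

A behavior sequence with no adjacent repeats yields a k x k transition
count matrix with structural zeros on the diagonal.  Expected counts under
quasi-independence come from iterative proportional fitting; departure is
tested with the likelihood-ratio G2 statistic on adjusted degrees of
freedom.  Per-transition significance uses a no-repeat permutation null.
Group-level summaries take medians across individuals and feed the
kinetogram exports.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .events_io import BehaviorSequence
from .exceptions import (
    ConvergenceError,
    InfeasibleSequenceError,
    PreconditionError,
    SequenceTooShortError,
)

__all__ = [
    "TransitionMatrix",
    "GTestResult",
    "TransitionTestResult",
    "GroupTransitionSummary",
    "transition_counts",
    "quasi_independence_expected",
    "g2_test",
    "permute_no_repeats",
    "permutation_transition_test",
    "group_transition_summary",
    "export_kinetogram",
    "kinetogram_graph",
]


@dataclass
class TransitionMatrix:
    labels: tuple[str, ...]
    observed: np.ndarray  # k x k ints, zero diagonal
    expected: np.ndarray | None = None

    def __post_init__(self):
        O = np.asarray(self.observed)
        if O.ndim != 2 or O.shape[0] != O.shape[1] or O.shape[0] != len(self.labels):
            raise PreconditionError("observed matrix must be k x k matching labels")
        if np.any(np.diag(O) != 0):
            raise PreconditionError("diagonal must be structurally zero")
        if np.any(O < 0):
            raise PreconditionError("counts must be non-negative")
        self.observed = O.astype(np.int64)

    @property
    def k(self) -> int:
        return len(self.labels)

    @property
    def total_transitions(self) -> int:
        return int(self.observed.sum())


@dataclass(frozen=True)
class GTestResult:
    g2: float
    df: int
    p: float | None
    defined: bool
    note: str = ""


@dataclass
class TransitionTestResult:
    """Per-transition observed counts, probabilities, and permutation p."""

    labels: tuple[str, ...]
    observed: np.ndarray
    probability: np.ndarray  # observed / total, k x k
    p: np.ndarray  # permutation p-values, k x k (diagonal NaN)
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.labels):
            for j, b in enumerate(self.labels):
                if i == j:
                    continue
                rows.append(
                    {
                        "from": a,
                        "to": b,
                        "observed": int(self.observed[i, j]),
                        "probability": float(self.probability[i, j]),
                        "p": float(self.p[i, j]),
                    }
                )
        return pd.DataFrame(rows, columns=["from", "to", "observed", "probability", "p"])


@dataclass
class GroupTransitionSummary:
    group: str
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: from, to, median_p, median_probability, significant, meaningful
    frequencies: dict[str, float] = field(default_factory=dict)  # relative behavior frequency


def sequence_codes(seq: BehaviorSequence) -> tuple[tuple[str, ...], np.ndarray]:
    labels = tuple(sorted(set(seq.labels)))
    index = {b: i for i, b in enumerate(labels)}
    return labels, np.fromiter((index[b] for b in seq.labels), dtype=np.int64, count=len(seq))


def _bigram_counts(codes: np.ndarray, k: int) -> np.ndarray:
    O = np.zeros((k, k), dtype=np.int64)
    if codes.size >= 2:
        np.add.at(O, (codes[:-1], codes[1:]), 1)
    return O


def transition_counts(seq: BehaviorSequence, min_transitions: int = 2) -> TransitionMatrix:
    """Observed first-order transition counts over the labels present."""
    if len(seq) < 2 or len(seq) - 1 < min_transitions:
        raise SequenceTooShortError(
            f"sequence of {len(seq)} behaviors has fewer than {min_transitions} transitions"
        )
    labels, codes = sequence_codes(seq)
    return TransitionMatrix(labels=labels, observed=_bigram_counts(codes, len(labels)))


def quasi_independence_expected(
    m: TransitionMatrix,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> TransitionMatrix:
    """Expected counts under quasi-independence via iterative scaling.

    Alternates row and column scaling of an off-diagonal-ones seed until
    every margin matches the observed margins within ``tol``.  Rows or
    columns with zero observed total are dropped from the fit (their
    expected cells stay 0).
    """
    O = m.observed.astype(float)
    k = m.k
    row_t = O.sum(axis=1)
    col_t = O.sum(axis=0)
    if (row_t > 0).sum() < 2 or (col_t > 0).sum() < 2:
        raise PreconditionError("need at least 2 nonzero rows and columns to fit")
    E = np.ones((k, k), dtype=float)
    np.fill_diagonal(E, 0.0)
    E[row_t == 0, :] = 0.0
    E[:, col_t == 0] = 0.0
    disc = np.inf
    for _ in range(max_iter):
        rs = E.sum(axis=1)
        scale = np.divide(row_t, rs, out=np.zeros_like(rs), where=rs > 0)
        E *= scale[:, None]
        cs = E.sum(axis=0)
        scale = np.divide(col_t, cs, out=np.zeros_like(cs), where=cs > 0)
        E *= scale[None, :]
        disc = max(
            np.abs(E.sum(axis=1) - row_t).max(),
            np.abs(E.sum(axis=0) - col_t).max(),
        )
        if disc < tol:
            break
    else:
        raise ConvergenceError(
            f"iterative scaling did not converge (discrepancy {disc:.3e})", discrepancy=disc
        )
    return TransitionMatrix(labels=m.labels, observed=m.observed, expected=E)


def g2_test(m: TransitionMatrix) -> GTestResult:
    """Likelihood-ratio test of observed counts against quasi-independence.

    G2 = 2 * sum O * ln(O / E) over cells with O > 0.  Degrees of freedom
    are (k - 1)**2 - k for the k x k table with k structural zeros, less
    one per empty observed row or column; df <= 0 marks the test undefined.
    """
    if m.expected is None:
        raise PreconditionError("expected counts missing; run quasi_independence_expected")
    O = m.observed.astype(float)
    E = m.expected
    mask = O > 0
    g2 = 2.0 * float(np.sum(O[mask] * np.log(O[mask] / E[mask])))
    k = m.k
    df = (k - 1) ** 2 - k
    df -= int((O.sum(axis=1) == 0).sum()) + int((O.sum(axis=0) == 0).sum())
    if df < 1:
        return GTestResult(g2=g2, df=df, p=None, defined=False,
                           note="degrees of freedom <= 0; test not defined")
    return GTestResult(g2=g2, df=df, p=float(stats.chi2.sf(g2, df=df)), defined=True)


# ---------------------------------------------------------------------------
# No-repeat permutation null

_REJECTION_CAP = 10_000


def _feasible(counts: np.ndarray, length: int) -> bool:
    return counts.max() <= (length + 1) // 2


def _constructive_arrangement(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random no-repeat arrangement by count-weighted greedy placement.

    Whenever one label holds more than half of the remaining slots it must
    be placed; otherwise the next label is drawn with probability
    proportional to its remaining count (excluding the previous label).
    Always succeeds on feasible multisets.
    """
    counts = counts.copy()
    total = int(counts.sum())
    out = np.empty(total, dtype=np.int64)
    prev = -1
    for pos in range(total):
        remaining = total - pos
        forced = np.flatnonzero(counts > remaining // 2)
        if forced.size and forced[0] != prev:
            choice = int(forced[0])
        else:
            w = counts.astype(float).copy()
            if prev >= 0:
                w[prev] = 0.0
            if w.sum() <= 0:
                raise InfeasibleSequenceError("greedy placement ran out of labels")
            choice = int(rng.choice(counts.size, p=w / w.sum()))
        out[pos] = choice
        counts[choice] -= 1
        prev = choice
    return out


def _swap_valid(perm: np.ndarray, i: int, j: int) -> bool:
    if i == j or perm[i] == perm[j]:
        return False
    a, b = perm[i], perm[j]
    n = perm.size

    def val(p: int):
        if p == i:
            return b
        if p == j:
            return a
        return perm[p]

    for p in (i, j):
        if p > 0 and val(p - 1) == val(p):
            return False
        if p < n - 1 and val(p) == val(p + 1):
            return False
    return True


def _repair(perm: np.ndarray, rng: np.random.Generator) -> np.ndarray | None:
    """Fix adjacent duplicates in-place by random validity-preserving swaps."""
    n = perm.size
    for _ in range(50):
        viol = np.flatnonzero(perm[1:] == perm[:-1])
        if viol.size == 0:
            return perm
        for i in viol:
            if perm[i] != perm[i + 1]:
                continue  # already fixed by an earlier swap this pass
            for _try in range(200):
                j = int(rng.integers(n))
                if _swap_valid(perm, i, j):
                    perm[i], perm[j] = perm[j], perm[i]
                    break
    return None


def permute_no_repeats_codes(codes: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random rearrangement of integer codes with no adjacent duplicates.

    Rejection-samples uniform shuffles (unbiased) while the expected number
    of adjacent collisions is small enough for rejection to be practical;
    longer or more repetitive sequences use a shuffle-and-repair sampler
    (random validity-preserving swaps on the collisions of one uniform
    shuffle), with a count-weighted constructive sampler as the final
    fallback for extreme multisets.
    """
    counts = np.bincount(codes, minlength=k)
    if not _feasible(counts, codes.size):
        raise InfeasibleSequenceError(
            "label multiset admits no arrangement without adjacent repeats"
        )
    n = codes.size
    # expected adjacent collisions of a uniform shuffle; acceptance ~ exp(-lam)
    lam = float((counts * (counts - 1)).sum()) / max(n, 1)
    if lam < 7.0:
        attempts = min(_REJECTION_CAP, int(20.0 * np.exp(lam)) + 10)
        for _ in range(attempts):
            perm = rng.permutation(codes)
            if perm.size < 2 or not np.any(perm[1:] == perm[:-1]):
                return perm
    perm = _repair(rng.permutation(codes), rng)
    if perm is not None:
        return perm
    # extreme multisets only: constructive samples are biased, so mix
    return _mix(_constructive_arrangement(counts, rng), rng, sweeps=4.0)


def _mix(perm: np.ndarray, rng: np.random.Generator, sweeps: float = 1.5) -> np.ndarray:
    """Randomize a valid arrangement by validity-preserving random swaps.

    Symmetric proposals accepted only when the result stays valid form a
    Metropolis chain whose stationary distribution is uniform over valid
    arrangements, washing out construction bias.
    """
    n = perm.size
    if n < 3:
        return perm
    m = int(sweeps * n)
    proposals = rng.integers(0, n, size=(m, 2))
    for i, j in proposals:
        if _swap_valid(perm, int(i), int(j)):
            perm[i], perm[j] = perm[j], perm[i]
    return perm


def permute_no_repeats(
    seq: BehaviorSequence,
    rng: np.random.Generator | int | None = None,
) -> BehaviorSequence:
    rng = np.random.default_rng(rng)
    labels, codes = sequence_codes(seq)
    perm = permute_no_repeats_codes(codes, len(labels), rng)
    return BehaviorSequence(
        subject_id=seq.subject_id,
        label=seq.label,
        labels=tuple(labels[c] for c in perm),
    )


def permutation_transition_test(
    seq: BehaviorSequence,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    strict: bool = True,
    min_transitions: int = 2,
) -> TransitionTestResult:
    """Per-transition permutation p-values against the no-repeat null.

    With ``strict`` (the default) p = #{permutations whose count exceeds
    the observed}/n_perm; otherwise the add-one convention
    (#{count >= observed} + 1)/(n_perm + 1) is used.
    """
    rng = np.random.default_rng(rng)
    m = transition_counts(seq, min_transitions=min_transitions)
    labels, codes = sequence_codes(seq)
    k = len(labels)
    obs = m.observed
    exceed = np.zeros((k, k), dtype=np.int64)
    for _ in range(n_perm):
        perm = permute_no_repeats_codes(codes, k, rng)
        counts = _bigram_counts(perm, k)
        if strict:
            exceed += counts > obs
        else:
            exceed += counts >= obs
    if strict:
        p = exceed / n_perm
    else:
        p = (exceed + 1) / (n_perm + 1)
    np.fill_diagonal(p, np.nan)
    total = m.total_transitions
    prob = obs / total if total else np.zeros_like(obs, dtype=float)
    return TransitionTestResult(
        labels=labels, observed=obs, probability=prob.astype(float), p=p, n_perm=n_perm
    )


def group_transition_summary(
    results: Iterable[TransitionTestResult],
    group: str,
    p_thresh: float = 0.01,
    prob_thresh: float = 0.075,
    frequencies: Sequence[dict[str, float]] | None = None,
) -> GroupTransitionSummary:
    """Median p and transition probability per transition across individuals.

    Individuals lacking a transition (label pair absent from their
    sequence) contribute probability 0 and p = 1, so medians are taken
    over every individual in the group.
    """
    results = list(results)
    if not results:
        raise PreconditionError("at least one individual result is required")
    pairs: set[tuple[str, str]] = set()
    for r in results:
        for i, a in enumerate(r.labels):
            for j, b in enumerate(r.labels):
                if i != j:
                    pairs.add((a, b))
    rows = []
    for a, b in sorted(pairs):
        ps, probs = [], []
        for r in results:
            if a in r.labels and b in r.labels:
                i, j = r.labels.index(a), r.labels.index(b)
                ps.append(float(r.p[i, j]))
                probs.append(float(r.probability[i, j]))
            else:
                ps.append(1.0)
                probs.append(0.0)
        med_p = float(np.median(ps))
        med_prob = float(np.median(probs))
        rows.append(
            {
                "from": a,
                "to": b,
                "median_p": med_p,
                "median_probability": med_prob,
                "significant": med_p <= p_thresh,
                "meaningful": med_prob >= prob_thresh,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["from", "to", "median_p", "median_probability", "significant", "meaningful"],
    )
    freq: dict[str, float] = {}
    if frequencies:
        all_behaviors = sorted({b for f in frequencies for b in f})
        for b in all_behaviors:
            freq[b] = float(np.median([f.get(b, 0.0) for f in frequencies]))
    else:
        # fall back to relative frequency implied by outgoing transition mass
        for r in results:
            for i, a in enumerate(r.labels):
                freq[a] = freq.get(a, 0.0) + float(r.probability[i, :].sum())
        total = sum(freq.values()) or 1.0
        freq = {b: v / total for b, v in freq.items()}
    return GroupTransitionSummary(group=group, table=table, frequencies=freq)


def kinetogram_graph(summary: GroupTransitionSummary) -> nx.DiGraph:
    """Directed graph of meaningful transitions (median probability >= threshold)."""
    G = nx.DiGraph(group=summary.group)
    for b, f in sorted(summary.frequencies.items()):
        G.add_node(b, frequency=float(f))
    for a, b, _p, prob, sig, meaningful in summary.table.itertuples(index=False, name=None):
        if meaningful:
            G.add_edge(a, b, weight=float(prob), significant=bool(sig))
    return G


def _write_dot(G: nx.DiGraph, path) -> None:
    lines = [f'digraph "{G.graph.get("group", "kinetogram")}" {{']
    for node, attrs in G.nodes(data=True):
        lines.append(f'  "{node}" [frequency={attrs.get("frequency", 0.0):.4f}];')
    for u, v, attrs in G.edges(data=True):
        color = "red" if attrs.get("significant") else "black"
        lines.append(
            f'  "{u}" -> "{v}" [weight={attrs.get("weight", 0.0):.4f}, color={color}];'
        )
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def export_kinetogram(summary: GroupTransitionSummary, path_stem) -> dict[str, str]:
    """Write the kinetogram as GraphML and DOT; returns the paths written."""
    G = kinetogram_graph(summary)
    graphml = f"{path_stem}.graphml"
    dot = f"{path_stem}.dot"
    nx.write_graphml(G, graphml)
    _write_dot(G, dot)
    return {"graphml": graphml, "dot": dot}
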