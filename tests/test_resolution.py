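import numpy as np
import pytest
from scipy import stats

from dyadom import resolution as R
from dyadom.bursts import BurstInterval
from dyadom.exceptions import AmbiguousRolesError, PhaseOrderingError
from dyadom.resolution import (
    AgonisticMatrix,
    agonistic_matrix,
    assign_eventual_dominant,
    compare_phase_behaviors,
    phase_proportions,
    phi_coefficient,
    resolve_difference,
    resolve_phi,
    segment_phases,
)

from conftest import make_log


def matrices(cells):
    return [AgonisticMatrix(i + 1, *abcd) for i, abcd in enumerate(cells)]


class TestPhi:
    def test_perfect_separation(self):
        r = phi_coefficient(AgonisticMatrix(1, 10, 0, 0, 10))
        assert r.phi == pytest.approx(1.0)
        assert r.chi_sq == pytest.approx(r.n * r.phi**2)

    def test_equivalent_mix_zero(self):
        r = phi_coefficient(AgonisticMatrix(1, 6, 4, 6, 4))
        assert r.phi == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_worked_example_against_oracle(self):
        # independent recomputation from the definition
        a, b, c, d = 8, 2, 3, 7
        phi_oracle = (a * d - b * c) / np.sqrt((a + b) * (c + d) * (a + c) * (b + d))
        n = a + b + c + d
        chi_oracle = n * phi_oracle**2
        p_oracle = stats.chi2.sf(chi_oracle, 1)
        r = phi_coefficient(AgonisticMatrix(1, a, b, c, d))
        assert r.phi == pytest.approx(phi_oracle, abs=1e-12)
        assert r.chi_sq == pytest.approx(chi_oracle, abs=1e-12)
        assert r.p == pytest.approx(p_oracle, abs=1e-12)
        # frozen values from the oracle
        assert r.phi == pytest.approx(0.5025189076296064, abs=1e-9)
        assert r.chi_sq == pytest.approx(5.050505050505051, abs=1e-9)
        assert r.p == pytest.approx(0.02461876138081506, abs=1e-9)

    def test_chi_sq_identity_exact(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            m = AgonisticMatrix(1, *rng.integers(1, 20, size=4).tolist())
            r = phi_coefficient(m)
            if not r.excluded:
                assert r.chi_sq == m.n * r.phi**2
                assert -1.0 <= r.phi <= 1.0
                assert 0.0 < r.p <= 1.0

    def test_small_n_excluded(self):
        assert phi_coefficient(AgonisticMatrix(1, 2, 1, 1, 1)).excluded

    def test_zero_margin_excluded(self):
        assert phi_coefficient(AgonisticMatrix(1, 10, 10, 0, 0)).excluded


class TestAssignRoles:
    def _log_two_bursts(self, x_counts, y_counts):
        # x_counts/y_counts: (n_agg, n_sub) placed inside burst [10, 40]
        rows = []
        t = 10.0
        for subj, (na, ns) in (("m1", x_counts), ("m2", y_counts)):
            for _ in range(na):
                rows.append(("d1", 1, subj, "lunge", t, t + 0.1)); t += 0.5
            for _ in range(ns):
                rows.append(("d1", 1, subj, "flee", t, t + 0.1)); t += 0.5
        return make_log(rows)

    def test_clear_dominant(self, eth):
        log = self._log_two_bursts((9, 1), (1, 9))
        bursts = [BurstInterval("d1", 1, 0.0, 100.0, 2, 1)]
        roles = assign_eventual_dominant(log, bursts, eth)
        assert roles == {"m1": "dom", "m2": "sub"}

    def test_tie_raises(self, eth):
        log = self._log_two_bursts((5, 5), (5, 5))
        bursts = [BurstInterval("d1", 1, 0.0, 100.0, 2, 1)]
        with pytest.raises(AmbiguousRolesError):
            assign_eventual_dominant(log, bursts, eth)

    def test_conflicting_conditions_raise(self, eth):
        # m1 higher on aggressive AND subordinate counts
        log = self._log_two_bursts((9, 9), (1, 1))
        bursts = [BurstInterval("d1", 1, 0.0, 100.0, 2, 1)]
        with pytest.raises(AmbiguousRolesError):
            assign_eventual_dominant(log, bursts, eth)


class TestAgonisticMatrix:
    def test_only_dominant_lunges(self, eth):
        rows = [("d1", 1, "m1", "lunge", float(t), float(t) + 0.1) for t in (10, 11, 12)]
        rows.append(("d1", 1, "m2", "idle", 50.0, 60.0))
        log = make_log(rows)
        burst = BurstInterval("d1", 1, 9.0, 13.0, 2, 1)
        m = agonistic_matrix(log, burst, {"m1": "dom", "m2": "sub"}, eth)
        assert (m.a, m.b, m.c, m.d) == (3, 0, 0, 0)

    def test_empty_burst(self, eth):
        log = make_log([("d1", 1, "m1", "lunge", 100.0, 101.0),
                        ("d1", 1, "m2", "flee", 100.5, 101.0)])
        burst = BurstInterval("d1", 1, 0.0, 50.0, 2, 1)
        m = agonistic_matrix(log, burst, {"m1": "dom", "m2": "sub"}, eth)
        assert m.n == 0


def phi_passes(m, alpha=0.1):
    r = phi_coefficient(m)
    if r.excluded:
        return None
    return r.phi > 0 and r.p < alpha


def brute_force_resolution(passes):
    """Oracle: scan every candidate k over (index, pass) lists."""
    informative = [(i, ok) for i, ok in passes if ok is not None]
    for k, _ in informative:
        if all(ok for i, ok in informative if i >= k):
            later = [ok for i, ok in informative if i >= k]
            if later and later[0]:
                return k
    return None


class TestResolvePhi:
    def test_direct_rule(self):
        ms = matrices([(1, 5, 5, 1), (9, 0, 1, 8), (10, 0, 0, 9)])
        # burst 1 fails (phi<0), bursts 2-3 pass
        res = resolve_phi(ms)
        assert res.resolved and res.resolution_burst_index == 2

    def test_all_nonpositive_unresolved(self):
        ms = matrices([(1, 5, 5, 1), (2, 6, 7, 2)])
        res = resolve_phi(ms)
        assert not res.resolved

    def test_no_informative_bursts(self):
        ms = matrices([(1, 1, 1, 1)])
        res = resolve_phi(ms)
        assert not res.resolved and "no informative" in res.reason

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(9)
        for _ in range(1000):
            n = int(rng.integers(1, 8))
            ms = matrices([tuple(rng.integers(0, 8, size=4).tolist()) for _ in range(n)])
            res = resolve_phi(ms)
            expect = brute_force_resolution(
                [(m.burst_index, phi_passes(m)) for m in ms]
            )
            got = res.resolution_burst_index if res.resolved else None
            assert got == expect

    def test_excluded_veto(self):
        ms = matrices([(9, 0, 1, 8), (1, 1, 1, 1)])  # final burst excluded (N=4)
        assert resolve_phi(ms).resolved
        assert not resolve_phi(ms, excluded_veto=True).resolved


class TestResolveDifference:
    def test_direct_rule(self):
        # per burst (a-c, b-d): (-3,2), (4,-1), (5,-4)
        ms = matrices([(0, 2, 3, 0), (4, 0, 0, 1), (5, 0, 0, 4)])
        res = resolve_difference(ms)
        assert res.resolved and res.resolution_burst_index == 2

    def test_all_zero_resolves_at_first(self):
        ms = matrices([(0, 0, 0, 0), (0, 0, 0, 0)])
        res = resolve_difference(ms)
        assert res.resolved and res.resolution_burst_index == 1

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(10)
        for _ in range(1000):
            n = int(rng.integers(1, 8))
            ms = matrices([tuple(rng.integers(0, 8, size=4).tolist()) for _ in range(n)])
            res = resolve_difference(ms)
            expect = brute_force_resolution(
                [(m.burst_index, (m.a - m.c) >= (m.b - m.d)) for m in ms]
            )
            got = res.resolution_burst_index if res.resolved else None
            assert got == expect


class TestSegmentPhases:
    def _log(self):
        rows = [("d1", d, s, "idle", 0.0, 1.0) for d in range(1, 6) for s in ("m1", "m2")]
        return make_log(rows)

    def test_worked_example(self):
        log = self._log()
        bursts = [
            BurstInterval("d1", 1, 100.0, 150.0, 2, 1),
            BurstInterval("d1", 2, 0.0, 50.0, 2, 2),
            BurstInterval("d1", 2, 200.0, 250.0, 2, 3),
            BurstInterval("d1", 2, 600.0, 700.0, 2, 4),
        ]
        rd = R.ResolutionResult("difference", True, 1, 1, 150.0)
        rp = R.ResolutionResult("phi", True, 4, 2, 1900.0)
        seg = segment_phases(log, bursts, rd, rp)
        assert seg.windows["pre"] == [(1, 0.0, 100.0)]
        assert seg.windows["middle"] == [(1, 100.0, 1200.0), (2, 0.0, 700.0)]
        assert seg.windows["post"] == [(2, 700.0, 1200.0)] + [
            (d, 0.0, 1200.0) for d in (3, 4, 5)
        ]

    def test_phi_unresolved_no_post(self):
        log = self._log()
        bursts = [BurstInterval("d1", 1, 100.0, 150.0, 2, 1)]
        rd = R.ResolutionResult("difference", True, 1, 1, 150.0)
        rp = R.ResolutionResult("phi", False)
        seg = segment_phases(log, bursts, rd, rp)
        assert seg.windows["post"] == []
        assert seg.windows["middle"][-1] == (5, 0.0, 1200.0)

    def test_partition_exact(self):
        log = self._log()
        bursts = [
            BurstInterval("d1", 2, 300.0, 400.0, 2, 1),
            BurstInterval("d1", 4, 500.0, 600.0, 2, 2),
        ]
        rd = R.ResolutionResult("difference", True, 1, 2, 1600.0)
        rp = R.ResolutionResult("phi", True, 2, 4, 4200.0)
        seg = segment_phases(log, bursts, rd, rp)
        total = sum(seg.duration(p) for p in R.PHASES)
        assert total == pytest.approx(5 * 1200.0, abs=1e-9)
        # per-day coverage
        for day in range(1, 6):
            spans = [
                (s, e)
                for p in R.PHASES
                for (d, s, e) in seg.windows[p]
                if d == day
            ]
            assert sum(e - s for s, e in spans) == pytest.approx(1200.0, abs=1e-9)

    def test_ordering_violation_raises(self):
        log = self._log()
        bursts = [
            BurstInterval("d1", 1, 100.0, 200.0, 2, 1),
            BurstInterval("d1", 3, 500.0, 600.0, 2, 2),
        ]
        rd = R.ResolutionResult("difference", True, 2, 3, 4200.0)
        rp = R.ResolutionResult("phi", True, 1, 1, 200.0)
        with pytest.raises(PhaseOrderingError):
            segment_phases(log, bursts, rd, rp)


class TestPhaseProportions:
    def _segmentation(self):
        return R.PhaseSegmentation(
            windows={
                "pre": [(1, 0.0, 100.0)],
                "middle": [(1, 100.0, 1200.0)],
                "post": [],
            }
        )

    def test_idle_full_pre(self, eth):
        log = make_log([
            ("d1", 1, "m1", "idle", 0.0, 100.0),
            ("d1", 1, "m2", "lunge", 0.0, 1.0),
        ])
        table = phase_proportions(log, "d1", self._segmentation(), eth)
        row = table[(table.subject_id == "m1") & (table.phase == "pre")
                    & (table.behavior == "idle")]
        assert row["proportion"].iloc[0] == pytest.approx(1.0)

    def test_absent_behavior_zero(self, eth):
        log = make_log([("d1", 1, "m1", "idle", 0.0, 100.0),
                        ("d1", 1, "m2", "idle", 0.0, 100.0)])
        table = phase_proportions(log, "d1", self._segmentation(), eth)
        row = table[(table.subject_id == "m1") & (table.phase == "pre")
                    & (table.behavior == "lunge")]
        assert row["proportion"].iloc[0] == 0.0

    def test_matches_rasterization(self, eth):
        rng = np.random.default_rng(4)
        rows = []
        for _ in range(40):
            onset = rng.uniform(0, 1150)
            rows.append(("d1", 1, "m1", "idle" if rng.random() < 0.5 else "rearing",
                         round(onset, 2), round(onset + rng.uniform(0, 40), 2)))
        rows.append(("d1", 1, "m2", "idle", 0.0, 10.0))
        log = make_log(rows)
        seg = self._segmentation()
        table = phase_proportions(log, "d1", seg, eth)
        # 0.01 s rasterization oracle over the pre phase [0, 100)
        grid = np.arange(0, 100.0, 0.01) + 0.005
        for behavior in ("idle", "rearing"):
            covered = np.zeros(grid.size, dtype=bool)
            for r in log.df.itertuples(index=False):
                if r.subject_id == "m1" and r.behavior == behavior:
                    covered |= (grid >= r.onset_s) & (grid < r.offset_s)
            expect = covered.mean()
            got = table[(table.subject_id == "m1") & (table.phase == "pre")
                        & (table.behavior == behavior)]["proportion"].iloc[0]
            assert got == pytest.approx(expect, abs=5e-3)


class TestComparePhases:
    def _table(self, dom_vals, sub_vals):
        import pandas as pd

        rows = []
        for i, (dv, sv) in enumerate(zip(dom_vals, sub_vals)):
            rows.append({"dyad_id": f"d{i}", "subject_id": "a", "phase": "pre",
                         "behavior": "digging", "proportion": dv, "phase_duration_s": 100})
            rows.append({"dyad_id": f"d{i}", "subject_id": "b", "phase": "pre",
                         "behavior": "digging", "proportion": sv, "phase_duration_s": 100})
        return pd.DataFrame(rows), {f"d{i}": {"a": "dom", "b": "sub"}
                                    for i in range(len(dom_vals))}

    def test_identical_proportions_p_one(self):
        table, roles = self._table([0.2] * 5, [0.2] * 5)
        out = compare_phase_behaviors(table, roles)
        assert out["p"].iloc[0] == 1.0
        assert out["note"].iloc[0] == "all differences zero"

    def test_consistent_dominance_minimal_p(self):
        rng = np.random.default_rng(1)
        dom = 0.5 + rng.uniform(0.01, 0.3, size=21)
        sub = dom - rng.uniform(0.01, 0.2, size=21)
        table, roles = self._table(dom.tolist(), sub.tolist())
        out = compare_phase_behaviors(table, roles)
        # exact two-sided p for n=21 all-positive differences = 2 * 2^-21
        assert out["p"].iloc[0] == pytest.approx(2 * 0.5**21, rel=1e-9)

    def test_role_swap_flips_statistic(self):
        rng = np.random.default_rng(6)
        dom = rng.uniform(0, 1, size=10)
        sub = rng.uniform(0, 1, size=10)
        t1, roles1 = self._table(dom.tolist(), sub.tolist())
        t2, roles2 = self._table(sub.tolist(), dom.tolist())
        r1 = compare_phase_behaviors(t1, roles1)
        r2 = compare_phase_behaviors(t2, roles2)
        assert r1["statistic"].iloc[0] == -r2["statistic"].iloc[0]
        assert r1["p"].iloc[0] == pytest.approx(r2["p"].iloc[0])
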