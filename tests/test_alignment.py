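"""Join alignment, gap filling and duplicate-row filtering."""

import itertools
import math

import numpy as np
import pytest

from decarbid.alignment import (
    AlignedFeature,
    FeatureTable,
    filter_duplicates,
    gap_fill,
    join_align,
)
from decarbid.feature_extraction import Feature, extract_features, mz_tolerance
from decarbid.runs import CentroidSpectrum, Run


def feat(mz, rt, area=1000.0, height=500.0, run_id=""):
    return Feature(
        mz=mz, rt_apex=rt, height=height, area=area,
        scan_first=0, scan_last=10, run_id=run_id,
    )


class TestJoinAlign:
    def test_two_runs_same_feature_merge_into_one_row(self):
        table = join_align(
            {
                "a": [feat(150.0000, 3.00, run_id="a")],
                "b": [feat(150.0005, 3.05, run_id="b")],
            },
            groups={"a": "vector", "b": "enzyme"},
        )
        assert len(table) == 1
        row = table.rows[0]
        assert set(row.members) == {"a", "b"}
        # consensus is the mean of member coordinates
        assert row.mz == pytest.approx(150.00025, abs=1e-9)
        assert row.rt == pytest.approx(3.025, abs=1e-9)

    def test_rt_separation_beyond_tolerance_keeps_rows_apart(self):
        table = join_align(
            {
                "a": [feat(150.0, 3.0, run_id="a")],
                "b": [feat(150.0, 3.5, run_id="b")],  # 0.5 min > 0.2 tol
            }
        )
        assert len(table) == 2
        for row in table.rows:
            assert len(row.members) == 1

    def test_mz_separation_beyond_tolerance_keeps_rows_apart(self):
        table = join_align(
            {
                "a": [feat(150.0, 3.0, run_id="a")],
                "b": [feat(150.01, 3.0, run_id="b")],  # 0.01 Da > tol
            }
        )
        assert len(table) == 2

    def test_one_to_one_matching_within_a_run(self):
        # two co-eluting features in run b must occupy two distinct rows
        table = join_align(
            {
                "a": [feat(150.0, 3.00, run_id="a"), feat(150.0, 3.15, run_id="a")],
                "b": [feat(150.0, 3.05, run_id="b"), feat(150.0, 3.12, run_id="b")],
            }
        )
        assert len(table) == 2
        for row in table.rows:
            assert set(row.members) == {"a", "b"}

    def test_feature_conservation(self):
        rng = np.random.default_rng(3)
        per_run = {}
        n_total = 0
        for rid in ("r1", "r2", "r3"):
            n = int(rng.integers(3, 8))
            n_total += n
            per_run[rid] = [
                feat(
                    float(rng.uniform(100, 400)),
                    float(rng.uniform(1, 7)),
                    run_id=rid,
                )
                for _ in range(n)
            ]
        table = join_align(per_run)
        assert sum(len(r.members) for r in table.rows) == n_total
        for row in table.rows:
            assert len(row.members) <= 3  # at most one feature per run

    def test_empty_input_is_an_error_and_empty_run_is_allowed(self):
        with pytest.raises(ValueError):
            join_align({})
        table = join_align({"a": [feat(150.0, 3.0, run_id="a")], "b": []})
        assert len(table) == 1
        assert table.run_ids == ["a", "b"]

    def test_rows_sorted_by_mz_then_rt(self):
        table = join_align(
            {"a": [feat(200.0, 1.0), feat(150.0, 5.0), feat(150.0, 2.0)]}
        )
        keys = [(r.mz, r.rt) for r in table.rows]
        assert keys == sorted(keys)


def brute_force_best_assignment(feats, rows, rt_tol=0.2):
    """Oracle: maximize matches, then minimize summed score, exhaustively."""

    def score(f, row):
        tol = mz_tolerance(row.mz)
        dmz = abs(f.mz - row.mz)
        drt = abs(f.rt_apex - row.rt)
        if dmz > tol or drt > rt_tol:
            return None
        return dmz / tol + drt / rt_tol

    best = (-1, math.inf)
    n_best = None
    choices = list(range(len(rows))) + [None]
    for combo in itertools.product(choices, repeat=len(feats)):
        used = [c for c in combo if c is not None]
        if len(used) != len(set(used)):
            continue
        total, n_matched, ok = 0.0, 0, True
        for f, c in zip(feats, combo):
            if c is None:
                continue
            s = score(f, rows[c])
            if s is None:
                ok = False
                break
            total += s
            n_matched += 1
        if not ok:
            continue
        if (-n_matched, total) < (-best[0], best[1]):
            best = (n_matched, total)
            n_best = combo
    return best, n_best


class TestJoinAlignOracle:
    def test_matches_exhaustive_optimum_on_random_instances(self):
        """The LSA-based matcher achieves the brute-force optimal score."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            n_rows = int(rng.integers(1, 5))
            n_feats = int(rng.integers(1, 5))
            base_mz = rng.uniform(100, 400, n_rows)
            base_rt = rng.uniform(1, 7, n_rows)
            first_run = [
                feat(float(m), float(t), run_id="a")
                for m, t in zip(base_mz, base_rt)
            ]
            feats = []
            for _ in range(n_feats):
                if rng.random() < 0.7:
                    k = int(rng.integers(0, n_rows))
                    m = base_mz[k] + rng.normal(0, 0.0015)
                    t = base_rt[k] + rng.normal(0, 0.08)
                else:
                    m = rng.uniform(100, 400)
                    t = rng.uniform(1, 7)
                feats.append(feat(float(m), float(t), run_id="b"))
            rows = [AlignedFeature(f.mz, f.rt_apex, members={"a": f}) for f in first_run]
            (n_opt, s_opt), _ = brute_force_best_assignment(feats, rows)

            table = join_align({"a": first_run, "b": feats})
            # reconstruct the achieved matching against the original rows
            n_got, s_got = 0, 0.0
            for row in table.rows:
                if "a" in row.members and "b" in row.members:
                    fa, fb = row.members["a"], row.members["b"]
                    orig = AlignedFeature(fa.mz, fa.rt_apex, members={"a": fa})
                    tol = mz_tolerance(orig.mz)
                    s_got += (
                        abs(fb.mz - orig.mz) / tol
                        + abs(fb.rt_apex - orig.rt) / 0.2
                    )
                    n_got += 1
            assert n_got == n_opt
            assert s_got == pytest.approx(s_opt, abs=1e-9)


def gaussian_scans(peaks, n_scans=120, dt=1.0 / 60.0):
    scans = []
    for i in range(n_scans):
        t = i * dt
        mzs, ints = [], []
        for mz, rt, height, sigma in peaks:
            y = height * math.exp(-0.5 * ((t - rt) / sigma) ** 2)
            if y >= 1.0:
                mzs.append(mz)
                ints.append(y)
        scans.append(CentroidSpectrum(t, "positive", np.array(mzs), np.array(ints)))
    return scans


class TestGapFill:
    def _tables(self):
        peak = (150.0, 1.0, 5000.0, 0.05)
        run_a = Run("a", "positive", gaussian_scans([peak]))
        run_b = Run("b", "positive", gaussian_scans([peak]))
        feats_a = extract_features(run_a)
        assert len(feats_a) == 1
        # run b contributes no detected features: its cell must be filled
        table = join_align({"a": feats_a, "b": []}, groups={"a": "vector", "b": "enzyme"})
        return table, run_a, run_b, feats_a[0]

    def test_filled_area_close_to_sister_run_detection(self):
        table, run_a, run_b, f_a = self._tables()
        gap_fill(table, {"a": run_a, "b": run_b})
        row = table.rows[0]
        assert row.status("b") == "gap_filled"
        assert row.status("a") == "detected"
        # identical raw signal: filled area within 20% of the detected area
        assert row.value("b") == pytest.approx(f_a.area, rel=0.2)

    def test_no_signal_leaves_cell_missing(self):
        table, run_a, _, _ = self._tables()
        empty = Run("b", "positive", gaussian_scans([(300.0, 5.0, 5000.0, 0.05)]))
        gap_fill(table, {"a": run_a, "b": empty})
        assert table.rows[0].status("b") == "missing"
        assert table.rows[0].value("b") == 0.0

    def test_detected_cells_never_modified(self):
        table, run_a, run_b, f_a = self._tables()
        before = table.rows[0].value("a")
        gap_fill(table, {"a": run_a, "b": run_b})
        assert table.rows[0].value("a") == before == f_a.area

    def test_idempotent(self):
        table, run_a, run_b, _ = self._tables()
        gap_fill(table, {"a": run_a, "b": run_b})
        first = table.rows[0].value("b")
        gap_fill(table, {"a": run_a, "b": run_b})
        assert table.rows[0].value("b") == first

    def test_single_point_uses_scan_interval(self):
        table, run_a, _, _ = self._tables()
        scans = gaussian_scans([])
        # one isolated point at the row's m/z and RT
        scans[60] = CentroidSpectrum(1.0, "positive", np.array([150.0]), np.array([900.0]))
        spike = Run("b", "positive", scans)
        gap_fill(table, {"a": run_a, "b": spike})
        assert table.rows[0].value("b") == pytest.approx(900.0 / 60.0, rel=1e-6)


class TestFilterDuplicates:
    def _table(self, rows_spec):
        rows = []
        for mz, rt, area in rows_spec:
            f = feat(mz, rt, area=area, run_id="a")
            rows.append(AlignedFeature(mz, rt, members={"a": f}))
        return FeatureTable(["a"], {"a": "vector"}, rows)

    def test_higher_total_intensity_wins(self):
        table = self._table([(150.0, 3.0, 100.0), (150.0005, 3.05, 900.0)])
        out = filter_duplicates(table)
        assert len(out) == 1
        assert out.rows[0].mz == 150.0005

    def test_tie_resolves_to_lower_mz(self):
        table = self._table([(150.0008, 3.0, 500.0), (150.0, 3.0, 500.0)])
        out = filter_duplicates(table)
        assert len(out) == 1
        assert out.rows[0].mz == 150.0

    def test_distinct_rows_untouched_and_idempotent(self):
        table = self._table([(150.0, 3.0, 500.0), (150.0, 3.5, 400.0), (151.0, 3.0, 300.0)])
        out = filter_duplicates(table)
        assert len(out) == 3
        out2 = filter_duplicates(out)
        assert [(r.mz, r.rt) for r in out2.rows] == [(r.mz, r.rt) for r in out.rows]

    def test_chain_collapse_leaves_no_pair_within_tolerance(self):
        # rows form a chain; result must contain no in-tolerance pair
        table = self._table(
            [(150.0, 3.0, 500.0), (150.0015, 3.1, 600.0), (150.003, 3.2, 400.0)]
        )
        out = filter_duplicates(table)
        for i, a in enumerate(out.rows):
            for b in out.rows[i + 1:]:
                tol = mz_tolerance(a.mz)
                assert not (abs(a.mz - b.mz) <= tol and abs(a.rt - b.rt) <= 0.2)
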