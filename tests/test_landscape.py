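"""Quartile assignment, metaprofiles, and interval-proximity statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from repliscape.config import AnalysisConfig
from repliscape.core import BinnedTrack, GenomeLayout, Origin
from repliscape.landscape import (
    assign_trep_quartiles,
    distance_to_nearest,
    mean_distance_by_class,
    metaprofile,
    overlap_with_sites,
    proximity_class_counts,
)


def make_origins(treps, chrom="chrI", spacing=5000):
    return [
        Origin(f"o{i}", chrom, 1000 + i * spacing, 1300 + i * spacing, "confirmed", t)
        for i, t in enumerate(treps)
    ]


class TestTrepQuartiles:
    def test_even_split_respects_order(self):
        origins = make_origins([40, 10, 30, 20, 35, 15, 25, 5])
        q = assign_trep_quartiles(origins)
        by_q = {k: sorted(n for n, v in q.items() if v == k) for k in (1, 2, 3, 4)}
        assert all(len(v) == 2 for v in by_q.values())
        assert by_q[1] == ["o1", "o7"]  # treps 10 and 5
        assert by_q[4] == ["o0", "o4"]  # treps 40 and 35

    def test_remainder_goes_to_earlier_quartiles(self):
        q = assign_trep_quartiles(make_origins(range(9)))
        sizes = [sum(1 for v in q.values() if v == k) for k in (1, 2, 3, 4)]
        assert sizes == [3, 2, 2, 2]

    def test_ties_broken_by_name_matches_sort_oracle(self, rng):
        treps = list(rng.choice([10.0, 20.0, 30.0], size=23))
        origins = make_origins(treps)
        q = assign_trep_quartiles(origins)
        ordered = sorted(origins, key=lambda o: (o.t_rep, o.name))
        sizes = [6, 6, 6, 5]
        expected, pos = {}, 0
        for k, size in zip((1, 2, 3, 4), sizes):
            for o in ordered[pos : pos + size]:
                expected[o.name] = k
            pos += size
        assert q == expected

    def test_too_few_or_untimed_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            assign_trep_quartiles(make_origins([1, 2, 3]))
        origins = make_origins([1, 2, 3, None])
        with pytest.raises(ValueError, match="lacking t_rep"):
            assign_trep_quartiles(origins)


class TestMetaprofile:
    def test_flat_track_gives_constant_profile(self):
        track = BinnedTrack(50, {"chrI": np.full(2000, 4.0)})
        interior = Origin("o0", "chrI", 49_900, 50_100, "confirmed", 10.0)
        prof = metaprofile(track, [interior], 5000)
        assert (prof.n == 1).all()
        np.testing.assert_allclose(prof.mean, 4.0)
        assert prof.offsets[0] == -prof.offsets[-1]

    def test_chromosome_edge_decrements_n(self):
        track = BinnedTrack(50, {"chrI": np.ones(2000)})
        edge = Origin("edge", "chrI", 900, 1100)  # 1 kb from the start
        interior = Origin("mid", "chrI", 49_900, 50_100)
        prof = metaprofile(track, [edge, interior], 40_000)
        # offsets reaching before position 0 lose the edge origin
        assert prof.n[0] == 1 and prof.n[len(prof.n) // 2] == 2

    def test_matches_per_origin_loop_oracle(self, rng):
        layout = GenomeLayout([("chrI", 100_000), ("chrII", 100_000)])
        track = BinnedTrack(
            50, {c: rng.poisson(3.0, 2000).astype(float) for c in layout.names}
        )
        origins = [
            Origin(f"o{i}", rng.choice(layout.names), int(p), int(p) + 200)
            for i, p in enumerate(rng.integers(0, 99_000, size=25))
        ]
        window = 5000
        prof = metaprofile(track, origins, window)
        half = window // 100
        sums = np.zeros(2 * half + 1)
        ns = np.zeros(2 * half + 1)
        for o in origins:
            vec = track.data[o.chrom]
            for j, off in enumerate(range(-half, half + 1)):
                idx = o.midpoint // 50 + off
                if 0 <= idx < len(vec):
                    sums[j] += vec[idx]
                    ns[j] += 1
        np.testing.assert_array_equal(prof.n, ns)
        np.testing.assert_allclose(prof.mean[ns > 0], (sums / np.maximum(ns, 1))[ns > 0])

    def test_empty_group_rejected(self):
        track = BinnedTrack(50, {"chrI": np.ones(100)})
        with pytest.raises(ValueError, match="empty"):
            metaprofile(track, [], 5000)


class TestDistanceToNearest:
    def test_edge_gap_example(self):
        d = distance_to_nearest([("chrI", 99_500, 100_500)], [("chrI", 150_000, 150_120)])
        assert d[0] == 49_500

    def test_overlap_gives_zero(self):
        d = distance_to_nearest([("chrI", 100, 300)], [("chrI", 250, 500)])
        assert d[0] == 0

    def test_missing_chromosome_flagged_nan(self):
        d = distance_to_nearest([("chrII", 0, 10)], [("chrI", 0, 10)])
        assert np.isnan(d[0])

    def test_matches_all_pairs_oracle(self, rng):
        chroms = ["chrI", "chrII"]
        queries = [
            (rng.choice(chroms), int(s), int(s) + int(rng.integers(1, 5000)))
            for s in rng.integers(0, 400_000, size=50)
        ]
        landmarks = [
            (rng.choice(chroms), int(s), int(s) + int(rng.integers(1, 2000)))
            for s in rng.integers(0, 400_000, size=20)
        ]
        out = distance_to_nearest(queries, landmarks)
        for (qc, qs, qe), got in zip(queries, out):
            best = np.inf
            for lc, ls, le in landmarks:
                if lc != qc:
                    continue
                if qs < le and ls < qe:
                    best = 0
                elif qe <= ls:
                    best = min(best, ls - qe)
                else:
                    best = min(best, qs - le)
            assert got == best


def classified_frame(rows):
    """rows: (name, chrom, midpoint, class)."""
    return pd.DataFrame(
        {
            "name": [r[0] for r in rows],
            "chrom": [r[1] for r in rows],
            "start": [r[2] - 150 for r in rows],
            "end": [r[2] + 150 for r in rows],
            "class": [r[3] for r in rows],
        }
    )


class TestProximityClassCounts:
    def test_boundary_is_inclusive(self, tiny_layout):
        # chrI CEN at [150_000, 150_120); midpoint exactly 20 kb left of it
        df = classified_frame([("a", "chrI", 130_000, "Rif1-repressed")])
        out = proximity_class_counts(df, tiny_layout, "CEN", 20_000)
        assert out.set_index("class").loc["Rif1-repressed", "within"] == 1

    def test_all_far_counts_beyond(self, tiny_layout):
        df = classified_frame([
            ("a", "chrII", 100_000, "Rif1-activated"),
            ("b", "chrII", 300_000, "Rif1-activated"),
        ])
        out = proximity_class_counts(df, tiny_layout, "TEL", 20_000)
        row = out.set_index("class").loc["Rif1-activated"]
        assert row["within"] == 0 and row["beyond"] == 2

    def test_within_beyond_sum_to_class_size(self, tiny_layout, rng):
        classes = ["Rif1-repressed", "Rif1-unregulated", "Rif1-activated"]
        rows = [
            (f"o{i}", rng.choice(tiny_layout.names), int(m), rng.choice(classes))
            for i, m in enumerate(rng.integers(1000, 220_000, size=60))
        ]
        df = classified_frame(rows)
        for landmark in ("CEN", "TEL"):
            out = proximity_class_counts(df, tiny_layout, landmark, 20_000)
            merged = out.set_index("class")
            for cls in set(r[3] for r in rows):
                total = sum(1 for r in rows if r[3] == cls)
                assert merged.loc[cls, "within"] + merged.loc[cls, "beyond"] == total

    def test_matches_brute_force_oracle(self, tiny_layout, rng):
        classes = ["Rif1-repressed", "Rif1-unregulated", "Rif1-activated"]
        rows = [
            (f"o{i}", rng.choice(tiny_layout.names), int(m), rng.choice(classes))
            for i, m in enumerate(rng.integers(500, 225_000, size=80))
        ]
        df = classified_frame(rows)
        out = proximity_class_counts(df, tiny_layout, "CEN", 20_000).set_index("class")
        for cls in classes:
            expected = 0
            for name, chrom, mid, c in rows:
                if c != cls:
                    continue
                s, e = tiny_layout.centromeres[chrom]
                dist = 0 if s <= mid < e else (s - mid if mid < s else mid - e)
                expected += dist <= 20_000
            if cls in out.index:
                assert out.loc[cls, "within"] == expected


class TestMeanDistanceByClass:
    def test_hand_worked_welch_example(self, tiny_layout):
        # two classes at hand-set CEN distances {100, 200} vs {400, 500} kb
        cen = tiny_layout.centromeres["chrII"][0]  # 200_000
        # place on chrII far from TELs; distances measured leftward from CEN
        def at_distance(d):
            return cen - d  # midpoint left of the centromere start

        rows = [
            ("a1", "chrII", at_distance(100_000), "Rif1-repressed"),
            ("a2", "chrII", at_distance(150_000), "Rif1-repressed"),
            ("b1", "chrII", at_distance(60_000), "Rif1-activated"),
            ("b2", "chrII", at_distance(110_000), "Rif1-activated"),
        ]
        df = classified_frame(rows)
        summary, pairs = mean_distance_by_class(df, tiny_layout, 20_000)
        s = summary.set_index("class")
        assert s.loc["Rif1-repressed", "mean_distance"] == pytest.approx(125_000)
        assert s.loc["Rif1-activated", "mean_distance"] == pytest.approx(85_000)
        # independent Welch computation from the closed form
        xa, xb = np.array([100_000.0, 150_000.0]), np.array([60_000.0, 110_000.0])
        se = np.sqrt(xa.var(ddof=1) / 2 + xb.var(ddof=1) / 2)
        t = (xa.mean() - xb.mean()) / se
        df_w = (xa.var(ddof=1) / 2 + xb.var(ddof=1) / 2) ** 2 / (
            (xa.var(ddof=1) / 2) ** 2 + (xb.var(ddof=1) / 2) ** 2
        )
        expected_p = 2 * stats.t.sf(abs(t), df_w)
        assert pairs.loc[0, "pvalue"] == pytest.approx(expected_p, rel=1e-9)

    def test_identical_samples_p_one_by_convention(self, tiny_layout):
        cen = tiny_layout.centromeres["chrII"][0]
        rows = [
            ("a1", "chrII", cen - 100_000, "Rif1-repressed"),
            ("a2", "chrII", cen - 100_000, "Rif1-repressed"),
            ("b1", "chrII", cen - 100_000, "Rif1-activated"),
            ("b2", "chrII", cen - 100_000, "Rif1-activated"),
        ]
        _, pairs = mean_distance_by_class(classified_frame(rows), tiny_layout, 20_000)
        assert pairs.loc[0, "pvalue"] == 1.0

    def test_pericentric_exclusion_does_not_touch_other_classes(self, tiny_layout):
        cen = tiny_layout.centromeres["chrII"][0]
        base = [
            ("a1", "chrII", cen - 100_000, "Rif1-repressed"),
            ("a2", "chrII", cen - 150_000, "Rif1-repressed"),
            ("b1", "chrII", cen - 60_000, "Rif1-activated"),
            ("b2", "chrII", cen - 110_000, "Rif1-activated"),
        ]
        with_pericentric = base + [("p1", "chrII", cen - 5_000, "Rif1-activated")]
        s_base, _ = mean_distance_by_class(classified_frame(base), tiny_layout, 20_000)
        s_extra, _ = mean_distance_by_class(
            classified_frame(with_pericentric), tiny_layout, 20_000
        )
        a = s_base.set_index("class")
        b = s_extra.set_index("class")
        pd.testing.assert_frame_equal(a, b)  # the pericentric origin is excluded

    def test_small_class_flagged(self, tiny_layout):
        cen = tiny_layout.centromeres["chrII"][0]
        rows = [
            ("a1", "chrII", cen - 100_000, "Rif1-repressed"),
            ("a2", "chrII", cen - 150_000, "Rif1-repressed"),
            ("b1", "chrII", cen - 60_000, "Rif1-activated"),
        ]
        _, pairs = mean_distance_by_class(classified_frame(rows), tiny_layout, 20_000)
        assert pairs.loc[0, "skipped"] and np.isnan(pairs.loc[0, "pvalue"])


class TestOverlapWithSites:
    def sites(self, tiny_layout, intervals):
        return pd.DataFrame(
            {
                "name": [f"s{i}" for i in range(len(intervals))],
                "feature_type": "ORF",
                "chrom": [c for c, *_ in intervals],
                "start": [s for _, s, _ in intervals],
                "end": [e for _, _, e in intervals],
                "win_start": [s for _, s, _ in intervals],
                "win_end": [e for _, _, e in intervals],
            }
        )

    def test_abutting_window_not_proximal_one_base_is(self, tiny_layout, config):
        df = classified_frame([("a", "chrI", 100_000, "Rif1-repressed")])
        # origin window [99_500, 100_500)
        abut = self.sites(tiny_layout, [("chrI", 100_500, 101_000)])
        touch = self.sites(tiny_layout, [("chrI", 100_499, 101_000)])
        out_abut = overlap_with_sites(df, abut, config)
        out_touch = overlap_with_sites(df, touch, config)
        assert out_abut.set_index("class").loc["all", "proximal"] == 0
        assert out_touch.set_index("class").loc["all", "proximal"] == 1

    def test_matches_quadratic_oracle(self, tiny_layout, config, rng):
        classes = ["Rif1-repressed", "Rif1-unregulated", "Rif1-activated"]
        rows = [
            (f"o{i}", rng.choice(tiny_layout.names), int(m), rng.choice(classes))
            for i, m in enumerate(rng.integers(1000, 220_000, size=40))
        ]
        df = classified_frame(rows)
        intervals = [
            (rng.choice(tiny_layout.names), int(s), int(s) + int(rng.integers(50, 4000)))
            for s in rng.integers(0, 220_000, size=30)
        ]
        sites = self.sites(tiny_layout, intervals)
        out = overlap_with_sites(df, sites, config).set_index("class")
        expected_total = 0
        for name, chrom, mid, cls in rows:
            lo, hi = mid - 500, mid + 500
            hit = any(c == chrom and s < hi and lo < e for c, s, e in intervals)
            expected_total += hit
        assert out.loc["all", "proximal"] == expected_total

    def test_subtelomeric_exclusion_shrinks_n(self, tiny_layout, config):
        rows = [
            ("sub", "chrI", 5_000, "Rif1-repressed"),  # 5 kb from the left TEL
            ("mid", "chrI", 100_000, "Rif1-repressed"),
        ]
        df = classified_frame(rows)
        sites = self.sites(tiny_layout, [("chrI", 99_800, 100_100)])
        full = overlap_with_sites(df, sites, config).set_index("class")
        excl = overlap_with_sites(
            df, sites, config, tiny_layout, exclude_subtelomeric=True
        ).set_index("class")
        assert full.loc["all", "n"] == 2 and excl.loc["all", "n"] == 1
        assert excl.loc["all", "proximal"] == 1


def test_quartile_metaprofiles_show_late_origin_deregulation(timepoint_result):
    """rif1Δ elevates later-quartile signal at 25 min while the earliest
    quartile is unchanged; by 35 min WT catches up but still trails."""
    prof = timepoint_result.profiles
    q1_25 = [prof[(25.0, s, 1)].center_mean(2500) for s in ("WT", "rif1d")]
    assert abs(q1_25[1] / q1_25[0] - 1.0) < 0.10
    for q in (3, 4):
        wt, mut = (prof[(25.0, s, q)].center_mean(2500) for s in ("WT", "rif1d"))
        assert mut > wt
    wt4_25 = prof[(25.0, "WT", 4)].center_mean(2500)
    wt4_35 = prof[(35.0, "WT", 4)].center_mean(2500)
    mut4_35 = prof[(35.0, "rif1d", 4)].center_mean(2500)
    assert wt4_35 > wt4_25
    assert wt4_35 < mut4_35
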