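"""Unit tests for the ion-carboxylate contact screening engine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from casite.contact import (
    apply_passage_mask,
    build_distance_table,
    candidate_report,
    capped_mean_distance,
    classify_initial_sites,
    count_screening_distances,
    detect_departures,
    distance_timecourse,
    fraction_within,
    group_center,
    refine_candidates,
    screen_pairs,
)
from casite.errors import (
    DomainError,
    EmptyInputError,
    InvalidCoordinateError,
    UnknownPairError,
)
from casite.trajectory import (
    CarboxylGroup,
    DepartureEvent,
    IonTrack,
    ScreeningConfig,
)

from conftest import brute_force_distances, make_bundle, random_bundle


class TestGroupCenter:
    def test_midpoint_identity_symmetry(self):
        assert np.allclose(group_center((0, 0, 0), (2, 0, 0)), (1, 0, 0))
        p = (3.5, -1.0, 2.0)
        assert np.allclose(group_center(p, p), p)
        a, b = (1.0, 2.0, 3.0), (-4.0, 0.5, 9.0)
        assert np.allclose(group_center(a, b), group_center(b, a))

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidCoordinateError):
            group_center((np.nan, 0, 0), (0, 0, 0))


class TestDistanceTable:
    def test_three_four_five(self):
        b = make_bundle([
            ("s0", 2.0, [0.0, 1.0],
             {"i": [[0, 0, 0], [0, 0, 0]]},
             {"g": [[[3, 4, 0], [3, 4, 0]], [[3, 4, 0], [3, 4, 0]]]}),
        ])
        table = build_distance_table(b, 1.0)
        assert np.allclose(table.frame["distance"], 5.0)

    def test_record_count_contract(self, rng):
        # 20 frames at 0.5 ns spacing in a 10 ns segment, sampled at 1 ns:
        # 10 sampled frames per (ion, group) pair
        times = 0.5 * np.arange(20)
        b = make_bundle([
            ("s0", 10.0, times,
             {f"i{k}": rng.uniform(-5, 5, (20, 3)) for k in range(2)},
             {f"g{k}": rng.uniform(-5, 5, (20, 2, 3)) for k in range(3)}),
        ])
        table = build_distance_table(b, 1.0)
        assert len(table) == 2 * 3 * 10
        assert count_screening_distances(1, 2, 3, 1, 10) == 60

    def test_matches_bruteforce_oracle(self, toy_bundle):
        table = build_distance_table(toy_bundle, 2.0)
        expected = brute_force_distances(toy_bundle, 2.0)
        got = list(
            table.frame[["segment_id", "time_ns", "ion_id", "group_id", "distance"]]
            .itertuples(index=False, name=None)
        )
        key = lambda r: r[:4]
        got, expected = sorted(got, key=key), sorted(expected, key=key)
        assert len(got) == len(expected)
        for g, e in zip(got, expected):
            assert g[:4] == e[:4]
            assert g[4] == pytest.approx(e[4], abs=1e-12)

    def test_empty_bundle_rejected(self):
        from casite.trajectory import TrajectoryBundle

        with pytest.raises(EmptyInputError):
            build_distance_table(
                TrajectoryBundle(segments=[], ions={}, groups={}), 1.0
            )


class TestCountScreeningDistances:
    def test_published_bookkeeping_and_variants(self):
        assert count_screening_distances(2, 18, 183, 6, 10) == 395280
        assert count_screening_distances(1, 1, 1, 1, 1) == 1
        # the per-channel reading of the same bookkeeping
        assert count_screening_distances(2, 9, 183, 6, 10) == 197640

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            count_screening_distances(2, 0, 183, 6, 10)


class TestScreenPairs:
    def _table_with_min(self, dmin):
        oxy = [[[dmin, 0, 0], [dmin, 0, 0]]] * 2
        b = make_bundle([
            ("s0", 2.0, [0.0, 1.0],
             {"i": [[0, 0, 0], [0, 0, 0]]},
             {"g": oxy}),
        ])
        return build_distance_table(b, 1.0)

    def test_strict_threshold(self):
        assert screen_pairs(self._table_with_min(9.9), 10.0) == {("i", "g")}
        assert screen_pairs(self._table_with_min(10.0), 10.0) == set()

    def test_matches_exhaustive_scan(self, toy_bundle):
        table = build_distance_table(toy_bundle, 3.0)
        cutoff = 35.0
        expected = set()
        for row in table.frame.itertuples():
            if row.distance < cutoff:
                expected.add((row.ion_id, row.group_id))
        assert screen_pairs(table, cutoff) == expected


class TestOccupancyMetrics:
    def test_fraction_within_examples(self):
        assert fraction_within([3, 5, 7], 6.0) == pytest.approx(2 / 3)
        assert fraction_within([3, 5, 7], 0.0) == 0.0
        with pytest.raises(EmptyInputError):
            fraction_within([], 6.0)

    @given(st.lists(st.floats(0.0, 50.0), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_fraction_monotone_in_cutoff(self, series):
        f4 = fraction_within(series, 4.0)
        f6 = fraction_within(series, 6.0)
        f20 = fraction_within(series, 20.0)
        assert 0.0 <= f4 <= f6 <= f20 <= 1.0

    def test_capped_mean_examples(self):
        assert capped_mean_distance([4, 6, 12], 10.0) == (5.0, 2)
        vals = [2.0, 3.0, 4.0]
        mean, n = capped_mean_distance(vals, 10.0)
        assert mean == pytest.approx(np.mean(vals)) and n == 3
        mean, n = capped_mean_distance([11, 12], 10.0)
        assert np.isnan(mean) and n == 0


class TestDepartures:
    def _stepping_bundle(self, step_at=5.0, dist=30.0):
        times = np.arange(0.0, 20.0, 0.5)
        xyz = np.zeros((len(times), 3))
        xyz[times >= step_at, 0] = dist
        oxy = np.zeros((len(times), 2, 3))
        return make_bundle([("s0", 20.0, times, {"i": xyz}, {"g": oxy})])

    def test_resident_ion_never_departs(self):
        b = self._stepping_bundle(dist=0.0)
        assert detect_departures(b, "i", ScreeningConfig()) is None

    def test_step_out_detected_at_step_time(self):
        b = self._stepping_bundle(step_at=5.0, dist=30.0)
        ev = detect_departures(b, "i", ScreeningConfig())
        assert ev is not None and ev.departure_time == pytest.approx(5.0)
        assert ev.vestibule == "AP-1"

    def test_short_excursion_ignored(self):
        times = np.arange(0.0, 20.0, 0.5)
        xyz = np.zeros((len(times), 3))
        xyz[(times >= 5.0) & (times < 8.0), 0] = 30.0  # 3 ns < 5 ns dwell
        b = make_bundle([("s0", 20.0, times, {"i": xyz},
                          {"g": np.zeros((len(times), 2, 3))})])
        assert detect_departures(b, "i", ScreeningConfig()) is None


class TestPassageMask:
    def test_no_departures_is_identity(self, toy_bundle):
        table = build_distance_table(toy_bundle, 3.0)
        masked = apply_passage_mask(table, [], toy_bundle)
        pd.testing.assert_frame_equal(masked.frame, table.frame)

    def test_foreign_records_removed_after_departure(self, rng):
        b = random_bundle(rng, n_frames=5, n_ions=2, n_groups=4, n_segments=2)
        # move one group to the central vestibule: foreign for AP-1 ions
        b.groups["g0"] = CarboxylGroup("g0", 100, "ASP", "1", "CV")
        table = build_distance_table(b, 3.0)
        ev = DepartureEvent("ion0", "AP-1", departure_time=6.0)
        masked = apply_passage_mask(table, [ev], b)
        f = masked.frame
        assert not (
            (f.ion_id == "ion0") & (f.time_ns > 6.0) & (f.group_id == "g0")
        ).any()
        # brute-force row count
        t = table.frame
        removed = (
            (t.ion_id == "ion0") & (t.time_ns > 6.0) & (t.group_id == "g0")
        ).sum()
        assert len(masked) == len(table) - removed
        # untouched before departure and for home-vestibule groups
        pre = t[(t.ion_id == "ion0") & (t.time_ns <= 6.0)]
        assert pre.merge(f).shape[0] == pre.shape[0]


class TestRefineCandidates:
    def _occupancy_bundle(self, frac):
        """Ion within 6 A for `frac` of each segment's refined frames."""
        dt = 0.4
        segs = []
        for s in range(2):
            t0 = s * 20.0
            times = t0 + dt * np.arange(50)
            xyz = np.full((50, 3), 20.0)
            n_close = int(round(frac * 50))
            xyz[:n_close] = [3.0, 0.0, 0.0]
            segs.append(
                ("seg%d" % s, 20.0, times, {"i": xyz},
                 {"g": np.zeros((50, 2, 3))})
            )
        return make_bundle(segs)

    def test_above_and_below_threshold(self):
        cfg = ScreeningConfig()
        flags, cands, _ = refine_candidates(
            self._occupancy_bundle(0.15), {("i", "g")}, cfg
        )
        assert cands == {"g"}
        flags, cands, _ = refine_candidates(
            self._occupancy_bundle(0.05), {("i", "g")}, cfg
        )
        assert cands == set()

    def test_flags_monotone_in_min_fraction(self):
        b = self._occupancy_bundle(0.15)
        loose = refine_candidates(
            b, {("i", "g")}, ScreeningConfig(min_fraction=0.05)
        )[1]
        strict = refine_candidates(
            b, {("i", "g")}, ScreeningConfig(min_fraction=0.5)
        )[1]
        assert strict <= loose

    def test_unknown_pair_rejected(self, toy_bundle):
        with pytest.raises(UnknownPairError):
            refine_candidates(toy_bundle, {("nope", "g0")}, ScreeningConfig())


class TestClassifyInitialSites:
    def _bundle(self, ion_pos):
        times = [0.0, 1.0]
        inner = np.broadcast_to(np.array([[0.0, 0, 0], [0.0, 0, 0]]), (2, 2, 3))
        outer = np.broadcast_to(np.array([[10.0, 0, 0], [10.0, 0, 0]]), (2, 2, 3))
        ions = {"i": IonTrack("i", "AP-1", "inner_AP")}
        groups = {
            "gin": CarboxylGroup("gin", 1, "GLU", "1", "AP"),
            "gout": CarboxylGroup("gout", 2, "GLU", "1", "AP"),
        }
        return make_bundle(
            [("s0", 2.0, times, {"i": [ion_pos, ion_pos]},
              {"gin": inner, "gout": outer})],
            ions_meta=ions, groups_meta=groups,
        )

    def test_zero_distance_and_tie_rule(self):
        anchors = {"AP-1": {"inner": ["gin"], "outer": ["gout"]}}
        assert classify_initial_sites(self._bundle([0, 0, 0]), anchors) == {
            "i": "inner_AP"
        }
        assert classify_initial_sites(self._bundle([10, 0, 0]), anchors) == {
            "i": "outer_AP"
        }
        # equidistant -> inner by the deterministic tie rule
        assert classify_initial_sites(self._bundle([5, 0, 0]), anchors) == {
            "i": "inner_AP"
        }


class TestTimecourseAndReport:
    def test_constant_trace_and_length(self):
        times = np.arange(0.0, 10.0, 0.1)
        n = len(times)
        b = make_bundle([
            ("s0", 10.0, times, {"i": np.zeros((n, 3))},
             {"g": np.broadcast_to(np.array([[3.0, 4, 0], [3.0, 4, 0]]),
                                   (n, 2, 3))}),
        ])
        tc = distance_timecourse(b, "i", ["g"], interval=0.4)
        assert np.allclose(tc["g"]["distance"], 5.0)
        assert len(tc["g"]) == int(10.0 / 0.4)

    def test_report_fraction_ordering_and_determinism(self, rng):
        b = random_bundle(rng, n_frames=8, n_ions=2, n_groups=3, n_segments=2)
        cfg = ScreeningConfig(screen_interval=2.0, refine_interval=1.0)
        rep1 = candidate_report(b, cfg)
        rep2 = candidate_report(b, cfg)
        pd.testing.assert_frame_equal(rep1.summary, rep2.summary)
        pd.testing.assert_frame_equal(rep1.per_pairing, rep2.per_pairing)
        for _, row in rep1.per_pairing.iterrows():
            assert row["fraction_lt_4"] <= row["fraction_lt_6"] <= row["fraction_lt_20"]
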