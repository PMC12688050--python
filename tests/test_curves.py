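"""Cumulative exposure curves, window rates, plateau rule, summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from excurves.curves import (
    WindowRate,
    class_mean_curve,
    curve_from_topic_stream,
    detect_plateau,
    pgy_exposure_summary,
    window_rates,
)
from excurves.simulate import plateau_topic_stream

# strategy: a stream of (day, topic-set) pairs
stream_strategy = st.lists(
    st.tuples(
        st.integers(min_value=0, max_value=400),
        st.sets(st.sampled_from([f"t{i}" for i in range(30)]), min_size=0, max_size=5),
    ),
    min_size=1,
    max_size=60,
)


def brute_force_cumulative(stream):
    """Union scan oracle."""
    out = []
    seen = set()
    for day, topics in sorted(stream, key=lambda x: x[0]):
        seen = seen | topics
        out.append((day, len(seen)))
    return out


class TestBuildCurve:
    def test_overlapping_sets_union(self):
        c = curve_from_topic_stream("r", [(0, {"a", "b"}), (1, {"b", "c"})])
        assert [v for _, v in c.cumulative] == [2, 3]

    def test_repeated_single_topic_stays_flat(self):
        c = curve_from_topic_stream("r", [(d, {"a"}) for d in range(5)])
        assert [v for _, v in c.cumulative] == [1, 1, 1, 1, 1]

    @given(stream_strategy)
    def test_matches_brute_force_union_scan(self, stream):
        c = curve_from_topic_stream("r", stream)
        assert c.cumulative == brute_force_cumulative(stream)

    @given(stream_strategy)
    def test_cumulative_is_monotone_nondecreasing(self, stream):
        c = curve_from_topic_stream("r", stream)
        vals = [v for _, v in c.cumulative]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_from_attribution_tables(self, small_cohort, vocabulary):
        """Curve built through the attribution path equals the stream path."""
        from excurves.attribution import attribute
        from excurves.curves import build_curve
        from excurves.model import training_day
        from excurves.notemap import map_notes

        catalog, lexicon, crosswalk = vocabulary
        data = small_cohort
        attr = attribute(data.team_events, data.shifts, data.residents)
        topics = map_notes(data.notes, lexicon, crosswalk)
        res = data.residents[0]
        c = build_curve(res, attr, data.encounters, topics)
        mine = attr[attr["resident_id"] == res.resident_id]
        arr = data.encounters.set_index("encounter_id")["arrival_time"]
        stream = [
            (training_day(res, arr.loc[e]), topics.get(e, set()))
            for e in mine["encounter_id"]
        ]
        oracle = curve_from_topic_stream(res.resident_id, stream)
        assert c.cumulative == oracle.cumulative


class TestWindowRates:
    def test_rate_per_100_patients(self):
        stream = [(d, set()) for d in range(25)] + [(0, {"a"}), (1, {"b"})]
        c = curve_from_topic_stream("r", stream)
        [w] = window_rates(c, window_days=30, step_days=30)
        assert w.n_patients == 27 and w.n_new_topics == 2
        assert w.rate == pytest.approx(100 * 2 / 27)

    def test_empty_window_is_undefined_not_zero(self):
        c = curve_from_topic_stream("r", [(0, {"a"}), (70, {"b"})])
        rates = window_rates(c, 30, 30)
        assert not rates[1].defined and np.isnan(rates[1].rate)
        assert rates[0].defined and rates[2].defined

    @given(stream_strategy)
    def test_matches_per_window_recount(self, stream):
        c = curve_from_topic_stream("r", stream)
        rates = window_rates(c, 30, 30)
        # oracle: recount first exposures and patients per window directly
        first = {}
        for day, topics in sorted(stream, key=lambda x: x[0]):
            for t in topics:
                first.setdefault(t, day)
        for w in rates:
            n_pat = sum(1 for d, _ in stream if w.start_day <= d < w.end_day)
            n_new = sum(1 for d in first.values() if w.start_day <= d < w.end_day)
            assert (w.n_patients, w.n_new_topics) == (n_pat, n_new)

    @given(stream_strategy)
    def test_tiling_windows_conserve_total_topics(self, stream):
        c = curve_from_topic_stream("r", stream)
        rates = window_rates(c, 30, 30)
        assert sum(w.n_new_topics for w in rates) == c.total_topics


def make_rates(values):
    out = []
    for i, v in enumerate(values):
        defined = v is not None
        out.append(
            WindowRate(i, 30 * i, 30 * (i + 1), 100 if defined else 0,
                       int(v) if defined else 0, v if defined else float("nan"), defined)
        )
    return out


class TestDetectPlateau:
    def test_plateau_starts_at_first_window_of_run(self):
        pl = detect_plateau(make_rates([12, 0, 0, 0]))
        assert pl.plateau_day == 30 and pl.plateau_month == 1.0

    def test_threshold_is_strict(self):
        pl = detect_plateau(make_rates([0.9, 1.0, 0.9, 0.9, 0.9]))
        assert pl.plateau_day == 60  # the 1.0 window does not qualify

    def test_no_plateau_when_rates_stay_high(self):
        pl = detect_plateau(make_rates([5, 2, 1.0, 1.5]))
        assert pl.plateau_day is None and pl.plateau_month is None

    def test_undefined_windows_break_runs(self):
        pl = detect_plateau(make_rates([0.5, 0.5, None, 0.5, 0.5, 0.5]))
        assert pl.plateau_day == 90

    def test_encounters_before_plateau_counted(self):
        stream = [(d, {"a"} if d == 0 else set()) for d in range(120)]
        c = curve_from_topic_stream("r", stream)
        rates = window_rates(c, 30, 30)
        pl = detect_plateau(rates, curve=c)
        # window 0 holds the only new topic (rate 3.3); the run starts at window 1
        assert pl.plateau_day == 30
        assert pl.encounters_before_plateau == 30

    def test_shuffling_events_after_plateau_never_moves_it_earlier(self):
        rng = np.random.default_rng(4)
        stream = plateau_topic_stream(300, seed=9)
        c = curve_from_topic_stream("r", stream)
        pl = detect_plateau(window_rates(c), curve=c)
        assert pl.plateau_day is not None
        post = [(d, t) for d, t in stream if d >= pl.plateau_day]
        days = [d for d, _ in post]
        for _ in range(5):
            perm = rng.permutation(len(post))
            shuffled = [(days[i], post[int(j)][1]) for i, j in enumerate(perm)]
            stream2 = [(d, t) for d, t in stream if d < pl.plateau_day] + shuffled
            c2 = curve_from_topic_stream("r", stream2)
            pl2 = detect_plateau(window_rates(c2), curve=c2)
            assert pl2.plateau_day is not None
            assert pl2.plateau_day >= pl.plateau_day

    @pytest.mark.parametrize("stop_day", [300, 600, 900])
    def test_recovers_generator_stop_day(self, stop_day):
        for seed in range(5):
            stream = plateau_topic_stream(stop_day, seed=seed)
            c = curve_from_topic_stream("r", stream)
            pl = detect_plateau(window_rates(c), curve=c)
            assert pl.plateau_day is not None
            assert abs(pl.plateau_day - stop_day) <= 30


class TestPgySummary:
    def test_cumulative_and_new_per_year(self):
        stream = [(0, {f"t{i}" for i in range(10)}), (400, {"t100", "t101"})]
        c = curve_from_topic_stream("r", stream)
        tbl = pgy_exposure_summary([c], catalog_size=895)
        assert tbl.loc[1, "cumulative_mean"] == 10
        assert tbl.loc[2, "cumulative_mean"] == 12
        assert list(tbl["new_mean"]) == [10, 2, 0, 0]

    def test_percent_of_catalog_rounded_to_one_decimal(self):
        c1 = curve_from_topic_stream("a", [(0, {f"t{i}" for i in range(565)})])
        c2 = curve_from_topic_stream("b", [(0, {f"t{i}" for i in range(567)})])
        tbl = pgy_exposure_summary([c1, c2], catalog_size=895)
        assert tbl.loc[4, "cumulative_mean"] == 566.0
        assert tbl.loc[4, "pct_of_catalog"] == 63.2

    def test_residents_without_events_excluded(self):
        c1 = curve_from_topic_stream("a", [(0, {"x"})])
        c_empty = curve_from_topic_stream("b", [])
        tbl = pgy_exposure_summary([c1, c_empty], catalog_size=10)
        assert tbl.loc[1, "n_residents"] == 1


class TestClassMeanCurve:
    def test_single_resident_identity(self):
        c = curve_from_topic_stream("r", [(0, {"a"}), (45, {"b"}), (100, {"c"})])
        mc = class_mean_curve([c], grid_days=30)
        by_day = dict(zip(mc["day"], mc["mean_cumulative_topics"]))
        assert by_day[0] == 1 and by_day[60] == 2 and by_day[120] == 3

    def test_pointwise_average(self):
        c1 = curve_from_topic_stream("a", [(0, {"x", "y"})])
        c2 = curve_from_topic_stream("b", [(0, {"p", "q", "r", "s"})])
        mc = class_mean_curve([c1, c2], grid_days=30)
        assert mc["mean_cumulative_topics"].iloc[0] == 3.0

    @given(st.lists(stream_strategy, min_size=1, max_size=4))
    def test_monotone_and_bounded_by_catalog(self, streams):
        curves = [curve_from_topic_stream(f"r{i}", s) for i, s in enumerate(streams)]
        mc = class_mean_curve(curves, grid_days=30)
        vals = mc["mean_cumulative_topics"].to_numpy()
        assert (np.diff(vals) >= -1e-12).all()
        assert (vals <= 895).all()
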