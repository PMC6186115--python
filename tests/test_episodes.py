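"""Episode segmentation, dose-rate arithmetic and classification rules."""

import itertools

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from haeclaims.episodes import (
    DIFFERENT_C1INH,
    EpisodeConfig,
    ON_DEMAND,
    PROPHYLACTIC,
    SC_ON_DEMAND,
    UNCLASSIFIED,
    average_weekly_dose,
    classify_episode,
    detect_rescue,
    segment_runs,
    summarize_episodes,
)

from conftest import make_fills

BASE = pd.Timestamp("2010-01-01")


def brute_force_runs(days, gap_limit):
    """Oracle: enumerate all 2^(n-1) split patterns; exactly one is valid.

    A valid segmentation has every within-run gap <= gap_limit and every
    between-run gap > gap_limit.
    """
    days = sorted(days)
    n = len(days)
    valid = []
    for pattern in itertools.product([0, 1], repeat=max(0, n - 1)):
        runs, current = [], [days[0]]
        ok = True
        for i, split in enumerate(pattern):
            gap = days[i + 1] - days[i]
            if split:
                if gap <= gap_limit:
                    ok = False
                    break
                runs.append(current)
                current = [days[i + 1]]
            else:
                if gap > gap_limit:
                    ok = False
                    break
                current.append(days[i + 1])
        if ok:
            runs.append(current)
            valid.append(runs)
    assert len(valid) == 1, "gap rule must define a unique segmentation"
    return valid[0]


class TestSegmentRuns:
    def test_weekly_fills_form_one_run(self):
        runs = segment_runs(make_fills(range(0, 140, 7)))
        assert len(runs) == 1
        assert len(runs[0].fills) == 20

    def test_long_gap_splits_runs(self):
        runs = segment_runs(make_fills([0, 7, 14, 120, 127]))
        assert [len(r.fills) for r in runs] == [3, 2]

    def test_negative_quantity_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            segment_runs(make_fills([0, 7], iu=-5.0))

    def test_mixed_patient_stream_rejected(self):
        fills = make_fills([0], pid="p1") + make_fills([7], pid="p2")
        with pytest.raises(ValueError, match="single patient"):
            segment_runs(fills)

    @settings(max_examples=150, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=400),
                    min_size=1, max_size=10, unique=True))
    def test_matches_brute_force_oracle(self, days):
        gap_limit = 45
        runs = segment_runs(make_fills(days),
                            EpisodeConfig(continuity_gap_days=gap_limit))
        expected = brute_force_runs(days, gap_limit)
        got = [[(f[0] - BASE).days for f in r.fills] for r in runs]
        assert got == expected

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=600),
                    min_size=1, max_size=15, unique=True))
    def test_partition_property(self, days):
        """Every fill lands in exactly one run; concatenation restores input."""
        runs = segment_runs(make_fills(days))
        recovered = [(f[0] - BASE).days for r in runs for f in r.fills]
        assert recovered == sorted(days)


class TestAverageWeeklyDose:
    def test_recommended_low_end_regimen_averages_1750(self):
        # 1000 IU every 4 days: 8 fills over days 0-28, 4-day terminal coverage
        runs = segment_runs(make_fills(range(0, 32, 4), iu=1000.0, supply=4))
        run = runs[0]
        assert run.span_days == 32
        assert average_weekly_dose(run) == pytest.approx(1750.0)

    def test_single_fill_one_week_coverage(self):
        runs = segment_runs(make_fills([0], iu=1500.0, supply=None))
        assert average_weekly_dose(runs[0]) == pytest.approx(1500.0)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 300), st.floats(0, 5000)),
                    min_size=1, max_size=12,
                    unique_by=lambda t: t[0]))
    def test_day_enumeration_oracle(self, day_iu):
        """IU summed over the covered span x 7 / span equals the rule."""
        fills = [("p1", "CINRYZE", BASE + pd.Timedelta(days=d), iu, 7)
                 for d, iu in day_iu]
        runs = segment_runs(fills, EpisodeConfig(continuity_gap_days=10_000))
        assert len(runs) == 1
        run = runs[0]
        days_sorted = sorted(d for d, _ in day_iu)
        span = days_sorted[-1] + 7 - days_sorted[0]
        total = sum(iu for _, iu in day_iu)
        assert average_weekly_dose(run) == pytest.approx(total * 7 / span)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 200), min_size=2, max_size=10, unique=True),
           st.floats(min_value=1.0, max_value=2000.0))
    def test_monotone_in_dose(self, days, extra_iu):
        """Adding IU to any fill never decreases the average weekly dose."""
        runs = segment_runs(make_fills(days, iu=1000.0),
                            EpisodeConfig(continuity_gap_days=10_000))
        base_avg = average_weekly_dose(runs[0])
        boosted = make_fills(days, iu=1000.0)
        p, pr, d, q, s = boosted[0]
        boosted[0] = (p, pr, d, q + extra_iu, s)
        runs2 = segment_runs(boosted, EpisodeConfig(continuity_gap_days=10_000))
        assert average_weekly_dose(runs2[0]) >= base_avg


class TestClassifyEpisode:
    @pytest.mark.parametrize("avg_iu, span, expected", [
        (1750, 91, PROPHYLACTIC),
        (1500, 91, PROPHYLACTIC),   # inclusive threshold boundary
        (1499.9, 180, ON_DEMAND),
        (2000, 60, UNCLASSIFIED),   # below the 13-week floor
    ])
    def test_classification_rule(self, avg_iu, span, expected):
        # one fill at day 0 carrying the full dose, supply = span days
        total = avg_iu * span / 7
        fills = [("p1", "CINRYZE", BASE, total, span)]
        run = segment_runs(fills)[0]
        assert run.span_days == span
        ep = classify_episode(run)
        assert ep.classification == expected

    def test_classification_invariants_on_random_runs(self):
        import numpy as np
        rng = np.random.default_rng(5)
        for _ in range(200):
            days = np.unique(rng.integers(0, 300, size=rng.integers(1, 12)))
            fills = make_fills(days, iu=float(rng.integers(100, 3000)))
            for run in segment_runs(fills):
                ep = classify_episode(run)
                if ep.classification == PROPHYLACTIC:
                    assert run.span_days >= 91 and ep.avg_weekly_dose >= 1500
                elif ep.classification == ON_DEMAND:
                    assert run.span_days >= 91 and ep.avg_weekly_dose < 1500
                else:
                    assert run.span_days < 91


def _prophylactic_episode(pid="p1", product="CINRYZE", start=0, weeks=13):
    fills = [(pid, product, BASE + pd.Timedelta(days=start + 7 * w), 1500.0, 7)
             for w in range(weeks)]
    return classify_episode(segment_runs(fills)[0])


def _pharm(rows):
    return pd.DataFrame(rows, columns=["patient_id", "fill_date", "product",
                                       "quantity_iu", "days_supply"])


class TestDetectRescue:
    def test_icatibant_during_episode_is_sc_rescue(self):
        ep = _prophylactic_episode()
        pharm = _pharm([("p1", BASE + pd.Timedelta(days=30), "ICATIBANT", None, None)])
        detect_rescue(ep, pharm)
        assert len(ep.rescue_events) == 1
        assert ep.rescue_events[0].kind == SC_ON_DEMAND

    def test_other_c1inh_brand_is_rescue(self):
        ep = _prophylactic_episode(product="CINRYZE")
        pharm = _pharm([("p1", BASE + pd.Timedelta(days=30), "BERINERT", 1500.0, None)])
        detect_rescue(ep, pharm)
        assert [e.kind for e in ep.rescue_events] == [DIFFERENT_C1INH]

    def test_same_brand_fill_is_never_rescue(self):
        ep = _prophylactic_episode(product="CINRYZE")
        pharm = _pharm([("p1", BASE + pd.Timedelta(days=30), "CINRYZE", 1000.0, 4)])
        detect_rescue(ep, pharm)
        assert ep.rescue_events == []

    def test_fill_outside_episode_ignored(self):
        ep = _prophylactic_episode()
        pharm = _pharm([("p1", BASE + pd.Timedelta(days=500), "ICATIBANT", None, None)])
        detect_rescue(ep, pharm)
        assert ep.rescue_events == []

    def test_requires_prophylactic_episode(self):
        run = segment_runs(make_fills([0, 7]))[0]
        ep = classify_episode(run)
        assert ep.classification == UNCLASSIFIED
        with pytest.raises(ValueError, match="prophylactic"):
            detect_rescue(ep, _pharm([]))


class TestSummarize:
    def test_empty_summary_flags_undefined_stats(self):
        s = summarize_episodes([])
        assert s["n_prophylactic"] == 0
        assert s["duration_defined"] is False
        assert s["duration_mean_days"] is None

    def test_patient_may_hold_multiple_episodes_of_both_classes(self):
        # two prophylactic runs and one long low-dose run, same patient
        eps = [_prophylactic_episode(start=0), _prophylactic_episode(start=200)]
        low = [("p1", "CINRYZE", BASE + pd.Timedelta(days=500 + 30 * k), 100.0, 30)
               for k in range(5)]
        eps.append(classify_episode(segment_runs(low)[0]))
        s = summarize_episodes(eps)
        assert s["n_prophylactic"] == 2
        assert s["n_on_demand"] == 1
        assert s["n_patients_prophylactic"] == 1
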