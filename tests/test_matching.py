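"""Propensity model, greedy matching, SMD balance and RR estimation."""

import numpy as np
import pandas as pd
import pytest

from haeclaims.matching import (
    DegenerateExposureError,
    MatchedSet,
    PropensityFit,
    balance_diagnostics,
    collapse_rare_levels,
    estimate_rr,
    fit_propensity,
    match_pairs,
    standardized_mean_difference,
)


def _fit_from_scores(scores: dict) -> PropensityFit:
    s = pd.Series(scores, dtype=float)
    return PropensityFit(scores=s, coefficients=pd.Series(dtype=float),
                         converged=True)


class TestFitPropensity:
    def test_independent_exposure_scores_near_marginal_rate(self):
        rng = np.random.default_rng(1)
        n = 1000
        covars = pd.DataFrame({
            "age": rng.integers(18, 65, n).astype(float),
            "region": rng.choice(["E", "W", "S"], n)})
        exposure = pd.Series(rng.random(n) < 0.3)
        fit = fit_propensity(covars, exposure)
        p = exposure.mean()
        se = np.sqrt(p * (1 - p) / n)
        assert abs(fit.scores.mean() - p) < 3 * se
        # individual scores hover near the marginal rate
        assert fit.scores.std() < 0.1

    def test_single_binary_covariate_matches_2x2_log_odds(self):
        # x=1: 30 exposed / 70 not; x=0: 10 exposed / 90 not
        x = pd.Series([1.0] * 100 + [0.0] * 100, name="x")
        y = pd.Series([1] * 30 + [0] * 70 + [1] * 10 + [0] * 90)
        fit = fit_propensity(x.to_frame(), y)
        expected_or = (30 / 70) / (10 / 90)
        assert fit.coefficients["x"] == pytest.approx(np.log(expected_or), rel=1e-4)

    def test_all_exposed_raises(self):
        covars = pd.DataFrame({"age": [30.0, 40.0]})
        with pytest.raises(DegenerateExposureError):
            fit_propensity(covars, pd.Series([1, 1]))

    def test_rare_levels_collapse(self):
        s = pd.Series(["A"] * 50 + ["B"] * 3, name="payer")
        collapsed = collapse_rare_levels(s, min_size=5)
        assert set(collapsed.unique()) == {"A", "OTHER"}

    def test_scores_in_open_unit_interval(self):
        rng = np.random.default_rng(2)
        covars = pd.DataFrame({"age": rng.normal(40, 10, 200)})
        exposure = pd.Series(rng.random(200) < 0.2)
        fit = fit_propensity(covars, exposure)
        assert (fit.scores > 0).all() and (fit.scores < 1).all()


class TestMatchPairs:
    def test_identical_scores_all_matched_distance_zero(self):
        fit = _fit_from_scores({"e1": 0.4, "e2": 0.4, "c1": 0.4, "c2": 0.4})
        exposure = pd.Series({"e1": True, "e2": True, "c1": False, "c2": False})
        m = match_pairs(fit, exposure, seed=0)
        assert len(m.pairs) == 2 and m.unmatched_exposed == []
        assert all(d == 0 for _, _, d in m.pairs)

    def test_exposed_outside_caliper_unmatched(self):
        fit = _fit_from_scores({"e1": 0.9, "c1": 0.1, "c2": 0.12, "c3": 0.11})
        exposure = pd.Series({"e1": True, "c1": False, "c2": False, "c3": False})
        m = match_pairs(fit, exposure, seed=0)
        assert m.pairs == [] and m.unmatched_exposed == ["e1"]

    def test_greedy_trace_small_example(self):
        # greedy without replacement: first processed exposed takes the
        # globally nearest control even if a later exposed needed it
        scores = {"e1": 0.50, "e2": 0.52, "c1": 0.51, "c2": 0.80}
        fit = _fit_from_scores(scores)
        exposure = pd.Series({k: k.startswith("e") for k in scores})
        m = match_pairs(fit, exposure, seed=1, caliper=np.inf)
        # whichever exposed goes first pairs with c1; the other gets c2
        assert {p[1] for p in m.pairs} == {"c1", "c2"}
        assert len(m.pairs) == 2

    def test_deterministic_given_seed_and_control_order_invariant(self):
        rng = np.random.default_rng(7)
        ids = [f"p{i}" for i in range(40)]
        scores = pd.Series(rng.uniform(0.1, 0.9, 40), index=ids)
        exposure = pd.Series(rng.random(40) < 0.3, index=ids)
        if exposure.sum() == 0:
            exposure.iloc[0] = True
        fit1 = PropensityFit(scores, pd.Series(dtype=float), True)
        m1 = match_pairs(fit1, exposure, seed=5)
        m2 = match_pairs(fit1, exposure, seed=5)
        assert m1.pairs == m2.pairs
        # permute control order in the score index
        perm = ids[::-1]
        fit2 = PropensityFit(scores.loc[perm], pd.Series(dtype=float), True)
        m3 = match_pairs(fit2, exposure.loc[perm], seed=5)
        assert sorted(m1.pairs) == sorted(m3.pairs)

    def test_controls_used_at_most_once(self):
        fit = _fit_from_scores({"e1": 0.4, "e2": 0.41, "c1": 0.4})
        exposure = pd.Series({"e1": True, "e2": True, "c1": False})
        m = match_pairs(fit, exposure, seed=0, caliper=np.inf)
        assert len(m.pairs) == 1 and len(m.unmatched_exposed) == 1


class TestEstimateRr:
    def test_equal_rates_give_rr_one(self):
        y = pd.Series([1] * 20 + [0] * 80 + [1] * 20 + [0] * 80)
        x = pd.Series([1] * 100 + [0] * 100)
        est = estimate_rr(y, x)
        assert est.rr == pytest.approx(1.0, abs=1e-6)

    def test_crude_rr_matches_2x2_closed_form(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n1, n0 = int(rng.integers(30, 200)), int(rng.integers(30, 200))
            a = int(rng.integers(1, n1))
            b = int(rng.integers(1, n0))
            y = pd.Series([1] * a + [0] * (n1 - a) + [1] * b + [0] * (n0 - b))
            x = pd.Series([1] * n1 + [0] * n0)
            est = estimate_rr(y, x)
            assert est.rr == pytest.approx((a / n1) / (b / n0), rel=1e-6)

    def test_zero_event_arm_flagged_unstable(self):
        y = pd.Series([1] * 5 + [0] * 45 + [0] * 50)
        x = pd.Series([1] * 50 + [0] * 50)
        est = estimate_rr(y, x)
        assert est.unstable and est.method == "katz_continuity"
        assert est.ci_low <= est.rr <= est.ci_high

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="no events"):
            estimate_rr(pd.Series([0, 0]), pd.Series([1, 0]))

    def test_ci_brackets_estimate(self):
        y = pd.Series([1] * 30 + [0] * 70 + [1] * 10 + [0] * 90)
        x = pd.Series([1] * 100 + [0] * 100)
        est = estimate_rr(y, x)
        assert est.ci_low <= est.rr <= est.ci_high
        assert est.ci_low > 0


class TestBalance:
    def test_identical_groups_zero_smd(self):
        covars = pd.DataFrame({"age": [30.0, 40.0, 30.0, 40.0],
                               "region": ["E", "W", "E", "W"]})
        exposure = pd.Series([True, True, False, False])
        table = balance_diagnostics(covars, exposure)
        assert (table["smd_pre"] == 0).all()

    def test_single_covariate_hand_formula(self):
        x1 = pd.Series([1.0, 2.0, 3.0])
        x0 = pd.Series([2.0, 3.0, 4.0, 5.0])
        pooled = np.sqrt((x1.var(ddof=1) + x0.var(ddof=1)) / 2)
        assert standardized_mean_difference(x1, x0) == pytest.approx(
            (x1.mean() - x0.mean()) / pooled)

    def test_matching_reduces_imbalance_on_confounded_data(self):
        improved = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 600
            age = rng.normal(40, 12, n)
            cci = rng.poisson(0.5, n).astype(float)
            logit = -3.5 + 0.05 * (age - 40) + 0.8 * cci
            exposure = pd.Series(rng.random(n) < 1 / (1 + np.exp(-logit)))
            if exposure.sum() < 5:
                continue
            covars = pd.DataFrame({"age": age, "cci": cci})
            fit = fit_propensity(covars, exposure)
            matched = match_pairs(fit, exposure, seed=seed)
            table = balance_diagnostics(covars, exposure, matched)
            if table["smd_post"].abs().mean() < table["smd_pre"].abs().mean():
                improved += 1
        assert improved >= 8  # balance improves in nearly every replicate
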