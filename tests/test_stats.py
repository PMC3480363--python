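"""Rating-scale scoring, LOCF, paired changes, regressions, completion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import attentrain as at
from attentrain import stats


def _table(rows):
    return pd.DataFrame(rows, columns=["subject_id", "week", "IA", "HI", "COM"])


class TestScoreItems:
    def test_all_zero(self):
        assert at.score_items([0] * 18) == (0, 0, 0)

    def test_scale_maxima(self):
        assert at.score_items([3] * 18) == (27, 27, 54)

    def test_alternating_matches_bruteforce(self):
        items = [1, 2] * 9
        ia, hi, com = at.score_items(items)
        assert ia == sum(items[:9])
        assert hi == sum(items[9:])
        assert com == ia + hi

    @given(st.lists(st.integers(0, 3), min_size=18, max_size=18))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_random_items_match_bruteforce(self, items):
        ia, hi, com = at.score_items(items)
        assert (ia, hi, com) == (sum(items[:9]), sum(items[9:]), sum(items))

    def test_invalid_items_rejected(self):
        with pytest.raises(ValueError):
            at.score_items([0] * 17)
        with pytest.raises(ValueError):
            at.score_items([0] * 17 + [4])


class TestLOCF:
    def test_complete_table_unchanged(self):
        rows = [("A", w, 10, 8, 18) for w in (0, 4, 8, 20, 24)]
        rows += [("B", w, 20, 15, 35) for w in (0, 4, 8, 20, 24)]
        out = at.locf(_table(rows))
        assert len(out) == 10
        assert (out[out["subject_id"] == "A"]["IA"] == 10).all()

    def test_fills_from_most_recent_earlier_week(self):
        rows = [("A", 0, 10, 8, 18), ("A", 8, 6, 5, 11)]
        rows += [("B", w, 20, 15, 35) for w in (0, 4, 8, 20, 24)]
        out = at.locf(_table(rows))
        a = out[out["subject_id"] == "A"].set_index("week")
        assert a.loc[20, "IA"] == 6 and a.loc[24, "IA"] == 6
        assert a.loc[4, "IA"] == 10  # carried forward from baseline
        assert a.loc[8, "IA"] == 6   # observed value never altered

    def test_no_followup_subject_dropped_when_flagged(self):
        rows = [("A", 0, 10, 8, 18)]
        rows += [("B", w, 20, 15, 35) for w in (0, 8)]
        out = at.locf(_table(rows), drop_no_followup=True)
        assert set(out["subject_id"]) == {"B"}
        kept = at.locf(_table(rows), drop_no_followup=False)
        assert set(kept["subject_id"]) == {"A", "B"}

    def test_missing_baseline_warns_and_drops(self):
        rows = [("A", 8, 10, 8, 18)]
        rows += [("B", w, 20, 15, 35) for w in (0, 8)]
        with pytest.warns(UserWarning, match="baseline"):
            out = at.locf(_table(rows))
        assert set(out["subject_id"]) == {"B"}

    def test_fills_come_from_strictly_earlier_weeks(self):
        ratings, _ = at.simulate_trial(at.TrialSimConfig(n_subjects=30, seed=2))
        out = at.locf(ratings)
        obs = ratings.set_index(["subject_id", "week"])
        for _, row in out.iterrows():
            key = (row["subject_id"], row["week"])
            if key in obs.index:
                assert row["IA"] == obs.loc[key, "IA"]  # observed untouched


class TestMeanChange:
    def test_identical_columns_degenerate(self):
        rows = [(f"S{i}", w, 10, 8, 18) for i in range(5) for w in (0, 8)]
        cs = at.mean_change(_table(rows), "IA", 0, 8)
        assert cs.mean_change == 0.0
        assert cs.degenerate and cs.p_value == 1.0

    def test_mean_of_diffs_equals_diff_of_means(self, rng):
        rows = []
        for i in range(40):
            a, b = rng.integers(0, 28, size=2)
            rows.append((f"S{i}", 0, a, 0, a))
            rows.append((f"S{i}", 8, b, 0, b))
        tbl = _table(rows)
        cs = at.mean_change(tbl, "IA", 0, 8)
        group_diff = (tbl[tbl.week == 8]["IA"].mean()
                      - tbl[tbl.week == 0]["IA"].mean())
        assert cs.mean_change == pytest.approx(group_diff, abs=1e-12)

    def test_known_shift_recovered(self):
        cfg = at.TrialSimConfig(n_subjects=200, effect_slope=0.0,
                                change_intercept={"IA": -5.0, "HI": -5.0},
                                residual_sd=3.0, dropout_times={}, seed=8)
        ratings, _ = at.simulate_trial(cfg)
        cs = at.mean_change(ratings, "IA", 0, 8)
        assert cs.mean_change == pytest.approx(-5.0, abs=0.5)

    def test_too_few_pairs_rejected(self):
        rows = [("A", 0, 10, 8, 18), ("A", 8, 9, 8, 17)]
        with pytest.raises(ValueError):
            at.mean_change(_table(rows), "IA", 0, 8)


class TestBaselinePredictsChange:
    def test_perfect_linear_relation_exact(self):
        rows = []
        for i, base in enumerate(range(4, 26, 2)):  # even, so 0.5*base is exact
            rows.append((f"S{i}", 0, base, 0, base))
            rows.append((f"S{i}", 8, round(base + 3 - 0.5 * base), 0, 0))
        beta, se, _ = at.baseline_predicts_change(_table(rows), "IA")
        assert beta == pytest.approx(-0.5, abs=1e-9)
        assert se == pytest.approx(0.0, abs=1e-9)

    def test_null_slope_type_one_behaviour(self):
        hits = 0
        for seed in range(100):
            cfg = at.TrialSimConfig(n_subjects=50, effect_slope=0.0,
                                    change_intercept={"IA": -4.0, "HI": -4.0},
                                    residual_sd=3.0, dropout_times={},
                                    seed=seed)
            ratings, _ = at.simulate_trial(cfg)
            beta, se, _ = at.baseline_predicts_change(ratings, "IA")
            hits += abs(beta) < 2 * se
        assert hits >= 90

    def test_zero_baseline_variance_rejected(self):
        rows = [(f"S{i}", w, 10, 8, 18) for i in range(5) for w in (0, 8)]
        with pytest.raises(ValueError):
            at.baseline_predicts_change(_table(rows), "IA")


class TestBASMChangeCorrelation:
    def test_strictly_decreasing_relation_rho_minus_one(self):
        rows, brows = [], []
        for i in range(6):
            rows.append((f"S{i}", 0, 20, 10, 30))
            rows.append((f"S{i}", 20, 20 - i, 10, 30 - i))
            brows.append({"subject_id": f"S{i}", "week": 0, "basm": 50.0})
            brows.append({"subject_id": f"S{i}", "week": 20,
                          "basm": 50.0 + 10.0 * i})
        rho, _ = at.basm_change_correlation(_table(rows), pd.DataFrame(brows),
                                            "IA")
        assert rho == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        rows, brows = [], []
        for i in range(6):
            rows.append((f"S{i}", 0, 20, 10, 30))
            rows.append((f"S{i}", 20, 15, 10, 25))
            brows.append({"subject_id": f"S{i}", "week": 0, "basm": 50.0})
            brows.append({"subject_id": f"S{i}", "week": 20, "basm": 40.0 + i})
        with pytest.raises(ValueError):
            at.basm_change_correlation(_table(rows), pd.DataFrame(brows), "IA")

    def test_permuted_pairing_consistent_with_null(self, rng):
        cfg = at.TrialSimConfig(n_subjects=60, dropout_times={}, seed=3)
        ratings, basm = at.simulate_trial(cfg)
        rho_obs, _ = at.basm_change_correlation(ratings, basm, "COM")
        subjects = basm["subject_id"].unique()
        null = []
        for _ in range(200):
            perm = dict(zip(subjects, rng.permutation(subjects)))
            shuffled = basm.assign(subject_id=basm["subject_id"].map(perm))
            null.append(at.basm_change_correlation(ratings, shuffled, "COM")[0])
        assert abs(rho_obs) > np.quantile(np.abs(null), 0.95)


class TestCompletionSummary:
    def test_study_disposition(self):
        disposition = {f"S{i}": None for i in range(17)}
        disposition.update({"S17": 2.0, "S18": 6.0, "S19": 6.0})
        assert at.completion_summary(disposition) == (20, 17, 85.0)

    def test_no_dropouts(self):
        assert at.completion_summary({"a": None, "b": None}) == (2, 2, 100.0)

    def test_all_drop_out(self):
        assert at.completion_summary({"a": 4.0, "b": 8.0}) == (2, 0, 0.0)


class TestVisitSummary:
    def test_table_layout_and_values(self):
        rows = [("A", 0, 10, 8, 18), ("A", 8, 6, 5, 11),
                ("B", 0, 20, 16, 36), ("B", 8, 12, 9, 21)]
        summary = stats.visit_summary(_table(rows), weeks=(0, 8))
        ia0 = summary[(summary.week == 0) & (summary.subscale == "IA")].iloc[0]
        assert ia0["n"] == 2 and ia0["mean"] == 15.0

    def test_mcmc_stub_raises(self):
        with pytest.raises(NotImplementedError):
            stats.impute_mcmc(_table([("A", 0, 1, 1, 2)]))
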