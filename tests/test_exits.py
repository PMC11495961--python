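import numpy as np
import pandas as pd
import pytest

from peristartle import annotation_agreement, score_exits
from peristartle.exits import test_exit_status_effect as exit_status_effect
from peristartle.cleaning import compute_body_metrics
from peristartle.exceptions import (
    EmptyComparisonError,
    EmptyGroupError,
    InsufficientClustersError,
)
from peristartle.exits import score_dataset_exits

from conftest import empty_exits, events_frame, track_from_beak
from oracles import naive_permutation_p


def exits_frame(rows):
    return pd.DataFrame(rows, columns=["bout_id", "frame"])


class TestScoreExits:
    def two_element_bout(self):
        return events_frame(
            [("b0", "mock_attack", "high", "duration", 100, 20),
             ("b0", "body_ripple", "high", "duration", 300, 20)]
        )

    def test_no_exits_all_zero(self):
        scored = score_exits(self.two_element_bout(), empty_exits())
        assert list(scored["outcome"]) == [0, 0]

    def test_exit_attributed_to_most_recent_preceding_element(self):
        scored = score_exits(self.two_element_bout(), exits_frame([("b0", 150)]))
        assert list(scored["outcome"]) == [1, 0]

    def test_exit_before_any_element_unattributed(self):
        scored = score_exits(self.two_element_bout(), exits_frame([("b0", 50)]))
        assert list(scored["outcome"]) == [0, 0]

    def test_max_lag_limits_attribution(self):
        scored = score_exits(
            self.two_element_bout(), exits_frame([("b0", 150)]), max_lag=30
        )
        assert list(scored["outcome"]) == [0, 0]

    def test_each_exit_attributed_at_most_once(self):
        events = events_frame(
            [("b0", "mock_attack", "high", "duration", 10, 5),
             ("b0", "head_bob", "low", "event", 50, 1),
             ("b0", "body_ripple", "high", "duration", 90, 5)]
        )
        exits = exits_frame([("b0", 55), ("b0", 95), ("b0", 97)])
        scored = score_exits(events, exits, class_filter=None)
        # 3 exits, but only 2 elements ever score 1
        assert scored["outcome"].sum() <= len(exits)
        assert list(scored["outcome"]) == [0, 1, 1]

    def test_class_filter_restricts_rows(self):
        events = events_frame(
            [("b0", "mock_attack", "high", "duration", 10, 5),
             ("b0", "head_bob", "low", "event", 50, 1)]
        )
        scored = score_exits(events, empty_exits(), class_filter="high")
        assert list(scored["element_type"]) == ["mock_attack"]

    def test_dataset_join_carries_status(self, small_dataset):
        scored = score_dataset_exits(small_dataset)
        assert {"male_id", "status", "date", "outcome"} <= set(scored.columns)
        assert (scored["intensity_class"] == "high").all()


def outcome_table(per_male):
    """per_male: list of (male_id, status, n_elements, n_exits)."""
    rows = []
    for male, status, n, k in per_male:
        for i in range(n):
            rows.append({"male_id": male, "status": status,
                         "date": "2018-09-01", "outcome": 1 if i < k else 0})
    return pd.DataFrame(rows)


class TestExitStatusEffect:
    def test_identical_groups_give_p_one(self):
        table = outcome_table(
            [(f"o{i}", "owner", 10, 3) for i in range(3)]
            + [(f"s{i}", "subordinate", 10, 3) for i in range(3)]
        )
        result = exit_status_effect(table)
        assert result.statistic == 0.0
        assert result.p_value == 1.0

    def test_exhaustive_matches_enumeration_oracle(self):
        """5 owners at 0/10 vs 5 subordinates at 5/10: the permutation p
        equals the exhaustive value over all 252 label assignments."""
        table = outcome_table(
            [(f"o{i}", "owner", 10, 0) for i in range(5)]
            + [(f"s{i}", "subordinate", 10, 5) for i in range(5)]
        )
        result = exit_status_effect(table)
        assert result.exhaustive and result.n_permutations == 252
        proportions = [0.0] * 5 + [0.5] * 5
        assert result.p_value == pytest.approx(naive_permutation_p(proportions, 5))
        # all-or-nothing separation: only the two extreme assignments match
        assert result.p_value == pytest.approx(2 / 252)

    def test_invariant_to_male_relabelling(self):
        table = outcome_table(
            [("a", "owner", 8, 1), ("b", "owner", 6, 2), ("c", "owner", 9, 0),
             ("d", "subordinate", 7, 3), ("e", "subordinate", 5, 2),
             ("f", "subordinate", 8, 4)]
        )
        renamed = table.copy()
        renamed["male_id"] = renamed["male_id"].map(lambda s: "x" + s[::-1])
        r1 = exit_status_effect(table)
        r2 = exit_status_effect(renamed)
        assert r1.p_value == r2.p_value
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_too_few_clusters_rejected(self):
        table = outcome_table(
            [("a", "owner", 5, 1), ("d", "subordinate", 5, 1),
             ("e", "subordinate", 5, 2)]
        )
        with pytest.raises(InsufficientClustersError):
            exit_status_effect(table)

    def test_missing_group_rejected(self):
        table = outcome_table([("a", "owner", 5, 1), ("b", "owner", 5, 2)])
        with pytest.raises(EmptyGroupError):
            exit_status_effect(table)

    def test_calibrated_under_equal_exit_probability(self):
        """With equal per-element exit probability in both groups the
        permutation test rejects at roughly the nominal 5% rate."""
        rng = np.random.default_rng(15)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            table = outcome_table(
                [(f"o{i}", "owner", int(rng.integers(5, 15)),
                  int(rng.binomial(10, 0.3))) for i in range(5)]
                + [(f"s{i}", "subordinate", int(rng.integers(5, 15)),
                    int(rng.binomial(10, 0.3))) for i in range(5)]
            )
            # regenerate outcomes properly per male element count
            rows = []
            for male, group in table.groupby("male_id"):
                n = len(group)
                outcomes = rng.random(n) < 0.3
                sub = group.copy()
                sub["outcome"] = outcomes.astype(int)
                rows.append(sub)
            table = pd.concat(rows, ignore_index=True)
            if exit_status_effect(table).p_value < 0.05:
                rejections += 1
        rate = rejections / n_sim
        # permutation tests on 252 assignments are discrete, hence
        # conservative; allow the band to extend below nominal
        assert 0.0 <= rate <= 0.08

    def test_mixed_model_contract(self):
        """The lme4-backed GLMM variant returns a valid likelihood-ratio
        test for the status fixed effect."""
        rng = np.random.default_rng(1)
        rows = []
        for i in range(6):
            for status, male in (("owner", f"o{i}"), ("subordinate", f"s{i}")):
                p = 0.2 if status == "owner" else 0.5
                for j in range(12):
                    rows.append({"male_id": male, "status": status,
                                 "date": f"2018-09-{(j % 3) + 1:02d}",
                                 "outcome": int(rng.random() < p)})
        result = exit_status_effect(pd.DataFrame(rows), method="mixed_model")
        assert result.df == 1
        assert result.chi2 >= 0.0
        assert 0.0 < result.p_value <= 1.0


class TestAnnotationAgreement:
    def auto_track(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        beak = [(float(x), float(y)) for x, y in rng.uniform(100, 200, (n, 2))]
        return track_from_beak("b0", beak)

    def test_identical_tracks_agree_perfectly(self):
        auto = self.auto_track()
        metrics = compute_body_metrics(auto)
        stats = annotation_agreement(auto, auto.copy(), metrics)
        assert np.allclose(stats["mean_error_px"], 0.0)
        assert np.allclose(stats["r_x"].dropna(), 1.0)

    def test_constant_offset_gives_hand_computed_error(self):
        auto = self.auto_track()
        manual = auto.copy()
        manual["x"] += 3.0
        manual["y"] += 4.0
        metrics = compute_body_metrics(auto)
        stats = annotation_agreement(auto, manual, metrics)
        assert np.allclose(stats["mean_error_px"], 5.0)
        assert np.allclose(stats["sd_error_px"], 0.0)
        # body-height fractions are exactly pixel errors / mean height
        np.testing.assert_allclose(
            stats["mean_error_bh"], stats["mean_error_px"] / 100.0
        )

    def test_shuffled_manual_destroys_correlation(self):
        auto = self.auto_track(n=200, seed=5)
        manual = auto.copy()
        beak = manual["keypoint"] == "beak_tip"
        rng = np.random.default_rng(6)
        manual.loc[beak, "y"] = rng.permutation(manual.loc[beak, "y"].to_numpy())
        metrics = compute_body_metrics(auto)
        stats = annotation_agreement(auto, manual, metrics).set_index("keypoint")
        assert abs(stats.loc["beak_tip", "r_y"]) < 0.2
        assert stats.loc["beak_tip", "n_frames"] == 200

    def test_disjoint_tracks_rejected(self):
        auto = self.auto_track(n=5)
        manual = auto.copy()
        manual["bout_id"] = "other"
        with pytest.raises(EmptyComparisonError):
            annotation_agreement(auto, manual, compute_body_metrics(auto))
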