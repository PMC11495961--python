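import numpy as np
import pandas as pd
import pytest

from peristartle import (
    InferenceConfig,
    SimulationConfig,
    WindowSpec,
    assemble_dataset,
    bootstrap_null,
    empirical_p,
    leave_one_out,
    simulate_dataset,
    window_sweep,
)
from peristartle.exceptions import EmptyGroupError, ParameterError
from peristartle.inference import eligible_frames
from peristartle.kinematics import RDSeries

from conftest import empty_exits, events_frame, metadata_for, track_from_beak
from oracles import naive_delta, naive_eligible, naive_exhaustive_null, naive_rd


def rd_map_of(values, bout_id="b0"):
    arr = np.asarray(values, dtype=float)
    return {bout_id: RDSeries(bout_id, arr, np.isfinite(arr))}


def male_of_bout(bouts, male="m1"):
    return pd.Series({b: male for b in bouts})


class TestEligibleFrames:
    def test_boundary_enumeration_30_frame_bout(self):
        """30 fully tracked frames, baseline 10 / post 10: frames 10–20
        are the only ones whose whole window fits with rd defined."""
        values = [np.nan] + [0.1] * 29
        out = eligible_frames(rd_map_of(values), WindowSpec(10, 10), male_of_bout(["b0"]))
        assert [f for _, f in out["m1"]] == list(range(10, 21))

    def test_window_larger_than_bout(self):
        values = [np.nan] + [0.1] * 19
        out = eligible_frames(rd_map_of(values), WindowSpec(10, 30), male_of_bout(["b0"]))
        assert out["m1"] == []

    def test_missing_value_removes_exactly_covering_windows(self):
        rng = np.random.default_rng(2)
        values = [np.nan] + list(rng.exponential(0.05, 99))
        values[40] = np.nan
        out = eligible_frames(rd_map_of(values), WindowSpec(6, 8), male_of_bout(["b0"]))
        naive = naive_eligible(
            [None if (isinstance(v, float) and np.isnan(v)) else v for v in values], 6, 8
        )
        assert [f for _, f in out["m1"]] == naive
        # the hole removes windows covering frame 40 and nothing else
        assert all(not (t - 5 <= 40 <= t + 7) for _, t in out["m1"])


class TestEmpiricalP:
    def test_observed_beats_all_999(self):
        null = np.arange(999) / 1000.0
        assert empirical_p(2.0, null) == pytest.approx(0.002)

    def test_observed_at_median_capped_at_one(self):
        null = np.linspace(-1, 1, 999)
        assert empirical_p(0.0, null) == 1.0

    def test_upper_tail_capped_when_observed_below_all(self):
        null = np.linspace(1, 2, 500)
        assert empirical_p(0.0, null, tail="upper") == 1.0
        assert empirical_p(0.0, null, tail="lower") == pytest.approx(1 / 501)

    def test_empty_null_rejected(self):
        with pytest.raises(ParameterError):
            empirical_p(0.0, np.array([]))


def single_male_dataset(beak_x, events, n=None):
    """One owner, one bout; beak moves along x as given."""
    beak = [(float(x), 0.0) for x in beak_x]
    tracks = track_from_beak("b0", beak)
    return assemble_dataset(
        tracks, metadata_for(["b0"]), events_frame(events), empty_exits()
    )


class TestBootstrapNull:
    def test_zero_signal_gives_p_one(self):
        dataset = single_male_dataset(
            [50.0] * 60, [("b0", "mock_attack", "high", "duration", 20, 5),
                          ("b0", "body_ripple", "high", "duration", 35, 5)]
        )
        null = bootstrap_null(
            dataset, "owner", "high", WindowSpec(10, 10),
            InferenceConfig(reps=100, seed=0),
        )
        assert null.observed == 0.0
        assert np.allclose(null.replicates, 0.0)
        assert null.p_value == 1.0
        assert not null.significant

    def test_exhaustive_matches_enumeration_oracle(self):
        """1 male, 12 eligible frames, 2 elements: the exhaustive null
        is exactly the 78 unordered with-replacement frame pairs."""
        rng = np.random.default_rng(12)
        beak_x = np.cumsum(rng.normal(0, 3.0, 31)) + 300
        dataset = single_male_dataset(
            beak_x, [("b0", "mock_attack", "high", "duration", 12, 3),
                     ("b0", "body_ripple", "high", "duration", 18, 3)]
        )
        null = bootstrap_null(
            dataset, "owner", "high", WindowSpec(10, 10),
            InferenceConfig(method="exhaustive"),
        )
        # independent reconstruction with naive loops
        beak = [(float(x), 0.0) for x in beak_x]
        rd = naive_rd(beak, 100.0)
        frames = naive_eligible(rd, 10, 10)
        assert len(frames) == 12
        values = [naive_delta(rd, t, 10, 10)[0] for t in frames]
        expected = naive_exhaustive_null([(values, 2)])
        assert len(null.replicates) == 78
        np.testing.assert_allclose(
            np.sort(null.replicates), np.sort(expected), atol=1e-12
        )
        # observed statistic: mean of the two element deltas
        obs = np.mean([naive_delta(rd, 12, 10, 10)[0], naive_delta(rd, 18, 10, 10)[0]])
        assert null.observed == pytest.approx(obs, abs=1e-12)

    def test_monte_carlo_approaches_exhaustive_quantiles(self):
        rng = np.random.default_rng(12)
        beak_x = np.cumsum(rng.normal(0, 3.0, 31)) + 300
        events = [("b0", "mock_attack", "high", "duration", 12, 3),
                  ("b0", "body_ripple", "high", "duration", 18, 3)]
        dataset = single_male_dataset(beak_x, events)
        window = WindowSpec(10, 10)
        exact = bootstrap_null(
            dataset, "owner", "high", window, InferenceConfig(method="exhaustive")
        )
        reps = 78 * 20
        mc = bootstrap_null(
            dataset, "owner", "high", window, InferenceConfig(reps=reps, seed=3)
        )
        tol = 1.0 / np.sqrt(reps)
        for q in (0.025, 0.25, 0.5, 0.75, 0.975):
            assert abs(
                np.quantile(mc.replicates, q) - np.quantile(exact.replicates, q)
            ) < tol

    def test_seed_determinism(self, small_dataset):
        config = InferenceConfig(reps=50, seed=77)
        a = bootstrap_null(small_dataset, "owner", "high", WindowSpec(10, 10), config)
        b = bootstrap_null(small_dataset, "owner", "high", WindowSpec(10, 10), config)
        np.testing.assert_array_equal(a.replicates, b.replicates)
        assert a.p_value == b.p_value

    def test_empty_group_errors(self, small_dataset):
        with pytest.raises(EmptyGroupError):
            bootstrap_null(
                small_dataset, "owner", "high", WindowSpec(10, 10),
                InferenceConfig(reps=10), exclude_males=tuple(
                    small_dataset.males_with_status("owner")
                ),
            )

    def test_balance_class_override_sets_draw_counts(self, small_dataset):
        config = InferenceConfig(reps=20, seed=1)
        default = bootstrap_null(
            small_dataset, "owner", "low", WindowSpec(10, 10), config
        )
        overridden = bootstrap_null(
            small_dataset, "owner", "low", WindowSpec(10, 10), config,
            balance_class="high",
        )
        low_counts = default.individuals.set_index("male_id")["n_draw"]
        high_counts = overridden.individuals.set_index("male_id")["n_draw"]
        assert not low_counts.equals(high_counts)
        summary = small_dataset.summary().set_index("male_id")
        for male, n in high_counts.items():
            assert n <= summary.loc[male, "n_high"]


class TestSweep:
    def test_default_grid_shape(self):
        config = InferenceConfig()
        assert len(config.post_sizes) == 47  # post sizes 4..50
        assert config.post_sizes[0] == 4 and config.post_sizes[-1] == 50
        assert config.baseline_sizes == (5, 10, 15, 20)

    def test_sweep_row_count_and_flags(self, small_dataset):
        config = InferenceConfig(
            reps=40, post_sizes=(4, 6, 8), baseline_sizes=(5, 10), seed=4
        )
        result = window_sweep(small_dataset, config, classes=("high",))
        assert len(result.table) == 3 * 2 * 2  # post x baseline x status
        sig = result.table["significant"]
        outside = (result.table["observed"] < result.table["q025"]) | (
            result.table["observed"] > result.table["q975"]
        )
        assert (sig == outside).all()

    def test_cells_individually_reproducible(self, small_dataset):
        config = InferenceConfig(reps=40, post_sizes=(5,), baseline_sizes=(10,), seed=9)
        a = window_sweep(small_dataset, config, classes=("high",))
        b = window_sweep(small_dataset, config, classes=("high",))
        pd.testing.assert_frame_equal(a.table, b.table)


class TestLeaveOneOut:
    def duplicated_male_dataset(self):
        config = SimulationConfig(
            n_owners=1, n_subordinates=0, bouts_per_male=(2, 2),
            bout_length_frames=(200, 200), startle_magnitude=0.2,
            startle_probability=1.0, exit_probability=0.0, seed=6,
        )
        base = simulate_dataset(config)
        # clone the male under new identifiers
        tracks2 = base.tracks.copy()
        tracks2["bout_id"] = tracks2["bout_id"].str.replace("owner_01", "owner_02")
        events2 = base.events.copy()
        events2["bout_id"] = events2["bout_id"].str.replace("owner_01", "owner_02")
        meta2 = base.metadata.copy()
        meta2["bout_id"] = meta2["bout_id"].str.replace("owner_01", "owner_02")
        meta2["male_id"] = "owner_02"
        return assemble_dataset(
            pd.concat([base.tracks, tracks2], ignore_index=True),
            pd.concat([base.metadata, meta2], ignore_index=True),
            pd.concat([base.events, events2], ignore_index=True),
            empty_exits(),
        )

    def test_identical_males_give_identical_rows(self):
        dataset = self.duplicated_male_dataset()
        table = leave_one_out(
            dataset, "owner", "high", WindowSpec(10, 10),
            InferenceConfig(reps=60, seed=2),
        )
        assert len(table) == 2
        cols = ["observed", "p_value", "q025", "q975", "significant"]
        assert table.loc[0, cols].tolist() == table.loc[1, cols].tolist()

    def test_single_male_group_rejected(self):
        config = SimulationConfig(
            n_owners=1, n_subordinates=0, bouts_per_male=(2, 2),
            bout_length_frames=(200, 200), seed=6,
        )
        dataset = simulate_dataset(config)
        with pytest.raises(ParameterError):
            leave_one_out(dataset, "owner", "high", WindowSpec(10, 10),
                          InferenceConfig(reps=10))

    def test_outlier_male_omission_drops_statistic_most(self, small_dataset):
        """Omitting the male with the largest individual mean lowers the
        group statistic the most; row count equals group size."""
        config = InferenceConfig(reps=60, seed=3)
        full = bootstrap_null(
            small_dataset, "owner", "high", WindowSpec(10, 10), config
        )
        table = leave_one_out(
            small_dataset, "owner", "high", WindowSpec(10, 10), config
        )
        assert len(table) == len(small_dataset.males_with_status("owner"))
        biggest = full.individuals.loc[
            full.individuals["mean"].idxmax(), "male_id"
        ]
        drop = full.observed - table.set_index("omitted_male")["observed"]
        assert drop.idxmax() == biggest
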