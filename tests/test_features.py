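"""Window binning, imputation strategies, missingness filter, stratified splits."""

import collections
import math

import numpy as np
import pandas as pd
import pytest

from fedsepsis import features, synth
from fedsepsis._rng import child_rng

from conftest import make_grid


def _events(rows):
    return pd.DataFrame(rows, columns=["patient_id", "time_h", "kind", "channel", "value"])


def _episode(start=0.0, n=4, pid="p1", label=False, onset=None):
    return {
        "patient_id": pid, "start_h": start, "end_h": start + n,
        "n_windows": n, "label": label, "onset_window": onset,
    }


class TestBinEvents:
    def test_multiple_values_averaged(self):
        events = _events(
            [("p1", 0.2, "vital", "hr", 4.0), ("p1", 0.8, "vital", "hr", 6.0)]
        )
        grid = features.bin_events(events, _episode(), ["hr"])
        assert grid.values[0, 0] == 5.0 and grid.mask[0, 0] == 1

    def test_empty_window_masked(self):
        grid = features.bin_events(_events([]), _episode(), ["hr"])
        assert grid.mask.sum() == 0

    def test_single_value_passthrough(self):
        events = _events([("p1", 2.5, "vital", "hr", 2.5)])
        grid = features.bin_events(events, _episode(), ["hr"])
        assert grid.values[2, 0] == 2.5

    def test_non_numeric_record_dropped(self, caplog):
        events = _events(
            [("p1", 0.5, "vital", "hr", "oops"), ("p1", 0.6, "vital", "hr", 3.0)]
        )
        grid = features.bin_events(events, _episode(), ["hr"])
        assert grid.values[0, 0] == 3.0

    def test_record_order_invariance(self):
        rng = np.random.default_rng(0)
        rows = [("p1", float(rng.uniform(0, 4)), "vital", "hr", float(rng.normal()))
                for _ in range(40)]
        a = features.bin_events(_events(rows), _episode(), ["hr"])
        b = features.bin_events(_events(rows[::-1]), _episode(), ["hr"])
        np.testing.assert_array_equal(a.mask, b.mask)
        np.testing.assert_allclose(
            a.values[a.mask == 1], b.values[b.mask == 1], rtol=1e-12
        )


class TestCarryForwardMean:
    def test_carry_forward(self):
        g = make_grid([[np.nan], [np.nan], [np.nan], [2.0], [np.nan], [np.nan], [np.nan]])
        out = features.impute_carry_forward_mean(g, {"c0": 9.0})
        np.testing.assert_allclose(out.values[3:, 0], 2.0)
        np.testing.assert_allclose(out.values[:3, 0], 9.0)  # nothing to carry yet
        assert out.mask.all()

    def test_later_value_overrides(self):
        g = make_grid([[np.nan], [np.nan], [np.nan], [2.0], [np.nan], [7.0], [np.nan]])
        out = features.impute_carry_forward_mean(g, {"c0": 0.0})
        assert out.values[4, 0] == 2.0 and out.values[6, 0] == 7.0

    def test_never_observed_channel_uses_global_mean(self):
        g = make_grid([[np.nan], [np.nan]])
        out = features.impute_carry_forward_mean(g, {"c0": 1.5})
        np.testing.assert_allclose(out.values, 1.5)

    def test_missing_global_mean_errors(self):
        g = make_grid([[1.0]])
        with pytest.raises(KeyError):
            features.impute_carry_forward_mean(g, {})


class TestDistinctValue:
    def test_fully_observed_unchanged(self):
        g = make_grid([[1.0, 2.0], [3.0, 4.0]])
        out = features.impute_distinct_value(g, 101)
        np.testing.assert_array_equal(out.values, g.values)

    def test_missing_cells_get_sentinel(self):
        g = make_grid([[np.nan], [np.nan]])
        out = features.impute_distinct_value(g, 101)
        np.testing.assert_allclose(out.values, 101.0)

    def test_default_sentinel_above_global_max(self):
        grids = [make_grid([[100.0], [np.nan]]), make_grid([[7.0], [55.5]])]
        sentinel = features.default_sentinel(grids)
        assert sentinel == 101
        features.check_sentinel(grids, sentinel)  # must not raise

    def test_colliding_sentinel_rejected(self):
        g = make_grid([[42.0], [np.nan]])
        with pytest.raises(ValueError):
            features.impute_distinct_value(g, 42)


def test_imputation_never_alters_observed_cells():
    rng = child_rng(0, "impute-prop")
    for _ in range(20):
        values = rng.normal(size=(6, 4))
        mask = (rng.random((6, 4)) < 0.6).astype(int)
        values = np.where(mask == 1, values, np.nan)
        if mask.sum() == 0:
            continue
        g = make_grid(values, mask)
        means = {c: 0.0 for c in g.channels}
        for out in (
            features.impute_carry_forward_mean(g, means),
            features.impute_distinct_value(g, features.default_sentinel([g])),
        ):
            np.testing.assert_array_equal(
                out.values[mask == 1], values[mask == 1]
            )


class TestFilterMissingness:
    def test_half_observed_retained(self):
        g = make_grid(np.where(np.eye(4) == 1, 1.0, np.nan))
        assert features.filter_missingness([g], 0.90) == [g]

    def test_fully_missing_dropped(self):
        g = make_grid(np.full((4, 4), np.nan))
        assert features.filter_missingness([g], 0.90) == []

    def test_constructed_fixture_counts(self):
        """10 episodes, 2 built above the threshold, 8 survive."""
        grids = []
        for i in range(10):
            values = np.ones((10, 10))
            if i < 2:  # 95% missing: above the 90% threshold
                mask = np.zeros((10, 10), dtype=int)
                mask.ravel()[:5] = 1
            else:  # 50% missing
                mask = np.zeros((10, 10), dtype=int)
                mask.ravel()[::2] = 1
            values = np.where(mask == 1, values, np.nan)
            grids.append(make_grid(values, mask, episode_id=f"e{i}"))
        kept = features.filter_missingness(grids, 0.90)
        assert len(kept) == 8
        assert {g.episode_id for g in kept} == {f"e{i}" for i in range(2, 10)}

    def test_feature_mode_drops_on_any_bad_channel(self):
        values = np.ones((10, 2))
        mask = np.ones((10, 2), dtype=int)
        mask[1:, 1] = 0  # second channel 90% missing
        g = make_grid(np.where(mask == 1, values, np.nan), mask)
        assert features.filter_missingness([g], 0.90, mode="feature") == []
        assert features.filter_missingness([g], 0.90, mode="episode") == [g]


class TestSplitEpisodes:
    def _grids(self, sizes):
        grids = []
        k = 0
        for (label, length), n in sizes.items():
            for _ in range(n):
                grids.append(
                    make_grid(np.ones((length, 1)), label=label, episode_id=f"e{k}")
                )
                k += 1
        return grids

    def test_small_stratum_omitted_entirely(self):
        grids = self._grids({(False, 10): 5})
        assert features.split_episodes(grids) == {}

    def test_stratum_of_twenty_splits_16_2_2(self):
        grids = self._grids({(False, 10): 20})
        asg = features.split_episodes(grids, seed=0)
        counts = collections.Counter(asg.values())
        assert counts == {"train": 16, "test": 2, "tune": 2}

    def test_split_is_a_partition(self):
        grids = self._grids({(False, 10): 30, (True, 10): 12, (False, 20): 9})
        asg = features.split_episodes(grids, seed=1)
        assert len(asg) == 51
        assert set(asg) == {g.episode_id for g in grids}

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            features.split_episodes([], fractions=(0.5, 0.2, 0.2))

    def test_large_cohort_fractions_and_prevalence_preserved(self):
        """Train share within 2 points of 80%; positive rate per split within 1.5 points."""
        cfg = synth.SynthConfig(n_patients=2000, seed=11)
        _, truth = synth.generate_cohort(cfg)
        grids = []
        for i, rec in enumerate(truth.itertuples(index=False)):
            length = int(math.floor(
                rec.true_onset_h if rec.true_septic else rec.discharge_h
            )) + 1
            grids.append(
                make_grid(np.ones((length, 1)), label=bool(rec.true_septic),
                          episode_id=rec.patient_id)
            )
        asg = features.split_episodes(grids, seed=11)
        counts = collections.Counter(asg.values())
        total = sum(counts.values())
        assert abs(counts["train"] / total - 0.8) < 0.02
        labels = {g.episode_id: g.label for g in grids}
        overall = np.mean([labels[e] for e in asg])
        for name in ("train", "test", "tune"):
            rate = np.mean([labels[e] for e, s in asg.items() if s == name])
            assert abs(rate - overall) < 0.015, name


class TestAssembleMultimodal:
    def test_short_embedding_dimension_arithmetic(self):
        g = make_grid(np.ones((4, 30)))
        out = features.assemble_multimodal(g, np.zeros((4, 768)))
        assert len(out.channels) == 798

    def test_long_embedding_dimension_arithmetic(self):
        g = make_grid(np.ones((4, 30)))
        out = features.assemble_multimodal(g, np.zeros((4, 3072)))
        assert len(out.channels) == 3102

    def test_zero_embedding_leaves_nontext_unchanged(self):
        g = make_grid(np.arange(8.0).reshape(4, 2))
        out = features.assemble_multimodal(g, np.zeros((4, 3)))
        np.testing.assert_array_equal(out.values[:, :2], g.values)
        np.testing.assert_array_equal(out.values[:, 2:], 0.0)

    def test_row_mismatch_rejected(self):
        g = make_grid(np.ones((4, 2)))
        with pytest.raises(ValueError):
            features.assemble_multimodal(g, np.zeros((5, 3)))
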