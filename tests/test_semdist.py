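"""Semantic distance, median split, inclusion filters."""

import numpy as np
import pandas as pd
import pytest

from oscflux import (apply_inclusion_filters, median_split, score_sequence,
                     semantic_distance, split_table)
from oscflux.semdist import score_table


def vectors_from_gram(gram: np.ndarray, names: list) -> dict:
    """Embed words with prescribed pairwise cosine similarities."""
    chol = np.linalg.cholesky(gram + 1e-12 * np.eye(len(gram)))
    return {n: chol[i] for i, n in enumerate(names)}


class TestSemanticDistance:
    def test_identical_vectors(self):
        v = np.array([1.0, 2.0, 3.0])
        assert semantic_distance(v, 5 * v) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_vectors(self):
        assert semantic_distance([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_opposite_vectors_clamped_and_logged(self, caplog):
        with caplog.at_level("INFO", logger="oscflux.semdist"):
            d = semantic_distance([1.0, 0.0], [-1.0, 0.0])
        assert d == 1.0
        assert any("clamped" in r.message for r in caplog.records)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero vector"):
            semantic_distance([0.0, 0.0], [1.0, 0.0])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            semantic_distance([1.0, 0.0], [1.0, 0.0, 0.0])


class TestScoreSequence:
    def test_single_response_identical_to_cue(self):
        vecs = {"cue": np.array([1.0, 0.0]), "r1": np.array([2.0, 0.0])}
        for mode in ("consecutive", "forward_flow"):
            assert score_sequence("cue", ["r1"], vecs, mode=mode) == [pytest.approx(0.0)]

    def test_pairwise_orthogonal_forward_flow(self):
        vecs = {w: np.eye(4)[i] for i, w in enumerate(["cue", "r1", "r2", "r3"])}
        out = score_sequence("cue", ["r1", "r2", "r3"], vecs, mode="forward_flow")
        assert out == [pytest.approx(1.0)] * 3

    def test_forward_flow_averages_distances_to_all_previous(self):
        # cue-r1 distance 0.2, r1-r2 distance 0.6, cue-r2 distance 0.8
        gram = np.array([[1.0, 0.8, 0.2],
                         [0.8, 1.0, 0.4],
                         [0.2, 0.4, 1.0]])
        vecs = vectors_from_gram(gram, ["cue", "r1", "r2"])
        out = score_sequence("cue", ["r1", "r2"], vecs, mode="forward_flow")
        assert out[0] == pytest.approx(0.2, abs=1e-6)
        assert out[1] == pytest.approx((0.8 + 0.6) / 2, abs=1e-6)

    def test_consecutive_equals_forward_flow_for_single_response(self):
        rng = np.random.default_rng(0)
        vecs = {"cue": rng.standard_normal(5), "r1": rng.standard_normal(5)}
        a = score_sequence("cue", ["r1"], vecs, mode="consecutive")
        b = score_sequence("cue", ["r1"], vecs, mode="forward_flow")
        assert a == b

    def test_missing_word_scored_nan_and_logged(self, caplog):
        vecs = {"cue": np.array([1.0, 0.0]), "r2": np.array([0.0, 1.0])}
        with caplog.at_level("WARNING", logger="oscflux.semdist"):
            out = score_sequence("cue", ["r1", "r2"], vecs)
        assert np.isnan(out[0])
        # r2 is scored against the last known vector (the cue)
        assert out[1] == pytest.approx(1.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            score_sequence("cue", [], {"cue": np.array([1.0, 0.0])})

    def test_skip_first_response_flag(self):
        vecs = {"cue": np.array([1.0, 0.0]), "r1": np.array([0.0, 1.0])}
        out = score_sequence("cue", ["r1"], vecs, score_first_against_cue=False)
        assert np.isnan(out[0])


class TestMedianSplit:
    def test_two_values(self):
        labels = median_split([0.1, 0.9])
        assert sorted(labels) == ["higher", "lower"]

    def test_all_equal_alternates_within_one(self):
        for n in (2, 3, 7, 10):
            labels = median_split([0.5] * n)
            counts = pd.Series(labels).value_counts()
            assert abs(counts.get("lower", 0) - counts.get("higher", 0)) <= 1

    def test_documented_tie_example(self):
        labels = list(median_split([0.1, 0.5, 0.5, 0.9]))
        assert labels == ["lower", "lower", "higher", "higher"]

    def test_fewer_than_two_scored_excluded(self):
        assert list(median_split([0.4])) == ["excluded"]
        assert list(median_split([0.4, np.nan])) == ["excluded", "excluded"]

    @pytest.mark.parametrize("seed", range(30))
    def test_balance_invariant_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 40)
        vals = np.round(rng.uniform(0, 1, n), rng.integers(0, 3))
        labels = pd.Series(median_split(vals))
        assert abs((labels == "lower").sum() - (labels == "higher").sum()) <= 1


class TestMedianSplitProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
                    min_size=2, max_size=60))
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_balance_holds_for_any_distance_multiset(self, values):
        labels = pd.Series(median_split(np.asarray(values)))
        assert abs((labels == "lower").sum() - (labels == "higher").sum()) <= 1
        assert not (labels == "excluded").any()


class TestInclusionFilters:
    def _records(self):
        rows = []
        for p, tt in [("p1", 5.0), ("p2", 5.0)]:
            for cond in ("free", "goal_directed"):
                for k in range(6):
                    rows.append({"participant": p, "condition": cond,
                                 "thinking_time": tt, "artefact_fraction": 0.0})
        return pd.DataFrame(rows)

    def test_clean_dataset_passes_unchanged(self):
        rec = self._records()
        kept, report = apply_inclusion_filters(rec)
        assert len(kept) == len(rec)
        assert report["epoch_thinking_time_lt_1s"] == 0
        assert report["participant_lt_10_responses"] == 0

    def test_short_thinking_time_rejected(self):
        rec = self._records()
        rec.loc[0, "thinking_time"] = 0.8
        kept, report = apply_inclusion_filters(rec)
        assert report["epoch_thinking_time_lt_1s"] == 1
        assert len(kept) == len(rec) - 1

    def test_artefact_fraction_rule(self):
        rec = self._records()
        rec.loc[3, "artefact_fraction"] = 0.25
        kept, report = apply_inclusion_filters(rec)
        assert report["epoch_artefact_gt_20pct"] == 1

    def test_participant_below_per_condition_minimum_excluded(self):
        rec = self._records()
        # p2 keeps only 4 epochs in the free condition
        drop = rec[(rec.participant == "p2") & (rec.condition == "free")].index[:2]
        rec = rec.drop(drop)
        kept, report = apply_inclusion_filters(rec)
        assert "p2" not in kept.participant.values
        assert report["participant_lt_5_per_condition"] == 1

    def test_three_sd_outlier_removed_entirely(self):
        rec = pd.concat([self._records()] + [
            pd.DataFrame([{"participant": f"x{i}", "condition": c,
                           "thinking_time": 5.0, "artefact_fraction": 0.0}
                          for c in ("free", "goal_directed") for _ in range(6)])
            for i in range(14)], ignore_index=True)
        participants = sorted(rec.participant.unique())
        measures = pd.DataFrame({
            "participant": participants,
            "burst_power": [1.0] * (len(participants) - 1) + [1000.0],
        })
        measures.iloc[:-1, 1] = np.linspace(0.9, 1.1, len(participants) - 1)
        kept, report = apply_inclusion_filters(rec, measures=measures)
        assert report["participant_outlier_3sd"] == 1
        assert participants[-1] not in kept.participant.values

    def test_idempotent(self):
        rec = self._records()
        rec.loc[0, "thinking_time"] = 0.5
        once, _ = apply_inclusion_filters(rec)
        twice, report2 = apply_inclusion_filters(once)
        pd.testing.assert_frame_equal(once, twice)
        assert report2["epoch_thinking_time_lt_1s"] == 0


class TestSplitTable:
    def test_split_is_per_participant_per_condition(self):
        rows = []
        for p in ("p1", "p2"):
            for cond in ("free", "goal_directed"):
                for k, d in enumerate([0.1, 0.3, 0.7, 0.9]):
                    rows.append({"participant": p, "item": "cue", "condition": cond,
                                 "order": k + 1, "word": f"w{k}", "distance": d})
        out = split_table(pd.DataFrame(rows))
        for (_, _), grp in out.groupby(["participant", "condition"]):
            assert sorted(grp.split) == ["higher", "higher", "lower", "lower"]

    def test_score_table_orders_within_item(self):
        vecs = {w: np.eye(3)[i] for i, w in enumerate(["cue", "a", "b"])}
        df = pd.DataFrame([
            {"participant": "p", "item": "cue", "condition": "free",
             "order": 2, "word": "b", "thinking_time": 2.0},
            {"participant": "p", "item": "cue", "condition": "free",
             "order": 1, "word": "a", "thinking_time": 2.0},
        ])
        scored = score_table(df, vecs)
        assert scored.sort_values("order").distance.tolist() == [
            pytest.approx(1.0), pytest.approx(1.0)]
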