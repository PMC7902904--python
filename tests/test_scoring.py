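import numpy as np
import pandas as pd
import pytest

import gazewm as gw
from gazewm.ingest import ActionEvent, derive_events, iter_displays
from gazewm.scoring import (count_features, error_rates,
                            feature_probabilities, tally_display)
from gazewm.sequencing import Sequence

from oracles import oracle_score_display


def _seq(events):
    s = Sequence(sequence_id=0, start_time_s=0.0, end_time_s=10.0)
    s.action_events = events
    return s


def _pickup(t=1.0, obj=1, model=True, corrective=False):
    return ActionEvent(time_s=t, kind="PICKUP", object_id=obj,
                       is_model_object=model, is_corrective=corrective)


def _place(t=2.0, obj=1, correct=True, corrective=False):
    return ActionEvent(time_s=t, kind="PLACE", object_id=obj,
                       is_model_object=True, placement_cell=0,
                       correct_location=correct, is_corrective=corrective)


class TestCountFeatures:
    @pytest.mark.parametrize("events,k", [
        ([], 0),
        ([_pickup()], 1),
        ([_pickup(), _place()], 2),
        ([_pickup(1), _place(2), _pickup(3, obj=2)], 3),
        ([_pickup(1), _place(2), _pickup(3, obj=2), _place(4, obj=2)], 4),
    ])
    def test_identity_plus_location_credits(self, events, k):
        assert count_features(_seq(events)).k == k

    def test_object_carried_across_boundary_splits_credit(self):
        # pickup in one sequence, placement in the next: identity goes to
        # the first, location to the second
        first = count_features(_seq([_pickup()]))
        second = count_features(_seq([_place()]))
        assert (first.n_identity, first.n_location) == (1, 0)
        assert (second.n_identity, second.n_location) == (0, 1)

    def test_distractor_pickup_earns_nothing_but_flags(self):
        fc = count_features(_seq([_pickup(model=False), _pickup(obj=2)]))
        assert fc.k == 1 and fc.has_identity_error

    def test_wrong_placement_earns_nothing_but_flags(self):
        fc = count_features(_seq([_pickup(), _place(correct=False)]))
        assert fc.k == 1 and fc.has_location_error

    def test_corrective_actions_earn_nothing(self):
        fc = count_features(_seq([
            _pickup(corrective=True), _place(corrective=True)]))
        assert fc.k == 0 and fc.n_corrective == 2


class TestTallyDisplay:
    def _scored(self, ks, ident=False, loc=False):
        return pd.DataFrame({"k": ks,
                             "has_identity_error": [ident] * len(ks),
                             "has_location_error": [loc] * len(ks)})

    def test_sixteen_one_feature_sequences(self):
        total, complete = tally_display(self._scored([1] * 16))
        assert (total, complete) == (16, True)

    def test_eight_two_feature_sequences(self):
        assert tally_display(self._scored([2] * 8)) == (16, True)

    def test_timeout_partial_total(self):
        total, complete = tally_display(self._scored([2, 2, 2]),
                                        completed=False)
        assert (total, complete) == (6, False)

    def test_inconsistent_complete_display_raises(self):
        with pytest.raises(AssertionError, match="expected 16"):
            tally_display(self._scored([2] * 7))


class TestFeatureProbabilities:
    def _table(self, ks):
        n = len(ks)
        return pd.DataFrame({
            "participant": [1] * n, "condition_deg": [0] * n,
            "k": ks, "truncated": [False] * n,
            "has_identity_error": [False] * n,
            "has_location_error": [False] * n,
        })

    def test_hand_computed_fixture(self):
        # 6 one-feature, 3 two-feature, 1 three-feature sequences
        out = feature_probabilities(self._table([1] * 6 + [2] * 3 + [3]))
        row = out.iloc[0]
        assert row["pct_1"] == pytest.approx(60.0)
        assert row["pct_2"] == pytest.approx(30.0)
        assert row["pct_3"] == pytest.approx(10.0)
        assert row["mean_k"] == pytest.approx(1.5)

    def test_degenerate_distribution(self):
        out = feature_probabilities(self._table([2] * 10))
        assert out.iloc[0]["pct_2"] == pytest.approx(100.0)
        assert out.iloc[0]["mean_k"] == pytest.approx(2.0)

    def test_pmf_sums_to_100(self, small_sim):
        out = feature_probabilities(small_sim["scored"])
        cols = [c for c in out.columns if c.startswith("pct_")]
        assert np.allclose(out[cols].sum(axis=1), 100.0)

    def test_k_above_four_binned_but_kept_in_mean(self):
        out = feature_probabilities(self._table([1, 6]))
        assert out.iloc[0]["pct_>4"] == pytest.approx(50.0)
        assert out.iloc[0]["mean_k"] == pytest.approx(3.5)

    def test_mean_k_nondecreasing_in_angle(self, small_sim):
        gm = gw.group_mean_probabilities(
            feature_probabilities(small_sim["scored"]))
        mk = gm.sort_values("condition_deg")["mean_k"].to_numpy()
        assert np.all(np.diff(mk) > 0)


class TestErrorRates:
    def test_direct_proportion(self):
        df = pd.DataFrame({
            "k": [1] * 100, "truncated": [False] * 100,
            "has_identity_error": [True] * 2 + [False] * 98,
            "has_location_error": [False] * 100,
        })
        out = error_rates(df)
        assert out["identity_pct"] == pytest.approx(2.0)
        assert out["location_pct"] == 0.0
        assert out["n_sequences"] == 100

    def test_zero_errors(self):
        df = pd.DataFrame({"k": [1], "truncated": [False],
                           "has_identity_error": [False],
                           "has_location_error": [False]})
        assert error_rates(df)["any_pct"] == 0.0


def test_scorer_matches_brute_force_oracle(small_sim):
    """Independent frame-level recount agrees with the pipeline scorer on
    every sequence of every display."""
    frames, mapping = small_sim["frames"], small_sim["mapping"]
    scored = small_sim["scored"]
    checked = 0
    for meta, block in iter_displays(frames):
        key = (meta["participant"], meta["run"], meta["display"])
        oracle = oracle_score_display(block, mapping[key])
        mine = scored[(scored["participant"] == key[0])
                      & (scored["run"] == key[1])
                      & (scored["display"] == key[2])
                      & ~scored["truncated"]].sort_values("sequence_id")
        assert [r["k"] for r in oracle] == mine["k"].tolist()
        assert [r["identity"] for r in oracle] == \
            mine["has_identity_error"].tolist()
        assert [r["location"] for r in oracle] == \
            mine["has_location_error"].tolist()
        checked += len(oracle)
    assert checked > 1000
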