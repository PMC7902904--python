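import io

import numpy as np
import pandas as pd
import pytest

import gazewm as gw
from gazewm.simulate import (ConfigurationError, _draw_composition,
                             _tilted_pmf, generate_display, simulate_display,
                             write_frame_log)


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestGenerateDisplay:
    @pytest.mark.parametrize("pool", [24, 40, 60])
    def test_invariants(self, pool):
        spec = generate_display(pool, _rng(3))
        assert len(spec.model_objects) == 8
        assert len(spec.distractor_objects) == 16
        assert len(set(spec.resource_objects)) == 24
        assert sorted(spec.cell_assignment.values()) == list(range(8))
        if pool == 24:
            assert set(spec.resource_objects) == set(range(24))

    def test_deterministic_under_fixed_seed(self):
        a = generate_display(60, _rng(7))
        b = generate_display(60, _rng(7))
        assert a == b

    def test_pool_too_small(self):
        with pytest.raises(ConfigurationError):
            generate_display(23, _rng(0))


def _forced_policy(k, **kw):
    pmf = {c: {k: 1.0} for c in (0, 45, 90, 135)}
    return gw.AgentPolicy(features_per_visit_pmf=pmf, zero_feature_rate=0.0,
                          identity_error_rate=0.0, location_error_rate=0.0,
                          **kw)


def _one_display(policy, seed=0, cond=0):
    rng = _rng(seed)
    spec = generate_display(60, rng)
    config = gw.SimulationConfig()
    geom = gw.TaskGeometry(model_angle_deg=cond)
    return simulate_display(spec, policy, geom, config, rng)


class TestSimulateDisplay:
    def test_forced_two_feature_policy_gives_eight_sequences(self):
        _, ledger = _one_display(_forced_policy(2))
        assert len(ledger) == 8
        assert all(row["k"] == 2 for row in ledger)

    def test_forced_one_feature_policy_gives_sixteen_sequences(self):
        _, ledger = _one_display(_forced_policy(1))
        assert len(ledger) == 16
        assert all(row["k"] == 1 for row in ledger)

    def test_certain_identity_errors_flag_every_sequence(self):
        policy = _forced_policy(2)
        policy.identity_error_rate = 1.0
        frames, ledger = _one_display(policy)
        assert all(row["has_identity_error"] for row in ledger)
        # recovery: the distractor is dropped (RELEASE without a cell)
        drops = (np.asarray(frames["controller_event"]) == "RELEASE") \
            & pd.isna(frames["placement_cell"])
        assert drops.sum() >= len(ledger)

    def test_conservation_pickups_equal_releases(self):
        frames, ledger = _one_display(_forced_policy(2), seed=5)
        ev = np.asarray(frames["controller_event"])
        placed = (ev == "RELEASE") & ~pd.isna(frames["placement_cell"])
        assert (ev == "PICKUP").sum() == (ev == "RELEASE").sum() == 8
        assert placed.sum() == 8
        assert sum(r["k"] for r in ledger) == 16

    def test_unreachable_total_falls_back_to_capped_composition(self):
        # 16 is not a multiple of 3, so a pure 3-feature policy cannot
        # land exactly; the final draw is truncated and flagged
        _, ledger = _one_display(_forced_policy(3))
        assert sum(r["k"] for r in ledger) == 16
        assert ledger[-1]["capped"]

    def test_timeout_truncates_and_flags(self):
        policy = _forced_policy(1, travel_base_s=3.0)
        frames, ledger = _one_display(policy, cond=135)
        assert ledger[0]["display_timed_out"]
        assert len(frames["frame"]) <= int(45.0 * 90)
        assert any(r["truncated"] for r in ledger)


class TestComposition:
    @pytest.mark.parametrize("cond", [0, 135])
    def test_tilted_marginals_match_policy(self, cond):
        pmf = gw.simulate.DEFAULT_FEATURES_PMF[cond]
        rng = _rng(11)
        counts = {k: 0 for k in pmf}
        for _ in range(4000):
            parts, capped = _draw_composition(pmf, 16, rng)
            assert sum(parts) == 16 and not capped
            for k in parts:
                counts[k] += 1
        total = sum(counts.values())
        for k, p in pmf.items():
            se = np.sqrt(p * (1 - p) / total)
            assert abs(counts[k] / total - p) < 4 * se + 1e-3

    def test_tilt_is_exact_by_dynamic_programming(self):
        from gazewm.simulate import _composition_marginal
        pmf = {1: 0.6, 2: 0.27, 3: 0.12, 4: 0.01}
        tilted = _tilted_pmf(pmf, 16)
        ks = np.array(sorted(tilted))
        m = _composition_marginal(
            np.array([tilted[int(k)] for k in ks]), ks, 16)
        assert np.allclose(m, [pmf[int(k)] for k in ks], atol=1e-9)


class TestExperiment:
    def test_run_and_condition_structure(self):
        config = gw.SimulationConfig(n_participants=1, displays_per_run=2)
        frames, ledger, displays = gw.simulate_experiment(config, rng_seed=4)
        per_cond = displays.groupby("condition_deg")["run"].nunique()
        assert (per_cond == 2).all()          # each condition in 2 runs
        assert displays.groupby("run")["condition_deg"].nunique().eq(1).all()
        assert len(displays) == 8 * 2

    def test_same_seed_gives_byte_identical_csv(self):
        config = gw.SimulationConfig(n_participants=1, runs_per_participant=4,
                                     displays_per_run=2)
        outs = []
        for _ in range(2):
            frames, _, _ = gw.simulate_experiment(config, rng_seed=9)
            buf = io.StringIO()
            write_frame_log(frames, buf)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]

    def test_adding_participants_preserves_earlier_streams(self):
        c2 = gw.SimulationConfig(n_participants=2, runs_per_participant=4,
                                 displays_per_run=2)
        c3 = gw.SimulationConfig(n_participants=3, runs_per_participant=4,
                                 displays_per_run=2)
        f2, _, _ = gw.simulate_experiment(c2, rng_seed=5)
        f3, _, _ = gw.simulate_experiment(c3, rng_seed=5)
        pd.testing.assert_frame_equal(
            f2, f3[f3["participant"] <= 2].reset_index(drop=True))

    def test_noise_layer_off_is_identity_and_on_perturbs(self):
        config = gw.SimulationConfig(n_participants=1, runs_per_participant=4,
                                     displays_per_run=1)
        frames, _, _ = gw.simulate_experiment(config, rng_seed=6)
        same = gw.add_gaze_noise(frames, _rng(0), flicker_prob=0.0)
        assert same is frames
        noisy = gw.add_gaze_noise(frames, _rng(0), flicker_prob=0.05)
        frac = (np.asarray(noisy["aoi"]) != np.asarray(frames["aoi"])).mean()
        assert 0.01 < frac < 0.06


class TestPolicyValidation:
    def test_bad_pmf_rejected(self):
        with pytest.raises(ConfigurationError):
            gw.AgentPolicy(features_per_visit_pmf={0: {1: 0.5}})

    def test_bad_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            gw.AgentPolicy(identity_error_rate=1.5)

    def test_geometry_angle_must_be_condition_level(self):
        with pytest.raises(ConfigurationError):
            gw.TaskGeometry(model_angle_deg=30)


def test_noise_degrades_ledger_agreement_monotonically():
    """Segmentation recovers the ledger exactly on clean output; AOI
    flicker noise can only lower agreement, and more noise lowers it
    further."""
    import gazewm.pipeline as pl
    from gazewm.ingest import model_objects_from_manifest

    config = gw.SimulationConfig(n_participants=2, runs_per_participant=4,
                                 displays_per_run=3)
    frames, ledger, displays = gw.simulate_experiment(config, rng_seed=8)
    mapping = model_objects_from_manifest(displays)
    agreements = []
    for level in (0.0, 0.02, 0.15):
        noisy = gw.add_gaze_noise(frames, np.random.default_rng(99), level)
        scored = gw.build_sequence_table(noisy, mapping)
        agreements.append(
            pl.compare_with_ledger(scored, ledger)["k_agreement"])
    assert agreements[0] == 1.0
    assert agreements[0] >= agreements[1] >= agreements[2]
    assert agreements[2] < 1.0
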