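"""Synthetic dual-registry generator: distributions, capture, corruption."""

import dataclasses
import math

import numpy as np
import pytest

from recapture.estimators import chapman_estimate
from recapture.linkage import link_records
from recapture.records import missingness_profile
from recapture.synthetic import (
    SimulationConfig,
    apply_capture,
    corrupt_registry,
    generate,
    load_config,
    save_config,
    simulate_events,
    truth_capture_counts,
)


def constant_capture(p_hospital, p_police, **kwargs):
    """Config with covariate-independent capture probabilities."""
    return SimulationConfig(
        hospital_base=float(np.log(p_hospital / (1 - p_hospital))) if 0 < p_hospital < 1 else (50.0 if p_hospital == 1 else -50.0),
        police_base=float(np.log(p_police / (1 - p_police))) if 0 < p_police < 1 else (50.0 if p_police == 1 else -50.0),
        hospital_effects={},
        police_effects={},
        **kwargs,
    )


class TestSimulateEvents:
    def test_empty_population(self):
        assert simulate_events(SimulationConfig(n_true=0)) == []

    def test_deterministic_under_fixed_seed(self):
        cfg = SimulationConfig(n_true=50, seed=9)
        assert simulate_events(cfg) == simulate_events(cfg)

    def test_gender_frequency_within_3se(self):
        cfg = SimulationConfig(n_true=2000, seed=4)
        events = simulate_events(cfg)
        males = sum(e.gender == "male" for e in events)
        se = math.sqrt(cfg.p_male * (1 - cfg.p_male) / cfg.n_true)
        assert abs(males / cfg.n_true - cfg.p_male) < 3 * se

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(p_male=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(road_user_probs={"pedestrian": 0.5})
        with pytest.raises(ValueError):
            SimulationConfig(age_jitter_years=-1)


class TestApplyCapture:
    def test_certain_capture_includes_everything(self):
        cfg = constant_capture(1, 1, n_true=100, seed=0)
        events = simulate_events(cfg)
        hospital, police, truth = apply_capture(events, cfg)
        assert len(hospital) == len(police) == 100
        assert len(truth.links) == 100

    def test_independent_half_capture_overlap(self):
        cfg = constant_capture(0.5, 0.5, n_true=4000, seed=1)
        events = simulate_events(cfg)
        _, _, truth = apply_capture(events, cfg)
        se = math.sqrt(4000 * 0.25 * 0.75)
        assert abs(len(truth.links) - 1000) < 3 * se

    def test_zero_police_capture_empties_registry(self):
        cfg = constant_capture(0.5, 0, n_true=200, seed=2)
        events = simulate_events(cfg)
        _, police, truth = apply_capture(events, cfg)
        assert len(police) == 0 and truth.links == []

    def test_link_table_ids_exist_in_registries(self):
        cfg = SimulationConfig(n_true=300, seed=3)
        events = simulate_events(cfg)
        hospital, police, truth = apply_capture(events, cfg)
        h_ids = {r.record_id for r in hospital.records}
        p_ids = {r.record_id for r in police.records}
        assert all(h in h_ids and p in p_ids for h, p in truth.links)
        assert len(truth.links) == int(
            (truth.captured_hospital & truth.captured_police).sum()
        )


class TestCorruptRegistry:
    def test_no_corruption_is_identity(self):
        cfg = SimulationConfig(
            n_true=100, seed=5, hospital_missing={}, police_missing={},
            age_jitter_years=0, time_jitter_minutes=0,
        )
        events = simulate_events(cfg)
        hospital, _, _ = apply_capture(events, cfg)
        assert corrupt_registry(hospital, cfg).records == hospital.records

    def test_age_missingness_rate_within_3se(self):
        cfg = dataclasses.replace(SimulationConfig(seed=6), n_true=2000)
        events = simulate_events(cfg)
        hospital, _, _ = apply_capture(events, cfg)
        corrupted = corrupt_registry(hospital, cfg)
        n = len(hospital)
        p = cfg.hospital_missing["age"]
        se = math.sqrt(n * p * (1 - p))
        assert abs(missingness_profile(corrupted)["age"] - n * p) < 3 * se

    def test_jitter_respects_bounds_and_count(self):
        cfg = SimulationConfig(
            n_true=300, seed=7, hospital_missing={}, police_missing={},
            age_jitter_years=2, time_jitter_minutes=60,
        )
        events = simulate_events(cfg)
        hospital, _, _ = apply_capture(events, cfg)
        corrupted = corrupt_registry(hospital, cfg)
        assert len(corrupted) == len(hospital)
        for before, after in zip(hospital.records, corrupted.records):
            assert abs(after.age - before.age) <= 2
            delta = abs((after.event_datetime - before.event_datetime).total_seconds())
            assert delta <= 3600


class TestStudyLikeDefaults:
    def test_expected_registry_sizes(self):
        # average over a few replicates: ~97 hospital, ~143 police captures
        d1s, d2s, ms = [], [], []
        for seed in range(10):
            _, _, truth = generate(SimulationConfig(seed=seed), corrupt=False)
            c = truth.capture_counts()
            d1s.append(c.d1)
            d2s.append(c.d2)
            ms.append(c.m)
        assert np.mean(d1s) == pytest.approx(97, abs=10)
        assert np.mean(d2s) == pytest.approx(143, abs=12)
        assert np.mean(ms) == pytest.approx(38, abs=8)

    def test_corruption_disabled_gives_perfect_linkage_recall(self):
        hospital, police, truth = generate(SimulationConfig(seed=8), corrupt=False)
        link = link_records(hospital, police)
        got = {(p.hospital_id, p.police_id) for p in link.pairs}
        assert set(truth.links) <= got

    def test_police_overrepresents_males_and_pedestrians(self):
        cfg = SimulationConfig(n_true=50_000, seed=9)
        events = simulate_events(cfg)
        hospital, police, _ = apply_capture(events, cfg)
        h_male = np.mean([r.gender == "male" for r in hospital.records])
        p_male = np.mean([r.gender == "male" for r in police.records])
        assert p_male > h_male
        h_ped = np.mean([r.road_user == "pedestrian" for r in hospital.records])
        p_ped = np.mean([r.road_user == "pedestrian" for r in police.records])
        assert p_ped > h_ped

    def test_stage_seeds_are_independent(self):
        # changing corruption must not change the latent events or captures
        cfg_a = SimulationConfig(seed=10)
        cfg_b = dataclasses.replace(cfg_a, hospital_missing={"age": 0.9})
        _, _, truth_a = generate(cfg_a)
        _, _, truth_b = generate(cfg_b)
        assert truth_a.events == truth_b.events
        assert truth_a.links == truth_b.links


class TestTruthCounts:
    def test_stratified_truth_counts_sum_to_pooled(self):
        _, _, truth = generate(SimulationConfig(seed=12), corrupt=False)
        pooled = truth.capture_counts()
        for factor in ("gender", "road_user", "victims_per_incident", "vehicles_per_incident"):
            strata = truth_capture_counts(truth, factor)
            assert sum(c.d1 for _, c in strata) == pooled.d1
            assert sum(c.d2 for _, c in strata) == pooled.d2
            assert sum(c.m for _, c in strata) == pooled.m


class TestConfigIO:
    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_true=123, seed=42)
        path = tmp_path / "config.yaml"
        save_config(cfg, path)
        assert load_config(path) == cfg
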