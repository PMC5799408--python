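import dataclasses
import math

import numpy as np
import pytest

from lickstruct import (
    SimConfig,
    ValidationError,
    handling_effect_preset,
    segment_clusters,
    simulate_experiment,
    simulate_lick_train,
    summarize_session,
)


class TestLickTrainGenerator:
    def test_deterministic_under_fixed_seed(self):
        cfg = handling_effect_preset()
        t1 = simulate_lick_train(cfg, ("tail", 4.0), 42)
        t2 = simulate_lick_train(cfg, ("tail", 4.0), 42)
        assert t1.timestamps == t2.timestamps

    def test_different_seeds_differ(self):
        cfg = handling_effect_preset()
        t1 = simulate_lick_train(cfg, ("tail", 4.0), 1)
        t2 = simulate_lick_train(cfg, ("tail", 4.0), 2)
        assert t1.timestamps != t2.timestamps

    def test_deterministic_sizes_recovered_exactly(self):
        # no size dispersion: every segmented cluster has exactly k licks
        k = 7
        cfg = dataclasses.replace(
            handling_effect_preset(),
            cluster_size_dispersion=math.inf,
            cluster_size_mean={c: float(k) for c in
                               handling_effect_preset().cluster_size_mean},
        )
        train = simulate_lick_train(cfg, ("tunnel", 16.0), 3)
        sizes = [c.size for c in segment_clusters(train, cfg.interbout_interval)]
        assert sizes and all(s == k for s in sizes)

    def test_segmentation_consistency_preset(self):
        # pauses >= threshold by construction, ILIs < threshold by truncation:
        # segmentation at the configured threshold can never merge or split
        # generated clusters, so every within-cluster gap is < threshold and
        # every between-cluster gap >= threshold
        cfg = handling_effect_preset()
        for seed in range(5):
            train = simulate_lick_train(cfg, ("tail", 16.0), seed)
            ts = np.asarray(train.timestamps)
            gaps = np.round(np.diff(ts), 2)
            assert np.all((gaps >= 0.25) | (gaps <= cfg.interbout_interval - 0.02 + 1e-9))

    def test_quantized_to_device_resolution(self):
        train = simulate_lick_train(handling_effect_preset(), ("tunnel", 4.0), 9)
        ticks = np.asarray(train.timestamps) / 0.01
        assert np.max(np.abs(ticks - np.round(ticks))) < 1e-6

    def test_monte_carlo_mean_cluster_size(self):
        # pooled over many clusters the empirical mean must sit within 3 SE
        # of the configured mean
        target = 5.0
        cfg = dataclasses.replace(
            handling_effect_preset(),
            cluster_size_mean={c: target for c in
                               handling_effect_preset().cluster_size_mean},
            drinking_fraction={c: 0.9 for c in
                               handling_effect_preset().drinking_fraction},
        )
        sizes = []
        seed = 0
        while len(sizes) < 10_000:
            train = simulate_lick_train(cfg, ("tail", 4.0), seed)
            sizes.extend(summarize_session(train, 0.25).cluster_sizes)
            seed += 1
        sizes = np.asarray(sizes[:10_000], dtype=float)
        se = sizes.std(ddof=1) / math.sqrt(len(sizes))
        assert abs(sizes.mean() - target) < 3 * se

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValidationError):
            simulate_lick_train(
                dataclasses.replace(handling_effect_preset(), ili_mean=0.3),
                ("tail", 4.0), 0)
        with pytest.raises(ValidationError):
            simulate_lick_train(
                dataclasses.replace(handling_effect_preset(), pause_shift=0.1),
                ("tail", 4.0), 0)


class TestExperimentGenerator:
    def test_counts_default_config(self, preset_experiment):
        exp = preset_experiment
        assert len(exp.subjects) == 32
        assert len(exp.trains) == 320          # 32 x 2 phases x 5 days
        assert len(exp.consumption) == 320

    def test_counterbalanced_crossover(self, preset_experiment):
        exp = preset_experiment
        truth = exp.ground_truth["subjects"]
        for handling in ("tail", "tunnel"):
            low_first = [s for s, d in truth.items()
                         if d["handling"] == handling and d["low_first"]]
            assert len(low_first) == 8
        # phase 1 days carry one concentration, phase 2 the other, per subject
        for sid in list(truth)[:4]:
            days = {(t.session_day, t.concentration) for t in exp.trains
                    if t.subject_id == sid}
            phase1 = {c for d, c in days if d < 29}
            phase2 = {c for d, c in days if d >= 29}
            assert len(phase1) == 1 and len(phase2) == 1
            assert phase1 != phase2

    def test_cagemates_share_handling(self, preset_experiment):
        by_cage = {}
        for s in preset_experiment.subjects:
            by_cage.setdefault(s.cage_id, set()).add(s.handling)
        assert all(len(v) == 1 for v in by_cage.values())
        assert all(
            sum(s.cage_id == c for s in preset_experiment.subjects) == 2
            for c in by_cage
        )

    def test_consumption_proportional_without_noise(self):
        cfg = dataclasses.replace(handling_effect_preset(),
                                  n_per_group=2, sessions_per_phase=1,
                                  consumption_noise_sd=0.0)
        exp = simulate_experiment(cfg, 21)
        licks = {(t.subject_id, t.session_day): t.n_licks for t in exp.trains}
        for r in exp.consumption:
            assert r.mass_consumed == pytest.approx(
                licks[(r.subject_id, r.session_day)] * cfg.volume_per_lick)

    def test_odd_group_size_rejected(self):
        with pytest.raises(ValidationError):
            simulate_experiment(
                dataclasses.replace(handling_effect_preset(), n_per_group=3), 0)

    def test_adding_subjects_preserves_existing_streams(self):
        cfg4 = dataclasses.replace(handling_effect_preset(), n_per_group=4)
        cfg8 = dataclasses.replace(handling_effect_preset(), n_per_group=8)
        e4 = simulate_experiment(cfg4, 13)
        e8 = simulate_experiment(cfg8, 13)

        def trains_by_pos(exp, n):
            out = {}
            for t in exp.trains:
                idx = int(t.subject_id[1:]) - 1
                group = "tail" if idx < n else "tunnel"
                pos = idx if idx < n else idx - n
                out.setdefault((group, pos, t.session_day), t.timestamps)
            return out

        t4 = trains_by_pos(e4, 4)
        t8 = trains_by_pos(e8, 8)
        for key, ts in t4.items():
            assert t8[key] == ts

    def test_ground_truth_logs_multipliers(self, preset_experiment):
        truth = preset_experiment.ground_truth
        assert truth["seed"] == 5
        some = next(iter(truth["subjects"].values()))
        assert {"cluster_multiplier", "engagement_multiplier",
                "handling"} <= set(some)

    def test_equalized_removes_condition_structure(self):
        cfg = handling_effect_preset().equalized()
        assert len(set(cfg.cluster_size_mean.values())) == 1
        assert len(set(cfg.drinking_fraction.values())) == 1
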