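import dataclasses

import numpy as np
import pytest
from scipy import stats

from crowlaw.io_annotations import read_audacity_labels
from crowlaw.menzerath import MenzerathParams, fit_simple
from crowlaw.sequence_builder import apply_exclusions, segment_sequences
from crowlaw.social_indices import elo_ratings
from crowlaw.synthetic import (
    GeneratorConfig,
    generate_dataset,
    generate_interactions,
    model_frame,
    recovery_experiment,
    summarize_recovery,
    write_dataset,
)


class TestGenerator:
    def test_noiseless_law_gives_exact_durations(self, noiseless_config):
        dataset = generate_dataset(noiseless_config)
        lengths_4 = dataset.calls[dataset.calls["true_length"] == 4]
        if len(lengths_4):
            assert np.allclose(lengths_4["duration_s"], 4.0**-0.5)
        lengths_2 = dataset.calls[dataset.calls["true_length"] == 2]
        assert np.allclose(lengths_2["duration_s"], 2.0**-0.5)

    def test_same_seed_reproduces_byte_identical_tables(self):
        config = GeneratorConfig(seed=9, sequences_per_individual=5)
        a = generate_dataset(config).calls.to_csv(index=False)
        b = generate_dataset(config).calls.to_csv(index=False)
        assert a == b

    def test_different_seeds_differ(self):
        a = generate_dataset(GeneratorConfig(seed=1, sequences_per_individual=5)).calls
        b = generate_dataset(GeneratorConfig(seed=2, sequences_per_individual=5)).calls
        assert not a.equals(b)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(sd_residual=-0.1)
        with pytest.raises(ValueError):
            GeneratorConfig(intersequence_gap=0.5)
        with pytest.raises(ValueError):
            GeneratorConfig(covariate_effects={"tail_length": 1.0})

    def test_mean_sequence_length_near_target(self):
        config = GeneratorConfig(seed=3, sequences_per_individual=200)
        dataset = generate_dataset(config)
        mean_length = dataset.truth["n_calls"] / dataset.truth["n_sequences"]
        assert mean_length == pytest.approx(config.mean_length, rel=0.1)


class TestRoundTrip:
    def test_label_files_reproduce_call_table(self, tmp_path):
        """Generator -> label files -> reader -> segmentation is lossless."""
        config = GeneratorConfig(
            seed=17, sequences_per_individual=8, unknown_caller_fraction=0.1
        )
        dataset = generate_dataset(config)
        write_dataset(dataset, tmp_path)
        records = []
        for path in sorted((tmp_path / "labels").glob("*.txt")):
            records.extend(read_audacity_labels(path, caller_id=path.stem))
        assert len(records) == dataset.truth["n_calls"]
        durations = sorted(r.duration for r in records)
        truth = sorted(dataset.calls["duration_s"])
        assert np.allclose(durations, truth, atol=2e-9)

        sequences = segment_sequences(records)
        assert len(sequences) == dataset.truth["n_sequences"]
        lengths = sorted(s.length for s in sequences)
        true_lengths = sorted(
            dataset.calls.groupby("true_sequence").size().tolist()
        )
        assert lengths == true_lengths

    def test_exclusion_audit_matches_generator_bookkeeping(self):
        config = GeneratorConfig(
            seed=23,
            sequences_per_individual=20,
            singleton_fraction=0.2,
            unknown_caller_fraction=0.05,
        )
        dataset = generate_dataset(config)
        sequences = segment_sequences(dataset.call_records)
        kept, audit = apply_exclusions(sequences)
        truth = dataset.truth
        # unknown-caller removal happens first; singletons among the
        # remaining sequences are dropped next
        unknown_seqs = set(
            dataset.calls.loc[dataset.calls.unknown_caller, "true_sequence"]
        )
        singleton_seqs = set(
            dataset.calls.groupby("true_sequence")
            .size()
            .pipe(lambda s: s[s == 1])
            .index
        )
        assert audit["unknown_caller"] == len(unknown_seqs)
        assert audit["singleton"] == len(singleton_seqs - unknown_seqs)
        assert len(kept) == truth["n_sequences"] - len(unknown_seqs | singleton_seqs)


class TestInteractions:
    def test_huge_rank_gap_makes_outcomes_deterministic(self):
        events = generate_interactions(
            seed=0, true_ranks={"A": 100.0, "B": 0.0}, n_events=50, rank_scale=0.0
        )
        assert all(e.winner == "A" for e in events)

    def test_equal_ranks_win_rate_near_half(self):
        events = generate_interactions(
            seed=1, true_ranks={"A": 0.0, "B": 0.0}, n_events=1000
        )
        wins_a = sum(e.winner == "A" for e in events)
        # 3.5 sigma binomial band around 500
        assert abs(wins_a - 500) < 3.5 * np.sqrt(1000 * 0.25)

    def test_elo_recovers_rank_order(self):
        """Well-separated hierarchy: fitted Elo order ~ true order."""
        ids = [f"i{k}" for k in range(6)]
        true_ranks = {ind: 3.0 * k for k, ind in enumerate(ids)}
        n_dyads = len(ids) * (len(ids) - 1) // 2
        events = generate_interactions(
            seed=2, true_ranks=true_ranks, n_events=50 * n_dyads, rank_scale=1.0
        )
        state = elo_ratings(events, individuals=ids)
        tau = stats.kendalltau(
            [true_ranks[i] for i in ids], [state.ratings[i] for i in ids]
        ).statistic
        assert tau >= 0.9

    def test_at_least_one_event_required(self):
        with pytest.raises(ValueError):
            generate_interactions(seed=0, true_ranks={"A": 0, "B": 1}, n_events=0)


class TestRecovery:
    def test_noise_free_recovery_is_exact(self, noiseless_config):
        config = dataclasses.replace(noiseless_config, sequences_per_individual=10)
        report = recovery_experiment(config, n_replicates=3)
        summary = summarize_recovery(report)
        assert summary["mean_bias"] == pytest.approx(0.0, abs=1e-8)
        assert summary["rmse"] == pytest.approx(0.0, abs=1e-8)

    def test_null_law_slopes_center_on_zero(self):
        config = GeneratorConfig(
            seed=31, law=MenzerathParams(a=0.3, b=0.0), sequences_per_individual=20
        )
        report = recovery_experiment(config, n_replicates=12)
        mean_slope = report["b_hat"].mean()
        se = report["b_hat"].std(ddof=1) / np.sqrt(len(report))
        assert abs(mean_slope) < 4 * se + 1e-3

    def test_more_sequences_reduce_error(self):
        """RMSE of the slope falls as sampling effort grows (3-point grid)."""
        rmses = []
        for n_seq in (8, 24, 72):
            config = GeneratorConfig(seed=77, sequences_per_individual=n_seq)
            report = recovery_experiment(config, n_replicates=8)
            rmses.append(summarize_recovery(report)["rmse"])
        assert rmses[2] < rmses[0]

    def test_shuffled_durations_destroy_the_length_effect(self, rng):
        """Permuting durations across sequences within individual removes
        the dependence of duration on sequence length."""
        config = GeneratorConfig(seed=41, sequences_per_individual=40)
        frame = model_frame(generate_dataset(config), segmented=False)
        hits = 0
        n_perm = 100
        for _ in range(n_perm):
            shuffled = frame.copy()
            shuffled["duration_s"] = shuffled.groupby("individual")[
                "duration_s"
            ].transform(lambda s: rng.permutation(s.to_numpy()))
            fit = fit_simple(shuffled)
            _, _, lo, hi = fit.estimates["Length"]
            hits += lo <= 0.0 <= hi
        assert hits >= 0.9 * n_perm
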