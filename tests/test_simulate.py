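"""Simulator unit tests: transcriptome, decay pools, read geometry, analytic oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from turnoverseq import (
    DecayParams,
    SimulationConfig,
    TranscriptModel,
    expected_index,
    sample_molecule_lengths,
    simulate_experiment,
    simulate_reads,
    simulate_transcriptome,
)


def _one_transcript(length=1000, tid="T", weight=1.0):
    return TranscriptModel(tid, length, "nuclear", "control", weight)


class TestTranscriptome:
    def test_empty_config_gives_empty_list(self):
        cfg = SimulationConfig(n_control=0, n_targets=0, n_chloroplast=0)
        assert simulate_transcriptome(cfg) == []

    def test_default_group_sizes(self):
        cfg = SimulationConfig()
        transcripts = simulate_transcriptome(cfg)
        assert len(transcripts) == 5719
        counts = pd.Series([t.group for t in transcripts]).value_counts()
        assert counts["control"] == 5617
        assert counts["exosome_target"] == 68
        assert counts["chloroplast"] == 34

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_control=50, n_targets=5, n_chloroplast=3, seed=1)
        a = simulate_transcriptome(cfg)
        b = simulate_transcriptome(cfg)
        assert a == b

    def test_chloroplast_origin_consistency(self):
        cfg = SimulationConfig(n_control=10, n_targets=5, n_chloroplast=5)
        for t in simulate_transcriptome(cfg):
            assert (t.group == "chloroplast") == (t.origin == "chloroplast")


class TestMoleculeLengths:
    def test_no_decay_keeps_full_length(self, rng):
        t = _one_transcript()
        pool = sample_molecule_lengths(t, DecayParams(f_intact=1.0), 500, rng)
        assert np.all(pool == t.length)

    def test_zero_draws(self, rng):
        t = _one_transcript()
        assert sample_molecule_lengths(t, DecayParams(f_intact=0.5), 0, rng).size == 0

    def test_uniform_law_mean(self, rng):
        # full truncation, uniform on {min_remaining..L}: closed-form mean
        t = _one_transcript(length=800)
        decay = DecayParams(f_intact=0.0, min_remaining=100)
        pool = sample_molecule_lengths(t, decay, 10_000, rng)
        assert pool.min() >= 100 and pool.max() <= 800
        width = 800 - 100 + 1
        se = width / np.sqrt(12) / np.sqrt(10_000)
        assert abs(pool.mean() - (100 + 800) / 2) < 3 * se

    def test_min_remaining_above_length_rejected(self, rng):
        t = _one_transcript(length=120)
        with pytest.raises(ValueError, match="min_remaining"):
            sample_molecule_lengths(t, DecayParams(f_intact=0.5, min_remaining=150), 5, rng)


class TestReads:
    def test_single_placement_when_molecule_equals_read(self, rng):
        t = _one_transcript(length=300)
        cfg = SimulationConfig(n_control=1, n_targets=0, n_chloroplast=0,
                               library_size=200, read_length=75)
        molecules = {t.id: np.full(10, 75, dtype=np.int64)}
        reads = simulate_reads(molecules, [t], cfg, "wt", rng)
        assert len(reads) == 200
        assert (reads["start"] == 0).all()

    def test_start_uniformity_chi_square(self, rng):
        # intact molecules: starts uniform on [0, L - r]; 10-bin chi-square
        t = _one_transcript(length=1000)
        cfg = SimulationConfig(n_control=1, n_targets=0, n_chloroplast=0,
                               library_size=50_000, read_length=75)
        molecules = {t.id: np.full(50_000, 1000, dtype=np.int64)}
        reads = simulate_reads(molecules, [t], cfg, "wt", rng)
        n_sites = 1000 - 75 + 1
        bins = np.histogram(reads["start"], bins=10, range=(0, n_sites))[0]
        p = stats.chisquare(bins).pvalue
        assert p > 0.01

    def test_truncated_pool_leaves_3prime_window_empty(self, rng):
        t = _one_transcript(length=1000)
        cfg = SimulationConfig(n_control=1, n_targets=0, n_chloroplast=0,
                               library_size=5_000, read_length=75)
        w = 200  # 3' window = starts [800, 1000)
        molecules = {t.id: np.full(100, 1000 - w, dtype=np.int64)}
        reads = simulate_reads(molecules, [t], cfg, "wt", rng)
        assert (reads["start"] < 800).all()

    def test_reads_stay_inside_molecules(self, small_experiment):
        cfg = small_experiment["config"]
        lengths = {t.id: t.length for t in small_experiment["transcripts"]}
        for sample, frame in small_experiment["reads"].items():
            ends = frame["start"].to_numpy() + frame["length"].to_numpy()
            caps = frame["transcript_id"].map(lengths).to_numpy()
            assert (frame["start"] >= 0).all()
            assert (ends <= caps).all()

    def test_library_size_respected(self, small_experiment):
        for frame in small_experiment["reads"].values():
            assert len(frame) == small_experiment["config"].library_size

    def test_short_molecules_skipped(self, rng):
        t = _one_transcript(length=300)
        cfg = SimulationConfig(n_control=1, n_targets=0, n_chloroplast=0,
                               library_size=100, read_length=75)
        molecules = {t.id: np.array([40, 300], dtype=np.int64)}
        reads = simulate_reads(molecules, [t], cfg, "wt", rng)
        assert len(reads) == 100  # all reads drawn from the one viable molecule


class TestExpectedIndex:
    def test_symmetry_without_edge_effect(self):
        # read length 1 removes the 3'-terminal edge effect: uniform starts
        # over the whole transcript make both windows equal
        value = expected_index(1000, DecayParams(f_intact=1.0), read_length=1)
        assert value == pytest.approx(1.0)

    def test_edge_effect_at_full_read_length(self):
        # intact molecules, fixed-length reads: the 3' window offers only
        # w - r + 1 feasible starts against w in the 5' window
        value = expected_index(1000, DecayParams(f_intact=1.0), read_length=75)
        assert value == pytest.approx(200 / (200 - 75 + 1))

    def test_full_truncation_signals_infinite_index(self):
        # starts in the 3' window [320, 400) need remaining >= 620 > L, so
        # the expected 3'-window count is exactly zero
        v = expected_index(
            400, DecayParams(f_intact=0.0, min_remaining=100), read_length=300
        )
        assert v == np.inf

    def test_monotone_in_decay(self):
        grid = [1.0, 0.8, 0.6, 0.4, 0.2, 0.0]
        values = [
            expected_index(1200, DecayParams(f_intact=f, min_remaining=150), 75)
            for f in grid
        ]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_monte_carlo_agreement(self, rng):
        # f_intact = 0.5, uniform truncation: simulate and compare within 3 SE
        L, r, n_reads = 1000, 75, 100_000
        decay = DecayParams(f_intact=0.5, min_remaining=150)
        t = _one_transcript(length=L)
        cfg = SimulationConfig(n_control=1, n_targets=0, n_chloroplast=0,
                               library_size=n_reads, read_length=r)
        pool = sample_molecule_lengths(t, decay, 4 * n_reads, rng)
        reads = simulate_reads({t.id: pool}, [t], cfg, "wt", rng)
        w = 200
        starts = reads["start"].to_numpy()
        n5 = int((starts < w).sum())
        n3 = int((starts >= L - w).sum())
        observed = n5 / n3
        expected = expected_index(L, decay, r)
        # variance inflated by pool reuse (~ reads per molecule)
        inflation = 1 + n_reads / (4 * n_reads)
        se = observed * np.sqrt(inflation * (1 / n5 + 1 / n3))
        assert abs(observed - expected) < 3 * se


class TestDeterminism:
    def test_identical_seeds_identical_reads(self):
        cfg = SimulationConfig(n_control=40, n_targets=5, n_chloroplast=3,
                               library_size=5_000, seed=3)
        _, reads_a, _ = simulate_experiment(cfg)
        _, reads_b, _ = simulate_experiment(cfg)
        for sample in reads_a:
            pd.testing.assert_frame_equal(reads_a[sample], reads_b[sample])


class TestPositionalBias:
    def test_linear_bias_shifts_reads_5prime(self, rng):
        t = _one_transcript(length=1000)
        cfg_flat = SimulationConfig(n_control=1, n_targets=0, n_chloroplast=0,
                                    library_size=30_000)
        cfg_bias = SimulationConfig(n_control=1, n_targets=0, n_chloroplast=0,
                                    library_size=30_000,
                                    positional_bias=("linear", -1.5))
        molecules = {t.id: np.full(30_000, 1000, dtype=np.int64)}
        flat = simulate_reads(molecules, [t], cfg_flat, "wt",
                              np.random.default_rng(1))
        biased = simulate_reads(molecules, [t], cfg_bias, "wt",
                                np.random.default_rng(1))
        assert biased["start"].mean() < flat["start"].mean()
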