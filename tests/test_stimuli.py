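import numpy as np
import pytest

from mrilnet.stimuli import (StimulusProgram, frozen_pattern_stream,
                             corrupt_stream, chunk_char_stream,
                             community_walk_stream, community_graph,
                             bar_image_stream, synth_correlated_sources,
                             mix_sources, amplitude_to_rate, bar_masks)


GENERATORS = {
    "frozen": lambda seed: frozen_pattern_stream(
        n_in=50, duration_ms=20_000, seed=seed),
    "chunks": lambda seed: chunk_char_stream(
        ["abcd", "efgh"], n_in=60, duration_ms=20_000, seed=seed),
    "community": lambda seed: community_walk_stream(
        n_in=60, steps=300, seed=seed),
    "bars": lambda seed: bar_image_stream(n_images=50, seed=seed),
}


@pytest.mark.parametrize("name", sorted(GENERATORS))
def test_generators_are_seed_deterministic_and_label_complete(name):
    gen = GENERATORS[name]
    a, b = gen(7), gen(7)
    assert np.array_equal(a.labels, b.labels)
    assert np.array_equal(a.rates_dense(), b.rates_dense())
    if a.raster is not None:
        assert np.array_equal(a.raster.time, b.raster.time)
    # every ms carries a label and rates are nonnegative
    assert a.labels.shape[0] == int(a.duration)
    assert np.all(a.rates >= 0)


class TestFrozenPatterns:
    def test_pattern_epochs_replay_identical_spikes(self):
        prog = frozen_pattern_stream(n_in=100, n_patterns=2, base_rate=0.02,
                                     duration_ms=60_000, seed=1)
        raster, tags = prog.raster, prog.event_tags
        starts, lengths = [], []
        lab = prog.labels
        # collect spikes of pattern 0 occurrences relative to epoch onset
        occ = {}
        for t, n, tag in zip(raster.time, raster.neuron, tags):
            if tag == 1 and lab[int(t)] == 0:
                slot = int(t // 50.0)
                occ.setdefault(slot, []).append((n, round(t - slot * 50.0, 9)))
        reps = [tuple(sorted(v)) for v in occ.values()]
        assert len(reps) > 5
        assert len(set(reps)) == 1  # frozen: identical at every occurrence

    def test_participant_rates_match_background(self):
        # population-mean rates of participants vs non-participants < 2%
        prog = frozen_pattern_stream(n_in=400, n_patterns=3, base_rate=0.01,
                                     assembly_fraction=0.5,
                                     duration_ms=200_000, seed=2)
        members = set(np.concatenate([np.array(m) for m in
                                      prog.meta["members"]]))
        part = np.array(sorted(members))
        nonpart = np.array(sorted(set(range(400)) - members))
        counts = prog.raster.counts()
        r_part = counts[part].mean() / prog.duration
        r_non = counts[nonpart].mean() / prog.duration
        assert abs(r_part - r_non) / r_non < 0.02

    def test_too_small_fraction_rejected(self):
        with pytest.raises(ValueError):
            frozen_pattern_stream(n_in=10, assembly_fraction=0.01,
                                  duration_ms=1000, seed=0)


class TestCorruptStream:
    @pytest.fixture
    def prog(self):
        return frozen_pattern_stream(n_in=80, n_patterns=1, base_rate=0.02,
                                     duration_ms=50_000, seed=3)

    def test_identity_when_all_knobs_off(self, prog):
        out = corrupt_stream(prog, 0.0, 0.0, 0.0, seed=0)
        assert np.array_equal(out.raster.time, prog.raster.time)
        assert np.array_equal(out.raster.neuron, prog.raster.neuron)

    def test_total_failure_removes_all_spikes(self, prog):
        out = corrupt_stream(prog, failure_prob=1.0, seed=0)
        assert len(out.raster) == 0

    def test_half_failure_is_binomial(self, prog):
        n0 = len(prog.raster)
        kept = [len(corrupt_stream(prog, failure_prob=0.5, seed=s).raster)
                for s in range(10)]
        se = np.sqrt(n0 * 0.25)
        assert abs(np.mean(kept) - 0.5 * n0) < 4 * se / np.sqrt(10)

    def test_background_ratio_adds_expected_count(self, prog):
        n_target = int((prog.event_tags == 1).sum())
        out = corrupt_stream(prog, background_ratio=2.0, seed=0)
        added = len(out.raster) - len(prog.raster)
        assert added == pytest.approx(2 * n_target, rel=0.1)

    def test_jitter_keeps_spikes_inside_epochs(self, prog):
        out = corrupt_stream(prog, jitter_sd_ms=20.0, seed=0)
        lab = prog.labels
        for t, tag in zip(out.raster.time, out.event_tags):
            if tag == 1:
                assert lab[int(t)] == 0  # still inside a pattern slot


class TestChunkChars:
    def test_neurons_burst_only_for_their_character(self):
        prog = chunk_char_stream(["ab"], n_in=20, duration_ms=3000, seed=4)
        prefs = np.array(prog.meta["prefs"])
        dense = prog.rates_dense()
        for j in range(20):
            on = dense[:, j] > 0
            if on.any():
                # when neuron j is on, the current char is its preference
                idx = np.array(prog.meta["char_sequence"])[
                    (np.nonzero(on)[0] // 30)]
                assert set(idx) == {prefs[j]}

    def test_disjoint_chunk_configuration(self):
        prog = chunk_char_stream(["abcd", "efgh", "ijkl"], n_in=1000,
                                 duration_ms=10_000, seed=5)
        assert prog.meta["alphabet"] == "abcdefghijkl"
        assert set(np.unique(prog.labels)) <= {0, 1, 2}
        assert prog.rates.shape == (12, 1000)

    def test_overlapping_chunks_share_characters(self):
        prog = chunk_char_stream(["abcd", "befg", "ehij"], n_in=100,
                                 duration_ms=10_000, seed=6)
        assert "b" in prog.meta["alphabet"] and "e" in prog.meta["alphabet"]
        assert len(prog.meta["alphabet"]) == 10  # 12 slots, 2 shared

    def test_distractors_insert_unlabeled_epochs(self):
        prog = chunk_char_stream(["abcd"], n_in=50, duration_ms=30_000,
                                 distractors=True, seed=7)
        assert prog.meta["alphabet"] == "abcdefghijklmnopqrstuvwxyz"
        assert (prog.labels == -1).any()
        assert (prog.labels == 0).any()

    def test_empty_chunks_rejected(self):
        with pytest.raises(ValueError):
            chunk_char_stream([], n_in=10, duration_ms=1000, seed=0)


class TestCommunityWalk:
    def test_graph_is_4_regular_on_15_nodes(self):
        adj = community_graph()
        assert adj.shape == (15, 15)
        assert np.all(adj.sum(axis=0) == 4)
        assert np.array_equal(adj, adj.T)

    def test_walk_only_visits_neighbors(self):
        prog = community_walk_stream(n_in=30, steps=2000, seed=8)
        adj = community_graph()
        walk = np.array(prog.meta["walk"])
        assert all(adj[a, b] for a, b in zip(walk[:-1], walk[1:]))

    def test_transition_frequencies_uniform_quarter(self):
        prog = community_walk_stream(n_in=10, steps=40_000, seed=9)
        walk = np.array(prog.meta["walk"])
        counts = {}
        for a, b in zip(walk[:-1], walk[1:]):
            counts[(a, b)] = counts.get((a, b), 0) + 1
        from_counts = np.bincount(walk[:-1], minlength=15)
        freqs = [counts[k] / from_counts[k[0]] for k in counts]
        assert np.max(np.abs(np.array(freqs) - 0.25)) < 0.04

    def test_stationary_occupancy_uniform(self):
        # the graph is regular, so the walk's stationary law is uniform
        prog = community_walk_stream(n_in=10, steps=60_000, seed=10)
        occ = np.bincount(np.array(prog.meta["walk"]), minlength=15)
        from scipy.stats import chisquare
        assert chisquare(occ).pvalue > 0.001


class TestBarImages:
    def test_presentation_timing_40_on_30_off(self):
        prog = bar_image_stream(n_images=20, present_ms=40, gap_ms=30, seed=11)
        dense = prog.rates_dense()
        on = dense.sum(axis=1) > 0
        lab = prog.labels
        for k in range(20):
            sl = slice(k * 70, k * 70 + 40)
            assert on[sl].all()
            assert set(lab[sl]) <= set(range(8))
            assert not on[k * 70 + 40:(k + 1) * 70].any()
            assert set(lab[k * 70 + 40:(k + 1) * 70]) == {-1}

    def test_zero_noise_is_deterministic_in_orientation(self):
        prog = bar_image_stream(n_images=40, noise_level=0.0, seed=12)
        dense = prog.rates_dense()
        by_ori = {}
        for k in range(40):
            ori = prog.labels[k * 70]
            img = dense[k * 70]
            by_ori.setdefault(ori, []).append(img)
        for ori, imgs in by_ori.items():
            for img in imgs[1:]:
                assert np.array_equal(img, imgs[0])

    def test_orthogonal_bars_overlap_minimally(self):
        masks = bar_masks(16, 8)
        m0, m90 = masks[0] > 0, masks[4] > 0
        overlap = (m0 & m90).sum()
        assert overlap < 0.25 * min(m0.sum(), m90.sum())


class TestSources:
    def test_independent_sources_uncorrelated(self):
        rs = [np.corrcoef(*synth_correlated_sources(
            correlation_mode="independent", seed=s))[0, 1] for s in range(6)]
        assert np.max(np.abs(rs)) < 0.15
        assert abs(np.mean(rs)) < 0.1

    def test_dependent_sources_in_target_band(self):
        rs = [np.corrcoef(*synth_correlated_sources(
            correlation_mode="dependent", seed=s))[0, 1] for s in range(6)]
        assert all(0.4 <= r <= 0.8 for r in rs)

    def test_identical_seed_identical_waveforms(self):
        a1, a2 = synth_correlated_sources(seed=3)
        b1, b2 = synth_correlated_sources(seed=3)
        assert np.array_equal(a1, b1) and np.array_equal(a2, b2)


class TestMixing:
    def test_zero_angle_is_identity(self, rng):
        x1, x2 = rng.normal(size=(2, 100))
        m1, m2, cfg = mix_sources(x1, x2, theta=0.0)
        assert np.allclose(m1, x1) and np.allclose(m2, x2)
        assert cfg.crosstalk == 0.0

    def test_forty_five_degrees_collapses_mixtures(self, rng):
        x1, x2 = rng.normal(size=(2, 100))
        m1, m2, cfg = mix_sources(x1, x2, theta=np.pi / 4)
        assert np.allclose(m1, m2)
        assert cfg.crosstalk == pytest.approx(1.0)

    def test_fixed_matrix_preset_has_crosstalk_half(self, rng):
        x1, x2 = rng.normal(size=(2, 50))
        _, _, cfg = mix_sources(x1, x2)
        assert np.array_equal(cfg.matrix, [[1.0, 0.5], [0.5, 1.0]])
        assert cfg.crosstalk == pytest.approx(0.5)

    def test_unmixing_recovers_sources(self, rng):
        x1, x2 = rng.normal(size=(2, 200))
        for theta in (0.1, 0.4, 0.7):
            m1, m2, cfg = mix_sources(x1, x2, theta=theta)
            rec = np.linalg.inv(cfg.matrix) @ np.vstack([m1, m2])
            assert np.max(np.abs(rec - np.vstack([x1, x2]))) < 1e-10


class TestAmplitudeToRate:
    def test_peak_maps_to_max_rate_and_scale_invariance(self):
        fs = 100.0
        t = np.arange(1000) / fs
        sig = np.sin(2 * np.pi * 0.5 * t)
        prog = amplitude_to_rate([sig, 2 * sig], n_in=10, fs=fs,
                                 max_rate=0.01)
        dense = prog.rates_dense()
        assert dense.max() == pytest.approx(0.01, rel=1e-3)
        # both halves encode the same normalized envelope
        assert np.allclose(dense[:, :5], dense[:, 5:], atol=1e-12)

    def test_quiet_segment_is_silent(self):
        fs = 100.0
        sig = np.r_[np.zeros(500), np.ones(500)]
        prog = amplitude_to_rate([sig], n_in=4, fs=fs)
        dense = prog.rates_dense()
        assert np.all(dense[:4000] <= 1e-6)

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            amplitude_to_rate([np.zeros(100)], n_in=4, fs=100.0)


def test_wav_round_trip(tmp_path):
    from mrilnet.stimuli import save_wav, load_wav
    x1, _ = synth_correlated_sources(duration_s=0.5, sample_rate=8000.0,
                                     seed=0, audio=True)
    save_wav(tmp_path / "a.wav", x1, 8000.0)
    back, fs = load_wav(tmp_path / "a.wav")
    assert fs == 8000.0
    assert len(back) == len(x1)
    scale = np.max(np.abs(x1)) or 1.0
    assert np.max(np.abs(back - x1 / scale)) < 1e-3  # 16-bit quantization


def test_program_save_load_round_trip(tmp_path):
    prog = frozen_pattern_stream(n_in=20, duration_ms=5_000, seed=3)
    prog.save(tmp_path / "prog")
    back = StimulusProgram.load(tmp_path / "prog")
    assert np.array_equal(back.labels, prog.labels)
    assert back.dt == prog.dt
    assert np.array_equal(back.raster.neuron, prog.raster.neuron)
    assert np.allclose(back.raster.time, prog.raster.time)


def test_time_slice_preserves_rates_and_shifts_raster():
    prog = frozen_pattern_stream(n_in=30, duration_ms=10_000, seed=13)
    part = prog.time_slice(2_000, 7_000)
    assert part.duration == 5_000
    assert part.labels.shape[0] == 5_000
    assert part.raster.time.max() < 5_000
    full_in_window = np.sum((prog.raster.time >= 2_000)
                            & (prog.raster.time < 7_000))
    assert len(part.raster) == full_in_window
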