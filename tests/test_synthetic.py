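"""Synthetic cohort generator: determinism, planted contrasts, consistency."""

import numpy as np
import pytest

import pawprint as pp


def _autocorr(x):
    x = x - x.mean()
    full = np.correlate(x, x, mode="full")[len(x) - 1 :]
    return full / full[0]


class TestDeterminism:
    def test_identical_config_identical_cohort(self):
        cfg = pp.SynthConfig(n_trials_per_group=2, seed=7)
        man1, tr1 = pp.generate_cohort(cfg)
        man2, tr2 = pp.generate_cohort(cfg)
        assert man1.equals(man2)
        for a, b in zip(tr1, tr2):
            np.testing.assert_array_equal(a.track.coords, b.track.coords)
            np.testing.assert_array_equal(a.render().frames, b.render().frames)

    def test_cohort_extension_preserves_existing_trials(self):
        small = pp.SynthConfig(n_trials_per_group=2, seed=7)
        large = pp.SynthConfig(n_trials_per_group=4, seed=7)
        _, tr_small = pp.generate_cohort(small)
        _, tr_large = pp.generate_cohort(large)
        by_id = {t.trial_id: t for t in tr_large}
        for t in tr_small:
            np.testing.assert_array_equal(t.track.coords, by_id[t.trial_id].track.coords)

    def test_grid_walk_deterministic(self, grid):
        w1 = pp.simulate_grid_walk(grid, 1.0, 50, seed=5)
        w2 = pp.simulate_grid_walk(grid, 1.0, 50, seed=5)
        np.testing.assert_array_equal(w1, w2)


class TestCohortStructure:
    def test_balanced_groups_and_manifest_columns(self, small_cohort):
        cfg, manifest, trials = small_cohort
        assert len(trials) == 2 * cfg.n_trials_per_group
        assert manifest.group.value_counts().tolist() == [8, 8]
        assert set(manifest.columns) >= {
            "trial_id", "animal_id", "litter_id", "group",
            "video_path", "track_path", "start_offset_frames",
        }

    def test_track_shapes_and_invariants(self, small_cohort):
        _, _, trials = small_cohort
        track = trials[0].track
        assert track.coords.shape == (150, len(pp.PART_NAMES), 2)
        assert np.all(np.isfinite(track.coords))
        assert np.all((track.likelihood >= 0) & (track.likelihood <= 1))

    def test_arena_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            pp.SynthConfig(arena_px=(60, 50))


class TestPlantedContrasts:
    def test_planted_limb_spread_exact_when_noise_free(self):
        # the planted posture means, rendered without sampling noise
        for mean in (96.2, 87.57):
            params = pp.GroupParams(limb_spread_px=(mean, 0.0))
            cfg = pp.SynthConfig(
                group_params=(params, params), keypoint_jitter_px=0.0, seed=1
            )
            _, trials = pp.generate_cohort(
                pp.SynthConfig(n_trials_per_group=1, group_params=(params, params),
                               keypoint_jitter_px=0.0, seed=1)
            )
            spread = pp.limb_spread(trials[0].track, frame_index=1)
            assert spread == pytest.approx(mean, abs=1e-9)

    def test_limb_spread_sample_mean_recovers_planted_mean(self):
        params = pp.GroupParams(limb_spread_px=(90.0, 8.0))
        cfg = pp.SynthConfig(n_trials_per_group=60, group_params=(params, params),
                             group_names=("a", "b"), seed=5)
        _, trials = pp.generate_cohort(cfg)
        vals = np.array([pp.limb_spread(t.track) for t in trials[:100]])
        sem = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 90.0) < 3 * sem + 1e-9

    def test_periodic_group_nose_autocorrelation_peaks_at_period(self):
        params = pp.GroupParams(period_frames=11, return_fidelity=1.0,
                                locomotion_rate=0.7)
        cfg = pp.SynthConfig(n_trials_per_group=3,
                             group_params=(pp.CONTROL_PARAMS, params), seed=9)
        _, trials = pp.generate_cohort(cfg)
        for trial in trials[3:]:
            nose_x = trial.track.part("nose")[:, 0]
            ac = _autocorr(nose_x)
            assert ac[11] > ac[10] and ac[11] > ac[12]

    def test_perfect_fidelity_track_is_exactly_periodic(self):
        params = pp.GroupParams(period_frames=11, return_fidelity=1.0,
                                locomotion_rate=0.7, start_latency_frames=0)
        _, track = pp.render_trial(params, seed=3)
        nose = track.part("nose")
        gaps = np.linalg.norm(nose[11:] - nose[:-11], axis=1)
        assert np.all(gaps < 2.0)

    def test_no_locomotion_full_latency_track_constant(self):
        params = pp.GroupParams(locomotion_rate=0.0, start_latency_frames=150)
        cfg = pp.SynthConfig(n_trials_per_group=1, group_params=(params, params),
                             keypoint_jitter_px=0.0, seed=2)
        _, trials = pp.generate_cohort(cfg)
        coords = trials[0].track.coords
        assert np.allclose(coords, coords[0])


class TestRendering:
    def test_single_frame_trial(self):
        frames, track = pp.render_trial(pp.CONTROL_PARAMS, n_frames=1, seed=0)
        assert frames.frames.shape[0] == 1
        assert track.n_frames == 1

    def test_rendered_centroid_matches_body_center_track(self, small_cohort):
        _, _, trials = small_cohort
        trial = trials[0]
        frames = trial.render().frames
        for t in (0, 75, 149):
            ys, xs = np.nonzero(frames[t] > 128)
            centroid = np.array([xs.mean(), ys.mean()])
            err = np.linalg.norm(centroid - trial.track.part("body_center")[t])
            assert err < 1.0
        trial.frames = None

    def test_body_parts_rendered_bright_at_track_coordinates(self, small_cohort):
        _, _, trials = small_cohort
        trial = trials[1]
        frame = trial.render().frames[0]
        for part in ("nose", "left_fore", "right_hind"):
            x, y = trial.track.part(part)[0]
            assert frame[int(round(y)), int(round(x))] > 200
        trial.frames = None


class TestGridWalk:
    def test_zero_rate_no_entries(self, grid):
        walk = pp.simulate_grid_walk(grid, 0.0, 100, seed=1)
        assert pp.square_sequence(walk, walk, grid) == []

    def test_entry_count_tracks_rate(self, grid):
        rate, fps, n = 1.2, 3.0, 600
        counts = []
        for seed in range(10):
            walk = pp.simulate_grid_walk(grid, rate, n, seed=seed, fps=fps)
            row = pp.score_measures(pp.square_sequence(walk, walk, grid), grid)
            counts.append(row.total / 2)  # same walk passed as both paws
        expected = rate * n / fps
        assert abs(np.mean(counts) - expected) / expected < 0.15

    def test_walk_starts_in_start_block(self, grid):
        walk = pp.simulate_grid_walk(grid, 1.0, 10, seed=3)
        assert pp.locate_square(*walk[0], grid) in grid.start_squares


class TestDlcRoundTrip:
    def test_csv_roundtrip_preserves_track(self, tmp_path, small_cohort):
        _, _, trials = small_cohort
        track = trials[0].track
        path = tmp_path / "track.csv"
        track.to_dlc_csv(path)
        # three header rows: scorer / bodyparts / coords
        header = path.read_text().splitlines()[:3]
        assert header[1].count("nose") == 3
        back = pp.read_dlc_csv(path, fps=track.fps)
        assert back.part_names == track.part_names
        np.testing.assert_allclose(back.coords, track.coords)
        np.testing.assert_allclose(back.likelihood, track.likelihood)
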