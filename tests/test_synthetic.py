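"""Synthetic-data generator: walkers, pheromone field, eggs, spikes, EAG."""

import numpy as np
import pytest
from scipy.stats import binom

from quadfly import (
    EggLayingConfig,
    Phase,
    PheromoneField,
    Quadrant,
    SimulationConfig,
    SpikeTrainConfig,
    ThreeWellPlate,
    attraction_index,
    delta_spikes,
    oviposition_preference_index,
    simulate_eag_trace,
    simulate_eggs,
    simulate_flies,
    simulate_spike_train,
    step_pheromone,
)
from quadfly.ephys import eag_peak
from quadfly.synthetic import run_post_stimulus_protocol

from conftest import quick_sim


class TestSimulateFlies:
    def test_sample_count_contract(self, arena):
        cfg = SimulationConfig(
            n_flies=3, frame_rate=12.0, phases=(Phase("pre", 7.5),), seed=4
        )
        ts = simulate_flies(cfg, arena)
        assert all(len(t) == round(12.0 * 7.5) for t in ts.tracks)

    def test_determinism_bitwise(self, arena):
        cfg = SimulationConfig(n_flies=6, frame_rate=10.0, phases=(Phase("pre", 5.0),), seed=7)
        a = simulate_flies(cfg, arena)
        b = simulate_flies(cfg, arena)
        for ta, tb in zip(a.tracks, b.tracks):
            assert np.array_equal(ta.xy, tb.xy)
            assert ta.sex == tb.sex

    def test_positions_confined_to_mask(self, arena):
        from shapely import contains_xy

        ts = quick_sim(arena, beta=2.0, seed=11, n_flies=8, duration=30.0)
        for t in ts.tracks:
            inside = contains_xy(arena.mask, t.xy[:, 0], t.xy[:, 1])
            assert inside.all()

    def test_unbiased_walk_has_zero_attraction(self, arena):
        """beta = 0: mean AI over replicate seeds is 0 within 3 SEM."""
        ais = [
            attraction_index(
                quick_sim(arena, beta=0.0, seed=s, duration=60.0), Quadrant.Q1
            ).AI
            for s in range(20)
        ]
        sem = np.std(ais, ddof=1) / np.sqrt(len(ais))
        assert abs(np.mean(ais)) < 3 * sem + 1e-12

    def test_stronger_bias_gives_stronger_attraction(self, arena):
        ai = {}
        for beta in (1.0, 5.0):
            ai[beta] = np.mean(
                [
                    attraction_index(
                        quick_sim(arena, beta=beta, seed=s, duration=60.0), Quadrant.Q1
                    ).AI
                    for s in range(20)
                ]
            )
        assert ai[5.0] > ai[1.0]

    def test_zero_duration_rejected(self, arena):
        with pytest.raises(ValueError):
            Phase("pre", 0.0)

    def test_field_arena_mismatch_rejected(self, arena):
        from quadfly import build_arena

        other = build_arena(10.0, 10.0)
        f = PheromoneField.for_arena(other)
        cfg = SimulationConfig(n_flies=2, frame_rate=5.0, phases=(Phase("pre", 2.0),))
        with pytest.raises(ValueError):
            simulate_flies(cfg, arena, pheromone=f)


class TestPheromoneField:
    def test_pure_decay_matches_closed_form(self, arena):
        f = PheromoneField.for_arena(arena, evaporation_rate=0.01)
        f.grid[50, 50] = 2.0
        f.grid[100, 120] = 3.0
        m0 = f.total_mass
        zeros = np.zeros_like(f.grid)
        t = 0.0
        for _ in range(25):
            step_pheromone(f, zeros, False, 4.0)
            t += 4.0
        assert f.total_mass == pytest.approx(m0 * np.exp(-0.01 * t), rel=1e-9)

    def test_large_temperature_factor_abolishes_mass(self, arena):
        f = PheromoneField.for_arena(arena, evaporation_rate=0.01, temperature_factor=1e4)
        f.grid[10, 10] = 1.0
        step_pheromone(f, np.zeros_like(f.grid), False, 10.0)
        assert f.total_mass < 1e-12

    def test_mass_balance_per_step(self, arena):
        """Deposit integral minus decay matches the field total exactly."""
        rng = np.random.default_rng(3)
        f = PheromoneField.for_arena(arena, evaporation_rate=0.02, deposit_rate=0.5)
        expected = 0.0
        dt = 0.3
        for _ in range(50):
            occ = np.zeros_like(f.grid)
            cells = rng.integers(0, f.grid.shape[0], (5, 2))
            occ[cells[:, 0], cells[:, 1]] = 1.0
            step_pheromone(f, occ, True, dt)
            expected = expected * np.exp(-0.02 * dt) + 0.5 * dt * occ.sum()
            assert f.total_mass == pytest.approx(expected, rel=1e-6)

    def test_female_only_agents_leave_field_empty(self, arena):
        f = PheromoneField.for_arena(arena)
        cfg = SimulationConfig(
            n_flies=6,
            frame_rate=5.0,
            phases=(Phase("stimulus", 20.0, Quadrant.Q1, odor_is_food=True),),
            sex_of_agents=("female",) * 6,
            seed=2,
        )
        simulate_flies(cfg, arena, pheromone=f)
        assert f.total_mass == 0.0

    def test_male_agents_deposit_only_in_odor_quadrant(self, arena):
        f = PheromoneField.for_arena(arena, evaporation_rate=0.0)
        cfg = SimulationConfig(
            n_flies=6,
            frame_rate=5.0,
            phases=(Phase("stimulus", 30.0, Quadrant.Q1, odor_is_food=True),),
            sex_of_agents=("male",) * 6,
            bias_strength=3.0,
            seed=2,
        )
        simulate_flies(cfg, arena, pheromone=f)
        assert f.total_mass > 0
        outside = ~f.quadrant_mask(Quadrant.Q1)
        assert f.grid[outside].sum() == 0.0

    def test_negative_dt_rejected(self, arena):
        f = PheromoneField.for_arena(arena)
        with pytest.raises(ValueError):
            step_pheromone(f, np.zeros_like(f.grid), False, -1.0)

    def test_bilinear_interpolation_recovers_linear_field(self, arena):
        f = PheromoneField.for_arena(arena, plume_sigma_cm=0.0)
        nr, nc = f.grid.shape
        rows, cols = np.meshgrid(np.arange(nr) + 0.5, np.arange(nc) + 0.5, indexing="ij")
        x, y = arena.px_to_cm(rows, cols)
        f.grid[:] = 2.0 * x + 3.0 * y
        xs = np.array([5.0, 9.3, 14.2])
        ys = np.array([4.1, 10.0, 12.7])
        np.testing.assert_allclose(f.interpolate(xs, ys), 2 * xs + 3 * ys, rtol=1e-9)
        gx, gy = f.gradient(xs, ys, sensed=False)
        np.testing.assert_allclose(gx, 2.0, rtol=1e-6)
        np.testing.assert_allclose(gy, 3.0, rtol=1e-6)


class TestPostStimulusProtocol:
    def test_male_deposition_yields_post_aggregation_female_does_not(self, arena):
        from quadfly.stats import post_stimulus_analysis

        post_ai = {}
        for sexes in ("male", "female"):
            ais = []
            for seed in (100, 200):
                run = run_post_stimulus_protocol(
                    arena,
                    seed=seed,
                    n_depositors=10,
                    n_detectors=10,
                    depositor_sexes=sexes,
                    stimulus_duration=60.0,
                    post_duration=120.0,
                    frame_rate=10.0,
                )
                _, post = post_stimulus_analysis(
                    run.stimulus_ts,
                    run.post_ts,
                    run.odor_quadrant,
                    run.rotation_applied,
                )
                ais.append(post.AI)
            post_ai[sexes] = np.mean(ais)
        assert post_ai["male"] > 0.3
        assert abs(post_ai["female"]) < 0.2

    def test_remapped_quadrant_follows_rotation(self, arena):
        run = run_post_stimulus_protocol(
            arena,
            seed=5,
            n_depositors=4,
            n_detectors=4,
            stimulus_duration=10.0,
            post_duration=10.0,
            frame_rate=5.0,
            odor_quadrant=Quadrant.Q1,
            rotation=90,
        )
        assert run.remapped_quadrant is Quadrant.Q2
        assert run.post_ts.arena.rotation == 90


class TestSimulateEggs:
    def test_degenerate_weights_put_all_eggs_in_one_well(self):
        eggs = simulate_eggs(
            EggLayingConfig((1.0, 0.0, 0.0), n_eggs_mean=80, seed=1), ThreeWellPlate()
        )
        assert (eggs["region"] == "well1").all()
        counts = [(eggs["region"] == f"well{i+1}").sum() for i in range(3)]
        assert oviposition_preference_index(counts, 0).OPI == 1.0

    def test_uniform_weights_within_multinomial_band(self, arena):
        eggs = simulate_eggs(
            EggLayingConfig((1, 1, 1, 1), n_eggs_mean=400, seed=3), arena
        )
        n = len(eggs)
        lo, hi = binom.ppf([0.005, 0.995], n, 0.25)
        for q in ("Q1", "Q2", "Q3", "Q4"):
            assert lo <= (eggs["region"] == q).sum() <= hi

    def test_weighted_quadrant_fraction_within_binomial_ci(self, arena):
        eggs = simulate_eggs(
            EggLayingConfig((5, 1, 1, 1), n_eggs_mean=2000, seed=9), arena
        )
        n = len(eggs)
        k = (eggs["region"] == "Q1").sum()
        lo, hi = binom.ppf([0.005, 0.995], n, 5 / 8)
        assert lo <= k <= hi

    def test_positions_match_region_labels(self, arena):
        from quadfly.geometry import assign_quadrants

        eggs = simulate_eggs(EggLayingConfig((1, 2, 3, 4), n_eggs_mean=300, seed=5), arena)
        labels = assign_quadrants(eggs["x_cm"].to_numpy(), eggs["y_cm"].to_numpy(), arena)
        expected = eggs["region"].map({"Q1": 0, "Q2": 1, "Q3": 2, "Q4": 3}).to_numpy()
        assert (labels == expected).all()

    def test_determinism_and_zero_weight_rejection(self, arena):
        a = simulate_eggs(EggLayingConfig((2, 1, 1, 1), seed=4), arena)
        b = simulate_eggs(EggLayingConfig((2, 1, 1, 1), seed=4), arena)
        assert a.equals(b)
        with pytest.raises(ValueError):
            EggLayingConfig((0.0, 0.0, 0.0))


class TestSimulateSpikeTrain:
    def test_no_modulation_gives_zero_mean_delta(self):
        deltas = [
            delta_spikes(
                simulate_spike_train(
                    SpikeTrainConfig(baseline_rate=20, evoked_rate=20, seed=s)
                )
            ).delta
            for s in range(1000)
        ]
        se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(np.mean(deltas)) < 3 * se + 1e-12

    def test_zero_rates_give_empty_train(self):
        tr = simulate_spike_train(SpikeTrainConfig(baseline_rate=0, evoked_rate=0, seed=1))
        assert tr.spike_times.size == 0

    def test_poisson_expectation_of_delta(self):
        deltas = [
            delta_spikes(
                simulate_spike_train(
                    SpikeTrainConfig(baseline_rate=10, evoked_rate=40, latency=0.5, seed=s)
                )
            ).delta
            for s in range(1000)
        ]
        se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert np.mean(deltas) == pytest.approx(30.0, abs=3 * se)

    def test_sorted_and_deterministic(self):
        a = simulate_spike_train(SpikeTrainConfig(seed=42))
        b = simulate_spike_train(SpikeTrainConfig(seed=42))
        assert np.array_equal(a.spike_times, b.spike_times)
        assert (np.diff(a.spike_times) >= 0).all()


class TestSimulateEAG:
    def test_noiseless_peak_equals_amplitude(self):
        t, v = simulate_eag_trace(2.0, onset=1.0, noise_sd=0.0, fs=1000.0, seed=0)
        m = eag_peak(v, 1000.0, baseline_window=(0.0, 1.0), response_window=(1.0, 3.0))
        assert m.peak_deflection_mV == pytest.approx(2.0, abs=1e-9)

    def test_zero_amplitude_zero_noise_gives_zero_peak(self):
        t, v = simulate_eag_trace(0.0, onset=1.0, noise_sd=0.0, fs=500.0, seed=0)
        m = eag_peak(v, 500.0, baseline_window=(0.0, 1.0), response_window=(1.0, 3.0))
        assert m.peak_deflection_mV == 0.0

    def test_noisy_peak_stays_near_amplitude(self):
        peaks = []
        for seed in range(100):
            _, v = simulate_eag_trace(2.0, onset=1.0, noise_sd=0.05, fs=1000.0, seed=seed)
            peaks.append(
                eag_peak(
                    v, 1000.0, baseline_window=(0.0, 1.0), response_window=(1.0, 3.0)
                ).peak_deflection_mV
            )
        assert min(peaks) > 1.8
        assert max(peaks) < 2.2


class TestRenderFrames:
    def test_single_fly_single_component_per_frame(self, arena):
        from skimage.measure import label

        ts = quick_sim(arena, beta=0.0, seed=3, n_flies=1, duration=2.0, frame_rate=5.0)
        frames = __import__("quadfly").render_frames(ts, arena, fly_radius_px=2)
        assert frames.dtype == np.uint8
        assert frames.shape[0] == 10
        for fr in frames:
            assert label(fr < 128).max() == 1

    def test_round_trip_centroid_error_below_half_pixel(self, arena):
        from quadfly import DetectionParams, detect_blobs, render_frames

        ts = quick_sim(arena, beta=0.0, seed=8, n_flies=1, duration=1.0, frame_rate=5.0)
        frames = render_frames(ts, arena, fly_radius_px=2)
        gt = ts.tracks[0]
        for k, fr in enumerate(frames):
            dets = detect_blobs(fr, DetectionParams(threshold=128), frame_index=k)
            assert len(dets) == 1
            row, col = arena.cm_to_px(gt.xy[k, 0], gt.xy[k, 1])
            assert np.hypot(dets[0].y - row, dets[0].x - col) < 0.5

    def test_overlapping_flies_fuse_into_one_component(self, arena):
        from skimage.measure import label

        from quadfly import render_frames
        from quadfly.tracking import Track, TrackSet

        a = Track(id=0, start_frame=0, xy=np.array([[9.0, 9.0]]))
        b = Track(id=1, start_frame=0, xy=np.array([[9.2, 9.0]]))  # 2 px apart
        ts = TrackSet(tracks=[a, b], frame_rate=5.0, arena=arena)
        frames = render_frames(ts, arena, fly_radius_px=2)
        assert label(frames[0] < 128).max() == 1

    def test_out_of_bounds_position_rejected(self, arena):
        from quadfly import render_frames
        from quadfly.tracking import Track, TrackSet

        t = Track(id=0, start_frame=0, xy=np.array([[25.0, 5.0]]))
        ts = TrackSet(tracks=[t], frame_rate=5.0, arena=arena)
        with pytest.raises(ValueError):
            render_frames(ts, arena)
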