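import numpy as np
import pytest

from quadfly import Phase, Quadrant, SimulationConfig, build_arena
from quadfly.tracking import Track, TrackSet


@pytest.fixture
def arena():
    return build_arena(19.5, 10.0, 0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def make_trackset(arena, samples_by_quadrant, frame_rate=30.0, jitter=0.0, seed=0):
    """Build a TrackSet with a given number of samples per quadrant.

    Samples are placed at (optionally jittered) quadrant centroids, one
    track per quadrant, frames consecutive from 0.
    """
    from quadfly.geometry import quadrant_centroid

    rng = np.random.default_rng(seed)
    tracks = []
    for i, (q, n) in enumerate(samples_by_quadrant.items()):
        if n == 0:
            continue
        cx, cy = quadrant_centroid(q, arena)
        xy = np.tile([cx, cy], (n, 1))
        if jitter:
            xy += rng.uniform(-jitter, jitter, xy.shape)
        tracks.append(Track(id=i, start_frame=0, xy=xy))
    return TrackSet(tracks=tracks, frame_rate=frame_rate, arena=arena)


def quick_sim(arena, beta, seed, n_flies=10, duration=60.0, frame_rate=5.0,
              phase="stimulus", odor_quadrant=Quadrant.Q1):
    cfg = SimulationConfig(
        n_flies=n_flies,
        frame_rate=frame_rate,
        phases=(Phase(phase, duration, odor_quadrant if phase == "stimulus" else None),),
        bias_strength=beta,
        seed=seed,
    )
    from quadfly import simulate_flies

    return simulate_flies(cfg, arena)
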