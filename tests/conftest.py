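import numpy as np
import pytest

from mechanoquant.simulate import FlecsSimSpec, simulate_flecs_stack


@pytest.fixture(scope="session")
def flecs_fixture():
    """Small mixed-occupancy micropattern movie with ground truth.

    Uses the spec'd assay geometry with a 30-frame movie and a stimulus at
    frame 10; half the patterns carry a cell.
    """
    spec = FlecsSimSpec(
        n_patterns=12,
        occupancy_fraction=0.5,
        contraction_rate=0.002,
        stimulus_multiplier=3.0,
        stimulus_frame=10,
        rng_seed=7,
    )
    stack, truth = simulate_flecs_stack(spec, n_frames=30)
    return spec, stack, truth


@pytest.fixture(scope="session")
def flecs_static_fixture():
    """No-contraction control movie: k=0, m=1."""
    spec = FlecsSimSpec(
        n_patterns=6,
        occupancy_fraction=1.0,
        contraction_rate=0.0,
        stimulus_multiplier=1.0,
        stimulus_frame=10,
        rng_seed=3,
    )
    stack, truth = simulate_flecs_stack(spec, n_frames=20)
    return spec, stack, truth


def match_tracks_to_truth(tracks, truth):
    """Pair measured pattern tracks with ground-truth rows by centroid."""
    t0 = truth[truth.frame == 0]
    pairs = []
    for tr in tracks:
        d = np.hypot(
            t0.centroid_y.to_numpy() - tr.centroid[0],
            t0.centroid_x.to_numpy() - tr.centroid[1],
        )
        pairs.append((tr, t0.iloc[int(np.argmin(d))]))
    return pairs
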