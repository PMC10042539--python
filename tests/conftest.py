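import logging
import warnings

import numpy as np
import pytest

from mitoqpi.config import RunConfig
from mitoqpi.pipeline import analyze_movie
from mitoqpi.synthetic import SynthParams, generate_timelapse

logging.disable(logging.CRITICAL)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_movie():
    """A small, fast synthetic co-culture movie with a known truth table.

    Half the founders are recipients so both classes are well represented
    even at this size.
    """
    params = SynthParams(
        n_cells=6,
        duration=6.0,
        image_shape=(256, 256),
        cell_radius=(8.0, 10.0),
        birth_mass=(120.0, 200.0),
        recipient_fraction=0.5,
        seed=3,
    )
    phase, rfp, donor, truth = generate_timelapse(params)
    return params, phase, rfp, donor, truth


@pytest.fixture(scope="session")
def small_movie_analysis(small_movie):
    _, phase, rfp, donor, _ = small_movie
    return analyze_movie(phase, rfp, donor, RunConfig())


def match_founders_to_tracks(truth, tracks):
    """Map each frame-0 track to the nearest ground-truth founder."""
    f0 = truth.frames[truth.frames.frame == 0]
    cells = truth.cells.set_index("cell_id")
    out = {}
    for tr in tracks:
        if tr.frame_indices[0] != 0:
            continue
        r0, c0 = tr.centroids[0]
        d = np.hypot(f0.row - r0, f0.col - c0)
        cell_id = int(f0.iloc[int(np.argmin(d))].cell_id)
        out[tr.track_id] = cells.loc[cell_id]
    return out
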