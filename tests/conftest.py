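import numpy as np
import pandas as pd
import pytest

from endomat import syndata


@pytest.fixture(scope="session")
def default_scene():
    """Reference synthetic scene: movie, latent tracks, scripted events."""
    return syndata.default_movie_scene(seed=0, n_frames=100)


@pytest.fixture(scope="session")
def small_optics():
    return syndata.OpticsParams(shape=(12, 48, 48))


@pytest.fixture()
def single_blob_movie(small_optics):
    """One bright stationary endosome, noise-free."""
    tracks = pd.DataFrame([{
        "track_id": 0, "frame": 0, "t": 0.0,
        "z": 0.0, "y": 0.0, "x": 0.0,
        "radius": 0.3, "b_appl1": 5000.0, "b_eea1": 0.0,
    }])
    noise = syndata.NoiseParams(poisson=False, read_sigma=0.0, background=0.0)
    return syndata.render_movie(tracks, small_optics, noise, seed=0,
                                frame_interval=3.0)
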