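import numpy as np
import pytest

from hyphatrack.config import ImagingConfig, SimulationConfig
from hyphatrack.datasets import write_dataset
from hyphatrack.render import render_frames
from hyphatrack.simulate import simulate_dataset


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 5-hypha rendered dataset with a replication and a branch event."""
    out = tmp_path_factory.mktemp("data") / "ds"
    sim = SimulationConfig(
        n_hyphae=5,
        n_frames=12,
        seed=5,
        replication_schedule=[(1, 3, 2)],
        branch_schedule=[(2, 3.0, 3, False)],
    )
    imaging = ImagingConfig()
    truths = simulate_dataset(sim)
    rendered = [render_frames(t, imaging, seed=5) for t in truths]
    write_dataset(truths, rendered, out, config=sim, imaging=imaging, seed=5)
    return {"dir": out, "truths": truths, "sim": sim, "imaging": imaging}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def gaussian_profile(grid_um, centers_um, amplitudes, sigma_um=0.15):
    """Noiseless multi-peak profile used as a detection oracle input."""
    y = np.zeros_like(grid_um)
    for c, a in zip(centers_um, amplitudes):
        y += a * np.exp(-0.5 * ((grid_um - c) / sigma_um) ** 2)
    return y
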