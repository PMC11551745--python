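import numpy as np
import pytest

from smmtracks import (CellGeometry, PopulationMixture, SimulationConfig,
                       preset, simulate_tracks)

# geometry big enough that confinement never matters over a track
FREE_GEOMETRY = CellGeometry(length=60.0, radius=15.0)


def free_config(fractions, D, *, seed=0, n_cells=20, n_molecules=30,
                n_frames=120, loc_noise_sigma=0.0, delta_t=0.030,
                **kwargs) -> SimulationConfig:
    """Unconfined, noiseless-by-default simulation config for oracle tests."""
    mix = PopulationMixture(np.asarray(fractions), np.asarray(D), delta_t)
    cfg = SimulationConfig(mixture=mix, seed=seed, n_cells=n_cells,
                           n_molecules=n_molecules, n_frames=n_frames,
                           loc_noise_sigma=loc_noise_sigma, delta_t=delta_t,
                           geometry=FREE_GEOMETRY, bleach_phase_frames=0,
                           **kwargs)
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def wildtype_small():
    """One modest wild-type dataset shared across read-only tests."""
    cfg = preset("wildtype", seed=11, n_cells=25)
    tracks, truth = simulate_tracks(cfg)
    return cfg, tracks, truth
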