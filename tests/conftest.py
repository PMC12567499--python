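import numpy as np
import pytest

from mtuforce import (
    ElectrodeGrid,
    IcaConfig,
    generate_sources,
    posture_activation,
    separate,
    spatial_mixing_matrix,
    synthesize_recording,
)
from mtuforce.synthetic import default_source_layout


@pytest.fixture(scope="session")
def grid():
    return ElectrodeGrid(rows=8, cols=8, pitch_mm=10.0)


@pytest.fixture(scope="session")
def noiseless_mixture(grid):
    """5 staggered-burst sources mixed noiselessly onto 64 channels, T=20000."""
    fs = 1000.0
    envelopes = posture_activation(
        "N", 5, fs, cycles=3, cycle_s=3.0, rest_s=2.0, duration_s=20.0
    )
    sources = generate_sources(5, 20.0, fs, envelopes=envelopes, seed=1)
    locations = default_source_layout(grid, 5)
    mixing = spatial_mixing_matrix(grid, locations, grid.pitch_mm)
    recording, truth = synthesize_recording(
        sources, mixing, grid, fs, source_locations_mm=locations
    )
    return recording, truth


@pytest.fixture(scope="session")
def fitted_ica(noiseless_mixture):
    recording, truth = noiseless_mixture
    return separate(recording, IcaConfig(seed=0)), recording, truth


def match_abs_pcc(estimated: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Greedy |PCC| matching of estimated to true sources; returns matched |r|."""
    k = truth.shape[0]
    C = np.abs(np.corrcoef(estimated, truth)[:k, k:])
    out = []
    free_e, free_t = list(range(k)), list(range(k))
    while free_e and free_t:
        sub = C[np.ix_(free_e, free_t)]
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        out.append(float(sub[i, j]))
        free_e.pop(i)
        free_t.pop(j)
    return np.array(out)
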