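"""Separate a noiseless synthetic mixture with maximum-likelihood ICA.

The recovered components should match the known ground-truth sources up to
permutation, sign and scale; the matched |Pearson r| quantifies recovery.
"""
import numpy as np

from mtuforce import (
    ElectrodeGrid, IcaConfig, generate_sources, posture_activation,
    separate, spatial_mixing_matrix, synthesize_recording,
)
from mtuforce.synthetic import default_source_layout

fs = 1000.0
grid = ElectrodeGrid(8, 8, 10.0)
envelopes = posture_activation("N", 5, fs, cycles=3, cycle_s=3.0, rest_s=2.0,
                               duration_s=20.0)
sources = generate_sources(5, 20.0, fs, envelopes=envelopes, seed=1)
locations = default_source_layout(grid, 5)
mixing = spatial_mixing_matrix(grid, locations, grid.pitch_mm)
recording, truth = synthesize_recording(sources, mixing, grid, fs)

result = separate(recording, IcaConfig(n_components=5, seed=0))
print(f"ICA: {result.n_iter} iterations, converged={result.converged}")
print(f"log-likelihood rose by {result.loglik_trace[-1] - result.loglik_trace[0]:.0f}")

C = np.abs(np.corrcoef(result.sources, truth.sources)[:5, 5:])
print("matched |PCC| per recovered component:", np.round(np.sort(C.max(axis=1)), 4))
print("values near 1 mean each recovered source is one true source")
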