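"""Component classification and MTU localization on the electrode grid.

After separation, each recovered component is labelled *emg_source* or
*noise* from its power spectrum: genuine EMG concentrates its energy in the
20-450 Hz band, whereas baseline drift, movement artefact and power-line
interference do not.  EMG components are then localized by treating the
absolute values of their estimated mixing column as electrode weights: the
weighted centroid of the electrode positions estimates the muscle-tendon
unit's position, and the share of the column's mass held by the peak
electrode serves as a confidence score.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .grid import ElectrodeGrid


@dataclass(frozen=True)
class ComponentLabel:
    index: int
    label: str                  # "emg_source" | "noise"
    emg_band_fraction: float
    peak_frequency_hz: float


@dataclass(frozen=True)
class MtuLocation:
    component: int
    centroid_mm: tuple[float, float]
    peak_electrode: tuple[int, int]   # (row, col)
    confidence: float                 # peak |A| share of column mass, in [0,1]


def classify_components(
    sources: np.ndarray,
    fs_hz: float,
    band_hz: tuple[float, float] = (20.0, 450.0),
    threshold: float = 0.7,
    powerline_hz: float = 50.0,
    notch_halfwidth_hz: float = 2.0,
    segment_s: float = 0.5,
) -> list[ComponentLabel]:
    """Label components as EMG source vs noise by in-band power fraction.

    The PSD of each component is an averaged periodogram (Welch, 0.5 s
    segments, 50% overlap).  The EMG band fraction is the power inside
    ``band_hz`` — excluding +/- ``notch_halfwidth_hz`` around the power-line
    frequency — divided by total power; a component is an EMG source iff
    the fraction reaches ``threshold``.
    """
    S = np.atleast_2d(np.asarray(sources, float))
    low, high = band_hz
    if not fs_hz > 2 * high:
        raise ValueError(f"band {band_hz} exceeds Nyquist for fs={fs_hz}")
    nperseg = int(round(segment_s * fs_hz))
    if S.shape[1] < nperseg:
        raise ValueError(
            f"components of {S.shape[1]} samples are shorter than one "
            f"{nperseg}-sample PSD segment"
        )
    labels = []
    for i, row in enumerate(S):
        freqs, psd = sps.welch(row, fs=fs_hz, nperseg=nperseg, noverlap=nperseg // 2)
        total = float(np.sum(psd))
        in_band = (freqs >= low) & (freqs <= high)
        in_band &= np.abs(freqs - powerline_hz) > notch_halfwidth_hz
        frac = float(np.sum(psd[in_band]) / total) if total > 0 else 0.0
        labels.append(
            ComponentLabel(
                index=i,
                label="emg_source" if frac >= threshold else "noise",
                emg_band_fraction=frac,
                peak_frequency_hz=float(freqs[np.argmax(psd)]),
            )
        )
    return labels


def localize_sources(
    mixing_estimate: np.ndarray,
    grid: ElectrodeGrid,
    labels: Sequence[ComponentLabel] | None = None,
) -> list[MtuLocation]:
    """Weighted-centroid localization of EMG components on the grid.

    For each component labelled emg_source (all components when ``labels``
    is None), electrode weights are the absolute mixing-column entries
    w_i = |A[i, j]|; the location estimate is the weight-weighted centroid
    of the electrode positions, the peak electrode is argmax w (ties break
    to the lowest row-major index), and confidence = max w / sum w.
    """
    A = np.asarray(mixing_estimate, float)
    if A.shape[0] != grid.n_electrodes:
        raise ValueError(
            f"mixing has {A.shape[0]} rows but grid has {grid.n_electrodes} electrodes"
        )
    if labels is None:
        indices = range(A.shape[1])
    else:
        indices = [lab.index for lab in labels if lab.label == "emg_source"]
    pos = grid.positions()
    out = []
    for j in indices:
        w = np.abs(A[:, j])
        mass = float(w.sum())
        if mass == 0:
            raise ValueError(f"mixing column {j} is all zero; cannot localize")
        centroid = (w @ pos) / mass
        peak = int(np.argmax(w))  # argmax takes the first maximum: lowest row-major
        out.append(
            MtuLocation(
                component=j,
                centroid_mm=(float(centroid[0]), float(centroid[1])),
                peak_electrode=grid.index_to_rowcol(peak),
                confidence=float(w[peak] / mass),
            )
        )
    return out


def match_locations(
    estimated: Sequence[MtuLocation] | Sequence[tuple[float, float]],
    truth_mm: Sequence[tuple[float, float]],
) -> list[float]:
    """Greedy minimal-distance matching of estimates to true locations.

    Repeatedly pairs the globally closest (estimate, truth) pair and removes
    both; returns the matched Euclidean distances in millimetres.
    """
    if len(estimated) == 0 or len(truth_mm) == 0:
        raise ValueError("both location lists must be nonempty")
    est = np.array(
        [e.centroid_mm if isinstance(e, MtuLocation) else e for e in estimated],
        dtype=float,
    )
    tru = np.asarray(truth_mm, float)
    d = np.sqrt(((est[:, None, :] - tru[None, :, :]) ** 2).sum(axis=2))
    distances = []
    free_e = list(range(len(est)))
    free_t = list(range(len(tru)))
    while free_e and free_t:
        sub = d[np.ix_(free_e, free_t)]
        i, j = np.unravel_index(np.argmin(sub), sub.shape)
        distances.append(float(sub[i, j]))
        free_e.pop(i)
        free_t.pop(j)
    return distances
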