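"""Ground-truthed synthetic high-density sEMG.

The simulator realizes the instantaneous linear mixing model

    x(t) = A s(t) + n(t)

with s(t) a set of statistically independent, band-limited (20-450 Hz),
amplitude-modulated noise sources (amplitude modulation makes them
super-Gaussian, which ICA needs), A a Gaussian spatial-decay mixing matrix
over a 2-D electrode grid, and n(t) broadband Gaussian noise plus an
optional power-line sinusoid.  Two posture-dependent activation patterns are
provided — neutral (N, lateral-dominant) and supinated (S, medial-dominant)
— together with a force trace driven linearly by the activation envelopes.

Everything is bit-reproducible under a fixed seed.  The simulator does not
model physiological MUAP waveforms, volume conduction, or fatigue.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grid import ElectrodeGrid
from .preprocessing import SemgRecording, butterworth_bandpass


@dataclass(frozen=True)
class SourceSpec:
    """Placement and spectral band of one simulated EMG source."""

    location_mm: tuple[float, float]
    spread_mm: float
    band_hz: tuple[float, float] = (20.0, 450.0)

    def __post_init__(self) -> None:
        if not self.spread_mm > 0:
            raise ValueError("source spread must be positive")
        low, high = self.band_hz
        if not 0 <= low < high:
            raise ValueError(f"invalid band {self.band_hz}")


@dataclass
class GroundTruth:
    """Everything the simulator knows that a real experiment would not."""

    sources: np.ndarray              # (n_sources, T)
    mixing: np.ndarray               # A, (n_channels, n_sources)
    source_locations_mm: list[tuple[float, float]]
    envelopes: np.ndarray            # (n_sources, T)
    force_n: np.ndarray              # (T,)

    def __post_init__(self) -> None:
        if self.mixing.shape != (self.mixing.shape[0], self.sources.shape[0]):
            raise ValueError("mixing columns must match source rows")
        if not np.all(np.isfinite(self.mixing)):
            raise ValueError("mixing matrix must be finite")
        if np.any(np.all(self.mixing == 0, axis=0)):
            raise ValueError("mixing matrix has an all-zero column")


def generate_sources(
    n_sources: int,
    duration_s: float,
    fs_hz: float,
    band_hz: tuple[float, float] = (20.0, 450.0),
    envelopes: Sequence[np.ndarray] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Independent band-limited amplitude-modulated noise sources.

    Each source is white Gaussian noise band-pass filtered to ``band_hz``
    and multiplied by its nonnegative activation envelope.  Sources draw
    from independent spawned random streams, so adding a source never
    perturbs the earlier ones.

    Returns an (n_sources, T) matrix with T = duration * fs samples.
    """
    if n_sources < 1:
        raise ValueError("need at least one source")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    low, high = band_hz
    if not (0 <= low < high and fs_hz > 2 * high):
        raise ValueError(f"band {band_hz} invalid for fs={fs_hz} Hz")
    T = int(round(duration_s * fs_hz))
    if envelopes is not None:
        if len(envelopes) != n_sources:
            raise ValueError("one envelope per source required")
        envelopes = [np.asarray(e, float) for e in envelopes]
        for e in envelopes:
            if e.shape != (T,):
                raise ValueError("envelope length must equal signal length")
            if np.any(e < 0):
                raise ValueError("envelopes must be nonnegative")
    streams = np.random.SeedSequence(seed).spawn(n_sources)
    out = np.empty((n_sources, T))
    for j, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        carrier = butterworth_bandpass(rng.standard_normal(T), fs_hz, low, high, order=4)
        # unit-RMS carrier so the envelope sets the amplitude scale
        rms = np.sqrt(np.mean(carrier**2))
        if rms > 0:
            carrier /= rms
        out[j] = carrier * envelopes[j] if envelopes is not None else carrier
    return out


def spatial_mixing_matrix(
    grid: ElectrodeGrid,
    locations_mm: Sequence[tuple[float, float]],
    spread_mm: float | Sequence[float],
) -> np.ndarray:
    """Gaussian spatial-decay mixing matrix A.

    A[i, j] = exp(-d(electrode_i, source_j)^2 / (2 spread_j^2)), each column
    max-normalized to 1.  Column normalization pins down ICA's inherent scale
    indeterminacy for ground-truth comparison.
    """
    if len(locations_mm) == 0:
        raise ValueError("at least one source location required")
    spreads = np.broadcast_to(np.asarray(spread_mm, float), (len(locations_mm),))
    if np.any(spreads <= 0):
        raise ValueError("all spreads must be positive")
    pos = grid.positions()                              # (n_electrodes, 2)
    loc = np.asarray(locations_mm, float)               # (n_sources, 2)
    d2 = ((pos[:, None, :] - loc[None, :, :]) ** 2).sum(axis=2)
    A = np.exp(-d2 / (2.0 * spreads[None, :] ** 2))
    return A / A.max(axis=0, keepdims=True)


def synthesize_recording(
    sources: np.ndarray,
    mixing: np.ndarray,
    grid: ElectrodeGrid,
    fs_hz: float,
    noise_sigma: float = 0.0,
    powerline: tuple[float, float] = (50.0, 0.0),
    seed: int = 0,
    source_locations_mm: Sequence[tuple[float, float]] | None = None,
    envelopes: np.ndarray | None = None,
    force_n: np.ndarray | None = None,
    posture: str | None = None,
) -> tuple[SemgRecording, GroundTruth]:
    """Mix sources onto the electrode grid and add noise.

    x(t) = A s(t) + n(t), with n(t) white Gaussian of standard deviation
    ``noise_sigma`` plus a common sinusoid at the power-line frequency
    (random phase, amplitude ``powerline[1]``; default amplitude 0).
    """
    S = np.asarray(sources, float)
    A = np.asarray(mixing, float)
    if A.ndim != 2 or S.ndim != 2 or A.shape[1] != S.shape[0]:
        raise ValueError(
            f"mixing shape {A.shape} incompatible with sources shape {S.shape}"
        )
    if A.shape[0] != grid.n_electrodes:
        raise ValueError("mixing rows must equal grid electrode count")
    T = S.shape[1]
    rng = np.random.default_rng(seed)
    X = A @ S
    if noise_sigma > 0:
        X = X + noise_sigma * rng.standard_normal(X.shape)
    pl_freq, pl_amp = powerline
    if pl_amp > 0:
        t = np.arange(T) / fs_hz
        phase = rng.uniform(0, 2 * np.pi)
        X = X + pl_amp * np.sin(2 * np.pi * pl_freq * t + phase)[None, :]
    locations = list(source_locations_mm) if source_locations_mm is not None else []
    truth = GroundTruth(
        sources=S,
        mixing=A,
        source_locations_mm=locations,
        envelopes=envelopes if envelopes is not None else np.zeros_like(S),
        force_n=force_n if force_n is not None else np.zeros(T),
    )
    rec = SemgRecording(samples=X, fs_hz=fs_hz, grid=grid, force=force_n, posture=posture)
    return rec, truth


def posture_activation(
    posture: str,
    n_sources: int,
    fs_hz: float,
    cycles: int = 5,
    cycle_s: float = 3.0,
    rest_s: float = 5.0,
    dominance_gain: float = 0.4,
    phase_span_s: float | None = None,
    duration_s: float | None = None,
) -> list[np.ndarray]:
    """Posture-dependent burst envelopes for repeated elbow flexion.

    ``cycles`` raised-cosine bursts of ``cycle_s`` seconds separated by
    ``rest_s`` seconds of rest emulate repeated flexion cycles.  In the
    neutral posture (N) the lateral compartment dominates: source 0 gets
    peak gain 1.0 and the last (medial) source ``dominance_gain`` < 1; the
    supinated posture (S) reverses the gradient.  Intermediate sources are
    linearly interpolated.

    Compartments do not fire in lock-step: within each cycle, source j's
    burst onset is delayed by ``j / (n_sources-1) * phase_span_s`` (default
    span two thirds of the burst), emulating sequential compartment
    recruitment through the movement.  The offsets matter statistically:
    sources sharing one identical envelope are co-modulated and therefore
    not separable by ICA, whereas phase-staggered bursts restore the
    empirical independence that separation relies on.  Bursts remain inside
    their cycle (``phase_span_s + cycle_s <= cycle_s + rest_s``), so shared
    rest intervals still exist where every envelope is exactly zero.
    """
    posture = posture.upper()
    if posture not in {"N", "S"}:
        raise ValueError(f"unknown posture {posture!r}; expected 'N' or 'S'")
    if cycles < 1 or cycle_s <= 0 or rest_s < 0:
        raise ValueError("cycles >= 1, cycle_s > 0, rest_s >= 0 required")
    if phase_span_s is None:
        phase_span_s = min(cycle_s * 2.0 / 3.0, rest_s)
    if phase_span_s > rest_s:
        raise ValueError("phase span must not exceed the rest interval")
    if duration_s is None:
        duration_s = (cycles - 1) * (cycle_s + rest_s) + cycle_s + phase_span_s
    T = int(round(duration_s * fs_hz))
    burst_n = int(round(cycle_s * fs_hz))
    period_n = int(round((cycle_s + rest_s) * fs_hz))
    burst = np.sin(np.pi * np.arange(burst_n) / burst_n) ** 2  # raised cosine, peak 1
    if n_sources == 1:
        gains = np.array([1.0])
        offsets = np.array([0.0])
    else:
        gains = np.linspace(1.0, dominance_gain, n_sources)
        offsets = np.linspace(0.0, phase_span_s, n_sources)
    if posture == "S":
        gains = gains[::-1]
    envelopes = []
    for g, off in zip(gains, offsets):
        e = np.zeros(T)
        off_n = int(round(off * fs_hz))
        for k in range(cycles):
            a = k * period_n + off_n
            b = min(a + burst_n, T)
            if a < T:
                e[a:b] = burst[: b - a]
        envelopes.append(g * e)
    return envelopes


def force_from_activation(
    envelopes: Sequence[np.ndarray],
    gains_n: Sequence[float],
    noise_sd_n: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Ground-truth force as a linear combination of activation envelopes.

    force(t) = sum_j gains[j] * envelope_j(t) + Gaussian noise, clipped at 0.
    Gains are in newtons per unit envelope.
    """
    gains = np.asarray(gains_n, float)
    if np.any(gains < 0):
        raise ValueError("gains must be nonnegative")
    env = [np.asarray(e, float) for e in envelopes]
    if len(env) != len(gains):
        raise ValueError("one gain per envelope required")
    T = env[0].shape[0]
    if any(e.shape != (T,) for e in env):
        raise ValueError("all envelopes must share the same length")
    force = np.zeros(T)
    for g, e in zip(gains, env):
        force += g * e
    if noise_sd_n > 0:
        force = force + noise_sd_n * np.random.default_rng(seed).standard_normal(T)
    return np.clip(force, 0.0, None)


def default_source_layout(
    grid: ElectrodeGrid, n_sources: int, margin_mm: float | None = None
) -> list[tuple[float, float]]:
    """Evenly spaced source locations along the grid's long (x) axis.

    Sources sit on the grid's horizontal midline, inset by ``margin_mm``
    (default one pitch) from each edge: index 0 is lateral (small x), the
    last is medial (large x).
    """
    if margin_mm is None:
        margin_mm = grid.pitch_mm
    width = (grid.cols - 1) * grid.pitch_mm
    height = (grid.rows - 1) * grid.pitch_mm
    y = height / 2.0
    if n_sources == 1:
        return [(width / 2.0, y)]
    xs = np.linspace(margin_mm, width - margin_mm, n_sources)
    return [(float(x), y) for x in xs]


def noise_sigma_for_snr(clean: np.ndarray, snr_db: float) -> float:
    """White-noise sigma giving the requested SNR against a clean mixture."""
    power = float(np.mean(np.square(clean)))
    return float(np.sqrt(power / (10.0 ** (snr_db / 10.0))))


def simulate_posture_recording(
    posture: str,
    grid: ElectrodeGrid,
    n_sources: int = 5,
    fs_hz: float = 1000.0,
    cycles: int = 5,
    cycle_s: float = 3.0,
    rest_s: float = 5.0,
    snr_db: float | None = 20.0,
    powerline: tuple[float, float] = (50.0, 0.0),
    source_spread_mm: float | None = None,
    force_gain_n: float = 40.0,
    force_noise_sd_n: float = 0.0,
    dominance_gain: float = 0.4,
    seed: int = 0,
) -> tuple[SemgRecording, GroundTruth]:
    """One complete simulated trial: envelopes, sources, mixing, noise, force.

    This is the study-condition generator the pipeline and tests share:
    posture-dependent activation over ``cycles`` flexion bursts, sources on
    the grid midline with Gaussian spread (default one pitch), additive
    noise at ``snr_db`` (None = noiseless), and a linear envelope->force map
    with ``force_gain_n`` newtons per source at full activation.
    """
    if source_spread_mm is None:
        source_spread_mm = grid.pitch_mm
    envelopes = posture_activation(
        posture, n_sources, fs_hz, cycles, cycle_s, rest_s, dominance_gain
    )
    duration_s = envelopes[0].shape[0] / fs_hz
    sources = generate_sources(
        n_sources, duration_s, fs_hz, envelopes=envelopes, seed=seed
    )
    locations = default_source_layout(grid, n_sources)
    A = spatial_mixing_matrix(grid, locations, source_spread_mm)
    force = force_from_activation(
        envelopes, [force_gain_n] * n_sources, force_noise_sd_n, seed=seed + 1
    )
    clean = A @ sources
    sigma = noise_sigma_for_snr(clean, snr_db) if snr_db is not None else 0.0
    return synthesize_recording(
        sources,
        A,
        grid,
        fs_hz,
        noise_sigma=sigma,
        powerline=powerline,
        seed=seed + 2,
        source_locations_mm=locations,
        envelopes=np.vstack(envelopes),
        force_n=force,
        posture=posture,
    )
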