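"""Hilbert spectral analysis of IMFs.

For each IMF x_i(t) the analytic signal z_i = x_i + i·H[x_i] gives an
instantaneous amplitude a_i(t) = |z_i|, an unwrapped phase β_i(t), and an
instantaneous frequency w_i(t) = (1/2π)·dβ_i/dt.  The original signal can
be re-expressed as Re Σ_i a_i(t)·exp(i∫w_i dt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, signal as sps, stats

from .emd import IMFSet

__all__ = ["InstantaneousTrack", "analytic_signal", "instantaneous_track",
           "tracks_from_imfs", "hilbert_reconstruct", "amplitude_vs_frequency",
           "AmplitudeFrequencyPairs", "EDGE_GUARD"]

# samples excluded from frequency statistics at each end, where the
# discrete Hilbert transform shows Gibbs-type artifacts
EDGE_GUARD = 16


def analytic_signal(x: np.ndarray) -> np.ndarray:
    """Analytic signal z = x + i·H[x] via the frequency-domain Hilbert transform."""
    x = np.asarray(x)
    if np.iscomplexobj(x):
        raise ValueError("analytic_signal expects a real input")
    if x.size < 16:
        raise ValueError("input too short")
    return sps.hilbert(x.astype(float))


@dataclass
class InstantaneousTrack:
    """Per-layer instantaneous amplitude / phase / frequency."""

    amplitude: np.ndarray   # |z(t)|, signal units
    phase: np.ndarray       # unwrapped arg z(t), rad
    frequency: np.ndarray   # dphase/dt / 2π, Hz
    fs: float
    layer_index: int = 0

    def __post_init__(self) -> None:
        if not (len(self.amplitude) == len(self.phase) == len(self.frequency)):
            raise ValueError("track arrays must share length")

    def interior(self, guard: int = EDGE_GUARD) -> slice:
        return slice(guard, len(self.amplitude) - guard)

    def mean_frequency(self, guard: int = EDGE_GUARD) -> float:
        """Amplitude-weighted time-mean instantaneous frequency (Hz)."""
        sl = self.interior(guard)
        a, f = self.amplitude[sl], self.frequency[sl]
        wsum = float(np.sum(a))
        if wsum == 0.0:
            return float(np.mean(f))
        return float(np.sum(a * f) / wsum)


def instantaneous_track(x: np.ndarray, fs: float, layer_index: int = 0) -> InstantaneousTrack:
    """Amplitude/phase/frequency track of one IMF-like component.

    Frequency comes from central differences of the unwrapped phase
    (one-sided at the ends).
    """
    z = analytic_signal(x)
    amp = np.abs(z)
    phase = np.unwrap(np.angle(z))
    freq = np.gradient(phase) * fs / (2.0 * np.pi)
    return InstantaneousTrack(amplitude=amp, phase=phase, frequency=freq,
                              fs=float(fs), layer_index=layer_index)


def tracks_from_imfs(imfset: IMFSet) -> list[InstantaneousTrack]:
    """One instantaneous track per IMF layer (residual excluded)."""
    return [instantaneous_track(imf, imfset.source_fs, layer_index=i + 1)
            for i, imf in enumerate(imfset.imfs)]


def hilbert_reconstruct(tracks: list[InstantaneousTrack]) -> np.ndarray:
    """Re Σ_i a_i(t)·exp(i·phase_i(t)) with trapezoidal phase integration.

    Each layer's phase is rebuilt as its initial unwrapped phase plus the
    running integral of the instantaneous frequency.
    """
    if not tracks:
        return np.zeros(0)
    n = len(tracks[0].amplitude)
    fs = tracks[0].fs
    for tr in tracks:
        if len(tr.amplitude) != n or tr.fs != fs:
            raise ValueError("tracks must share length and sampling rate")
    out = np.zeros(n)
    for tr in tracks:
        phase = tr.phase[0] + 2.0 * np.pi * integrate.cumulative_trapezoid(
            tr.frequency, dx=1.0 / fs, initial=0.0)
        out += np.real(tr.amplitude * np.exp(1j * phase))
    return out


@dataclass
class AmplitudeFrequencyPairs:
    """Pooled (frequency, amplitude) samples across layers, plus binned medians."""

    frequency: np.ndarray
    amplitude: np.ndarray
    bin_centers: np.ndarray
    bin_median_amplitude: np.ndarray

    def spearman(self, max_points: int = 2000, seed: int = 0) -> tuple[float, float]:
        """Spearman rank correlation of amplitude against frequency.

        Subsamples to at most ``max_points`` pooled points (seeded) so the
        p-value is comparable across signal lengths.
        """
        n = self.frequency.size
        if n > max_points:
            idx = np.random.default_rng(seed).choice(n, size=max_points, replace=False)
            f, a = self.frequency[idx], self.amplitude[idx]
        else:
            f, a = self.frequency, self.amplitude
        rho, p = stats.spearmanr(f, a)
        return float(rho), float(p)


def amplitude_vs_frequency(tracks: list[InstantaneousTrack], n_bins: int = 30,
                           guard: int = EDGE_GUARD,
                           amplitude_floor_quantile: float = 0.1) -> AmplitudeFrequencyPairs:
    """Pool per-sample (w_i(t), a_i(t)) pairs and bin amplitude by frequency.

    Edge samples are excluded, as are samples whose amplitude falls below
    the pooled amplitude-floor quantile (where instantaneous frequency is
    numerically meaningless).  Returned bins are the occupied ones only.
    """
    if not tracks:
        raise ValueError("need at least one track")
    fs, am = [], []
    for tr in tracks:
        sl = tr.interior(guard)
        fs.append(tr.frequency[sl])
        am.append(tr.amplitude[sl])
    f = np.concatenate(fs)
    a = np.concatenate(am)
    floor = np.quantile(a, amplitude_floor_quantile)
    keep = (a > floor) & np.isfinite(f) & (f > 0)
    f, a = f[keep], a[keep]
    if f.size == 0:
        raise ValueError("no usable (frequency, amplitude) pairs")
    edges = np.linspace(f.min(), f.max() * (1 + 1e-12), n_bins + 1)
    which = np.clip(np.digitize(f, edges) - 1, 0, n_bins - 1)
    centers, medians = [], []
    for b in range(n_bins):
        m = which == b
        if np.any(m):
            centers.append(0.5 * (edges[b] + edges[b + 1]))
            medians.append(float(np.median(a[m])))
    return AmplitudeFrequencyPairs(frequency=f, amplitude=a,
                                   bin_centers=np.asarray(centers),
                                   bin_median_amplitude=np.asarray(medians))
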