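"""Separation-quality metrics.

Two figures of merit compare an extracted blood signal against the pure
reference:

* Ef — relative error of the mean-frequency curve,
  Ef = Σ_t (F(t) − F_s(t))² / Σ_t F_s(t)², where F_s is the mean
  frequency of the reference and F that of the estimate.  As defined
  there is no square root: Ef is a ratio of summed squares.
* MRE — mean relative error of the power spectrum,
  MRE = (1/M)·Σ_i [ Σ_f |P1(f,i) − P2(f,i)| / Σ_f P2(f,i) ], over M
  equal time segments, P2 being the reference spectrum.

Both are non-negative, zero iff the curves/spectra are identical, and
invariant under a common rescaling of both arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal import SampledSignal

__all__ = ["MeanFrequencyCurve", "SegmentedPSD", "mean_frequency_curve",
           "ef_metric", "segmented_psd", "mre_metric"]


@dataclass
class MeanFrequencyCurve:
    """Short-time first-spectral-moment track F(t)."""

    times: np.ndarray      # window centers, s
    mean_freq: np.ndarray  # Hz

    def __post_init__(self) -> None:
        if len(self.times) != len(self.mean_freq):
            raise ValueError("times and mean_freq must share length")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.mean_freq))):
            raise ValueError("curve values must be finite")


@dataclass
class SegmentedPSD:
    """Per-segment power spectral density on a common frequency grid."""

    freqs: np.ndarray      # Hz
    density: np.ndarray    # shape (n_segments, n_freqs), power/Hz

    def __post_init__(self) -> None:
        self.density = np.atleast_2d(self.density)
        if self.density.shape[1] != len(self.freqs):
            raise ValueError("density columns must match the frequency grid")
        if np.any(self.density < 0):
            raise ValueError("spectral density must be non-negative")

    @property
    def n_segments(self) -> int:
        return self.density.shape[0]


def mean_frequency_curve(x: SampledSignal, window: float = 0.064,
                         hop: float = 0.016) -> MeanFrequencyCurve:
    """Mean-frequency curve from Hann-windowed short-time periodograms.

    F per window is the first spectral moment Σ f·P(f) / Σ P(f).
    ``window`` and ``hop`` are in seconds (64 ms / 16 ms defaults).
    """
    sig = x.real_view()
    nwin = int(round(window * sig.fs))
    nhop = max(1, int(round(hop * sig.fs)))
    if nwin < 8:
        raise ValueError("window must span at least 8 samples")
    if nwin > sig.n:
        raise ValueError("window longer than the signal")
    win = sps.get_window("hann", nwin)
    freqs = np.fft.rfftfreq(nwin, d=1.0 / sig.fs)
    starts = np.arange(0, sig.n - nwin + 1, nhop)
    times = np.empty(starts.size)
    mf = np.empty(starts.size)
    for j, s0 in enumerate(starts):
        seg = sig.samples[s0:s0 + nwin] * win
        power = np.abs(np.fft.rfft(seg)) ** 2
        total = power.sum()
        mf[j] = float(freqs @ power / total) if total > 0 else 0.0
        times[j] = sig.t0 + (s0 + (nwin - 1) / 2.0) / sig.fs
    return MeanFrequencyCurve(times=times, mean_freq=mf)


def ef_metric(F: MeanFrequencyCurve, F_s: MeanFrequencyCurve) -> float:
    """Relative error of the mean-frequency curve against reference F_s."""
    if len(F.times) != len(F_s.times) or not np.allclose(F.times, F_s.times):
        raise ValueError("curves must be aligned on the same times")
    denom = float(np.sum(F_s.mean_freq ** 2))
    if denom == 0.0:
        raise ValueError("reference curve is identically zero; Ef undefined")
    return float(np.sum((F.mean_freq - F_s.mean_freq) ** 2) / denom)


def segmented_psd(x: SampledSignal, n_segments: int = 8,
                  nperseg: int | None = None) -> SegmentedPSD:
    """Welch PSD of each of ``n_segments`` equal contiguous time segments."""
    if n_segments < 1:
        raise ValueError("need at least one segment")
    sig = x.real_view()
    seg_len = sig.n // n_segments
    if seg_len < 16:
        raise ValueError("segments shorter than 16 samples")
    nps = min(nperseg or 256, seg_len)
    densities = []
    freqs = None
    for i in range(n_segments):
        seg = sig.samples[i * seg_len:(i + 1) * seg_len]
        f, p = sps.welch(seg, fs=sig.fs, nperseg=nps, detrend=False)
        freqs = f
        densities.append(p)
    return SegmentedPSD(freqs=freqs, density=np.vstack(densities))


def mre_metric(P1: SegmentedPSD, P2: SegmentedPSD) -> float:
    """Segment-averaged relative PSD error of P1 against reference P2."""
    if P1.n_segments != P2.n_segments:
        raise ValueError("segment counts differ")
    if len(P1.freqs) != len(P2.freqs) or not np.allclose(P1.freqs, P2.freqs):
        raise ValueError("frequency grids differ")
    ref_tot = P2.density.sum(axis=1)
    if np.any(ref_tot == 0):
        raise ValueError("reference segment with zero total power; MRE undefined")
    per_seg = np.abs(P1.density - P2.density).sum(axis=1) / ref_tot
    return float(per_seg.mean())
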