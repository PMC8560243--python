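"""Uniformly sampled time series — the common currency between all stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SampledSignal"]


@dataclass
class SampledSignal:
    """A uniformly sampled real- or complex-valued time series.

    Parameters
    ----------
    samples : ndarray
        Sample values, real or complex, 1-D.
    fs : float
        Sampling rate in Hz. Must be positive.
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if self.samples.size < 2:
            raise ValueError("signal needs at least 2 samples")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    @property
    def is_complex(self) -> bool:
        return np.iscomplexobj(self.samples)

    def real_view(self) -> "SampledSignal":
        """Real part of the signal (identity for real signals).

        Sifting-based decomposition is defined for real series; complex
        baseband signals are reduced to their in-phase component first.
        """
        if not self.is_complex:
            return self
        return SampledSignal(np.ascontiguousarray(self.samples.real), self.fs, self.t0)

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.abs(self.samples) ** 2)))

    def __len__(self) -> int:
        return self.n


def check_uniform_times(times: np.ndarray, rtol: float = 1e-6) -> float:
    """Validate a strictly increasing uniform time grid; return the step."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("need a 1-D time grid with at least 2 points")
    dt = np.diff(times)
    if np.any(dt <= 0):
        raise ValueError("times must be strictly increasing")
    if np.ptp(dt) > rtol * dt.mean():
        raise ValueError("times must be uniformly spaced")
    return float(dt.mean())
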