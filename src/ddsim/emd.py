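"""Empirical mode decomposition by cubic-spline envelope sifting.

A real signal x(t) is decomposed into intrinsic mode functions (IMFs)
x_1..x_{N-1} plus a residual r(t),

    x(t) = sum_i x_i(t) + r(t),

by repeatedly subtracting the mean of the cubic-spline envelopes through
the local maxima and minima (sifting) until a Cauchy-type stopping ratio
falls below a threshold, then iterating on the remainder until it is
monotone / trend-like.  Layers are ordered from the highest oscillation
frequency downward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .signal import SampledSignal

__all__ = ["SiftSettings", "IMFSet", "find_extrema", "envelope_mean",
           "sift_one_imf", "decompose"]


@dataclass
class SiftSettings:
    """Sifting controls.

    sd_threshold is the classic Cauchy stopping ratio
    sum((h_prev - h)^2) / sum(h_prev^2); 0.2 is Huang's default.
    boundary_mode 'mirror' reflects two extrema beyond each end before
    spline fitting; 'clamp' instead anchors the envelopes at the end
    samples.
    """

    max_imfs: int = 12
    max_sift_iters: int = 100
    sd_threshold: float = 0.2
    boundary_mode: str = "mirror"

    def __post_init__(self) -> None:
        if self.max_imfs < 1:
            raise ValueError("max_imfs must be >= 1")
        if not self.sd_threshold > 0:
            raise ValueError("sd_threshold must be positive")
        if self.boundary_mode not in ("mirror", "clamp"):
            raise ValueError("boundary_mode must be 'mirror' or 'clamp'")


@dataclass
class IMFSet:
    """Ordered IMFs plus residual from one decomposition run."""

    imfs: list
    residual: np.ndarray
    source_fs: float

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    @property
    def n_layers(self) -> int:
        """Total layer count N, counting the residual as the final layer."""
        return len(self.imfs) + 1

    def layer(self, i: int) -> np.ndarray:
        """1-based layer access; layer N is the residual."""
        if not 1 <= i <= self.n_layers:
            raise IndexError(f"layer {i} out of range 1..{self.n_layers}")
        return self.residual if i == self.n_layers else self.imfs[i - 1]

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict interior maxima and minima.

    Plateaus of equal consecutive samples contribute their midpoint
    index (deterministic tie-break).  A constant signal has no extrema.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    dx = np.diff(x)
    nz = np.flatnonzero(dx)
    if nz.size < 2:
        return np.array([], dtype=int), np.array([], dtype=int)
    s = np.sign(dx[nz])
    turn = np.flatnonzero(s[:-1] != s[1:])
    # extremum (or plateau) spans samples nz[j]+1 .. nz[j+1]
    idx = (nz[turn] + 1 + nz[turn + 1]) // 2
    maxima = idx[s[turn] > 0]
    minima = idx[s[turn] < 0]
    return maxima, minima


class _MonotoneResidual(Exception):
    """Raised internally when too few extrema remain to build envelopes."""


def _extend(idx: np.ndarray, val: np.ndarray, n: int, mode: str,
            x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Add boundary knots so the spline is anchored beyond [0, n-1]."""
    if mode == "clamp":
        knots_i = np.concatenate(([0], idx, [n - 1]))
        knots_v = np.concatenate(([x[0]], val, [x[n - 1]]))
        # dedupe in case an extremum already sits at a boundary
        knots_i, keep = np.unique(knots_i, return_index=True)
        return knots_i, knots_v[keep]
    # mirror: reflect up to two extrema across each end sample
    kl = min(2, idx.size)
    left_i = (2 * 0 - idx[:kl])[::-1] - 0  # reflect about sample 0
    left_v = val[:kl][::-1]
    right_i = 2 * (n - 1) - idx[-kl:][::-1]
    right_v = val[-kl:][::-1]
    knots_i = np.concatenate((left_i, idx, right_i))
    knots_v = np.concatenate((left_v, val, right_v))
    knots_i, keep = np.unique(knots_i, return_index=True)
    return knots_i, knots_v[keep]


def envelope_mean(x: np.ndarray, settings: SiftSettings | None = None) -> np.ndarray:
    """Pointwise mean of the cubic-spline upper and lower envelopes.

    Raises ValueError when fewer than 2 maxima or 2 minima exist (the
    caller treats that as the monotone-residual terminal condition).
    """
    settings = settings or SiftSettings()
    x = np.asarray(x, dtype=float)
    mx, mn = find_extrema(x)
    if mx.size < 2 or mn.size < 2:
        raise _MonotoneResidual("fewer than 2 maxima or minima")
    n = x.size
    ui, uv = _extend(mx, x[mx], n, settings.boundary_mode, x)
    li, lv = _extend(mn, x[mn], n, settings.boundary_mode, x)
    grid = np.arange(n)
    upper = CubicSpline(ui, uv)(grid)
    lower = CubicSpline(li, lv)(grid)
    return 0.5 * (upper + lower)


def sift_one_imf(x: np.ndarray, settings: SiftSettings | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Extract one IMF from x; returns (imf, remainder) with imf+remainder == x."""
    settings = settings or SiftSettings()
    x = np.asarray(x, dtype=float)
    h = x.copy()
    for _ in range(settings.max_sift_iters):
        try:
            m = envelope_mean(h, settings)
        except _MonotoneResidual:
            break
        h_new = h - m
        denom = float(np.sum(h * h))
        if denom == 0.0:
            h = h_new
            break
        sd = float(np.sum((h - h_new) ** 2)) / denom
        h = h_new
        if sd < settings.sd_threshold:
            break
    return h, x - h


def decompose(x: SampledSignal | np.ndarray, settings: SiftSettings | None = None,
              fs: float | None = None) -> IMFSet:
    """Full EMD of a real signal into IMFs plus a monotone/trend residual.

    Sifting is applied to successive remainders until the remainder has
    fewer than 2 maxima or 2 minima, or ``max_imfs`` layers were taken.
    The sum of all IMFs and the residual reproduces the input to within
    floating-point round-off.
    """
    settings = settings or SiftSettings()
    if isinstance(x, SampledSignal):
        if x.is_complex:
            raise ValueError("decompose expects a real signal; take real_view() first")
        samples, fs = x.samples, x.fs
    else:
        samples = np.asarray(x)
        if np.iscomplexobj(samples):
            raise ValueError("decompose expects a real signal; take the real part first")
        fs = fs or 1.0
    samples = samples.astype(float)
    if samples.size < 16:
        raise ValueError("signal too short to decompose")

    imfs: list[np.ndarray] = []
    rem = samples.copy()
    while len(imfs) < settings.max_imfs:
        mx, mn = find_extrema(rem)
        if mx.size < 2 or mn.size < 2:
            break
        imf, rem = sift_one_imf(rem, settings)
        if not np.any(imf):
            break
        imfs.append(imf)
    return IMFSet(imfs=imfs, residual=rem, source_fs=float(fs))
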