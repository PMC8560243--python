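"""Synthetic Doppler signal generator with known blood / wall ground truth.

Physics emulated
----------------
* Blood: a sum of point scatterers advected by a Womersley pulsatile
  velocity profile in a straight round tube.  Each scatterer at relative
  radial position ``y`` contributes a constant-amplitude phasor whose
  phase accumulates at the Doppler rate implied by its velocity.
* Wall: the vessel cross-sectional area follows an exponential
  pressure–area law ``S(t) = a·exp(b·P(t)) + c``; the radial wall
  velocity ``dr/dt`` (with ``r = sqrt(S/π)``) drives a constant-modulus
  Doppler phasor of amplitude ``a_w`` — the low-frequency, high-amplitude
  clutter component.
* White complex Gaussian noise at a configured SNR relative to the
  blood component.

The simulator works at complex baseband: the carrier term ``ω0·t`` is
demodulated away and only the Doppler phase is synthesized.  The RF form
of the single-scatterer echo is kept in :func:`scatterer_signal`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
from scipy import integrate, special

from .signal import SampledSignal, check_uniform_times

__all__ = [
    "ScattererParams",
    "FlowProfileParams",
    "WallModelParams",
    "DopplerGeometry",
    "SimConfig",
    "SimulationTruth",
    "scatterer_signal",
    "pressure_waveform",
    "womersley_profile",
    "wall_area",
    "wall_radius_and_velocity",
    "wall_doppler_signal",
    "simulate_composite",
    "doppler_frequency",
]


# --------------------------------------------------------------------------
# parameter records
# --------------------------------------------------------------------------

@dataclass
class ScattererParams:
    """One blood particle's echo parameters.

    ``field_weight`` (A_i) describes the acoustic field at the particle's
    position, ``scatter_coeff`` (B_i) its scattering strength.  The
    transmit/receive gate windows are functions of time bounded in [0, 1]
    (``None`` means fully open).  ``motion_phase`` is the Doppler phase
    phi_d(t) accrued by the particle's motion, in radians.
    """

    field_weight: float = 1.0
    scatter_coeff: float = 1.0
    carrier_angular_freq: float = 2 * np.pi * 5e6
    phase_offset: float = 0.0
    motion_phase: Optional[Callable[[np.ndarray], np.ndarray]] = None
    tx_gate: Optional[Callable[[np.ndarray], np.ndarray]] = None
    rx_gate: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self) -> None:
        if not self.carrier_angular_freq > 0:
            raise ValueError("carrier angular frequency must be positive")


@dataclass
class FlowProfileParams:
    """Womersley pulsatile-flow parameters.

    The axial velocity at relative radius ``y`` in [0, 1] is

        s(y, t) = 2·v0·(1 − y²) + Σ_p v_p·|ψ_p(y)|·cos(p·w·t + ε_p + χ_p(y))

    where ψ_p is the complex Womersley shape function of harmonic p
    (order-0/order-1 Bessel functions of argument α_p·i^{3/2}, with
    α_p = α·sqrt(p)) normalised to unit cross-sectional mean, and
    χ_p = arg ψ_p.  v0 is the mean (steady) velocity in cm/s and v_p the
    magnitude of the p-th Fourier coefficient of the mean-velocity curve.
    """

    mean_velocity: float = 7.0                 # v0, cm/s
    harmonic_amplitudes: tuple = (3.0, 1.5)    # v_p, cm/s
    harmonic_phases: tuple = (0.0, np.pi / 2)  # ε_p, rad
    heart_angular_freq: float = 2 * np.pi * 1.2  # w, rad/s (72 bpm)
    womersley_alpha: float = 3.0               # α at the fundamental

    def __post_init__(self) -> None:
        if self.mean_velocity < 0:
            raise ValueError("mean velocity must be non-negative")
        if not self.heart_angular_freq > 0:
            raise ValueError("heart angular frequency must be positive")
        if not self.womersley_alpha > 0:
            raise ValueError("Womersley number must be positive")
        if len(self.harmonic_amplitudes) != len(self.harmonic_phases):
            raise ValueError("harmonic amplitude/phase arrays must match")


@dataclass
class WallModelParams:
    """Pressure–area law of the vessel wall and wall-echo amplitude.

    ``S(t) = area_scale·exp(pressure_coeff·P(t)) + area_offset`` with the
    published constants a = 3.6 cm², b = −0.0119 /mmHg, c = 3.05 cm².
    ``wall_amp`` (a_w) is the constant modulus of the wall Doppler phasor;
    clutter is typically 20–60 dB above the blood signal.
    """

    area_scale: float = 3.6       # a, cm^2
    pressure_coeff: float = -0.0119  # b, 1/mmHg
    area_offset: float = 3.05     # c, cm^2
    wall_amp: float = 50.0        # a_w, dimensionless

    def __post_init__(self) -> None:
        if not self.area_scale > 0:
            raise ValueError("area scale must be positive")


@dataclass
class DopplerGeometry:
    """Carrier frequency, beam-to-flow angle and sound speed.

    The Doppler shift of a target moving at v (cm/s) is
    f_d = 2·f0·v·cos(θ)/c.
    """

    f0: float = 5e6            # Hz
    angle_deg: float = 30.0    # beam-to-flow angle
    c_sound: float = 1540.0    # m/s

    @property
    def hz_per_cm_s(self) -> float:
        """Doppler shift in Hz per cm/s of target velocity."""
        return 2.0 * self.f0 * np.cos(np.deg2rad(self.angle_deg)) / (self.c_sound * 100.0)


@dataclass
class SimConfig:
    """Full generator configuration; seeded runs are bit-reproducible.

    ``y_max`` is the fraction of the lumen radius covered by the sample
    volume: scatterers in the slowest near-wall annulus are outside the
    range gate, which keeps the blood Doppler band above ~100 Hz at the
    default flow.  The pressure waveform is a harmonic-rich arterial
    pulse (normalised harmonic mix scaled to ``pressure_amp`` mmHg of
    half peak-to-peak) whose sharp systolic upstroke drives realistic
    wall accelerations.
    """

    seed: int = 0
    fs: float = 10_000.0       # Hz, baseband
    duration: float = 2.0      # s
    n_scatterers: int = 200
    snr_db: float = 20.0       # relative to the blood component RMS
    blood_amp: float = 1.0     # overall blood RMS scale
    y_max: float = 0.9         # sample-volume fraction of the lumen radius
    pressure_mean: float = 90.0   # mmHg
    pressure_amp: float = 25.0    # mmHg, half peak-to-peak
    pressure_harmonics: tuple = (1.0, 0.35, 0.15, 0.06)
    pressure_phases: tuple = (0.0, 0.9, 1.8, 2.6)
    flow: FlowProfileParams = field(default_factory=FlowProfileParams)
    wall: WallModelParams = field(default_factory=WallModelParams)
    geometry: DopplerGeometry = field(default_factory=DopplerGeometry)

    def __post_init__(self) -> None:
        if not 0.0 < self.y_max <= 1.0:
            raise ValueError("y_max must lie in (0, 1]")
        if len(self.pressure_harmonics) != len(self.pressure_phases):
            raise ValueError("pressure harmonic/phase arrays must match")


@dataclass
class SimulationTruth:
    """A composite signal together with its known components.

    ``composite.samples == blood_truth.samples + wall_truth.samples + noise``
    holds elementwise to machine precision.
    """

    composite: SampledSignal
    blood_truth: SampledSignal
    wall_truth: SampledSignal
    noise: np.ndarray
    noise_sd: float
    seed: int
    config: SimConfig


# --------------------------------------------------------------------------
# elementary models
# --------------------------------------------------------------------------

def scatterer_signal(p: ScattererParams, times: np.ndarray,
                     baseband: bool = False) -> SampledSignal:
    """Echo of a single blood particle.

    RF form (default): A·B·cos(ω0·t + φ_d(t) + ψ)·C_t(t)·C_r(t).
    Baseband form: the carrier term is removed and the complex phasor
    A·B·exp(i(φ_d(t) + ψ))·C_t·C_r is returned instead.
    """
    dt = check_uniform_times(times)
    times = np.asarray(times, dtype=float)
    phase_d = p.motion_phase(times) if p.motion_phase is not None else np.zeros_like(times)
    amp = p.field_weight * p.scatter_coeff
    if baseband:
        carrier = np.exp(1j * (phase_d + p.phase_offset))
    else:
        carrier = np.cos(p.carrier_angular_freq * times + phase_d + p.phase_offset)
    out = amp * carrier
    for gate in (p.tx_gate, p.rx_gate):
        if gate is not None:
            g = np.asarray(gate(times), dtype=float)
            if np.any(g < -1e-12) or np.any(g > 1 + 1e-12):
                raise ValueError("gate functions must be bounded in [0, 1]")
            out = out * g
    return SampledSignal(out, fs=1.0 / dt, t0=float(times[0]))


def _womersley_psi(alpha: float, y) -> np.ndarray:
    """Complex Womersley shape function, unit cross-sectional mean."""
    z = alpha * 1j ** 1.5
    num = z * special.jv(0, z) - z * special.jv(0, np.multiply(y, z))
    den = z * special.jv(0, z) - 2.0 * special.jv(1, z)
    return num / den


def womersley_profile(fp: FlowProfileParams, y: float,
                      times: np.ndarray) -> np.ndarray:
    """Axial blood velocity (cm/s) at relative radius ``y`` over time.

    Reduces to the steady parabola 2·v0·(1 − y²) when all harmonic
    amplitudes are zero; obeys no-slip at y = 1 for the steady term.
    """
    y = float(y)
    if not 0.0 <= y <= 1.0:
        raise ValueError("relative radius y must lie in [0, 1]")
    times = np.asarray(times, dtype=float)
    v = 2.0 * fp.mean_velocity * (1.0 - y * y) * np.ones_like(times)
    for p, (vp, eps) in enumerate(zip(fp.harmonic_amplitudes, fp.harmonic_phases), start=1):
        if vp == 0:
            continue
        psi = _womersley_psi(fp.womersley_alpha * np.sqrt(p), y)
        v = v + vp * np.abs(psi) * np.cos(p * fp.heart_angular_freq * times + eps + np.angle(psi))
    return v


def wall_area(wp: WallModelParams, pressure: np.ndarray) -> np.ndarray:
    """Vessel cross-sectional area S(t) = a·exp(b·P(t)) + c, cm²."""
    pressure = np.asarray(pressure, dtype=float)
    if not np.all(np.isfinite(pressure)):
        raise ValueError("pressure must be finite")
    return wp.area_scale * np.exp(wp.pressure_coeff * pressure) + wp.area_offset


def wall_radius_and_velocity(wp: WallModelParams,
                             pressure: SampledSignal) -> tuple[np.ndarray, np.ndarray]:
    """Wall radius r = sqrt(S/π) (cm) and radial velocity dr/dt (cm/s).

    The derivative uses central differences in the interior and one-sided
    differences at the ends.
    """
    S = wall_area(wp, pressure.samples)
    if np.any(S <= 0):
        raise ValueError("vessel area must stay positive")
    r = np.sqrt(S / np.pi)
    v = np.gradient(r, 1.0 / pressure.fs)
    return r, v


def doppler_frequency(velocity_cm_s, geom: DopplerGeometry) -> np.ndarray:
    """Doppler shift (Hz) of a target moving at ``velocity_cm_s``."""
    return np.asarray(velocity_cm_s) * geom.hz_per_cm_s


def _doppler_phase(velocity_cm_s: np.ndarray, fs: float,
                   geom: DopplerGeometry) -> np.ndarray:
    """Accumulated Doppler phase 2π·∫f_d dτ by trapezoidal integration."""
    fd = doppler_frequency(velocity_cm_s, geom)
    return 2.0 * np.pi * integrate.cumulative_trapezoid(fd, dx=1.0 / fs, initial=0.0)


def wall_doppler_signal(wp: WallModelParams, wall_velocity: SampledSignal,
                        geom: DopplerGeometry | None = None) -> SampledSignal:
    """Constant-modulus wall clutter phasor x_w(t) = a_w·exp(i·φ_d(t)).

    φ_d accumulates the Doppler phase of the wall's radial motion; the
    modulus is exactly a_w everywhere.
    """
    geom = geom or DopplerGeometry()
    v = np.asarray(wall_velocity.samples, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("wall velocity must be finite")
    phase = _doppler_phase(v, wall_velocity.fs, geom)
    return SampledSignal(wp.wall_amp * np.exp(1j * phase),
                         fs=wall_velocity.fs, t0=wall_velocity.t0)


# --------------------------------------------------------------------------
# full composite
# --------------------------------------------------------------------------

def pressure_waveform(config: "SimConfig", t: np.ndarray) -> np.ndarray:
    """Arterial blood-pressure pulse P(t) in mmHg.

    A normalised sum of heart-rate harmonics scaled so that
    ``pressure_amp`` equals half the peak-to-peak pulse pressure.
    """
    w = config.flow.heart_angular_freq
    pulse = np.zeros_like(t)
    for h, (amp, ph) in enumerate(zip(config.pressure_harmonics,
                                      config.pressure_phases), start=1):
        pulse += amp * np.sin(h * w * t + ph)
    span = (pulse.max() - pulse.min()) / 2.0
    if span > 0:
        pulse /= span
    return config.pressure_mean + config.pressure_amp * pulse

def _max_blood_velocity(fp: FlowProfileParams) -> float:
    v = 2.0 * fp.mean_velocity
    for p, vp in enumerate(fp.harmonic_amplitudes, start=1):
        # |psi| peaks on the axis for moderate alpha; bound it there
        v += abs(vp) * abs(_womersley_psi(fp.womersley_alpha * np.sqrt(p), 0.0))
    return v


def simulate_composite(config: SimConfig) -> SimulationTruth:
    """Generate a composite blood + wall + noise baseband signal.

    Scatterers sit at stratified-random relative radii y in [0, 1) with
    uniform random phase offsets; each follows the local Womersley
    velocity.  Identical seeds give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.fs * config.duration))
    if n < 2:
        raise ValueError("duration too short for the sampling rate")
    t = np.arange(n) / config.fs

    max_fd = _max_blood_velocity(config.flow) * config.geometry.hz_per_cm_s
    if config.fs < 2.0 * max_fd:
        raise ValueError(
            f"fs={config.fs} Hz violates Nyquist for the configured flow "
            f"(max Doppler shift ~{max_fd:.0f} Hz)")

    # blood: stratified radial positions across the sample volume
    ns = config.n_scatterers
    if ns > 0 and config.blood_amp != 0:
        y = config.y_max * (np.arange(ns) + rng.random(ns)) / ns
        psi0 = rng.uniform(0.0, 2.0 * np.pi, ns)
        blood = np.zeros(n, dtype=complex)
        per_amp = config.blood_amp / np.sqrt(ns)
        for j in range(ns):
            v_j = womersley_profile(config.flow, y[j], t)
            phase = _doppler_phase(v_j, config.fs, config.geometry)
            blood += per_amp * np.exp(1j * (phase + psi0[j]))
    else:
        # keep the stream state independent of the branch taken
        rng.random(ns)
        rng.uniform(0.0, 2.0 * np.pi, ns)
        blood = np.zeros(n, dtype=complex)

    # wall
    pressure = SampledSignal(pressure_waveform(config, t), fs=config.fs)
    _, v_wall = wall_radius_and_velocity(config.wall, pressure)
    wall = wall_doppler_signal(config.wall,
                               SampledSignal(v_wall, fs=config.fs),
                               config.geometry)
    wall_samples = wall.samples if config.wall.wall_amp != 0 else np.zeros(n, dtype=complex)

    # noise at SNR relative to the blood component
    blood_rms = float(np.sqrt(np.mean(np.abs(blood) ** 2)))
    if np.isfinite(config.snr_db) and blood_rms > 0:
        noise_sd = blood_rms * 10.0 ** (-config.snr_db / 20.0)
    else:
        noise_sd = 0.0
    noise = (noise_sd / np.sqrt(2.0)) * (rng.standard_normal(n) + 1j * rng.standard_normal(n)) \
        if noise_sd > 0 else np.zeros(n, dtype=complex)

    composite = blood + wall_samples + noise
    return SimulationTruth(
        composite=SampledSignal(composite, fs=config.fs),
        blood_truth=SampledSignal(blood, fs=config.fs),
        wall_truth=SampledSignal(wall_samples, fs=config.fs),
        noise=noise,
        noise_sd=noise_sd,
        seed=config.seed,
        config=config,
    )
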