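"""NPZ / CSV persistence for signals, simulation truths and IMF sets."""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path

import numpy as np

from .emd import IMFSet
from .signal import SampledSignal
from .simulate import SimulationTruth

__all__ = ["save_truth", "load_truth", "save_signal", "load_signal",
           "save_imfset", "load_imfset", "signal_to_csv", "signal_from_csv"]


def _config_json(config) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, (tuple, list)):
            return [enc(v) for v in o]
        return o
    return json.dumps(enc(config))


def save_truth(path, truth: SimulationTruth) -> None:
    np.savez(path,
             composite=truth.composite.samples,
             blood=truth.blood_truth.samples,
             wall=truth.wall_truth.samples,
             noise=truth.noise,
             fs=truth.composite.fs,
             seed=truth.seed,
             noise_sd=truth.noise_sd,
             params=_config_json(truth.config))


def load_truth(path) -> dict:
    """Load a saved truth archive into a dict of SampledSignals + metadata."""
    with np.load(path, allow_pickle=False) as z:
        fs = float(z["fs"])
        return {
            "composite": SampledSignal(z["composite"], fs),
            "blood": SampledSignal(z["blood"], fs),
            "wall": SampledSignal(z["wall"], fs),
            "noise": z["noise"],
            "seed": int(z["seed"]),
            "noise_sd": float(z["noise_sd"]),
            "params": json.loads(str(z["params"])),
        }


def save_signal(path, sig: SampledSignal, **extra) -> None:
    np.savez(path, samples=sig.samples, fs=sig.fs, t0=sig.t0, **extra)


def load_signal(path, key: str = "samples") -> SampledSignal:
    with np.load(path, allow_pickle=False) as z:
        if key not in z:
            # accept truth archives as signal sources
            key = "composite" if "composite" in z else key
        t0 = float(z["t0"]) if "t0" in z else 0.0
        return SampledSignal(z[key], float(z["fs"]), t0)


def save_imfset(path, imfset: IMFSet) -> None:
    arrays = {f"imf_{i + 1:02d}": imf for i, imf in enumerate(imfset.imfs)}
    np.savez(path, residual=imfset.residual, fs=imfset.source_fs, **arrays)


def load_imfset(path) -> IMFSet:
    with np.load(path, allow_pickle=False) as z:
        keys = sorted(k for k in z.files if k.startswith("imf_"))
        return IMFSet(imfs=[z[k] for k in keys], residual=z["residual"],
                      source_fs=float(z["fs"]))


def signal_to_csv(path, sig: SampledSignal) -> None:
    """Two-column (time_s, value) CSV; complex signals get real/imag columns."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        if sig.is_complex:
            w.writerow(["time_s", "value_real", "value_imag"])
            for t, v in zip(sig.times, sig.samples):
                w.writerow([repr(float(t)), repr(float(v.real)), repr(float(v.imag))])
        else:
            w.writerow(["time_s", "value"])
            for t, v in zip(sig.times, sig.samples):
                w.writerow([repr(float(t)), repr(float(v))])


def signal_from_csv(path) -> SampledSignal:
    data = np.genfromtxt(path, delimiter=",", names=True)
    t = data["time_s"]
    if "value_imag" in (data.dtype.names or ()):
        samples = data["value_real"] + 1j * data["value_imag"]
    else:
        samples = data["value"]
    dt = np.diff(t)
    fs = 1.0 / float(dt.mean())
    return SampledSignal(samples, fs, t0=float(t[0]))
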