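# ddsim — Doppler blood-flow / vessel-wall signal separation

Ultrasound Doppler measures blood velocity from the frequency shift of
echoes scattered by moving blood cells, but the raw signal also carries
the echo of the pulsating vessel wall — a low-frequency component whose
amplitude can exceed the blood signal by 20–60 dB. Unremoved clutter
biases every downstream velocity estimate; a fixed high-pass "wall
filter" either leaks clutter or amputates slow diastolic flow. `ddsim`
is a toolkit for researchers in biomedical signal processing who want a
fully reproducible, ground-truth-equipped testbed for this separation
problem.

The package provides:

- a **physical simulator**: Womersley pulsatile flow
  (`v(y,t) = 2v₀(1−y²) + Σₚ vₚ|ψₚ(y)|cos(pwt+εₚ+χₚ)`) sampled by
  randomly placed scatterers, an exponential pressure–area wall model
  (`S(t) = a·e^{bP(t)} + c`) driving a constant-modulus clutter phasor,
  and white noise — composite, blood and wall returned separately;
- **empirical mode decomposition** (cubic-spline envelope sifting) and
  **Hilbert spectral analysis** (instantaneous amplitude/frequency per
  intrinsic mode function);
- the **optimized separator**: IMF layers are classified into blood /
  mixed / wall; mixed layers are cleaned with an adaptive sigmoid-gated
  threshold `sgn(x)(|x| − 2σᵢ/(1+e^{L(x²−σᵢ²)}))` scaled by the robust
  noise-power ladder `σ₁ = MAD(x₁)/0.6745`, `σᵢ = σ₁·2^{−(i−1)/2}`;
  the wall is reconstructed as `w(t) = Σ_{k}^{M−1} ŵᵢ + Σ_{M}^{N} xᵢ`
  and blood = composite − wall;
- two **baselines** (plain EMD truncation; zero-phase Butterworth
  high-pass) and the **evaluation metrics**
  `Ef = Σ(F−F_s)²/ΣF_s²` (mean-frequency-curve error) and
  `MRE = (1/M)ΣᵢΣ_f|P₁−P₂|/Σ_fP₂` (segmented PSD error);
- **trial statistics** for the accompanying two-arm clinical tables
  (efficacy rates, incidences, 2×2 chi-square, t from summary moments).

See `docs/methods.md` for the full model description and design
rationale.

## Worked example

```python
from ddsim import SimConfig, simulate_composite, separate, baseline_highpass
from ddsim.pipeline import evaluate_separation

truth = simulate_composite(SimConfig(seed=1))       # 2 s at 10 kHz
res = separate(truth.composite)
print("classification:", res.classification)
m = evaluate_separation(truth, res.blood)
print(f"optimized  Ef={m['ef']:.3f}  MRE={m['mre']:.3f}  r={m['correlation']:.3f}")
m = evaluate_separation(truth, baseline_highpass(truth.composite).blood)
print(f"high-pass  Ef={m['ef']:.3f}  MRE={m['mre']:.3f}  r={m['correlation']:.3f}")
```

prints

```
classification: LayerClassification(k=2, M=3, N=7)
optimized  Ef=0.096  MRE=0.366  r=0.800
high-pass  Ef=0.151  MRE=1.429  r=0.621
```

The decomposition produced 7 layers; layer 1 is pure blood, layer 2 is
mixed (blood sharing a layer with the sparse systolic clutter burst and
cleaned by the threshold), layers 3–7 are wall. The optimized separator
tracks the true blood signal's mean-frequency curve about a third
closer (Ef 0.096 vs 0.151), reproduces its power spectrum four times
more accurately (MRE 0.366 vs 1.429), and correlates better with the
ground truth (r = 0.80 vs 0.62) than a 60 Hz wall filter, which both
leaks the systolic clutter shoulder and cuts slow blood flow.

## Command line

Every stage is exposed as a `ddsim` subcommand operating on NPZ/CSV/
JSON/YAML files:

```sh
ddsim simulate --seed 3 --out truth.npz
ddsim emd      --in truth.npz --out imfs.npz
ddsim hht      --in imfs.npz  --out tracks.npz
ddsim separate --in truth.npz --method optimized --out sep.npz
ddsim evaluate --est sep.npz  --truth truth.npz --out metrics.json
ddsim trial    --out trial.json
ddsim bench    --seed 1 --seeds 20 --out-dir run/
ddsim fixtures --out-dir fixtures/
```

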