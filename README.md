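# fearcond

Analysis toolkit for threat-conditioning neural recordings: single-neuron
encoding models with a time kernel, population-state analyses, two-channel
fiber-photometry processing, and behavioral indices — exercised end-to-end
on a bundled synthetic-data generator with known ground truth.

It is written for systems-neuroscience analysts working downstream of
calcium-imaging trace extraction (CNMF-E-style ΔF/F CSV exports) or
photometry acquisition, who need tested, reproducible implementations of
the standard fear-conditioning analysis battery.

## What it computes

**Time-kernel encoding model.** Each neuron's 500-ms-binned trace
*y<sub>t</sub>* is regressed on trial-split, lagged task indicators and
lagged speed plus an autoregressive term:

```
y_t = β₀ y_{t−1} + Σₙ Σᵢ β₁ₙᵢ Toneₙ(t−i) + Σₙ Σᵢ β₂ₙᵢ Shockₙ(t−i)
    + Σₙ Σᵢ β₃ₙᵢ ITIₙ(t−i) + Σᵢ β₄ᵢ Speed(t−i) + ε_t
```

with a 5-bin (2.5 s) kernel. A variable is *encoded* when removing all of
its columns significantly reduces explained variance (partial F-test on
the extra sum of squares, rank-aware because the lagged dummy coding is
structurally collinear). Per-trial tests, reactivation probability,
speed-tuning curves and collinearity diagnostics (VIF > 10,
condition index > 30, minimum-eigenvalue path) are built on the same fit.

**Population state.** Baseline Z-scoring against the first 5 minutes, the
T×T population-vector Pearson-correlation (PCC) matrix with epoch-wise
means (diagonal factored out), PCA trajectories through neural state
space, the Mahalanobis distance
d<sub>M</sub> = √((x̄−ȳ)ᵀS⁻¹(x̄−ȳ)) between baseline and post-shock
centroids, a repeated stratified 75/25 logistic classifier of (PC1, PC2)
coordinates, and Kolmogorov–Smirnov comparisons of per-cell mean-Z
distributions.

**Photometry.** Isosbestic (405 nm) control-channel drift correction by
affine least squares, session and 20-s peri-event Z-scoring, signed
trapezoidal AUCs over the standard cue-locked windows (0–10, 10–28,
28–33, 33–50 s), and refractory-separated transient counting.

**Behavior.** A speed-threshold freezing surrogate, the cue
discrimination index (F₊−F₋)/(F₊+F₋), the novel-object difference index,
and the Y-maze spontaneous-alternation percentage.

**Synthetic data.** Session schedules (conditioning: 30-s tones
co-terminating with 2-s shocks; cue discrimination: interleaved 10-s
CS+/CS− cues), neural populations generated from the same linear model
the encoder fits (so recovery is exactly well-posed), two-channel
photometry with bleaching and a shared motion artifact, speed traces with
post-shock freezing, and a controllable post-shock population-state shift.

## Worked example

```python
import fearcond as fc

cfg = fc.RunConfig(n_neurons=50, fraction_tuned=0.2, effect_size=1.0,
                   shift_gain=1.0, shared_factor_sd=0.3,
                   with_photometry=True, seed=42)
report = fc.run_pipeline(cfg)
for key in ("fraction_encoding_footshock", "mahalanobis_shift",
            "classifier_accuracy", "classifier_chance"):
    print(f"{key}: {report.scalars[key]:.4g}")
print(report.tables["epoch_pcc"].to_string(index=False))
```

prints

```
fraction_encoding_footshock: 0.24
mahalanobis_shift: 10.84
classifier_accuracy: 1
classifier_chance: 0.6095
   epoch  mean_pcc
baseline -0.001651
     cue  0.498441
   shock  0.686505
     iti  0.724617
```

20% of the simulated neurons carry a shock weight and the encoder flags
24% (the extra 4% reflects shift-driven activity changes plus the nominal
5% false-positive rate); the injected post-shock state shift separates the
baseline and post-shock PC clouds by ≈11 pooled within-group standard
deviations, so held-out classification is perfect against a 61%
majority-class chance level; and the shared latent factor raises
within-epoch population-vector correlations in post-shock epochs (shock,
ITI) far above the baseline level near 0.

The same stages are available from a shell:

```sh
fearcond simulate --n-neurons 50 --seed 42 --out run/sim
fearcond encode --activity run/sim/activity.csv \
    --schedule run/sim/schedule.json --speed run/sim/speed.csv --out run/enc
fearcond report --seed 42 --out run/report
```

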