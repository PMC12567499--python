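# mtuforce

Localizing key muscle–tendon units (MTUs) and predicting muscle force from
high-density surface EMG (HD-sEMG).

A 2-D electrode grid over a muscle records a linear mixture
`x(t) = A s(t) + n(t)` of the electrical activity of several muscle
compartments. `mtuforce` separates that mixture, finds where each source
sits on the grid, and regresses the muscle's force output from the
separated signals:

1. **Preprocessing** — zero-phase frequency-domain Butterworth band-pass
   (20–450 Hz), sliding 0.5 s / 0.2 s analysis windows, MVC normalization.
2. **Separation** — maximum-likelihood ICA: centering, PCA whitening to
   5 components, then natural-gradient ascent on
   `L(W) = Σ_t Σ_i log p(y_i(t)) + T log|det W|` with a hyperbolic-secant
   source prior (score `−tanh`), learning rate 0.020, tolerance 1e-4.
3. **Localization** — spectral EMG-vs-noise classification of each
   component (EMG-band power fraction ≥ 0.7), then a weighted centroid of
   electrode positions under the mixing-column magnitudes `|Â[:, j]|`.
4. **Force prediction** — a from-scratch backpropagation MLP (two hidden
   layers × 5 sigmoid units, linear output) trained full-batch with
   learning rate 0.3 and momentum 0.9 to a target MSE of 0.001, on windowed
   RMS features of the EMG sources.
5. **Evaluation** — Pearson correlation `r = Cov(X,Y)/(σ_X σ_Y)` with
   (n−1) denominators, per-sample relative error in percent, seeded 8:2
   train/test split and 5-fold cross-validation.

A ground-truthed synthetic HD-sEMG generator (independent band-limited
amplitude-modulated sources, Gaussian spatial mixing over the grid,
posture-dependent N/S activation patterns, envelope-driven force) makes the
whole chain testable without any recorded data. See `docs/methods.md` for
the model and its assumptions.

## Worked example

```python
from mtuforce import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=0))
print(result.report.to_dict())
```

prints

```
{'pcc': 0.9989, 'mean_relative_error_pct': 9.6, 'max_relative_error_pct': 56.9,
 'mse': 6.82, 'n_samples': 73}
```

— on 73 held-out analysis windows from the simulated two-posture protocol,
predicted force correlates with ground truth at r = 0.999; over the active
windows (force above 5% of peak) the mean prediction error is 9.6% and the
worst single window 56.9% (relative error is large where the denominator is
small). The same run localizes all five simulated sources per posture to
within ~1.5 mm on a 10 mm-pitch grid, e.g.

```
posture N: centroid errors [0.23, 0.41, 0.59, 1.39, 1.51] mm
posture S: centroid errors [0.09, 0.12, 0.28, 1.15, 1.5] mm
```

The `examples/` directory has one short script per capability (simulation,
separation, localization, force regression, full pipeline); each prints
the numbers it computes and what they mean. A thin CLI wraps the same
library calls:

```bash
mtuforce simulate --posture N --seed 7 --out-dir out
mtuforce localize out/recording.csv out/recording.json --out-dir out
mtuforce pipeline --seed 7 --out-dir out
mtuforce sweep-lr --rates 0.1,0.3,0.5
```

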