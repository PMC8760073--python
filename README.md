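# wmcode

Analysis of spatial working-memory population codes in prefrontal
microelectrode-array recordings, for a naturalistic 9-target task with a
drug-injection timeline (pre / early post / late post-injection trial
blocks), plus a synthetic-session generator so the full chain runs with no
data download.

## What it computes

Given a session (trials with cue → delay → response epochs, per-unit spike
events, mean waveforms, gaze tables, navigation trajectories), the pipeline
produces:

* **Behavior** — percent correct per injection period with exact binomial
  tests against the 9-target chance level (1/9 ≈ 11%), response times, and
  a 5×5 trajectory-occupancy grid (25 cells × 9 target conditions = 225
  values per session) with increase-only difference maps between periods.
* **Single-unit tuning** — one-way ANOVA of epoch-averaged firing rate on
  target location, with a 50× balanced-subsampling median procedure to
  equalise trial counts across periods; preferred / least-preferred
  locations; ranked-tuning slopes (rate vs. preference rank 1..9); Gaussian
  spike-density functions (SD 150 ms); a second-order polynomial surface
  fit `f(x,y) = p00 + p10 x + p01 y + p20 x² + p02 y² + p11 xy` for display.
* **Ensemble decoding** — linear SVM (z-scored rates, inner search for the
  penalty C) with 5-fold cross-validation, class balancing by subsampling
  (×20), greedy ensemble growth to 16 units, and a 10× label-shuffle null.
* **Population-code decomposition** — for binary left/right discrimination
  by small ensembles: population signal `PS = |Δf|`, projected precision
  `PP = √(Σᵢ cos²θ̂ᵢ / σ̂ᵢ²)` from the eigendecomposition of the
  within-class covariance Σ, theoretical decoding accuracy
  `DPt = Φ(PS·PP/2)`, and its empirical counterpart `DPe` from a
  cross-validated linear discriminant sharing the same
  shrinkage-regularised Σ, over random ensembles of 2/3/5 units with a
  top-quartile selection.
* **Cell typing** — spike-waveform peak-to-trough width via ×100
  cubic-spline upsampling, 1- vs 2-Gaussian mixture selection by AIC, and a
  narrow-/broad-spiking boundary at the component-density crossing; plus
  the downstream contrast of preferred / least-preferred rates per class.
* **Gaze controls** — on-target fixation-time proportion, decoding the
  target from 16-cell fixation-count maps, decoding the eye's screen
  region from neural activity, and saccade tuning in retinocentric vs
  spatiocentric frames with cross-frame power matching.

The synthetic generator emulates the statistical structure these analyses
assume — 9-location Gaussian-bump tuning in two waveform classes, shared
trial gain producing count correlations, a perturbation mode with
cell-type-specific rate changes, period-dependent behavior and gaze — and
emits ground truth alongside each session (never read by the analyses).

## Worked example

```python
from wmcode import GeneratorConfig, generate_session
from wmcode.tuning import epoch_rates, tuning_census, rate_matrix
from wmcode.decoding import decode_cv

rec, truth = generate_session(GeneratorConfig(), seed=11)
census = tuning_census(rec, epoch="delay", seed=0)
print(census.groupby("period")["selective"].mean().round(2))

rates = epoch_rates(rec, "delay")
X, info = rate_matrix(rates)
pre = (info["period"] == "pre").to_numpy()
res = decode_cv(X[pre][:, :16], info.loc[pre, "target_column"], seed=0)
print(round(res.accuracy, 3))
```

prints

```
period
early_post    0.23
late_post     0.86
pre           1.00
Name: selective, dtype: float64
0.774
```

i.e. every unit in this session is delay-tuned before injection, the tuned
fraction collapses to ~23% in the early post-injection block and recovers
late — the generator's drug effect as seen through the ANOVA census — and
a 16-unit ensemble decodes the target column at ~77% versus a 33% chance
level.

A command-line interface mirrors the library
(`wmcode simulate|behavior|trajectory|tuning|decode|popcode|waveforms|gaze|all`,
each with `--config`, `--seed`, `--out`).

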