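# Methods

## Task and data model

A session is one recording experiment in a virtual 9-target spatial
working-memory task. Targets form a 3×3 grid with 290 arena-unit spacing,
centred at the origin; columns are indexed left→right and rows near→far,
and the grid column (left/center/right) is the class label for pooled
decoding. Each trial presents the target for 3000 ms (cue), removes it for
2000 ms (delay), then enables navigation; the analysed response window is
the first 2000 ms after navigation onset. All times are milliseconds from
session start and every epoch window is half-open `[on, off)`, so a spike
is counted in exactly one epoch. Trials are labelled by injection period
from their start time: `pre` before the injection, `early_post` within
30 min of it, `late_post` from 30 to 60 min. Assignment of a trial that
spans the 30-min boundary follows its start time.

Sessions are stored either as a directory of CSV tables plus a
`session.json` sidecar or as one HDF5 file with the same tables; the two
dialects round-trip identically. Validation enforces spike→unit
referential integrity, epoch ordering and spans, and period-label
consistency.

## Synthetic sessions

The generator emulates the statistical structure the analyses assume; its
defaults are the study conditions used by the test suite and the
acceptance script.

* **Tuning.** Each unit's delay-epoch tuning curve is a Gaussian bump over
  the grid coordinates: `rate(loc) = b + a·exp(−d²/2w²)` with baseline
  `b = 3 Hz`, peak `b + a = 8 Hz`, bandwidth `w = 290` arena units (one
  grid spacing), and a uniformly drawn preferred location. The cue and
  delay epochs share the curve; the response epoch damps the tuned
  component by 0.7; the 500 ms pre-cue interval fires at baseline. The
  peak/noise combination is chosen so the pre-injection delay-tuned
  fraction sits near 0.9 rather than saturating at 1, leaving headroom for
  the perturbation to be measurable.
* **Variability.** Counts are conditionally Poisson given a per-trial
  multiplicative gain `max(0.05, 1 + ρ·z_trial + s·z_unit,trial)` with
  shared-gain strength ρ = 0.2 (producing positive noise correlations that
  grow with ρ) and private dispersion s = 0.25 (over-dispersing counts,
  Fano factor > 1). Spike times are uniform within epochs.
* **Perturbation.** In the early post-injection period narrow-spiking (NS)
  units have their tuned amplitude multiplied by `g_NS = 0.5`
  (a rate decrease concentrated at preferred locations), and broad-spiking
  (BS) units gain `δ_BS·(1 − bump) = 4 Hz` at their least-preferred
  locations (an increase away from the preferred location). The late
  period retains 35% of the early effect. Effect sizes are calibration
  choices — the direction and significance of the effects, not their
  magnitudes, are the reproduction targets.
* **Waveforms.** Widths are drawn from a two-Gaussian mixture (means
  220 µs NS / 420 µs BS, SD 40 µs); each unit's mean waveform is a
  biphasic two-Gaussian template sampled at 30 kHz whose trough-to-peak
  interval equals the drawn width, so the width pipeline can be checked
  against ground truth.
* **Behavior and gaze.** Correct probability, response-time mean, and
  trajectory dispersion are per-period parameters (defaults 0.80/0.50/0.70,
  4.0/5.5/4.5 s, 25/80/40 arena units); trajectories are straight paths
  start→target plus Brownian-bridge lateral noise whose midpoint SD is the
  dispersion parameter (incorrect trials head to a random wrong target).
  Fixations arrive at 3 Hz and land in the target's screen cell with
  probability 0.15, otherwise uniformly; saccades connect consecutive
  fixations. A perception-control mode makes the behavior parameters
  period-independent.

What the generator deliberately does not emulate: temporal spike dynamics
within epochs (ramping, oscillations), rate-dependent waveform changes,
realistic saccade kinematics, and any dependence of neural activity on eye
position. Passing tests therefore demonstrate the correctness and
calibration of the analysis chain under the assumed count model, not that
the biological claims hold in new data.

## Tuning statistics

Selectivity is a classical one-way fixed-effects ANOVA on epoch-averaged
rates with location as the factor. To compare periods at matched power,
each unit's trials are subsampled without replacement to its minimum
per-location count across the three periods, 50 times, and the median
p-value is kept; when counts are already equal the procedure reduces
exactly to the full-data ANOVA. Two α levels coexist: 0.05 for the tuning
census and 0.1 for the lenient inclusion feeding the NS/BS contrast.
Constant-rate units are skipped, ties in preferred location break toward
the lowest index and are flagged.

Ranked slopes sort each unit's nine location means from preferred to least
preferred, normalise by the unit maximum (config-switchable), average over
units, and fit a least-squares line against rank 1..9; sharper tuning means
a more negative slope. Spike-density functions are plain convolutions with
an untruncated Gaussian kernel (SD 150 ms, mass 1 per spike, peak
≈ 2.66 Hz per spike); edges are not renormalised, so estimates are biased
low within ~2 kernel SDs of a window edge. The polynomial surface fit is a
display aid solved by least squares (6 coefficients, 9 points).

## Decoding

The multiclass decoder is a linear SVM (liblinear, one-vs-rest) on z-scored
rates. The scaler and the penalty C live inside the cross-validated
pipeline: C is selected per training fold by an inner 3-fold search over
{10⁻², 10⁻¹, 1, 10, 10²}, so no test-fold information reaches training.
Classes are balanced by subsampling to the smallest class, 20 times, with
stratified 5-fold cross-validation per draw; accuracy is the mean over
folds and draws, and confusions are summed. Greedy ensembles start from
the best single unit and add the candidate that maximises accuracy, to 16
units; ties go to the lowest unit id. Selection is frozen on pre-injection
trials and the frozen ensemble is evaluated per period (the alternative,
per-period selection, is a function argument away). The greedy search
scores candidates with a lighter protocol (2 balancing draws, fixed C);
reported accuracies always use the full protocol. Chance is estimated by
10 label shuffles under the identical protocol, and a session whose null
mean exceeds the binomial 2-SE band around chance is flagged for
exclusion.

## Population signal and projected precision

For binary left/right discrimination by an ensemble of N units with trial
rate vectors x:

* `Δf` is the vector of per-unit class-mean differences; `PS = |Δf|`;
  `u_Δf = Δf/PS` (undefined at PS = 0, in which case DPt = 0.5 and PP is
  reported as not applicable).
* Σ is the pooled within-class covariance with analytic shrinkage of the
  off-diagonal entries toward zero (Schäfer–Strimmer intensity
  `λ* = Σ_{i≠j} Var̂(s_ij) / Σ_{i≠j} s_ij²`, clipped to [0,1]). Shrinking
  toward the diagonal keeps per-unit variances intact and Σ positive
  definite at the small trial counts where 2–5-unit ensembles are used.
* With eigenpairs (σ̂ᵢ², vᵢ) of Σ and cos θ̂ᵢ = vᵢ·u_Δf:
  `PP = √(Σᵢ cos²θ̂ᵢ/σ̂ᵢ²)` and `DPt = Φ(PS·PP/2)` with Φ the standard
  normal CDF. The cos² terms sum to 1; PP² is bracketed by the inverse
  extreme eigenvalues; scaling all rates by c multiplies PS by c and PP by
  1/c, leaving DPt invariant.
* `DPe` is the 5-fold cross-validated accuracy of a linear discriminant
  `w = Σ⁻¹Δf` thresholded at the projected midpoint (equal priors after
  balancing), using the same shrunk Σ — so DPe and DPt are estimates of
  the same quantity and are directly comparable. Their agreement is
  checked with an unpaired rank test across ensembles, the appropriate
  sensitivity for an equivalence control: DPe carries a small (<0.01)
  cross-validation pessimism that a paired test on hundreds of ensembles
  would resolve even when the two measures agree to within half a percent.

Random sweeps draw ensembles of 2, 3, and 5 units (without replacement
within an ensemble; all unique combinations when fewer than requested
exist) from units with mean rate > 0.5 Hz, and flag the top quartile by
DPe within each size, per period.

## Waveform classification

Widths are measured on ×100 cubic-spline-upsampled mean waveforms as the
absolute time between the voltage minimum and maximum; both extrema must
be interior to the trace (monotone or single-signed waveforms are
excluded), which also makes the width invariant to polarity and affine
voltage scaling. After dropping widths above 675 µs, 1- and 2-Gaussian
models are fitted by maximum likelihood (EM, 10 restarts) and compared by
AIC. When the 2-Gaussian model wins, the NS/BS boundary is the crossing of
the two weighted component densities between the means — the histogram's
valley; exact-boundary ties classify as BS. Identical components make the
boundary undefined and the fit degenerate (all units one class, flagged).
At desk-scale unit counts the mixture should be fitted on widths pooled
across sessions and the resulting boundary applied per session.

## Gaze analyses

Fixations shorter than 6 ms are dropped everywhere. The on-target
proportion is summed on-target fixation time over summed fixation time in
the delay epoch of correct trials; "on target" means inside the 16-cell
screen-grid cell containing the target's screen projection, tying the
scoring window to the same spatial scale as the fixation-map decoder. That
decoder counts fixations in the 4×4 screen grid per trial and classifies
with the standard SVM protocol; its paired neural comparator uses the same
trials and 16 units. Eye-region decoding classifies each fixation's screen
quadrant from all units' within-fixation rates (4-fold CV, chance 25%);
sessions missing a region are excluded. Saccade tuning bins saccades by
quadrant in a retinocentric frame (displacement sign) and a spatiocentric
frame (landing quadrant), equalises power by rank-pairing bins across
frames and randomly dropping saccades from the larger bin, requires ≥10
saccades per bin and ≥3 acceptable bins, and tests each unit's
per-saccade rates (200 ms from saccade onset) with Kruskal–Wallis.

## Reproducibility and problem sizes

Every stochastic step takes a seed derived from the master seed by hashing
`master:stage:key` (SHA-256, 31 bits), so stages are independently
re-runnable and identical configurations produce byte-identical outputs.
Defaults for synthetic studies are 32 units (8 NS, 24 BS, 25% multiunit)
and 12 trials per location per period (324 trials), the largest trial
count that fits the 30-min injection blocks given the behavior defaults;
effect-recovery studies use 10 seeded replicate sessions, ensemble sweeps
150–1000 random ensembles, and Monte-Carlo oracles 10⁵ draws. These sizes
are the package's desk-scale defaults; all of them are function arguments.

## Known limitations

Epoch-constant rates make the SDF analyses a smoke test rather than a
probe of temporal structure. The shuffle-null flag uses a normal
approximation to the binomial band. The plane fit is unregularised and
display-only. Session-level mixture fits below ~50 widths are refused
rather than attempted. The empirical 75th-percentile ensemble selection is
per period by default; freezing on the pre-period is available but not the
default.
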