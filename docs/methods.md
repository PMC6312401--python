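# Methods

`oriem` reconstructs orientation-selective information from multichannel EEG
with a forward (inverted) encoding model and tests how repetition and
expectation modulate it.  Because the recorded data of such experiments are
not bundled with the package, every stage is validated against a synthetic
forward simulation whose ground truth is known exactly.  This note documents
the models, the parameters that matter, the numerical choices, and what the
synthetic validation does and does not establish.

## The task and the factorial design

Each trial presents two Gabors 600 ms apart (stimulus onset asynchrony);
orientations come from a 9-value grid, 0-160 deg in 20-deg steps.  In a
*repeating* block 80% of trials repeat the first Gabor's orientation; in an
*alternating* block 80% alternate.  Crossing trial type with block type
gives the 2x2 factorial (expected/unexpected x repeat/alternate), so
repetition and expectation are orthogonal factors.  The generator enforces
the contingencies exactly per block (108/27 in a 135-trial block), balances
the second-Gabor orientation over the grid within every condition cell, and
flags exactly 10% of a session's trials as colour targets (a task flag
only).  Exact counts require `trials_per_block` divisible by 45 and an even
block count; violations raise a configuration error naming the constraint.
First-Gabor orientations on alternate trials cycle through shuffled decks of
the 8 non-matching grid values (a without-replacement scheme); the precise
counterbalancing of first against second orientations is a reconstruction —
the design only guarantees per-cell second-orientation balance.

## The encoding model

At one time point, sensor data `B` (sensors x trials) are modelled as
`B = W C`, where `C` holds basis-function activations of each trial's
presented orientation and `W` is a spatial weight matrix.  The basis is nine
half-cosines raised to the 8th power, centred on the grid orientations:
non-negative, 180-deg periodic, unit peak, zero at 90-deg orientation
distance, and with a channel sum constant in orientation (315/128), so the
basis tiles orientation space without bias.  Weights are ordinary least
squares on training trials, `W = B C'(C C')^-1`, and held-out trials are
inverted through `C2 = (W'W)^-1 W' B2`.  (These are the unique least-squares
forms consistent with the stated matrix shapes.)  Estimation runs in a 16 ms
sliding window (window-averaged samples as features, keeping the regression
at sensors x channels), with cross-validation so no trial ever contributes
to the weights used to reconstruct it.  Reconstructed 9-vectors are
circularly shifted so each trial's presented orientation sits at 0-deg
offset ("centering"), which allows averaging across orientations.

Fold assignment deals the trials of every orientation x condition cell
round-robin over folds.  This guarantees full-rank training sets and keeps
each fold's condition mixture constant, which matters because the inversion
normalises overall scale by the training set's mean tuning gain (see
*Amplitude scale* below).  Leave-one-out is available (`cv="loo"`); at the
package's reduced problem sizes 10-fold is the default and agrees with
leave-one-out to machine precision in the noiseless limit.

### Amplitude scale and what the encoder can recover

Two structural facts about this estimator are worth stating explicitly,
because they determine what "parameter recovery" can mean:

1. **Shape normalisation.**  With balanced training data the reconstruction
   of any orientation-tuned signal whose trial-to-activation map is
   circulant is the encoder's *own* basis profile — the model relabels its
   input into its own coordinates.  A recovered tuning width therefore
   reflects the basis (Gaussian-equivalent width ~19.8 deg for the
   half-cosine^8 profile), not the width of the underlying neural tuning.
   The simulator consequently injects the basis profile itself (so the
   noiseless round trip is exact), and records the injection's
   Gaussian-equivalent width as the recoverable ground truth.
2. **Scale normalisation.**  Because weights are refit at every time point,
   a uniform gain `g` on the data cancels: the noiseless reconstruction of a
   trial with gain `g_i` is `(g_i / g-bar) x profile`, with `g-bar` the mean
   training gain.  Condition gain *ratios* are recovered directly; absolute
   gains are recovered only after rescaling by `g-bar`, which the scoring
   stage takes from the simulator's ground truth (the only stage allowed to
   read it).  Fitted amplitudes are additionally divided by the tuning-fit
   amplitude of the unit profile (1.011; the Gaussian/half-cosine shape
   mismatch) when converted to the injected-gain scale.

## Tuning quantification

Centered responses, averaged per condition and smoothed along time with a
Gaussian kernel (the "16 ms window" is read as FWHM, truncated at +-2 SD,
reflected edges), are summarised by the four-parameter Gaussian
`G(x) = A exp(-(x - phi)^2 / (2 sigma^2)) + C`: amplitude `A` is the amount
of orientation-selective activity, `sigma` the width, `C` a non-selective
baseline.  The fit is deterministic: a separable scan over a 21 x 52
(phi, sigma) start grid — `A` and `C` are closed-form for fixed
(phi, sigma) — followed by one bounded least-squares polish.  Bounds are
sigma in [5, 90] deg and phi in [-20, 20] deg: nine points cannot constrain
wider or far-shifted Gaussians, and the bounds force a flat curve into
`A ~ 0` rather than a huge sigma.  A flat-model candidate caps the residual
sum of squares.  Two estimator refinements matter at small sample sizes:

- **Count matching.**  The fit's amplitude estimate carries a positive bias
  that grows with the noise of the averaged curve.  The 80/20 design makes
  the expectation conditions 4:1 unbalanced, so comparing a 648-trial
  average against a 162-trial average confounds the condition effect with a
  bias difference.  By default the majority condition is therefore fit on
  disjoint count-matched subsets and the parameters averaged
  (`match_counts=True`), equalising curve noise across conditions without
  discarding data.
- **Pinned centre for contrasts.**  Centered curves peak at 0 deg by
  construction, so for condition *contrasts* the centre is fixed
  (`fix_phi=True` in the desk-scale pipeline): a free centre latches onto
  noise peaks, inflating both the variance and the bias of `A`.  The full
  four-parameter fit (free phi) remains the default of the public functions
  and is used for parameter reporting and at full scale.

## Decoding

The backward decoder is the 'diaglinear' Gaussian discriminant: diagonal
covariance pooled across the nine orientation classes, uniform priors,
argmax posterior ('diagquadratic', per-class variances, is available by
flag).  Features are identical to the encoder's window-averaged sensor
values, so encoder/decoder comparisons are like-for-like.  Training pools
conditions; accuracies are scored per condition from the stored per-trial
predictions.  Chance is 1/9; the headline summary is peak accuracy in the
600 ms after second-Gabor onset.

## Statistics

Group inference is nonparametric: under the null each subject's difference
series is symmetric around zero, so whole-subject sign flips are
exchangeable.  The group statistic is the one-sample t; clusters form at the
parametric t threshold for the pointwise alpha (two-sided alpha is split),
contiguity is 1-D adjacency or 4-connectivity on time x time maps, cluster
mass is the summed t, and the corrected p-value of a cluster is the +1
corrected fraction of permutations whose maximum |mass| reaches it.  The
observed statistic is computed through the same vectorised code path as the
permuted statistics, so the identity permutation reproduces it exactly — a
requirement for correct p-values at small n, where identity draws are
common.

With five subjects there are only 2^5 = 32 flip patterns, and both the
identity and the global flip reproduce the observed maximum mass under a
two-sided test, so two-sided cluster p-values cannot fall below ~0.06.  The
desk-scale pipeline therefore tests condition contrasts one-sided in the
direction of the hypothesis (`cluster_tail="greater"`); at 15 subjects the
two-sided test (the convention for real cohorts) has full resolution and is
the full-scale default.  Permutation defaults are scaled down (1000 for
time series, 500 for generalisation maps); the full-scale counts (50000 /
5000) are one flag away.

ERP components are measured on 2-40 Hz band-passed condition averages over
the occipito-parietal sensor group: P1 is the largest positivity 80-110 ms
after stimulus onset, N1 the largest negativity 90-130 ms, ties resolving
to the earliest latency.  Paired t-tests on component amplitudes and on
early-window tuning amplitudes are classical and two-sided.

## The synthetic cohort

The simulator injects, per trial, the basis-profile channel activation of
the second-Gabor orientation, projected to 64 sensors through a forward
matrix whose orthonormal columns are shaped by an occipito-parietal
topography, scaled by a condition gain, a smooth envelope locked to
second-Gabor onset (zero before +50 ms, plateau 120-250 ms, decayed by
470 ms), and a log-normal per-subject gain (sd 0.2).  Defaults state the
study conditions: expected gain 0.41, unexpected 0.67 (the published group
amplitudes), 256 Hz, epochs -0.5 to 1.25 s, 64 sensors with the standard
BioSemi 10-20 labels.

No noise model is published, so the noise level is a design choice of the
generator: 0.8 uV white plus 0.8 uV pink (1/f) per sensor, chosen once so
that single-subject amplitude uncertainty at the package's reduced problem
sizes (5 subjects, 6 blocks = 810 trials) is commensurate with the
published group-level effect at full scale (15 subjects, 5400 trials).
Real recordings are noisier per trial by roughly the square root of the
trial-count ratio; the reduced scale trades trials for noise so that desk
runs finish in minutes.  With these conditions the expectation contrast is
detected as a significant directional cluster in about 80% of simulated
cohorts, equal-gain cohorts stay below the nominal false-positive rate, and
the cluster test's family-wise error rate on pure-null cohorts calibrates
to ~0.04-0.07 at nominal 0.05.

What the simulation does *not* emulate: eye and muscle artefacts, channel
drop-outs, line noise, spatially correlated noise (an optional mixing
matrix hook exists but is off), evoked non-orientation-selective ERP
structure, and any behavioural data.  Passing tests therefore establish the
correctness and calibration of the *analysis machinery*, not the
recoverability of effects from real recordings.

## Problem sizes and reproducibility

Desk-scale defaults — 5 subjects, 6 blocks, 10-fold CV, 16 ms windows at
8 ms steps over -100 to +450 ms around the second Gabor, 1000/500
permutations — complete a full pipeline run in well under a minute and the
whole validation suite in minutes.  `--full-scale` switches to 15 subjects,
20 blocks, leave-one-out CV, 4 ms steps and 50000/5000 permutations.  Every
stochastic stage derives its seed from the run's master seed through
`numpy.random.SeedSequence` spawn keys, so a (config, seed) pair fully
determines every numeric output; re-running a pipeline reproduces its CSVs
byte for byte.

## Known limitations

- Recovered tuning width is basis-determined (see above); the simulator's
  `tuning_width_deg` shapes the injected profile only under the optional
  `signal_profile="gaussian"` setting, and the encoder will still
  renormalise it.
- Absolute amplitude recovery requires the ground-truth mean training gain;
  blind analyses recover ratios and time courses, not absolute gains.
- The noisy-regime amplitude estimate retains a small positive bias (a
  fraction of the curve noise SD) even with count matching; contrasts
  between count-matched conditions are unbiased to first order.
- Spatial (electrode-adjacency) cluster correction over scalp maps is not
  implemented; cluster correction covers time series and time x time maps.
- No artefact-component removal (ICA) or bad-channel repair is provided;
  the container assumes clean channels.
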