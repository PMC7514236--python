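# Methods

This note documents the models, defaults and design choices behind
`eegskip`, what the synthetic data does and does not emulate, and the
known limitations of the method itself.

## Preprocessing chain

Stages run in a fixed order per trial: linked-mastoid re-referencing
(subtract 0.5·(TP9+TP10) from every channel) → baseline correction
(subtract the per-channel mean of the 3 s fixation window from the
viewing segment) → epoching (contiguous non-overlapping epochs from video
onset; 1 s for the entropy path, 500 ms for the power path; trailing
partial epochs dropped, since coarse graining needs a fixed epoch length)
→ band-pass filtering → downsampling to 500 Hz.

* **Filter**: 4th-order Butterworth, applied forward-backward
  (zero-phase) so the three band series stay time-aligned; theta 4–7 Hz,
  mu 8–13 Hz, beta 14–35 Hz. The mu band coincides with the alpha range
  and serves as the alpha signal in the arousal/valence indices.
* **Downsampling** picks every k-th sample; after the ≤35 Hz band-pass no
  anti-alias filter is needed at a 500 Hz target. Filtering at the native
  rate and then decimating is numerically equivalent (within filter
  tolerance) to the reverse order at these band edges.
* **Scalp average** excludes the mastoids (they are the reference);
  averaging before or after the identical per-channel linear filter is
  mathematically the same, and the implementation averages first for
  speed. No EOG/ICA artifact removal is implemented; an optional
  amplitude-threshold epoch-rejection hook exists and is off by default.
* **Band power** is the mean squared amplitude of the filtered epoch —
  the simplest estimator consistent with "power in the band".
* Indices are 0-based with half-open spans throughout.

## Entropy

Sample entropy uses the standard conventions: Chebyshev distance,
similarity "≤ r", self-matches excluded, both counts over the N−m
templates that admit a length-(m+1) extension, natural logarithm. The
embedding length defaults to m = 2 (the standard choice for short
physiological series; configurable and echoed in reports). The tolerance
is fixed once per epoch at r = 0.15·std of the scale-1 series and reused
at all scales, so coarse-graining-induced variance reduction is itself
part of the multiscale profile. Scales where the coarse series is shorter
than m+2 samples or yields no matching pair are recorded as missing and
excluded from the scale average (count logged) rather than poisoning the
trial; the `+inf` sentinel is returned only from the low-level function.

The pair counter is JIT-compiled (numba) with a pure-numpy vectorized
fallback; both produce integer counts and are verified against a
brute-force O(N²) enumeration, so the optimization cannot change any
result.

## Features

* The CV of Eq.-style "sd/mean on 1 s epochs" is computed over a sliding
  window of W = 5 consecutive per-epoch band-entropy values (stride 1);
  the RCV feature is the max−min of the resulting CV series. This is the
  reading that yields both a "range during the video" and per-scale
  curves; W is configurable, and the alternative reading (CV across the
  10 MSE scales within each epoch) is available via
  `FeatureConfig(cv_across_scales=True)`.
* Default entropy features use the 10-scale mean; per-scale relevance
  curves recompute them at a single scale.
* Epochs where any band/source entropy is undefined are dropped jointly
  across bands so index arithmetic always pairs values from the same
  epoch. Trials with fewer than W+1 usable entropy epochs (6 s at the
  defaults) are excluded and logged.
* CV2 returns 0 with fewer than two supra-threshold peaks (no variability
  evidence; count logged). Peak pairs summing to zero are skipped. For
  sign-changing indices (valence) the CV2 statistic can be negative —
  the [0, 2) bound holds only for positive peak sequences; the formula is
  applied verbatim.
* Zero denominators in any index raise a degenerate-input error and
  exclude the epoch (engagement/arousal) or trial rather than emitting
  non-finite features.

All nine features are scale-free (power ratios, std-relative tolerances,
CV, CV2, and ranges thereof), so multiplying the raw amplitudes by any
positive constant leaves the whole feature table unchanged to floating-
point precision — verified to ≤1e−9 relative in the acceptance checks.

## Classifiers and validation

"SVM" is a linear soft-margin SVM (C = 1): no specific solver or kernel
is canonical for this feature set, and a linear margin keeps the
nine-dimensional problem interpretable. kNN uses city-block distance with
k = 10 (k is clipped to the training-fold size on very small folds); the
random forest uses 100 trees with a fixed seed. Features are z-scored
with training-fold statistics for SVM/kNN (city-block distances are
otherwise dominated by the widest-ranged feature); the forest is
scale-invariant and unstandardized.

Leave-one-subject-out reports the unweighted mean of per-subject
accuracies. The repeated holdout draws unstratified pseudorandom 10%
test splits (500 by default) from a seeded generator, independent of the
labels, so the skip- and interest-task accuracy distributions from the
same seed are paired by split; splits whose test part misses a class are
redrawn with a bounded retry. A stratified variant is available by flag.
The Wilcoxon signed-rank comparison discards zero differences, uses the
exact distribution for ≤25 nonzero pairs and the normal approximation
with continuity correction above, and rejects at α/9 = 0.05/9 ≈ 0.00556.

## Synthetic sessions

The generator emulates the experiment's structure — 32-channel 10–20
montage, 3 s baseline, ~60 s (default 20 s for desk-scale runs) videos,
skipped trials ending uniformly at 30–90% of the video, binary
skip/interest responses with P(interest | not skipped) elevated — and a
minimal signal model: per band, a narrowband oscillatory source
(theta 5–6.5, mu 9–12, beta 17–25 Hz) multiplied by a slowly varying
log-normal envelope (exponential of an Ornstein–Uhlenbeck process,
τ ≈ 1 s, relative variance 0.15), over per-channel pink noise plus a
common-mode pink background; mastoids carry attenuated background only.
The log-normal envelope was chosen over a clipped linear one because it
is strictly positive and its relative variance can be scaled *exactly* by
the effect multiplier.

Class effects: for not-skipped trials the beta envelope's relative
variance is multiplied by (1 + effect_size); for interested trials the
mu/beta amplitudes at F4 and F3 are modulated in opposite directions with
depth proportional to effect_size. Effects live in envelope
*variability*, not mean power, because the nine features are range/
variability statistics. With effect_size = 0 the labels never touch the
signal path. Generation is deterministic in (config, subject id) via a
CRC-derived per-subject seed, and the random-draw order is independent of
effect_size, so cohorts at different effect sizes are coupled by common
random numbers — which is what makes the separation-vs-effect-size
monotonicity measurable with modest sample sizes.

Default amplitudes (µV): theta 6, mu 5, beta 4 narrowband sources,
background 6 per channel plus 3 common-mode. These were chosen once, at
design time, to give per-epoch entropies a realistic mid-range (band
SNR of order 1 at frontal channels) so that envelope fluctuations move
both power and entropy.

What the generator does **not** emulate: forward-modeled cortical
sources, eye blinks/EOG, electrode drift, inter-subject montage
variation, or any real relationship between video content and EEG.
Passing tests on synthetic data demonstrate the pipeline's correctness
and its sensitivity to envelope-variance effects — not that real viewers
produce such effects.

## The trial-length confound

All six entropy features are ranges over the trial, and a max−min over
more epochs is stochastically larger. Because skipped videos end early
(30–90% of the length), trial duration alone carries the skip label: on a
null cohort (effect_size = 0, 4 subjects × 45 trials) LoSOCV skip
accuracies reach ~70–80% and, through the skip–interest label
correlation, interest accuracies ~60–66% — far outside the binomial band
around the majority rate. A length-matched control
(`SimConfig(truncate_skipped=False)`: skip labels kept, every video
watched in full) restores chance-level accuracies for all three
classifiers and both tasks, isolating duration as the sole null signal.
This is a property of range-type features applied to variable-length
trials, not an implementation artifact, and it applies equally to real
deployments of this feature set: part of any skip-prediction accuracy is
the button press itself, not brain state. `scripts/acceptance.py` reports
both the as-designed and the length-matched null accuracies.

## Problem sizes and runtime

Desk-scale defaults are fs = 500 Hz and 20 s videos; fs = 2000 Hz
reproduces the acquisition-rate setting and exercises the downsampling
stage. The validation suite uses 4 subjects × 45 videos for the null and
effect-recovery cohorts and 8 subjects per effect size for the
monotonicity sweep (a standardized-mean-difference comparison needs the
extra precision); the relevance grid in the acceptance script uses 20
holdout repetitions per cell. A full acceptance run is a few minutes on
one CPU; entropy dominates and is linear in the number of epochs.

## Known limitations

* Negative CV2 values are possible for the valence index (see above).
* The Wilcoxon pairing assumes both tasks were evaluated on identical
  splits; with different seeds the test is still valid but less powerful.
* Missing-scale handling (mean over available scales) slightly biases the
  entropy average on epochs where high scales are degenerate.
* EDF storage quantizes amplitudes to 16 bits over the per-channel range;
  round-trip error is bounded by half the quantization step.
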