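# Methods

This note documents the models, rules and numerical choices implemented in
`mvinfo`, the assumptions behind them, and what the synthetic data do and
do not establish.

## Decoding model

The classifier is multi-class LDA over channel patterns at a single time
point. With class means μ_k and a shared covariance Σ, the posterior under
uniform priors is the softmax of −½(x−μ_k)ᵀΣ⁻¹(x−μ_k); this is exactly the
Bayes posterior of the shared-covariance Gaussian model, and the test
suite verifies agreement with a brute-force density-evaluation oracle to
1e-8. Uniform priors are justified because every design is balanced by
stratification before folding (trials are subsampled so each color ×
motion cell has the minimum joint cell count; the subsample is chosen by a
single seeded global ranking so that relabelling classes keeps the same
trials).

Σ is the pooled within-class covariance (denominator n − K) shrunk toward
a scaled identity: Σ = (1−α)S + α(tr S/p)I. The default α = 0.1 keeps the
LDA form while guaranteeing invertibility when channels outnumber trials
(hundreds of sensors) or features are collinear; at α = 0 a numerically
singular S raises with advice to use positive shrinkage (singularity is
detected from the Cholesky pivot ratio at a 1e-6 relative tolerance).

Cross-validation: folds are assigned by a single seeded global permutation
dealt round-robin within each class, making fold membership independent of
how classes are named (confusion tensors are therefore exactly
equivariant under class relabelling). Sensor-style analyses use 10 folds;
short sequence-design sessions use 2 folds with per-fold oversampling that
fills every (stimulus × sequence-position) cell up to the fold's maximum
cell count by resampling with replacement *within the fold only* — the
no-leakage property is tested by decoding pure noise with oversampling
active, which stays at chance. Held-out predicted probabilities are pooled
over folds and then averaged per true class (for balanced folds, pooling
before or after averaging coincides; pooled-then-averaged is implemented).

12-class confusion matrices are regridded to 8 classes by bilinear
interpolation on the (true angle × predicted angle) torus followed by row
renormalization, which restores row-stochasticity exactly; the smooth-
kernel regridding error is a few percent, tested against a kernel oracle.

## Cluster sign-permutation test

Per time point, a one-tailed one-sample t-test over sessions (after
subtracting chance 1/K) at the cluster-forming threshold p < 0.01 defines
contiguous clusters; cluster mass is the sum of t-values (the
field-standard summed statistic — mass is not otherwise defined). The
null multiplies each session's timecourse by a random sign; per
permutation only the maximum cluster mass is kept, and observed clusters
get p = (b+1)/(m+1). Sign symmetry of chance-level information is the only
assumption. A 500-dataset null simulation (8 sessions, Gaussian noise,
1,000 flips) keeps the family-wise error at the nominal level (measured
0.056 with an accepted band of [0.02, 0.075]). Correction across regions
is Bonferroni on cluster p-values.

## Latency rules

Sessions are normalized to map chance to 0 and the post-stimulus peak to
1, and included only when the post-stimulus peak above chance is at least
1.5× the largest *absolute* baseline deviation (t < 0). The peak is the
first post-stimulus local maximum (plateau samples count; boundaries are
one-sided) reaching 75 % of the global post-stimulus maximum, so an early
shoulder below that fraction is skipped while an early qualifying peak
wins over a later, higher one. The latency is the half-peak crossing on
the *rising flank of the chosen peak*: the estimator walks back from the
peak to the last sample below half and interpolates linearly between the
bracketing samples. A forward-from-onset scan would latch onto early
sub-threshold bumps that the 75 % rule deliberately skipped; on monotone
rises both definitions coincide, and on a linear ramp the crossing is
exact (the 0→1 ramp between 100 and 200 ms returns 150 ms exactly). The
10 ms grid makes interpolation necessary: reported latencies (~80–100 ms)
fall between samples.

The group latency is the latency of the session-mean normalized
timecourse, not the mean of per-session latencies — more robust for noisy
single sessions. Bootstrap CIs resample sessions with replacement
(replicates with undefined latency are dropped); group contrasts reshuffle
group labels and recompute both group latencies per permutation, with
permutations yielding undefined latencies counted as extreme
(conservative). Inclusion masks are fixed before permutation, not
recomputed per shuffle.

## RSA

Representation matrices are confusion tensors averaged over 50–250 ms.
Similarity is the Pearson correlation over all K(K−1) off-diagonal cells —
both triangles, since confusions need not be symmetric; only the diagonal
is removed. The permutation null reassigns stimulus labels to rows and
columns of one matrix simultaneously (shuffling one matrix is
statistically equivalent to shuffling both under exchangeability);
p-values are two-sided on |r| with the +1 correction, and permutations are
sampled with replacement so n_perm may exceed K!. Constant off-diagonals
make r undefined and are flagged rather than silently zeroed.

## Tuning and bimodality

Collapsing pools the K wrapped diagonals of the confusion matrix, so total
probability is conserved (offsets × K cells each). The bimodality index
(P180 − mean(P±135)) / (Pmax − Pmin) uses the mean of the two
next-to-opposite offsets (asymmetric confusions are averaged), is affine
invariant by construction, and is defined as 0 for a flat curve. Group
bimodality is a one-sided one-sample t-test against 0; a zero-variance
sample returns p = 1 when the common value is ≤ 0 (no positive evidence).
The similarity-vs-bimodality regression fits pairwise similarity on
|ΔBI| across entity pairs by OLS and reports R² and the slope p; a
constant predictor is flagged degenerate.

Single-channel tuning selects channels by one-way ANOVA (p < 0.05) on
per-trial responses — mean amplitude in a configurable window, default
50–250 ms to match the RSA window, or mean squared amplitude as the
"power" response for LFP-like signals (band and window are otherwise
unspecified, so mean square over the response window is used). Curves are
aligned to the preferred stimulus with ties broken toward the lowest class
angle (determinism).

## Preprocessing

All filters are Butterworth of the stated order applied forward-reverse
(zero-phase; the effective order doubles), via second-order sections with
reflect padding. MUA: band-pass 500–6000 Hz (2nd order), rectification,
low-pass 250 Hz, resample to 1 kHz — the rectified in-band sine recovers
the analytic mean 2a/π. LFP: low-pass 500 Hz plus local bipolar pairs.
Scalp chains: polyphase down-sampling (which includes the anti-alias
low-pass at the new Nyquist, not otherwise specified) and an average
reference that zeroes the instantaneous channel mean. The common analysis
band is 0.1–10 Hz, 4th order, two-pass. Note that a 0.1 Hz corner implies
multi-second edge transients; attenuation tests therefore measure
spectrally in the signal's interior. Epochs are cut on a fixed −250…500 ms
grid at 10 ms steps (76 samples, t = 0 on-grid); overlapping windows from
rapid streams legitimately share samples.

## Synthetic-data generator

The generator produces the statistical structure the analyses assume, not
biophysically detailed signals:

* **Stimuli** — two protocols: 12 classes / 150 ms stimuli / 50 ms ISI /
  sequences of 6, and 8 classes / 100 ms / 20 ms / sequences of 8; labels
  drawn independently and uniformly per event. Angles are in degrees,
  classes at bin centers, circular differences mapped to (−180, 180].
* **Tuning** — unimodal: a von-Mises-shaped bump exp(κ(cos Δ − 1)),
  normalized so the preferred stimulus evokes baseline + amplitude;
  bimodal (axis tuning): the same bump on the doubled angle, exactly
  180°-periodic; untuned: baseline only. Default κ = 2 gives a half-width
  near one 45° class step.
* **Dynamics** — each evoked response is a half-cosine bump sin(πu)
  starting at the population's onset latency. The default width is 40 ms:
  a compact transient that fits the rapid stimulus stream (stimuli every
  120–200 ms) and whose rise completes within two 10 ms grid steps, so the
  half-peak latency of the resulting information timecourse sits within
  one grid step of the onset parameter — which is what makes onset
  recovery by the half-max rule well-posed on this grid.
* **Noise and scale** — additive white Gaussian noise per sample, default
  amplitude 1.0 against noise SD 0.35 for 12-unit populations. This
  yields peak single-trial probabilities of roughly 0.5–0.8 over a 0.125
  chance level: clearly suprathreshold, far from ceiling, and sampled at
  100 Hz directly on the analysis grid.
* **Sensors** — a linear forward model (sources × channels gain, smooth
  Gaussian leadfields along a unit occipito-frontal coordinate) plus
  sensor noise; LCMV unit-gain filters invert it.
* **Eye traces** — vertical position with curvature (second time
  derivative) gain·(L − L_eq), sign-flipped between the two minimum-motion
  conditions, probed at 19 L values around the reference; positional noise
  SD 0.01 units, comparable to video eye-tracker noise relative to the
  drift amplitudes simulated.
* **Luminance confounds** — an optional untuned evoked component scaled by
  stimulus contrast (1.0 at level 1, 0.8 at the 20 %-reduced level 2).

What the generator does *not* emulate: spike trains and refractoriness,
oscillatory or 1/f background activity, correlated noise between channels,
response adaptation across the stimulus sequence, incomplete fixation
sequences, and realistic volume-conduction geometry. Passing tests
therefore establish the correctness and calibration of the analysis
machinery under its own assumptions — not that real recordings satisfy
those assumptions.

## Problem sizes and runtimes

The test suite and acceptance checks run at desk scale: 800–2,000 events
per session, 1–20 channels, 2- or 10-fold CV, 200–2,000 permutations, 500
null datasets for the cluster-test calibration, 20 seeds for latency
recovery and 100 for the equiluminance readout. The full default pipeline
configuration (8 sessions, 2,000 stimuli each) is sized for single-CPU
runs; permutation counts are reducible by a single fast factor without
changing any statistical definition.

## Known limitations

* The searchlight's feature set is the source plus its nearest neighbors
  along a 1-D coordinate (default: the source alone); the spatial extent
  of a realistic searchlight is not modelled.
* The latency permutation test keeps inclusion masks fixed across
  permutations.
* Confusion-tensor storage assumes a uniform circular class grid.
* The luminance half-space analysis uses a single balanced split per axis
  rather than a nested cross-validation in time.
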