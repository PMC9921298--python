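# Methods

This note documents the models, defaults, and numerical choices behind
`stridewarp`, and what the synthetic generator does and does not emulate.

## Stride pipeline

A gait cycle is the half-open interval between two consecutive same-side foot
strikes; strike times map to sample indices by `floor(t * rate)` (with a 1e-9
guard against float round-off on grid-aligned times), so consecutive cycles
tile the recording with no overlap and no gap. The sensor sits on the
prosthetic-side thigh, so prosthetic-side strikes delimit cycles by default;
the side is configurable for control scenarios.

The pipeline order is segment → resample → magnitude: each of the three axes
is linearly interpolated onto L points spanning normalized stride time [0, 1],
and the magnitude sqrt(vx² + vy² + vz²) is taken per normalized sample.
Resampling before the (nonlinear) magnitude differs from the reverse order
only at the level of interpolation error, but one order had to be fixed for
reproducibility. L defaults to 101 — 0–100% of the gait cycle in 1% steps, the
standard convention for gait-cycle normalization. Linear interpolation is the
default because it is monotone, endpoint-preserving, and idempotent at length
L; a cubic-spline option exists behind a flag. No amplitude normalization is
applied: both distance metrics are scale-covariant and the classifier is
invariant under common scaling, so units (deg/s assumed in files) do not
affect decisions. No stride-level outlier rejection is applied by default; a
hook can exclude strides whose duration exceeds a chosen multiple of the
median.

## Distance metrics

* **Normed Euclidean**: sqrt(Σ (xᵢ − yᵢ)² / n), the RMS pointwise error of two
  equal-length strides.
* **DTW**: squared local errors D(i,j) = (xᵢ − yⱼ)², accumulated by
  Θ(i,j) = D(i,j) + min[Θ(i−1,j−1), Θ(i−1,j), Θ(i,j−1)] with Θ(1,1) = D(1,1).
  The returned value is the raw final cost Θ(n,m) — not square-rooted and not
  path-length-normalized — because any strictly monotone transform of the
  distances leaves every nearest-neighbor decision unchanged, and the raw
  accumulated cost is the simplest faithful definition.

The warping window is a Sakoe–Chiba band |i − j| ≤ w, with cells outside the
band treated as +∞; w defaults to ceil(0.10 · L) (11 samples at L = 101), a
standard choice when no empirically tuned value is available, and is exposed
in the configuration. A band too narrow for the length difference
(|n − m| > w) is an error rather than a silent fallback. Useful identities,
all enforced by tests: w = 0 on equal lengths gives exactly
n · euclidean_normed², the cost is non-increasing in w, and the unconstrained
program equals brute-force minimization over all monotone complete warping
paths.

The implementation keeps two rolling rows of Θ and batches the inner loop
across many stride pairs at once (a (pairs, L) vectorized dynamic program), so
a full cross-validation with DTW on ~100 strides per class runs in seconds
without approximations, lower bounds, or early abandoning.

## Classifier

The pairwise distance itself is the lone feature: a held-out stride takes the
majority label of its k nearest training strides. k defaults to 1, following
the nearest-neighbor lineage of this family of methods, and is constrained odd
so two-class votes cannot tie; exact distance ties break toward the lower
training index, making every decision deterministic. An alternative reading of
a distance-based rule — assign to the class with the smaller mean distance —
is available as `rule="mean-distance"` but is not the default.

Class sizes are equalized before cross-validation by truncating the larger
class, keeping the earliest strides (the most rested gait); random subsampling
is available. Folds are stratified and shuffled from an explicit seed (default
17); both classes share one fold permutation, which keeps fold sizes balanced
per class and makes the whole procedure exactly symmetric under a class-label
swap (swapping the training sets swaps the per-class accuracies and maps every
condition fraction f to 1 − f). Each fold holds out 20% of each class; the
report gives per-fold and mean ± SD per-class accuracies, the pooled accuracy,
and the F1 score over pooled held-out predictions with POST_P as the positive
class. MID_P and POST_NP strides are classified against the full equalized
PRE/POST sets (not per-fold models).

The variance summary averages the per-timepoint sample SD (denominator n − 1)
across strides, per condition, over the L timepoints; the F-value is the
larger of the two means over the smaller. It is a dispersion-change summary,
not an ANOVA statistic — where the source material is ambiguous between
averaging SDs and variances, this package averages SDs and labels the output
accordingly.

## Gait parameters and significance

Stance time pairs each strike with the next same-side foot-off; a leading off
is ignored and a trailing strike is skipped with a warning. The symmetry ratio
is prosthetic/non-prosthetic, so values below 1 mean reduced prosthetic-side
stance (the clinically typical deficit). Double support is the total
intersection of the two sides' stance intervals clipped to the cycle, as a
percentage of cycle duration. Step length of a side at its strike is the
forward inter-foot distance at that instant (nearest-sample lookup); the
at-strike convention is applied consistently to both sides. ROM is max − min
of the joint angle within the cycle.

Statistical testing treats strides as observations: conditions are not paired
at stride level, so the omnibus test is a one-way fixed-effects ANOVA across
the four conditions per parameter (at least two conditions with at least three
samples each). Tukey-HSD pairwise comparisons run only when the omnibus test
is significant, and a parameter is flagged changed when the PRE_NP-vs-POST_P
adjusted p-value is below alpha (default 0.05). Overall gait change requires
≥ 50% of testable parameters flagged; untestable parameters (e.g. knee ROM
with a locked prosthetic knee) leave the denominator. Under the global null
the omnibus rejection rate is alpha by construction, while the gated,
multiplicity-adjusted changed flag is deliberately conservative — its null
rate sits well below alpha, which is the cost of Tukey's family-wise error
control and is verified, not assumed, by the calibration tests.

## Synthetic generator

Each stride's magnitude waveform is a baseline (25 deg/s) plus Gaussian bumps
in normalized stride time; the two-bump default (centers 0.28 and 0.72, sigmas
0.10 and 0.07, amplitudes 130 and 260 deg/s) mimics the stance and swing peaks
of a thigh angular-velocity profile. The sum-of-bumps family was chosen over a
harmonic series because each clinically meaningful change (peak height, peak
timing) maps to a single parameter. Gait change is a per-bump
(amplitude, center) offset applied fully to POST_P and scaled by a blend
λ ∈ [0, 1] for MID_P (default 0.5) and POST_NP (default 0.8); the default
offset (+20 and +45 deg/s, +0.02 cycle on the swing peak) puts cross-validated
accuracy in the mid-to-high 90s — clearly separable but not trivially so, the
regime this method is intended for. Stride-to-stride variability combines
per-stride jitter of the bump parameters (SD 10 deg/s amplitude, 0.012 cycle
center, 0.006 width) with isotropic per-axis sensor noise (SD 6 deg/s); a
variance-ratio knob scales both for the shifted class (linearly in λ), so the
mean per-timepoint SD of POST_P is approximately that multiple of PRE_NP's —
with a zero waveform shift, a ratio of 2.13 is recovered within a few percent.

The waveform is decomposed onto fixed unit direction cosines
(0.8, 0.5, 0.33)/‖·‖ so the magnitude reconstructs it exactly before noise.
Stride durations are Normal(1.1 s, 0.05 s) truncated above 0.3 s and quantized
to whole samples at 100 Hz; all emitted events sit exactly on the sample grid.
This quantization is what makes the generator's ground truth exact: stance
times and segmentation boundaries are recovered to float precision, and
nearest-sample position lookups land on stance plateaus, so configured step
lengths are recovered exactly. Stance occupies 0.62 of each cycle and the
contralateral side is offset by 0.5 of the cycle, giving ~24% double support —
ordinary walking physiology; both are configurable, and a configuration with
no double support at all is rejected. One tail pseudo-stride past the final
strike lets both sides close their last stance phase inside the recording.
Joint angles are per-cycle cosines achieving a per-stride ROM drawn around
class-blended means; foot positions advance by class-blended step lengths at
each landing and stay flat through stance. All randomness flows from one root
seed through named substreams (durations, shape, noise, kinematics), so
components can be frozen independently and a fixed seed reproduces a session
bit for bit.

What the generator does *not* emulate: forward dynamics or joint coupling
(angles, positions and the gyro waveform are generated independently given the
blend), soft-tissue artifact, sensor drift or calibration error, turning
strides at walkway ends, fatigue trends within a trial, and specific
amputation etiologies. Passing tests therefore show that the pipeline's logic
and statistics behave correctly under controlled, known-truth conditions —
not that the classifier reaches any particular accuracy on real recordings.

## Problem sizes and numerical choices

The test suite and the acceptance script run sessions of 100–125 strides per
condition (the protocol scale) at L = 101; calibration claims pool 20 seeded
replicates, and the null calibration of the significance machinery uses 100
to 200 replicates of 10 parameters × 4 conditions × 100 samples. Monte-Carlo
assertions use 3-standard-error bands around their analytic targets.
Degenerate inputs fail loudly rather than silently: empty training sets,
mismatched lengths, even k, infeasible DTW bands, single-stride variance
summaries and non-positive stance times all raise with a message naming the
violated contract. File parsing is header-driven, never positional, and a
declared sample rate that disagrees with a file's time column by more than 1%
is an error, not a resample.
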