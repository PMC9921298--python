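# stridewarp

Person-specific classification of gait change from a single thigh-mounted
gyroscope, for researchers and rehabilitation engineers who want to know
whether an individual's walking pattern actually changed over a gait-training
session — without a lab full of cameras.

## The problem and the method

During physiotherapy-led gait training (e.g. for lower-limb prosthesis users),
a clinician needs an objective signal that the participant's gait before the
session (PRE-NP) differs from their gait after it (POST-P), and how the
mid-session (MID-P) and post-rest (POST-NP) trials relate to those two states.
`stridewarp` implements a stride-based time-series approach:

1. **Segmentation.** The tri-axial angular velocity recording is cut into gait
   cycles at consecutive same-side foot strikes, using a foot-contact event
   table.
2. **Time normalization.** Each axis of each stride is resampled to a fixed
   length *L* (default 101 points, 0–100% of the gait cycle), removing cadence
   differences so only the waveform shape matters.
3. **Magnitude.** The three axes collapse to one signal per stride,
   |v| = sqrt(v_x² + v_y² + v_z²).
4. **Distance.** Strides are compared with either the normed Euclidean
   distance ‖x − y‖ = sqrt(Σᵢ (xᵢ − yᵢ)² / n) (the RMS error) or dynamic time
   warping with squared local errors,
   Θ(i,j) = D(i,j) + min[Θ(i−1,j−1), Θ(i−1,j), Θ(i,j−1)],
   under a fixed Sakoe–Chiba window (default 10% of *L*); the accumulated cost
   Θ(n,m) is the distance.
5. **Classification.** The pairwise distance is the lone feature of a
   k-nearest-neighbor classifier (default k = 1). Class sizes are equalized,
   and five-fold cross-validation (20% held out per fold) yields per-class
   accuracies and an F1 score (POST-P positive). MID-P and POST-NP strides are
   then classified against the full trained classes, giving the fraction
   assigned to each state.
6. **Validation.** Ten common gait parameters (stance times, stance-time
   symmetry ratio, double-support %, step lengths, knee/hip flexion–extension
   ROM) are computed per stride; a one-way ANOVA across the four conditions
   with Tukey-HSD post hoc decides which parameters changed, and gait is
   declared changed overall when ≥ 50% of testable parameters did. A variance
   summary (mean per-timepoint stride SD per condition and their
   larger/smaller F-ratio) flags unequal stride dispersion, a known failure
   mode for kNN on overlapping classes.

Because recordings of this kind are rarely shareable, the package ships a
first-class synthetic session generator (`synthetic_gait`) that emulates the
full four-condition protocol — 100–125 strides per condition at 100 Hz, a
controllable PRE→POST waveform shift, blendable intermediate conditions, a
dispersion-ratio knob, and a no-change control scenario — with complete ground
truth for every generated quantity.

## Worked example

```python
from stridewarp import (
    Condition, DTWConfig, Side, SynthSessionConfig, build_stride_set,
    classify_condition, cross_validate, default_window, generate_session,
    variance_summary,
)

session = generate_session(SynthSessionConfig(seed=42))
sets = {
    cond: build_stride_set(session.recordings[cond], session.events[cond],
                           Side.PRO, L=101)
    for cond in Condition
}

dtw = DTWConfig(window=default_window(101))
result = cross_validate(sets[Condition.PRE_NP], sets[Condition.POST_P],
                        metric="dtw", dtw_config=dtw, k=1, seed=17)
print(f"PRE-NP accuracy: {result.mean_accuracy_pre:.4f} +/- {result.sd_accuracy_pre:.4f}")
print(f"POST-P accuracy: {result.mean_accuracy_post:.4f} +/- {result.sd_accuracy_post:.4f}")
print(f"F1 (POST-P positive): {result.f1:.4f}")

frac_pre, frac_post = classify_condition(
    sets[Condition.MID_P], sets[Condition.PRE_NP], sets[Condition.POST_P],
    metric="dtw", dtw_config=dtw)
print(f"MID-P classified PRE-NP: {frac_pre:.3f}, POST-P: {frac_post:.3f}")

vs = variance_summary(sets[Condition.PRE_NP], sets[Condition.POST_P])
print(f"F-value: {vs.f_value:.4f}")
```

prints

```
PRE-NP accuracy: 1.0000 +/- 0.0000
POST-P accuracy: 0.9735 +/- 0.0391
F1 (POST-P positive): 0.9864
MID-P classified PRE-NP: 0.553, POST-P: 0.447
F-value: 1.0866
```

Read: the classifier separates pre- from post-training strides almost
perfectly (fold-mean accuracies 1.00 and 0.97, F1 0.99), the mid-session
trial — generated halfway between the two gait states (blend 0.5) — splits
roughly 50/50 between them, and stride-to-stride dispersion is similar in the
two trials (F close to 1).

The same pipeline is available from the shell:

```bash
stridewarp simulate --outdir sim/ --seed 42
stridewarp report --indir sim/ --outdir out/          # full session report
stridewarp classify --pre-gyro sim/gyro_pre_np.csv --pre-events sim/events_pre_np.csv \
    --post-gyro sim/gyro_post_p.csv --post-events sim/events_post_p.csv \
    --metric dtw --out result.json
```

`report` writes `classification.json`, `variance.json`, `significance.json`
and `magnitude_curves.csv` (per-condition mean ± SD magnitude profiles).

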