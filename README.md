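# gaitdtw

Template-based detection of gait events from a single-axis foot-worn
gyrometer, with Dynamic Time Warping (DTW) boundary refinement.

## The problem

Clinical gait analysis needs the start and end of every stance phase —
the Initial Contact (IC, heel strike) and Final Contact (FC, toe off) —
from wearable-sensor recordings. Healthy steps share a common waveform
on the sagittal (y-axis) angular-velocity channel, but they differ in
duration, amplitude and, crucially, in *non-linear* internal timing: the
phases between heel strike, foot flat, heel off and toe off stretch and
shrink independently across subjects and walking speeds. A detector
built around a single prototype step must therefore tolerate non-linear
time deformation. `gaitdtw` is for researchers in wearable-sensor gait
analysis who want such a detector, its template-learning strategies, and
a fully annotated synthetic test bed, as an importable Python library
(with a thin `gaitdtw` CLI for shell use).

## The method

**Detection.** A library of stance templates slides along the signal
`x`; a Pearson correlation is computed at every position, and local
maxima above a threshold become candidate steps, accepted greedily by
decreasing correlation under a hard non-overlap rule. Each accepted
detection `[t_IC, t_FC]` has its template's length.

**Refinement.** Around each detection, all lags
`(k, l) ∈ [-z, z]²` are scanned and the refined boundaries are

    (k*, l*) = argmin_(k,l) DTW(x[t_IC + k : t_FC + l], p)

with `t_IC* = t_IC + k*`, `t_FC* = t_FC + l*`, where `p` is the matched
template. The DTW distance is the minimum cumulative cost over
boundary-anchored, monotone, unit-step warping paths restricted to a
Sakoe–Chiba-style band `|j − i| ≤ maxsamp`, with the pointwise cost

    d(u_i, v_j) = ((u_i − ū)/σ_u − (v_j − v̄)/σ_v)²

so amplitude scale and offset are free. Defaults: `z = 10`,
`maxsamp = 20`, threshold 0.7, 100 Hz sampling.

**Template strategies.** S1 random step(s) from a training set; S2 the
DTW medoid (minimum summed DTW distance to all training steps); S3
linear fusion (z-normalise, linearly resample to the median length,
average); S4 non-linear fusion (DTW-align all steps onto a median-length
calibration step, average); S5 an analytic piecewise-affine idealised
step of 63 samples encoding the stance-phase shape between gait events.

**Evaluation.** A detection is correct when the midpoint of its
boundaries lies inside an annotated step (one-to-one); precision,
recall, and per-step absolute timing errors ΔStart, ΔEnd, ΔDuration in
milliseconds are reported.

Because real annotated cohorts of this kind are not redistributable, the
package ships a synthetic-data module generating annotated trials with
the same structure (warped, rescaled, noisy instances of a prototype
step separated by quiescent swing segments) and exact ground truth.

## Worked example

```python
from gaitdtw import (DetectorConfig, SynthParams, build_library,
                     detect_and_refine, evaluate_cohort, synth_cohort)

cohort = synth_cohort(SynthParams(seed=123))     # 20 trials x 8 steps
library = build_library("S5")                    # analytic template
config = DetectorConfig()                        # z=10, maxsamp=20
per_trial = [(detect_and_refine(sig, library, config, "dtw"), anns)
             for sig, anns in cohort.trials]
print(evaluate_cohort(per_trial, 100.0).summary())
```

prints

```
{'precision': 1.0, 'recall': 1.0, 'n_detected': 160, 'n_annotated': 160,
 'n_correct': 160,
 'delta_start_ms': {'mean': 0.375, 'sd': 1.899...},
 'delta_end_ms': {'mean': 2.625, 'sd': 5.182...},
 'delta_duration_ms': {'mean': 3.0, 'sd': 5.338...}}
```

every one of the 160 synthetic stance phases is found (precision and
recall 1.0) and the refined IC boundaries are on average 0.375 ms
(under a twentieth of a sample) from the ground truth. The scripts in
`examples/` walk through each capability — DTW alignment, template
building, detection + refinement, evaluation, and the experiment
protocols — and print a line explaining each number.

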