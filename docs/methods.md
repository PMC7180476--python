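# Methods

This note documents the model, the numerical choices, and what the
synthetic test bed does and does not show. It states no result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Signal model and conventions

A trial is a single-channel angular-velocity series (y-axis gyrometer of
a foot-mounted inertial unit, nominally 100 Hz). Indices are 0-based; a
stance interval `[ic, fc]` is inclusive at both ends, so its duration is
`fc − ic + 1` samples; milliseconds are `samples × 1000 / rate` (10 ms
per sample at 100 Hz). Only the stance (support) phase is modelled — the
detector's "step" is the IC→FC interval; swing is treated as quiescent
background.

## Banded DTW

The alignment engine computes the classic dynamic program over unit
steps (1,0), (0,1), (1,1), unweighted, with boundary anchoring and a
Sakoe–Chiba-style band. Choices that were genuinely open:

- **Pointwise distance.** `d(u_i, v_j) = (zu_i − zv_j)²` where `zu, zv`
  are the whole input series z-normalised once (population divisor N).
  Per-series normalisation makes the distance invariant to positive
  affine rescaling of either input; it is *not* re-computed per window
  pair inside the refinement scan beyond each candidate window being a
  series in its own right.
- **Band strictness.** The band is non-strict, `|j − i| ≤ maxsamp`. A
  strict inequality would make the extreme refinement lags
  `(k, l) = (−z, +z)` infeasible at the defaults `z = 10, maxsamp = 20`
  (window vs template length difference exactly 20), silently shrinking
  the scan; the non-strict band keeps all `(2z+1)²` lags valid.
- **Cost normalisation.** The distance is the plain cumulative sum, not
  divided by path length. Consequence: in the refinement scan, shorter
  windows sum fewer terms and are slightly favoured, a bias the
  evaluation quantifies rather than hides (ΔEnd is the metric most
  affected). The signed-error diagnostics in `EvalReport` make this
  visible.
- **Tie-breaking.** Equal-cost predecessors resolve diagonal, then
  vertical, then horizontal, so the reported path is unique and tests
  are reproducible. Multiple globally optimal paths of equal cost are
  possible; only the path (not the distance) depends on this rule.
- **Degenerate inputs.** Constant series (σ = 0) and length-1 series are
  rejected with `DegenerateSeriesError`; a band narrower than the length
  difference raises `BandInfeasibleError`, distinguishable from all
  other failures.

The DP kernel is compiled with numba; `dtw_bruteforce` is a deliberately
memoisation-free exhaustive path enumeration (lengths ≤ 10) kept as the
independent oracle the test suite compares against.

## Detection and refinement

The greedy matcher pools, across all templates, the local maxima
(strictly greater than both neighbours) of the sliding Pearson profile
that exceed `correlation_threshold` (default 0.7 — the matching stage's
only free parameter; published descriptions of this matcher leave it
unstated), visits them by decreasing correlation and accepts a candidate
only if its window overlaps no earlier acceptance. Zero-variance windows
get correlation 0 and a warning.

Refinement scans all lags `(k, l) ∈ [−z, z]²`. Lags whose window leaves
the signal or is shorter than 2 samples are skipped, not clamped
(clamping would silently change the window length); lags whose window
length differs from the template's by more than the band are likewise
skipped. Argmin ties prefer the least perturbation (`|k| + |l|`, then
lexicographic), so refinement of an already-perfect detection leaves it
in place. The refined FC is `t_FC + l*` (the second lag of the
minimisation). Non-overlap is *not* re-enforced after refinement;
overlapping refined pairs are counted and logged. The Pearson-criterion
variant runs the same scan but maximises the correlation after linearly
resampling each window to the template length — by construction it can
only model linear time rescaling, which is exactly the contrast the E4
experiment probes.

## Template strategies

- **S2 medoid** includes each candidate's zero self-distance in the sum
  (a harmless constant) and breaks ties towards the lowest step id, so
  the result is independent of collection order. Raw (unnormalised)
  samples are stored for S1/S2: detection correlation is scale-invariant
  and the DTW distance z-normalises internally, so normalising first
  would change nothing downstream.
- **S3** z-normalises, linearly resamples to the collection's median
  length (endpoints to endpoints, interior by linear interpolation) and
  averages. For an even step count the lower-middle length is the
  median. An averaged template that comes out constant (e.g. mirror
  image steps) is rejected as degenerate rather than silently used.
- **S4** picks its calibration step among steps of exactly the median
  length by the medoid rule; when a collection has no step of exactly
  that length (possible on small synthetic collections), it falls back
  to the closest length, tie to the shorter. Alignment averages, for
  each calibration sample, all step samples matched to it on the unique
  optimal path under the tie-break above.
- **S5** evaluates the piecewise-affine idealised stance waveform at
  integer abscissae 1..63 (its interval ends overlap at the five
  interior breakpoints, where the function is continuous, so
  first-matching-interval evaluation is unambiguous). The amplitudes
  are dimensionless post-normalisation values — scale is irrelevant to
  both matching and DTW. Other lengths evaluate the function on a
  uniformly rescaled abscissa; fewer than 6 samples (one per breakpoint)
  is rejected.

## Evaluation

"Inside" is inclusive of both annotation endpoints and midpoints are
compared as reals (half-integer midpoints are legal), avoiding parity
artefacts. When several detections land in one annotation the
midpoint-closest one survives, tie to the earlier detection; the recall
side applies the symmetric rule with annotations and detections
swapped. Δ metrics are reported as mean (SD) of *absolute* errors in
ms; signed errors are kept alongside for bias diagnostics. Precision is
undefined (None) with no detections, recall with no annotations.

## Synthetic cohorts

The generator emulates the structure the detector assumes: trials of 8
stances (near the reference population's 7.5/trial mean) at 100 Hz;
stance lengths uniform on `median ± spread` (median 63 samples, the
reference population's median stance duration); within-step monotone
random warps with deviation from the diagonal bounded by
`warp_intensity` (default 8, inside the downstream band of 20); per-step
amplitude scale, offset, and white noise (`noise_sd` is in prototype
units; the prototype spans about 3.4 units, so the default 0.05 is a
low-noise regime); smooth low-variance swing segments of 35–50 samples
between stances, making stance roughly 60% of a cycle; and per-subject
stance-duration offsets and amplitude factors for between-subject
variability. Defaults were fixed once from these considerations.

The warp map is a random monotone lattice path: increments in {0, 1}
when the output is at least as long as the prototype (surjective — every
prototype sample is used), and {1, 2} when shorter (some prototype
samples are skipped; a surjective unit-step map cannot shrink). When the
drawn length equals the prototype's, the constraints force the identity,
so equal-length steps differ from the prototype only by scale, offset
and noise — and their noiseless DTW distance is exactly zero. For
warped lengths the distance is merely *near* zero: resampling changes
the step's own mean and standard deviation, so the z-normalised values
on the generating alignment differ slightly. The test suite asserts
exact zero for the identity case and a small bound otherwise.

What passing tests on this generator shows: the pipeline recovers
boundaries whose deformation model (bounded monotone warp + affine
amplitude + white noise) matches its assumptions, at the configured
sizes. What it does not show: robustness to real-world artefacts the
generator omits — sensor drift and baseline wander, U-turns, step
asymmetry between feet, pathological gait, annotation error in the
ground truth, and swing-phase dynamics (swing is noise here, so the
false-positive behaviour on structured swing movement is untested).

## Experiment protocols and sizes

The four runners mirror the published protocol at reduced scale, chosen
so the full suite runs comfortably on one CPU: the refinement experiment
uses 12 trials × 8 steps with 5 random-template simulations (training
trials held out of the test set, per-step errors concatenated across
simulations); the strategy comparison 5–20 trials; the z-sweep 3–5
trials over z = 0..20; the criterion comparison 8 trials with both
refinements applied to the *same* initial detections and differences
paired per annotated step. Error magnitudes on synthetic cohorts are
generator-specific; the protocols assert directions and bounds
(refinement reduces errors; DTW ≤ Pearson under non-linear warps;
indistinguishable under purely linear rescaling — operationalised as a
paired t-test at the 1% level plus a one-sample mean bound), not
published magnitudes, which depend on the original 13-subject,
7414-step instrumented-walkway database that is not redistributable.

## Known limitations

- The cumulative (unnormalised) DTW cost biases refinement towards
  slightly shorter windows; see above.
- The greedy matcher's threshold (0.7) is a free parameter; very noisy
  or low-amplitude steps can fall below it and are then invisible to
  refinement.
- Detections may overlap after refinement; downstream consumers needing
  disjoint intervals must resolve overlaps themselves (the count is
  logged).
- `maxsamp` must be at least `2z` for the full scan to be feasible;
  the configuration warns otherwise and infeasible lags are skipped.
- The evaluation's duplicate-resolution rule (midpoint-closest, tie to
  earlier) is one of several defensible readings of "all but one are
  false"; with accurate detectors the choice is immaterial.
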