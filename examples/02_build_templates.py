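"""Build a step template by each of the five library strategies.

Steps are cut from a synthetic annotated cohort; S1 picks random steps,
S2 the DTW medoid, S3/S4 fuse all steps linearly / non-linearly, and S5
is the analytic piecewise-affine step (no training data needed).
"""

from gaitdtw import (
    SynthParams,
    build_library,
    extract_steps,
    median_length,
    merge_collections,
    synth_cohort,
)

cohort = synth_cohort(SynthParams(n_trials=5, seed=42))
collection = merge_collections(
    [extract_steps(sig, anns) for sig, anns in cohort.trials]
)
print(f"{len(collection)} training steps, median length {median_length(collection)} samples")

for strategy in ("S1", "S2", "S3", "S4", "S5"):
    library = build_library(strategy, collection, n=1, seed=7)
    t = library.templates[0]
    print(f"{strategy}: {len(t):3d} samples  source={t.source}")
# S3/S4/S5 always have the median length; S1/S2 keep the raw length of the
# step they select.
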