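"""Scaled-down experiment protocols over synthetic cohorts.

Four experiments probe the method:

E1  effect of the DTW refinement for random-template libraries (one and
    ten templates), averaged over independent template draws with the
    training steps' trials excluded from the test set;
E2  comparison of the learned/analytic single-template strategies
    (S2, S3, S4, S5), all with DTW refinement;
E3  sensitivity of the timing errors to the scan half-width z;
E4  DTW versus Pearson refinement on the same initial detections,
    reported as paired per-step error differences.

Observed error magnitudes depend on the cohort at hand; the experiments
are about directions and trends, not absolute numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .core import DetectorConfig, Detection, StepAnnotation, TemplateLibrary
from .detector import detect_and_refine, detect_steps, refine_detection_dtw, refine_detection_pearson
from .errors import ValidationError
from .evaluation import evaluate_cohort, match_detections, timing_errors
from .synthetic import SynthCohort
from .templates import StepCollection, build_library, merge_collections, extract_steps

__all__ = ["ExperimentSpec", "run_experiment_1", "run_experiment_2",
           "run_experiment_3", "run_experiment_4", "run_experiment"]


@dataclass
class ExperimentSpec:
    """Protocol parameters shared by the experiment runners."""

    experiment: str = "E1"
    strategies: tuple[str, ...] = ("S2", "S3", "S4", "S5")
    library_sizes: tuple[int, ...] = (1, 10)
    z_values: tuple[int, ...] = tuple(range(0, 21))
    n_simulations: int = 20
    seed: int = 0
    config: DetectorConfig = field(default_factory=DetectorConfig)

    def __post_init__(self) -> None:
        if self.experiment not in ("E1", "E2", "E3", "E4"):
            raise ValidationError(f"unknown experiment {self.experiment!r}")
        if self.n_simulations < 1:
            raise ValidationError("n_simulations must be >= 1")


def _cohort_steps(cohort: SynthCohort) -> tuple[StepCollection, dict[str, int]]:
    """All annotated steps pooled, plus a step-id -> trial-index map."""
    collections = []
    owner: dict[str, int] = {}
    for ti, (signal, anns) in enumerate(cohort.trials):
        c = extract_steps(signal, anns)
        collections.append(c)
        for sid in c.ids:
            owner[sid] = ti
    return merge_collections(collections), owner


def _provenance(spec: ExperimentSpec, cohort: SynthCohort, **extra) -> dict:
    return {
        "experiment": spec.experiment,
        "seed": spec.seed,
        "config": {
            "correlation_threshold": spec.config.correlation_threshold,
            "z": spec.config.z,
            "maxsamp": spec.config.maxsamp,
        },
        "cohort": {"n_trials": len(cohort), "n_steps": cohort.n_steps,
                   "manifest_seed": cohort.manifest.get("seed")},
        **extra,
    }


def run_experiment_1(cohort: SynthCohort, spec: ExperimentSpec) -> dict:
    """Random-template strategies with and without DTW refinement.

    For each library size, n_simulations independent draws are made; the
    trials contributing a training step are held out of the test set,
    and per-step errors are concatenated across simulations.
    """
    collection, owner = _cohort_steps(cohort)
    rate = cohort.trials[0][0].sampling_rate_hz
    report: dict = _provenance(spec, cohort, n_simulations=spec.n_simulations)
    for n_templates in spec.library_sizes:
        rows = {}
        for criterion in ("none", "dtw"):
            per_trial: list[tuple[Sequence[Detection], Sequence[StepAnnotation]]] = []
            for sim in range(spec.n_simulations):
                library = build_library("S1", collection, n=n_templates,
                                        seed=spec.seed * 10007 + sim, maxsamp=spec.config.maxsamp)
                train_trials = {owner[t.source] for t in library}
                test = [trial for ti, trial in enumerate(cohort.trials) if ti not in train_trials]
                if not test:
                    raise ValidationError(
                        f"experiment 1: all {len(cohort)} trials used for training "
                        f"with library size {n_templates}"
                    )
                for signal, anns in test:
                    dets = detect_and_refine(signal, library, spec.config, criterion)
                    per_trial.append((dets, anns))
            rows["no_refinement" if criterion == "none" else "dtw"] = (
                evaluate_cohort(per_trial, rate).summary()
            )
        report[f"S1-{n_templates}"] = rows
    return report


def run_experiment_2(cohort: SynthCohort, spec: ExperimentSpec) -> dict:
    """One row per single-template strategy (S2/S3/S4/S5), DTW refinement."""
    collection, _ = _cohort_steps(cohort)
    rate = cohort.trials[0][0].sampling_rate_hz
    report = _provenance(spec, cohort, strategies=list(spec.strategies))
    for strategy in spec.strategies:
        library = build_library(strategy, collection, maxsamp=spec.config.maxsamp, seed=spec.seed)
        per_trial = [
            (detect_and_refine(signal, library, spec.config, "dtw"), anns)
            for signal, anns in cohort.trials
        ]
        report[strategy] = evaluate_cohort(per_trial, rate).summary()
    return report


def run_experiment_3(cohort: SynthCohort, spec: ExperimentSpec,
                     library: Optional[TemplateLibrary] = None) -> dict:
    """Timing errors versus the scan half-width z, for the S5 template.

    Initial detections are computed once per trial; each z value re-runs
    only the refinement. z = 0 reproduces the unrefined errors.
    """
    if library is None:
        library = build_library("S5")
    rate = cohort.trials[0][0].sampling_rate_hz
    initial = [(detect_steps(signal, library, spec.config), anns)
               for signal, anns in cohort.trials]
    curve = []
    for z in spec.z_values:
        cfg = replace(spec.config, z=int(z))
        per_trial = []
        for (signal, _), (dets, anns) in zip(cohort.trials, initial):
            refined = [refine_detection_dtw(signal, d, library.get(d.template_id), cfg)
                       for d in dets]
            per_trial.append((refined, anns))
        summary = evaluate_cohort(per_trial, rate).summary()
        summary["z"] = int(z)
        curve.append(summary)
    report = _provenance(spec, cohort, z_values=[int(z) for z in spec.z_values])
    report["curve"] = curve
    return report


def run_experiment_4(cohort: SynthCohort, spec: ExperimentSpec,
                     library: Optional[TemplateLibrary] = None) -> dict:
    """DTW versus Pearson refinement on identical initial detections.

    Per-step pairing joins the two refined matchings on the annotation id,
    so every difference compares the two criteria on the same true step.
    """
    if library is None:
        library = build_library("S5")
    rate = cohort.trials[0][0].sampling_rate_hz
    per_trial_dtw, per_trial_pea = [], []
    paired: dict[str, dict] = {}
    for signal, anns in cohort.trials:
        dets = detect_steps(signal, library, spec.config)
        ref_d = [refine_detection_dtw(signal, d, library.get(d.template_id), spec.config)
                 for d in dets]
        ref_p = [refine_detection_pearson(signal, d, library.get(d.template_id), spec.config)
                 for d in dets]
        per_trial_dtw.append((ref_d, anns))
        per_trial_pea.append((ref_p, anns))
        for tag, refined in (("dtw", ref_d), ("pearson", ref_p)):
            matching = match_detections(refined, anns)
            errs = timing_errors(matching, rate)
            for (d, a), ds, de, du in zip(matching.pairs, errs["delta_start_ms"],
                                          errs["delta_end_ms"], errs["delta_duration_ms"]):
                paired.setdefault(a.step_id, {})[tag] = (float(ds), float(de), float(du))
    both = {k: v for k, v in paired.items() if "dtw" in v and "pearson" in v}
    diffs = {
        "delta_start_ms": sorted(v["dtw"][0] - v["pearson"][0] for v in both.values()),
        "delta_end_ms": sorted(v["dtw"][1] - v["pearson"][1] for v in both.values()),
        "delta_duration_ms": sorted(v["dtw"][2] - v["pearson"][2] for v in both.values()),
    }
    report = _provenance(spec, cohort, n_paired_steps=len(both))
    report["dtw"] = evaluate_cohort(per_trial_dtw, rate).summary()
    report["pearson"] = evaluate_cohort(per_trial_pea, rate).summary()
    report["paired_differences_sorted"] = diffs
    return report


def run_experiment(cohort: SynthCohort, spec: ExperimentSpec) -> dict:
    runner = {"E1": run_experiment_1, "E2": run_experiment_2,
              "E3": run_experiment_3, "E4": run_experiment_4}[spec.experiment]
    return runner(cohort, spec)
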