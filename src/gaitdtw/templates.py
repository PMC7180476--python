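"""Construction of the step-template library.

Five strategies build prototype stance waveforms from an annotated step
collection:

S1  random selection of one or more training steps;
S2  the DTW medoid — the step minimising the summed DTW distance to all
    steps in the collection;
S3  linear fusion — z-normalise every step, linearly resample to the
    collection's median length, average sample-wise;
S4  non-linear fusion — z-normalise, pick a median-length calibration
    step by the medoid rule, re-align every step onto it along the
    optimal DTW path (each calibration sample receives the mean of the
    step samples matched to it), then average;
S5  a knowledge-based piecewise-affine idealised step, encoding the
    angular-velocity shape of the stance phase (heel-strike transient,
    foot-flat plateau, pre-swing negative swing) with affine segments
    between gait events.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np

from .core import GaitSignal, StepAnnotation, StepCollection, Template, TemplateLibrary
from .dtw import dtw, dtw_distance, znorm
from .errors import BandInfeasibleError, DegenerateSeriesError, ValidationError

__all__ = [
    "extract_steps",
    "median_length",
    "strategy_random",
    "strategy_dtw_medoid",
    "strategy_linear_fusion",
    "align_to_calibration",
    "strategy_nonlinear_fusion",
    "strategy_piecewise",
    "piecewise_step_function",
    "pairwise_dtw_matrix",
    "build_library",
]


def extract_steps(signal: GaitSignal, annotations: Sequence[StepAnnotation]) -> StepCollection:
    """Cut the annotated stance waveforms [ic, fc] (inclusive) out of a signal."""
    steps, ids = [], []
    for k, a in enumerate(annotations):
        steps.append(np.array(signal.samples[a.ic : a.fc + 1]))
        ids.append(a.step_id or f"{signal.trial_id or 'trial'}:{k}")
    return StepCollection(steps=steps, ids=ids)


def merge_collections(collections: Sequence[StepCollection]) -> StepCollection:
    steps, ids = [], []
    for c in collections:
        steps.extend(c.steps)
        ids.extend(c.ids)
    return StepCollection(steps=steps, ids=ids)


def median_length(collection: StepCollection) -> int:
    """Median step length; for an even count, the lower middle value."""
    if len(collection) == 0:
        raise ValidationError("median_length: empty collection")
    lengths = sorted(s.size for s in collection.steps)
    return int(lengths[(len(lengths) - 1) // 2])


def strategy_random(collection: StepCollection, n: int, seed: int) -> TemplateLibrary:
    """S1: n distinct training steps drawn uniformly without replacement.

    The selected step ids are recorded as each template's source so the
    caller can exclude those steps (or their trials) from test data.
    """
    if not 1 <= n <= len(collection):
        raise ValidationError(f"strategy_random: n = {n} not in [1, {len(collection)}]")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(collection), size=n, replace=False)
    templates = [
        Template(
            samples=collection.steps[i],
            strategy="S1",
            source=collection.ids[i],
            template_id=f"S1:{collection.ids[i]}",
        )
        for i in chosen
    ]
    return TemplateLibrary(templates=templates)


def pairwise_dtw_matrix(collection: StepCollection, maxsamp: Union[int, None] = 20) -> np.ndarray:
    """Symmetric matrix of pairwise DTW distances (zero diagonal)."""
    n = len(collection)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                mat[i, j] = mat[j, i] = dtw_distance(collection.steps[i], collection.steps[j], maxsamp)
            except BandInfeasibleError as exc:
                raise BandInfeasibleError(
                    f"steps {collection.ids[i]!r} (len {collection.steps[i].size}) and "
                    f"{collection.ids[j]!r} (len {collection.steps[j].size}): {exc}"
                ) from exc
    return mat


def strategy_dtw_medoid(collection: StepCollection, maxsamp: Union[int, None] = 20) -> Template:
    """S2: the step with minimum summed DTW distance to every step.

    The sum includes the candidate's own zero self-distance; ties are
    broken towards the lowest step id so the medoid does not depend on
    collection order.
    """
    if len(collection) == 0:
        raise ValidationError("strategy_dtw_medoid: empty collection")
    sums = pairwise_dtw_matrix(collection, maxsamp).sum(axis=1)
    best = min(range(len(collection)), key=lambda i: (sums[i], collection.ids[i]))
    return Template(
        samples=collection.steps[best],
        strategy="S2",
        source=collection.ids[best],
        template_id=f"S2:{collection.ids[best]}",
    )


def resample_linear(x: np.ndarray, n_out: int) -> np.ndarray:
    """Linear resampling on a uniform grid; endpoints map to endpoints."""
    if n_out < 2:
        raise ValidationError(f"resample_linear: n_out = {n_out} < 2")
    x = np.asarray(x, dtype=float)
    return np.interp(np.linspace(0.0, 1.0, n_out), np.linspace(0.0, 1.0, x.size), x)


def strategy_linear_fusion(collection: StepCollection) -> Template:
    """S3: z-normalise, linearly resample to the median length, average."""
    if len(collection) == 0:
        raise ValidationError("strategy_linear_fusion: empty collection")
    target = median_length(collection)
    stack = np.stack([resample_linear(znorm(s), target) for s in collection.steps])
    mean = stack.mean(axis=0)
    if float(np.std(mean)) == 0.0:
        raise DegenerateSeriesError(
            "strategy_linear_fusion: averaged template is constant (steps cancelled out)"
        )
    return Template(samples=mean, strategy="S3", source=f"linear-fusion-of-{len(collection)}",
                    template_id="S3:fusion")


def align_to_calibration(
    step: Sequence[float], calibration: Sequence[float], maxsamp: Union[int, None] = 20
) -> np.ndarray:
    """Non-linear time renormalisation of a step onto a calibration step.

    Computes the optimal DTW path between the calibration (index i) and
    the step (index j); output sample i is the arithmetic mean of all
    step samples matched with calibration sample i. The result has the
    calibration's length.
    """
    step = np.asarray(step, dtype=float)
    calibration = np.asarray(calibration, dtype=float)
    res = dtw(calibration, step, maxsamp)
    out = np.zeros(calibration.size)
    counts = np.zeros(calibration.size)
    for i, j in res.path.pairs:
        out[i] += step[j]
        counts[i] += 1
    return out / counts


def _calibration_index(collection: StepCollection, normed: list[np.ndarray], maxsamp) -> int:
    """Pick the S4 calibration step: median length, then medoid rule.

    When no step has exactly the median length, fall back to the steps
    whose length is closest to it (tie towards the shorter).
    """
    target = median_length(collection)
    lengths = np.array([s.size for s in collection.steps])
    candidates = np.flatnonzero(lengths == target)
    if candidates.size == 0:
        gap = np.abs(lengths - target)
        best_gap = gap.min()
        candidates = np.flatnonzero(gap == best_gap)
        shortest = lengths[candidates].min()
        candidates = candidates[lengths[candidates] == shortest]
    def mean_dist(i: int) -> float:
        return float(np.mean([dtw_distance(normed[i], s, maxsamp) for s in normed]))
    return min(candidates, key=lambda i: (mean_dist(int(i)), collection.ids[int(i)]))


def strategy_nonlinear_fusion(collection: StepCollection, maxsamp: Union[int, None] = 20) -> Template:
    """S4: DTW-align all z-normalised steps onto a calibration step, average."""
    if len(collection) == 0:
        raise ValidationError("strategy_nonlinear_fusion: empty collection")
    normed = [znorm(s) for s in collection.steps]
    ci = _calibration_index(collection, normed, maxsamp)
    calibration = normed[ci]
    try:
        aligned = np.stack([align_to_calibration(s, calibration, maxsamp) for s in normed])
    except BandInfeasibleError as exc:
        raise BandInfeasibleError(f"strategy_nonlinear_fusion: {exc}") from exc
    mean = aligned.mean(axis=0)
    if float(np.std(mean)) == 0.0:
        raise DegenerateSeriesError("strategy_nonlinear_fusion: averaged template is constant")
    return Template(
        samples=mean,
        strategy="S4",
        source=f"nonlinear-fusion-of-{len(collection)}-cal-{collection.ids[int(ci)]}",
        template_id="S4:fusion",
    )


# Affine branches (lo, hi, slope, intercept) of the idealised stance
# waveform, on the abscissa x in [1, 63]. Evaluation uses the first
# matching interval; the function is continuous at every interior
# breakpoint, so the overlap at interval ends is unambiguous.
_PIECEWISE_BRANCHES: tuple[tuple[float, float, float, float], ...] = (
    (1.0, 3.0, 0.3, -0.7),
    (3.0, 5.0, -0.8, 2.6),
    (5.0, 16.0, 0.2, -2.4),
    (16.0, 44.0, 0.0, 0.8),
    (44.0, 54.0, -0.34, 15.76),
    (54.0, 63.0, 0.2, -13.4),
)


def piecewise_step_function(x: float) -> float:
    """The piecewise-affine idealised stance waveform f(x), x in [1, 63]."""
    for lo, hi, slope, intercept in _PIECEWISE_BRANCHES:
        if lo <= x <= hi:
            return slope * x + intercept
    raise ValidationError(f"piecewise_step_function: x = {x} outside [1, 63]")


def strategy_piecewise(n_samples: int = 63) -> Template:
    """S5: the analytic piecewise-affine template.

    At the default length of 63 samples (the median stance duration of
    the population the model describes) f is evaluated at integer
    x = 1..63; other lengths evaluate f on a uniformly rescaled abscissa.
    """
    if n_samples < 6:
        raise ValidationError(f"strategy_piecewise: n_samples = {n_samples} < 6 breakpoints")
    if n_samples == 63:
        xs = np.arange(1, 64, dtype=float)
    else:
        xs = np.linspace(1.0, 63.0, n_samples)
    samples = np.array([piecewise_step_function(float(x)) for x in xs])
    return Template(samples=samples, strategy="S5", source="analytic", template_id="S5:analytic")


def build_library(
    strategy: str,
    collection: Optional[StepCollection] = None,
    *,
    n: int = 1,
    seed: int = 0,
    maxsamp: Union[int, None] = 20,
    n_samples: int = 63,
) -> TemplateLibrary:
    """Build a one-strategy library; S1 takes (n, seed), S5 needs no collection."""
    if strategy == "S5":
        return TemplateLibrary(templates=[strategy_piecewise(n_samples)])
    if collection is None:
        raise ValidationError(f"build_library: strategy {strategy} requires a step collection")
    if strategy == "S1":
        return strategy_random(collection, n=n, seed=seed)
    if strategy == "S2":
        return TemplateLibrary(templates=[strategy_dtw_medoid(collection, maxsamp)])
    if strategy == "S3":
        return TemplateLibrary(templates=[strategy_linear_fusion(collection)])
    if strategy == "S4":
        return TemplateLibrary(templates=[strategy_nonlinear_fusion(collection, maxsamp)])
    raise ValidationError(f"build_library: unknown strategy {strategy!r}")
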