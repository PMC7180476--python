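"""Two-stage step detection: greedy template matching, then a lag-scan refinement.

Stage one slides every template of the library along the signal, computes
a Pearson correlation at each position, keeps local maxima above a
threshold, and accepts candidates greedily by decreasing correlation
under a hard non-overlap rule. Each accepted detection has the length of
the template that produced it — inherently suboptimal when the true
stance durations differ from the template lengths.

Stage two corrects for that: around each detection's boundaries a
(2z+1)^2 grid of lags (k, l) in [-z, z]^2 is scanned, and the window
x[ic+k : fc+l] minimising the banded DTW distance to the template (or,
in the comparator variant, maximising the Pearson correlation after
linear resampling) provides the refined boundaries ic* = ic + k*,
fc* = fc + l*.
"""

from __future__ import annotations

import logging
import warnings
from typing import Literal, Sequence

import numpy as np

from .core import Detection, DetectorConfig, GaitSignal, Template, TemplateLibrary
from .dtw import _dtw_distance_prenormed, znorm
from .errors import DegenerateSeriesError, RefinementInfeasibleError, ValidationError
from .templates import resample_linear

logger = logging.getLogger("gaitdtw.detector")

Criterion = Literal["dtw", "pearson", "none"]

__all__ = ["correlation_profile", "detect_steps", "refine_detection_dtw",
           "refine_detection_pearson", "detect_and_refine"]


def correlation_profile(signal: GaitSignal, template: Template) -> np.ndarray:
    """Pearson correlation of the template with every signal window.

    Element t is the correlation between the template and the window
    [t, t + L - 1]; the profile has length ``len(signal) - L + 1``.
    Zero-variance windows get correlation 0 and trigger a warning.
    """
    x = signal.samples
    t = template.samples
    L = t.size
    if L > x.size:
        raise ValidationError(f"template length {L} exceeds signal length {x.size}")
    windows = np.lib.stride_tricks.sliding_window_view(x, L)
    tc = t - t.mean()
    st = float(t.std())
    sw = windows.std(axis=1)
    num = windows @ tc  # == sum over window of (w - wbar) * tc since tc sums to 0
    degenerate = sw == 0.0
    denom = L * sw * st
    profile = np.zeros(windows.shape[0])
    np.divide(num, denom, out=profile, where=~degenerate)
    np.clip(profile, -1.0, 1.0, out=profile)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance windows: correlation set to 0",
            stacklevel=2,
        )
        profile[degenerate] = 0.0
    return profile


def _local_maxima(profile: np.ndarray) -> np.ndarray:
    """Interior indices strictly greater than both neighbours."""
    if profile.size < 3:
        return np.array([], dtype=int)
    inner = profile[1:-1]
    return np.flatnonzero((inner > profile[:-2]) & (inner > profile[2:])) + 1


def _enforce_separation(peaks: np.ndarray, profile: np.ndarray, min_sep: int) -> np.ndarray:
    if min_sep <= 0 or peaks.size == 0:
        return peaks
    kept: list[int] = []
    for p in sorted(peaks, key=lambda p: (-profile[p], p)):
        if all(abs(p - q) >= min_sep for q in kept):
            kept.append(int(p))
    return np.array(sorted(kept), dtype=int)


def detect_steps(
    signal: GaitSignal, library: TemplateLibrary, config: DetectorConfig
) -> list[Detection]:
    """Greedy template matching: candidates from all templates' correlation
    local maxima above threshold, accepted in decreasing correlation order
    if the template can be placed without overlapping an earlier acceptance.

    Returns detections sorted by ic; each records its generating template
    and has exactly that template's length.
    """
    candidates: list[tuple[float, int, int, Template]] = []
    for order, template in enumerate(library):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            profile = correlation_profile(signal, template)
        peaks = _local_maxima(profile)
        peaks = peaks[profile[peaks] > config.correlation_threshold]
        peaks = _enforce_separation(peaks, profile, config.min_peak_separation)
        for p in peaks:
            candidates.append((float(profile[p]), int(p), order, template))
    # decreasing correlation; position then library order break exact ties
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    accepted: list[Detection] = []
    for corr, t, _, template in candidates:
        ic, fc = t, t + len(template) - 1
        if any(not (fc < d.ic or ic > d.fc) for d in accepted):
            continue
        accepted.append(Detection(ic=ic, fc=fc, template_id=template.template_id,
                                  correlation=corr, refined=False))
    accepted.sort(key=lambda d: d.ic)
    logger.info("detect_steps: %d candidates -> %d detections", len(candidates), len(accepted))
    return accepted


def _scan_lags(signal: GaitSignal, detection: Detection, z: int):
    """Yield (k, l, window_start, window_stop_inclusive) for all valid lags."""
    n = len(signal)
    for k in range(-z, z + 1):
        for l in range(-z, z + 1):
            a = detection.ic + k
            b = detection.fc + l
            if a < 0 or b > n - 1 or b - a + 1 < 2:
                continue
            yield k, l, a, b


def refine_detection_dtw(
    signal: GaitSignal, detection: Detection, template: Template, config: DetectorConfig
) -> Detection:
    """Move the detection to the lag (k*, l*) minimising the banded DTW
    distance between x[ic+k : fc+l] and the template.

    Lags whose window leaves the signal, is shorter than 2 samples,
    is constant, or differs from the template length by more than the
    band are skipped. Ties prefer the least perturbation (smallest
    |k| + |l|, then lexicographic (k, l)).
    """
    zt = znorm(template.samples)
    Lt = zt.size
    best = None
    n_skipped = 0
    for k, l, a, b in _scan_lags(signal, detection, config.z):
        wlen = b - a + 1
        if abs(wlen - Lt) > config.maxsamp:
            n_skipped += 1
            continue
        window = signal.samples[a : b + 1]
        try:
            zw = znorm(window)
        except DegenerateSeriesError:
            n_skipped += 1
            continue
        cost = _dtw_distance_prenormed(zw, zt, config.maxsamp)
        key = (cost, abs(k) + abs(l), k, l)
        if best is None or key < best[0]:
            best = (key, a, b)
    if best is None:
        raise RefinementInfeasibleError(
            f"no valid lag for detection [{detection.ic},{detection.fc}] with z={config.z}"
        )
    (cost, _, _, _), a, b = best
    if n_skipped:
        logger.debug("refine_detection_dtw: skipped %d lags", n_skipped)
    return Detection(ic=a, fc=b, template_id=detection.template_id,
                     correlation=detection.correlation, dtw_cost=float(cost), refined=True)


def refine_detection_pearson(
    signal: GaitSignal, detection: Detection, template: Template, config: DetectorConfig
) -> Detection:
    """Comparator refinement: same lag scan, but each candidate window is
    linearly resampled to the template length and the Pearson correlation
    is maximised. This allows only linear time rescaling of the window,
    unlike the DTW criterion's non-linear warps.
    """
    t = template.samples
    tc = t - t.mean()
    st = float(t.std())
    Lt = t.size
    best = None
    for k, l, a, b in _scan_lags(signal, detection, config.z):
        window = signal.samples[a : b + 1]
        if float(window.std()) == 0.0:
            continue
        w = resample_linear(window, Lt)
        sw = float(w.std())
        if sw == 0.0:
            continue
        corr = float((w - w.mean()) @ tc / (Lt * sw * st))
        key = (-corr, abs(k) + abs(l), k, l)
        if best is None or key < best[0]:
            best = (key, a, b, corr)
    if best is None:
        raise RefinementInfeasibleError(
            f"no valid lag for detection [{detection.ic},{detection.fc}] with z={config.z}"
        )
    _, a, b, corr = best
    return Detection(ic=a, fc=b, template_id=detection.template_id,
                     correlation=float(np.clip(corr, -1.0, 1.0)), refined=True)


def detect_and_refine(
    signal: GaitSignal,
    library: TemplateLibrary,
    config: DetectorConfig,
    criterion: Criterion = "dtw",
) -> list[Detection]:
    """Full pipeline: greedy matching followed by the chosen refinement.

    criterion "none" returns the unrefined detections. Refined detections
    may overlap (non-overlap is not re-enforced after the lag scan); any
    such overlap is logged.
    """
    detections = detect_steps(signal, library, config)
    if criterion == "none":
        return detections
    if criterion not in ("dtw", "pearson"):
        raise ValidationError(f"unknown refinement criterion {criterion!r}")
    refine = refine_detection_dtw if criterion == "dtw" else refine_detection_pearson
    refined = [refine(signal, d, library.get(d.template_id), config) for d in detections]
    refined.sort(key=lambda d: (d.ic, d.fc))
    n_overlap = sum(1 for p, c in zip(refined, refined[1:]) if c.ic <= p.fc)
    if n_overlap:
        logger.info("detect_and_refine: %d overlapping detection pairs after refinement", n_overlap)
    return refined
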