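"""Domain types shared across the package.

Conventions
-----------
Indices are 0-based throughout. A stance interval ``[ic, fc]`` is inclusive
at both ends, so its duration in samples is ``fc - ic + 1``. Milliseconds
are derived as ``samples * 1000 / sampling_rate_hz`` (10 ms per sample at
the nominal 100 Hz).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError

STRATEGIES = ("S1", "S2", "S3", "S4", "S5")


def _as_float_array(samples: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name}: expected a 1-D sequence, got shape {arr.shape}")
    return arr


@dataclass
class GaitSignal:
    """One trial's single-axis angular-velocity series (y-axis gyrometer, deg/s)."""

    samples: np.ndarray
    sampling_rate_hz: float = 100.0
    trial_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = _as_float_array(self.samples, "GaitSignal.samples")
        if self.samples.size < 1:
            raise ValidationError("GaitSignal: empty series")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("GaitSignal: non-finite samples")
        if not self.sampling_rate_hz > 0:
            raise ValidationError("GaitSignal: sampling_rate_hz must be > 0")

    def __len__(self) -> int:
        return int(self.samples.size)

    def ms_per_sample(self) -> float:
        return 1000.0 / self.sampling_rate_hz


@dataclass(frozen=True)
class StepAnnotation:
    """Ground-truth stance interval: ic = initial contact, fc = final contact.

    Both indices are inclusive sample positions in the trial's signal.
    """

    ic: int
    fc: int
    step_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.ic < self.fc):
            raise ValidationError(f"StepAnnotation: need 0 <= ic < fc, got ic={self.ic} fc={self.fc}")

    @property
    def duration(self) -> int:
        return self.fc - self.ic + 1

    @property
    def midpoint(self) -> float:
        return (self.ic + self.fc) / 2.0


def validate_annotations(annotations: Sequence[StepAnnotation], signal_length: Optional[int] = None) -> list[StepAnnotation]:
    """Sort annotations by ic and enforce non-overlap (and range if a length is given)."""
    ordered = sorted(annotations, key=lambda a: a.ic)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.ic <= prev.fc:
            raise ValidationError(
                f"overlapping stance intervals: [{prev.ic},{prev.fc}] and [{cur.ic},{cur.fc}]"
            )
    if signal_length is not None:
        for a in ordered:
            if a.fc >= signal_length:
                raise ValidationError(f"annotation [{a.ic},{a.fc}] exceeds signal length {signal_length}")
    return ordered


@dataclass
class Detection:
    """A detected stance interval with its provenance and fit scores.

    Before refinement ``fc - ic + 1`` equals the matched template's length
    and ``dtw_cost`` is None; refinement fills ``dtw_cost`` and may move
    both boundaries by at most the scan half-width z.
    """

    ic: int
    fc: int
    template_id: str
    correlation: float
    dtw_cost: Optional[float] = None
    refined: bool = False

    def __post_init__(self) -> None:
        if not self.ic < self.fc:
            raise ValidationError(f"Detection: need ic < fc, got ic={self.ic} fc={self.fc}")
        if not -1.0 - 1e-9 <= self.correlation <= 1.0 + 1e-9:
            raise ValidationError(f"Detection: correlation {self.correlation} outside [-1, 1]")
        if self.dtw_cost is not None and self.dtw_cost < 0:
            raise ValidationError("Detection: dtw_cost must be non-negative")

    @property
    def duration(self) -> int:
        return self.fc - self.ic + 1

    @property
    def midpoint(self) -> float:
        return (self.ic + self.fc) / 2.0


@dataclass
class Template:
    """A prototype stance waveform with provenance.

    strategy is one of S1 (random pick), S2 (DTW medoid), S3 (linear
    fusion), S4 (non-linear DTW fusion), S5 (piecewise-affine analytic).
    """

    samples: np.ndarray
    strategy: str
    source: str = ""
    template_id: str = ""

    def __post_init__(self) -> None:
        self.samples = _as_float_array(self.samples, "Template.samples")
        if self.strategy not in STRATEGIES:
            raise ValidationError(f"Template: unknown strategy {self.strategy!r}")
        if self.samples.size < 2:
            raise ValidationError("Template: length must be >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("Template: non-finite samples")
        if float(np.std(self.samples)) == 0.0:
            raise ValidationError("Template: constant waveform (sigma = 0)")
        if not self.template_id:
            self.template_id = f"{self.strategy}:{self.source or 'template'}"

    def __len__(self) -> int:
        return int(self.samples.size)


@dataclass
class TemplateLibrary:
    templates: list[Template] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.templates:
            raise ValidationError("TemplateLibrary: empty")
        ids = [t.template_id for t in self.templates]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"TemplateLibrary: duplicate template ids {ids}")

    def __iter__(self):
        return iter(self.templates)

    def __len__(self) -> int:
        return len(self.templates)

    def get(self, template_id: str) -> Template:
        for t in self.templates:
            if t.template_id == template_id:
                return t
        raise KeyError(template_id)


@dataclass(frozen=True)
class WarpingPath:
    """Boundary-anchored monotone index-pair sequence produced by DTW."""

    pairs: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple((int(i), int(j)) for i, j in self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)

    def validate(self, nu: int, nv: int, maxsamp: Optional[int] = None) -> None:
        """Check boundary, monotone unit-step and band invariants; raise ValidationError."""
        p = self.pairs
        if not p:
            raise ValidationError("WarpingPath: empty")
        if p[0] != (0, 0) or p[-1] != (nu - 1, nv - 1):
            raise ValidationError(f"WarpingPath: boundary violated: {p[0]} .. {p[-1]} for ({nu},{nv})")
        for (i0, j0), (i1, j1) in zip(p, p[1:]):
            if (i1 - i0, j1 - j0) not in ((1, 0), (0, 1), (1, 1)):
                raise ValidationError(f"WarpingPath: non-unit step {(i0, j0)} -> {(i1, j1)}")
        if maxsamp is not None:
            for i, j in p:
                if abs(j - i) > maxsamp:
                    raise ValidationError(f"WarpingPath: pair {(i, j)} outside band {maxsamp}")


@dataclass
class DtwResult:
    """Optimal banded alignment: cumulative cost and the path achieving it."""

    distance: float
    path: WarpingPath


@dataclass
class DetectorConfig:
    """Detector parameters.

    correlation_threshold
        Minimum Pearson correlation for a local maximum to become a
        candidate detection (the matching stage's only free parameter).
    z
        Half-width, in samples, of the refinement lag scan: (2z+1)^2
        boundary combinations are tested per detection.
    maxsamp
        Sakoe-Chiba-style band half-width for DTW inside refinement.
    min_peak_separation
        Optional minimum distance between retained peaks of one
        template's correlation profile (0 disables the filter).
    """

    correlation_threshold: float = 0.7
    z: int = 10
    maxsamp: int = 20
    min_peak_separation: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.correlation_threshold < 1.0:
            raise ValidationError("DetectorConfig: correlation_threshold must be in (0, 1)")
        if self.z < 0 or self.maxsamp < 1 or self.min_peak_separation < 0:
            raise ValidationError("DetectorConfig: negative parameter")
        if 2 * self.z > self.maxsamp:
            warnings.warn(
                f"DetectorConfig: 2*z = {2 * self.z} exceeds maxsamp = {self.maxsamp}; "
                "extreme refinement lags will be band-infeasible and skipped",
                stacklevel=2,
            )


@dataclass
class StepCollection:
    """Step waveforms cut from annotated signals, with parallel identifiers."""

    steps: list[np.ndarray]
    ids: list[str]

    def __post_init__(self) -> None:
        if len(self.steps) != len(self.ids):
            raise ValidationError("StepCollection: steps and ids lengths differ")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("StepCollection: duplicate ids")
        self.steps = [_as_float_array(s, "StepCollection.step") for s in self.steps]
        for s, sid in zip(self.steps, self.ids):
            if s.size < 2:
                raise ValidationError(f"StepCollection: step {sid} shorter than 2 samples")
            if float(np.std(s)) == 0.0:
                raise ValidationError(f"StepCollection: step {sid} is constant")

    def __len__(self) -> int:
        return len(self.steps)


@dataclass
class EvalReport:
    """Event-level scores: precision, recall and per-step timing errors (ms).

    The delta_* arrays hold one absolute error per correct detection;
    signed_* keep the signed values (detected minus annotated) for
    diagnostics. Precision is None when nothing was detected, recall is
    None when nothing was annotated.
    """

    precision: Optional[float]
    recall: Optional[float]
    delta_start_ms: np.ndarray
    delta_end_ms: np.ndarray
    delta_duration_ms: np.ndarray
    signed_start_ms: np.ndarray
    signed_end_ms: np.ndarray
    signed_duration_ms: np.ndarray
    n_detected: int = 0
    n_annotated: int = 0
    n_correct: int = 0

    def __post_init__(self) -> None:
        for name in ("delta_start_ms", "delta_end_ms", "delta_duration_ms",
                     "signed_start_ms", "signed_end_ms", "signed_duration_ms"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.delta_start_ms.size
        if not (self.delta_end_ms.size == n == self.delta_duration_ms.size):
            raise ValidationError("EvalReport: delta arrays have unequal lengths")
        if np.any(self.delta_start_ms < 0) or np.any(self.delta_end_ms < 0) or np.any(self.delta_duration_ms < 0):
            raise ValidationError("EvalReport: absolute errors must be non-negative")

    def summary(self) -> dict:
        def stats(a: np.ndarray) -> dict:
            if a.size == 0:
                return {"mean": None, "sd": None}
            return {"mean": float(np.mean(a)), "sd": float(np.std(a))}

        return {
            "precision": self.precision,
            "recall": self.recall,
            "n_detected": self.n_detected,
            "n_annotated": self.n_annotated,
            "n_correct": self.n_correct,
            "delta_start_ms": stats(self.delta_start_ms),
            "delta_end_ms": stats(self.delta_end_ms),
            "delta_duration_ms": stats(self.delta_duration_ms),
        }
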