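"""Synthetic annotated gyrometer gait trials.

Emulates the statistical structure of foot-worn gyrometer recordings of
healthy straight-line walking: ~100 Hz sampling, around 8 stance phases
per trial, stance durations centred on a median of 63 samples, stance
waveforms shaped like the piecewise-affine idealised step, per-step
amplitude scaling and offset, within-step non-linear time warps bounded
in deviation, additive white noise on stances, and quiescent low-variance
swing segments between stances (stance is roughly 60% of a cycle, so
default swings of 35-50 samples follow 57-71-sample stances). Subjects
differ by a small stance-duration offset and an amplitude factor,
emulating between-subject speed/style variability.

Every annotation is exact by construction, so the generator supports
parameter-recovery tests that real annotated data cannot.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np

from .core import GaitSignal, StepAnnotation, Template, validate_annotations
from .errors import ValidationError
from .templates import resample_linear, strategy_piecewise

__all__ = ["SynthParams", "SynthCohort", "random_monotone_warp", "synth_step",
           "synth_trial", "synth_cohort", "write_cohort", "read_cohort"]


@dataclass
class SynthParams:
    """Generator settings; defaults describe the reference cohort.

    noise_sd is the white-noise standard deviation in prototype units
    (the prototype spans about [-2.6, 0.8]); amplitudes are arbitrary
    since detection z-normalises everything away.
    """

    n_trials: int = 20
    steps_per_trial: int = 8
    sampling_rate_hz: float = 100.0
    stance_len_median: int = 63
    stance_len_spread: int = 6
    warp_intensity: int = 8
    warp_mode: Literal["nonlinear", "linear"] = "nonlinear"
    amp_scale_range: tuple[float, float] = (0.8, 1.2)
    amp_base: float = 100.0
    offset_range: tuple[float, float] = (-10.0, 10.0)
    noise_sd: float = 0.05
    swing_len_range: tuple[int, int] = (35, 50)
    swing_noise_rel: float = 0.02
    n_subjects: int = 5
    subject_len_jitter: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.steps_per_trial < 1:
            raise ValidationError("SynthParams: n_trials and steps_per_trial must be >= 1")
        if self.stance_len_spread < 0 or self.warp_intensity < 0 or self.noise_sd < 0:
            raise ValidationError("SynthParams: negative spread/warp/noise")
        if self.amp_scale_range[0] <= 0 or self.amp_scale_range[0] > self.amp_scale_range[1]:
            raise ValidationError("SynthParams: amp_scale_range must be a positive interval")
        if self.swing_len_range[0] < 1 or self.swing_len_range[0] > self.swing_len_range[1]:
            raise ValidationError("SynthParams: swing_len_range must be a non-degenerate positive interval")
        if self.warp_mode == "nonlinear" and (
            self.stance_len_spread + self.subject_len_jitter > self.warp_intensity
        ):
            raise ValidationError(
                "SynthParams: stance_len_spread + subject_len_jitter must not exceed "
                "warp_intensity, or drawn lengths become warp-infeasible"
            )


def random_monotone_warp(
    length_in: int, length_out: int, warp_intensity: int, rng: np.random.Generator
) -> np.ndarray:
    """Random monotone map from the output grid onto the input grid.

    Returns an integer array m of size length_out with m[0] = 0,
    m[-1] = length_in - 1, non-decreasing increments (0/1 when the output
    is at least as long as the input, 1/2 when it is shorter, so input
    samples may be skipped when shrinking), and bounded deviation from
    the diagonal: |m[i] - i * length_in / length_out| <= warp_intensity.
    With warp_intensity 0 and equal lengths the map is the identity.
    """
    if length_in < 2 or length_out < 2:
        raise ValidationError("random_monotone_warp: lengths must be >= 2")
    if abs(length_in - length_out) > warp_intensity and length_in != length_out:
        raise ValidationError(
            f"random_monotone_warp: |{length_in} - {length_out}| exceeds warp_intensity {warp_intensity}"
        )
    expanding = length_out >= length_in
    lo_inc, hi_inc = (0, 1) if expanding else (1, 2)
    slope = length_in / length_out
    m = np.empty(length_out, dtype=int)
    m[0] = 0
    pos = 0
    for i in range(1, length_out):
        remaining_positions = length_out - 1 - i
        units_needed = length_in - 1 - pos
        options = []
        for inc in (lo_inc, hi_inc):
            nxt = pos + inc
            left = units_needed - inc
            if not (remaining_positions * lo_inc <= left <= remaining_positions * hi_inc):
                continue
            if abs(nxt - i * slope) > warp_intensity:
                continue
            options.append(inc)
        if not options:  # forced move back towards the diagonal
            inc = lo_inc if units_needed - lo_inc <= remaining_positions * hi_inc else hi_inc
        elif len(options) == 1:
            inc = options[0]
        else:
            # bias towards finishing exactly at length_in - 1
            p_hi = (units_needed - remaining_positions * lo_inc) / (
                (remaining_positions + 1) * (hi_inc - lo_inc)
            )
            inc = hi_inc if rng.random() < min(max(p_hi, 0.0), 1.0) else lo_inc
        pos += inc
        m[i] = pos
    if m[-1] != length_in - 1:
        raise ValidationError("random_monotone_warp: internal error, endpoint missed")
    return m


def synth_step(
    prototype: Optional[Template],
    params: SynthParams,
    rng: np.random.Generator,
    *,
    len_offset: int = 0,
    amp_factor: float = 1.0,
) -> tuple[np.ndarray, int]:
    """Draw one stance waveform: warp, scale, offset, noise.

    The stance length is uniform on
    [median - spread, median + spread] (+ a per-subject offset), so the
    empirical median of many draws equals the configured median. Returns
    (waveform, drawn length).
    """
    if prototype is None:
        prototype = strategy_piecewise()
    proto = prototype.samples
    centre = params.stance_len_median + len_offset
    length = int(centre + rng.integers(-params.stance_len_spread, params.stance_len_spread + 1))
    length = max(length, 6)
    if params.warp_mode == "nonlinear":
        warp = random_monotone_warp(proto.size, length, params.warp_intensity, rng)
        base = proto[warp]
    else:
        base = resample_linear(proto, length)
    amp = float(rng.uniform(*params.amp_scale_range)) * params.amp_base * amp_factor
    offset = float(rng.uniform(*params.offset_range))
    noise = rng.normal(0.0, params.noise_sd, length) if params.noise_sd > 0 else 0.0
    return (base + noise) * amp + offset, length


def _swing_segment(length: int, params: SynthParams, rng: np.random.Generator) -> np.ndarray:
    """Quiescent inter-stance segment: smooth low-variance noise around 0."""
    sd = params.swing_noise_rel * params.amp_base
    if sd == 0.0:
        return np.zeros(length)
    white = rng.normal(0.0, 1.0, length + 6)
    smooth = np.convolve(white, np.ones(7) / 7.0, mode="valid")
    return smooth * (sd / (1.0 / np.sqrt(7.0)))


def synth_trial(
    params: SynthParams,
    rng: np.random.Generator,
    *,
    trial_id: str = "trial",
    subject_id: str = "subject",
    prototype: Optional[Template] = None,
    len_offset: int = 0,
    amp_factor: float = 1.0,
) -> tuple[GaitSignal, list[StepAnnotation]]:
    """One trial: alternating swing segments and annotated stance steps."""
    segments: list[np.ndarray] = []
    annotations: list[StepAnnotation] = []
    cursor = 0
    for k in range(params.steps_per_trial):
        swing_len = int(rng.integers(params.swing_len_range[0], params.swing_len_range[1] + 1))
        segments.append(_swing_segment(swing_len, params, rng))
        cursor += swing_len
        wave, length = synth_step(prototype, params, rng, len_offset=len_offset, amp_factor=amp_factor)
        segments.append(wave)
        annotations.append(StepAnnotation(ic=cursor, fc=cursor + length - 1, step_id=f"{trial_id}:{k}"))
        cursor += length
    tail = int(rng.integers(params.swing_len_range[0], params.swing_len_range[1] + 1))
    segments.append(_swing_segment(tail, params, rng))
    samples = np.concatenate(segments)
    signal = GaitSignal(samples=samples, sampling_rate_hz=params.sampling_rate_hz,
                        trial_id=trial_id, subject_id=subject_id)
    return signal, validate_annotations(annotations, len(signal))


@dataclass
class SynthCohort:
    """A set of independent synthetic trials plus the generating manifest."""

    trials: list[tuple[GaitSignal, list[StepAnnotation]]]
    manifest: dict

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_steps(self) -> int:
        return sum(len(anns) for _, anns in self.trials)


def synth_cohort(params: SynthParams, prototype: Optional[Template] = None) -> SynthCohort:
    """n_trials independent trials, reproducible from params.seed.

    Trials are assigned round-robin to n_subjects synthetic subjects,
    each with its own stance-duration offset and amplitude factor.
    """
    rng = np.random.default_rng(params.seed)
    offsets = rng.integers(-params.subject_len_jitter, params.subject_len_jitter + 1,
                           size=params.n_subjects)
    amp_factors = rng.uniform(0.9, 1.1, size=params.n_subjects)
    trials = []
    for t in range(params.n_trials):
        s = t % params.n_subjects
        signal, anns = synth_trial(
            params, rng,
            trial_id=f"trial{t:03d}", subject_id=f"subj{s:02d}",
            prototype=prototype,
            len_offset=int(offsets[s]), amp_factor=float(amp_factors[s]),
        )
        trials.append((signal, anns))
    manifest = dataclasses.asdict(params)
    manifest["prototype"] = prototype.template_id if prototype is not None else "S5:analytic"
    return SynthCohort(trials=trials, manifest=manifest)


def write_cohort(cohort: SynthCohort, out_dir) -> None:
    from .io import write_annotations, write_signal

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(cohort.manifest, indent=1, default=str))
    for signal, anns in cohort.trials:
        write_signal(signal, out / f"{signal.trial_id}.signal.csv")
        write_annotations(anns, out / f"{signal.trial_id}.annotations.csv")


def read_cohort(in_dir) -> SynthCohort:
    from .io import read_annotations, read_signal

    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text()) if (src / "manifest.json").exists() else {}
    trials = []
    for sig_path in sorted(src.glob("*.signal.csv")):
        signal = read_signal(sig_path)
        ann_path = sig_path.with_name(sig_path.name.replace(".signal.csv", ".annotations.csv"))
        anns = read_annotations(ann_path, signal_length=len(signal))
        trials.append((signal, anns))
    if not trials:
        raise ValidationError(f"read_cohort: no *.signal.csv files in {src}")
    return SynthCohort(trials=trials, manifest=manifest)
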