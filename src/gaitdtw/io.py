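"""Delimited-text readers and writers.

All files are comma-separated with a header row; lines starting with '#'
are comments and carry sidecar metadata (sampling rate, trial ids).
Indices on disk use the same convention as in memory: 0-based, stance
intervals inclusive at both ends. Samples are written with repr precision
so write-then-read round-trips are exact for indices and good to >= 15
significant digits for floats.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import EvalReport, GaitSignal, StepAnnotation, Template, validate_annotations
from .errors import FileFormatError, ValidationError

PathLike = Union[str, Path]


def _read_meta(path: Path) -> dict:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta


def read_signal(path: PathLike) -> GaitSignal:
    """Read a signal CSV (columns sample_index, gyro_y) into a GaitSignal."""
    path = Path(path)
    meta = _read_meta(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FileFormatError(f"{path}: {exc}") from exc
    if not {"sample_index", "gyro_y"} <= set(df.columns):
        raise FileFormatError(f"{path}: expected columns sample_index, gyro_y, got {list(df.columns)}")
    if len(df) == 0:
        raise FileFormatError(f"{path}: empty series")
    values = pd.to_numeric(df["gyro_y"], errors="coerce")
    if values.isna().any():
        bad = df.loc[values.isna()].index[0]
        raise FileFormatError(f"{path}: non-numeric gyro_y value at data row {bad}")
    order = pd.to_numeric(df["sample_index"], errors="coerce")
    if order.isna().any() or not np.array_equal(order.to_numpy(), np.arange(len(df))):
        raise FileFormatError(f"{path}: sample_index must run 0..N-1 in order")
    return GaitSignal(
        samples=values.to_numpy(dtype=float),
        sampling_rate_hz=float(meta.get("sampling_rate_hz", 100.0)),
        trial_id=meta.get("trial_id", ""),
        subject_id=meta.get("subject_id", ""),
    )


def write_signal(signal: GaitSignal, path: PathLike) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# gaitdtw signal (0-based sample_index; gyro_y in deg/s)\n")
        fh.write(f"# sampling_rate_hz: {signal.sampling_rate_hz!r}\n")
        if signal.trial_id:
            fh.write(f"# trial_id: {signal.trial_id}\n")
        if signal.subject_id:
            fh.write(f"# subject_id: {signal.subject_id}\n")
        fh.write("sample_index,gyro_y\n")
        for i, v in enumerate(signal.samples):
            fh.write(f"{i},{float(v)!r}\n")


def read_annotations(path: PathLike, signal_length: Optional[int] = None) -> list[StepAnnotation]:
    """Read an annotation CSV (step_id, ic, fc); returns annotations sorted by ic.

    Overlapping intervals or fc < ic raise; when signal_length is given,
    out-of-range indices raise as well.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", dtype={"step_id": str})
    except pd.errors.EmptyDataError:
        return []
    except pd.errors.ParserError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc
    if len(df) == 0:
        return []
    if not {"step_id", "ic", "fc"} <= set(df.columns):
        raise FileFormatError(f"{path}: expected columns step_id, ic, fc, got {list(df.columns)}")
    anns = []
    for _, row in df.iterrows():
        try:
            ic, fc = int(row["ic"]), int(row["fc"])
        except (TypeError, ValueError) as exc:
            raise FileFormatError(f"{path}: non-integer ic/fc in row {row.to_dict()}") from exc
        anns.append(StepAnnotation(ic=ic, fc=fc, step_id=str(row["step_id"])))
    return validate_annotations(anns, signal_length)


def write_annotations(annotations: Sequence[StepAnnotation], path: PathLike) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# gaitdtw annotations (0-based, [ic, fc] inclusive)\n")
        fh.write("step_id,ic,fc\n")
        for a in sorted(annotations, key=lambda a: a.ic):
            fh.write(f"{a.step_id},{a.ic},{a.fc}\n")


def read_template(path: PathLike) -> Template:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc
    for key in ("strategy", "samples"):
        if key not in payload:
            raise FileFormatError(f"{path}: missing field {key!r}")
    try:
        return Template(
            samples=np.asarray(payload["samples"], dtype=float),
            strategy=payload["strategy"],
            source=payload.get("source", ""),
            template_id=payload.get("template_id", ""),
        )
    except ValidationError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc


def write_template(template: Template, path: PathLike) -> None:
    path = Path(path)
    payload = {
        "strategy": template.strategy,
        "source": template.source,
        "template_id": template.template_id,
        "samples": [float(v) for v in template.samples],
    }
    path.write_text(json.dumps(payload, indent=1))


def write_report(report: EvalReport, path: PathLike) -> None:
    """Write an EvalReport as JSON: summary plus the per-step error arrays."""
    path = Path(path)
    payload = report.summary()
    payload["per_step"] = {
        "delta_start_ms": report.delta_start_ms.tolist(),
        "delta_end_ms": report.delta_end_ms.tolist(),
        "delta_duration_ms": report.delta_duration_ms.tolist(),
        "signed_start_ms": report.signed_start_ms.tolist(),
        "signed_end_ms": report.signed_end_ms.tolist(),
        "signed_duration_ms": report.signed_duration_ms.tolist(),
    }
    path.write_text(json.dumps(payload, indent=1))


def read_report(path: PathLike) -> EvalReport:
    payload = json.loads(Path(path).read_text())
    per = payload["per_step"]
    return EvalReport(
        precision=payload["precision"],
        recall=payload["recall"],
        delta_start_ms=np.asarray(per["delta_start_ms"]),
        delta_end_ms=np.asarray(per["delta_end_ms"]),
        delta_duration_ms=np.asarray(per["delta_duration_ms"]),
        signed_start_ms=np.asarray(per["signed_start_ms"]),
        signed_end_ms=np.asarray(per["signed_end_ms"]),
        signed_duration_ms=np.asarray(per["signed_duration_ms"]),
        n_detected=payload.get("n_detected", 0),
        n_annotated=payload.get("n_annotated", 0),
        n_correct=payload.get("n_correct", 0),
    )
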