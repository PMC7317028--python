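"""Data model and I/O for fluorescence traces, protocol marks and reports.

Trace files are plain CSV with a ``time_s,intensity`` header, comma separator
and dot decimal.  Protocol marks (cuff timing) live in a JSON sidecar named
``<trace>.marks.json`` next to the trace, or are passed explicitly.  Analysis
results are written as a JSON report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

#: tolerated deviation of successive time steps from the nominal step, seconds
UNIFORMITY_TOL_S = 1e-6


class TraceFormatError(ValueError):
    """Raised for malformed trace files or invalid trace data."""


@dataclass(frozen=True)
class ProtocolMarks:
    """Cuff-protocol timing, seconds from recording start.

    The default full protocol records a >= 3 min baseline, a 3 min arterial
    occlusion (cuff inflated 60 mm Hg above systolic pressure) and >= 3 min
    of reperfusion.
    """

    baseline_start_s: float
    occlusion_start_s: float
    release_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not (self.baseline_start_s < self.occlusion_start_s
                < self.release_s < self.end_s):
            raise ValueError(
                "protocol marks must be ordered baseline_start < "
                "occlusion_start < release < end")

    @property
    def occlusion_duration_s(self) -> float:
        return self.release_s - self.occlusion_start_s

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ProtocolMarks":
        return cls(**{f.name: float(d[f.name]) for f in dataclasses.fields(cls)})


@dataclass(frozen=True)
class SubjectRecord:
    """Per-subject covariates: sex, age (years), BMI (kg/m^2), BP (mm Hg)."""

    subject_id: str
    sex: str
    age: float
    bmi: float
    sbp: float
    dbp: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if not (self.sbp > self.dbp > 0):
            raise ValueError("blood pressure must satisfy sbp > dbp > 0")


@dataclass(frozen=True)
class RawTrace:
    """A uniformly sampled fluorescence recording in arbitrary units."""

    subject_id: str
    times: np.ndarray
    intensities: np.ndarray
    sampling_rate: float
    marks: ProtocolMarks | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        intens = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", intens)
        if times.ndim != 1 or intens.ndim != 1 or len(times) != len(intens):
            raise TraceFormatError("times and intensities must be equal-length 1-D")
        if len(times) < 2:
            raise TraceFormatError("a trace needs at least 2 samples")
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise TraceFormatError("non-uniform sampling: times must be strictly increasing")
        nominal = 1.0 / self.sampling_rate
        if np.max(np.abs(steps - nominal)) > UNIFORMITY_TOL_S:
            raise TraceFormatError(
                f"non-uniform sampling: step deviates from 1/{self.sampling_rate} Hz "
                f"by more than {UNIFORMITY_TOL_S} s")
        if np.any(intens <= 0):
            raise TraceFormatError("intensities must be strictly positive")

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0]) + 1.0 / self.sampling_rate

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of a single-trace analysis.

    Durations are seconds; all windows are half-open ``[start, end)``.
    ``band_edges`` split the sub-cardiac spectrum into endothelial
    (0, e0], neurogenic (e0, e1] and myogenic (e1, e2] bands.
    """

    normalization_window: tuple[float, float] = (60.0, 120.0)
    rest_discard_s: float = 60.0
    rest_duration_s: float = 150.0
    reperfusion_duration_s: float = 150.0
    hyperemia_search_s: float = 60.0
    band_edges: tuple[float, float, float] = (0.021, 0.052, 0.15)
    cardiac_band: tuple[float, float] = (0.6, 2.0)
    prediction_level: float = 0.95
    quartile_fraction: float = 0.25
    fm_scale: float = 1e6
    reperfusion_anchor: str = "minimum"  # or "release"
    matched_rest_interval: bool = True
    allow_truncation: bool = False
    aggregation: str = "mean"  # across repeated measurements
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("rest_discard_s", "rest_duration_s",
                     "reperfusion_duration_s", "hyperemia_search_s"):
            if getattr(self, name) <= 0 and name != "rest_discard_s":
                raise ValueError(f"{name} must be positive")
        if self.rest_discard_s < 0:
            raise ValueError("rest_discard_s must be >= 0")
        edges = tuple(self.band_edges)
        if any(b <= a for a, b in zip(edges, edges[1:])) or edges[0] <= 0:
            raise ValueError("band_edges must be positive and strictly increasing")
        if self.reperfusion_anchor not in ("minimum", "release"):
            raise ValueError("reperfusion_anchor must be 'minimum' or 'release'")
        if not 0 < self.prediction_level < 1:
            raise ValueError("prediction_level must be in (0, 1)")
        if not 0 < self.quartile_fraction < 1:
            raise ValueError("quartile_fraction must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("normalization_window", "band_edges", "cardiac_band"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# trace CSV


def read_trace_csv(path: str | Path,
                   sampling_rate_hint: float | None = None,
                   subject_id: str | None = None,
                   marks: ProtocolMarks | None = None) -> RawTrace:
    """Read a ``time_s,intensity`` CSV into a :class:`RawTrace`.

    The sampling rate is inferred from the median time step and, if
    ``sampling_rate_hint`` is given, checked against it (1% tolerance).
    A ``<trace>.marks.json`` sidecar is loaded automatically unless ``marks``
    is passed.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"time_s", "intensity"} - set(df.columns)
    if missing:
        raise TraceFormatError(f"{path.name}: missing column(s) {sorted(missing)}")
    times = df["time_s"].to_numpy(dtype=float)
    intens = df["intensity"].to_numpy(dtype=float)
    if len(times) < 2:
        raise TraceFormatError(f"{path.name}: fewer than 2 samples")
    steps = np.diff(times)
    if np.any(steps <= 0):
        raise TraceFormatError(f"{path.name}: non-uniform sampling (non-increasing times)")
    fs = 1.0 / float(np.median(steps))
    if sampling_rate_hint is not None and abs(fs - sampling_rate_hint) > 0.01 * sampling_rate_hint:
        raise TraceFormatError(
            f"{path.name}: inferred sampling rate {fs:.3f} Hz conflicts with "
            f"hint {sampling_rate_hint} Hz")
    if marks is None:
        sidecar = path.with_suffix(path.suffix + ".marks.json")
        alt = path.with_name(path.stem + ".marks.json")
        for cand in (alt, sidecar):
            if cand.exists():
                marks = read_marks_json(cand)
                break
    return RawTrace(subject_id=subject_id or path.stem, times=times,
                    intensities=intens, sampling_rate=fs, marks=marks)


def write_trace_csv(trace: RawTrace, path: str | Path,
                    write_marks: bool = True) -> None:
    """Write a trace as CSV (12 significant digits) plus marks sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("time_s,intensity\n")
        for t, v in zip(trace.times, trace.intensities):
            fh.write(f"{t:.12g},{v:.12g}\n")
    if write_marks and trace.marks is not None:
        write_marks_json(trace.marks, path.with_name(path.stem + ".marks.json"))


def read_marks_json(path: str | Path) -> ProtocolMarks:
    with open(path) as fh:
        return ProtocolMarks.from_dict(json.load(fh))


def write_marks_json(marks: ProtocolMarks, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(marks.to_dict(), fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# reports


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(results: Mapping[str, Any], path: str | Path) -> None:
    """Serialize an analysis report to JSON.

    Apart from the ``generated_at`` timestamp the output is a deterministic
    function of ``results``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = dict(_jsonable(results))
    doc["generated_at"] = datetime.now(timezone.utc).isoformat()
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_report(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# cohort tables

COHORT_REQUIRED = ("subject_id", "sex", "age", "bmi", "sbp", "dbp")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort table; requires subject covariate columns.

    Optional measurement columns: ``fm``, ``fm_r``, ``pie_myo``,
    ``pie_myo_r``, ``repeat_index``.
    """
    df = pd.read_csv(path)
    missing = set(COHORT_REQUIRED) - set(df.columns)
    if missing:
        raise TraceFormatError(f"cohort table missing column(s) {sorted(missing)}")
    return df


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
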