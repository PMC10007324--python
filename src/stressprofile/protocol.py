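"""Stress-profile session structure and recording / cohort-table I/O.

A stress profile is a staged laboratory session in which multichannel
physiology (blood volume pulse, abdominal respiration, skin conductance)
is recorded continuously while the subject moves through a fixed sequence
of stages: a resting *baseline*, then psychological *stressor* tasks
alternating with quiet *recovery* periods.  The default protocol is nine
2-minute stages sampled at 256 Hz.

This module defines the protocol and recording containers, readers and
writers for the delimited-text interchange formats, and the stage
segmentation that every downstream computation relies on.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "StageSpec",
    "ProtocolDefinition",
    "Recording",
    "StageSegments",
    "CohortTable",
    "default_protocol",
    "read_protocol",
    "write_protocol",
    "read_recording",
    "write_recording",
    "segment_stages",
    "read_cohort_table",
    "write_cohort_table",
    "CHANNELS",
    "CHANNEL_UNITS",
]

ROLES = ("baseline", "stressor", "recovery")

#: Canonical channel order used throughout the pipeline.
CHANNELS = ("blood_volume_pulse", "respiration", "skin_conductance")
CHANNEL_UNITS = {"blood_volume_pulse": "%", "respiration": "%", "skin_conductance": "uS"}

# Case-insensitive header synonyms accepted by the recording reader.
_CHANNEL_SYNONYMS = {
    "blood_volume_pulse": "blood_volume_pulse",
    "bvp": "blood_volume_pulse",
    "blood volume pulse": "blood_volume_pulse",
    "respiration": "respiration",
    "resp": "respiration",
    "abdominal_respiration": "respiration",
    "abdominal respiration": "respiration",
    "breathing": "respiration",
    "skin_conductance": "skin_conductance",
    "skin conductance": "skin_conductance",
    "sc": "skin_conductance",
    "gsr": "skin_conductance",
    "eda": "skin_conductance",
}

_TIME_COLUMNS = {"time", "t", "time_s", "seconds", "timestamp"}


class ProtocolError(ValueError):
    """Raised when a protocol, recording or cohort table violates its contract."""


@dataclass(frozen=True)
class StageSpec:
    """One stage of the session: ordinal position, label, role and duration."""

    index: int
    label: str
    role: str
    duration_s: float

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ProtocolError(f"stage role must be one of {ROLES}, got {self.role!r}")
        if not self.duration_s > 0:
            raise ProtocolError(f"stage {self.label!r}: duration must be > 0")


@dataclass(frozen=True)
class ProtocolDefinition:
    """The staged session layout plus the acquisition sampling rate."""

    stages: tuple[StageSpec, ...]
    sampling_rate: float
    name: str = "stress-profile"

    def __post_init__(self) -> None:
        if not self.sampling_rate > 0:
            raise ProtocolError("sampling_rate must be positive")
        if len(self.stages) < 3:
            raise ProtocolError("a protocol needs at least 3 stages")
        baselines = [s for s in self.stages if s.role == "baseline"]
        if len(baselines) != 1 or self.stages[0].role != "baseline":
            raise ProtocolError("exactly one baseline stage is required and it must be first")
        indices = [s.index for s in self.stages]
        if indices != list(range(1, len(self.stages) + 1)):
            raise ProtocolError("stage indices must be consecutive from 1")

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    @property
    def total_duration_s(self) -> float:
        return float(sum(s.duration_s for s in self.stages))

    @property
    def total_samples(self) -> int:
        """Expected sample count per channel for an untrimmed recording."""
        return int(sum(round(s.duration_s * self.sampling_rate) for s in self.stages))

    def stage_samples(self) -> list[int]:
        return [int(round(s.duration_s * self.sampling_rate)) for s in self.stages]


def default_protocol(sampling_rate: float = 256.0) -> ProtocolDefinition:
    """The standard 9-stage stress profile: 2-minute stages, baseline first,
    four stressor tasks (Stroop, mental arithmetic, auditory, emotional
    recall) alternating with four recovery periods.  276,480 samples per
    channel at the default 256 Hz.
    """
    labels_roles = [
        ("baseline", "baseline"),
        ("stroop", "stressor"),
        ("recovery1", "recovery"),
        ("arithmetic", "stressor"),
        ("recovery2", "recovery"),
        ("auditory", "stressor"),
        ("recovery3", "recovery"),
        ("emotional", "stressor"),
        ("recovery4", "recovery"),
    ]
    stages = tuple(
        StageSpec(index=i + 1, label=lab, role=role, duration_s=120.0)
        for i, (lab, role) in enumerate(labels_roles)
    )
    return ProtocolDefinition(stages=stages, sampling_rate=float(sampling_rate))


def read_protocol(path: str | Path) -> ProtocolDefinition:
    """Load a protocol from a YAML/JSON document.

    Schema::

        name: stress-profile            # optional
        sampling_rate_hz: 256
        stages:
          - {label: baseline, role: baseline, duration_s: 120}
          - {label: stroop,   role: stressor, duration_s: 120}
          ...
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return protocol_from_dict(doc)


def protocol_from_dict(doc: Mapping) -> ProtocolDefinition:
    try:
        rate = float(doc["sampling_rate_hz"])
        raw_stages = doc["stages"]
    except (KeyError, TypeError) as exc:
        raise ProtocolError(f"protocol document missing required key: {exc}") from exc
    stages = tuple(
        StageSpec(
            index=i + 1,
            label=str(st["label"]),
            role=str(st["role"]),
            duration_s=float(st["duration_s"]),
        )
        for i, st in enumerate(raw_stages)
    )
    return ProtocolDefinition(stages=stages, sampling_rate=rate, name=str(doc.get("name", "stress-profile")))


def write_protocol(protocol: ProtocolDefinition, path: str | Path) -> None:
    doc = {
        "name": protocol.name,
        "sampling_rate_hz": protocol.sampling_rate,
        "stages": [
            {"label": s.label, "role": s.role, "duration_s": s.duration_s}
            for s in protocol.stages
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class Recording:
    """A subject-session multichannel time series.

    ``samples`` is a float array of shape (n_samples, n_channels) with
    columns in the canonical order given by ``channels``.  ``meta`` carries
    provenance such as the number of leading samples removed by the offset
    trim (key ``"trimmed_samples"``), which stage segmentation consults.
    """

    subject_id: str
    session: str  # "pre", "post" or "other"
    channels: tuple[str, ...]
    samples: np.ndarray
    sampling_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ProtocolError("samples must be a 2-D (time x channel) array")
        if self.samples.shape[1] != len(self.channels):
            raise ProtocolError("channel count does not match sample matrix width")
        if self.session not in ("pre", "post", "other"):
            raise ProtocolError("session must be 'pre', 'post' or 'other'")
        if not np.isfinite(self.samples).all():
            raise ProtocolError("recording contains missing or non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def trimmed_samples(self) -> int:
        return int(self.meta.get("trimmed_samples", 0))

    def replace(self, samples: np.ndarray, **meta_updates) -> "Recording":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Recording(
            subject_id=self.subject_id,
            session=self.session,
            channels=self.channels,
            samples=samples,
            sampling_rate=self.sampling_rate,
            meta=meta,
        )


class StageSegments(dict):
    """Map stage index -> half-open sample interval [start, end).

    Intervals are 0-based row coordinates into the (possibly trimmed)
    recording, pairwise disjoint, ordered and contiguous.
    """

    def validate(self, n_rows: int) -> None:
        keys = sorted(self)
        expected_start = 0
        for k in keys:
            start, end = self[k]
            if start != expected_start or end <= start:
                raise ProtocolError("stage intervals must be contiguous, ordered and non-empty")
            expected_start = end
        if expected_start != n_rows:
            raise ProtocolError(
                f"stage intervals cover {expected_start} rows but the recording has {n_rows}"
            )


def segment_stages(recording: Recording, protocol: ProtocolDefinition) -> StageSegments:
    """Partition the recording rows into protocol stages.

    Stage k of duration d_k receives the next round(d_k * fs) rows.  When a
    leading offset trim removed rows (recorded in the recording metadata),
    the deficit is charged entirely to stage 1: stage clocks are anchored to
    wall-clock time in the laboratory, so the baseline simply loses its
    first samples and later stage boundaries keep their positions in time.
    """
    counts = protocol.stage_samples()
    trimmed = recording.trimmed_samples
    if trimmed >= counts[0]:
        raise ProtocolError("offset trim consumed the entire baseline stage")
    counts[0] -= trimmed
    if sum(counts) > recording.n_samples:
        raise ProtocolError(
            f"protocol requires {sum(counts)} samples but recording has {recording.n_samples}"
        )
    segments = StageSegments()
    start = 0
    for spec, c in zip(protocol.stages, counts):
        segments[spec.index] = (start, start + c)
        start += c
    segments.validate(start)
    return segments


def _normalize_header(name: str) -> str | None:
    key = name.strip().lower().replace("-", " ")
    if key in _TIME_COLUMNS:
        return None
    return _CHANNEL_SYNONYMS.get(key) or _CHANNEL_SYNONYMS.get(key.replace(" ", "_"))


def read_recording(
    path: str | Path,
    protocol: ProtocolDefinition,
    *,
    subject_id: str | None = None,
    session: str = "other",
    length_tolerance_s: float = 1.0,
) -> Recording:
    """Read a delimited-text recording and validate it against the protocol.

    The file must be comma- or tab-delimited (autodetected) with a header
    row naming the three channels; header matching is case-insensitive over
    a synonym list (``BVP``, ``GSR``, ``SC`` ...).  An optional time column
    is ignored.  The row count must match the protocol's expected sample
    count within ``length_tolerance_s`` seconds of samples.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        head = fh.readline()
    sep = "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","
    df = pd.read_csv(path, sep=sep)

    mapping: dict[str, str] = {}
    for col in df.columns:
        canon = _normalize_header(str(col))
        if canon is not None and canon not in mapping:
            mapping[canon] = col
    missing = [c for c in CHANNELS if c not in mapping]
    if missing:
        raise ProtocolError(f"{path.name}: missing channel column(s): {', '.join(missing)}")

    data = df[[mapping[c] for c in CHANNELS]]
    try:
        matrix = data.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ProtocolError(f"{path.name}: non-numeric cell in channel data: {exc}") from exc
    if not np.isfinite(matrix).all():
        raise ProtocolError(f"{path.name}: recording contains missing or non-finite values")

    expected = protocol.total_samples
    tol = int(round(length_tolerance_s * protocol.sampling_rate))
    if abs(matrix.shape[0] - expected) > tol:
        raise ProtocolError(
            f"{path.name}: {matrix.shape[0]} rows but protocol expects {expected} "
            f"(tolerance +/-{tol})"
        )
    return Recording(
        subject_id=subject_id if subject_id is not None else path.stem,
        session=session,
        channels=CHANNELS,
        samples=matrix,
        sampling_rate=protocol.sampling_rate,
    )


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a recording as CSV with canonical channel headers."""
    df = pd.DataFrame(recording.samples, columns=list(recording.channels))
    df.to_csv(path, index=False, float_format="%.6f")


@dataclass
class CohortTable:
    """Per-subject pre/post RSI values with the post-minus-pre difference.

    The difference column is always recomputed from the pre and post values;
    RSI values must be finite and non-negative.
    """

    frame: pd.DataFrame  # columns: subject, rsi_pre, rsi_post, difference

    def __post_init__(self) -> None:
        required = {"subject", "rsi_pre", "rsi_post"}
        if not required.issubset(self.frame.columns):
            raise ProtocolError(f"cohort table needs columns {sorted(required)}")
        vals = self.frame[["rsi_pre", "rsi_post"]].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ProtocolError("cohort table contains non-finite RSI values")
        if (vals < 0).any():
            raise ProtocolError("cohort table contains negative RSI values")
        self.frame = self.frame.copy()
        self.frame["difference"] = self.frame["rsi_post"] - self.frame["rsi_pre"]

    @classmethod
    def from_values(
        cls, subjects: Sequence[str], rsi_pre: Iterable[float], rsi_post: Iterable[float]
    ) -> "CohortTable":
        return cls(
            pd.DataFrame(
                {"subject": list(subjects), "rsi_pre": list(rsi_pre), "rsi_post": list(rsi_post)}
            )
        )

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def pre(self) -> np.ndarray:
        return self.frame["rsi_pre"].to_numpy(dtype=float)

    @property
    def post(self) -> np.ndarray:
        return self.frame["rsi_post"].to_numpy(dtype=float)

    @property
    def differences(self) -> np.ndarray:
        return self.frame["difference"].to_numpy(dtype=float)


def read_cohort_table(path: str | Path | io.IOBase) -> CohortTable:
    """Read a cohort CSV with columns subject,rsi_pre,rsi_post.

    A stored difference column, if present, is checked against the
    recomputed post-minus-pre value to 3 decimals and then replaced.
    """
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "difference" in df.columns:
        stored = df["difference"].to_numpy(dtype=float)
        recomputed = df["rsi_post"].to_numpy(dtype=float) - df["rsi_pre"].to_numpy(dtype=float)
        if np.nanmax(np.abs(stored - recomputed)) > 5e-4:
            raise ProtocolError("stored difference column disagrees with post - pre beyond 3 dp")
        df = df.drop(columns=["difference"])
    return CohortTable(df)


def write_cohort_table(table: CohortTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False)
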