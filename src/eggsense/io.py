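"""Readers and writers for the EGG CSV dialect and derived tables.

The on-disk formats are deliberately plain: UTF-8 CSV with a header row,
comma separator and dot decimal.  An EGG recording is stored as
``time_s,ch1[,ch2,ch3,...]`` with time in seconds from segment start;
events (button presses) and artifact masks live in optional sidecar files.
Feature tables are ordinary CSVs whose feature columns follow a fixed,
documented order so that round-trips are loss-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "EggRecord",
    "SegmentPlan",
    "FEATURE_COLUMNS",
    "CONDITIONS",
    "FormatError",
    "RateError",
    "SchemaError",
    "read_recording",
    "write_recording",
    "read_feature_table",
    "write_feature_table",
    "read_segment_plan",
    "write_segment_plan",
]

#: Canonical feature-column order of the 17-feature battery.
FEATURE_COLUMNS = [
    "RMS",
    "median",
    "DF",
    "MagDF",
    "CS",
    "SDV",
    "SampEntT_m2",
    "SampEntT_m3",
    "SampEntT_m4",
    "SampEntP_m2",
    "SampEntP_m3",
    "SampEntP_m4",
    "SpectEnt",
    "Autocorr",
    "SD1",
    "SD2",
    "SDEGG",
]

#: Segment condition vocabulary (recording protocol order).
CONDITIONS = ("baseline", "highway", "countryside", "rest")

#: Metadata columns carried alongside the features.
META_COLUMNS = ["subject_id", "condition", "nausea", "snr_tag"]


class FormatError(ValueError):
    """Malformed EGG CSV (missing columns, non-monotone time...)."""


class RateError(ValueError):
    """Sampling rate inferred from the time column disagrees with the expected rate."""


class SchemaError(ValueError):
    """Feature table does not match the documented schema."""


@dataclass
class EggRecord:
    """A sampled multi-channel EGG signal in microvolts.

    Parameters
    ----------
    subject_id : str
        Identifier of the recorded subject.
    channels : ndarray, shape (n_channels, n_samples)
        Sample values in µV.
    fs : float
        Sampling rate in Hz (gastric slow waves are ~3 cpm, so 2 Hz
        amply covers the 1–10 cpm analysis band).
    start_time : float
        Offset of the first sample, seconds.
    artifact_mask : ndarray of bool, same shape as ``channels``
        True where a sample is considered an artifact.
    events : ndarray
        Button-press times in seconds (point events, half-open segment
        convention applies downstream).
    """

    subject_id: str
    channels: np.ndarray
    fs: float = 2.0
    start_time: float = 0.0
    artifact_mask: np.ndarray | None = None
    events: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.channels.shape, dtype=bool)
        else:
            self.artifact_mask = np.atleast_2d(np.asarray(self.artifact_mask, dtype=bool))
            if self.artifact_mask.shape != self.channels.shape:
                raise ValueError(
                    "artifact_mask shape "
                    f"{self.artifact_mask.shape} != channels shape {self.channels.shape}"
                )
        self.events = np.sort(np.asarray(self.events, dtype=float))
        if self.events.size and (
            self.events.min() < 0 or self.events.max() > self.duration_s
        ):
            raise ValueError("event times must lie within [0, duration]")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds from segment start."""
        return self.start_time + np.arange(self.n_samples) / self.fs


@dataclass
class SegmentPlan:
    """Ordered, non-overlapping labelled intervals of one recording session.

    The default protocol has exactly four intervals per subject:
    baseline, highway drive, countryside drive, post-drive rest.
    """

    intervals: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for name, start, end in self.intervals:
            if name not in CONDITIONS:
                raise ValueError(f"unknown condition {name!r}; expected one of {CONDITIONS}")
            if not start < end:
                raise ValueError(f"interval {name!r}: start {start} must be < end {end}")
            if start < prev_end:
                raise ValueError(f"interval {name!r} overlaps the previous interval")
            prev_end = end

    @classmethod
    def default(cls, segment_duration_s: float = 420.0) -> "SegmentPlan":
        d = segment_duration_s
        return cls([(c, i * d, (i + 1) * d) for i, c in enumerate(CONDITIONS)])


def write_recording(record: EggRecord, path: str | Path) -> None:
    """Write an :class:`EggRecord` plus sidecar event/mask files.

    ``<stem>.csv`` holds ``time_s,ch1,...``; ``<stem>.events.csv`` the
    button presses; ``<stem>.mask.csv`` the artifact mask as sparse
    ``sample_index,channel`` pairs.  Sidecars are written only when
    non-empty.
    """
    path = Path(path)
    cols = {"time_s": record.time}
    for i in range(record.n_channels):
        cols[f"ch{i + 1}"] = record.channels[i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")
    if record.events.size:
        pd.DataFrame({"time_s": record.events}).to_csv(
            path.with_suffix(".events.csv"), index=False, float_format="%.12g"
        )
    if record.artifact_mask.any():
        ch, idx = np.nonzero(record.artifact_mask)
        pd.DataFrame({"sample_index": idx, "channel": ch}).to_csv(
            path.with_suffix(".mask.csv"), index=False
        )


def read_recording(
    path: str | Path, fs_expected: float = 2.0, subject_id: str | None = None
) -> EggRecord:
    """Read an EGG CSV (plus sidecars, if present) into an :class:`EggRecord`.

    The sampling rate is inferred from the median time step and must agree
    with ``fs_expected`` within 1 %.

    Raises
    ------
    FormatError
        Missing/unknown columns or a non-monotone time axis.
    RateError
        Inferred rate differs from ``fs_expected`` by more than 1 %.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: missing required column 'time_s'")
    ch_cols = [c for c in df.columns if c != "time_s"]
    if not ch_cols or any(not c.startswith("ch") for c in ch_cols):
        raise FormatError(f"{path}: expected channel columns 'ch1', 'ch2', ...")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    fs = 1.0 / np.median(dt)
    if abs(fs - fs_expected) > 0.01 * fs_expected:
        raise RateError(
            f"{path}: inferred fs {fs:.4g} Hz does not match expected {fs_expected:.4g} Hz"
        )
    channels = df[ch_cols].to_numpy(dtype=float).T

    events = np.empty(0)
    ev_path = path.with_suffix(".events.csv")
    if ev_path.exists():
        events = pd.read_csv(ev_path)["time_s"].to_numpy(dtype=float)
    mask = np.zeros(channels.shape, dtype=bool)
    mask_path = path.with_suffix(".mask.csv")
    if mask_path.exists():
        m = pd.read_csv(mask_path)
        mask[m["channel"].to_numpy(int), m["sample_index"].to_numpy(int)] = True

    return EggRecord(
        subject_id=subject_id or path.stem,
        channels=channels,
        fs=fs_expected,
        start_time=float(t[0]),
        artifact_mask=mask,
        events=events,
    )


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table CSV in the canonical column order.

    Values survive a round trip to at least 12 significant digits.
    """
    _check_feature_schema(table)
    ordered = table[META_COLUMNS + FEATURE_COLUMNS]
    ordered.to_csv(Path(path), index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature-table CSV, validating the schema."""
    df = pd.read_csv(Path(path), dtype={"subject_id": str, "snr_tag": str})
    _check_feature_schema(df)
    extra = set(df.columns) - set(META_COLUMNS + FEATURE_COLUMNS)
    if extra:
        raise SchemaError(f"unknown feature columns: {sorted(extra)}")
    return df[META_COLUMNS + FEATURE_COLUMNS]


def _check_feature_schema(df: pd.DataFrame) -> None:
    missing = [c for c in META_COLUMNS + FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table is missing columns: {missing}")
    nausea = df["nausea"].to_numpy()
    if not np.isin(nausea, (0, 1)).all():
        raise SchemaError("nausea column must be 0/1")


def write_segment_plan(plan: SegmentPlan, path: str | Path) -> None:
    """Write a segment plan as YAML (or JSON if the suffix is .json)."""
    payload = {
        "intervals": [
            {"name": n, "start_s": float(s), "end_s": float(e)}
            for n, s, e in plan.intervals
        ]
    }
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def read_segment_plan(path: str | Path) -> SegmentPlan:
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return SegmentPlan(
        [(d["name"], float(d["start_s"]), float(d["end_s"])) for d in payload["intervals"]]
    )
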