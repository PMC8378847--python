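"""Data containers and on-disk formats.

Physiological recordings follow the BIDS physio convention (TSV with a JSON
sidecar holding ``SamplingFrequency``, ``StartTime`` and ``Columns``).  ROI
time-series travel as TSV matrices (time x ROI, header row of ROI IDs) with a
JSON sidecar carrying the repetition time, phase-encoding tag and subject /
session metadata.  Motion parameters are 6-column TSV in the order
[trans_x, trans_y, trans_z, rot_x, rot_y, rot_z], rotations in radians.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


class UnusableRecordingError(ValueError):
    """A physiological recording too degenerate to analyse (flat line, <2 beats)."""


@dataclass
class PhysioRecording:
    """Concurrent pulse-oximeter and breathing-belt traces."""

    cardiac: np.ndarray
    respiratory: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.cardiac = np.asarray(self.cardiac, dtype=float)
        self.respiratory = np.asarray(self.respiratory, dtype=float)
        if self.cardiac.shape != self.respiratory.shape:
            raise ValueError("cardiac and respiratory channels must have equal length")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        return self.cardiac.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.cardiac.size) / self.fs


@dataclass
class UniformSeries:
    """A series on a uniform time grid (heart rate in bpm, respiratory flow in a.u.)."""

    values: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.fs


@dataclass
class MotionParams:
    """Realignment parameters: frames x 6 (mm, rad)."""

    values: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != 6:
            raise ValueError("motion parameters must have 6 columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("motion parameters must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.tr


@dataclass
class ROITimeseries:
    """Parcellated BOLD series: frames x ROI, plus atlas metadata."""

    values: np.ndarray
    tr: float
    roi_labels: list[str]
    network_labels: dict[str, str] = field(default_factory=dict)
    encoding: str | None = None
    subject: str | None = None
    session: str | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.roi_labels):
            raise ValueError("number of ROI labels must match number of columns")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.tr

    def networks(self) -> list[str]:
        return [self.network_labels.get(r, "none") for r in self.roi_labels]

    def with_values(self, values: np.ndarray) -> "ROITimeseries":
        return ROITimeseries(
            values=values,
            tr=self.tr,
            roi_labels=list(self.roi_labels),
            network_labels=dict(self.network_labels),
            encoding=self.encoding,
            subject=self.subject,
            session=self.session,
        )


# ---------------------------------------------------------------------------
# readers / writers


def write_physio(recording: PhysioRecording, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {"cardiac": recording.cardiac, "respiratory": recording.respiratory}
    )
    df.to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")
    sidecar = {
        "SamplingFrequency": recording.fs,
        "StartTime": recording.start_time,
        "Columns": ["cardiac", "respiratory"],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_physio(path: str | Path) -> PhysioRecording:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    df = pd.read_csv(path, sep="\t", header=None, names=meta["Columns"])
    return PhysioRecording(
        cardiac=df["cardiac"].to_numpy(),
        respiratory=df["respiratory"].to_numpy(),
        fs=float(meta["SamplingFrequency"]),
        start_time=float(meta.get("StartTime", 0.0)),
    )


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".tsv.gz", ".tsv"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_motion(motion: MotionParams, path: str | Path) -> None:
    pd.DataFrame(motion.values, columns=MOTION_COLUMNS).to_csv(
        Path(path), sep="\t", index=False, float_format="%.8g"
    )


def read_motion(path: str | Path, tr: float) -> MotionParams:
    df = pd.read_csv(Path(path), sep=r"\s+")
    return MotionParams(values=df[MOTION_COLUMNS].to_numpy(), tr=tr)


def write_roi_timeseries(ts: ROITimeseries, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(ts.values, columns=ts.roi_labels).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )
    sidecar = {
        "tr": ts.tr,
        "encoding": ts.encoding,
        "subject": ts.subject,
        "session": ts.session,
        "networks": ts.network_labels,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_roi_timeseries(path: str | Path) -> ROITimeseries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(_sidecar_path(path).read_text())
    return ROITimeseries(
        values=df.to_numpy(),
        tr=float(meta["tr"]),
        roi_labels=list(df.columns),
        network_labels=meta.get("networks", {}),
        encoding=meta.get("encoding"),
        subject=meta.get("subject"),
        session=meta.get("session"),
    )


def write_matrix(values: np.ndarray, path: str | Path, labels: list[str] | None = None) -> None:
    n = values.shape[0]
    cols = labels if labels is not None else [str(i) for i in range(n)]
    pd.DataFrame(values, columns=cols).to_csv(
        Path(path), sep="\t", index=False, float_format="%.8g"
    )


def read_matrix(path: str | Path) -> np.ndarray:
    return pd.read_csv(Path(path), sep="\t").to_numpy()
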