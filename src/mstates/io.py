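"""Containers and text I/O for multichannel recordings and montages.

The native on-disk format is plain text: a whitespace/tab-delimited
channels x samples matrix with a JSON sidecar carrying the sampling rate,
channel labels and metadata.  EDF files can be read when ``mne`` is
installed (optional extra ``mstates[edf]``); EDF writing is not supported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .exceptions import InvalidArgumentError

__all__ = [
    "Recording",
    "read_matrix",
    "write_matrix",
    "read_edf",
    "read_montage",
    "write_montage",
]


@dataclass
class Recording:
    """One subject's EEG: ``data`` is channels x samples in microvolts.

    ``group`` tags cohort membership ("A"/"B" in synthetic cohorts) and may
    be ``None`` for ungrouped data.
    """

    data: np.ndarray
    sfreq: float
    channel_labels: list[str] = field(default_factory=list)
    subject_id: str = ""
    group: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidArgumentError("data must be a 2-D channels x samples array")
        if self.data.shape[0] < 2 or self.data.shape[1] < 2:
            raise InvalidArgumentError("need at least 2 channels and 2 samples")
        if not np.all(np.isfinite(self.data)):
            raise InvalidArgumentError("data contains non-finite values")
        if not self.sfreq > 0:
            raise InvalidArgumentError("sfreq must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:03d}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise InvalidArgumentError("channel_labels length mismatch")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sfreq

    def copy_with(self, **changes) -> "Recording":
        return replace(self, **changes)


def write_matrix(recording: Recording, path: str | Path) -> None:
    """Write a recording as a delimited text matrix plus a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, recording.data, fmt="%.8g", delimiter="\t")
    sidecar = {
        "sfreq": recording.sfreq,
        "channel_labels": recording.channel_labels,
        "subject_id": recording.subject_id,
        "group": recording.group,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_matrix(path: str | Path, sfreq: float | None = None) -> Recording:
    """Read a delimited channels x samples matrix (JSON sidecar optional)."""
    path = Path(path)
    data = np.loadtxt(path, ndmin=2)
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if sfreq is None:
        sfreq = meta.get("sfreq")
    if sfreq is None:
        raise InvalidArgumentError(f"no sampling rate: pass sfreq= or provide {sidecar.name}")
    return Recording(
        data=data,
        sfreq=float(sfreq),
        channel_labels=list(meta.get("channel_labels", [])),
        subject_id=str(meta.get("subject_id", path.stem)),
        group=meta.get("group"),
    )


def read_edf(path: str | Path, subject_id: str = "", group: str | None = None) -> Recording:
    """Read an EDF file via mne (requires the ``edf`` extra)."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover - environment dependent
        raise ImportError("EDF reading requires mne: pip install mstates[edf]") from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(
        data=raw.get_data() * 1e6,  # volts -> microvolts
        sfreq=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        subject_id=subject_id or Path(path).stem,
        group=group,
    )


def write_montage(positions: np.ndarray, labels: list[str], path: str | Path) -> None:
    """Write electrode positions as ``label x y z`` whitespace-delimited rows."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 3:
        raise InvalidArgumentError("positions must be n x 3")
    with open(path, "w") as fh:
        for lab, (x, y, z) in zip(labels, positions):
            fh.write(f"{lab}\t{x:.8g}\t{y:.8g}\t{z:.8g}\n")


def read_montage(path: str | Path) -> tuple[np.ndarray, list[str]]:
    labels: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
    return np.asarray(rows, dtype=float), labels
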