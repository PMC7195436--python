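"""Containers for snapshot-based recordings and the seizure catalog.

A recording is a time-ordered stream of short fixed-rate snippets
("segments"), one per channel, sampled every ``cadence_min`` minutes.
Timestamps are seconds from the start of the recording; CSV export maps
them onto an ISO-8601 axis anchored at :data:`EPOCH`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

EPOCH = datetime(2020, 1, 1)


class MalformedStreamError(ValueError):
    pass


@dataclass
class SegmentStream:
    """Per-channel 1-s snapshots at a fixed cadence with a missingness mask.

    Attributes
    ----------
    timestamps : (n_segments,) float array
        Segment start times in seconds; strictly increasing, constant step.
    data : (n_channels, n_segments, n_samples) float array
        Snapshot samples.  Masked segments hold NaN.
    mask : (n_segments,) bool array
        True where the segment is missing.
    rate_hz : float
        Within-segment sampling rate.
    cadence_min : float
        Spacing between consecutive segments, minutes.
    metadata : dict
        Free-form provenance (filter history, config hash, ...).
    """

    timestamps: np.ndarray
    data: np.ndarray
    mask: np.ndarray
    rate_hz: float = 400.0
    cadence_min: float = 2.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.data = np.asarray(self.data)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 3:
            raise MalformedStreamError("data must be (channels, segments, samples)")
        n_seg = self.timestamps.shape[0]
        if self.data.shape[1] != n_seg or self.mask.shape[0] != n_seg:
            raise MalformedStreamError("timestamps, data and mask disagree on segment count")
        dt = np.diff(self.timestamps)
        if n_seg > 1 and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise MalformedStreamError("timestamps must be strictly increasing at constant cadence")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_segments(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def missing_fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0

    def copy(self) -> "SegmentStream":
        return SegmentStream(
            self.timestamps.copy(), self.data.copy(), self.mask.copy(),
            self.rate_hz, self.cadence_min, dict(self.metadata),
        )

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("timestamps", data=self.timestamps)
            f.create_dataset("mask", data=self.mask)
            f.create_dataset("data", data=self.data.astype(np.float32))
            f.attrs["cadence_min"] = self.cadence_min
            f.attrs["rate_hz"] = self.rate_hz
            for key, val in self.metadata.items():
                if isinstance(val, (str, int, float, bool)):
                    f.attrs[f"meta_{key}"] = val

    @classmethod
    def from_hdf5(cls, path) -> "SegmentStream":
        import h5py

        with h5py.File(path, "r") as f:
            meta = {
                k[5:]: (v.item() if hasattr(v, "item") else v)
                for k, v in f.attrs.items()
                if k.startswith("meta_")
            }
            return cls(
                timestamps=f["timestamps"][:],
                data=f["data"][:].astype(float),
                mask=f["mask"][:].astype(bool),
                cadence_min=float(f.attrs["cadence_min"]),
                rate_hz=float(f.attrs["rate_hz"]),
                metadata=meta,
            )


@dataclass
class SeizureCatalog:
    """Seizure onset times (seconds) and durations (seconds)."""

    onsets_s: np.ndarray
    durations_s: np.ndarray

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        self.durations_s = np.asarray(self.durations_s, dtype=float)
        if self.onsets_s.shape != self.durations_s.shape:
            raise ValueError("onsets and durations must have equal length")
        if self.onsets_s.size > 1 and np.any(np.diff(self.onsets_s) <= 0):
            raise ValueError("seizure onsets must be strictly increasing")

    def __len__(self) -> int:
        return int(self.onsets_s.size)

    def to_csv(self, path) -> None:
        iso = [(EPOCH + timedelta(seconds=float(t))).isoformat() for t in self.onsets_s]
        pd.DataFrame({"onset_time_iso": iso, "duration_s": self.durations_s}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "SeizureCatalog":
        df = pd.read_csv(path)
        onsets = np.array(
            [(datetime.fromisoformat(s) - EPOCH).total_seconds() for s in df["onset_time_iso"]]
        )
        return cls(onsets, df["duration_s"].to_numpy(dtype=float))
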