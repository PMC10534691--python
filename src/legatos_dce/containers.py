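"""In-memory containers shared across the pipeline: 4D image/concentration
series and the vascular input function."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .acquisition import DEFAULT_HCT


def default_affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


@dataclass
class ImageSeries:
    """A 4D dynamic volume (x, y, z, t) on a regular grid.

    ``data`` units are either scanner signal or gadolinium concentration (mM);
    ``units`` records which. ``times`` is the frame time base in seconds on
    the shared experiment clock.
    """

    data: np.ndarray
    times: np.ndarray
    voxel_size: tuple[float, float, float]
    units: str = "mM"
    affine: np.ndarray | None = None
    flags: np.ndarray | None = None  # per-voxel bool, True = unreliable

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("series data must be 4-D (x, y, z, t)")
        if self.times.ndim != 1 or self.times.size != self.data.shape[3]:
            raise ValueError("times must match the last data axis")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("time base must be strictly increasing")
        if self.affine is None:
            self.affine = default_affine(self.voxel_size)

    @property
    def shape(self):
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def curve(self, index) -> np.ndarray:
        """Concentration/signal-time curve of one voxel."""
        return self.data[index[0], index[1], index[2], :]

    def same_space(self, other: "ImageSeries", atol: float = 1e-6) -> bool:
        """True when origin and orientation agree (co-registered grids;
        the voxel size itself may differ between series)."""
        a, b = self.affine, other.affine
        if not np.allclose(a[:3, 3], b[:3, 3], atol=atol):
            return False
        da = a[:3, :3] / np.linalg.norm(a[:3, :3], axis=0)
        db = b[:3, :3] / np.linalg.norm(b[:3, :3], axis=0)
        return np.allclose(da, db, atol=atol)


ConcentrationSeries = ImageSeries


@dataclass
class VascularInputFunction:
    """Plasma concentration versus time with dose-calibration metadata.

    ``cp`` is the plasma-space curve (mM). The whole-blood curve is
    ``cb = cp * (1 - hct)`` by construction, so the two representations stay
    consistent by the stored haematocrit.
    """

    times: np.ndarray
    cp: np.ndarray
    hct: float = DEFAULT_HCT
    dose_calibration_ratio: float = 1.0
    source_voxel_indices: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        if self.times.shape != self.cp.shape or self.times.ndim != 1:
            raise ValueError("times and cp must be matching 1-D arrays")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("VIF time base must be strictly increasing")
        if not (0 <= self.hct < 1):
            raise ValueError("hct must be in [0, 1)")

    @classmethod
    def from_whole_blood(cls, times, cb, hct=DEFAULT_HCT, **kw):
        cb = np.asarray(cb, dtype=float)
        return cls(times=times, cp=cb / (1.0 - hct), hct=hct, **kw)

    @property
    def cb(self) -> np.ndarray:
        """Whole-blood concentration (mM)."""
        return self.cp * (1.0 - self.hct)

    def cp_at(self, t) -> np.ndarray:
        """Linear interpolation of the plasma curve (zero before arrival of
        data, held constant after the last sample)."""
        return np.interp(t, self.times, self.cp, left=0.0, right=self.cp[-1])

    def rescaled(self, factor: float) -> "VascularInputFunction":
        """Amplitude-scaled copy (e.g. low-dose -> full-dose units)."""
        return VascularInputFunction(
            times=self.times.copy(), cp=self.cp * factor, hct=self.hct,
            dose_calibration_ratio=self.dose_calibration_ratio,
            source_voxel_indices=self.source_voxel_indices)

    def covers(self, t) -> bool:
        t = np.asarray(t)
        return bool(t.min() >= self.times[0] - 1e-9
                    and t.max() <= self.times[-1] + 1e-9)

    def to_csv(self, path, metadata_path=None) -> None:
        pd.DataFrame({"time_s": self.times, "cp_mM": self.cp}).to_csv(
            path, index=False)
        if metadata_path is not None:
            meta = {"hct": self.hct,
                    "dose_calibration_ratio": self.dose_calibration_ratio,
                    "n_source_voxels":
                        None if self.source_voxel_indices is None
                        else int(np.asarray(self.source_voxel_indices).shape[0])}
            Path(metadata_path).write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path, hct=DEFAULT_HCT) -> "VascularInputFunction":
        df = pd.read_csv(path)
        return cls(times=df["time_s"].to_numpy(),
                   cp=df["cp_mM"].to_numpy(), hct=hct)
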