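"""Acquisition metadata for one DCE series (temporal/spatial geometry and
pulse-sequence constants), with YAML sidecar I/O."""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import yaml

#: gadoterate r1 at 1.5 T, s^-1 mM^-1
DEFAULT_R1_RELAXIVITY = 3.6
#: SPGR repetition time, s
DEFAULT_TR = 0.0045
#: blood haematocrit fraction
DEFAULT_HCT = 0.42
#: variable-flip-angle baseline acquisition, degrees
VFA_FLIP_ANGLES = (2.0, 8.0, 15.0, 20.0)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Geometry and sequence constants of one dynamic SPGR series.

    Attributes
    ----------
    frame_interval : float
        Time between dynamic frames, seconds.
    n_frames : int
        Number of dynamic frames.
    voxel_size : tuple of float
        Voxel dimensions in mm.
    flip_angle_deg : float
        Flip angle of the dynamic series.
    tr : float
        Repetition time, seconds.
    dose_ml : float
        Injected contrast volume for this series, mL.
    relaxivity_r1 : float
        Longitudinal relaxivity of the contrast agent, s^-1 mM^-1.
    t_start : float
        Acquisition time of the first frame, seconds (shared clock across
        the two series of a dual-injection protocol).
    """

    frame_interval: float
    n_frames: int
    voxel_size: tuple[float, float, float]
    flip_angle_deg: float = 15.0
    tr: float = DEFAULT_TR
    dose_ml: float = 15.0
    relaxivity_r1: float = DEFAULT_R1_RELAXIVITY
    t_start: float = 0.0

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel dimensions must all be > 0")
        if self.tr <= 0 or self.relaxivity_r1 <= 0:
            raise ValueError("tr and relaxivity_r1 must be > 0")

    @property
    def times(self) -> np.ndarray:
        """Frame mid-times in seconds."""
        return self.t_start + self.frame_interval * np.arange(self.n_frames)

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def replace(self, **kw) -> "AcquisitionSpec":
        return replace(self, **kw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["voxel_size"] = list(self.voxel_size)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "AcquisitionSpec":
        d = yaml.safe_load(Path(path).read_text())
        d["voxel_size"] = tuple(d["voxel_size"])
        return cls(**d)


def ldht_spec(**overrides) -> AcquisitionSpec:
    """Low-dose high-temporal series: 1 s frames, 300 frames,
    2.5 x 2.5 x 6.35 mm voxels, 3 mL pre-bolus."""
    base = AcquisitionSpec(frame_interval=1.0, n_frames=300,
                           voxel_size=(2.5, 2.5, 6.35), dose_ml=3.0)
    return base.replace(**overrides) if overrides else base


def fdhs_spec(**overrides) -> AcquisitionSpec:
    """Full-dose high-spatial series: 10.7 s frames, 60 frames,
    1 x 1 x 2 mm voxels, full dose (0.2 mL/kg minus the 3 mL pre-bolus)."""
    base = AcquisitionSpec(frame_interval=10.7, n_frames=60,
                           voxel_size=(1.0, 1.0, 2.0), dose_ml=12.0,
                           t_start=300.0)
    return base.replace(**overrides) if overrides else base


def dose_ratio_from_weight(weight_kg: float = 75.0,
                           dose_per_kg_ml: float = 0.2,
                           prebolus_ml: float = 3.0) -> float:
    """Nominal full-dose / pre-bolus concentration scale factor.

    The full FDHS dose is ``0.2 mL/kg x weight - 3 mL pre-bolus``; the ratio
    against the 3 mL pre-bolus calibrates the two series onto one
    concentration scale.
    """
    full = dose_per_kg_ml * weight_kg - prebolus_ml
    if full <= 0:
        raise ValueError("weight too small for the dosing scheme")
    return full / prebolus_ml
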