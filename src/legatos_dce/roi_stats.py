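"""ROI statistics, histograms, tumour volumes and response classification."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RoiSummary", "roi_volume", "classify_response", "summarize_roi",
           "percent_change"]

#: volumetric response rule: absolute (cm^3) and relative reduction thresholds
RESPONSE_ABS_CM3 = 0.125
RESPONSE_REL = 0.05

HISTOGRAM_BINS = 64
#: upper histogram edge per parameter (units of the map)
HISTOGRAM_CAPS = {"ktrans": 0.5, "fp": 1.5, "ps": 0.5, "rfp": 1.0,
                  "vp": 0.2, "ve": 1.0, "cbf": 2.5}


def roi_volume(mask: np.ndarray, voxel_size_mm) -> float:
    """ROI volume in cm^3 from a binary mask and the voxel size in mm."""
    mask = np.asarray(mask)
    if mask.dtype != bool and not np.isin(np.unique(mask), (0, 1)).all():
        raise ValueError("mask must be binary")
    return float(mask.astype(bool).sum() * np.prod(voxel_size_mm) / 1000.0)


def classify_response(vol_d0_cm3: float, vol_d90_cm3: float) -> str:
    """'responder' iff the volume falls by more than 0.125 cm^3 and/or by
    more than 5% relative to baseline."""
    if vol_d0_cm3 < 0 or vol_d90_cm3 < 0:
        raise ValueError("volumes must be >= 0")
    if vol_d0_cm3 == 0:
        raise ValueError("baseline volume is zero")
    drop = vol_d0_cm3 - vol_d90_cm3
    if drop > RESPONSE_ABS_CM3 or drop / vol_d0_cm3 > RESPONSE_REL:
        return "responder"
    return "non-responder"


def percent_change(x_d0: float, x_d90: float) -> float:
    """Signed percentage change 100*(d90 - d0)/d0."""
    if x_d0 == 0:
        raise ValueError("zero baseline value")
    return 100.0 * (x_d90 - x_d0) / x_d0


@dataclass
class RoiSummary:
    """Descriptive statistics of the kinetic maps over one ROI."""

    roi_id: str
    n_voxels: int
    volume_cm3: float
    stats: pd.DataFrame                       # per-parameter mean/median/...
    histograms: dict[str, tuple] = field(default_factory=dict)
    n_excluded: int = 0

    def to_csv(self, path) -> None:
        df = self.stats.copy()
        df.insert(0, "roi_id", self.roi_id)
        df.insert(1, "n_voxels", self.n_voxels)
        df.insert(2, "volume_cm3", self.volume_cm3)
        df.to_csv(path)


def summarize_roi(maps, mask: np.ndarray, voxel_size_mm, roi_id: str = "roi",
                  flags: np.ndarray | None = None,
                  bins: int = HISTOGRAM_BINS, caps: dict | None = None) -> RoiSummary:
    """Mean/median/SD/min/max and histograms per parameter over the unflagged
    ROI voxels.

    ``maps`` is a dict of named parameter volumes (or an object exposing
    ``params()`` returning one, e.g. a kinetic-maps result). Flagged voxels
    are excluded from every statistic and the excluded count is reported.
    Histograms use ``bins`` equal-width bins over [0, cap] per parameter.
    """
    if hasattr(maps, "params"):
        flags = maps.flags != 0 if flags is None and hasattr(maps, "flags") else flags
        maps = maps.params()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    good = mask if flags is None else (mask & ~np.asarray(flags, dtype=bool))
    caps = {**HISTOGRAM_CAPS, **(caps or {})}
    rows, hists = [], {}
    for name, vol in maps.items():
        v = np.asarray(vol)[good]
        v = v[np.isfinite(v)]
        if v.size:
            rows.append({"parameter": name, "n": int(v.size),
                         "mean": float(v.mean()), "median": float(np.median(v)),
                         "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                         "min": float(v.min()), "max": float(v.max())})
            cap = caps.get(name, float(v.max()) or 1.0)
            counts, edges = np.histogram(np.clip(v, 0, cap), bins=bins,
                                         range=(0.0, cap))
            hists[name] = (edges, counts)
        else:
            rows.append({"parameter": name, "n": 0, "mean": np.nan,
                         "median": np.nan, "sd": np.nan, "min": np.nan,
                         "max": np.nan})
    return RoiSummary(roi_id=roi_id,
                      n_voxels=int(good.sum()),
                      volume_cm3=round(roi_volume(good, voxel_size_mm), 2),
                      stats=pd.DataFrame(rows).set_index("parameter"),
                      histograms=hists,
                      n_excluded=int((mask & ~good).sum()))
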