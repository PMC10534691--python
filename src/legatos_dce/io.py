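"""NIfTI import/export for series and parameter maps (nibabel-backed)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .acquisition import AcquisitionSpec
from .containers import ImageSeries, default_affine

__all__ = ["save_series", "load_series", "save_map", "load_map"]


def save_series(series: ImageSeries, path, spec: AcquisitionSpec | None = None,
                sidecar: str | Path | None = None) -> None:
    """Write a 4D series as NIfTI; optionally an acquisition YAML sidecar
    (which also records the explicit frame times, e.g. for a series with
    extra baseline frames)."""
    import yaml

    img = nib.Nifti1Image(series.data.astype(np.float32), series.affine)
    img.header["pixdim"][4] = (np.diff(series.times).mean()
                               if series.n_frames > 1 else 0.0)
    nib.save(img, str(path))
    if spec is not None:
        target = Path(sidecar) if sidecar is not None else \
            Path(str(path).removesuffix(".gz").removesuffix(".nii") + ".yaml")
        spec.to_yaml(target)
        d = yaml.safe_load(target.read_text())
        d["frame_times"] = [float(t) for t in series.times]
        target.write_text(yaml.safe_dump(d, sort_keys=False))


def load_series(path, spec: AcquisitionSpec | None = None,
                sidecar=None, units="mM") -> ImageSeries:
    """Read a 4D NIfTI; frame times come from the sidecar (explicit
    ``frame_times`` if present, else the spec's uniform time base)."""
    import yaml

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4D NIfTI series")
    times = None
    if sidecar is not None:
        d = yaml.safe_load(Path(sidecar).read_text())
        times = d.pop("frame_times", None)
        if spec is None:
            spec = AcquisitionSpec(**{**d, "voxel_size": tuple(d["voxel_size"])})
    if spec is not None:
        times = spec.times if times is None else np.asarray(times)
        voxel = spec.voxel_size
    else:
        dt = float(img.header["pixdim"][4]) or 1.0
        times = dt * np.arange(data.shape[3])
        voxel = tuple(float(v) for v in img.header.get_zooms()[:3])
    return ImageSeries(data=data, times=times, voxel_size=voxel, units=units,
                       affine=img.affine)


def save_map(volume: np.ndarray, path, voxel_size=(1.0, 1.0, 2.0),
             affine=None) -> None:
    aff = affine if affine is not None else default_affine(voxel_size)
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), aff),
             str(path))


def load_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)
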