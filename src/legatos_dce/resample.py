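"""Grid resampling between the high-spatial and low-spatial lattices.

Downsampling is volume-conserving averaging (partial-volume forward model);
upsampling is nearest-parent block assignment so each fine voxel inherits its
containing coarse voxel's value. Grids are assumed axis-aligned with a shared
origin (co-registration is out of scope and asserted upstream).
"""

from __future__ import annotations

import numpy as np

__all__ = ["block_average", "area_average", "downsample", "upsample_nearest_parent",
           "integer_factors"]


def integer_factors(fine_voxel, coarse_voxel, tol=1e-9):
    """Per-axis coarse/fine ratios if all are integers, else None."""
    out = []
    for f, c in zip(fine_voxel, coarse_voxel):
        r = c / f
        if abs(r - round(r)) > tol or r < 1 - tol:
            return None
        out.append(int(round(r)))
    return tuple(out)


def block_average(data: np.ndarray, factors) -> np.ndarray:
    """Average over non-overlapping integer blocks. Trailing time axes of a
    4D array are preserved. Shape must be divisible by the factors."""
    fx, fy, fz = factors
    nx, ny, nz = data.shape[:3]
    if nx % fx or ny % fy or nz % fz:
        raise ValueError(
            f"grid shape {data.shape[:3]} not divisible by factors {factors}")
    rest = data.shape[3:]
    out = data.reshape(nx // fx, fx, ny // fy, fy, nz // fz, fz, *rest)
    return out.mean(axis=(1, 3, 5))


def _overlap_matrix(n_src: int, h_src: float, n_dst: int, h_dst: float) -> np.ndarray:
    """1-D volume-overlap weights between two grids sharing origin 0.

    Row j holds the fractional contribution of each source voxel to
    destination voxel j, normalised over the covered length (so constants map
    to constants even at a partially covered boundary)."""
    src_lo = np.arange(n_src) * h_src
    src_hi = src_lo + h_src
    w = np.zeros((n_dst, n_src))
    for j in range(n_dst):
        lo, hi = j * h_dst, (j + 1) * h_dst
        ov = np.minimum(src_hi, hi) - np.maximum(src_lo, lo)
        ov = np.clip(ov, 0.0, None)
        s = ov.sum()
        if s <= 0:
            raise ValueError("destination voxel not covered by source grid")
        w[j] = ov / s
    return w


def area_average(data: np.ndarray, fine_voxel, coarse_voxel, coarse_shape) -> np.ndarray:
    """Volume-weighted averaging onto an arbitrary coarser axis-aligned grid
    (handles non-integer voxel-size ratios such as 1 mm -> 2.5 mm)."""
    out = data
    for ax in range(3):
        w = _overlap_matrix(data.shape[ax], fine_voxel[ax],
                            coarse_shape[ax], coarse_voxel[ax])
        out = np.moveaxis(np.tensordot(w, np.moveaxis(out, ax, 0), axes=(1, 0)), 0, ax)
    return out


def coarse_shape_for(fine_shape, fine_voxel, coarse_voxel):
    """Largest coarse grid fully inside the fine-grid extent (>= 1 per axis)."""
    return tuple(max(1, int(np.floor(n * f / c + 1e-9)))
                 for n, f, c in zip(fine_shape, fine_voxel, coarse_voxel))


def downsample(data: np.ndarray, fine_voxel, coarse_voxel, mode: str = "auto",
               coarse_shape=None) -> np.ndarray:
    """Partial-volume downsampling.

    mode='auto' uses exact block averaging when the voxel-size ratios are
    integer and raises otherwise; mode='area' always uses volume-weighted
    overlap averaging. Non-integer ratios therefore require an explicit
    resampling mode.
    """
    factors = integer_factors(fine_voxel, coarse_voxel)
    if mode == "auto":
        if factors is None:
            raise ValueError(
                "non-integer downsampling factors for voxel sizes "
                f"{fine_voxel} -> {coarse_voxel}; pass mode='area' explicitly")
        mode = "block"
    if mode == "block":
        if factors is None:
            raise ValueError("block mode requires integer voxel-size ratios")
        return block_average(data, factors)
    if mode == "area":
        if coarse_shape is None:
            coarse_shape = coarse_shape_for(data.shape[:3], fine_voxel, coarse_voxel)
        return area_average(data, fine_voxel, coarse_voxel, coarse_shape)
    raise ValueError(f"unknown resampling mode {mode!r}")


def upsample_nearest_parent(data: np.ndarray, coarse_voxel, fine_voxel,
                            fine_shape) -> np.ndarray:
    """Each fine voxel inherits the value of the coarse voxel containing its
    centre (clamped at the boundary). Preserves the coarse series' intrinsic
    low-resolution content; trailing time axes pass through."""
    idx = []
    for ax in range(3):
        centres = (np.arange(fine_shape[ax]) + 0.5) * fine_voxel[ax]
        i = np.floor(centres / coarse_voxel[ax]).astype(int)
        idx.append(np.clip(i, 0, data.shape[ax] - 1))
    return data[np.ix_(idx[0], idx[1], idx[2])]
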