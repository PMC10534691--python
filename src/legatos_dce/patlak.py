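"""Patlak-plot estimation of low-level permeability.

Dividing the unidirectional-uptake model
``C_t = vp C_p + Ktrans int C_p`` by ``C_p`` gives the Patlak plot

    C_t(t)/C_p(t) = vp + Ktrans * (int_0^t C_p dtau) / C_p(t),

whose abscissa is the concentration-stretched time ``t_stretch`` (units of
time, not laboratory time). The hybrid variant used for normal-appearing
brain fixes ``vp`` from the extended Tofts fit of the same reconstructed
volume, leaving Ktrans as the only free parameter of a no-intercept
regression. Backflux makes the plot sub-linear, so Patlak Ktrans
underestimates the extended Tofts Ktrans wherever washout is non-negligible
(tumour); in low-permeability tissue the two agree.

Least squares is unweighted; the noise distortion introduced by the
linearising division is not re-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .containers import ImageSeries, VascularInputFunction

__all__ = ["patlak_transform", "PatlakModel", "PatlakResults",
           "fit_patlak_fixed_vp"]

#: frames with C_p below this fraction of the VIF peak are dropped
CP_FLOOR_FRACTION = 0.05


def _stretch_axis(times_s, cp, cp_floor):
    """t_stretch (min) and the usable-frame mask."""
    integ = cumulative_trapezoid(cp, np.asarray(times_s) / 60.0, initial=0.0)
    used = cp > cp_floor
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(used, integ / cp, np.nan)
    return x, used


def patlak_transform(conc_voxel: np.ndarray, vif: VascularInputFunction,
                     times_s=None, cp_floor_frac: float = CP_FLOOR_FRACTION):
    """Patlak coordinates for one voxel curve.

    Returns ``(x, y, used)`` with ``y = C_t/C_p`` and
    ``x = (int C_p)/C_p`` (minutes) on the frames where C_p exceeds the
    floor; dropped frames are reported through ``used``.
    """
    times_s = vif.times if times_s is None else np.asarray(times_s)
    cp = vif.cp_at(times_s)
    floor = cp_floor_frac * cp.max()
    x, used = _stretch_axis(times_s, cp, floor)
    if not used.any():
        raise ValueError("no frames with usable plasma concentration")
    y = np.where(used, np.asarray(conc_voxel, dtype=float) / np.where(used, cp, 1.0),
                 np.nan)
    return x[used], y[used], used


@dataclass
class PatlakResults:
    """Patlak fit per voxel: ``ktrans`` slope (min^-1), ``vp``
    (fixed input or fitted intercept), goodness-of-fit ``r2`` and the number
    of frames used."""

    ktrans: np.ndarray
    vp: np.ndarray
    r2: np.ndarray
    n_points_used: int
    vp_fixed: bool
    flags: np.ndarray
    mask: np.ndarray

    def summary(self) -> pd.DataFrame:
        ok = self.mask & ~self.flags
        rows = []
        for name, arr in (("ktrans", self.ktrans), ("vp", self.vp)):
            v = arr[ok]
            rows.append({"parameter": name, "n": int(v.size),
                         "median": float(np.median(v)) if v.size else np.nan,
                         "mean": float(np.mean(v)) if v.size else np.nan})
        df = pd.DataFrame(rows).set_index("parameter")
        df.attrs["vp_fixed"] = self.vp_fixed
        df.attrs["n_points_used"] = self.n_points_used
        return df


class PatlakModel:
    """Voxelwise Patlak regression over a concentration series.

    Parameters
    ----------
    conc : ImageSeries
    vif : VascularInputFunction
    mask : bool ndarray, optional
    vp_map : ndarray, optional
        Known plasma-volume map (e.g. from the extended Tofts fit); when
        given, Ktrans is the slope of the no-intercept regression of
        ``y - vp`` on ``t_stretch``. When absent the conventional
        two-parameter (slope + intercept) plot is fitted and the result is
        flagged accordingly.
    frame_window : slice or bool array, optional
        Frames entering the regression; default all frames above the C_p
        floor. For dual-temporal-resolution data pass the parenchymal-phase
        frames, where unidirectional uptake holds best.
    """

    def __init__(self, conc: ImageSeries, vif: VascularInputFunction,
                 mask=None, vp_map=None, frame_window=None,
                 cp_floor_frac: float = CP_FLOOR_FRACTION):
        self.conc = conc
        self.vif = vif
        self.mask = (np.ones(conc.shape, dtype=bool) if mask is None
                     else np.asarray(mask, dtype=bool))
        if vp_map is not None:
            vp_map = np.asarray(vp_map, dtype=float)
            if vp_map.shape != conc.shape:
                raise ValueError("vp_map grid mismatch")
        self.vp_map = vp_map
        t = conc.times
        cp = vif.cp_at(t)
        floor = cp_floor_frac * cp.max()
        x, used = _stretch_axis(t, cp, floor)
        if frame_window is not None:
            sel = np.zeros(t.size, dtype=bool)
            sel[frame_window] = True
            used &= sel
        if not used.any():
            raise ValueError("no usable frames for the Patlak regression")
        self.used = used
        self.x = x[used]
        self.cp_used = cp[used]

    def fit(self) -> PatlakResults:
        y = self.conc.data[..., self.used] / self.cp_used
        x = self.x
        m = self.mask
        shape = self.conc.shape
        kt = np.zeros(shape)
        r2 = np.zeros(shape)
        flags = ~m
        if self.vp_map is not None:
            vp = self.vp_map
            resid0 = y - vp[..., None]
            sxx = float(np.dot(x, x))
            kt_m = resid0 @ x / sxx
            pred = kt_m[..., None] * x
            ss_res = ((resid0 - pred) ** 2).sum(-1)
            ss_tot = (resid0 ** 2).sum(-1)
            vp_fixed = True
        else:
            xm = x.mean()
            dx = x - xm
            sxx = float(np.dot(dx, dx))
            ym = y.mean(-1)
            kt_m = (y - ym[..., None]) @ dx / sxx
            vp = ym - kt_m * xm
            pred = vp[..., None] + kt_m[..., None] * x
            ss_res = ((y - pred) ** 2).sum(-1)
            ss_tot = ((y - ym[..., None]) ** 2).sum(-1)
            vp_fixed = False
        with np.errstate(divide="ignore", invalid="ignore"):
            r2_m = 1.0 - ss_res / ss_tot
        kt = np.where(m, kt_m, 0.0)
        r2 = np.where(m & np.isfinite(r2_m), r2_m, 0.0)
        return PatlakResults(ktrans=kt, vp=np.where(m, vp, 0.0), r2=r2,
                             n_points_used=int(self.used.sum()),
                             vp_fixed=vp_fixed, flags=flags, mask=m)


def fit_patlak_fixed_vp(conc: ImageSeries, vif: VascularInputFunction,
                        vp_map: np.ndarray | None, mask=None,
                        frame_window=None) -> PatlakResults:
    """Hybrid low-level-permeability Ktrans with vp fixed from the extended
    Tofts fit. A missing ``vp_map`` falls back to the two-parameter Patlak
    plot (the result's ``vp_fixed`` flag records which was used)."""
    return PatlakModel(conc, vif, mask=mask, vp_map=vp_map,
                       frame_window=frame_window).fit()
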