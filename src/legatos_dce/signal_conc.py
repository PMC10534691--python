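"""Variable-flip-angle T1 mapping and SPGR signal <-> concentration
conversion.

The spoiled gradient-echo steady-state signal is

    S = M0 sin(a) (1 - E1) / (1 - E1 cos(a)),   E1 = exp(-TR * R1),

and contrast concentration acts through the linear (fast-water-exchange)
relaxivity model R1(t) = R1_0 + r1 * C(t). No water-exchange or B1
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .acquisition import AcquisitionSpec
from .containers import ImageSeries

__all__ = ["spgr_signal", "VfaT1Model", "T1MapResults", "fit_vfa_t1",
           "signal_to_concentration", "concentration_to_signal"]


def spgr_signal(m0, r1, flip_angle_deg, tr):
    """SPGR steady-state signal; broadcasts over voxel arrays."""
    a = np.deg2rad(flip_angle_deg)
    e1 = np.exp(-tr * np.asarray(r1, dtype=float))
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


def _invert_spgr(signal, m0, flip_angle_deg, tr):
    """Solve the SPGR equation for E1; returns (e1, valid)."""
    a = np.deg2rad(flip_angle_deg)
    ms = np.asarray(m0, dtype=float) * np.sin(a)
    s = np.asarray(signal, dtype=float)
    denom = ms - s * np.cos(a)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (ms - s) / denom
    valid = np.isfinite(e1) & (e1 > 0.0) & (e1 < 1.0) & (denom > 0)
    return e1, valid


@dataclass
class T1MapResults:
    """Voxelwise baseline relaxation fit.

    ``r1_0`` is the pre-contrast longitudinal relaxation rate (s^-1), ``m0``
    the equilibrium signal scale; ``valid`` is False where the fit failed
    (flagged, never silently zeroed)."""

    r1_0: np.ndarray
    m0: np.ndarray
    fit_residual: np.ndarray
    valid: np.ndarray
    method: str

    @property
    def t1_0(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.where(self.valid, 1.0 / self.r1_0, np.nan)

    def summary(self) -> pd.DataFrame:
        v = self.valid
        rows = {"n_voxels": int(v.size), "n_valid": int(v.sum())}
        for name, arr in (("T1_0_s", self.t1_0), ("M0", self.m0)):
            vals = arr[v]
            rows[f"{name}_median"] = float(np.median(vals)) if vals.size else np.nan
        return pd.DataFrame([rows])


class VfaT1Model:
    """Variable-flip-angle T1 estimation from multi-angle SPGR baselines.

    Parameters
    ----------
    signals : ndarray, shape (n_angles, ...) or dict {angle_deg: volume}
    flip_angles_deg : sequence of float (ignored when a dict is given)
    tr : float, seconds
    mask : bool ndarray, optional
    """

    def __init__(self, signals, flip_angles_deg=None, tr=0.0045, mask=None):
        if isinstance(signals, dict):
            flip_angles_deg = sorted(signals)
            signals = np.stack([signals[a] for a in flip_angles_deg])
        self.signals = np.asarray(signals, dtype=float)
        self.angles = np.asarray(flip_angles_deg, dtype=float)
        if self.angles.size < 2 or np.unique(self.angles).size < 2:
            raise ValueError("need at least two distinct flip angles")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("non-finite signals")
        self.tr = float(tr)
        self.mask = mask

    def fit(self, method: str = "linear") -> T1MapResults:
        """method='linear' is the DESPOT1 linearised solve
        (y = S/sin(a) against x = S/tan(a), slope E1); method='nls' polishes
        it with per-voxel nonlinear least squares."""
        a = np.deg2rad(self.angles).reshape((-1,) + (1,) * (self.signals.ndim - 1))
        s = self.signals
        y = s / np.sin(a)
        x = s / np.tan(a)
        n = self.angles.size
        xm, ym = x.mean(0), y.mean(0)
        sxx = ((x - xm) ** 2).sum(0)
        with np.errstate(divide="ignore", invalid="ignore"):
            e1 = ((x - xm) * (y - ym)).sum(0) / sxx
        b = ym - e1 * xm
        valid = (np.isfinite(e1) & (e1 > 0) & (e1 < 1) & (b > 0)
                 & (s > 0).all(axis=0))
        if self.mask is not None:
            valid &= self.mask
        with np.errstate(divide="ignore", invalid="ignore"):
            r1 = -np.log(np.clip(e1, 1e-12, 1 - 1e-12)) / self.tr
            m0 = b / (1.0 - np.clip(e1, 1e-12, 1 - 1e-12))
        r1 = np.where(valid, r1, np.nan)
        m0 = np.where(valid, m0, np.nan)

        if method == "nls":
            it = np.ndindex(s.shape[1:]) if s.ndim > 1 else [()]
            for ix in it:
                if not valid[ix]:
                    continue
                sv = s[(slice(None),) + ix]

                def resid(p):
                    return spgr_signal(p[0], p[1], self.angles, self.tr) - sv

                sol = least_squares(resid, x0=[m0[ix], r1[ix]],
                                    bounds=([0, 1e-3], [np.inf, 100.0]))
                m0[ix], r1[ix] = sol.x
        elif method != "linear":
            raise ValueError(f"unknown method {method!r}")

        pred = spgr_signal(m0, r1, a, self.tr)
        sq = np.nansum((pred - s) ** 2, axis=0)
        res = np.sqrt(np.where(valid, sq, np.nan) / n)
        return T1MapResults(r1_0=r1, m0=m0, fit_residual=res, valid=valid,
                            method=method)


def fit_vfa_t1(vfa_volumes, spec: AcquisitionSpec | None = None, mask=None,
               flip_angles_deg=None, tr=None, method="linear") -> T1MapResults:
    """Functional wrapper around :class:`VfaT1Model`."""
    tr = tr if tr is not None else (spec.tr if spec else 0.0045)
    return VfaT1Model(vfa_volumes, flip_angles_deg, tr=tr, mask=mask).fit(method)


def signal_to_concentration(series: ImageSeries, t1map: T1MapResults,
                            spec: AcquisitionSpec,
                            n_baseline_frames: int | None = 10) -> ImageSeries:
    """Convert a dynamic SPGR series to gadolinium concentration.

    When ``n_baseline_frames`` is given, the per-voxel signal scale is
    anchored on the pre-bolus baseline mean together with the VFA R1_0 (so the
    baseline concentration is ~0 by construction). When ``None`` (a series
    with no unenhanced baseline, e.g. the parenchymal-phase series of a
    dual-injection protocol), the VFA-fitted M0 is used directly.

    Enhancement outside the invertible range of the SPGR equation is clamped
    and flagged.
    """
    s = series.data
    a = spec.flip_angle_deg
    r1_0 = t1map.r1_0
    if n_baseline_frames is not None:
        if n_baseline_frames < 1 or n_baseline_frames > series.n_frames:
            raise ValueError("invalid number of baseline frames")
        s0 = s[..., :n_baseline_frames].mean(axis=-1)
        e10 = np.exp(-spec.tr * r1_0)
        sin_a, cos_a = np.sin(np.deg2rad(a)), np.cos(np.deg2rad(a))
        with np.errstate(divide="ignore", invalid="ignore"):
            m0 = s0 * (1.0 - e10 * cos_a) / (sin_a * (1.0 - e10))
    else:
        m0 = t1map.m0

    e1, ok = _invert_spgr(s, m0[..., None], a, spec.tr)
    e1 = np.clip(np.where(ok, e1, np.nan), 1e-12, 1 - 1e-12)
    with np.errstate(invalid="ignore"):
        r1_t = -np.log(e1) / spec.tr
        conc = (r1_t - r1_0[..., None]) / spec.relaxivity_r1
    bad_voxel = ~t1map.valid | ~ok.all(axis=-1)
    # clamp non-invertible frames to the nearest finite value (flagged above)
    conc = np.where(np.isfinite(conc), conc, 0.0)
    conc[~t1map.valid] = 0.0
    return ImageSeries(data=conc, times=series.times,
                       voxel_size=series.voxel_size, units="mM",
                       affine=series.affine, flags=bad_voxel)


def concentration_to_signal(conc: ImageSeries, t1map: T1MapResults,
                            spec: AcquisitionSpec) -> ImageSeries:
    """Forward SPGR encoding of a concentration series (inverse pair of
    :func:`signal_to_concentration` on the invertible domain)."""
    r1 = t1map.r1_0[..., None] + spec.relaxivity_r1 * conc.data
    sig = spgr_signal(t1map.m0[..., None], r1, spec.flip_angle_deg, spec.tr)
    return ImageSeries(data=sig, times=conc.times, voxel_size=conc.voxel_size,
                       units="signal", affine=conc.affine, flags=conc.flags)
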