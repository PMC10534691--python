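"""Early-time-points microsphere cerebral blood flow.

Within an early time window (ETW) in which no tracer has yet left the
tissue, the microsphere model holds:

    C_t(t) = f * int_0^t C_b(t') dt',   t in ETW,

so the absolute blood flow ``f`` (mL min^-1 mL^-1) is the slope of the
no-intercept regression of C_t on the running integral of the whole-blood
input. The window runs from bolus arrival to the first-pass peak of the VIF
(a conservative venous-outflow-free surrogate). High-spatial-resolution CBF
follows either by rescaling the coarse-grid map with the LEGATOS calibration
ratio or by estimating directly on the rescaled concatenated volume; the
estimator is linear in C_t, so the two routes agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .containers import ImageSeries, VascularInputFunction
from .resample import upsample_nearest_parent

__all__ = ["EarlyTimeWindow", "select_etw", "estimate_cbf_et",
           "rescale_cbf_to_hs", "detect_bolus_arrival"]


class PeaklessVifError(ValueError):
    """The VIF has no detectable first-pass peak."""


@dataclass(frozen=True)
class EarlyTimeWindow:
    """Frame window [start_index, end_index] on the high-temporal time base,
    with the selection rule recorded for provenance."""

    start_index: int
    end_index: int
    selection_rule_id: str = "arrival-to-vif-peak"

    def __post_init__(self):
        if self.end_index < self.start_index or self.start_index < 0:
            raise ValueError("empty early time window")

    @property
    def slice(self) -> slice:
        return slice(self.start_index, self.end_index + 1)


def detect_bolus_arrival(times, curve, n_baseline: int = 10,
                         k_sd: float = 3.0) -> int:
    """First of two consecutive frames with clear enhancement.

    The threshold is baseline mean + ``k_sd`` * baseline SD, with the
    baseline taken from the leading frames below 5% of peak (at most
    ``n_baseline``); a floor of 5% of peak guards against a noise-free or
    very short baseline, and the two-frame requirement rejects single
    noise spikes."""
    curve = np.asarray(curve, dtype=float)
    if curve.size < 3:
        raise PeaklessVifError("curve too short")
    floor = 0.05 * curve.max()
    pre = np.flatnonzero(curve >= floor)
    n0 = int(pre[0]) if pre.size else 0
    base = curve[:min(n0, n_baseline)]
    thr = floor
    if base.size >= 3:
        thr = max(thr, base.mean() + k_sd * base.std())
    above = curve > thr
    sustained = np.flatnonzero(above[:-1] & above[1:])
    if sustained.size == 0:
        raise PeaklessVifError("no bolus arrival detected")
    return int(sustained[0])


def select_etw(vif: VascularInputFunction, n_baseline: int = 10,
               k_sd: float = 3.0) -> EarlyTimeWindow:
    """Window from bolus arrival to the VIF first-pass peak.

    The peak is located on a lightly smoothed copy of the curve (3-point
    moving average): the first pass has a flat top, where frame noise
    otherwise jitters the argmax and asymmetrically lengthens the window.
    A VIF that is still rising at its final sample has no resolved first
    pass and is rejected.
    """
    cp = vif.cp
    start = detect_bolus_arrival(vif.times, cp, n_baseline, k_sd)
    smooth = np.convolve(cp, np.ones(3) / 3.0, mode="same") \
        if cp.size >= 3 else cp
    peak = int(np.argmax(smooth))
    if peak <= start or int(np.argmax(cp)) >= cp.size - 1 \
            or peak >= cp.size - 2:
        raise PeaklessVifError("VIF has no first-pass peak after arrival")
    return EarlyTimeWindow(start_index=start, end_index=peak)


def estimate_cbf_et(conc_ht: ImageSeries, vif: VascularInputFunction,
                    etw: EarlyTimeWindow) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise early-time-points CBF map (mL min^-1 mL^-1).

    Regresses C_t(t) on the running integral of the whole-blood concentration
    (no intercept — the model has none) over the ETW frames. Returns
    ``(cbf, flags)``; voxels are flagged where the integrated blood
    concentration carries no signal. Invariant to a common time shift of
    tissue and blood curves.
    """
    t = conc_ht.times
    if etw.end_index >= t.size:
        raise ValueError("early time window exceeds the series")
    cb = vif.cb
    if vif.times.shape != t.shape or not np.allclose(vif.times, t):
        cb = np.interp(t, vif.times, cb, left=0.0, right=cb[-1])
    x_full = cumulative_trapezoid(cb, t / 60.0, initial=0.0)  # mM * min
    x = x_full[etw.slice]
    sxx = float(np.dot(x, x))
    if sxx <= 0:
        raise ValueError("integrated blood concentration is zero in the window")
    y = conc_ht.data[..., etw.slice]
    cbf = y @ x / sxx
    flags = ~np.isfinite(cbf)
    return np.where(flags, 0.0, cbf), flags


def rescale_cbf_to_hs(cbf_ht: np.ndarray, ratio_calib: np.ndarray,
                      ldht_voxel, hs_voxel,
                      flags_ht: np.ndarray | None = None):
    """High-spatial CBF: upsample the coarse map by nearest-parent block
    assignment and multiply voxelwise by the calibration ratio
    (CBF_ET-HS = CBF_ET-HT * ratio_calib). Flags propagate."""
    up = upsample_nearest_parent(cbf_ht, ldht_voxel, hs_voxel,
                                 ratio_calib.shape)
    if up.shape != ratio_calib.shape:
        raise ValueError("calibration-ratio grid mismatch")
    out = up * ratio_calib
    if flags_ht is None:
        return out, np.zeros_like(out, dtype=bool)
    fl = upsample_nearest_parent(flags_ht.astype(np.uint8), ldht_voxel,
                                 hs_voxel, ratio_calib.shape).astype(bool)
    return out, fl
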