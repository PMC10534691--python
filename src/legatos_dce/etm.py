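"""Voxelwise extended Tofts model fitting.

The model::

    C_t(t) = vp C_p(t) + Ktrans \\int_0^t C_p(tau) exp(-(Ktrans/ve)(t-tau)) dtau

is fitted per voxel by bounded nonlinear least squares with a small fixed set
of multi-start initialisations. The convolution is evaluated by an
exponential-kernel recursion that is exact for piecewise-linear C_p on the
(non-uniform) dual-temporal-resolution time base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from ._kinetics import expconv, etm_curve
from .containers import ImageSeries, VascularInputFunction

__all__ = ["etm_forward", "ExtendedToftsModel", "KineticMapsResults", "fit_etm"]

#: status flag bits
FLAG_ALLZERO = 1
FLAG_BOUND = 2
FLAG_NOCONV = 4

_DEFAULT_BOUNDS = ((0.0, 5.0), (0.0, 1.0), (1e-3, 1.0))  # Ktrans, vp, ve
_DEFAULT_STARTS = ((0.05, 0.01, 0.2), (0.3, 0.05, 0.4), (0.8, 0.1, 0.7))


def etm_forward(ktrans: float, vp: float, ve: float,
                vif: VascularInputFunction, times_s) -> np.ndarray:
    """Extended Tofts tissue curve for a VIF sampled onto ``times_s``
    (seconds). Exact for piecewise-linear C_p."""
    times_s = np.asarray(times_s, dtype=float)
    cp = vif.cp_at(times_s)
    return etm_curve(ktrans, vp, ve, cp, times_s)


@dataclass
class KineticMapsResults:
    """Voxelwise kinetic parameter maps with fit diagnostics.

    ``ktrans`` (min^-1), ``vp``/``ve`` (fractions), ``fit_rmse`` (mM) and a
    bitmask ``flags`` (1 = all-zero input, 2 = bound hit, 4 = not converged)
    on the fitted grid. Derived flow/permeability maps (``cbf``, ``fp``,
    ``ps``, ``rfp``) may be attached by the downstream stages."""

    ktrans: np.ndarray
    vp: np.ndarray
    ve: np.ndarray
    fit_rmse: np.ndarray
    flags: np.ndarray
    mask: np.ndarray
    voxel_size: tuple[float, float, float] | None = None
    extra: dict = field(default_factory=dict)

    @property
    def n_fitted(self) -> int:
        return int(self.mask.sum())

    @property
    def ok(self) -> np.ndarray:
        """Voxels fitted without any quality flag."""
        return self.mask & (self.flags == 0)

    def __getitem__(self, name: str) -> np.ndarray:
        if name in ("ktrans", "vp", "ve", "fit_rmse"):
            return getattr(self, name)
        return self.extra[name]

    def params(self) -> dict[str, np.ndarray]:
        out = {"ktrans": self.ktrans, "vp": self.vp, "ve": self.ve}
        out.update(self.extra)
        return out

    def plot_map(self, name: str = "ktrans", z: int | None = None, ax=None,
                 **imshow_kw):
        """Axial slice of one parameter map (flagged voxels masked)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        vol = np.where(self.ok, self[name], np.nan)
        z = vol.shape[2] // 2 if z is None else z
        im = ax.imshow(vol[:, :, z].T, origin="lower", **imshow_kw)
        ax.set_title(name)
        plt.colorbar(im, ax=ax)
        return ax

    def summary(self) -> pd.DataFrame:
        """Median/mean table of the unflagged fitted voxels."""
        ok = self.ok
        rows = []
        for name, arr in self.params().items():
            v = arr[ok]
            v = v[np.isfinite(v)]
            rows.append({"parameter": name,
                         "n": int(v.size),
                         "median": float(np.median(v)) if v.size else np.nan,
                         "mean": float(np.mean(v)) if v.size else np.nan,
                         "sd": float(np.std(v, ddof=1)) if v.size > 1 else np.nan})
        df = pd.DataFrame(rows).set_index("parameter")
        df.attrs["n_fitted"] = self.n_fitted
        df.attrs["n_flagged"] = int((self.mask & (self.flags != 0)).sum())
        return df


class ExtendedToftsModel:
    """Extended Tofts model over a concentration series.

    Parameters
    ----------
    conc : ImageSeries
        4D concentration volume (mM); the VIF must share its time base span.
    vif : VascularInputFunction
        Plasma input in the same concentration units as ``conc``.
    mask : ndarray of bool, optional
        Voxels to fit (default: all).
    bounds : ((lo, hi), ...) for (Ktrans, vp, ve)
        Box constraints; defaults Ktrans in [0, 5] min^-1, vp in [0, 1],
        ve in [1e-3, 1].
    delay_s : float
        Global bolus-arrival shift applied to the VIF (a single shift, not
        per voxel).
    """

    def __init__(self, conc: ImageSeries, vif: VascularInputFunction,
                 mask=None, bounds=_DEFAULT_BOUNDS, delay_s: float = 0.0,
                 starts=_DEFAULT_STARTS):
        self.conc = conc
        self.vif = vif
        self.times = np.asarray(conc.times, dtype=float)
        self.cp = vif.cp_at(self.times - delay_s)
        if mask is None:
            mask = np.ones(conc.shape, dtype=bool)
        self.mask = np.asarray(mask, dtype=bool)
        if self.mask.shape != conc.shape:
            raise ValueError("mask does not match the series grid")
        self.bounds = bounds
        self.starts = [np.asarray(s, dtype=float) for s in starts]
        self._tmin = self.times / 60.0

    # -- single-curve machinery ------------------------------------------

    def _predict(self, theta, out=None):
        kt, vp, ve = theta
        return vp * self.cp + kt * expconv(self._tmin, self.cp, kt / max(ve, 1e-12))

    def fit_curve(self, y: np.ndarray):
        """Fit one concentration-time curve; returns (theta, rmse, flags)."""
        if not np.any(y):
            return np.zeros(3), 0.0, FLAG_ALLZERO
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])

        def resid(th):
            return self._predict(th) - y

        best = None
        for x0 in self.starts:
            sol = least_squares(resid, np.clip(x0, lo, hi), bounds=(lo, hi),
                                method="trf", xtol=1e-12, ftol=1e-12,
                                gtol=1e-12, max_nfev=200)
            if best is None or sol.cost < best.cost:
                best = sol
        flags = 0
        if best.status <= 0:
            flags |= FLAG_NOCONV
        atol = 1e-9 + 1e-6 * (hi - lo)
        # a Ktrans estimate resting on its physical zero is not a failure
        hit = (np.abs(best.x - hi) < atol) | (np.abs(best.x - lo) < atol)
        hit[0] &= best.x[0] > atol[0]
        if np.any(hit):
            flags |= FLAG_BOUND
        rmse = float(np.sqrt(2.0 * best.cost / y.size))
        return best.x, rmse, flags

    # -- volume fit -------------------------------------------------------

    def fit(self) -> KineticMapsResults:
        shape = self.conc.shape
        kt = np.zeros(shape)
        vp = np.zeros(shape)
        ve = np.zeros(shape)
        rmse = np.zeros(shape)
        flags = np.zeros(shape, dtype=np.int8)
        data = self.conc.data
        for ix in zip(*np.nonzero(self.mask)):
            theta, r, f = self.fit_curve(data[ix])
            kt[ix], vp[ix], ve[ix] = theta
            rmse[ix], flags[ix] = r, f
        return KineticMapsResults(ktrans=kt, vp=vp, ve=ve, fit_rmse=rmse,
                                  flags=flags, mask=self.mask,
                                  voxel_size=self.conc.voxel_size)

    def plot_fit(self, index, results: KineticMapsResults, ax=None):
        """Measured curve and fitted model for one voxel."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y = self.conc.curve(index)
        theta = (results.ktrans[index], results.vp[index], results.ve[index])
        ax.plot(self.times, y, ".", label="measured")
        ax.plot(self.times, self._predict(theta), "-", label="extended Tofts")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("concentration (mM)")
        ax.legend()
        return ax


def fit_etm(conc: ImageSeries, vif: VascularInputFunction, mask=None,
            **kw) -> KineticMapsResults:
    """Functional wrapper: ``ExtendedToftsModel(conc, vif, mask).fit()``."""
    return ExtendedToftsModel(conc, vif, mask=mask, **kw).fit()
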