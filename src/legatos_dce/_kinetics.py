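"""Low-level tracer-kinetic forward models.

All kernels work on a strictly increasing time base in *minutes* and treat the
driving plasma curve as piecewise linear between samples, for which the
exponential convolution is evaluated exactly per segment (recursion, not FFT:
the dual-temporal-resolution time base is non-uniform).

Rate-type parameters (``fp``, ``ps``, ``ktrans``, ``kep``) are in min^-1 /
mL min^-1 mL^-1; volume fractions are dimensionless.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "expconv",
    "etm_curve",
    "tcxm_curve",
    "aath_curve",
    "ktrans_from_fp_ps",
]


@njit(cache=False)
def expconv(t: np.ndarray, c: np.ndarray, k: float) -> np.ndarray:
    """Exact ``\\int_0^t c(tau) exp(-k (t - tau)) dtau`` for piecewise-linear c.

    ``k = 0`` degenerates to the running integral of ``c`` (trapezoid-exact
    for piecewise-linear input).
    """
    n = t.shape[0]
    out = np.zeros(n)
    for i in range(1, n):
        dt = t[i] - t[i - 1]
        c0 = c[i - 1]
        slope = (c[i] - c0) / dt
        x = k * dt
        if x > 1e-4:
            e = np.exp(-x)
            a0 = (1.0 - e) / k
            a1 = (dt * (1.0 - e) - (1.0 - e - x * e) / k) / k
            out[i] = out[i - 1] * e + c0 * a0 + slope * a1
        else:
            # series expansion: avoids catastrophic cancellation for k*dt -> 0
            e = np.exp(-x)
            a0 = dt * (1.0 - x / 2.0 + x * x / 6.0)
            a1 = dt * dt * (0.5 - x / 6.0 + x * x / 24.0)
            out[i] = out[i - 1] * e + c0 * a0 + slope * a1
    return out


def _as_minutes(t_s: np.ndarray) -> np.ndarray:
    t = np.asarray(t_s, dtype=float) / 60.0
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time base must be 1-D with at least two samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time base must be strictly increasing")
    return t


def etm_curve(ktrans: float, vp: float, ve: float,
              cp: np.ndarray, t_s: np.ndarray) -> np.ndarray:
    """Extended Tofts tissue curve.

    C_t(t) = vp*C_p(t) + Ktrans * int_0^t C_p(tau) exp(-Ktrans/ve (t-tau)) dtau

    Parameters
    ----------
    ktrans : float
        Transfer constant (min^-1).
    vp, ve : float
        Plasma / extravascular-extracellular volume fractions.
    cp : ndarray
        Plasma concentration (mM) sampled on ``t_s``.
    t_s : ndarray
        Time base in seconds, strictly increasing.
    """
    if ktrans < 0 or vp < 0 or ve < 0:
        raise ValueError("negative kinetic parameters")
    t = _as_minutes(t_s)
    cp = np.ascontiguousarray(cp, dtype=float)
    if ktrans == 0.0:
        return vp * cp
    if ve <= 0:
        raise ValueError("ve must be > 0 when ktrans > 0")
    kep = ktrans / ve
    return vp * cp + ktrans * expconv(t, cp, kep)


def ktrans_from_fp_ps(fp: float, ps: float) -> float:
    """Flow/permeability hybrid transfer constant Ktrans = Fp*PS/(Fp+PS)."""
    if fp == 0.0 and ps == 0.0:
        return 0.0
    if np.isinf(fp):
        return ps
    return fp * ps / (fp + ps)


def tcxm_curve(fp: float, ps: float, vp: float, ve: float,
               cp: np.ndarray, t_s: np.ndarray) -> np.ndarray:
    """Two-compartment exchange model (2CXM) tissue curve.

    Solves::

        vp dC1/dt = Fp (C_p - C1) + PS (C2 - C1)
        ve dC2/dt = PS (C1 - C2)
        C_t = vp C1 + ve C2

    exactly per segment of a piecewise-linear C_p via eigendecomposition of the
    2x2 system (each eigenmode is an exponential convolution).

    Limiting cases are handled analytically: ``fp = inf`` (fast exchange)
    reduces to the extended Tofts model with Ktrans = PS; ``ps = 0`` or
    ``ve = 0`` to a single well-mixed plasma compartment; ``vp = 0`` to the
    Kety/Tofts model with Ktrans = Fp*PS/(Fp+PS).
    """
    if ps < 0 or vp < 0 or ve < 0 or (not np.isinf(fp) and fp < 0):
        raise ValueError("negative kinetic parameters")
    if vp + ve > 1.0 + 1e-12:
        raise ValueError("vp + ve must not exceed 1")
    t = _as_minutes(t_s)
    cp = np.ascontiguousarray(cp, dtype=float)

    if fp == 0.0 or (vp == 0.0 and ve == 0.0):
        return np.zeros_like(cp)
    if np.isinf(fp):
        # fast-exchange limit: plasma compartment tracks C_p instantaneously
        if ps == 0.0 or ve == 0.0:
            return vp * cp
        return etm_curve(ps, vp, ve, cp, t_s)
    if ps == 0.0 or ve == 0.0:
        # no extraction: single plasma compartment with rate Fp/vp
        if vp == 0.0:
            return np.zeros_like(cp)
        return fp * expconv(t, cp, fp / vp)
    if vp == 0.0:
        kt = ktrans_from_fp_ps(fp, ps)
        return etm_curve(kt, 0.0, ve, cp, t_s)

    a = (fp + ps) / vp
    b = ps / vp
    c = ps / ve
    tr = -(a + c)
    disc = (a - c) ** 2 + 4.0 * b * c
    sq = np.sqrt(disc)
    lam1 = 0.5 * (tr + sq)
    lam2 = 0.5 * (tr - sq)
    # mode weights for unit input into the plasma compartment
    w = (fp / vp) * c / (lam1 - lam2)
    z1 = w * expconv(t, cp, -lam1)
    z2 = -w * expconv(t, cp, -lam2)
    x1 = (c + lam1) / c * z1 + (c + lam2) / c * z2
    x2 = z1 + z2
    ct = vp * x1 + ve * x2
    # tiny negative excursions from float cancellation only
    return np.where(ct < 0, 0.0, ct)


def aath_curve(fp: float, ps: float, vp: float, ve: float,
               cp: np.ndarray, t_s: np.ndarray) -> np.ndarray:
    """Adiabatic tissue-homogeneity (plug-flow capillary) tissue curve.

    The vascular space is a plug-flow tube with transit time Tc = vp/Fp, so
    no tracer reaches the venous outflow before one full transit — the regime
    the early-time-points microsphere model presumes. After the transit the
    extracted fraction E = 1 - exp(-PS/Fp) washes out of the interstitium at
    k_ep = E*Fp/ve. Impulse residue::

        R(s) = 1                          0 <= s < Tc
        R(s) = E exp(-k_ep (s - Tc))      s >= Tc

    and C_t = Fp (C_p * R). Shares the (Fp, PS, vp, ve) parameterisation of
    the two-compartment exchange model.
    """
    if ps < 0 or vp < 0 or ve < 0 or (not np.isinf(fp) and fp < 0):
        raise ValueError("negative kinetic parameters")
    t = _as_minutes(t_s)
    cp = np.ascontiguousarray(cp, dtype=float)
    if fp == 0.0 or (vp == 0.0 and ve == 0.0):
        return np.zeros_like(cp)
    if np.isinf(fp):
        if ps == 0.0 or ve == 0.0:
            return vp * cp
        return etm_curve(ps, vp, ve, cp, t_s)
    if vp == 0.0:
        kt = ktrans_from_fp_ps(fp, ps)
        return etm_curve(kt, 0.0, ve, cp, t_s)
    tc = vp / fp
    integral = np.concatenate([[0.0], np.cumsum(
        0.5 * (cp[1:] + cp[:-1]) * np.diff(t))])
    i_shift = np.interp(t - tc, t, integral, left=0.0)
    vasc = integral - i_shift
    if ps == 0.0 or ve == 0.0:
        return fp * vasc
    e = 1.0 - np.exp(-ps / fp)
    kep = e * fp / ve
    ec = expconv(t, cp, kep)
    ec_shift = np.interp(t - tc, t, ec, left=0.0)
    return fp * (vasc + e * ec_shift)
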