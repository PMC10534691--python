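"""Separation of the hybrid transfer constant into flow and permeability.

With Ktrans = Fp*PS/(Fp + PS), a flow estimate from the microsphere stage
(Fp = CBF_ET * (1 - Hct)) lets PS be recovered as

    PS = Ktrans / (1 - Ktrans/Fp),

and the flow-to-(flow+permeability) ratio

    R_Fp = Ktrans/PS = Fp/(Fp + PS)

ranges over (0, 1]: ~1 where permeability limits uptake, small where flow
does. Voxels with Ktrans >= Fp (PS undefined/unphysical) are flagged and
excluded from ROI statistics rather than clipped, so medians are never
driven by a cap value.
"""

from __future__ import annotations

import numpy as np

from .acquisition import DEFAULT_HCT

__all__ = ["fp_from_cbf", "ps_from_ktrans_fp", "rfp_from_fp_ps",
           "derive_flow_permeability"]

#: Ktrans/Fp above which the PS denominator (< 0.05) is deemed unstable
UNSTABLE_RATIO = 0.95


def fp_from_cbf(cbf: np.ndarray, hct: float = DEFAULT_HCT) -> np.ndarray:
    """Plasma flow from whole-blood flow: Fp = CBF_ET * (1 - Hct)."""
    if not (0 <= hct < 1):
        raise ValueError("hct must be in [0, 1)")
    return np.asarray(cbf, dtype=float) * (1.0 - hct)


def ps_from_ktrans_fp(ktrans: np.ndarray, fp: np.ndarray):
    """Permeability-surface area product PS = Ktrans / (1 - Ktrans/Fp).

    Returns ``(ps, flags)``. Flagged (NaN) voxels: Ktrans/Fp above
    ``UNSTABLE_RATIO`` (including Ktrans >= Fp) or Fp = 0 with Ktrans > 0.
    """
    ktrans = np.asarray(ktrans, dtype=float)
    fp = np.asarray(fp, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(fp > 0, ktrans / fp, np.inf)
        ps = ktrans / (1.0 - ratio)
    flags = (ratio > UNSTABLE_RATIO) & (ktrans > 0)
    ps = np.where(ktrans == 0, 0.0, ps)
    ps = np.where(flags, np.nan, ps)
    return ps, flags


def rfp_from_fp_ps(fp: np.ndarray, ps: np.ndarray):
    """R_Fp = Fp/(Fp + PS) in [0, 1]; flagged (NaN) where Fp + PS = 0."""
    fp = np.asarray(fp, dtype=float)
    ps = np.asarray(ps, dtype=float)
    denom = fp + ps
    with np.errstate(divide="ignore", invalid="ignore"):
        rfp = fp / denom
    flags = ~(denom > 0) | ~np.isfinite(rfp)
    return np.where(flags, np.nan, rfp), flags


def derive_flow_permeability(ktrans: np.ndarray, cbf: np.ndarray,
                             hct: float = DEFAULT_HCT) -> dict[str, np.ndarray]:
    """Fp, PS and R_Fp maps from Ktrans and CBF_ET; combined flag volume
    under ``'flags'``."""
    fp = fp_from_cbf(cbf, hct)
    ps, f1 = ps_from_ktrans_fp(ktrans, fp)
    rfp, f2 = rfp_from_fp_ps(fp, ps)
    return {"fp": fp, "ps": ps, "rfp": rfp, "flags": f1 | f2}
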