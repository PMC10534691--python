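"""End-to-end multi-model analysis of a dual-injection acquisition.

Chains the full method: signal -> concentration conversion for both series,
surrogate-VIF extraction and dual-injection concatenation, LEGATOS
reconstruction, extended Tofts fitting, early-time-points CBF with
calibration-ratio rescaling, flow/permeability separation (Fp, PS, R_Fp) and
the hybrid fixed-vp Patlak fit for low-level permeability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import DEFAULT_HCT
from .containers import ImageSeries, VascularInputFunction
from .dro import DualAcquisition
from .etcbf import estimate_cbf_et, rescale_cbf_to_hs, select_etw
from .etm import ExtendedToftsModel, KineticMapsResults
from .legatos import DTRVolume, legatos_reconstruct
from .patlak import PatlakResults, fit_patlak_fixed_vp
from .ps_derivation import derive_flow_permeability
from .resample import downsample
from .signal_conc import fit_vfa_t1, signal_to_concentration
from .vif import concatenate_dual_injection_vif, extract_vif

__all__ = ["AnalysisResult", "reconstruct_concentrations", "analyze"]


@dataclass
class AnalysisResult:
    """All intermediate and final products of one analysis run."""

    ldht_conc: ImageSeries
    fdhs_conc: ImageSeries
    vif: VascularInputFunction            # full-dose units, concatenated
    recon: ImageSeries                    # rescaled high-spatiotemporal volume
    dtr: DTRVolume
    etm: KineticMapsResults
    cbf_ht: np.ndarray
    cbf_hs: np.ndarray
    patlak: PatlakResults | None = None
    extras: dict = field(default_factory=dict)

    @property
    def maps(self) -> dict[str, np.ndarray]:
        out = self.etm.params()
        out["cbf"] = self.cbf_hs
        return out


def _pool_t1(t1map, mask):
    """Blood T1 is one tissue: replace the per-voxel baseline fit inside the
    vessel candidate mask by its median, so voxelwise T1 noise cannot couple
    into the max-enhancement VIF voxel selection."""
    ok = mask & t1map.valid
    if not ok.any():
        return t1map
    t1map.r1_0 = t1map.r1_0.copy()
    t1map.m0 = t1map.m0.copy()
    t1map.r1_0[mask] = np.median(t1map.r1_0[ok])
    t1map.m0[mask] = np.median(t1map.m0[ok])
    t1map.valid = t1map.valid | mask
    return t1map


def reconstruct_concentrations(sim: DualAcquisition, *,
                               n_baseline_frames: int = 10,
                               vessel_mask_ld=None, vessel_mask_hs=None):
    """Signal -> concentration for both series of a simulated acquisition.

    The LDHT series is anchored on its pre-bolus baseline; the FDHS
    (parenchymal-phase) series has no unenhanced baseline and uses the
    VFA-fitted M0 instead. When vessel candidate masks are given, the T1 fit
    is pooled (median) across each mask before conversion. Series already in
    concentration units pass through unchanged.
    """
    if sim.ldht.units == "mM":
        ld = ImageSeries(sim.ldht.data * sim.dose_ratio, sim.ldht.times,
                         sim.ldht.voxel_size, units="mM")
        return ld, sim.fdhs, None, None
    t1_ld = fit_vfa_t1(sim.vfa_ldht, tr=sim.ldht_spec.tr)
    t1_fd = fit_vfa_t1(sim.vfa_hs, tr=sim.fdhs_spec.tr)
    if vessel_mask_ld is not None:
        t1_ld = _pool_t1(t1_ld, vessel_mask_ld)
    if vessel_mask_hs is not None:
        t1_fd = _pool_t1(t1_fd, vessel_mask_hs)
    ld = signal_to_concentration(sim.ldht, t1_ld, sim.ldht_spec,
                                 n_baseline_frames=n_baseline_frames)
    fd = signal_to_concentration(sim.fdhs, t1_fd, sim.fdhs_spec,
                                 n_baseline_frames=sim.n_fdhs_baseline or None)
    if vessel_mask_ld is not None:
        # vessel voxels: convert against the pooled VFA M0 instead of the
        # per-voxel baseline. A noisy per-voxel baseline acts as a whole-curve
        # scale error (amplified near SPGR saturation), and the
        # max-enhancement VIF selection would then pick exactly the inflated
        # curves; with a pooled M0 the conversion scale is uniform across
        # candidates.
        ld_m0 = signal_to_concentration(sim.ldht, t1_ld, sim.ldht_spec,
                                        n_baseline_frames=None)
        ld.data[vessel_mask_ld] = ld_m0.data[vessel_mask_ld]
    if vessel_mask_hs is not None:
        fd_m0 = signal_to_concentration(sim.fdhs, t1_fd, sim.fdhs_spec,
                                        n_baseline_frames=None)
        fd.data[vessel_mask_hs] = fd_m0.data[vessel_mask_hs]
    # to full-dose concentration units
    ld = ImageSeries(ld.data * sim.dose_ratio, ld.times, ld.voxel_size,
                     units="mM", flags=ld.flags)
    return ld, fd, t1_ld, t1_fd


def analyze(sim: DualAcquisition, *, fit_mask=None, patlak_mask=None,
            vessel_mask_hs=None, n_vif_voxels: int = 10,
            hct: float = DEFAULT_HCT, with_patlak: bool = True) -> AnalysisResult:
    """Run the full multi-model pipeline on one dual acquisition.

    ``fit_mask`` restricts the (per-voxel, nonlinear) extended Tofts fit;
    ``patlak_mask`` defaults to the same mask. ``vessel_mask_hs`` defaults to
    the phantom's vessel compartment — for real data a sagittal-sinus
    candidate mask must be supplied.
    """
    if vessel_mask_hs is None:
        vessel_mask_hs = sim.phantom.mask("vessel")
    if sim.ldht.shape != vessel_mask_hs.shape:
        frac = downsample(vessel_mask_hs.astype(float),
                          sim.phantom.voxel_size, sim.ldht_spec.voxel_size,
                          mode="area")
        vessel_mask_ld = frac > 0.99
    else:
        vessel_mask_ld = vessel_mask_hs
    ld_conc, fd_conc, _, _ = reconstruct_concentrations(
        sim, vessel_mask_ld=vessel_mask_ld, vessel_mask_hs=vessel_mask_hs)
    # the LDHT block is already in full-dose units here, so the dual-injection
    # concatenation runs at dose_ratio 1 and the VIF is full-dose throughout
    vif_ld = extract_vif(ld_conc, vessel_mask_ld, n_vif_voxels, hct=hct)
    vif_fd = extract_vif(fd_conc, vessel_mask_hs, n_vif_voxels, hct=hct)
    vif = concatenate_dual_injection_vif(vif_ld, vif_fd, dose_ratio=1.0)

    recon, dtr = legatos_reconstruct(ld_conc, fd_conc, dose_ratio=1.0)

    if fit_mask is None:
        fit_mask = np.ones(recon.shape, dtype=bool)
    etm_res = ExtendedToftsModel(recon, vif, mask=fit_mask).fit()

    etw = select_etw(vif)
    cbf_ht, cbf_flags = estimate_cbf_et(ld_conc, vif, etw)
    cbf_hs, _ = rescale_cbf_to_hs(cbf_ht, dtr.ratio_calib,
                                  sim.ldht_spec.voxel_size,
                                  sim.fdhs_spec.voxel_size,
                                  flags_ht=cbf_flags)
    flow = derive_flow_permeability(etm_res.ktrans, cbf_hs, hct)
    etm_res.extra.update(cbf=cbf_hs, fp=flow["fp"], ps=flow["ps"],
                         rfp=flow["rfp"])
    etm_res.flags = etm_res.flags | np.where(flow["flags"], np.int8(8), np.int8(0))

    pat = None
    if with_patlak:
        pat = fit_patlak_fixed_vp(
            recon, vif, vp_map=etm_res.vp,
            mask=patlak_mask if patlak_mask is not None else fit_mask,
            frame_window=slice(dtr.junction_index + 1, None))

    return AnalysisResult(ldht_conc=ld_conc, fdhs_conc=fd_conc, vif=vif,
                          recon=recon, dtr=dtr, etm=etm_res, cbf_ht=cbf_ht,
                          cbf_hs=cbf_hs, patlak=pat,
                          extras={"etw": etw})
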