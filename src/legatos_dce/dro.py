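"""Digital reference object: dual-injection, dual-temporal-resolution
synthetic acquisitions from known ground truth.

The forward tissue model is the full two-compartment exchange model (2CXM),
so the extended Tofts, Patlak and microsphere estimators downstream are
genuinely approximations under test; an ``kinetics='etm'`` mode generates
extended-Tofts curves instead for exact round-trip experiments.

The simulator emulates the *effective* concatenated experiment of a
dual-injection protocol: tracer kinetics are linear in dose, so the low-dose
high-temporal (LDHT) series is the full-dose experiment scaled down by the
dose ratio and sampled on the coarse spatial / fine temporal lattice, while
the full-dose high-spatial (FDHS) series samples the same experiment on the
fine spatial / coarse temporal lattice. Second-injection transients and
pre-bolus residual offsets are not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kinetics import aath_curve, etm_curve, ktrans_from_fp_ps, tcxm_curve
from .acquisition import AcquisitionSpec, DEFAULT_HCT, VFA_FLIP_ANGLES, \
    fdhs_spec, ldht_spec
from .containers import ImageSeries, VascularInputFunction
from .resample import downsample
from .signal_conc import spgr_signal
from .vif import population_aif

__all__ = [
    "TissueCompartment", "GroundTruthPhantom", "DualAcquisition",
    "simulate_tissue_curve", "simulate_dual_acquisition",
    "simulate_dual_concentration", "brain_phantom", "thin_structure_phantom",
    "pure_parent_mask", "sigma_for_snr",
]


@dataclass(frozen=True)
class TissueCompartment:
    """Ground-truth kinetic and relaxation parameters of one compartment.

    ``fp``/``ps`` in mL min^-1 mL^-1 (``fp=inf`` marks fast exchange, used
    for pure-blood voxels), ``vp``/``ve`` fractions, ``t1_0`` seconds,
    ``m0`` equilibrium signal (0 = no MR signal, e.g. air)."""

    name: str
    fp: float
    ps: float
    vp: float
    ve: float
    t1_0: float
    m0: float = 1000.0

    def __post_init__(self):
        if not (0 <= self.vp <= 1 and 0 <= self.ve <= 1
                and self.vp + self.ve <= 1 + 1e-12):
            raise ValueError(f"{self.name}: vp/ve outside the physical simplex")
        if self.ps < 0 or (not np.isinf(self.fp) and self.fp < 0):
            raise ValueError(f"{self.name}: Fp and PS must be >= 0")
        if self.t1_0 <= 0:
            raise ValueError(f"{self.name}: T1_0 must be > 0")

    @property
    def ktrans(self) -> float:
        """Hybrid flow-permeability transfer constant Fp*PS/(Fp+PS)."""
        return ktrans_from_fp_ps(self.fp, self.ps)


@dataclass
class GroundTruthPhantom:
    """Compartment label volume on the high-spatial grid plus per-compartment
    truth, haematocrit, noise level and seed."""

    label_volume: np.ndarray
    compartments: dict[int, TissueCompartment]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 2.0)
    hct: float = DEFAULT_HCT
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.label_volume = np.asarray(self.label_volume)
        if self.label_volume.ndim != 3:
            raise ValueError("label volume must be 3-D")
        missing = set(np.unique(self.label_volume)) - set(self.compartments)
        if missing:
            raise ValueError(f"labels without compartment truth: {missing}")
        if not (0 <= self.hct < 1):
            raise ValueError("hct must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def shape(self):
        return self.label_volume.shape

    def mask(self, name: str) -> np.ndarray:
        labs = [k for k, c in self.compartments.items() if c.name == name]
        if not labs:
            raise KeyError(name)
        return np.isin(self.label_volume, labs)

    def truth_map(self, param: str) -> np.ndarray:
        """Voxelwise ground-truth map ('fp', 'ps', 'vp', 've', 'ktrans',
        'cbf', 't1_0') on the high-spatial grid."""
        lut = np.zeros(max(self.compartments) + 1)
        for k, c in self.compartments.items():
            if param == "cbf":
                v = 0.0 if np.isinf(c.fp) else c.fp / (1.0 - self.hct)
            elif param == "ktrans":
                v = c.ktrans
            else:
                v = getattr(c, param)
            lut[k] = v if np.isfinite(v) else np.nan
        return lut[self.label_volume]


def simulate_tissue_curve(compartment: TissueCompartment,
                          vif: VascularInputFunction,
                          times_s: np.ndarray,
                          kinetics: str = "2cxm") -> np.ndarray:
    """Noise-free tissue concentration-time curve for one compartment.

    ``kinetics='2cxm'`` uses the two-compartment exchange forward model (a
    well-mixed vascular space; the extended Tofts model is its fast-exchange
    limit); ``kinetics='aath'`` the plug-flow-capillary adiabatic
    tissue-homogeneity model, whose finite vascular transit time is the
    premise of the early-time-points microsphere estimator;
    ``kinetics='etm'`` generates the extended Tofts curve with
    Ktrans = Fp*PS/(Fp+PS).
    """
    times_s = np.asarray(times_s, dtype=float)
    if np.any(np.diff(times_s) <= 0):
        raise ValueError("time base must be strictly increasing")
    if not vif.covers(times_s):
        raise ValueError("VIF does not cover the requested time base")
    cp = vif.cp_at(times_s)
    c = compartment
    if kinetics == "2cxm":
        return tcxm_curve(c.fp, c.ps, c.vp, c.ve, cp, times_s)
    if kinetics == "aath":
        return aath_curve(c.fp, c.ps, c.vp, c.ve, cp, times_s)
    if kinetics == "etm":
        return etm_curve(c.ktrans, c.vp, c.ve, cp, times_s)
    raise ValueError(f"unknown kinetics {kinetics!r}")


# ---------------------------------------------------------------------------
# phantom factories


def _brain_compartments(hct: float) -> dict[int, TissueCompartment]:
    return {
        0: TissueCompartment("csf", 0.0, 0.0, 0.0, 0.0, 4.0),
        1: TissueCompartment("nawm", 0.145, 6.2e-4, 0.010, 0.20, 0.65),
        2: TissueCompartment("nagm", 0.348, 1.5e-3, 0.030, 0.22, 1.20),
        3: TissueCompartment("tumour", 0.514, 0.169, 0.047, 0.519, 1.50),
        4: TissueCompartment("vessel", np.inf, 0.0, 1.0 - hct, 0.0, 1.40),
    }


def brain_phantom(shape=(48, 48, 24), voxel_size=(1.0, 1.0, 2.0),
                  hct=DEFAULT_HCT, noise_sigma=0.0, seed=0) -> GroundTruthPhantom:
    """Default brain-like phantom: white-matter bulk, a grey-matter slab, a
    centimetre-scale tumour block (vestibular schwannomas are cm-scale, i.e.
    large against the coarse arterial-phase grid), a sagittal-sinus-like
    vessel rod and a CSF block.

    Compartment truth: tumour flow/permeability at the vestibular-schwannoma
    scale (Fp ~ 0.5, PS ~ 0.17 mL min^-1 mL^-1, vp ~ 0.05, ve ~ 0.5), normal
    white/grey matter at low-level permeability (Ktrans ~ 6e-4 / 1.5e-3
    min^-1) with grey > white throughout.
    """
    nx, ny, nz = shape
    lab = np.ones(shape, dtype=np.int16)              # NAWM bulk
    lab[nx - max(nx // 7, 3):, :, :] = 2              # NAGM slab
    # tumour: ~20 mm cube centred off-axis
    dx = max(int(round(20.0 / voxel_size[0])), 4)
    dz = max(int(round(20.0 / voxel_size[2])), 3)
    x0, y0 = int(nx * 0.38), int(ny * 0.45)
    z0 = max((nz - dz) // 2, 0)
    lab[x0:min(x0 + dx, nx - max(nx // 7, 3)),
        y0:min(y0 + dx, ny), z0:z0 + dz] = 3
    w = max(int(round(7.5 / voxel_size[0])), 2)       # >= 3 coarse voxels wide
    vz = max(int(round(14.0 / voxel_size[2])), 2)
    lab[max(nx // 10, 1):max(nx // 10, 1) + w, :,
        max((nz - vz) // 2, 0):max((nz - vz) // 2, 0) + vz] = 4  # vessel rod
    lab[:max(nx // 14, 1), :, :] = 0                  # CSF block
    return GroundTruthPhantom(lab, _brain_compartments(hct),
                              voxel_size=voxel_size, hct=hct,
                              noise_sigma=noise_sigma, seed=seed)


def pure_parent_mask(phantom: GroundTruthPhantom, coarse_voxel, name: str,
                     resample_mode: str = "area") -> np.ndarray:
    """Fine-grid voxels whose containing coarse voxel samples only the named
    compartment (i.e. free of cross-compartment partial volume)."""
    from .resample import upsample_nearest_parent

    frac = downsample(phantom.mask(name).astype(float), phantom.voxel_size,
                      coarse_voxel, mode=resample_mode)
    pure = upsample_nearest_parent(frac > 1.0 - 1e-9, coarse_voxel,
                                   phantom.voxel_size, phantom.shape)
    return pure & phantom.mask(name)


def thin_structure_phantom(shape=(32, 32, 18), voxel_size=(1.0, 1.0, 2.0),
                           hct=DEFAULT_HCT, noise_sigma=0.0,
                           seed=0) -> GroundTruthPhantom:
    """Partial-volume stress phantom: a one-fine-voxel-thick (2 mm) bright,
    highly vascular plate embedded in dark low-flow tissue, plus a vessel rod
    for VIF extraction. A coarse (6+ mm) slice mixes the plate with its dark
    neighbours, so unrescaled coarse-grid estimates are biased low inside the
    plate."""
    nx, ny, nz = shape
    # plate = 5 x dark in all four kinetic parameters: the 2CXM tissue curve
    # is homogeneous of degree 1 in (Fp, PS, vp, ve), so the plate curve is
    # exactly five times the dark curve and the partial-volume mixture is a
    # pure amplitude error — the regime the calibration ratio corrects.
    comps = {
        0: TissueCompartment("csf", 0.0, 0.0, 0.0, 0.0, 4.0),
        1: TissueCompartment("dark", 0.100, 4.0e-3, 0.010, 0.12, 0.80),
        2: TissueCompartment("plate", 0.500, 2.0e-2, 0.050, 0.60, 1.30),
        4: TissueCompartment("vessel", np.inf, 0.0, 1.0 - hct, 0.0, 1.40),
    }
    lab = np.ones(shape, dtype=np.int16)
    zc = nz // 2
    lab[nx // 3:, nx // 6:, zc] = 2                  # 2 mm plate
    w = max(int(round(7.5 / voxel_size[0])), 2)
    dz = max(int(round(14.0 / voxel_size[2])), 2)
    lab[1:1 + w, :, 1:1 + dz] = 4
    return GroundTruthPhantom(lab, comps, voxel_size=voxel_size, hct=hct,
                              noise_sigma=noise_sigma, seed=seed)


# ---------------------------------------------------------------------------
# acquisition simulation


@dataclass
class DualAcquisition:
    """One simulated dual-injection experiment.

    ``ldht``/``fdhs`` hold the dynamic series (signal units unless simulated
    directly in concentration space), ``vfa_hs``/``vfa_ldht`` the multi-flip-
    angle baselines per grid, ``vif_full`` the ground-truth plasma curve in
    full-dose units on the union time base, ``curves_full`` the noise-free
    full-dose tissue curve per compartment label."""

    ldht: ImageSeries
    fdhs: ImageSeries
    vfa_hs: dict[float, np.ndarray]
    vfa_ldht: dict[float, np.ndarray]
    vif_full: VascularInputFunction
    curves_full: dict[int, np.ndarray]
    phantom: GroundTruthPhantom
    ldht_spec: AcquisitionSpec
    fdhs_spec: AcquisitionSpec
    dose_ratio: float
    kinetics: str = "2cxm"
    n_fdhs_baseline: int = 3

    @property
    def union_times(self) -> np.ndarray:
        return self.vif_full.times

    def truth_concentration(self, times=None) -> ImageSeries:
        """Noise-free full-dose HS concentration volume at the requested
        frame times (default: the full union time base)."""
        t = self.union_times if times is None else np.asarray(times)
        idx = np.searchsorted(self.union_times, t)
        if not np.allclose(self.union_times[idx], t):
            raise ValueError("times must be a subset of the union time base")
        lut = np.zeros((max(self.curves_full) + 1, t.size))
        for k, cur in self.curves_full.items():
            lut[k] = cur[idx]
        return ImageSeries(lut[self.phantom.label_volume], t,
                           self.phantom.voxel_size, units="mM")


def _label_volume_series(phantom, curves, idx) -> np.ndarray:
    lut = np.zeros((max(curves) + 1, idx.size))
    for k, cur in curves.items():
        lut[k] = cur[idx]
    return lut[phantom.label_volume]


def _apply_noise(rng, vol, sigma, model):
    if sigma == 0.0 or model == "none":
        return vol
    if model == "rician":
        n1 = rng.normal(0.0, sigma, vol.shape)
        n2 = rng.normal(0.0, sigma, vol.shape)
        return np.sqrt((vol + n1) ** 2 + n2 ** 2)
    if model == "gaussian":
        return vol + rng.normal(0.0, sigma, vol.shape)
    raise ValueError(f"unknown noise model {model!r}")


#: effective times (s) of the FDHS pre-injection baseline frames: before the
#: second injection no full-dose tracer is present, which maps to pre-bolus
#: times of the effective single-bolus experiment
FDHS_BASELINE_TIMES = (4.35, 9.85, 15.35)


def _simulate_conc_blocks(phantom, ldht_sp, fdhs_sp, kinetics, vif,
                          resample_mode, fdhs_baseline=FDHS_BASELINE_TIMES):
    t_ld = ldht_sp.times
    t_fd = np.concatenate([np.asarray(fdhs_baseline, dtype=float),
                           fdhs_sp.times])
    if fdhs_sp.times[0] <= t_ld[-1]:
        raise ValueError("FDHS series must start after the LDHT series")
    if any(c < f for c, f in zip(ldht_sp.voxel_size, fdhs_sp.voxel_size)):
        raise ValueError("FDHS grid must be at least as fine as the LDHT grid")
    t_union = np.unique(np.concatenate([t_ld, t_fd]))
    dose_ratio = fdhs_sp.dose_ml / ldht_sp.dose_ml
    if dose_ratio < 1:
        raise ValueError("LDHT dose must not exceed the FDHS dose")
    if vif is None:
        vif = population_aif(t_union, dose_ml=fdhs_sp.dose_ml, hct=phantom.hct)
    curves = {int(k): simulate_tissue_curve(c, vif, t_union, kinetics)
              for k, c in phantom.compartments.items()}
    idx_ld = np.searchsorted(t_union, t_ld)
    idx_fd = np.searchsorted(t_union, t_fd)
    hs_ld = _label_volume_series(phantom, curves, idx_ld)
    hs_fd = _label_volume_series(phantom, curves, idx_fd)
    ld_conc = downsample(hs_ld, phantom.voxel_size, ldht_sp.voxel_size,
                         mode=resample_mode) / dose_ratio
    return t_ld, t_fd, vif, curves, hs_fd, ld_conc, dose_ratio


def simulate_dual_concentration(phantom: GroundTruthPhantom,
                                ldht_sp: AcquisitionSpec | None = None,
                                fdhs_sp: AcquisitionSpec | None = None,
                                *, kinetics="2cxm", vif=None,
                                resample_mode="auto",
                                conc_noise_sigma=0.0) -> DualAcquisition:
    """Dual acquisition directly in concentration space (optionally with
    additive Gaussian concentration noise) — the unit-test mode that skips
    the MR signal layer."""
    ldht_sp = ldht_sp or ldht_spec()
    fdhs_sp = fdhs_sp or fdhs_spec()
    t_ld, t_fd, vif, curves, hs_fd, ld_conc, dose_ratio = \
        _simulate_conc_blocks(phantom, ldht_sp, fdhs_sp, kinetics, vif,
                              resample_mode)
    rng = np.random.default_rng(phantom.seed)
    ld = _apply_noise(rng, ld_conc, conc_noise_sigma, "gaussian")
    fd = _apply_noise(rng, hs_fd, conc_noise_sigma, "gaussian")
    return DualAcquisition(
        ldht=ImageSeries(ld, t_ld, ldht_sp.voxel_size, units="mM"),
        fdhs=ImageSeries(fd, t_fd, fdhs_sp.voxel_size, units="mM"),
        vfa_hs={}, vfa_ldht={}, vif_full=vif, curves_full=curves,
        phantom=phantom, ldht_spec=ldht_sp, fdhs_spec=fdhs_sp,
        dose_ratio=dose_ratio, kinetics=kinetics,
        n_fdhs_baseline=len(FDHS_BASELINE_TIMES))


def simulate_dual_acquisition(phantom: GroundTruthPhantom,
                              ldht_sp: AcquisitionSpec | None = None,
                              fdhs_sp: AcquisitionSpec | None = None,
                              *, kinetics="2cxm", vif=None,
                              noise_model="rician",
                              resample_mode="auto",
                              vfa_angles=VFA_FLIP_ANGLES) -> DualAcquisition:
    """Simulate the full dual-injection protocol in signal units.

    The high-spatial truth is block-averaged (partial volume) onto the LDHT
    grid, scaled to the low dose and SPGR-encoded; the FDHS volume is encoded
    at full dose on the fine grid. Rician noise of ``phantom.noise_sigma``
    (signal units) is applied to every dynamic frame and every VFA volume.
    Reproducible bit-for-bit under a fixed ``phantom.seed``.
    """
    ldht_sp = ldht_sp or ldht_spec()
    fdhs_sp = fdhs_sp or fdhs_spec()
    t_ld, t_fd, vif, curves, hs_fd, ld_conc, dose_ratio = \
        _simulate_conc_blocks(phantom, ldht_sp, fdhs_sp, kinetics, vif,
                              resample_mode)
    r1_hs = 1.0 / phantom.truth_map("t1_0")
    m0_hs = phantom.truth_map("m0")
    r1_ld = downsample(r1_hs, phantom.voxel_size, ldht_sp.voxel_size,
                       mode=resample_mode)
    m0_ld = downsample(m0_hs.astype(float), phantom.voxel_size,
                       ldht_sp.voxel_size, mode=resample_mode)

    sig_ld = spgr_signal(m0_ld[..., None],
                         r1_ld[..., None] + ldht_sp.relaxivity_r1 * ld_conc,
                         ldht_sp.flip_angle_deg, ldht_sp.tr)
    sig_fd = spgr_signal(m0_hs[..., None],
                         r1_hs[..., None] + fdhs_sp.relaxivity_r1 * hs_fd,
                         fdhs_sp.flip_angle_deg, fdhs_sp.tr)

    rng = np.random.default_rng(phantom.seed)
    sig = phantom.noise_sigma
    sig_ld = _apply_noise(rng, sig_ld, sig, noise_model)
    sig_fd = _apply_noise(rng, sig_fd, sig, noise_model)
    vfa_hs, vfa_ld = {}, {}
    for a in vfa_angles:
        vfa_hs[a] = _apply_noise(rng, spgr_signal(m0_hs, r1_hs, a, fdhs_sp.tr),
                                 sig, noise_model)
        vfa_ld[a] = _apply_noise(rng, spgr_signal(m0_ld, r1_ld, a, ldht_sp.tr),
                                 sig, noise_model)

    return DualAcquisition(
        ldht=ImageSeries(sig_ld, t_ld, ldht_sp.voxel_size, units="signal"),
        fdhs=ImageSeries(sig_fd, t_fd, fdhs_sp.voxel_size, units="signal"),
        vfa_hs=vfa_hs, vfa_ldht=vfa_ld, vif_full=vif, curves_full=curves,
        phantom=phantom, ldht_spec=ldht_sp, fdhs_spec=fdhs_sp,
        dose_ratio=dose_ratio, kinetics=kinetics,
        n_fdhs_baseline=len(FDHS_BASELINE_TIMES))


def sigma_for_snr(phantom: GroundTruthPhantom, spec: AcquisitionSpec,
                  snr: float) -> float:
    """Noise level giving the requested baseline SNR (mean pre-contrast
    tissue signal divided by sigma) for the given series settings."""
    if snr <= 0:
        raise ValueError("snr must be > 0")
    r1 = 1.0 / phantom.truth_map("t1_0")
    m0 = phantom.truth_map("m0")
    s = spgr_signal(m0, r1, spec.flip_angle_deg, spec.tr)
    return float(s[m0 > 0].mean() / snr)
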