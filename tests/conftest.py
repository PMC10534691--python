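"""Shared fixtures: digital-reference-object experiments reused across the
module and acceptance tests.

The full-protocol runs are expensive (whole pipeline incl. voxelwise fits),
so they are session-scoped and each carries everything downstream tests
need: the simulated acquisition, the analysis result, the phantom and the
evaluation masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import legatos_dce as ldce
from legatos_dce import dro


def subsample_mask(mask: np.ndarray, n: int, seed: int) -> np.ndarray:
    """Deterministic random subset of a boolean mask (median evaluation does
    not need every voxel of a large homogeneous compartment)."""
    idx = np.flatnonzero(mask.ravel())
    take = np.random.default_rng(seed).choice(idx, min(n, idx.size),
                                              replace=False)
    out = np.zeros(mask.shape, dtype=bool).ravel()
    out[take] = True
    return out.reshape(mask.shape)


@dataclass
class DroRun:
    sim: dro.DualAcquisition
    result: ldce.AnalysisResult
    phantom: dro.GroundTruthPhantom
    fit_mask: np.ndarray
    masks: dict


def _specs():
    return ldce.ldht_spec(), ldce.fdhs_spec()


@pytest.fixture(scope="session")
def etm_snr20_run() -> DroRun:
    """Extended-Tofts-generated brain phantom at baseline SNR 20, full
    pipeline with the tumour compartment fitted (seeded subsample)."""
    ldsp, fdsp = _specs()
    ph = dro.brain_phantom(seed=7)
    ph.noise_sigma = dro.sigma_for_snr(ph, ldsp, 20.0)
    sim = dro.simulate_dual_acquisition(ph, ldsp, fdsp, kinetics="etm",
                                        noise_model="rician",
                                        resample_mode="area")
    fit_mask = subsample_mask(ph.mask("tumour"), 300, seed=1)
    res = ldce.analyze(sim, fit_mask=fit_mask, with_patlak=False)
    return DroRun(sim, res, ph, fit_mask, {"tumour": ph.mask("tumour")})


@pytest.fixture(scope="session")
def aath_snr20_run() -> DroRun:
    """Plug-flow (AATH) brain phantom at SNR 20 for microsphere CBF
    recovery; no voxelwise nonlinear fits."""
    from legatos_dce.resample import downsample

    ldsp, fdsp = _specs()
    ph = dro.brain_phantom(seed=11)
    ph.noise_sigma = dro.sigma_for_snr(ph, ldsp, 20.0)
    sim = dro.simulate_dual_acquisition(ph, ldsp, fdsp, kinetics="aath",
                                        noise_model="rician",
                                        resample_mode="area")
    res = ldce.analyze(sim, fit_mask=np.zeros(ph.shape, dtype=bool),
                       with_patlak=False)
    frac = downsample(ph.mask("tumour").astype(float), ph.voxel_size,
                      ldsp.voxel_size, mode="area")
    return DroRun(sim, res, ph, np.zeros(ph.shape, bool),
                  {"tumour": ph.mask("tumour"),
                   "tumour_pure_ld": frac > 1 - 1e-9})


@pytest.fixture(scope="session")
def patlak_snr50_run() -> DroRun:
    """Extended-Tofts brain phantom at SNR 50; normal-appearing white and
    grey matter fitted for low-level permeability recovery."""
    ldsp, fdsp = _specs()
    ph = dro.brain_phantom(seed=13)
    ph.noise_sigma = dro.sigma_for_snr(ph, ldsp, 50.0)
    sim = dro.simulate_dual_acquisition(ph, ldsp, fdsp, kinetics="etm",
                                        noise_model="rician",
                                        resample_mode="area")
    nawm = subsample_mask(ph.mask("nawm"), 600, seed=2)
    nagm = subsample_mask(ph.mask("nagm"), 300, seed=3)
    res = ldce.analyze(sim, fit_mask=nawm | nagm)
    return DroRun(sim, res, ph, nawm | nagm,
                  {"nawm": nawm, "nagm": nagm})


@pytest.fixture(scope="session")
def thin_structure_run() -> DroRun:
    """Noise-free plug-flow thin-structure phantom: the partial-volume
    stress case for the calibration-ratio rescaling."""
    ldsp, fdsp = _specs()
    ph = dro.thin_structure_phantom()
    sim = dro.simulate_dual_acquisition(ph, ldsp, fdsp, kinetics="aath",
                                        noise_model="none",
                                        resample_mode="area")
    res = ldce.analyze(sim, fit_mask=np.zeros(ph.shape, dtype=bool),
                       with_patlak=False)
    return DroRun(sim, res, ph, np.zeros(ph.shape, bool),
                  {"plate": ph.mask("plate"), "dark": ph.mask("dark")})


@pytest.fixture(scope="session")
def aif300():
    """Population arterial curve over a 300 s high-temporal window,
    full-dose units."""
    t = np.arange(0.0, 300.0)
    return ldce.population_aif(t, dose_ml=12.0)
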