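# legatos-dce

High-spatial-resolution, multi-model pharmacokinetic analysis of
dual-injection, dual-temporal-resolution (DTR) DCE-MRI — the acquisition
scheme in which a low-dose, high-temporal-resolution (LDHT) series captures
the arterial first pass (Δt = 1 s, coarse voxels) and a full-dose,
high-spatial-resolution (FDHS) series captures the slow parenchymal phase
(Δt = 10.7 s, 1 × 1 × 2 mm³ voxels). The package is aimed at quantitative
neuroimaging researchers who need whole-brain maps of both flow and
permeability — e.g. for monitoring antiangiogenic therapy of NF2-related
vestibular schwannoma, where the capillary permeability–surface area product
changes far more than blood flow does.

## What it computes

1. **LEGATOS reconstruction** — the two concentration series are
   concatenated on the fine grid (arterial phase inherited from the coarse
   parent voxels, dose-scaled), and the arterial phase of every voxel is
   rescaled by a voxelwise calibration ratio estimated around the series
   junction, restoring the spatial detail lost to partial volume.
2. **Extended Tofts model (ETM)** per voxel on the reconstructed volume:

   C_t(t) = v_p C_p(t) + K^trans ∫₀ᵗ C_p(τ) e^{−(K^trans/v_e)(t−τ)} dτ

   giving K^trans (min⁻¹), v_p and v_e.
3. **Early-time-points microsphere CBF**: within the window from bolus
   arrival to the first-pass peak of the vascular input function (VIF),
   C_t(t) = f·∫ C_b dt′, so f = CBF_ET is a no-intercept regression slope;
   rescaling by the calibration ratio gives the high-spatial CBF map
   (CBF_ET-HS = CBF_ET-HT · ratio_calib).
4. **Flow/permeability separation**: F_p = CBF_ET·(1 − Hct),
   PS = K^trans/(1 − K^trans/F_p), R_Fp = F_p/(F_p + PS) ∈ (0, 1]
   (≈1 permeability-limited, small flow-limited).
5. **Hybrid fixed-v_p Patlak** for low-level permeability in
   normal-appearing brain: C_t/C_p = v_p + K^trans·t_stretch with v_p fixed
   from the ETM fit, leaving K^trans as the only free parameter.
6. A **digital reference object (DRO)**: dual-resolution synthetic
   acquisitions (SPGR signal model, variable-flip-angle baselines, Rician
   noise) from known ground truth, so every estimator above is validated by
   parameter recovery.

## Worked example

Simulate the default brain phantom (white/grey matter, a 2 cm
vestibular-schwannoma-like tumour with F_p = 0.514 mL min⁻¹ mL⁻¹,
PS = 0.169 mL min⁻¹ mL⁻¹, v_p = 0.047, v_e = 0.519, and a
sagittal-sinus-like vessel) at baseline SNR 20, then run the full pipeline:

```python
import numpy as np
import legatos_dce as ldce
from legatos_dce import dro

ldsp, fdsp = ldce.ldht_spec(), ldce.fdhs_spec()
ph = dro.brain_phantom(seed=7)
ph.noise_sigma = dro.sigma_for_snr(ph, ldsp, 20.0)
sim = dro.simulate_dual_acquisition(ph, ldsp, fdsp, kinetics="aath",
                                    noise_model="rician", resample_mode="area")

tumour = ph.mask("tumour")
fit = np.zeros_like(tumour)
fit.ravel()[np.random.default_rng(1).choice(
    np.flatnonzero(tumour.ravel()), 300, replace=False)] = True

res = ldce.analyze(sim, fit_mask=fit, with_patlak=False)
print(res.etm.summary().round(4))
```

```
             n  median    mean      sd
parameter
ktrans     298  0.1404  0.1506  0.0515
vp         298  0.0317  0.0344  0.0165
ve         298  0.5223  0.5389  0.1079
cbf        298  0.8826  0.9565  0.4572
fp         298  0.5119  0.5548  0.2652
ps         298  0.2000  0.2202  0.0919
rfp        298  0.7116  0.7073  0.0905
```

The tumour medians recover the ground truth: CBF 0.88 vs 0.886
(= 0.514/0.58) and F_p 0.51 vs 0.514 are essentially exact; K^trans 0.140
and v_p 0.032 carry the expected extended-Tofts approximation error on
plug-flow-generated curves (the ETM has no vascular transit time), which
propagates into PS 0.20 vs 0.169. R_Fp ≈ 0.71 marks the tumour as largely
permeability-limited. Two voxels were excluded by fit-quality flags
(`res.etm.flags`).

A command line covers the file-based workflow:

```bash
dce simulate --config phantom.yaml --out sim/ --seed 3
dce legatos  --ldht ld.nii.gz --fdhs fd.nii.gz \
             --ldht-config ld.yaml --fdhs-config fd.yaml \
             --dose-ratio 4.0 --out dtr.nii.gz --ratio ratio.nii.gz
dce stats    --maps maps/ --mask tumour.nii.gz --out stats.csv
```

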