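# Methods

This note records the models implemented, the numerical choices made where
the design was genuinely open, and what the synthetic experiments do and do
not demonstrate.

## Tracer-kinetic models

All concentrations are gadolinium concentrations in mM; rate parameters
(F_p, PS, K^trans) are in mL min⁻¹ mL⁻¹ ≡ min⁻¹; v_p, v_e are volume
fractions with v_p + v_e ≤ 1; whole-blood and plasma concentrations are
related by C_b = C_p (1 − Hct).

**Extended Tofts (ETM).** C_t = v_p C_p + K^trans (C_p ⊛ e^{−k_ep t}),
k_ep = K^trans/v_e. The convolution is computed by an exponential-kernel
recursion that is exact for piecewise-linear C_p on an arbitrary strictly
increasing time base — necessary because the reconstructed series is
non-uniform (1 s arterial frames followed by 10.7 s parenchymal frames).
A series expansion replaces the closed-form segment integrals when
k·Δt < 10⁻⁴ to avoid cancellation; k = 0 degenerates to the running
integral (the Patlak limit).

**Two-compartment exchange (2CXM).** The simulator's default forward model:
well-mixed plasma and interstitial compartments coupled by PS, solved
exactly per segment by eigendecomposition of the 2×2 rate matrix (each
eigenmode is one exponential convolution). Limits are handled analytically:
F_p = ∞ reduces exactly to the ETM with K^trans = PS; PS = 0 to a single
plasma compartment; v_p = 0 to the Kety model with
K^trans = F_p·PS/(F_p + PS).

**Plug-flow capillary (AATH).** The adiabatic tissue-homogeneity model with
the same (F_p, PS, v_p, v_e) parameterisation: a plug-flow vascular space
with transit time T_c = v_p/F_p, extraction E = 1 − e^{−PS/F_p} and
interstitial washout k_ep = E·F_p/v_e. Before one full transit *no* tracer
reaches the venous outflow, which is precisely the microsphere premise.
This matters for validation: in a well-mixed compartment model venous
outflow starts instantaneously, and we measured that even a 1 s
early-time window then carries a ≥10% flow underestimate (−31% for the
arrival-to-peak window at the tumour operating point). The early-time-points
CBF estimator is therefore validated against plug-flow curves; against
2CXM curves it reports the (documented) compartmental outflow bias, which
is a property of that forward model rather than of the estimator. Both
forward models remain available, and which one a given experiment used is
part of its definition.

The recovery experiments for the ETM and Patlak stages use ETM-generated
curves (round-trip logic: the estimator is checked against data satisfying
its own assumptions, so residual error isolates the reconstruction and
noise chain). Cross-model behaviour is tested separately: the ETM fit of a
2CXM curve recovers K^trans = F_p·PS/(F_p+PS) within ~2% in the
permeability-limited regime and within ~6% at the tumour operating point,
where the missing vascular transit also depresses fitted v_p.

## Signal model and conversion

SPGR steady state, S = M0 sin α (1 − E1)/(1 − E1 cos α), E1 = e^{−TR·R1},
with linear relaxivity R1(t) = R1_0 + r1·C(t) (no water-exchange or B1
correction). Defaults (config-exposed): r1 = 3.6 s⁻¹ mM⁻¹ (gadoterate at
1.5 T), TR = 4.5 ms, dynamic flip angle 15°, VFA angles 2/8/15/20°,
Hct = 0.42. Baseline T1 comes from a DESPOT1 linearised VFA fit (optional
per-voxel nonlinear polish); failed voxels are flagged, never silently
zeroed.

Dynamic conversion inverts the SPGR equation per frame. Two anchorings are
provided: per-voxel pre-bolus baseline (LDHT series; 10 baseline frames by
default) and VFA-M0 (for series without a usable unenhanced baseline).
Negative concentrations from noise are retained through fitting (unbiased
least squares) and only clipped for map export. Enhancement outside the
invertible domain is clamped and the voxel flagged.

Two noise-robustness choices in the pipeline deserve explanation because
both were found, by measurement on the simulator, to be necessary rather
than cosmetic:

- **Pooled blood T1.** Within the vessel candidate mask, R1_0 and M0 are
  replaced by their mask medians before conversion, and vessel voxels are
  converted with M0 anchoring. A noisy per-voxel baseline acts as a
  whole-curve multiplicative error that grows near SPGR saturation, and
  the max-enhancement VIF selection preferentially picks the inflated
  curves (+12% first-pass amplitude at SNR 20 → −14% CBF). Blood is one
  tissue; pooling its T1 is standard practice and removes the coupling.
- **Junction tail extrapolation is log-linear.** The washout tail decays
  roughly exponentially; a straight-line extrapolation across the junction
  over-predicts it by ~7%, which would propagate into the entire
  parenchymal portion of the concatenated VIF.

## Vascular input function

The surrogate VIF is extracted semi-automatically: within a candidate mask
(superior-sagittal-sinus-like), the n = 10 voxels with greatest first-pass
peak enhancement are averaged (ties broken by lowest linear index; the
selected indices are recorded). The measured curve is whole blood; the
pipeline works in plasma space throughout (C_p = C_b/(1 − Hct)).

The dual-injection VIF concatenates the LDHT curve with the later
parenchymal phase of the FDHS curve scaled down by the dose ratio
(default (0.2 mL/kg × 75 kg − 3 mL)/3 mL = 4.0, config-exposed), plus a
least-squares junction gain against the log-linearly extrapolated LDHT
tail over the first three FDHS frames. Kinetic fitting uses the
concatenated VIF in full-dose units.

## LEGATOS reconstruction

Step 1 concatenates: the LDHT block is dose-scaled to full-dose units and
placed on the fine grid by nearest-parent block assignment (each fine voxel
inherits its coarse parent's curve, so the arterial phase keeps its
intrinsic low resolution and *all* spatial detail is carried by the
calibration ratio); the junction is the last LDHT frame.

Step 2 rescales: per fine voxel, ratio_calib multiplies the arterial phase.
The estimator implemented here is

ratio_v = g · mean_w(C_HS[v]) / mean_w(block-mean of C_HS over v's parent),

with w the first three parenchymal frames. The denominator equals the
coarse parent's measured level at the junction and is common-mode within
each parent block, so the spatial pattern comes solely from the
high-spatial numerator, and the within-parent mean of child ratios is 1 by
construction. An earlier variant divided by a per-voxel extrapolation of
the arterial tail; because that denominator is noisy and must pass a
validity floor, conditioning on "denominator above floor" selects
over-predicted denominators and collapses the ratio in weakly enhancing
tissue (measured median 0.41 in white matter at SNR 50). The global gain g
defaults to 1 — kinetic estimates are invariant to a scale shared by
tissue and VIF, so a residual common dose-calibration error is harmless —
with an optional data-driven mode ('tail-extrapolation', estimated over
strongly enhancing blocks only). Blocks below a 0.02 mM floor are flagged
and take the median valid ratio.

Because the coarse/fine voxel-size ratio of the default protocol
(2.5/1, 6.35/2) is non-integer, downsampling offers exact block averaging
for integer ratios and volume-weighted overlap averaging ('area') otherwise;
the mode must be chosen explicitly for non-integer geometry.

## Early-time-points CBF

The early time window runs from bolus arrival (first of two consecutive
frames above baseline mean + 3 SD, floored at 5% of peak) to the VIF
first-pass peak; the rule identifier is stored with the window. CBF is the
no-intercept regression slope of C_t on ∫C_b dt (mM·min), per voxel,
vectorised. The high-spatial map is either the coarse map times
ratio_calib or the same estimator run on the rescaled volume; the estimator
is linear in C_t, so the two routes agree identically (tested to ≤5%).

## PS and R_Fp

PS = K^trans/(1 − K^trans/F_p) and R_Fp = F_p/(F_p + PS) are evaluated
voxelwise. Voxels with K^trans/F_p > 0.95 (denominator < 0.05), F_p = 0
with K^trans > 0, or F_p + PS = 0 are flagged NaN and excluded from ROI
statistics — never clipped to a cap, so medians cannot be driven by a cap
value.

## Hybrid fixed-v_p Patlak

The Patlak plot y = C_t/C_p vs t_stretch = ∫C_p/C_p uses frames with
C_p above 5% of the VIF peak, restricted (by default in the pipeline) to
the parenchymal phase where unidirectional uptake holds best. With v_p
fixed from the ETM fit, K^trans is the slope of the no-intercept regression
of y − v_p on t_stretch; without a v_p map the conventional two-parameter
plot is fitted and the result marked accordingly. Least squares is
unweighted; the noise distortion introduced by the linearising division is
not re-weighted. On backflux-free data the fixed-v_p Patlak agrees with the
generating K^trans to <2%; with tumour-level backflux it underestimates the
ETM value, as expected for a unidirectional model.

## Digital reference object

The DRO emulates the *effective* concatenated experiment of the
dual-injection protocol: since tracer kinetics are linear in dose, the
LDHT series is the full-dose experiment scaled by 1/dose_ratio and sampled
on the coarse grid at 1 s, and the FDHS series is the same experiment on
the fine grid at 10.7 s. Second-injection transients and the pre-bolus
residual offset are not simulated; the FDHS pre-injection baseline frames
are represented by three frames at effective pre-bolus times, preserving
the protocol's baseline-anchored conversion. The driving arterial curve is
a gamma-variate first pass (arrival 20 s, peak ~8 s later) with a
bi-exponential recirculation/washout tail, amplitude linear in dose
(whole-blood peak 5 mM at the full 0.2 mL/kg dose).

Default phantom: 48 × 48 × 24 voxels of 1 × 1 × 2 mm³ with white-matter
bulk (F_p 0.145, PS 6.2 × 10⁻⁴, v_p 0.01, v_e 0.20, T1 0.65 s), a
grey-matter slab (0.348, 1.5 × 10⁻³, 0.03, 0.22, 1.2 s), a 2 cm tumour
block at the vestibular-schwannoma operating point (0.514, 0.169, 0.047,
0.519, 1.5 s), a vessel rod thick enough to contain pure coarse voxels,
and a CSF block (zero enhancement, exercising the flag paths). The tumour
is deliberately centimetre-scale — large against the 2.5 × 2.5 × 6.35 mm³
arterial grid, as the clinical tumours are — so compartment medians are
dominated by voxels whose coarse parents are tissue-pure. The
thin-structure phantom embeds a one-voxel-thick (2 mm) bright plate in
dark tissue with all four kinetic parameters scaled by exactly 5; the
tissue curve is homogeneous of degree 1 in (F_p, PS, v_p, v_e), so the
plate curve is exactly five times the dark curve and the partial-volume
mixture is a pure amplitude error — the regime the calibration ratio is
designed to correct.

Noise is Rician on magnitude signal (applied to every dynamic frame and
every VFA volume; a Gaussian mode and a direct concentration-space mode
exist for unit tests), with `sigma_for_snr` defining SNR as mean
pre-contrast tissue signal over sigma. All randomness flows from a single
integer seed; outputs are bit-reproducible.

What the phantom does *not* emulate: motion, B1 inhomogeneity, k-space
undersampling, bolus delay/dispersion between sinus and tissue (a delay
parameter exists, default 0, since no protocol-derived value is
available), spatially continuous parameter variation, and the
second-injection transient. Passing recovery tests therefore demonstrate
correctness of the reconstruction and estimation chain under the stated
forward models and noise — not robustness to scanner physics beyond them.

## Problem sizes and evaluation choices

Recovery experiments use the full 300 + 60 frame protocol on the
48 × 48 × 24 mm-scale grid described above, with voxelwise nonlinear fits
evaluated on seeded random subsamples (300 tumour, 600 white-matter, 300
grey-matter voxels) — compartment medians are stable at these sizes and
the experiments complete in tens of seconds on one CPU. Microsphere CBF
is evaluated on coarse voxels whose parents are purely tumour, separating
estimator accuracy (this experiment) from partial-volume behaviour (the
thin-structure experiment). The ETM fit uses bounded trust-region least
squares (K^trans ∈ [0, 5] min⁻¹, v_p ∈ [0, 1], v_e ∈ [10⁻³, 1]) from
three fixed starts, flags bound-hits and non-convergence, and guarantees
the returned fit is no worse than any start.

## Known limitations

- The calibration-ratio estimator reconstructs the published "level and
  rescale" idea from its description; the original derivation is in prior
  work not reproducible here, so agreement is by behaviour (no-op on
  homogeneous data, exact correction of proportional-curve partial volume),
  not by formula.
- ETM estimates on data with finite vascular transit (2CXM/plug-flow)
  inherit the model's missing-transit bias, most visible in v_p; PS
  derived from such K^trans is correspondingly biased (~+18% at the tumour
  operating point in the worked example).
- The arrival-to-peak early-time window slightly exceeds the tumour
  capillary transit time, leaving a ~−6% residual CBF bias even on
  plug-flow data; shortening the window trades this against noise.
- Image co-registration and tissue segmentation are out of scope: inputs
  are assumed co-registered (asserted via affines) and masks are supplied
  or simulated.
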