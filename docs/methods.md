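# Methods

This note documents the models, numerical choices and known limits of
`bbbdce`, in the order data flow through the pipeline.

## Signal model and T1 mapping

All signal physics is the steady-state spoiled gradient-echo (SPGR)
equation `S = M0 sin α (1 − E1)/(1 − E1 cos α)`, `E1 = exp(−TR/T1)`.
TE is sub-millisecond (0.99 ms), so T2* decay is neglected: no T2* term
appears anywhere in the model. No B1 correction is applied: the T1 mapping
and the dynamic run use the same sequence, so a B1-driven flip-angle error
biases both conversions in the same direction and largely cancels in the
concentration estimate.

The variable-flip-angle fit uses the standard linearization
`S/sin α = E1 · (S/tan α) + M0(1 − E1)`, solved per voxel by ordinary
least squares. On noise-free data this is the exact inverse of the forward
model. A voxel is flagged `fit_ok = False` (never an exception, never a
silent zero) when:

- the fitted slope falls outside (0, 1) — no real T1 exists;
- the implied M0 is non-positive;
- the refitted SPGR signals misfit the observations by more than 5%
  relative RMS (`consistency_tol`). This screen catches data that are
  *internally* inconsistent with the flip-angle dependence — e.g. a voxel
  with identical signal at every flip angle admits a formally valid slope
  (≈ cos of the mean flip angle) but cannot be SPGR data. 5% sits well
  above the per-voxel noise of the intended SNR regime and well below the
  ≈ 7% misfit of the degenerate constant-signal case.

Invalidity propagates as flags/NaN through concentration conversion,
region averaging (invalid voxels are dropped per frame, with counts
reported) and the curve fits.

## Signal-to-concentration conversion

Baseline `R1(0)` is taken as `1/T10` from the VFA fit, and M0 likewise —
not re-estimated from the pre-injection frames. The per-frame inversion is
`q = S/(M0 sin α)`, `E1 = (1 − q)/(1 − q cos α)`, `R1 = −ln E1 / TR`,
`C = (R1 − 1/T10)/r1`, with relaxivity r1 = 4 s⁻¹ mM⁻¹. Frames where
`q cos α ≥ 1` or `E1 ∉ (0, 1)` (outside the physical branch — possible
under extreme noise or T1-shortening saturation) are flagged invalid.
Within the working range the SPGR signal is strictly increasing in C, so
the inversion is single-valued; the round trip is exact to < 10⁻⁸ mM for
T10 ∈ [300, 4500] ms and C ∈ [0, 5] mM.

Units: TR and T1 in milliseconds, relaxation rates in s⁻¹, concentrations
in mM, the kinetic time axis in minutes (Patlak units are per minute).

## Arterial input function

The AIF is the concentration curve of the single arterial-mask voxel with
the maximal *positive* excursion above its pre-injection baseline
(gadolinium raises SPGR signal at this dose, so absolute change is not
used). Selection is invariant to constant offsets; ties break to the
lowest flat index. No partial-volume, inflow or hematocrit correction is
applied — K_i is defined relative to the *whole-blood* tracer
concentration. A mask with no enhancing voxel raises a no-bolus error
rather than returning a degenerate curve.

## Patlak estimation

The plot coordinates are `x = ∫₀ᵗ C_a dτ / C_a(t)` (minutes) and
`y = C_t/C_a`; the integral uses the trapezoidal rule from the first frame
(pre-injection frames contribute ≈ 0, the lowest-order scheme consistent
with 3.2 s sampling). Points with `C_a(t) < c_min · max(C_a)` (default
c_min = 0.05) are excluded to avoid division by near-zero; the threshold
is configurable.

The line is fitted by OLS to the **last two-thirds of the frames** —
interpreted as indexing *time* (frames 101–300 of 300), applied before
validity filtering, because the stated purpose of the restriction is
steady-state arterial concentration. `K_i = 100 · slope / ρ` and
`CBV = 100 · intercept / ρ` with ρ = 1 g ml⁻¹. Fitting operates on
region-mean curves; voxelwise fitting is available through the same API
but is noise-sensitive and not the default path. Fewer than 3 usable
points raises a named fit error.

The one-compartment no-backflux premise means the model *underestimates*
K_i when back-diffusion exists; this is asserted directionally in the
tests, not corrected.

## Perfusion deconvolution

The discrete convolution operator A is lower-triangular with trapezoid
end-weights (`A @ ones` reproduces the running trapezoid integral of C_a
exactly). Standard-form Tikhonov (identity penalty, not a derivative
penalty) is solved in closed form by SVD with filter factors
`σ²/(σ² + λ²)`; λ is specified relative to the largest singular value
(default `lambda_rel = 0.1`; no automatic selection rule is imposed — the
default is explicit and overridable). Singular values below machine
precision × σ_max are dropped, so `lambda_rel = 0` reduces to the
pseudo-inverse. All frames enter the deconvolution. CBF is read as
100 · max(h) — robust to small bolus delays — rather than h(0). The
operator is causal/linear (no block-circulant delay handling): AIF and
tissue come from the same acquisition, so gross delays do not arise.

## Regions and drift

Probability masks threshold at `p ≥ threshold` (default 1.0, i.e. zero
tolerance for partial-volume voxels; inclusive so exactly-1.0 qualifies).
NAWM = white-matter mask ∧ (lesion probability exactly 0) — strict zero,
per the defining rule. Region means are unweighted; the default order is
*average the signal, then convert* (noise-robust); convert-then-average is
available via `convert_order="voxelwise"` and agrees on noise-free data.

Scanner drift is estimated as the OLS slope of the region-mean signal of a
contrast-free series, normalized to the fitted intercept, in % min⁻¹. The
main pipeline reports drift but does not correct it (an off-by-default
correction exists). The phantom shows why this matters: at the emulated
0.2 %/min drift the late-time tissue signal rise masquerades as uptake and
biases K_i upward by an amount comparable to NAWM K_i itself — drift
limits the *absolute* accuracy of K_i, though group contrasts survive when
drift is shared.

## Cohort statistics

- **Bland–Altman**: differences method1 − method2; LoA = mean ± 1.96 SD
  (z, not t); each LoA's 95% CI uses `t(n−1)` with `SE = √(3s²/n)`. This
  is the only multiplier combination that reproduces the published worked
  example's four CI bounds from its printed mean/SD. `loa_width` is
  computed as 3.92·s directly so the identity holds to the last bit.
- **ICC(3,1)**: two-way mixed, single-measure, consistency:
  `(MSR − MSE)/(MSR + (k−1)MSE)`; the residual sum of squares is computed
  from the interaction terms directly (the subtraction form cancels
  catastrophically when columns are shift-identical). CI via the standard
  F construction (McGraw–Wong).
- **ANCOVA**: `ki ~ group + age`; type-II sums of squares; partial
  η² = SS_group/(SS_group + SS_err); estimated marginal means at the
  grand-mean age. A zero-variance covariate degrades to one-way ANOVA.
- **Paired tests**: Wilcoxon signed-rank with the exact null for n ≤ 25
  (no ties), tie-corrected normal approximation otherwise; paired t as the
  parametric option.
- No multiple-testing correction (p-values are reported unadjusted); no
  log-transformation of K_i by default (the simulated cohorts are
  approximately normal; a transform can be applied upstream).

## The phantom: what it emulates and what it does not

Geometry is an abstract label map (blocks of voxels per compartment:
artery, GM, NAWM, enhancing lesion) — no anatomy, no registration, no
spatial placement rules. Compartment defaults: typical 3 T baseline T1s;
NAWM K_i 0.020 (healthy) with 0.052 as the patient-group cohort mean;
lesion K_i 0.139; GM/WM CBV ratio 1.9; CBF 55/27/30 ml (100 g)⁻¹ min⁻¹.

The AIF is a gamma-variate first pass (peak ≈ 3 mM, matching a half-dose
bolus) plus recirculation — modelled as the first pass dispersed through
an exponential transit-time kernel, which yields the physiological
shoulder without a spurious second local maximum — plus a slow washout
whose onset follows the cumulative first pass (same reason) and whose
decay keeps the late curve near 10% of peak, as blood-pool gadolinium
behaves over 16 minutes.

Tissue curves follow the irreversible one-compartment forward model
`C_t = K_i' ∫C_a + V_b' C_a`. Two vascular variants exist:

- **instantaneous** (default): the `V_b' C_a` term as written. This
  matches the fitted Patlak model exactly, so closure tests recover K_i,
  CBV and T1 to machine precision — but the curve then carries no
  meaningful transit-time information for deconvolution.
- **dispersed**: the vascular term becomes the discrete convolution of
  C_a with `F' exp(−t/θ)`, with θ solved (Brent) so the residue channel's
  *discrete trapezoid* area equals V_b' exactly. This carries a
  recoverable flow truth: deconvolution returns max(h) = F' + K_i'
  (≈ 0.1% high, far inside the 2% closure band). Mean transit times below
  half a frame interval are not representable on the grid and are
  rejected. The Patlak intercept on dispersed data is biased by
  ≈ MTT/τ_washout (a few tenths of a percent) — the known physical limit
  of the instantaneous-vascular assumption — so the exact CBV closure is
  asserted on the instantaneous variant.

Noise is Gaussian on the signal (default SD 0.2 a.u., roughly SNR 70 on
the baseline white-matter signal), appropriate for region-mean curves; it
is not Rician, so single-voxel magnitude statistics at very low SNR are
not faithfully emulated. Drift is multiplicative-linear at 0.2 %/min by
default. The cohort generator draws per-subject latent K_i from the group
normal distributions and observes it twice with independent method error
(SD 0.0285 per measurement, giving a pair-difference SD ≈ 0.040 and an
ICC in the moderate band). All randomness flows from a single mandatory
seed; equal seeds give bit-identical output.

Passing closure tests therefore demonstrate the *implementation* inverts
its own forward physics; they do not validate the model against real
tissue (water exchange, B1, motion, Rician noise and real AIF dispersion
are all outside the generator).

## Problem sizes and calibration checks

The phantom runs 145 voxels × 300 frames with a 300×300 SVD per region —
seconds per full pipeline. The statistical calibration simulates 1000 null
cohorts (n = 13 + 12) and measures the ANCOVA group-test rejection rate at
α = 0.05; the power check uses 200 replicates at a group difference of
0.042. With the study's unequal group ages the group factor and the age
covariate are correlated, which costs power: the measured rate is ≈ 0.65,
and the test bounds it from below accordingly.

## Known limitations

- No B1 mapping, water-exchange or bookend T1 correction.
- No bolus-arrival/delay estimation or circular deconvolution variants.
- Voxelwise K_i maps are supported but slow and noise-sensitive by design.
- The published subject-level group results depend on undeposited scans;
  they enter this package only as generator defaults and plausibility
  bands, never as assertions about real subjects.
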