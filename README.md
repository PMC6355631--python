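# bbbdce

Quantification of low-level blood–brain-barrier (BBB) leakage from dynamic
contrast-enhanced (DCE) MRI, with a digital phantom for end-to-end testing.

## The problem

Subtle BBB breakdown — as in normal-appearing white matter (NAWM) of people
with multiple sclerosis — leaks gadolinium at rates far below what visible
lesion enhancement produces. Measuring it needs a long dynamic acquisition,
careful conversion of signal to concentration, and a kinetic model that is
robust at very low contrast-to-noise. This package implements that
measurement chain for a whole-brain 3 T protocol (300 frames at 3.2 s,
half-dose bolus injected after frame 10, TR 2.48 ms, flip 15°, variable
flip angle pre-scan at 5/10/15/18°) and the group-level statistics used to
compare analysis methods and cohorts.

## The model

**Relaxometry.** The spoiled gradient-echo steady-state signal is
`S = M0 sin α (1 − E1)/(1 − E1 cos α)`, `E1 = exp(−TR/T1)`. Fitting the
variable-flip-angle (VFA) stack per voxel gives baseline `T1` (T10) and
`M0`; the dynamic signal is then inverted frame by frame to
`R1(t) = −ln E1(t)/TR` and converted to gadolinium concentration through
the relaxivity r1: `C(t) = (R1(t) − 1/T10)/r1`.

**Patlak plot.** For an irreversibly-taken-up tracer,

```
C_t(t)/C_a(t) = K_i · [∫₀ᵗ C_a dτ / C_a(t)] + V_b
```

is a straight line: the slope `K_i` (ml (100 g)⁻¹ min⁻¹, assuming tissue
density 1 g ml⁻¹) is the influx constant — the volume of blood cleared of
contrast per unit time — and the intercept `V_b` is the cerebral blood
volume (CBV). Only the last two-thirds of the frames are fitted, where the
arterial concentration is quasi-steady. The arterial input `C_a(t)` comes
from the carotid voxel with the largest signal excursion during bolus
passage.

**Perfusion.** Cerebral blood flow (CBF) is estimated model-free by
Tikhonov-regularized deconvolution of the tissue curve with the AIF:
`min ‖Ah − C_t‖² + λ²‖h‖²` solved via the SVD of the discrete convolution
operator `A` with filter factors `σ²/(σ² + λ²)`; CBF = 100 · max(h).

**Agreement statistics.** Bland–Altman limits of agreement (±1.96 SD, with
t-based confidence intervals), the two-way mixed single-measure consistency
ICC(3,1), ANCOVA of patient-vs-control K_i with age as covariate, paired
Wilcoxon tests, and multivariate regression of K_i on CBV, CBF and tissue
type.

**Digital phantom.** `make_phantom` synthesizes the whole acquisition from
known per-compartment truths (T10, K_i, CBV, CBF) through the same physics
the pipeline inverts — including a parametric AIF, scanner drift
(0.2 %/min) and Gaussian noise — so every stage can be verified by closure:
noise-free phantom in, configured truths out. `make_cohort` simulates the
two-method, two-group subject table for the statistics layer.

## Worked example

```python
from bbbdce import (PhantomConfig, make_phantom, fit_vfa_t1, extract_aif)
from bbbdce.pipeline import quantify_regions

cfg = PhantomConfig(noise_sd=0.0, drift_pct_per_min=0.0, seed=7)
stack, series, masks, truth = make_phantom(cfg)
t1m0 = fit_vfa_t1(stack)                       # VFA T1/M0 map
aif = extract_aif(series, masks["artery"], t1m0)
res = quantify_regions(series, t1m0, aif,
                       {k: v for k, v in masks.items() if k != "artery"})
print(res["NAWM"].patlak.summary())
```

```
Patlak one-compartment fit [NAWM]
----------------------------------------------
K_i        0.02000  (SE 0.00000)  ml/100g/min
CBV        1.80000  (SE 0.00000)  ml/100g
r^2        1.00000
n_fit      200
```

The noise-free phantom was generated with NAWM K_i = 0.020 ml (100 g)⁻¹
min⁻¹ and CBV = 1.8 ml (100 g)⁻¹; the pipeline returns exactly those
values with a perfect line fit over the 200 late frames — the
generator/pipeline closure that anchors the test suite. On the simulated
cohort (25 subjects, two analysis methods):

```python
from bbbdce import make_cohort, bland_altman, icc_single_measure_consistency
table, _ = make_cohort(seed=1)
wide = table.pivot_table(index="subject_id", columns="method", values="ki")
print(bland_altman(wide["roi"].to_numpy(), wide["segmentation"].to_numpy()).summary())
```

```
Bland-Altman agreement
----------------------------------------------------
n                                25
Mean difference            -0.00040
SD of difference            0.03426
Upper 95% LoA               0.06674  (95% CI 0.04225 to 0.09123)
Lower 95% LoA              -0.06755  (95% CI -0.09204 to -0.04306)
Width between LoA           0.13429
```

The mean difference near zero says the two analysis paths agree on average;
the limits of agreement bound the typical per-subject disagreement in K_i
units.

A CLI wraps the same stages:
`bbbdce quantify --seed 4 --out-dir out/`,
`bbbdce stats --seed 4 --out stats.json`.

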