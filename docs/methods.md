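# Methods

`issmri` quantifies the microstructure of the brain interstitial space
(ISS) and the clearance of interstitial fluid (ISF) from dynamic
T1-weighted MRI of a locally injected Gd-DTPA tracer, and provides the
simulation machinery to validate every step of that quantification without
animal data.

## Forward model

A bolus of `Q` = 20 nmol Gd-DTPA (10 mmol/L × 2 μL) is infused into deep
grey matter over 10 minutes. In the porous-medium description of brain
tissue, tracer released at a point spreads by hindered diffusion through
the ISS (volume fraction `α`) and is removed by first-order clearance, so
the ISF concentration around an instantaneous point source is

    C(r, t) = (Q/α) (4π D* t)^(−3/2) exp(−r²/(4 D* t) − k′ t)

with `D*` the effective diffusion coefficient (mm²/s) and `k′` the
clearance rate constant (1/s). With Q in nmol and r in mm, C is in mM.
Tortuosity is defined against a free-medium reference coefficient `D`:

    λ = sqrt(D / D*)

λ ≥ 1 in a classically tortuous medium; the package permits and flags
λ < 1 (fitted D* above the configured free coefficient) rather than
rejecting it, since group-level estimates below 1 do occur in pathology.

The 10-minute infusion is short against the first scan at 30 minutes, so
the default treats the source as instantaneous with the model clock
started at the infusion midpoint (`t_model = t + 300 s`). A superposition
mode that integrates point releases across the infusion window is provided
and shows the approximation errs < 5% at the first scan time (median
≈ 0.1%) over the region holding tracer.

Assumptions: homogeneous isotropic medium, no bulk-flow/advection term, no
spatially varying D*, spatially uniform first-order loss. These match the
scale of the question being asked (single-ROI group comparison), not the
full physiology.

## Signal model and phantoms

Gd-DTPA raises the water longitudinal rate linearly,
`R1(C) = 1/T1 + r1 α C` (the factor α converts ISF concentration to moles
per tissue volume). Two monotone signal laws are provided:

* saturation-recovery `S = S0 (1 − exp(−TR·R1))` (default; exact analytic
  inverse), and
* an inversion-prepared form `S = S0 sin(FA)(1 − 2e^(−TI·R1) + e^(−TR·R1))`
  using the protocol's TI (numeric inverse).

Only monotone invertibility matters downstream; the acquisition constants
are the study protocol's (TR 1500 ms, TE 3.7 ms, TI 900 ms, flip 12°,
0.5 mm isotropic voxels, scans at 0.5–8 h), while `r1 = 3.7 /(mM·s)`
(typical Gd-DTPA at 3 T), `T1 = 1000 ms` and `α = 0.2` (textbook grey-matter
ISS fraction) are documented defaults, all configurable. The default free
coefficient `D = 3.8 × 10⁻⁴ mm²/s` (Gd-DTPA in dilute medium at 37 °C) is
likewise a config parameter and is always reported next to λ.

Phantom studies draw each subject's (D*, k′) log-normally around a group's
central values with a chosen coefficient of variation, evaluate the closed
form on a 64³ grid of 0.5 mm voxels (3.2 cm cube — holds > 99% of tracer
mass over 8 h at study-scale D*), convert to signal, and add Rician noise
to baseline and frames. Noise level can be set directly (fraction of S0)
or via a target peak-increment SNR; "SNR 20" means the maximum noiseless
signal increment is 20× the per-channel noise σ. All randomness derives
from one integer seed; reruns are bit-identical.

What the phantoms do *not* emulate: anatomy (the background is uniform),
coil shading, motion beyond integer-voxel shifts, partial-volume CSF,
advective ISF flow, and needle-track backflow. Passing recovery tests
therefore demonstrates correctness of the estimation chain under the
stated model, not robustness to every in-vivo confound.

## Preprocessing

* **Registration** — exhaustive integer-voxel translation (±`max_shift`)
  maximizing normalized cross-correlation against the pre-injection
  baseline, scored over the valid overlap region only. Head-fixed rodent
  imaging at 0.5 mm voxels does not warrant rotations or sub-voxel
  interpolation, and integer shifts keep the operation exactly testable.
  Constant (featureless) frames get a zero shift and a warning. Simulated
  studies are generated aligned, so the analysis default is `max_shift=0`;
  raise it for real data.
* **Baseline subtraction** — increments `frame − baseline`; negative
  values are preserved. The increment noise scale is the standard
  deviation pooled over the eight 5³-voxel corner blocks, which are
  tracer-free by construction in this geometry.
* **Concentration conversion** — the signal law's inverse maps increments
  to ISF mM. The public concentration field is non-negative (negative
  increments → 0). Increments above 90% of the law's supremum sit where
  the inverse amplifies noise without bound; they are clipped to the
  concentration at that fraction and flagged per-voxel, and the clip
  fraction is logged.

  Alongside the public field the conversion carries a *signed estimation
  field*: the same smooth inverse analytically continued through zero,
  minus the delta-method noise bias `σ²/2 · (f⁻¹)″`. Two numerical facts
  force this companion: (i) zero-clipping puts a positive noise floor
  under every tracer-free voxel, and (ii) the inverse of any saturating
  law is convex, so applying it to noisy increments adds a small positive
  offset per voxel — ~2 × 10⁻³ mM here, which summed over a 64³ volume
  masquerades as ~14 nmol of tracer, five times the true late-time
  amount. Both effects would otherwise inflate apparent spread and
  suppress apparent clearance.

## Parameter estimation

`fit_diffusion_model` fits all masked (voxel, time) samples jointly to the
closed form with free parameters {amplitude A = Q/α, D*, k′, source
position}. Joint space-time fitting is what decouples D* (spatial profile
width) from k′ (late-time amplitude) with only ~10 frames.

Numerical choices:

* A and D* are optimized in log₁₀ space; bounds D* ∈ [10⁻⁶, 10⁻²] mm²/s,
  k′ ∈ [0, 10⁻²] /s; the source is bounded to ±1 mm around its initial
  estimate (the concentration-weighted centroid of the first frame),
  reflecting needle-placement uncertainty while keeping the problem
  identifiable.
* Deterministic multistart: a log-spaced 4×4 grid of (D*, k′) starts with
  the amplitude solved in closed form at each start; the best start seeds
  a bounded trust-region least-squares solve.
* The voxel mask takes voxels whose signed concentration exceeds
  `mask_snr` (default 3) × the concentration-space noise floor at ≥ 1
  time point, keeps the largest connected component (the physical
  spreading region is one blob; isolated suprathreshold voxels are noise
  excursions whose selection-conditioned values bias the fit), and
  dilates it by 4 voxels so that inclusion of the near-threshold band is
  geometric rather than conditioned on each voxel's own noise. All time
  samples of a masked voxel enter the fit. Sample count is capped
  (deterministic stride) at 120 000.
* The residual is evaluated in **signal space** when the series carries
  its signal law (the pipeline always attaches it): `residual =
  law(C_model) − increment_observed`. MR noise is additive and symmetric
  in signal space, whereas a plain concentration-space least squares is
  biased by the convex, heteroscedastic inverse near saturation (measured
  bias on SNR-20 sham phantoms: D* +7%, k′ −25%). This is exactly a
  weighted concentration-space fit with weights equal to the signal-law
  slope. For bare concentration series (no law attached) the fit falls
  back to concentration space with unit weights and treats
  saturation-clipped samples as right-censored (one-sided residual).
* 95% confidence intervals come from the Jacobian at the optimum
  (log-normal for D*, truncated normal at 0 for k′); R² and RMSE are
  reported in residual space.

Degenerate inputs: all-zero concentration → "no tracer detected"; fewer
than 3 frames or 50 masked samples → error; non-convergence after
multistart → error carrying the best residual.

## ISS metrics

* **Spreading region** — a voxel is "lightened" when its increment exceeds
  `k_sigma` (default 3) × the estimated increment noise; volume = count ×
  0.125 mm³. The curve, its maximum `v_max` and the time of maximum
  `t_max` are reported with the threshold used. Raising the threshold can
  only shrink volumes (tested property). Note the plain threshold counts
  ~0.1% of background voxels under noise; volumes are descriptive, not
  acceptance-bearing.
* **Half-life** — computed on the total in-brain amount
  `A(t) = α Σ C·ΔV` of the signed field (an unbiased amount estimate;
  see above). The default log-linear method regresses log A on time over
  all points from the global maximum onward and reports
  `t½ = ln 2 / rate` in minutes; an interpolation method returns the time
  at which A first falls to half its peak. Both agree exactly on a pure
  exponential. For the pure forward model t½ ≈ ln 2 / k′; on real data
  the two differ because t½ also absorbs diffusion out of the field of
  view and bulk ISF outflow — reports should state both numbers, and the
  per-subject report does. Total amount was chosen over peak-voxel
  concentration because it is robust to registration jitter; a peak-voxel
  reading can be assembled from the concentration series directly.

## Group statistics

Per-metric group summaries (mean ± SEM) feed a one-way fixed-effects ANOVA
computed from sums of squares, followed by the Student–Newman–Keuls
stepwise range procedure: group means are ordered and a pair spanning `p`
ordered means is significant when its range exceeds
`q(α; p, df_within) · sqrt(MS_within/n_h)`, stepping down and never
testing a pair nested inside a non-significant span. Studentized-range
quantiles come from `scipy.stats.studentized_range`; an independent test
recomputes every decision from scratch. Unequal group sizes use the
harmonic mean n with a logged note. α defaults to 0.05.

The reference table of group parameters bundled with the generator
(`GROUP_PARAMS`) lists each group's central D*, k′, λ and t½ together with
between-subject standard deviations; the power study draws per-subject
metric values from these Normal distributions. In-vivo reports of this
design often print "± SEM", but at n = 10 that reading would imply
per-subject λ scatter of ±1.0 around 1.56 — physically implausible — so
the table's ± values are defined and used as between-subject SDs; this is
a modelling choice of the generator, stated here once.

## Validation studies and problem sizes

`issmri.validation` packages the calibration experiments the test suite
and `scripts/acceptance.py` run:

* `recovery_study`: 10 phantoms per group at the group's central values
  (zero between-subject CV isolates measurement noise), SNR 20, 64³ grid,
  11 volumes — the chain recovers median D* within ~1%, k′ within ~3%,
  λ within ~1% of truth.
* `half_life_recovery`: exponential amount curves at the groups'
  half-lives, 2% multiplicative noise at the 0.5–8 h schedule, 20 seeds.
* `group_power_study`: 50 metric-level replicates of the three-group
  design; rotenone vs sham is declared by SNK in ≥ 90% of replicates for
  D*, λ, k′ and t½.

These sizes run the whole validation in a few minutes on one CPU and give
medians stable to well under the tolerances being checked; they are the
package's chosen defaults, and all are parameters.

## Known limitations

* The tortuosity report is only as meaningful as the configured `D`; a
  single `D` cannot make all three groups' published (D*, λ) pairs
  mutually consistent, so λ is always reported together with the `D`
  used.
* No advection: clearance by bulk ISF flow is absorbed into k′ and t½
  rather than modelled.
* Integer-voxel registration cannot correct rotations or sub-voxel
  drift.
* The saturated core (top ~10% of the signal law's range) contributes no
  quantitative information; with very high doses or very slow diffusion
  the usable shell shrinks and CIs widen accordingly.
* Rician noise is treated as symmetric at the working SNR (baseline SNR
  ≈ 70 here); very low SNR acquisitions would need the full Rician
  likelihood.
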