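# Methods

## Forward electromagnetic model

The simulator models a single transverse slice at the 3 T proton Larmor
frequency (42.577 MHz/T × 3 T = 127.731 MHz ≈ 128 MHz). For a z-invariant
geometry with constant permeability μ₀, Maxwell's equations reduce exactly to
the scalar transverse-magnetic (TM) problem for the longitudinal electric
field,

    ∇²Ez − iωμ₀ γ̃ Ez = 0,     γ̃ = σ + iωε₀ε_r,

discretized with the 5-point stencil on a uniform grid and solved as one
sparse complex system with Dirichlet boundary values (direct solve; relative
residual checked to 1e-10). Faraday's law gives the positively rotating RF
field

    H⁺ = (∂ₓEz + i ∂ᵧEz) / (2ωμ₀),

computed by central differences (one-sided at edges). Verified properties:
second-order convergence against the analytic plane wave (error ratio ≈ 4 per
grid halving) and exact linearity in the boundary data.

**Illumination.** The default boundary condition is a birdcage-like standing
cylindrical mode `Ez = J₀(kr)` with `k² = −iωμ₀γ̃` taken from the
object-average admittivity; a travelling plane wave is also available and is
used for the convergence oracles. A single plane wave has an identically
linear phase (`∇²φ = 0`), which renders phase-only reconstruction degenerate,
so the standing-wave default keeps all three estimators well-posed.

**Echo synthesis.** Transceive phase is modelled as twice the transmit phase
(transmit ≈ receive), so the noiseless echo phase is `2·arg H⁺` and the
magnitude `|H⁺|·exp(−TE/T2)`; defaults follow a 6-echo acquisition, first
echo 12 ms, 12 ms spacing, uniform T2 = 80 ms. Independent complex Gaussian
noise per echo uses per-channel SD `mean|H⁺|/SNR`. Echoes are combined by a
magnitude²-weighted circular mean (wrap-insensitive, ML-like weighting) and
the combined phase unwrapped with 2-D quality-guided unwrapping
(scikit-image) before any Laplacian is taken.

## Reconstruction

All stencil outputs exclude a 2-pixel rim; error metrics additionally erode
each tissue label (default 3 px) to separate interior accuracy from boundary
artifacts.

**Phase-based:** `σ = ∇²φ_tr/(2μ₀ω)`. Residual phase wraps (neighbour jumps
> π) are detected, warned about and invalidated.

**Standard (Helmholtz) MREPT:** `γ̃ = ∇²H⁺/(iωμ₀H⁺)`, with pixels below a
magnitude floor (1e-6 × median |H⁺|) invalidated. Exact where γ̃ is locally
constant; exhibits the characteristic overshoot at tissue interfaces.

**cr-MREPT.** Differentiating the Helmholtz identity with the Wirtinger-type
operator `D = ∂ₓ + i∂ᵧ` (for which `D̄D = ∇²`) eliminates Ez exactly and
yields, for `β = 1/γ̃`,

    β∇²H⁺ + F·∇β = iωμ₀H⁺,   Fx = ∂ₓH⁺ − i∂ᵧH⁺,  Fy = iFx,

valid for arbitrary in-plane σ, ε — including across boundaries, which is why
cr-MREPT suppresses the interface overshoot. The discrete system uses central
differences for ∇β, an added artificial-diffusion (regularization) term
c∇²β, and Dirichlet β on the mask boundary ring; β is obtained by a sparse
direct solve and σ = Re(1/β). (The permittivity channel Im-part is computed
but is not a validated output.)

Numerical choices that required a decision:

- **Regularization coefficient.** Default `c = 0.01·dx·median|F|`. Scaling c
  linearly in dx keeps the mesh Péclet number `|F|dx/(2c)` constant under
  refinement; with a c ∝ dx² rule the Péclet number grows as 1/dx and the
  central-difference convection operator develops large oscillatory errors on
  fine grids (observed: per-label median errors rising from ~3–5% at
  dx = 1.8 mm to ~17–28% at dx = 0.9 mm). Sensitivity: on the two-compartment
  benchmark, scale factors 0.0025–0.02 all give 2–5% per-label median error
  across dx = 0.9–3.6 mm; 0.05 and above over-smooths (≥ 10% error), and
  c = 0 is unusable because the operator degenerates where |F| → 0 (the
  well-known artifact at the convective-field null of standing-wave
  illumination). The coefficient is exposed everywhere (`c_diff`).
- **Boundary β.** Default is the median of the complex Helmholtz estimate
  over a band 3–6 px *inside* the mask, assigned uniformly to the ring. On
  the ring itself any estimate straddles the object/air admittivity jump and
  is badly wrong, and the convection-dominated system amplifies boundary
  errors; a few pixels inside, the outer compartment is locally homogeneous
  and the estimate is accurate (homogeneous inverse crime then exact to
  1e-12). A phase-based variant (`bc_values="phase"`) exists but discards the
  imaginary part of β, which is not negligible at 128 MHz. Explicit constants
  or maps can be passed (the tests use the true β for inverse-crime checks).
- **Global phase.** All estimators must be invariant to `H⁺ → e^{iθ}H⁺`.
  Every term of the cr system scales with θ except the real diffusion term,
  so assembly first normalizes the global phase at the max-|H⁺| anchor pixel,
  making the invariance exact rather than O(c).

**Phase-based σ/2 limit.** In this 2-D TM world H⁺ is a *derivative* field:
for the birdcage mode, `H⁺ ∝ J₁(kr)e^{iθ}` — a phase vortex whose radial
phase accumulates at half the rate of the node-less J₀-like B1⁺ of real 3-D
coils (near the axis `arg J₁(kr) ≈ const + r²ωμ₀σ/8` versus
`arg J₀(kr) ≈ r²ωμ₀σ/4`). Consequently `∇²(2 arg H⁺)/(2μ₀ω) → σ/2`, and the
phase-based estimator recovers ≈ 50% of the true conductivity (measured
0.50σ on small domains). This is a faithful property of the 2-D reduction,
not of the estimator as used on real 3-D data; the Helmholtz-exact estimators
(std, cr) are unaffected. A green phase-based test therefore establishes the
estimator's formula and wrap handling, not clinical-accuracy expectations.

**Smoothing.** Gaussian smoothing takes FWHM in mm (`sd = FWHM/√(8 ln 2)`),
reflective boundaries; FWHM 10 mm is the conventional pre-GLM setting.

## Cohort simulator

The generator emulates a 74-subject cross-sectional cohort: group sizes
24/27/23 (CN/MCI/AD); ages normal at (73.0 ± 4.7), (74.2 ± 4.4),
(76.1 ± 7.6) years; MMSE normal truncated to [0, 30] at (27.8 ± 2.3),
(26.8 ± 1.2), (19.6 ± 4.2); male fractions 0.50 / 1/3 / 6/23. ROI values per
subject, ROI and measure follow

    value = center(group) + slope·(age − age_group) + sign·s·severity + noise,

with group centers at the published medians and total within-group SD =
IQR/1.349 (normal-family reading of the printed median (IQR) summaries).
Design choices:

- **Age slope** is centered on each group's nominal mean age: the published
  group medians already contain whatever age effect exists, so a pooled-age
  term would double-count it. Slopes are scaled to pooled age correlations of
  +0.35 (HFC) and −0.30 (volumes), matching the reported rank-correlation
  range; measured pooled Spearman ρ ≈ 0.35 at n = 74.
- **Severity coupling.** Each subject's standardized within-group MMSE
  deficit acts as a shared latent severity entering HFC positively and the
  volumes negatively, carrying 15% of the within-group variance. This yields
  age-adjusted MMSE partial correlations with the published signs; pooled
  magnitudes exceed the published ones because the between-group separation
  dominates a pooled correlation in clean synthetic data.
- **Physical ranges.** HFC is clipped positive; GMV/WMV to (0, 1). TIV ~
  N(1450, 130) mL (not in the published tables; a typical elderly value).

What the generator does *not* emulate: atrophy topography, non-normal/skewed
marker distributions, scanner/site effects, comorbidity structure. One
consequence is quantified in the calibration tests: the published ROI table,
read through the normal family, implies a CN-vs-AD insular-HFC population AUC
of Φ(d/√2) ≈ 0.925 (d = 0.074/0.036), slightly above the observed 0.902 —
the real data were evidently heavier-tailed than the normal emulation. The
200-seed bracket check on AUC ∈ [0.80, 0.97] therefore sits at ≈ 88%
in-bracket (essentially all excursions above 0.97, i.e. the synthetic cohort
separates *too well*), which the acceptance suite reports rather than hides.
Subject maps render ROI values onto a labelled template with a within-ROI
demeaned smooth field plus voxel noise, so ROI means stay exactly at the
table values.

## Statistics

- ANOVA accepts raw groups or printed (n, mean, sd) summaries (exact sum-of-
  squares reconstruction); Scheffé uses the (k−1)·F_crit criterion.
  Kruskal–Wallis is tie-corrected with χ²(k−1) p-values; all-identical input
  returns H = 0, p = 1. Conover–Iman uses pooled mid-ranks, the tie-adjusted
  rank variance deflated by (N−1−H)/(N−k), and t(N−k) p-values, unadjusted by
  default (Bonferroni optional).
- Partial correlation is Pearson-on-residuals with df = n − k − 2; a
  rank-transformed variant is available (`method="spearman"`). Normality
  (KS) is reported as a diagnostic only, never an automatic test switch.
- AUC is the Mann–Whitney concordance (ties ½), oriented to ≥ 0.5; the
  optimal criterion maximizes Youden's J with ties broken toward higher
  specificity; the p-value against AUC = 0.5 uses the Hanley–McNeil normal
  approximation (DeLong comparison tests are out of scope). Logistic models
  are unpenalized IRLS fits (gradient tolerance 1e-8, max 100 iterations)
  with collinearity rejection and perfect-separation flagging; combined
  models are fitted and evaluated on the same sample, as conventional for
  added-value tables — combined AUCs are optimistically biased and are
  within-cohort comparisons, not validated classifiers.
- The voxel-wise GLM is ordinary least squares run for all voxels at once
  (cell-means group coding plus centered covariates), with exact t/F
  contrast p-values, BH-FDR within the analysis mask, and cluster-extent
  filtering (face connectivity by default, the common SPM convention;
  configurable). FDR is applied before the extent rule; both the order and
  the 100-voxel default are configurable.

## Reproducibility

A single integer seed drives every stage: `SeedSequence(seed).spawn` expands
it into fixed-order child seeds (echo noise, demographics, ROI values, maps).
Studies write CSV/NIfTI outputs plus a JSON sidecar with the seeds, the
parameters and a config hash; reruns at the same seed are bit-identical.

## Known limitations

Single-slice 2-D model (no slice profile, no 3-D coil field — hence the
phase-based σ/2 limit above); Gaussian noise only (no physiological or motion
artifacts); uniform T2 by default (spatially varying T2 biases the magnitude
channel of std/cr reconstruction); no spatial normalization/segmentation
(maps are generated in a common labelled space by construction); in-sample
ROC evaluation without cross-validation.
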