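# hfcmri

Phantom-based simulation and statistics pipeline for **high-frequency
conductivity (HFC) mapping** in dementia imaging.

At 3 T the RF field of an MRI scanner drives a ~128 MHz current through the
head; the induced, admittivity-dependent B1 field can be inverted for the
tissue conductivity σ (S/m) without electrodes — MR electrical properties
tomography (MREPT). Elevated insular HFC has been proposed as an imaging
marker that separates Alzheimer's disease (AD) patients from cognitively
normal (CN) elderly, complementing hippocampal gray-matter volume (GMV).
Clinical MRI of that kind is not publicly shareable, so this package provides
the full desk-scale analogue for methods work and power analysis:

1. **Electromagnetic phantom simulation** (`hfcmri.phantom`) — 2-D
   transverse-magnetic forward model `∇²Ez − iωμ₀γ̃Ez = 0` over a piecewise
   admittivity map `γ̃ = σ + iωε`, solved with 5-point finite differences;
   `H⁺ = (∂ₓEz + i∂ᵧEz)/(2ωμ₀)`; multi-echo spin-echo transceive phase with
   T2 decay and complex Gaussian noise (6 echoes, TE = 12…72 ms).
2. **Conductivity reconstruction** (`hfcmri.recon`) — three estimators:
   phase-based `σ = ∇²φ_tr/(2μ₀ω)`; standard Helmholtz MREPT
   `γ̃ = ∇²H⁺/(iωμ₀H⁺)`; and convection–reaction (cr-)MREPT in the unknown
   `β = 1/γ̃`,

   ```
   c∇²β + F·∇β + (∇²H⁺)β = iωμ₀H⁺,   Fx = ∂ₓH⁺ − i∂ᵧH⁺,  Fy = iFx,
   ```

   which stays exact across tissue boundaries; the artificial-diffusion
   coefficient `c` regularizes the discrete first-order operator.
3. **Cohort simulation** (`hfcmri.cohort`) — a three-group CN/MCI/AD cohort
   (n = 24/27/23) with ages, sex, MMSE and per-ROI HFC/GMV/WMV values whose
   group medians and IQRs follow published AD-signature-ROI tables
   (hippocampus, insula, precuneus, middle temporal gyrus).
4. **Statistics** (`hfcmri.stats`, `hfcmri.roc`, `hfcmri.glm`) — ANOVA with
   Scheffé post-hoc (raw data or printed summary statistics), tie-corrected
   Kruskal–Wallis with Conover–Iman post-hoc, χ², Spearman and age-adjusted
   partial correlation; Mann–Whitney AUC with Youden-optimal criterion and
   Hanley–McNeil p-values, logistic added-value models; voxel-wise
   ANCOVA/regression GLM with BH-FDR and cluster-extent filtering.

## Worked example

```python
from hfcmri import RunConfig, run_phantom_study, run_cohort_study

out = run_phantom_study(RunConfig(seed=1, out_dir="results/phantom"))
print(out["report"][["method", "median_label1", "median_label2"]])

res = run_cohort_study(RunConfig(seed=1, out_dir="results/cohort"))
roc = res["roc"].set_index("markers")
print(roc.loc[["insula_hfc", "gmv+insula_hfc"], "CN_vs_AD_auc"])
```

prints (seed 1):

```
  method  median_label1  median_label2
   phase         0.2651         0.3109
     std         0.3400         0.5900
      cr         0.3361         0.5821

insula_hfc        0.920
gmv+insula_hfc    0.987
```

The phantom is a WM-like head disk (σ = 0.34 S/m, label 1) with a GM-like
inclusion (σ = 0.59 S/m, label 2), imaged noiselessly. The Helmholtz-exact
estimators recover both compartments (std is exact in this inverse-crime
setting; cr is within ~1.5% while also suppressing the boundary overshoot
that std produces at the interface). The phase-based estimator lands near
σ/2 — an intrinsic limit of phase-only reconstruction under the 2-D model's
vortex-shaped H⁺, documented in `docs/methods.md`. In the cohort half, the
simulated insular HFC separates CN from AD with AUC ≈ 0.92, and adding
hippocampal GMV raises the in-sample logistic AUC further.

The same pipelines are scriptable from the shell:

```sh
hfcmri run-all --seed 1 --out results/
hfcmri roc results/cohort/roi_values.csv --combine hippocampus:GMV --combine insula:HFC
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computation from scratch at the given seed — the
full phantom study (simulation, forward solve, echo synthesis, all three
reconstructions, error report) and the full cohort study (simulation plus
the group-comparison, correlation and ROC tables) — prints the headline
reconstruction medians and AUCs, and writes the results JSON to `--out`.
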