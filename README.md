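# bnctdose

Voxel dosimetry for boron neutron capture therapy (BNCT) with a
PET-quantified **heterogeneous** intratumoral boron distribution.

Most BNCT treatment planning assumes the boron carrier (¹⁰B-BPA) is spread
uniformly through the tumor at a single tumor-to-normal ratio (TNR). In
reality ¹⁸F-BPA PET shows strongly non-uniform uptake, and because ¹⁰B both
receives dose (via ¹⁰B(n,α)⁷Li) and depresses the thermal neutron flux
(self-shielding), a uniform-boron assumption distorts the dose distribution:
it hides cold spots in low-uptake regions and overestimates prescription
indices such as Ḋ₈₀. `bnctdose` implements the full correction chain for
medical physicists and method developers:

1. **SUV / TNR mapping** — per-voxel standardized uptake value from PET
   intensity, `SUV(V) = I(V)·ACF·BW / (ID·2^(−Δt/T))`, resampled onto the
   CT grid where the GTV is delineated, and normalized by the mean SUV of a
   normal-tissue ROI to give a per-voxel TNR map.
2. **Conservation-normalized grouping** — the TNR field is quantized into
   `I` evenly spaced concentration groups (default 50) with midpoints
   `mid_i = (upper−lower)/I·(i−0.5)+lower`, group index
   `i = ⌈I·(v−lower)/(upper−lower)⌉`, and a normalization factor
   `k = Σ_V v(V) / Σ_i N_i·mid_i` so the total number of boron-10 atoms is
   exactly conserved. A conversion factor ξ anchors TNR = 1 to a prescribed
   blood ¹⁰B concentration (ppm by mass).
3. **Flux engine with self-shielding** — a deterministic reference engine
   attenuates a broad parallel thermal beam,
   `φ = φ₀·exp(−∫[Σ_t + σ_B·n_B10(s)]ds)`, so boron-rich regions depress
   their own and downstream flux. Per-voxel capture rate `R_B10 = σ_B·φ`,
   boron dose `D_B(V) = N_B10(V)·R_B10(V)·E_cap/Mass(V)`, and
   flux-proportional neutron/photon components.
4. **Weighted dose and reporting** — bioequivalent total
   `D_BNCT = CBE·D_B + RBE_N·D_N + RBE_P·D_P` (defaults 3.8 / 3.2 / 1.0),
   cumulative DVHs, Ḋmax/Ḋmin/Ḋmean/Ḋ₈₀ statistics, and side-by-side
   homogeneous-vs-heterogeneous comparison tables with component breakdowns
   at the extremum voxels.
5. **Synthetic phantoms** — CT/PET/ROI fixtures with known truth TNR fields
   (uniform, gradient, Gaussian blob, bimodal), Gaussian PSF blur and exact
   block-average downsampling to a coarser PET grid, reproducing the
   partial-volume effect so every stage is testable without patient data.

## Worked example

Generate a phantom with a linear TNR gradient (1.5 → 4.0 across a 10 mm
tumor sphere, 5 mm PET PSF, 5×5×3 mm PET voxels) and compare both dose
modes:

```bash
python - <<'EOF'
from bnctdose import RunConfig, PhantomSpec
RunConfig(phantom=PhantomSpec(tnr_field=("gradient", 1.5, 4.0)), seed=1).save("example.yaml")
EOF
bnctdose all --config example.yaml --out example_run --seed 1
```

which prints (dose rates in cGy-Eq/s):

```
ROI GTV: 4224 voxels, TNR 1.38-3.02 (mean 2.14)
groupwise: I=50, k=0.999773
roi         method  d_max   d_min  d_mean    d_80
GTV           homo  1.624   1.312   1.466   1.394
GTV         hetero  2.020   0.942   1.465   1.229
GTV difference_pct 24.402 -28.181  -0.061 -11.845
```

Reading the numbers: PSF blur and the coarse PET grid shrink the recovered
TNR range (truth 1.5–4.0 → 1.38–3.02, the partial-volume effect). The mean
dose rate is essentially method-independent (−0.06 %) because grouping
conserves the total boron load, but the uniform-boron assumption
overestimates the minimum dose rate by 28 % and Ḋ₈₀ by 12 % — exactly the
cold-spot masking the heterogeneous method corrects. The output directory
contains the TNR histogram, grouping report, per-mode dose fields and DVHs
(NIfTI/CSV), comparison tables, dose-slice images and a full run log;
stage-wise subcommands (`phantom`, `suv`, `group`, `dose`, `report`) run the
same chain incrementally.

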