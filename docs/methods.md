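# Methods

## Problem and model

BNCT delivers dose through three channels: the ¹⁰B(n,α)⁷Li capture
reaction, fast/thermal neutron interactions with tissue (¹H(n,n')p,
¹⁴N(n,p)¹⁴C), and photons. The bioequivalent dose rate combines the
physical components with radiobiological weights,

    D_BNCT = CBE·D_B + RBE_N·D_N + RBE_P·D_P    [Gy-Eq/s],

with defaults CBE = 3.8 (tumor, BPA), RBE_N = 3.2, RBE_P = 1.0. The boron
component dominates in tumor, so the spatial distribution of ¹⁰B — the
product of where the drug accumulates and where thermal neutrons survive —
controls the dose distribution.

The package quantifies the drug term from ¹⁸F-BPA PET. Per-voxel SUV is

    SUV(V) = intensity(V)·ACF·BW / (ID·2^(−Δt/T)),

where Δt = measurement − scan time in minutes (signed; decay of the tracer
during the acquisition itself is neglected) and T is the tracer half-life
(F-18: 109.771 min). TNR(V) = SUV(V)/SUV_mean(normal ROI) serves as the
relative boron concentration, with TNR = 1 anchored to a prescribed blood
¹⁰B level. SUV's kg/ml unit mix is never converted onward: the anchor
constant ξ (atoms per voxel per unit TNR) absorbs it.

### Grouping with conservation

Carrying one material per voxel is impractical for a transport engine, so
the TNR field over the ROI is quantized into I evenly spaced groups
(default I = 50; the material count scales as M×I, which is why I stays
small). Midpoints, ceiling group index and the conservation factor k are

    mid_i = (upper−lower)/I·(i−0.5) + lower,
    i(V)  = ⌈I·(v(V)−lower)/(upper−lower)⌉  clamped to [1, I],
    k     = Σ_V v(V) / Σ_i N_i·mid_i,

so grouped atom totals ξ·k·Σ N_i·mid_i equal exact totals ξ·Σ v(V) by
construction (the package asserts 1e-9 relative; measured agreement is at
float64 rounding). The ceiling index is ill-defined only at the ROI lower
bound (it yields 0) and is clamped to 1; a value exactly on an interior
edge belongs to the group whose upper edge it is, per the ceiling
arithmetic. A degenerate ROI (upper == lower) collapses to one group with
k = 1.

### Dose scoring

The heterogeneous mode transports with the **grouped** boron map (that is
the point of grouping) but scores the boron dose with the **exact**
per-voxel atom count N_B10(V) = ξ·v(V), which is closer to the true dose
than the quantized value. The homogeneous mode assigns every ROI voxel the
ROI-mean TNR. Capture energy is assumed locally deposited:

    D_B(V) = N_B10(V)·R_B10(V)·E_cap / Mass(V),   R_B10(V) = σ_B·φ(V).

Masses come from voxel volume times density; the default density model
assigns water (1.0 g/cm³) to all ROI voxels, with a 3-point piecewise-
linear HU→density lookup (air/water/bone) available when a CT calibration
is wanted.

## Reference transport engine

The engine is a deterministic narrow-beam attenuation model, not Monte
Carlo: a broad parallel thermal beam enters one grid face and each voxel
column is ray-marched,

    φ(center of voxel j) = φ₀·exp(−Σ_{upstream} μ·Δ − μ_j·Δ/2),
    μ = Σ_t + σ_B·n_B10  [1/cm],

which reproduces the closed-form exponential exactly on uniform media
(flux is evaluated at voxel centers). The boron term gives the two effects
that matter for the homo/hetero contrast — boron-weighted dose and
self-shielding/flux depression — and can be switched off independently of
dose scoring (`BeamConfig.self_shielding`) to isolate conservation
properties. The engine sits behind `compute_dose_field`, so a Monte Carlo
engine producing the same per-voxel R_B10 tally can replace it.

Default constants (all config-overridable) are standard literature
magnitudes: σ_B = 3837 b (2200 m/s ¹⁰B capture), E_cap = 2.33 MeV locally
deposited (α + ⁷Li, excluding the 478 keV prompt photon), Σ_t = 0.1 /cm
generic tissue removal, φ₀ = 1e9 n/cm²/s, neutron kerma 3e-13 Gy·cm² and a
flux-proportional photon proxy 1.5e-12 Gy·cm² (capture-gamma background;
the constant beam-port term defaults to 0 so all outputs are linear in
φ₀). With a 25 ppm blood ¹⁰B level and ~1 mm³ water voxels these produce
tumor dose rates of order 1–2 cGy-Eq/s with an 85–95 % boron fraction,
i.e. clinically shaped numbers; the absolute scale cancels from every
homo-vs-hetero ratio, which is the quantity of interest.

## Reporting conventions

- Statistics: Ḋmax/Ḋmin are single-voxel extrema; Ḋmean the unweighted ROI
  mean; Ḋ₈₀ the dose covering 80 % of the ROI, computed bin-free by linear
  interpolation on the descending-sorted voxel doses at rank 0.8·N.
- DVH curves use 200 uniform bins from 0 to the field maximum; statistics
  never come from the binned curve.
- Differences are 100·(hetero − homo)/homo, sign retained, printed at one
  decimal. Component percentages are taken against the sum of the three
  weighted components at that voxel. Rates are reported in cGy-Eq/s
  (internally SI).
- Extremum component breakdowns are evaluated at the argmax/argmin voxel
  of each method's own weighted total dose.

## Coordinate and I/O conventions

LPS patient space, 0-based indices, voxel values at voxel centers,
physical position = origin + direction·(spacing ⊙ index). NIfTI files
(RAS) are sign-flipped on read/write. DICOM series are sorted along the
slice normal with uniform-spacing enforcement (the offending slice is
named on failure) and rescale slope/intercept applied. PET is always
resampled (trilinear) onto the CT grid, where the GTV is delineated;
reference-grid voxels outside the PET extent are filled with 0 and
counted in the log. ROI membership is voxel-center-in-polygon (even-odd
rule, no partial-voxel weighting); polygon contours with fewer than three
points, non-planar contours, or contours enclosing no voxel center are
hard errors.

## Synthetic phantoms

The generator emulates the acquisition features the method is sensitive
to: a CT-resolution truth TNR field inside an ellipsoidal tumor (uniform,
linear gradient, Gaussian blob or bimodal), isotropic Gaussian PSF blur
(default FWHM 5 mm), exact block-average downsampling to the PET grid, and
optional Poisson noise (off by default so unit tests are deterministic).
PET spacing is constrained to integer multiples of the CT spacing so
downsampling is exactly mean-preserving; the defaults (1 mm CT,
5×5×3 mm PET) mirror the clinical brain PET/CT voxel mismatch. The normal
ROI is a fixed cuboid away from the tumor with baseline SUV 1.0.

The default comparison phantom orients the TNR gradient perpendicular to
the beam axis inside a sphere centered on the grid's symmetry point. With
self-shielding disabled the flux then depends only on depth while the
slab-mean TNR equals the ROI mean at every depth, so the homogeneous and
heterogeneous ROI-mean boron doses agree exactly — the sharpest available
test of atom conservation through the whole chain. The "sharp" variant
(no PSF, PET grid = CT grid) removes partial-volume confounding for that
test; the blurred variants exercise it deliberately.

What the phantoms do **not** model: PET reconstruction (sinograms, OSEM,
scatter/randoms), registration error between PET and CT, anatomical
heterogeneity (CT is uniform water), or energy-dependent neutron spectra.
Passing tests therefore demonstrate correctness of the computational
chain and the qualitative physics (conservation, self-shielding,
partial-volume trends, DVH broadening), not clinical accuracy for any
patient.

## Numerical choices

- Resampling uses ITK trilinear interpolation, which reproduces affine
  fields exactly; identical grids short-circuit to a copy so identity
  resampling is bitwise.
- TNR floor: none by default (clinical GTVs can contain TNR < 1; those
  voxels are exactly the cold spots of interest).
- Histogram upper bin is closed (numpy convention); the cumulative
  volume-fraction curve is a suffix sum, anchored at exactly 1 and 0.
- Test tolerances for phantom-recovery checks use an a priori blur-leakage
  bound — the tumor/background contrast lost in a boundary shell one PSF
  FWHM thick — rather than tuned constants.
- All randomness (phantom noise, test fields) flows from a single integer
  seed; pipeline artifacts are byte-reproducible for a fixed seed.

## Problem sizes

The standard phantom suite uses 60³–64³ CT grids (~0.2 M voxels, ~4 k–34 k
tumor voxels), which resolves the sphere against both the PSF and the PET
blocks while keeping the full suite and the acceptance script at desk
scale (seconds per pipeline run).

## Known limitations

- The reference engine is one-dimensional per column: no scatter, no
  angular redistribution, no buildup; flux depression is therefore
  somewhat sharper than a Monte Carlo engine would produce.
- Neutron/photon components are flux-proportional proxies with constant
  kerma coefficients; normal-tissue CBE values and beam-port photon
  spectra are out of scope.
- ξ applies the blood-ppm anchor to TNR rather than raw SUV; the two
  differ only by the constant normal-tissue baseline absorbed into ξ, and
  every homo/hetero contrast is invariant to the anchor (tested).
- No deformable or automated rigid registration: PET and CT are assumed
  co-registered (an optional rigid 4×4 transform is accepted); no
  registration QC metric is invented.
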