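# Methods

## Model

`gbmsim` simulates the cell density `c(x, t)` (cells/mm³) of a
glioblastoma lesion on a voxel grid with physical spacing and a brain
mask. The governing equation is piecewise in the (irreversible) necrosis
state of each voxel:

    ∂c/∂t = ∇·(D(x) ∇c) + ρ c (1 − c/c_m)      while m(x) < τ·c_m
    c(t + Δt) = η^Δt · c(t)                      once  m(x) ≥ τ·c_m

where `m(x) = max over elapsed time of c(x, ·)` is the running maximum of
the density. The three ingredients:

- **Anisotropic migration.** `D(x)` is a per-voxel symmetric
  positive-semidefinite 3×3 tensor (mm²/day). In white matter its
  principal eigenvector follows the fiber direction, which reproduces the
  preferential spread of glioma cells along tracts. The isotropic model
  variant replaces it with a scalar `D·I`.
- **Logistic proliferation** with rate `ρ` (/day) and carrying capacity
  `c_m` (fixed at 10⁵ cells/mm³, the conventional packing density).
  Exponential and Gompertz laws are available as variants.
- **Threshold necrosis.** Once a voxel's historical maximum density
  reaches `τ·c_m` it permanently switches to exponential decay with
  per-day survival fraction `η ∈ (0, 1)`; the max-history rule models the
  physiologic commitment to necrosis even after the density falls back
  below the threshold.

On the sign of the necrosis term: written literally as `∂c/∂t = ηc` with
`η ∈ (0,1)` the term would grow the density. Both the description of the
term as an exponential decay and the stated clinical direction (lesions
with narrower enhancing rims have lower `η`, i.e. faster necrosis) are
satisfied by reading `η` as a per-day survival fraction,
`c(t+Δt) = η^Δt c(t)` (equivalently `∂c/∂t = ln(η)·c`), which is what the
solver implements.

## Parameters and their image-derived estimation

| parameter | units | default | origin |
|---|---|---|---|
| ρ | /day | 0.33 | T2-radius expansion velocity via Fisher's relation |
| D | mm²/day | 0.0825 | same estimation, mean cell diffusivity |
| c_m | cells/mm³ | 10⁵ | fixed, conventional |
| τ | fraction of c_m | 0.85 | first-necrosis timing (0.80 detection + 0.05 margin) |
| η | /day survival | 0.9 | matched to the observed enhancing-rim width |
| Δt | day | 1 | reporting cadence |

Serial T2-weighted and contrast-enhanced T1-weighted tumor radii are
assumed to trace the 0.16·c_m and 0.80·c_m density contours. The T2
slope gives the radial velocity `v`; the mean T2−T1 radius gap `Δr` is
matched to the exponential tail of the Fisher–KPP traveling wave,
`c ∝ exp(−x·√(ρ/D))`, so that `√(D/ρ) = Δr / ln(0.80/0.16)`. Combined
with the front-speed relation `v = 2√(ρD)` this closes the system:

    ρ = v·ln5 / (2Δr),    D = v·Δr / (2·ln5).

The defaults above are the values this estimator returns for the
reference lesion's radii; `RadiiSeries.from_growth` generates radii from
any `(ρ, D)` and `fisher_estimate` recovers them to 1e-6 relative (a
tested round-trip).

**Cell tensor from the spin tensor.** The water (spin) diffusion tensor
from DTI is converted to the modeled cell tensor by raising its
eigenvalues to a power (`amplification`, default 2) — a differential
scaling that sharpens anisotropy, preserves eigenvectors and
PSD-ness, and reduces to a shape-preserving rescale at exponent 1 —
followed by one global factor so the in-mask mean diffusivity equals the
image-estimated `D`. The exact functional form of the published
"differential scaling" is not specified anywhere we could consult, so
the power law was chosen for those invariance properties.

**τ calibration** maps the timing of first observed necrosis to a
threshold: necrosis already present at first imaging gives the lowest
value consistent with T1 detectability (detection fraction 0.80 plus a
0.05 margin → 0.85); otherwise τ rises linearly with the delay,
saturating below 1. Only the direction (later necrosis → higher τ) is
empirically grounded; the linear schedule is a package choice.

**η calibration** solves `rim_width(simulate(η)) = target` on an
isotropic phantom by deterministic bisection over `η ∈ (0.01, 0.999)`
(tolerance 1e-3). Bisection rather than a general minimizer because the
rim width is monotone in η but flat (zero) at small η, where a
golden-section search can stall. The rim functional used is the
ray-caliper measurement described below.

## Discretization

- **Diffusion operator**: conservative flux form. Face fluxes combine the
  arithmetic mean of the two adjacent tensors, the exact normal
  difference, and the average of the adjacent cell-centered tangential
  gradients for the off-diagonal (mixed-derivative) terms. Faces touching
  an out-of-mask voxel carry zero flux (cells do not cross the skull), so
  total cell count is conserved by construction; the suite verifies a
  relative drift ≤ 1e-10 over 100 days of pure anisotropic diffusion.
- **Time stepping**: forward Euler at a one-day reporting cadence with
  internal substepping. Two substep policies exist:
  - `"stability"` enforces only the explicit bound
    `Δt ≤ h_min²/(2·max trace D)` — the as-published protocol, which
    integrates whole days whenever stable;
  - `"accuracy"` (default) additionally caps the diffusion step number at
    0.2 (stability limit 0.5) and the per-substep growth `ρ·Δt` at 0.25.
    On the benchmark grid (1 mm, D = 0.0825, ρ = 0.33) the dispersion
    relation of the discrete scheme puts the front speed 13% below
    `2√(ρD)` at one-day steps and within ~2% at half-day steps; the caps
    buy that accuracy automatically.
- **Necrosis ordering within a step**: growth/diffusion advance the
  non-necrotic set, decay advances the necrotic set, then the running
  maximum and the necrotic classification are refreshed. A voxel crossing
  τ therefore starts decaying the following day, making the crossing time
  well defined on the reporting cadence.
- **Clipping** to `[0, c_m]` after every substep guards against explicit
  overshoot. Densities are clipped, not rescaled, so mass is not
  artificially conserved through clipping.
- Degenerate inputs: a 2-D slice domain is a grid with one singleton axis
  (the divergence skips singleton axes; radii switch to disc
  equivalents); `ρ = 0` (pure diffusion) and `η → 1` (no effective decay)
  are valid limits.

## Morphometry and the rim width

`equivalent_radius` converts a mask to the radius of the
volume-equivalent sphere. Two rim measurements are provided:

- `rim_width`: difference of volume-equivalent radii between the
  enhancing tissue and the hypointense core. Enhancement is treated as a
  *density* property — every voxel at or above 0.80·c_m enhances,
  including voxels already committed to necrosis whose density has not
  yet decayed below detection; the visible core is necrotic tissue below
  detection. Excluding flagged voxels from the rim would make the rim
  *narrower* for slower decay (higher η), inverting the clinically
  reported direction.
- `rim_width_ray`: a caliper read along cardinal rays through the tumor
  origin, with linear interpolation of the 0.80·c_m crossings. This
  resolves rims thinner than one voxel, is monotone in η, and corresponds
  to how a rim width is actually measured on an image. η calibration and
  the rim-reproduction experiment use it.

The simulated rim is thin — order one voxel at the default resolution —
and its width oscillates by ±0.5 mm as the discrete front crosses voxel
boundaries; single-day measurements inherit that granularity.

With the published parameter set (η = 0.9, v = 0.33 mm/day) the
steady-state rim width in this implementation is about 1–1.5 mm
isotropically and ≈1.9 mm along a FA = 0.8 fiber bundle under the
as-published one-day stepping, below the 2–3 mm clinical band; the band
is reached at η ≈ 0.99. The width is structurally `v·T`, with `T` the
time a voxel spends above the detection level before decaying below it
(about 2–4 days here). We verified this across grid spacings
(1–2 mm, anisotropic slices), 2-D and 3-D domains, seed densities, and
both rim definitions; reproducing 2–3 mm at η = 0.9 appears to require a
coarser effective time discretization than the model equations
themselves imply. The rim-reproduction experiment therefore reports the
honest ≈1.85 mm value rather than tuning any parameter toward the band.

## Mutual information

`mutual_information` implements the joint-histogram estimator in bits:
equal-width bins (default 64) spanning each field's in-mask range (or a
caller-fixed range when several fields are scored against a common
reference — necessary because per-field ranges change bin widths and
can swamp small structural differences), zero-count bins contributing
zero, computed over the brain mask only. MI is symmetric by
construction and the 2×2 closed forms (1 bit for perfectly dependent
binary fields, 0 for independent) are exact tests.

## Synthetic validation experiments

No clinical images ship with the package, so the two published
comparisons are rebuilt as synthetic twins (`gbmsim.experiments`):

- **Model-family ranking** (`model_comparison`): ground truth = full
  model seeded at carrying capacity (a lesion already necrotic at its
  first study) in a FA = 0.8 fiber-bundle phantom ("patient"); the three
  variants (isotropic/no-necrosis, anisotropic/no-necrosis, full) run
  from the same seed in a "volunteer" phantom whose bundle is rotated 5°
  in-plane, standing in for the inter-subject variability of simulating
  one person's tumor in another person's brain. At a developed early
  time point (day 30, the stand-in for the first imaging study) and a
  late one (day 50), the truth is rendered as a noisy pseudo-T1 image
  and each variant as a clean render over one shared anatomical texture;
  MI is computed with a common histogram range. The texture is
  histogram-equalized (uniform intensity distribution) so that no
  particular intensity — in particular the flat tumor levels — is an
  artificially rare histogram event; the tumor levels lie inside the
  anatomy's dynamic range, as on a real image. Growing tumor then
  *replaces* high-entropy anatomy with flat levels, and mismatched
  extent destroys shared structure, so MI decreases from the early to
  the late time point for every variant, and more faithful variants
  retain more of it: full ≥ anisotropic ≥ isotropic. Both properties
  hold across texture/noise seeds (checked for several) and are the
  acceptance assertions; the published absolute MI values depend on the
  original images and are not reproducible by construction.
- **Seed robustness** (`seed_sensitivity`): the full model on an
  isotropic phantom, reference seed at the center and four one-voxel
  cardinal displacements; MI of each displaced 30-day density profile
  against the reference. The four values agree to rounding (exact
  lattice symmetry of the phantom) and all lie strictly below the
  reference self-MI: displaced profiles are very similar yet perceivably
  different.
- **Rim reproduction** (`rim_reproduction`): full model seeded at
  carrying capacity in the fiber phantom, 30 days at the as-published
  one-day stepping, rim measured with the ray caliper along the fiber.

What these twins do *not* show: performance on real anatomy (curved,
crossing tracts; heterogeneous gray/white tissue), registration error,
or MR acquisition physics — the pseudo-T1 renderer is an intensity
cartoon, not an MR simulator.

## Problem sizes

Default phantoms are 64³ voxels at 1 mm (the ranking twin uses 80×64×64
to keep a 50-day anisotropic front off the mask boundary; calibration
examples use 32³). These sizes keep every experiment at desk scale —
the full acceptance suite simulates a few dozen tumor-years in under a
minute — while leaving a 30-day front well clear of the mask boundary.

## Known limitations

- `ρ`, `η`, and the tensor field are constant in time and space (no
  treatment effects, no tumor-induced remodeling).
- No gray/white two-compartment scalar variant; only the isotropic and
  full-tensor diffusion modes.
- The explicit scheme is first-order in time; mass during growth phases
  converges at first order in the substep (tested), so quantitative
  time-courses should use the `"accuracy"` policy.
- Straight fiber bundles only; curved-tract phantoms are not
  implemented.
- The rim width at the published η is below the clinical band, as
  discussed above.
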