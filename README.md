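# gbmsim

Image-driven simulation of glioblastoma multiforme (GBM) proliferation
and necrosis on a voxel grid.

GBM lesions grow by intrinsic cell division, migrate preferentially
along white-matter fiber bundles, and — uniquely among common brain
tumors — collapse centrally into necrosis once the local cell density
outstrips its supporting tissue. `gbmsim` implements a
reaction–diffusion model of all three processes,

    ∂c/∂t = ∇·(D(x) ∇c) + ρ c (1 − c/c_m)     while max-history m(x) < τ·c_m
    c(t+Δt) = η^Δt · c(t)                       once  m(x) ≥ τ·c_m  (forever),

with `c(x,t)` the tumor cell density (cells/mm³), `D(x)` the per-voxel
cell diffusion tensor derived from diffusion-tensor MRI, `ρ` the
proliferation rate, `c_m = 10⁵ cells/mm³` the carrying capacity, `τ` the
necrosis threshold, and `η ∈ (0,1)` the per-day survival fraction of
necrotic tissue. The max-history rule makes necrosis irreversible.

The model is *lesion-specific*: its free parameters are estimated from
each patient's serial MR imaging. Tumor radii measured on T2-weighted
and contrast-enhanced T1-weighted images trace the 0.16·c_m and 0.80·c_m
density contours; the radial velocity `v` and the T2–T1 contour gap
`Δr`, combined through Fisher's traveling-wave relation `v = 2√(ρD)`
and the wave-tail decay length `√(D/ρ) = Δr/ln 5`, yield `ρ` and `D`.
The threshold `τ` comes from the timing of first observed necrosis and
`η` from the width of the enhancing rim.

The package is aimed at computational-oncology researchers who want a
reproducible, fully synthetic-testable implementation of this model
family: solver, parameter estimation, phantoms (no clinical data
required), mutual-information validation metrics, and a CLI.

## Worked example

Estimate a lesion's parameters from serial radii, then simulate 30 days
of the full model seeded in a coherent white-matter bundle phantom:

```python
from gbmsim import (GrowthParams, RadiiSeries, fisher_estimate, make_state,
                    simulate, ModelVariant, rim_width_ray)
from gbmsim.phantoms import PhantomSpec, make_fiber_phantom

# serial imaging: T1/T2 radii (mm) measured 30 days apart
radii = RadiiSeries(times=(0, 30), r_t1=(9.195, 19.095), r_t2=(10.0, 19.9))
est = fisher_estimate(radii)
print(f"v   = {est.v:.3f} mm/day")
print(f"rho = {est.rho:.3f} /day")
print(f"D   = {est.d_mean:.4f} mm^2/day")

params = GrowthParams(rho=est.rho, c_m=1e5, tau=0.85, eta=0.9)
spec = PhantomSpec(shape=(64, 64, 64), medium="fiber_bundle",
                   mean_diffusivity=est.d_mean, fa_target=0.8)
grid, tensor = make_fiber_phantom(spec)
state = make_state(grid, (32, 32, 32), params.c_m, params)
snaps = simulate(state, tensor, params,
                 ModelVariant(diffusion="tensor", necrosis=True),
                 n_days=30, snapshot_every=5, substep_policy="stability")

final = snaps[-1]
print(f"necrotic voxels at day 30: {int(final.necrotic.sum())}")
print(f"enhancing rim width along the fiber: "
      f"{rim_width_ray(final, params.c_m, axis=0, center=(32, 32, 32)):.2f} mm")
```

prints

```
v   = 0.330 mm/day
rho = 0.330 /day
D   = 0.0825 mm^2/day
necrotic voxels at day 30: 75
enhancing rim width along the fiber: 1.85 mm
```

The estimator recovers the reference lesion's proliferation rate
(0.33/day — several times the published GBM cohort mean of 0.089/day)
and diffusivity from the radii alone. After 30 days the simulated lesion
has a central necrotic core surrounded by a thin bright shell of viable,
enhancing tumor about 1.9 mm wide — the characteristic ring-enhancing
morphology; slower necrotic decay (η → 1) widens the ring and faster
decay narrows it.

## Command line

```sh
gbmsim phantom --medium fiber_bundle --fa 0.8 --out-dir ph/
gbmsim estimate radii.csv --out params.json
gbmsim simulate --mask ph/mask.nii.gz --tensor ph/tensor.nii.gz \
    --rho 0.33 --seed-voxel 32 32 32 --days 30 --out-dir run/
gbmsim mi run/density_t0030.00.nii.gz observed.nii.gz --mask ph/mask.nii.gz
gbmsim calibrate-eta --target-rim 2.5
gbmsim seed-sensitivity --grid-size 48 --days 20 --out mi.csv
```

Fields are NIfTI (tensors as 4-D volumes with the six lower-triangular
components Dxx, Dxy, Dyy, Dxz, Dyz, Dzz), radii and logs are CSV, and
every simulation directory carries a JSON provenance sidecar sufficient
to re-run it bit-identically.

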