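# eisr — resolution analysis for Born-approximation inverse scattering

`eisr` is a Python toolkit for quantifying the resolution of far-field
electromagnetic inverse scattering (EIS), the imaging modality behind
microwave medical sensing (breast, brain-stroke and bone imaging).  It is
aimed at researchers who want to understand — and reproduce with desk-scale
computations — why EIS reconstructions of *extended* scatterers routinely
appear to beat the half-wavelength diffraction limit while point scatterers
do not.

The package provides, in one consistent 2-D TM framework:

* a pulse-basis **method-of-moments forward solver** (exact contrast-current
  solution, far-field data on an antenna ring);
* the **two-step Born inversion**: minimum-norm current via truncated-SVD
  pseudo-inverse of the surface Green operator, then cell-wise least-squares
  contrast over the incidences;
* the analytic **spread functions**: the point spread function
  PSF(x) = [J0(k₀x)]², the thin-ring Fourier-transform kernel k₀ΔR·J0(k₀ρ)
  it derives from, and the general spread function χ ∗ PSF for extended
  scatterers, with closed-form derivatives;
* three **resolution criteria** as bracketed root finds:
  * *Rayleigh* — first PSF null, σ = 0.383 λ;
  * *Sparrow* — vanishing midpoint curvature of the joint profile,
    σ = 0.344 λ for points, and edge-to-edge σ = d − 2r for equal cylinders
    (σ = 0.152 m for r = 0.1 m at 300 MHz: super-resolution);
  * *modified Sparrow* — for asymmetric pairs, a saddle condition
    f'(g) = f''(g) = 0 at the interior stationary point g.

## Worked example

```python
from eisr import (PhysicalConfig, ScattererSpec, rayleigh_resolution,
                  sparrow_resolution_points, sparrow_resolution_cylinders,
                  modified_sparrow_resolution)

config = PhysicalConfig(frequency=300e6)          # lambda = 1 m exactly

print(rayleigh_resolution(config).sigma_wavelengths)       # 0.3827398747803136
print(sparrow_resolution_points(config).sigma_wavelengths) # 0.34440443440998053
print(sparrow_resolution_cylinders(0.1, config).sigma)     # 0.152091523296877

asym = modified_sparrow_resolution(
    ScattererSpec("point", (-0.2, 0.0), 0.0, 1.1),
    ScattererSpec("point", (+0.2, 0.0), 0.0, 1.2),
    config,
)
print(asym.sigma, asym.gaussian_point_g)  # 0.38237759535938964 -0.20084203832225367
```

Reading the numbers: two equal points stop being distinguishable below
0.344 λ, but two 0.1 m cylinders resolve down to a 0.152 m edge gap —
finer than λ/2 — because their images are wide interval integrals of the PSF
whose central dip survives longer.  Making the pair asymmetric (εr 1.1 vs
1.2) *worsens* the limit to 0.382 m, with the emerging dip displaced to
g ≈ −0.20 m on the weaker scatterer's side.

The full imaging pipeline is equally scriptable:

```python
from eisr import figure_fixture, reconstruct

scene, config, ring = figure_fixture("fig4g")   # two r=0.1 m cylinders, 0.20 m gap
image = reconstruct(scene, ring, config)        # forward solve + Born inversion
x, profile = image.cross_section(0.0)           # normalised |chi_sol| at y=0
```

The `examples/` directory holds one narrative script per capability
(`point_spread_function.py`, `resolution_limits.py`,
`cylinder_super_resolution.py`, `asymmetric_scatterers.py`); each prints the
numbers above with a line of interpretation.  A thin CLI wraps the same
functions:

```bash
eisr resolve --criterion rayleigh
eisr invert --scene fig3g --out out/
eisr psf-check --out out/
```

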