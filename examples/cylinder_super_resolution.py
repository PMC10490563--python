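"""Edge-to-edge Sparrow resolution of extended cylinders: super-resolution.

For extended scatterers the relevant separation is between edges, not
centres.  Sweeping the cylinder radius shows the edge-to-edge Sparrow limit
shrinking well below the half-wavelength diffraction limit — the mechanism
behind apparent super-resolution of extended objects under weak scattering.
The inverse query finds the radius at which the pair resolves at 0.25 λ.
"""

import numpy as np

from eisr import (
    PhysicalConfig,
    radius_for_target_resolution,
    sparrow_resolution_cylinders,
)

config = PhysicalConfig(frequency=300e6)
lam = config.wavelength

print("radius (lambda)   edge-to-edge sigma (lambda)")
for r in np.array([0.02, 0.05, 0.1, 0.15]) * lam:
    result = sparrow_resolution_cylinders(r, config)
    print(f"    {r/lam:5.2f}            {result.sigma_wavelengths:6.3f}")

reference = sparrow_resolution_cylinders(0.1, config)
print()
print(f"two r = 0.1 m cylinders at 300 MHz resolve at sigma = "
      f"{reference.sigma:.3f} m ({reference.sigma_wavelengths:.3f} lambda)")

r_star = radius_for_target_resolution(0.25 * lam, config)
print(f"sigma = 0.25 lambda is reached at radius r = {r_star/lam:.3f} lambda")
print()
print("Larger cylinders resolve at smaller edge gaps: their images are wide,")
print("overlapping interval integrals of the PSF whose central curvature")
print("flips sign earlier than for points.")
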