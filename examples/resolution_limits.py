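"""Rayleigh and Sparrow two-point resolution limits of the squared-J0 PSF.

Both criteria are root finds on the analytic spread profiles: Rayleigh looks
for the first null of one point's image, Sparrow for the separation at which
the dip between two images just vanishes (zero curvature at the midpoint).
"""

from eisr import PhysicalConfig, rayleigh_resolution, sparrow_resolution_points

config = PhysicalConfig(frequency=300e6)

rayleigh = rayleigh_resolution(config)
sparrow = sparrow_resolution_points(config)

print(f"Rayleigh limit : {rayleigh.sigma_wavelengths:.3f} wavelengths "
      f"({rayleigh.sigma:.3f} m at 300 MHz)")
print(f"Sparrow limit  : {sparrow.sigma_wavelengths:.3f} wavelengths "
      f"({sparrow.sigma:.3f} m at 300 MHz)")
print()
print("Sparrow sits below Rayleigh: two equal points remain distinguishable")
print("until their joint image loses its central dip at 0.344 wavelengths,")
print("slightly closer than the 0.383-wavelength first-null criterion.")
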