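"""Physical configuration shared by every stage of the pipeline.

A single monochromatic TM configuration is described by its frequency and the
background medium.  Everything downstream (Green kernels, spread functions,
resolution criteria) depends only on the derived free-space wavenumber ``k0``.

By default the speed of light is rounded to ``3e8 m/s`` so that 300 MHz maps
to a wavelength of exactly 1 m; resolution results quoted in wavelengths then
coincide digit-for-digit with their metric counterparts at 300 MHz.  The CODATA
value is available via ``speed_of_light=C_PHYSICAL``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

C_EXACT = 3.0e8
C_PHYSICAL = 299_792_458.0


@dataclass(frozen=True)
class PhysicalConfig:
    """Frequency, background permittivity and derived wave quantities.

    Parameters
    ----------
    frequency:
        Operating frequency in Hz, strictly positive.
    background_permittivity:
        Relative permittivity of the homogeneous background (1 = free space).
    speed_of_light:
        Propagation speed used to derive the wavelength, in m/s.  Defaults to
        the rounded ``3e8`` so that λ(300 MHz) = 1 m exactly.
    """

    frequency: float
    background_permittivity: float = 1.0
    speed_of_light: float = C_EXACT

    def __post_init__(self) -> None:
        if not self.frequency > 0:
            raise ValueError(f"frequency must be positive, got {self.frequency}")
        if not self.background_permittivity > 0:
            raise ValueError("background permittivity must be positive")

    @property
    def wavelength(self) -> float:
        """Free-space wavelength λ = c / f in metres."""
        return self.speed_of_light / self.frequency

    @property
    def wavenumber(self) -> float:
        """Free-space wavenumber k0 = 2π/λ in rad/m, strictly positive."""
        return 2.0 * math.pi / self.wavelength
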