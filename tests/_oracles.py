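"""Independent numerical oracles used by the test suite.

Everything here is deliberately implemented along a different route from the
package (mode-matching series, nested adaptive quadrature, brute-force
discrete Fourier sums, finite differences) so that agreement is evidence, not
tautology.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.special import h1vp, hankel1, jv, jvp


def cylinder_series_far_field(
    receivers: np.ndarray,
    incident_angle: float,
    radius: float,
    eps_r: float,
    k0: float,
    n_terms: int = 25,
) -> np.ndarray:
    """Exact TM plane-wave scattering by a homogeneous dielectric cylinder.

    Classic cylindrical-harmonic mode matching: expand incident, interior and
    scattered fields in Bessel/Hankel modes and enforce continuity of Ez and
    its radial derivative at the cylinder surface.  Valid at any distance
    (receivers need not be in the far field).

    Convention note: the package's integral-equation kernel is the *negative*
    of the radiating Helmholtz Green function, so its solved far field for
    contrast χ coincides with the physical scattered field of a cylinder with
    contrast −χ.  Pass ``eps_r = 2 − eps_solver`` when validating the solver.
    """
    k1 = k0 * np.sqrt(complex(eps_r))
    u0, u1 = k0 * radius, k1 * radius
    rho = np.linalg.norm(receivers, axis=1)
    phi = np.arctan2(receivers[:, 1], receivers[:, 0])
    out = np.zeros(len(receivers), dtype=complex)
    for n in range(-n_terms, n_terms + 1):
        num = k1 * jvp(n, u1) * jv(n, u0) - k0 * jvp(n, u0) * jv(n, u1)
        den = k0 * h1vp(n, u0) * jv(n, u1) - k1 * jvp(n, u1) * hankel1(n, u0)
        b_n = num / den
        out += (1j**n) * b_n * hankel1(n, k0 * rho) * np.exp(1j * n * (phi - incident_angle))
    return out


def self_term_quadrature(cell_size: float, k0: float) -> complex:
    """k0² ∫_square −(j/4) H0(1)(k0 ρ) dA by nested adaptive quadrature.

    Polar coordinates over one octant of the square (×8 by symmetry); the
    Jacobian removes the logarithmic singularity at the origin, so plain
    adaptive quadrature converges cleanly.
    """
    h = cell_size / 2.0

    def radial(theta: float, part) -> float:
        rmax = h / np.cos(theta)
        return quad(
            lambda r: part(hankel1(0, k0 * r)) * r, 0.0, rmax, epsabs=1e-12
        )[0]

    re = quad(lambda t: radial(t, np.real), 0.0, np.pi / 4, epsabs=1e-12)[0]
    im = quad(lambda t: radial(t, np.imag), 0.0, np.pi / 4, epsabs=1e-12)[0]
    return complex(k0**2 * (-0.25j) * 8.0 * (re + 1j * im))


def annulus_transform_profile(
    ring_radius: float, thickness: float, rhos: np.ndarray, pixel: float | None = None
) -> np.ndarray:
    """Brute-force 2-D Fourier transform of an annulus, sampled along an axis.

    Rasterises the annulus of radius R and width ΔR in the frequency plane and
    sums exp(+j 2π k·x) over its pixels for x = (ρ, 0).  Returned normalised
    to the value at ρ = 0, which removes the pixelised-area factor.
    """
    if pixel is None:
        pixel = thickness / 5.0
    half = ring_radius + thickness
    coords = np.arange(-half, half + pixel, pixel)
    KX, KY = np.meshgrid(coords, coords)
    KR = np.hypot(KX, KY)
    mask = np.abs(KR - ring_radius) <= thickness / 2.0
    kx = KX[mask]
    vals = np.exp(2j * np.pi * kx[None, :] * np.asarray(rhos)[:, None]).sum(axis=1)
    return np.real(vals) / mask.sum()


def central_difference(fn, x, h: float):
    """Second-order central first derivative."""
    return (fn(x + h) - fn(x - h)) / (2.0 * h)


def central_second_difference(fn, x, h: float):
    """Second-order central second derivative."""
    return (fn(x + h) - 2.0 * fn(x) + fn(x - h)) / h**2


def count_peaks_dense(profile, lo: float, hi: float, n: int = 4001) -> int:
    """Brute-force local-maximum count of a callable profile on [lo, hi]."""
    xs = np.linspace(lo, hi, n)
    v = np.asarray(profile(xs))
    return int(np.count_nonzero((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])))
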