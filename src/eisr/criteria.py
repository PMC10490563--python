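"""Two-scatterer resolution criteria for Born-approximation imaging.

Three criteria are implemented, all as bracketed root finds on the analytic
joint spread profiles of `eisr.spread`:

Rayleigh
    σ is the first null of the point spread function: the image of one point
    sits on the first zero of the other's.  Gives 0.383λ.

Sparrow (symmetric pairs)
    σ is the smallest separation at which the dip at the profile midpoint
    just vanishes — the second derivative of the joint profile is zero at
    x = 0.  Points give 0.344λ; for equal cylinders the criterion is applied
    edge-to-edge, σ = d − 2r, and improves (shrinks) as the radius grows —
    the origin of apparent super-resolution for extended scatterers.

Modified Sparrow (asymmetric pairs)
    With unequal weights or radii the emerging dip is not at the midpoint.
    The criterion tracks the interior stationary point g of the profile (the
    "Gaussian point") and finds the smallest separation at which it becomes
    degenerate: f'(g) = 0 and f''(g) = 0 simultaneously — the saddle at which
    a dip is born.  σ = d* − a1 − a2.  For identical scatterers this reduces
    exactly to the symmetric criterion with g = 0.

Search constants (brackets, sample densities, tolerances) are module-level
and logged per run so every root find is reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, fsolve

from .config import PhysicalConfig
from .scenes import ScattererSpec
from scipy.special import j0

from .spread import SpreadProfile, pair_profile, two_point_profile

logger = logging.getLogger(__name__)

#: dense-scan sampling density for locating stationary points (samples per λ)
SAMPLES_PER_WAVELENGTH = 2000
#: bisection tolerance on separations, in wavelengths
SEPARATION_TOL_WL = 1e-6
#: tolerance on the Gaussian-point location, metres
GAUSSIAN_POINT_TOL = 1e-8
#: stationary points are searched this far (in λ) beyond the two centres;
#: near dip emergence the saddle can sit slightly outside them
WINDOW_MARGIN_WL = 0.2
GAUSSIAN_WINDOW_MARGIN_WL = 0.05


@dataclass(frozen=True)
class ResolutionResult:
    """Outcome of one resolution criterion.

    ``critical_separation_d`` is centre-to-centre; ``sigma`` is edge-to-edge,
    σ = d − a1 − a2 with a_i the edge-to-centre distances (0 for points).
    ``gaussian_point_g`` is the interior stationary point at the critical
    separation (0 for symmetric pairs, None where the criterion has no such
    notion).
    """

    criterion: str
    critical_separation_d: float
    sigma: float
    sigma_wavelengths: float
    scatterer_edges: tuple[float, float] = (0.0, 0.0)
    gaussian_point_g: float | None = None


def _result(
    criterion: str,
    d: float,
    edges: tuple[float, float],
    config: PhysicalConfig,
    g: float | None,
) -> ResolutionResult:
    sigma = d - edges[0] - edges[1]
    return ResolutionResult(
        criterion=criterion,
        critical_separation_d=d,
        sigma=sigma,
        sigma_wavelengths=sigma / config.wavelength,
        scatterer_edges=edges,
        gaussian_point_g=g,
    )


def _stationary_points(
    profile: SpreadProfile, lo: float, hi: float, wavelength: float
) -> list[float]:
    """All roots of f' in [lo, hi], by dense sign-change scan + Brent refinement."""
    n = max(int(SAMPLES_PER_WAVELENGTH * (hi - lo) / wavelength), 8)
    xs = np.linspace(lo, hi, n)
    v = np.asarray(profile.first_derivative(xs))
    roots = []
    sign = np.sign(v)
    for i in np.flatnonzero(sign[:-1] * sign[1:] < 0):
        roots.append(
            brentq(profile.first_derivative, xs[i], xs[i + 1], xtol=1e-14)
        )
    roots.extend(xs[np.flatnonzero(v == 0.0)])
    return sorted(roots)


def rayleigh_resolution(config: PhysicalConfig) -> ResolutionResult:
    """First null of the PSF: σ solves J0(k0 σ) = 0, bracketed bisection.

    Scale-invariant in wavelengths (0.383λ at any frequency).
    """
    lam = config.wavelength
    # the PSF touches zero without crossing; bisect on its signed amplitude J0
    sigma = brentq(
        lambda x: j0(config.wavenumber * x),
        0.1 * lam,
        0.5 * lam,
        xtol=SEPARATION_TOL_WL * lam * 1e-4,
    )
    logger.info("Rayleigh: sigma = %.6f m (%.4f wavelengths)", sigma, sigma / lam)
    return _result("rayleigh", sigma, (0.0, 0.0), config, None)


def sparrow_resolution_points(
    config: PhysicalConfig, weights: tuple[float, float] = (1.0, 1.0)
) -> ResolutionResult:
    """Smallest d with f''(0; d) = 0 for two equal points (0.344λ).

    The midpoint condition only characterises dip emergence for a symmetric
    pair; unequal weights must go through `modified_sparrow_resolution`.
    """
    if weights[0] != weights[1]:
        raise ValueError(
            "the midpoint Sparrow condition requires equal weights; "
            "use modified_sparrow_resolution for asymmetric pairs"
        )
    lam = config.wavelength

    def midpoint_curvature(d):
        return two_point_profile(d, weights, config).second_derivative(0.0)

    d_star = _smallest_sign_change(midpoint_curvature, 0.1 * lam, 0.5 * lam, lam)
    logger.info("Sparrow (points): sigma = %.6f m", d_star)
    return _result("sparrow", d_star, (0.0, 0.0), config, 0.0)


def sparrow_resolution_cylinders(
    r: float, config: PhysicalConfig, weights: tuple[float, float] = (1.0, 1.0)
) -> ResolutionResult:
    """Edge-to-edge Sparrow resolution of two equal cylinders of radius r.

    Finds the smallest centre separation where the four-boundary-term second
    derivative of the interval-integrated profile vanishes at the midpoint;
    σ = d − 2r.
    """
    if not r > 0:
        raise ValueError("radius must be positive")
    if weights[0] != weights[1]:
        raise ValueError("equal weights required; use the modified criterion")
    lam = config.wavelength

    def midpoint_curvature(d):
        return pair_profile(d, (r, r), weights, config).second_derivative(0.0)

    d_star = _smallest_sign_change(
        midpoint_curvature, 0.01 * lam, 2 * r + 0.6 * lam, lam
    )
    logger.info("Sparrow (cylinders r=%.4f): sigma = %.6f m", r, d_star - 2 * r)
    return _result("sparrow", d_star, (r, r), config, 0.0)


def _smallest_sign_change(fn, lo: float, hi: float, wavelength: float) -> float:
    """First root of ``fn`` on [lo, hi]: coarse scan, then Brent to 1e-6 λ."""
    step = 0.005 * wavelength
    ds = np.arange(lo, hi + step, step)
    vals = np.array([fn(d) for d in ds])
    idx = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
    if idx.size == 0:
        raise RuntimeError(
            f"no sign change of the criterion condition on [{lo}, {hi}] m"
        )
    i = idx[0]
    return brentq(fn, ds[i], ds[i + 1], xtol=SEPARATION_TOL_WL * wavelength * 1e-2)


def radius_for_target_resolution(
    sigma_target: float, config: PhysicalConfig
) -> float:
    """Cylinder radius whose equal-pair Sparrow resolution equals ``sigma_target``.

    Outer bisection on r nested over the cylinder Sparrow root find.  The
    point limit bounds the achievable range from above (σ → 0.344λ as r → 0).
    """
    lam = config.wavelength

    def gap(r):
        return sparrow_resolution_cylinders(r, config).sigma - sigma_target

    lo, hi = 1e-4 * lam, 0.3 * lam
    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo * g_hi > 0:
        raise ValueError(
            f"target resolution {sigma_target} m is outside the range achievable "
            f"for radii in [{lo}, {hi}] m"
        )
    r = brentq(gap, lo, hi, xtol=1e-7 * lam)
    logger.info("radius for sigma=%.4f m: r = %.6f m", sigma_target, r)
    return r


def gaussian_point(
    profile: SpreadProfile, d: float, config: PhysicalConfig
) -> float:
    """Interior stationary point of an asymmetric joint profile.

    Returns the root of f' between the two component centres (the window is
    widened by 0.05λ on each side, since near dip emergence the stationary
    point can sit marginally outside them).  Preference order: the stationary
    point with f'' > 0 and the lowest intensity (the dip); if the profile is
    fully merged and monotone between the peaks, the interior critical point
    with the lowest intensity is reported.
    """
    lam = config.wavelength
    m = GAUSSIAN_WINDOW_MARGIN_WL * lam
    roots = _stationary_points(profile, -d / 2 - m, d / 2 + m, lam)
    if not roots:
        raise ValueError("profile has no stationary point between the centres")
    dips = [g for g in roots if profile.second_derivative(g) > 0]
    candidates = dips if dips else roots
    return min(candidates, key=lambda g: float(profile(g)))


def modified_sparrow_resolution(
    spec1: ScattererSpec,
    spec2: ScattererSpec,
    config: PhysicalConfig,
    d_max: float | None = None,
) -> ResolutionResult:
    """Resolution of a possibly asymmetric pair via the Gaussian-point saddle.

    Each scatterer contributes a spread-profile component weighted by its
    contrast (point → weighted PSF, cylinder → interval-integrated PSF).  The
    critical separation d* is where the interior stationary point g becomes a
    degenerate saddle, f'(g) = 0 ∧ f''(g) = 0: below d* the profile rises
    monotonically into the single surviving peak, above d* a dip and a second
    peak exist.  Located by bisection on the count of interior stationary
    points, then polished on the two-equation saddle system.  σ = d* − a1 − a2.

    Identical scatterers reduce exactly to the symmetric Sparrow criterion
    (g = 0), and are dispatched to it.
    """
    lam = config.wavelength
    w = (spec1.contrast(config), spec2.contrast(config))
    edges = (spec1.edge_distance, spec2.edge_distance)

    if spec1.kind == spec2.kind and edges[0] == edges[1] and w[0] == w[1]:
        if spec1.kind == "point":
            base = sparrow_resolution_points(config)
        else:
            base = sparrow_resolution_cylinders(edges[0], config)
        return _result(
            "modified_sparrow", base.critical_separation_d, edges, config, 0.0
        )

    def profile(d):
        return pair_profile(d, edges, w, config)

    margin = WINDOW_MARGIN_WL * lam

    def n_stationary(d):
        return len(
            _stationary_points(profile(d), -d / 2 - margin, d / 2 + margin, lam)
        )

    d_lo = max(0.05 * lam, 0.25 * (edges[0] + edges[1]))
    d_hi = edges[0] + edges[1] + 0.6 * lam if d_max is None else d_max
    ds = np.arange(d_lo, d_hi, 0.01 * lam)
    counts = [n_stationary(d) for d in ds]
    bracket = None
    for i in range(len(ds) - 1):
        if counts[i] == 1 and counts[i + 1] >= 3:
            bracket = (ds[i], ds[i + 1])
            break
    if bracket is None:
        raise RuntimeError(
            f"no dip emergence found for separations in [{d_lo:.3f}, {d_hi:.3f}] m "
            f"(stationary-point counts {sorted(set(counts))})"
        )
    lo, hi = bracket
    while hi - lo > SEPARATION_TOL_WL * lam:
        mid = 0.5 * (lo + hi)
        if n_stationary(mid) >= 3:
            hi = mid
        else:
            lo = mid
    # just above the transition the newborn stationary pair is nearly
    # coincident; its midpoint seeds the saddle polish
    roots = _stationary_points(profile(hi), -hi / 2 - margin, hi / 2 + margin, lam)
    gaps = np.diff(roots)
    j = int(np.argmin(gaps))
    g0 = 0.5 * (roots[j] + roots[j + 1])
    d_star, g = hi, g0

    def saddle_system(v):
        gg, dd = v
        p = profile(dd)
        return [p.first_derivative(gg), p.second_derivative(gg)]

    sol, info, ier, _ = fsolve(saddle_system, [g0, hi], full_output=True)
    if ier == 1 and abs(sol[1] - hi) < 1e-3 * lam:
        g, d_star = float(sol[0]), float(sol[1])
    logger.info(
        "modified Sparrow: d* = %.6f m, g = %.6f m, sigma = %.6f m",
        d_star,
        g,
        d_star - edges[0] - edges[1],
    )
    return _result("modified_sparrow", d_star, edges, config, g)


def count_interior_maxima(
    x: np.ndarray, values: np.ndarray, half_width: float
) -> int:
    """Local maxima of a sampled cross-section within |x| ≤ half_width.

    The window keeps the analysis on the inter-scatterer structure and away
    from the PSF side lobes further out.
    """
    mask = np.abs(np.asarray(x)) <= half_width
    q = np.asarray(values)[mask]
    return int(np.count_nonzero((q[1:-1] > q[:-2]) & (q[1:-1] > q[2:])))


def dip_present(
    x: np.ndarray,
    values: np.ndarray,
    separation: float,
    config: PhysicalConfig,
    margin_wl: float = 0.15,
) -> bool:
    """Whether a reconstruction cross-section shows two peaks with a dip.

    ``separation`` is the centre-to-centre distance of the underlying pair;
    the peak count is taken within |x| ≤ d/2 + margin.
    """
    half = separation / 2 + margin_wl * config.wavelength
    return count_interior_maxima(x, values, half) >= 2
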