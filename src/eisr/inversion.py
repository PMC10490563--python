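"""Two-step Born-approximation inversion.

Step one recovers the minimum-norm (radiating) contrast current from far-field
data through the truncated pseudo-inverse of the surface operator,

    Jsol = V Σ⁻¹ U* Es,      GS = U Σ V*,

equivalent to the normal-equations form GS*(GS GS*)⁻¹ Es on the retained
subspace.  Step two recovers the contrast by cell-wise least squares over the
incidences under the weak-scattering linearisation J ≈ χ Ei:

    χsol = Σ_n Jsol_n Ei_n* / Σ_n Ei_n Ei_n*.

Truncation of the singular spectrum is the explicit, logged stand-in for the
implicit regularisation that a finite receiver count provides: the retained
right-singular subspace is the "radiating" current space, its complement the
non-radiating space that far-field data cannot see.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import PhysicalConfig
from .forward import build_surface_operator, solve_forward
from .scenes import AntennaRing, ContrastScene, ImagingDomain

logger = logging.getLogger(__name__)

DEFAULT_SVD_REL_TOL = 1e-3


@dataclass(frozen=True)
class SVDFactors:
    """SVD of the surface operator with a truncation index.

    Singular values are non-increasing; the first ``truncation_index`` of them
    (those ≥ rel_tol × σ_max) span the radiating subspace.
    """

    U: np.ndarray = field(repr=False)
    singular_values: np.ndarray
    Vh: np.ndarray = field(repr=False)
    truncation_index: int

    @classmethod
    def from_operator(
        cls, GS: np.ndarray, rel_tol: float = DEFAULT_SVD_REL_TOL
    ) -> "SVDFactors":
        if not 0 < rel_tol < 1:
            raise ValueError("rel_tol must lie in (0, 1)")
        U, s, Vh = np.linalg.svd(GS, full_matrices=False)
        if s.size == 0 or s[0] == 0.0:
            k = 0
        else:
            k = int(np.count_nonzero(s >= rel_tol * s[0]))
        logger.debug("SVD truncation: retaining %d of %d singular values", k, s.size)
        return cls(U=U, singular_values=s, Vh=Vh, truncation_index=k)

    @property
    def retained_Vh(self) -> np.ndarray:
        return self.Vh[: self.truncation_index]


@dataclass(frozen=True)
class CurrentDecomposition:
    """Radiating / non-radiating split of a contrast current.

    ``J_plus + J_minus`` reconstructs the input exactly; the parts are
    orthogonal, and GS annihilates ``J_minus`` up to the truncation level.
    """

    J_plus: np.ndarray = field(repr=False)
    J_minus: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class ReconstructedImage:
    """Complex contrast image on the scene grid plus display normalisation."""

    chi_sol: np.ndarray = field(repr=False)
    domain: ImagingDomain
    normalization: float

    def magnitude(self) -> np.ndarray:
        return np.abs(self.chi_sol)

    def normalized_magnitude(self) -> np.ndarray:
        """|χsol| scaled so the peak is 1 (the quantity used for dip analysis)."""
        return np.abs(self.chi_sol) / self.normalization

    def cross_section(self, y: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        """Normalized |χsol| along the grid row nearest ``y``."""
        iy = int(np.argmin(np.abs(self.domain.y_centers - y)))
        return self.domain.x_centers, self.normalized_magnitude()[iy, :]


def min_norm_current(
    Es: np.ndarray,
    svd: SVDFactors,
) -> np.ndarray:
    """Minimum-norm current V Σ⁻¹ U* Es on the retained singular subspace.

    Returns one current column per incidence; the result lies in the row space
    of GS by construction.  Fails explicitly when no singular value survives
    truncation (no radiating information in the data).
    """
    if svd.truncation_index == 0:
        raise ValueError("all singular values below tolerance: no radiating data")
    k = svd.truncation_index
    Uk = svd.U[:, :k]
    sk = svd.singular_values[:k]
    return svd.Vh[:k].conj().T @ ((Uk.conj().T @ Es) / sk[:, None])


def decompose_current(J: np.ndarray, svd: SVDFactors) -> CurrentDecomposition:
    """Project a current onto the radiating subspace and its complement."""
    Vk = svd.retained_Vh.conj().T  # cells × k
    if J.shape[0] != Vk.shape[0]:
        raise ValueError(
            f"current has {J.shape[0]} cells, operator has {Vk.shape[0]}"
        )
    J_plus = Vk @ (Vk.conj().T @ J)
    return CurrentDecomposition(J_plus=J_plus, J_minus=J - J_plus)


def born_contrast(Jsol: np.ndarray, Ei: np.ndarray) -> np.ndarray:
    """Cell-wise least-squares contrast Σ_n Jsol_n Ei_n* / Σ_n |Ei_n|².

    With unit-magnitude plane waves the denominator is just the incidence
    count.  Accepts (cells,) or (cells × incidences) arrays.
    """
    Jsol = np.atleast_2d(Jsol.T).T
    Ei = np.atleast_2d(Ei.T).T
    denom = (Ei * Ei.conj()).sum(axis=1).real
    if np.any(denom == 0):
        raise ValueError("zero incident field at some cell")
    return (Jsol * Ei.conj()).sum(axis=1) / denom


def reconstruct(
    scene: ContrastScene,
    ring: AntennaRing,
    config: PhysicalConfig,
    svd_rel_tol: float = DEFAULT_SVD_REL_TOL,
) -> ReconstructedImage:
    """Full pipeline: exact forward data → minimum-norm current → contrast.

    The forward solve provides the synthetic far-field data; the inversion
    then only sees ``Es``, the surface operator and the incident fields.
    Deterministic for a fixed configuration.
    """
    fields = solve_forward(scene, ring, config)
    GS = build_surface_operator(scene.domain, ring, config)
    svd = SVDFactors.from_operator(GS, rel_tol=svd_rel_tol)
    Jsol = min_norm_current(fields.Es, svd)
    chi = born_contrast(Jsol, fields.Ei)
    grid = chi.reshape(scene.domain.ny, scene.domain.nx)
    peak = float(np.abs(grid).max())
    return ReconstructedImage(
        chi_sol=grid, domain=scene.domain, normalization=peak if peak > 0 else 1.0
    )
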