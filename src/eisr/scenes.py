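"""Synthetic dielectric scenes: scatterer specs, imaging grid and antenna ring.

The imaging domain is a rectangle tiled by square cells; cell centres are
ordered row-major (y varies slowest, x fastest) and that ordering is the
contract for every flattened field or operator in the package.  A scene is a
set of parametric scatterers (single-cell "points" or homogeneous cylinders)
together with its rasterised contrast map χ = (εr − εbg)/εbg.

`figure_fixture` reproduces the two-scatterer study configurations used
throughout the package's worked examples: pairs of weak point scatterers and
pairs of dielectric cylinders at 300 MHz at separations that straddle the
Sparrow limits.  The grid (2 m × 2 m, λ/50 cells), the ring (radius 10λ,
36 transmitters / 36 receivers) and the default point permittivity (1.1) are
this package's choices, made for far-field validity and weak-contrast Born
accuracy; fixtures document them rather than inherit them from elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml

from .config import PhysicalConfig

ScattererKind = Literal["point", "cylinder"]

#: center-to-center separations (m) of the two-point study scenes
POINT_SEPARATIONS = {"fig3a": 0.30, "fig3d": 0.34, "fig3g": 0.38}
ASYM_POINT_SEPARATIONS = {"fig5a": 0.34, "fig5d": 0.38, "fig5g": 0.42}
#: edge-to-edge gaps (m) of the two-cylinder study scenes
CYLINDER_GAPS = {"fig4a": 0.12, "fig4d": 0.16, "fig4g": 0.20}
ASYM_CYLINDER_GAPS = {"fig6a": 0.11, "fig6d": 0.15, "fig6g": 0.19}

FIXTURE_NAMES = (
    ("fig2",)
    + tuple(POINT_SEPARATIONS)
    + tuple(CYLINDER_GAPS)
    + tuple(ASYM_POINT_SEPARATIONS)
    + tuple(ASYM_CYLINDER_GAPS)
)


@dataclass(frozen=True)
class ScattererSpec:
    """One parametric scatterer.

    ``kind="point"`` occupies exactly one grid cell (radius is ignored and
    treated as 0); ``kind="cylinder"`` covers every cell whose centre lies
    within ``radius`` of ``center``.
    """

    kind: ScattererKind
    center: tuple[float, float]
    radius: float = 0.0
    relative_permittivity: float = 1.1

    def __post_init__(self) -> None:
        if self.kind not in ("point", "cylinder"):
            raise ValueError(f"unknown scatterer kind {self.kind!r}")
        if self.kind == "cylinder" and not self.radius > 0:
            raise ValueError("cylinder radius must be positive")
        if self.kind == "point" and self.radius != 0.0:
            raise ValueError("point scatterers have radius 0")

    def contrast(self, config: PhysicalConfig) -> float:
        """χ = (εr − εbg)/εbg; non-negative by the weak-scatterer convention."""
        chi = (
            self.relative_permittivity - config.background_permittivity
        ) / config.background_permittivity
        if chi < 0:
            raise ValueError(
                "scatterer permittivity below background is not supported"
            )
        return chi

    @property
    def edge_distance(self) -> float:
        """Edge-to-centre distance a (0 for points, radius for cylinders)."""
        return self.radius if self.kind == "cylinder" else 0.0


@dataclass(frozen=True)
class ImagingDomain:
    """Rectangular grid of square cells tiling ``extent`` exactly.

    ``extent`` is (x_min, x_max, y_min, y_max) in metres.  Cell centres are
    offset half a cell from the edges; the flattened index of cell (ix, iy)
    is ``iy * nx + ix``.
    """

    extent: tuple[float, float, float, float]
    cell_size: float

    def __post_init__(self) -> None:
        x0, x1, y0, y1 = self.extent
        if not (x1 > x0 and y1 > y0 and self.cell_size > 0):
            raise ValueError("degenerate imaging domain")
        for span in (x1 - x0, y1 - y0):
            n = span / self.cell_size
            if abs(n - round(n)) > 1e-9 * max(1.0, n):
                raise ValueError(
                    f"cell size {self.cell_size} does not tile span {span} exactly"
                )

    @property
    def nx(self) -> int:
        return round((self.extent[1] - self.extent[0]) / self.cell_size)

    @property
    def ny(self) -> int:
        return round((self.extent[3] - self.extent[2]) / self.cell_size)

    @property
    def x_centers(self) -> np.ndarray:
        return self.extent[0] + (np.arange(self.nx) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        return self.extent[2] + (np.arange(self.ny) + 0.5) * self.cell_size

    @property
    def cell_centers(self) -> np.ndarray:
        """(nx*ny, 2) array of cell-centre coordinates, row-major in y then x."""
        X, Y = np.meshgrid(self.x_centers, self.y_centers)
        return np.column_stack([X.ravel(), Y.ravel()])

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def contains(self, center: tuple[float, float], radius: float = 0.0) -> bool:
        x0, x1, y0, y1 = self.extent
        cx, cy = center
        return (
            x0 <= cx - radius
            and cx + radius <= x1
            and y0 <= cy - radius
            and cy + radius <= y1
        )


@dataclass(frozen=True)
class AntennaRing:
    """Far-field measurement circle: plane-wave transmitters and point receivers.

    Transmit angles and receiver positions are uniformly spaced on [0, 2π).
    Far-field validity of the asymptotic receive model requires a radius of at
    least ~10 wavelengths; `eisr.forward.build_operators` warns below that.
    """

    radius: float
    n_transmitters: int = 36
    n_receivers: int = 36

    def __post_init__(self) -> None:
        if not (self.radius > 0 and self.n_transmitters > 0 and self.n_receivers > 0):
            raise ValueError("invalid antenna ring")

    @property
    def transmit_angles(self) -> np.ndarray:
        return np.arange(self.n_transmitters) * 2.0 * np.pi / self.n_transmitters

    @property
    def receiver_positions(self) -> np.ndarray:
        th = np.arange(self.n_receivers) * 2.0 * np.pi / self.n_receivers
        return self.radius * np.column_stack([np.cos(th), np.sin(th)])


@dataclass(frozen=True)
class ContrastScene:
    """Parametric scatterers plus their rasterised contrast map.

    ``chi`` has shape (ny, nx) on the domain grid; ``chi.ravel()`` follows the
    domain's flattened cell ordering.
    """

    domain: ImagingDomain
    specs: tuple[ScattererSpec, ...]
    chi: np.ndarray = field(repr=False)

    @property
    def support(self) -> np.ndarray:
        """Flattened indices of cells with non-zero contrast."""
        return np.flatnonzero(self.chi.ravel())


def build_scene(
    specs: Sequence[ScattererSpec],
    domain: ImagingDomain,
    config: PhysicalConfig,
) -> ContrastScene:
    """Rasterise scatterer specs onto the imaging grid.

    A cylinder covers every cell whose centre is within its radius; a point
    occupies the single cell whose centre is nearest its location.  Raises if
    any scatterer pokes outside the domain.
    """
    chi = np.zeros((domain.ny, domain.nx))
    xc = domain.x_centers
    yc = domain.y_centers
    for spec in specs:
        if not domain.contains(spec.center, spec.edge_distance):
            raise ValueError(
                f"scatterer at {spec.center} (radius {spec.edge_distance}) "
                f"lies outside the imaging domain {domain.extent}"
            )
        value = spec.contrast(config)
        if spec.kind == "cylinder":
            X, Y = np.meshgrid(xc - spec.center[0], yc - spec.center[1])
            chi[X**2 + Y**2 <= spec.radius**2] = value
        else:
            ix = int(np.argmin(np.abs(xc - spec.center[0])))
            iy = int(np.argmin(np.abs(yc - spec.center[1])))
            chi[iy, ix] = value
    return ContrastScene(domain=domain, specs=tuple(specs), chi=chi)


def default_domain() -> ImagingDomain:
    """2 m × 2 m grid with 0.02 m (λ/50 at 300 MHz) cells, centred at origin."""
    return ImagingDomain(extent=(-1.0, 1.0, -1.0, 1.0), cell_size=0.02)


def default_ring() -> AntennaRing:
    """Radius 10 m (10λ at 300 MHz), 36 transmitters and 36 receivers."""
    return AntennaRing(radius=10.0, n_transmitters=36, n_receivers=36)


def figure_fixture(
    name: str, frequency: float = 300e6
) -> tuple[ContrastScene, PhysicalConfig, AntennaRing]:
    """Return one of the named two-scatterer (or single-point) study scenes.

    fig2        one point scatterer at the origin.
    fig3a/d/g   two εr=1.1 points, centre separations 0.30 / 0.34 / 0.38 m.
    fig4a/d/g   two r=0.1 m εr=1.1 cylinders, edge gaps 0.12 / 0.16 / 0.20 m.
    fig5a/d/g   points εr=1.1 and 1.2, centre separations 0.34 / 0.38 / 0.42 m.
    fig6a/d/g   cylinders r=0.1 and 0.15 m (εr=1.1), edge gaps 0.11/0.15/0.19 m.

    Point separations are centre-to-centre; cylinder separations are
    edge-to-edge, matching the d − 2a edge convention used by the extended
    Sparrow criterion.
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    config = PhysicalConfig(frequency=frequency)
    domain = default_domain()
    ring = default_ring()

    def points(d: float, eps2: float = 1.1) -> list[ScattererSpec]:
        return [
            ScattererSpec("point", (-d / 2, 0.0), 0.0, 1.1),
            ScattererSpec("point", (+d / 2, 0.0), 0.0, eps2),
        ]

    def cylinders(gap: float, r1: float, r2: float) -> list[ScattererSpec]:
        d = gap + r1 + r2  # edge gap -> centre separation
        return [
            ScattererSpec("cylinder", (-d / 2, 0.0), r1, 1.1),
            ScattererSpec("cylinder", (+d / 2, 0.0), r2, 1.1),
        ]

    if name == "fig2":
        specs = [ScattererSpec("point", (0.0, 0.0), 0.0, 1.1)]
    elif name in POINT_SEPARATIONS:
        specs = points(POINT_SEPARATIONS[name])
    elif name in ASYM_POINT_SEPARATIONS:
        specs = points(ASYM_POINT_SEPARATIONS[name], eps2=1.2)
    elif name in CYLINDER_GAPS:
        specs = cylinders(CYLINDER_GAPS[name], 0.1, 0.1)
    else:
        specs = cylinders(ASYM_CYLINDER_GAPS[name], 0.1, 0.15)
    return build_scene(specs, domain, config), config, ring


def load_scene_config(
    path: str | Path,
) -> tuple[ContrastScene, PhysicalConfig, AntennaRing]:
    """Read a YAML scene description.

    Expected keys::

        frequency_hz: 300e6
        domain: {extent: [x_min, x_max, y_min, y_max], cell_size: 0.02}
        ring: {radius: 10.0, n_tx: 36, n_rx: 36}
        scatterers:
          - {kind: cylinder, center: [-0.2, 0.0], radius: 0.1, epsilon_r: 1.1}
    """
    raw = yaml.safe_load(Path(path).read_text())
    config = PhysicalConfig(frequency=float(raw["frequency_hz"]))
    dom = raw.get("domain", {})
    domain = ImagingDomain(
        extent=tuple(float(v) for v in dom.get("extent", (-1.0, 1.0, -1.0, 1.0))),
        cell_size=float(dom.get("cell_size", 0.02)),
    )
    rg = raw.get("ring", {})
    ring = AntennaRing(
        radius=float(rg.get("radius", 10.0)),
        n_transmitters=int(rg.get("n_tx", 36)),
        n_receivers=int(rg.get("n_rx", 36)),
    )
    specs = [
        ScattererSpec(
            kind=s["kind"],
            center=tuple(float(v) for v in s["center"]),
            radius=float(s.get("radius", 0.0)),
            relative_permittivity=float(s.get("epsilon_r", 1.1)),
        )
        for s in raw.get("scatterers", [])
    ]
    return build_scene(specs, domain, config), config, ring
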