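"""CSV / JSON / PNG writers for grids, profiles and resolution reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .config import PhysicalConfig
from .criteria import ResolutionResult
from .scenes import ImagingDomain


def write_grid(
    values: np.ndarray, domain: ImagingDomain, path: str | Path
) -> Path:
    """Write a 2-D grid as CSV with an x-coordinate header row and a
    y-coordinate first column.  Values must be finite and real."""
    values = np.asarray(values)
    if values.shape != (domain.ny, domain.nx):
        raise ValueError(f"grid shape {values.shape} does not match domain")
    if not np.all(np.isfinite(values)):
        raise ValueError("grid contains non-finite values")
    path = Path(path)
    header = "," + ",".join(repr(float(x)) for x in domain.x_centers)
    rows = [header]
    for y, row in zip(domain.y_centers, values):
        rows.append(repr(float(y)) + "," + ",".join(repr(float(v)) for v in row))
    path.write_text("\n".join(rows) + "\n")
    return path


def read_grid(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of `write_grid`: returns (x, y, values)."""
    lines = Path(path).read_text().strip().splitlines()
    x = np.array([float(v) for v in lines[0].split(",")[1:]])
    y, vals = [], []
    for line in lines[1:]:
        parts = line.split(",")
        y.append(float(parts[0]))
        vals.append([float(v) for v in parts[1:]])
    return x, np.array(y), np.array(vals)


def write_profile(
    x: np.ndarray, values: np.ndarray, path: str | Path
) -> Path:
    """Two-column CSV (x, intensity)."""
    path = Path(path)
    lines = ["x,intensity"] + [
        f"{repr(float(a))},{repr(float(b))}" for a, b in zip(x, values)
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_report(
    result: ResolutionResult, config: PhysicalConfig, path: str | Path
) -> Path:
    """JSON resolution report; gaussian_point_m is null when not applicable."""
    path = Path(path)
    payload = {
        "criterion": result.criterion,
        "sigma_m": result.sigma,
        "sigma_wavelengths": result.sigma_wavelengths,
        "critical_separation_m": result.critical_separation_d,
        "gaussian_point_m": result.gaussian_point_g,
        "frequency_hz": config.frequency,
        "wavelength_m": config.wavelength,
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def save_png(
    values: np.ndarray, domain: ImagingDomain, path: str | Path, title: str = ""
) -> Path:
    """Render a grid as a PNG image with physical axes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    x0, x1, y0, y1 = domain.extent
    im = ax.imshow(
        values, origin="lower", extent=(x0, x1, y0, y1), cmap="viridis"
    )
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
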