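"""PMC surface matrix, surface/radar rendering, and concavity reporting.

The nine primary scores of a policy are arranged row-major into a 3x3
matrix (row 1 = X1, X2, X3; row 2 = X4, X5, X6; row 3 = X7, X8, X9) and
rendered as a 3-D surface. Depressions in the surface mark weak policy
dimensions: the concavity report quantifies each cell's depression as
``1 - score``, an in-package quantification of what the surface shows
visually.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import matplotlib

matplotlib.use("Agg")  # headless, deterministic backend

import matplotlib.pyplot as plt
import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .errors import PmcError
from .pmc import PmcResult, PrimaryScoreVector

__all__ = [
    "SurfaceMatrix",
    "surface_matrix",
    "upsample",
    "render_surface",
    "render_radar",
    "concavity_report",
    "ConcavityReport",
]


@dataclass(frozen=True)
class SurfaceMatrix:
    """3x3 row-major arrangement of the nine primary scores."""

    values: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.values) != 3 or any(len(row) != 3 for row in self.values):
            raise PmcError("surface matrix must be 3x3")
        if any(not 0 <= v <= 1 for row in self.values for v in row):
            raise PmcError("surface cells must lie in [0, 1]")

    def to_array(self) -> np.ndarray:
        return np.array(self.values, dtype=float)

    def flatten(self) -> tuple[float, ...]:
        """Row-major flattening; recovers X1..X9 in order."""
        return tuple(v for row in self.values for v in row)


def surface_matrix(vector: PrimaryScoreVector) -> SurfaceMatrix:
    """Arrange a 9-score vector into the 3x3 surface matrix."""
    scores = vector.scores
    if len(scores) != 9:
        raise PmcError(f"surface matrix needs exactly 9 scores, got {len(scores)}")
    rows = tuple(tuple(scores[r * 3 + c] for c in range(3)) for r in range(3))
    return SurfaceMatrix(rows)


def upsample(
    matrix: SurfaceMatrix,
    factor: int = 10,
    method: Literal["bilinear", "bicubic"] = "bilinear",
) -> np.ndarray:
    """Interpolate the 3x3 grid onto a ``(2*factor+1)`` square grid.

    ``factor=1`` returns the matrix unchanged. Bilinear interpolation is
    bounded by the cell extremes; bicubic (a order-3 spline) may overshoot
    slightly and is offered for smoother renders only.
    """
    if factor < 1:
        raise PmcError("upsample factor must be >= 1")
    grid = matrix.to_array()
    if factor == 1:
        return grid
    n = 2 * factor + 1
    coords = np.linspace(0.0, 2.0, n)
    if method == "bilinear":
        interp = RegularGridInterpolator(([0.0, 1.0, 2.0], [0.0, 1.0, 2.0]), grid)
        yy, xx = np.meshgrid(coords, coords, indexing="ij")
        return interp(np.stack([yy.ravel(), xx.ravel()], axis=1)).reshape(n, n)
    if method == "bicubic":
        yy, xx = np.meshgrid(coords, coords, indexing="ij")
        return ndimage.map_coordinates(grid, [yy, xx], order=3, mode="nearest")
    raise ValueError(f"unknown interpolation method {method!r}")


_PRIMARY_LABELS = tuple(f"X{i}" for i in range(1, 10))


def render_surface(
    matrix: SurfaceMatrix,
    path: str | Path,
    factor: int = 10,
    method: Literal["bilinear", "bicubic"] = "bilinear",
    cmap: str = "viridis",
    title: str = "",
    dpi: int = 120,
) -> Path:
    """Render the PMC surface to a raster (PNG) or vector (SVG) file.

    Deterministic for fixed options: identical inputs write identical
    files. The vertical axis is fixed to [0, 1] so surfaces of different
    policies are visually comparable.
    """
    grid = upsample(matrix, factor=factor, method=method)
    n = grid.shape[0]
    xx, yy = np.meshgrid(np.linspace(0, 2, n), np.linspace(0, 2, n))
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    ax.plot_surface(xx, yy, grid, cmap=cmap, vmin=0.0, vmax=1.0, antialiased=True)
    ax.set_zlim(0.0, 1.0)
    ax.set_xticks([0, 1, 2], ["1", "2", "3"])
    ax.set_yticks([0, 1, 2], ["1", "2", "3"])
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    ax.set_zlabel("score")
    if title:
        ax.set_title(title)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=dpi, metadata=_stable_metadata(path))
    plt.close(fig)
    return path


def render_radar(
    results: Sequence[PmcResult],
    path: str | Path,
    dpi: int = 120,
    title: str = "",
) -> Path:
    """Radar chart: one closed 9-axis polygon per policy, axes X1..X9,
    radial range [0, 1]."""
    if not results:
        raise PmcError("no results to plot")
    angles = np.linspace(0, 2 * np.pi, 9, endpoint=False)
    closed = np.concatenate([angles, angles[:1]])
    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="polar")
    for result in results:
        scores = result.primary_scores.scores
        if len(scores) != 9:
            raise PmcError("radar chart expects 9 primary scores per policy")
        values = np.concatenate([scores, scores[:1]])
        ax.plot(closed, values, linewidth=1.2, label=result.policy)
    ax.set_xticks(angles)
    ax.set_xticklabels(_PRIMARY_LABELS)
    ax.set_ylim(0.0, 1.0)
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=8)
    if title:
        ax.set_title(title)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=dpi, bbox_inches="tight", metadata=_stable_metadata(path))
    plt.close(fig)
    return path


def _stable_metadata(path: Path) -> dict | None:
    # strip creation dates so repeated renders are byte-identical
    suffix = path.suffix.lower()
    if suffix == ".svg":
        return {"Date": None}
    if suffix == ".png":
        return {"Software": "pmcindex"}
    return None


@dataclass(frozen=True)
class ConcavityReport:
    """Per-cell depressions of a surface matrix.

    ``depressions`` maps primary id ("X1".."X9") to ``1 - score``; ``deepest``
    lists every id attaining the maximum depression (ties preserved, schema
    order).
    """

    depressions: dict[str, float]
    deepest: tuple[str, ...]
    max_depression: float

    @property
    def total_depression(self) -> float:
        return float(sum(self.depressions.values()))


def concavity_report(matrix: SurfaceMatrix) -> ConcavityReport:
    """Quantify each cell's depression as ``1 - score``.

    A flat all-ones surface has zero depression everywhere; the deepest
    cell(s) mark the dimension(s) most in need of improvement.
    """
    flat = matrix.flatten()
    depressions = {
        label: round(1.0 - value, 12) for label, value in zip(_PRIMARY_LABELS, flat)
    }
    max_dep = max(depressions.values())
    deepest = tuple(k for k, v in depressions.items() if v == max_dep)
    return ConcavityReport(depressions=depressions, deepest=deepest, max_depression=max_dep)
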