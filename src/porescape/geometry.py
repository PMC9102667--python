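"""Pore-curvature geometry.

A cell resting on the inner wall of a spherical scaffold macropore
experiences a curvature set by the pore radius r.  Two summaries are used:

* the principal curvature 1/r (and, for a sphere, the Gaussian curvature
  1/r²), and
* the solid angle Ω = A / r² subtended by a cell of surface area A — the
  area of the spherical cap the cell covers, projected to the unit sphere.

The cell itself is modeled as a prolate spheroid (long symmetry axis =
cell width, transverse diameter = cell height), whose closed-form surface
area feeds Ω.  Pore radii come either from nominal porogen sieve ranges or
from measured longest-chord (maximum Feret) diameters on binary masks of
micrographs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import label, regionprops

from .errors import InvalidInputError

__all__ = [
    "SpheroidCell",
    "PoreGeometry",
    "PoreMeasurementSet",
    "spheroid_surface_area",
    "solid_angle",
    "curvature_from_radius",
    "measure_pore_diameters",
]


def spheroid_surface_area(height_um: float, width_um: float) -> float:
    """Closed-form surface area of a prolate spheroid, in μm².

    ``width_um`` is the full length of the polar (symmetry) axis and
    ``height_um`` the full transverse (equatorial) diameter.  Reduces to
    the sphere formula 4πR² when the two are equal.  If ``height_um``
    exceeds ``width_um`` the axes are swapped with a warning, so the
    spheroid is always prolate.
    """
    if height_um <= 0 or width_um <= 0:
        raise InvalidInputError(
            f"spheroid axes must be positive, got height={height_um}, width={width_um}"
        )
    if height_um > width_um:
        warnings.warn(
            "height exceeds width; swapping axes to keep the spheroid prolate",
            stacklevel=2,
        )
        height_um, width_um = width_um, height_um
    a = height_um / 2.0  # equatorial semi-axis
    c = width_um / 2.0  # polar semi-axis, c >= a
    if math.isclose(a, c, rel_tol=1e-12):
        return 4.0 * math.pi * a * a
    e = math.sqrt(1.0 - (a * a) / (c * c))
    return 2.0 * math.pi * a * a * (1.0 + (c / (a * e)) * math.asin(e))


def solid_angle(cell_area_um2: float, pore_radius_um: float) -> float:
    """Solid angle Ω = A / r² (steradians) subtended by a cell of surface
    area ``cell_area_um2`` on a spherical pore wall of radius ``pore_radius_um``.

    Dimensionless (sr): invariant under uniform rescaling of all lengths,
    and strictly decreasing in the pore radius.
    """
    if cell_area_um2 <= 0 or pore_radius_um <= 0:
        raise InvalidInputError(
            f"area and radius must be positive, got A={cell_area_um2}, r={pore_radius_um}"
        )
    return cell_area_um2 / (pore_radius_um * pore_radius_um)


def curvature_from_radius(
    radius_um: float, kind: Literal["principal", "gaussian"] = "principal"
) -> float:
    """Curvature of a sphere of radius ``radius_um``.

    ``kind="principal"`` returns 1/r (μm⁻¹); ``kind="gaussian"`` returns
    1/r² (μm⁻²), the product of the two equal principal curvatures.
    """
    if radius_um <= 0:
        raise InvalidInputError(f"radius must be positive, got {radius_um}")
    if kind == "principal":
        return 1.0 / radius_um
    if kind == "gaussian":
        return 1.0 / (radius_um * radius_um)
    raise InvalidInputError(f"unknown curvature kind {kind!r}")


@dataclass(frozen=True)
class SpheroidCell:
    """A cell idealized as a prolate spheroid.

    ``height_um`` is the full transverse diameter and ``width_um`` the full
    long-axis length; the default 10 × 20 μm is a typical adherent
    mesenchymal stem cell.
    """

    height_um: float = 10.0
    width_um: float = 20.0

    def __post_init__(self) -> None:
        if self.height_um <= 0 or self.width_um <= 0:
            raise InvalidInputError("cell axes must be positive")
        if self.height_um > self.width_um:
            object.__setattr__(self, "height_um", self.width_um)
            object.__setattr__(self, "width_um", self.height_um)

    @property
    def surface_area_um2(self) -> float:
        return spheroid_surface_area(self.height_um, self.width_um)


@dataclass(frozen=True)
class PoreGeometry:
    """Curvature summary of a macropore population.

    ``mean_radius_um`` defaults to the midpoint of the nominal diameter
    range divided by two; pass a measured mean radius to override.
    """

    diameter_range_um: tuple[float, float]
    mean_radius_um: float

    def __post_init__(self) -> None:
        low, high = self.diameter_range_um
        if not (0 < low < high):
            raise InvalidInputError(f"need 0 < low < high, got ({low}, {high})")
        if not (low / 2.0 <= self.mean_radius_um <= high / 2.0):
            raise InvalidInputError(
                f"mean radius {self.mean_radius_um} outside [{low / 2}, {high / 2}]"
            )

    @classmethod
    def from_diameter_range(
        cls, low_um: float, high_um: float, mean_radius_um: float | None = None
    ) -> "PoreGeometry":
        if mean_radius_um is None:
            mean_radius_um = (low_um + high_um) / 4.0  # midpoint diameter / 2
        return cls((low_um, high_um), mean_radius_um)

    @property
    def mean_curvature_per_um(self) -> float:
        return curvature_from_radius(self.mean_radius_um, "principal")

    @property
    def gaussian_curvature_per_um2(self) -> float:
        return curvature_from_radius(self.mean_radius_um, "gaussian")

    def solid_angle_sr(self, cell: SpheroidCell) -> float:
        return solid_angle(cell.surface_area_um2, self.mean_radius_um)


@dataclass(frozen=True)
class PoreMeasurementSet:
    """Longest-chord diameters, one per labeled pore component."""

    diameters_um: tuple[float, ...]
    pixel_size_um: float

    @property
    def n_pores(self) -> int:
        return len(self.diameters_um)

    @property
    def mean_diameter_um(self) -> float:
        return float(np.mean(self.diameters_um)) if self.diameters_um else float("nan")

    @property
    def mean_radius_um(self) -> float:
        return self.mean_diameter_um / 2.0


def _max_feret_px(coords: np.ndarray) -> float:
    """Maximum pairwise distance between pixel centers of one component.

    Uses the convex hull so only hull vertices are compared; falls back to
    all pixel pairs for degenerate (collinear / tiny) components.
    """
    if len(coords) == 1:
        return 0.0
    pts = coords.astype(float)
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:  # collinear component
            pass
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def measure_pore_diameters(
    pore_mask: np.ndarray, pixel_size_um: float
) -> PoreMeasurementSet:
    """Per-pore longest chord (maximum Feret diameter) from a binary mask.

    Pores are 8-connected foreground components; the longest chord of a
    component is the maximum distance between any two of its pixel centers,
    reported in μm.
    """
    if pixel_size_um <= 0:
        raise InvalidInputError("pixel size must be positive")
    mask = np.asarray(pore_mask)
    if mask.ndim != 2:
        raise InvalidInputError("pore mask must be a 2-D raster")
    vals = np.unique(mask)
    if mask.dtype != bool and len(vals) > 2:
        raise InvalidInputError("pore mask must be binary (background 0)")
    fg = mask.astype(bool)
    if not fg.any():
        warnings.warn("empty pore mask: no pores to measure", stacklevel=2)
        return PoreMeasurementSet((), pixel_size_um)
    labels = label(fg, connectivity=2)
    diameters = [
        _max_feret_px(region.coords) * pixel_size_um for region in regionprops(labels)
    ]
    return PoreMeasurementSet(tuple(diameters), pixel_size_um)
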