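"""Equal-area region partitioning of larval rearing containers.

The water surface of a rearing container is divided into three regions of
exactly equal area: an *edge* region that touches the container wall, a
*central* region in the middle of the water surface, and an *intermediate*
region between the two.  For circular containers the regions are concentric
annuli; for rectangular containers they are constant-width frames solved from
a quadratic so that each frame encloses exactly one third of the surface.

All physical quantities are in centimetres (areas in cm²).  Region assignment
uses the distance of a point from the nearest wall, which makes the circular
and rectangular cases share one convention: a point exactly on a boundary
belongs to the more wall-ward region, so rasterisation is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

#: Region names ordered from the wall inwards.
REGIONS = ("edge", "intermediate", "central")

#: Integer labels used in rasterised region masks (0 = background).
REGION_LABELS = {"edge": 1, "intermediate": 2, "central": 3}


class GeometryError(ValueError):
    """Invalid container geometry (non-positive or missing dimensions)."""


class OutOfBoundsError(GeometryError):
    """A point lies outside the container footprint."""


@dataclass(frozen=True)
class Container:
    """Physical description of a rearing vessel.

    Parameters
    ----------
    shape :
        ``"circle"`` or ``"rectangle"``.
    water_volume_ml :
        Volume of water in the container (ml); the denominator of all
        larva/ml densities.
    n_larvae :
        Nominal number of larvae stocked in the container.
    length_cm, width_cm :
        Footprint of a rectangular container.
    diameter_cm :
        Footprint of a circular container.
    depth_cm :
        Container depth; informational only (regions are 2-D).
    """

    shape: Literal["circle", "rectangle"]
    water_volume_ml: float
    n_larvae: int = 0
    length_cm: float | None = None
    width_cm: float | None = None
    diameter_cm: float | None = None
    depth_cm: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("circle", "rectangle"):
            raise GeometryError(f"unknown container shape {self.shape!r}")
        if self.shape == "rectangle":
            if self.length_cm is None or self.width_cm is None:
                raise GeometryError("rectangle requires length_cm and width_cm")
            if self.length_cm <= 0 or self.width_cm <= 0:
                raise GeometryError("rectangle dimensions must be positive")
        else:
            if self.diameter_cm is None:
                raise GeometryError("circle requires diameter_cm")
            if self.diameter_cm <= 0:
                raise GeometryError("circle diameter must be positive")
        if self.depth_cm is not None and self.depth_cm <= 0:
            raise GeometryError("depth_cm must be positive")
        if self.water_volume_ml <= 0:
            raise GeometryError("water_volume_ml must be positive")
        if self.n_larvae < 0:
            raise GeometryError("n_larvae must be non-negative")

    @property
    def surface_area_cm2(self) -> float:
        if self.shape == "rectangle":
            return self.length_cm * self.width_cm
        return math.pi * (self.diameter_cm / 2.0) ** 2

    @property
    def footprint_cm(self) -> tuple[float, float]:
        """(extent along x, extent along y) of the bounding box."""
        if self.shape == "rectangle":
            return (self.length_cm, self.width_cm)
        return (self.diameter_cm, self.diameter_cm)

    @classmethod
    def from_dict(cls, d: dict) -> "Container":
        known = {
            "shape", "water_volume_ml", "n_larvae",
            "length_cm", "width_cm", "diameter_cm", "depth_cm",
        }
        unknown = set(d) - known
        if unknown:
            raise GeometryError(f"unknown container keys: {sorted(unknown)}")
        try:
            return cls(**d)
        except TypeError as exc:  # missing required field
            raise GeometryError(str(exc)) from exc


@dataclass(frozen=True)
class RegionSpec:
    """The three equal-area regions of a container surface.

    ``wall_distances_cm`` holds the two boundary distances (d1, d2) measured
    from the wall: a point at wall distance ``d`` is *edge* if ``d <= d1``,
    *intermediate* if ``d1 < d <= d2`` and *central* otherwise.  For circles
    the equivalent boundary radii are exposed via :attr:`boundary_radii_cm`.
    """

    shape: Literal["circle", "rectangle"]
    areas_cm2: dict = field(default_factory=dict)
    wall_distances_cm: tuple[float, float] = (0.0, 0.0)
    total_area_cm2: float = 0.0

    def __post_init__(self) -> None:
        d1, d2 = self.wall_distances_cm
        if not (0 < d1 < d2):
            raise GeometryError("boundaries must satisfy 0 < inner < outer")
        areas = [self.areas_cm2[r] for r in REGIONS]
        for a in areas:
            if not math.isclose(a, self.total_area_cm2 / 3.0, rel_tol=1e-9):
                raise GeometryError("regions are not equal-area")
        if not math.isclose(sum(areas), self.total_area_cm2, rel_tol=1e-9):
            raise GeometryError("region areas do not tile the surface")

    @property
    def region_area_cm2(self) -> float:
        """Common area of each region (one third of the surface)."""
        return self.total_area_cm2 / 3.0

    def boundary_radii_cm(self, container: Container) -> tuple[float, float]:
        """(central radius, intermediate outer radius) for circles."""
        if container.shape != "circle":
            raise GeometryError("boundary radii are defined for circles only")
        R = container.diameter_cm / 2.0
        d1, d2 = self.wall_distances_cm
        return (R - d2, R - d1)

    def to_frame(self) -> pd.DataFrame:
        d1, d2 = self.wall_distances_cm
        outer = [d1, d2, float("nan")]
        inner = [0.0, d1, d2]
        return pd.DataFrame(
            {
                "region": list(REGIONS),
                "area_cm2": [self.areas_cm2[r] for r in REGIONS],
                "wall_distance_inner_cm": inner,
                "wall_distance_outer_cm": outer,
            }
        )


def solve_rectangle_margins(length_cm: float, width_cm: float) -> tuple[float, float]:
    """Constant-width margins realising the equal-area frames of a rectangle.

    The outer margin ``m_outer`` satisfies ``(L - 2m)(W - 2m) = (2/3) L W``
    (the edge frame holds one third of the area) and the inner margin
    ``m_inner`` satisfies ``(L - 2m)(W - 2m) = (1/3) L W``.  Both are the
    smaller root of the corresponding quadratic ``4m² - 2(L+W)m + (1-f)LW = 0``
    whose discriminant ``4(L+W)² - 16(1-f)LW >= 4(L-W)² + ...`` is positive
    for all positive L, W and f in (0, 1).
    """
    if length_cm <= 0 or width_cm <= 0:
        raise GeometryError("rectangle dimensions must be positive")

    def margin(inner_fraction: float) -> float:
        # 4m^2 - 2(L+W)m + (1 - f) L W = 0, smaller root
        s = length_cm + width_cm
        c = (1.0 - inner_fraction) * length_cm * width_cm
        disc = s * s - 4.0 * c
        return (s - math.sqrt(disc)) / 4.0

    m_outer = margin(2.0 / 3.0)
    m_inner = margin(1.0 / 3.0)
    return m_outer, m_inner


def region_boundaries(container: Container) -> RegionSpec:
    """Construct the three equal-area regions of a container surface.

    For circles, the boundary radii are ``R·sqrt(1/3)`` (central) and
    ``R·sqrt(2/3)`` (intermediate/edge); for rectangles, constant-width
    margins from :func:`solve_rectangle_margins`.
    """
    total = container.surface_area_cm2
    if container.shape == "circle":
        R = container.diameter_cm / 2.0
        r_central = R * math.sqrt(1.0 / 3.0)
        r_outer = R * math.sqrt(2.0 / 3.0)
        d1, d2 = R - r_outer, R - r_central
        area_central = math.pi * r_central**2
        area_inter = math.pi * r_outer**2 - area_central
        area_edge = total - math.pi * r_outer**2
    else:
        L, W = container.length_cm, container.width_cm
        m_outer, m_inner = solve_rectangle_margins(L, W)
        d1, d2 = m_outer, m_inner
        inner2 = (L - 2 * m_outer) * (W - 2 * m_outer)
        inner1 = (L - 2 * m_inner) * (W - 2 * m_inner)
        area_edge = total - inner2
        area_inter = inner2 - inner1
        area_central = inner1
    areas = {"edge": area_edge, "intermediate": area_inter, "central": area_central}
    return RegionSpec(
        shape=container.shape,
        areas_cm2=areas,
        wall_distances_cm=(d1, d2),
        total_area_cm2=total,
    )


def wall_distance(x, y, container: Container):
    """Distance (cm) from point(s) to the nearest container wall.

    Coordinates: rectangles use a corner origin with ``0 <= x <= L`` and
    ``0 <= y <= W``; circles use a centre origin.  Raises
    :class:`OutOfBoundsError` if any point lies outside the footprint
    (beyond a 1e-9 cm tolerance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    tol = 1e-9
    if container.shape == "rectangle":
        L, W = container.length_cm, container.width_cm
        if np.any(x < -tol) or np.any(x > L + tol) or np.any(y < -tol) or np.any(y > W + tol):
            raise OutOfBoundsError("point outside rectangular footprint")
        return np.minimum(np.minimum(x, L - x), np.minimum(y, W - y))
    R = container.diameter_cm / 2.0
    r = np.hypot(x, y)
    if np.any(r > R + tol):
        raise OutOfBoundsError("point outside circular footprint")
    return R - r


def assign_region(point, container: Container, spec: RegionSpec | None = None) -> str:
    """Region label for a single point (see :func:`wall_distance` for axes)."""
    if spec is None:
        spec = region_boundaries(container)
    x, y = point
    d = float(wall_distance(x, y, container))
    d1, d2 = spec.wall_distances_cm
    if d <= d1:
        return "edge"
    if d <= d2:
        return "intermediate"
    return "central"


def assign_regions(x, y, container: Container, spec: RegionSpec | None = None) -> np.ndarray:
    """Vectorised region assignment; returns integer labels (1/2/3)."""
    if spec is None:
        spec = region_boundaries(container)
    d = wall_distance(x, y, container)
    d1, d2 = spec.wall_distances_cm
    labels = np.full(np.shape(d), REGION_LABELS["central"], dtype=np.uint8)
    labels[d <= d2] = REGION_LABELS["intermediate"]
    labels[d <= d1] = REGION_LABELS["edge"]
    return labels


def region_label_mask(
    container: Container,
    spec: RegionSpec | None = None,
    px_per_cm: float = 25.0,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Rasterise the region partition onto a pixel grid.

    Returns a uint8 image with values 0/1/2/3 for background / edge /
    intermediate / central.  Pixels are classified by their centres; the grid
    origin is the image top-left corner (row ~ y, column ~ x), following the
    usual image convention.
    """
    if px_per_cm <= 0:
        raise GeometryError("px_per_cm must be positive")
    if spec is None:
        spec = region_boundaries(container)
    ext_x, ext_y = container.footprint_cm
    if shape is None:
        shape = (int(round(ext_y * px_per_cm)), int(round(ext_x * px_per_cm)))
    n_rows, n_cols = shape
    ys = (np.arange(n_rows) + 0.5) / px_per_cm
    xs = (np.arange(n_cols) + 0.5) / px_per_cm
    X, Y = np.meshgrid(xs, ys)
    out = np.zeros(shape, dtype=np.uint8)
    if container.shape == "circle":
        R = container.diameter_cm / 2.0
        Xc, Yc = X - ext_x / 2.0, Y - ext_y / 2.0
        inside = np.hypot(Xc, Yc) <= R
        if inside.any():
            out[inside] = assign_regions(Xc[inside], Yc[inside], container, spec)
    else:
        inside = (X <= container.length_cm) & (Y <= container.width_cm)
        out[inside] = assign_regions(X[inside], Y[inside], container, spec)
    return out
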