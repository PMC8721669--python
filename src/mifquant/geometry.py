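"""Region algebra on slide geometry.

Margin-band construction around the invasive tumor edge, seeded tile
sampling inside the central tumor, polygon areas, point membership and
point-to-mucosa depth. All lengths are micrometers; areas are returned in
mm². Coordinates are snapped to a 0.001 µm grid before predicates so that
point-on-boundary cases are stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, MultiPolygon, Point, Polygon, box
from shapely.geometry.base import BaseGeometry

from .core import UM2_PER_MM2
from .errors import GeometryError, InputError, SamplingError

SNAP_GRID_UM = 0.001


def snap(geom: BaseGeometry) -> BaseGeometry:
    """Snap coordinates to the stability grid."""
    return shapely.set_precision(geom, SNAP_GRID_UM)


def area_mm2(region: BaseGeometry) -> float:
    """Polygon area (holes subtracted) converted to mm²."""
    if not isinstance(region, (Polygon, MultiPolygon)):
        raise GeometryError("area_mm2 expects a polygon")
    if not region.is_valid:
        raise GeometryError("self-intersecting polygon")
    return region.area / UM2_PER_MM2


@dataclass
class MarginBand:
    """Band of tissue around (or inside) the invasive tumor edge."""

    source_id: str
    width_um: float
    direction: str
    band: BaseGeometry

    @property
    def area_mm2(self) -> float:
        return self.band.area / UM2_PER_MM2


def compute_margin(
    tumor: BaseGeometry,
    width_um: float = 250.0,
    direction: str = "outward",
    source_id: str = "central_tumor",
) -> MarginBand:
    """Build the invasive-margin band from the outermost tumor edge.

    ``outward`` (default): buffer(tumor, w) − tumor, a rim of width w that
    shares no interior with the tumor. ``inward``: tumor − buffer(tumor, −w).
    ``symmetric``: buffer(+w) − buffer(−w).
    """
    if width_um <= 0:
        raise GeometryError("margin width must be > 0")
    if not tumor.is_valid:
        raise GeometryError("invalid tumor polygon")
    if tumor.area == 0:
        raise GeometryError("degenerate (zero-area) tumor polygon")
    if direction == "outward":
        band = tumor.buffer(width_um).difference(tumor)
    elif direction == "inward":
        band = tumor.difference(tumor.buffer(-width_um))
    elif direction == "symmetric":
        band = tumor.buffer(width_um).difference(tumor.buffer(-width_um))
    else:
        raise GeometryError(f"unknown margin direction {direction!r}")
    return MarginBand(source_id, width_um, direction, band)


@dataclass
class TileGrid:
    """Non-overlapping axis-aligned square sampling tiles."""

    edge_um: float
    seed: int
    tiles: list[Polygon] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tiles)


def sample_tiles(
    central_tumor: BaseGeometry,
    n: int = 30,
    edge_um: float = 500.0,
    seed: int = 0,
) -> TileGrid:
    """Sample ``n`` disjoint square tiles fully inside the central tumor.

    Candidate tiles live on a regular lattice with pitch ``edge_um`` (hence
    pairwise disjoint); ``n`` of the admissible candidates are chosen by a
    seeded draw without replacement, so the result is deterministic per seed.
    """
    if n < 1:
        raise SamplingError("need n >= 1 tiles")
    if central_tumor.area < n * edge_um**2:
        raise SamplingError(
            f"region area {central_tumor.area:.0f} µm² cannot hold {n} tiles "
            f"of edge {edge_um} µm"
        )
    minx, miny, maxx, maxy = central_tumor.bounds
    xs = np.arange(minx, maxx - edge_um + 1e-9, edge_um)
    ys = np.arange(miny, maxy - edge_um + 1e-9, edge_um)
    candidates = [
        box(x, y, x + edge_um, y + edge_um)
        for x in xs
        for y in ys
        if central_tumor.covers(box(x, y, x + edge_um, y + edge_um))
    ]
    if len(candidates) < n:
        raise SamplingError(
            f"only {len(candidates)} admissible tiles fit; requested {n}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n, replace=False)
    return TileGrid(edge_um=edge_um, seed=seed,
                    tiles=[candidates[i] for i in sorted(chosen)])


def points_in_region(
    x: np.ndarray, y: np.ndarray, region: BaseGeometry
) -> np.ndarray:
    """Boolean membership of points in a region; boundary counts as inside."""
    geom = snap(region)
    shapely.prepare(geom)
    return shapely.intersects_xy(geom, np.round(np.asarray(x, float), 3),
                                 np.round(np.asarray(y, float), 3))


def depth_to_mucosa(x: float, y: float, mucosa: LineString) -> float:
    """Minimum Euclidean distance (µm) from a point to the mucosal line."""
    if mucosa is None or mucosa.is_empty or len(mucosa.coords) == 0:
        raise InputError("empty mucosa polyline")
    return float(mucosa.distance(Point(x, y)))
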