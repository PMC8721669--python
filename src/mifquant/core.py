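"""Core data model: cell tables, labeled regions, cohort manifests.

Cells are rows of a pandas DataFrame with point coordinates in micrometers
and binary marker calls; regions are shapely geometries tagged with a label
from a fixed vocabulary. Coordinates use a per-slide Cartesian frame with y
increasing toward deeper tissue (the mucosal surface sits near minimal y in
synthetic slides). Areas are computed in µm² and reported in mm².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from shapely.geometry import LineString, MultiPolygon, Polygon
from shapely.geometry.base import BaseGeometry

from .errors import GeometryError, SchemaError, ValidationError

#: The six markers of the main panel, in canonical column order.
CORE_MARKERS = ("CD3", "CD8", "FoxP3", "CD20", "CD68", "PanCK")
#: Maturation-panel markers (follicular dendritic cells / germinal centers).
OPTIONAL_MARKERS = ("CD21", "CD23")

CELL_ID = "cell_id"
X, Y = "x_um", "y_um"
#: Canonical cell-table column order used by writers.
CELL_COLUMNS = (CELL_ID, X, Y) + CORE_MARKERS

#: Region label vocabulary.
REGION_LABELS = (
    "central_tumor",
    "tumor_parenchyma",
    "stroma",
    "margin_band",
    "mucosa_line",
    "tls",
    "tile",
)

#: When a point sits on a shared boundary, membership is resolved toward the
#: label that appears first here (point-in-polygon with closed boundaries).
LABEL_PRIORITY = (
    "tls",
    "tumor_parenchyma",
    "stroma",
    "margin_band",
    "central_tumor",
    "tile",
)

UM2_PER_MM2 = 1e6


def validate_cells(df: pd.DataFrame, require_markers: bool = True) -> pd.DataFrame:
    """Validate a cell table against the data model and return it.

    Checks: required columns present, unique cell ids, finite coordinates,
    and binary marker values for every marker column that exists.
    """
    required = [CELL_ID, X, Y]
    if require_markers:
        required += list(CORE_MARKERS)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"cell table is missing required column {col!r}")
    if df[CELL_ID].duplicated().any():
        dup = df.loc[df[CELL_ID].duplicated(), CELL_ID].iloc[0]
        raise ValidationError(f"duplicate cell_id {dup!r}")
    xy = df[[X, Y]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        bad = int(np.where(~np.isfinite(xy).all(axis=1))[0][0])
        raise ValidationError(f"non-finite coordinate at row {bad}")
    for col in CORE_MARKERS + OPTIONAL_MARKERS:
        if col not in df.columns:
            continue
        vals = df[col].to_numpy()
        ok = np.isin(vals, (0, 1))
        if not ok.all():
            bad = int(np.where(~ok)[0][0])
            raise ValidationError(
                f"marker {col!r} has non-binary value {vals[bad]!r} at row {bad}"
            )
    return df


@dataclass
class Region:
    """A labeled geometry: polygon for areas, polyline for the mucosa."""

    label: str
    geometry: BaseGeometry
    id: str

    def validate(self) -> "Region":
        if self.label not in REGION_LABELS:
            raise ValidationError(
                f"unknown region label {self.label!r} for feature {self.id!r}"
            )
        if self.label == "mucosa_line":
            if not isinstance(self.geometry, LineString):
                raise GeometryError(
                    f"mucosa_line {self.id!r} must be a LineString"
                )
        else:
            if not isinstance(self.geometry, (Polygon, MultiPolygon)):
                raise GeometryError(
                    f"region {self.id!r} ({self.label}) must be a polygon"
                )
            if not self.geometry.is_valid:
                raise GeometryError(
                    f"region {self.id!r} ({self.label}) has invalid geometry "
                    "(self-intersection?)"
                )
        return self


@dataclass
class RegionSet:
    """Ordered collection of labeled regions for one slide."""

    regions: list[Region] = field(default_factory=list)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def add(self, region: Region) -> None:
        self.regions.append(region.validate())

    def by_label(self, label: str) -> list[Region]:
        return [r for r in self.regions if r.label == label]

    def first(self, label: str) -> Region | None:
        for r in self.regions:
            if r.label == label:
                return r
        return None

    def validate(self) -> "RegionSet":
        for r in self.regions:
            r.validate()
        return self


#: Outcome vocabulary per cohort arm.
COHORT_OUTCOMES = {
    "untreated": {"recurrence", "no_recurrence", "unknown"},
    "treated": {"CR", "non_CR", "unknown"},
}


def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort manifest table."""
    for col in ("patient_id", "cohort", "outcome"):
        if col not in df.columns:
            raise SchemaError(f"manifest is missing required column {col!r}")
    if df["patient_id"].duplicated().any():
        raise ValidationError("manifest patient_id values must be unique")
    for _, row in df.iterrows():
        allowed = COHORT_OUTCOMES.get(row["cohort"])
        if allowed is None:
            raise ValidationError(f"unknown cohort {row['cohort']!r}")
        if row["outcome"] not in allowed:
            raise ValidationError(
                f"outcome {row['outcome']!r} not valid for cohort "
                f"{row['cohort']!r}"
            )
    return df
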