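"""Readers and writers for the pipeline's on-disk formats.

Cells travel as UTF-8 CSV (dot decimal) with the canonical header
``cell_id,x_um,y_um,CD3,CD8,FoxP3,CD20,CD68,PanCK[,CD21,CD23,...]``; regions
as GeoJSON FeatureCollections whose coordinates are micrometers in a
non-geographic slide frame (declared in a top-level ``crs_note`` property).
Extra CSV columns are preserved as annotations. Readers reject exactly what
the writers cannot produce, so write∘read round-trips are stable.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape

from .core import (
    CELL_COLUMNS,
    OPTIONAL_MARKERS,
    Region,
    RegionSet,
    validate_cells,
    validate_manifest,
)
from .errors import GeometryError, SchemaError

CRS_NOTE = "cartesian micrometers, per-slide origin, y toward deeper tissue"


# ---------------------------------------------------------------- cell tables

def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-cell CSV table."""
    df = pd.read_csv(path)
    return validate_cells(df)


def write_cell_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cell table with canonical column order.

    Canonical columns first (optional markers when present), then any
    annotation columns in their existing order.
    """
    validate_cells(df)
    lead = [c for c in CELL_COLUMNS if c in df.columns]
    lead += [c for c in OPTIONAL_MARKERS if c in df.columns]
    rest = [c for c in df.columns if c not in lead]
    df[lead + rest].to_csv(path, index=False)


# -------------------------------------------------------------------- regions

def read_regions(path: str | Path) -> RegionSet:
    """Read a GeoJSON FeatureCollection into a validated RegionSet."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise SchemaError("regions file must be a GeoJSON FeatureCollection")
    rs = RegionSet()
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        if "label" not in props:
            raise SchemaError(f"feature {i} has no 'label' property")
        geom = shape(feat["geometry"])
        region = Region(
            label=props["label"],
            geometry=geom,
            id=str(props.get("id", feat.get("id", i))),
        )
        try:
            rs.add(region)
        except GeometryError as err:
            raise GeometryError(f"feature {region.id!r}: {err}") from err
    return rs


def write_regions(regions: RegionSet, path: str | Path) -> None:
    """Write a RegionSet as GeoJSON, preserving region order and vertices."""
    feats = []
    for r in regions:
        feats.append(
            {
                "type": "Feature",
                "properties": {"label": r.label, "id": r.id},
                "geometry": mapping(r.geometry),
            }
        )
    doc = {"type": "FeatureCollection", "crs_note": CRS_NOTE, "features": feats}
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ------------------------------------------------------------------- manifest

def read_manifest(path: str | Path) -> pd.DataFrame:
    return validate_manifest(pd.read_csv(path))


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    validate_manifest(df)
    df.to_csv(path, index=False)
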