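"""Tertiary lymphoid structure (TLS) architecture.

Detection of dense lymphocyte aggregates from the cell point pattern,
per-TLS composition features (B cell, CD4 T, CD8 T, FoxP3 T, macrophage
densities), maturation staging from CD21⁺ follicular-dendritic-cell networks
and CD23⁺ germinal-center zones, and superficial/deep stratification by
distance to the mucosal surface.

The detector replaces manual/trained annotation with a documented rule:
single-linkage components of lymphocytes at a fixed link radius, kept when
large enough and sufficiently B-cell rich. Pre-annotated TLS polygons, when
present in the region set, bypass detection.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from shapely.geometry import LineString, MultiPoint, Polygon
from shapely.geometry.base import BaseGeometry

from .config import AnalysisConfig
from .core import RegionSet
from .errors import GeometryError, StateError
from .geometry import area_mm2, depth_to_mucosa, points_in_region
from .phenotyping import LYMPHOCYTES, TLS_FEATURES

log = logging.getLogger(__name__)

MATURATION_STAGES = ("Early", "PFL", "SFL")

#: Truth table (FDC present, GC present) -> maturation stage. A germinal
#: center without a detectable FDC network is biologically anomalous but
#: still a secondary follicle; it is staged SFL and logged.
_STAGE_TABLE = {
    (False, False): "Early",
    (True, False): "PFL",
    (True, True): "SFL",
    (False, True): "SFL",
}


def detect_tls(
    cells: pd.DataFrame,
    config: AnalysisConfig,
    exclude: BaseGeometry | None = None,
) -> list[Polygon]:
    """Detect TLS as dense, B-cell-rich lymphocyte aggregates.

    Single-linkage components over lymphocytes (B cells ∪ T subsets) at
    ``link_radius_um``; a component is kept iff it has at least
    ``min_lymphocytes`` cells and a B-cell fraction ≥ ``min_b_fraction``.
    The reported polygon is the component convex hull dilated by half the
    link radius.

    ``exclude`` masks tissue out of the search — typically the central
    tumor plus invasive margin, since TLS are peritumoral structures and a
    dense diffuse stromal infiltrate belongs to compartment quantification,
    not to TLS detection.
    """
    if "phenotype" not in cells.columns:
        raise StateError("phenotypes not assigned")
    lymph = cells[cells["phenotype"].isin(LYMPHOCYTES)]
    if exclude is not None and len(lymph):
        inside = points_in_region(
            lymph["x_um"].to_numpy(float), lymph["y_um"].to_numpy(float),
            exclude,
        )
        lymph = lymph[~inside]
    if len(lymph) < config.min_lymphocytes:
        return []
    pts = lymph[["x_um", "y_um"]].to_numpy(float)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=config.link_radius_um, output_type="ndarray")
    n = len(pts)
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, comp = connected_components(adj, directed=False)
    is_b = (lymph["phenotype"] == "B_cell").to_numpy()
    polygons: list[Polygon] = []
    for cid in np.unique(comp):
        members = comp == cid
        size = int(members.sum())
        if size < config.min_lymphocytes:
            continue
        if is_b[members].mean() < config.min_b_fraction:
            continue
        hull = MultiPoint(pts[members]).convex_hull
        polygons.append(hull.buffer(config.link_radius_um / 2))
    return polygons


def tls_composition(
    cells: pd.DataFrame, tls: BaseGeometry
) -> tuple[np.ndarray, float]:
    """Density vector over the five composition features, plus area (mm²).

    Raw densities; the clustering pseudo-count is applied downstream, not
    here.
    """
    area = area_mm2(tls)
    if area <= 0:
        raise GeometryError("zero-area TLS polygon")
    inside = points_in_region(
        cells["x_um"].to_numpy(float), cells["y_um"].to_numpy(float), tls
    )
    counts = cells.loc[inside, "phenotype"].value_counts()
    dens = np.array([counts.get(ph, 0) / area for ph in TLS_FEATURES], float)
    return dens, area


def stage_maturation(
    cells: pd.DataFrame,
    tls: BaseGeometry,
    min_cd21: int = 5,
    min_cd23: int = 5,
) -> str:
    """Stage a TLS as Early / PFL / SFL from CD21/CD23 positives inside it.

    FDC network present iff the TLS holds at least ``min_cd21`` CD21⁺ cells;
    germinal center present iff at least ``min_cd23`` CD23⁺ cells. Returns
    ``"unstaged"`` when the maturation panel is absent.
    """
    if "CD21" not in cells.columns or "CD23" not in cells.columns:
        return "unstaged"
    inside = points_in_region(
        cells["x_um"].to_numpy(float), cells["y_um"].to_numpy(float), tls
    )
    fdc = int(cells.loc[inside, "CD21"].sum()) >= min_cd21
    gc = int(cells.loc[inside, "CD23"].sum()) >= min_cd23
    if gc and not fdc:
        log.warning("TLS with germinal center but no FDC network; staged SFL")
    return _STAGE_TABLE[(fdc, gc)]


def classify_depth(
    tls: BaseGeometry, mucosa: LineString | None, superficial_depth_um: float
) -> tuple[str, float]:
    """(depth class, depth µm) of a TLS centroid relative to the mucosa.

    Superficial iff centroid depth ≤ threshold (closed boundary). Without a
    mucosa line the TLS is depth-unstaged.
    """
    if mucosa is None:
        return "unstaged", np.nan
    c = tls.centroid
    depth = depth_to_mucosa(c.x, c.y, mucosa)
    # closed boundary, stabilized against float noise in the centroid
    is_superficial = depth <= superficial_depth_um + 1e-6
    return ("superficial" if is_superficial else "deep"), depth


def build_tls_records(
    cells: pd.DataFrame,
    regions: RegionSet,
    config: AnalysisConfig,
    patient_id: str = "",
    detect: bool = False,
) -> pd.DataFrame:
    """Assemble one record per TLS: polygon, area, features, depth, stage.

    Pre-annotated ``tls`` polygons in ``regions`` are used unless ``detect``
    forces the point-pattern detector (or none are annotated).
    """
    annotated = regions.by_label("tls")
    if annotated and not detect:
        polys = [r.geometry for r in annotated]
        ids = [r.id for r in annotated]
    else:
        exclude = None
        tumor = regions.first("central_tumor")
        if tumor is not None:
            exclude = tumor.geometry
            band = regions.first("margin_band")
            if band is not None:
                exclude = exclude.union(band.geometry)
        polys = detect_tls(cells, config, exclude=exclude)
        ids = [f"{patient_id}_tls{i}" for i in range(len(polys))]
    mucosa_region = regions.first("mucosa_line")
    mucosa = mucosa_region.geometry if mucosa_region else None
    rows = []
    for tid, poly in zip(ids, polys):
        dens, area = tls_composition(cells, poly)
        depth_class, depth = classify_depth(
            poly, mucosa, config.superficial_depth_um
        )
        stage = stage_maturation(cells, poly, config.min_cd21, config.min_cd23)
        row = {
            "tls_id": tid,
            "patient_id": patient_id,
            "area_mm2": area,
            "depth_um": depth,
            "depth_class": depth_class,
            "maturation": stage,
            "polygon_wkt": poly.wkt,
        }
        row.update({f"density_{ph}": d for ph, d in zip(TLS_FEATURES, dens)})
        rows.append(row)
    cols = (
        ["tls_id", "patient_id", "area_mm2"]
        + [f"density_{ph}" for ph in TLS_FEATURES]
        + ["depth_um", "depth_class", "maturation", "polygon_wkt"]
    )
    return pd.DataFrame(rows, columns=cols)


def maturation_fractions(records: pd.DataFrame) -> pd.DataFrame:
    """Per-patient (× depth class) fractions of TLS maturation stages.

    Only staged TLS contribute; a patient with no staged TLS in a depth
    class is excluded (logged).
    """
    staged = records[records["maturation"].isin(MATURATION_STAGES)]
    dropped = set(records["patient_id"]) - set(staged["patient_id"])
    for pid in sorted(dropped):
        log.info("patient %s excluded from maturation fractions: no staged TLS",
                 pid)
    rows = []
    for (pid, depth_class), grp in staged.groupby(
        ["patient_id", "depth_class"], sort=True
    ):
        total = len(grp)
        fr = {
            stage: (grp["maturation"] == stage).sum() / total
            for stage in MATURATION_STAGES
        }
        rows.append(
            {
                "patient_id": pid,
                "depth_class": depth_class,
                "n_tls": total,
                **{f"frac_{s}": fr[s] for s in MATURATION_STAGES},
            }
        )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "depth_class", "n_tls"]
        + [f"frac_{s}" for s in MATURATION_STAGES],
    )
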