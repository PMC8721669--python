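"""Compartment densities, tile heterogeneity, T-cell fractions and
inflamed/excluded/desert immune-phenotype calling.

Densities are phenotype counts per compartment divided by compartment area
(cells/mm²). A tumor is called *inflamed* when cytotoxic CD8 T cells reach
the tumor-parenchyma threshold, *excluded* when they reach the stroma (or
margin) threshold while failing the parenchyma one, and *desert* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .core import RegionSet
from .errors import ConfigError, InputError, QuantificationError, StateError
from .geometry import TileGrid, area_mm2, points_in_region
from .phenotyping import PHENOTYPES, T_SUBSETS

#: Compartments quantified for every slide.
COMPARTMENTS = ("tumor_parenchyma", "stroma", "central_tumor", "margin_band")


def quantify_compartments(
    cells: pd.DataFrame, regions: RegionSet
) -> pd.DataFrame:
    """Per-compartment, per-phenotype counts, areas and densities.

    Returns a long-format DataFrame (compartment, phenotype, count, area_mm2,
    density, undefined). ``central_tumor`` counts the parenchyma∪stroma
    union; a zero-area compartment is flagged undefined rather than divided.
    """
    if "phenotype" not in cells.columns:
        raise StateError("phenotypes not assigned")
    x = cells["x_um"].to_numpy(float)
    y = cells["y_um"].to_numpy(float)
    rows = []
    for comp in COMPARTMENTS:
        region = regions.first(comp)
        if region is None:
            if comp == "central_tumor":
                # fall back to parenchyma ∪ stroma
                par, st = regions.first("tumor_parenchyma"), regions.first("stroma")
                if par is None or st is None:
                    raise QuantificationError("missing compartment central_tumor")
                geom = par.geometry.union(st.geometry)
            else:
                raise QuantificationError(f"missing compartment {comp}")
        else:
            geom = region.geometry
        area = area_mm2(geom)
        inside = points_in_region(x, y, geom)
        labels = cells.loc[inside, "phenotype"]
        counts = labels.value_counts()
        for ph in PHENOTYPES:
            c = int(counts.get(ph, 0))
            undefined = area == 0
            rows.append(
                {
                    "compartment": comp,
                    "phenotype": ph,
                    "count": c,
                    "area_mm2": area,
                    "density": np.nan if undefined else c / area,
                    "undefined": undefined,
                }
            )
    return pd.DataFrame(rows)


def get_density(profile: pd.DataFrame, compartment: str, phenotype: str) -> float:
    sel = profile[
        (profile["compartment"] == compartment)
        & (profile["phenotype"] == phenotype)
    ]
    if sel.empty:
        raise QuantificationError(
            f"no density for {phenotype} in {compartment}"
        )
    return float(sel["density"].iloc[0])


def tile_heterogeneity(
    cells: pd.DataFrame, tiles: TileGrid
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tile densities plus a dispersion summary (median, IQR).

    Returns (tile_table, summary): one density row per tile × phenotype and,
    per phenotype, the median and interquartile range across tiles.
    """
    if len(tiles) == 0:
        raise InputError("no tiles")
    if "phenotype" not in cells.columns:
        raise StateError("phenotypes not assigned")
    x = cells["x_um"].to_numpy(float)
    y = cells["y_um"].to_numpy(float)
    tile_area = tiles.edge_um**2 / 1e6
    rows = []
    for i, tile in enumerate(tiles.tiles):
        inside = points_in_region(x, y, tile)
        counts = cells.loc[inside, "phenotype"].value_counts()
        for ph in PHENOTYPES:
            rows.append(
                {
                    "tile": i,
                    "phenotype": ph,
                    "count": int(counts.get(ph, 0)),
                    "density": counts.get(ph, 0) / tile_area,
                }
            )
    table = pd.DataFrame(rows)
    summaries = []
    for ph, grp in table.groupby("phenotype", sort=False):
        d = grp["density"].to_numpy()
        q1, med, q3 = np.percentile(d, [25, 50, 75])
        summaries.append(
            {"phenotype": ph, "median": med, "iqr": q3 - q1, "n_tiles": len(d)}
        )
    return table, pd.DataFrame(summaries)


def t_cell_fractions(profile: pd.DataFrame) -> pd.DataFrame:
    """Fractions of CD8/FoxP3/CD4 T cells among total T, per compartment.

    Fractions sum to 1 where total T > 0; otherwise the row is flagged
    undefined.
    """
    rows = []
    for comp, grp in profile.groupby("compartment", sort=False):
        counts = {
            ph: int(grp.loc[grp["phenotype"] == ph, "count"].iloc[0])
            for ph in T_SUBSETS
        }
        total = sum(counts.values())
        for ph in T_SUBSETS:
            rows.append(
                {
                    "compartment": comp,
                    "phenotype": ph,
                    "count": counts[ph],
                    "fraction": counts[ph] / total if total else np.nan,
                    "undefined": total == 0,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ImmunePhenotypeCall:
    """One tumor's immune-phenotype call with its evidence."""

    label: str  # inflamed | excluded | desert
    cd8_tumor: float
    cd8_stroma: float
    cd8_margin: float
    cd8_tumor_high: float
    cd8_stroma_high: float
    used_margin: bool


def classify_immune_phenotype(
    profile: pd.DataFrame, config: AnalysisConfig
) -> ImmunePhenotypeCall:
    """Call inflamed/excluded/desert from CD8 T-cell densities.

    Pure decision rule: inflamed iff parenchyma CD8 ≥ ``cd8_tumor_high``;
    else excluded iff max(stroma, margin) CD8 ≥ ``cd8_stroma_high`` (margin
    participation toggled by ``use_margin_for_excluded``); else desert.
    """
    if config.cd8_tumor_high is None or config.cd8_stroma_high is None:
        raise ConfigError("CD8 thresholds missing")
    cd8_tumor = get_density(profile, "tumor_parenchyma", "CD8_T")
    cd8_stroma = get_density(profile, "stroma", "CD8_T")
    cd8_margin = get_density(profile, "margin_band", "CD8_T")
    if cd8_tumor >= config.cd8_tumor_high:
        label = "inflamed"
    else:
        peri = max(cd8_stroma, cd8_margin) if config.use_margin_for_excluded \
            else cd8_stroma
        label = "excluded" if peri >= config.cd8_stroma_high else "desert"
    return ImmunePhenotypeCall(
        label=label,
        cd8_tumor=cd8_tumor,
        cd8_stroma=cd8_stroma,
        cd8_margin=cd8_margin,
        cd8_tumor_high=config.cd8_tumor_high,
        cd8_stroma_high=config.cd8_stroma_high,
        used_margin=config.use_margin_for_excluded,
    )


def phenotype_distribution(labels: list[str] | pd.Series) -> pd.DataFrame:
    """Patient counts and integer percentages per immune-phenotype label."""
    labels = list(labels)
    if not labels:
        raise InputError("no immune-phenotype calls")
    total = len(labels)
    rows = []
    for label in ("inflamed", "excluded", "desert"):
        n = labels.count(label)
        rows.append(
            {"label": label, "n": n, "pct": int(round(100 * n / total))}
        )
    return pd.DataFrame(rows)
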