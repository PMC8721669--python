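"""Synthetic cohort generator.

Emits slides with the statistical structure the analysis assumes — plus
ground truth — so every pipeline stage has a truth surface:

* per-patient heterogeneous immune densities (lognormal across patients,
  with a shared per-patient "immune tone" correlating compartments),
* margin enrichment of immune cells relative to stroma,
* TLS as dense disc-shaped lymphocyte aggregates whose per-subset counts
  follow one of five compositional archetypes (1: FoxP3-T-low, 2: low
  overall density, 3: CD4-T-low, 4: CD8-T-low and densest overall,
  5: macrophage-low),
* depth structure (superficial TLS near the mucosa are CD4-enriched and
  early-stage-enriched) and CD21/CD23 maturation markers.

Geometry per slide: the mucosal surface is the line y = 0; tissue deepens
with y. The central tumor is a disc split into an inner parenchyma disc and
a stroma annulus; the invasive margin is an outward band. TLS discs are
placed outside tumor and margin. All randomness flows from one master seed
through a documented counter scheme (per-slide seed = SeedSequence([seed,
patient_index])), so cohorts are reproducible and slides independent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, box

from .core import CORE_MARKERS, OPTIONAL_MARKERS, Region, RegionSet
from .errors import ConfigError
from .geometry import points_in_region
from .phenotyping import TLS_FEATURES
from .tls import MATURATION_STAGES

log = logging.getLogger(__name__)

#: Archetype mean log-densities (natural log of cells/mm²) for the features
#: (B_cell, CD4_T, CD8_T, FoxP3_T, Macrophage). The five rows form a regular
#: simplex in log space (each archetype uniquely low in one subset) with a
#: mild overall-density grading 2 < 3 < 4.
ARCHETYPE_LOG_MEANS = np.array(
    [
        [9.3657, 5.9657, 5.7657, 2.3373, 6.0657],  # 1: FoxP3 T-cell low
        [6.4873, 5.9157, 5.7157, 5.1157, 6.0157],  # 2: low overall density
        [9.3657, 3.1373, 5.7657, 5.1657, 6.0657],  # 3: CD4 T-cell low
        [9.4157, 6.0157, 2.9873, 5.2157, 6.1157],  # 4: CD8 T-cell low, densest
        [9.3657, 5.9657, 5.7657, 5.1657, 3.2373],  # 5: macrophage low
    ]
)
ARCHETYPE_NAMES = (
    "FoxP3 T-cell low",
    "low overall density",
    "CD4 T-cell low",
    "CD8 T-cell low",
    "macrophage low",
)
#: Observed TLS counts per composition cluster in the untreated reference
#: cohort; the generator mixes archetypes in these proportions.
ARCHETYPE_COUNTS = (19, 165, 203, 341, 26)
ARCHETYPE_WEIGHTS = np.array(ARCHETYPE_COUNTS) / float(sum(ARCHETYPE_COUNTS))


def default_archetypes() -> pd.DataFrame:
    """The five TLS composition archetypes (mean log densities + weights)."""
    df = pd.DataFrame(
        ARCHETYPE_LOG_MEANS, columns=[f"log_{ph}" for ph in TLS_FEATURES]
    )
    df.insert(0, "archetype", np.arange(1, 6))
    df.insert(1, "name", ARCHETYPE_NAMES)
    df["weight"] = ARCHETYPE_WEIGHTS
    return df


# per-compartment (median cells/mm², log-sd) for each phenotype
_DENSITY = {
    "tumor_parenchyma": {
        "B_cell": (15.0, 1.0),
        "CD4_T": (60.0, 0.8),
        "CD8_T": (35.0, 1.0),
        "FoxP3_T": (30.0, 0.9),
        "Macrophage": (100.0, 0.7),
        "Tumor_cell": (800.0, 0.3),
        "Other": (150.0, 0.5),
    },
    "stroma": {
        "B_cell": (40.0, 1.0),
        "CD4_T": (150.0, 0.8),
        "CD8_T": (55.0, 1.0),
        "FoxP3_T": (40.0, 0.9),
        "Macrophage": (150.0, 0.7),
        "Tumor_cell": (0.0, 0.0),
        "Other": (300.0, 0.5),
    },
    "background": {
        "B_cell": (5.0, 0.8),
        "CD4_T": (15.0, 0.8),
        "CD8_T": (10.0, 0.8),
        "FoxP3_T": (5.0, 0.8),
        "Macrophage": (30.0, 0.6),
        "Tumor_cell": (0.0, 0.0),
        "Other": (80.0, 0.5),
    },
}

_MARKER_OF = {
    "B_cell": {"CD20": 1},
    "CD8_T": {"CD3": 1, "CD8": 1},
    "FoxP3_T": {"CD3": 1, "FoxP3": 1},
    "CD4_T": {"CD3": 1},
    "Macrophage": {"CD68": 1},
    "Tumor_cell": {"PanCK": 1},
    "Other": {},
}


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort."""

    n_patients: int = 32
    cohort: str = "untreated"
    outcome_probs: dict = field(
        default_factory=lambda: {"recurrence": 19 / 31, "no_recurrence": 12 / 31}
    )
    # slide geometry (µm)
    slide_width_um: float = 12_000.0
    slide_depth_um: float = 9_000.0
    tumor_radius_um: float = 3_000.0
    tumor_center_depth_um: float = 5_000.0
    stroma_fraction: float = 0.45
    margin_width_um: float = 250.0
    # compartment densities
    density_log: dict = field(default_factory=lambda: _DENSITY)
    patient_tone_sd: float = 0.5  # shared immune-tone shift (log units)
    margin_enrichment_factor: float = 2.0
    margin_cd8_multiplier: float = 1.0  # margin-only CD8 scaling (this slide)
    margin_cd8_no_recurrence_multiplier: float = 1.0  # optional effect
    cd8_foxp3_coupling: float = 0.0  # optional fraction coupling
    # TLS model
    tls_rate_median: float = 16.5
    tls_rate_log_sd: float = 0.866  # lognormal-mixed Poisson -> mean ~24
    tls_radius_median_um: float = 150.0
    tls_radius_log_sd: float = 0.25
    archetype_log_means: np.ndarray = field(
        default_factory=lambda: ARCHETYPE_LOG_MEANS.copy()
    )
    archetype_weights: np.ndarray = field(
        default_factory=lambda: ARCHETYPE_WEIGHTS.copy()
    )
    archetype_log_sd: float = 0.2
    # depth model
    frac_superficial: float = 0.25
    superficial_cd4_multiplier: float = 3.0
    superficial_depth_um: float = 1_000.0
    stage_probs: dict = field(
        default_factory=lambda: {
            "superficial": {"Early": 0.6, "PFL": 0.25, "SFL": 0.15},
            "deep": {"Early": 0.3, "PFL": 0.3, "SFL": 0.4},
        }
    )
    include_maturation_panel: bool = True

    def validate(self) -> "CohortSpec":
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        w = np.asarray(self.archetype_weights, float)
        if w.shape != (5,) or not np.isclose(w.sum(), 1.0) or (w < 0).any():
            raise ConfigError("archetype weights must be 5 nonneg values summing to 1")
        if np.asarray(self.archetype_log_means).shape != (5, 5):
            raise ConfigError("archetype table must be 5 archetypes x 5 features")
        for cls, probs in self.stage_probs.items():
            if not np.isclose(sum(probs.get(s, 0) for s in MATURATION_STAGES), 1.0):
                raise ConfigError(f"stage probabilities for {cls!r} must sum to 1")
        for comp in ("tumor_parenchyma", "stroma", "background"):
            if comp not in self.density_log:
                raise ConfigError(f"density table missing compartment {comp!r}")
        if not 0 < self.stroma_fraction < 1:
            raise ConfigError("stroma_fraction must be in (0,1)")
        if self.margin_enrichment_factor < 1:
            raise ConfigError("margin_enrichment_factor must be >= 1")
        op = self.outcome_probs
        if not np.isclose(sum(op.values()), 1.0):
            raise ConfigError("outcome probabilities must sum to 1")
        return self

    def with_patients(self, n: int) -> "CohortSpec":
        return replace(self, n_patients=n)


@dataclass
class GroundTruth:
    """Truth surface for one slide."""

    cell_phenotypes: pd.Series  # indexed like the cell table
    tls: pd.DataFrame  # tls_id, archetype, depth_class, maturation, x, y, r
    compartment_areas_mm2: dict


def slide_seed(master_seed: int, patient_index: int) -> int:
    """Derived per-slide seed (documented counter scheme)."""
    ss = np.random.SeedSequence([int(master_seed), int(patient_index)])
    return int(ss.generate_state(1)[0] % 2**31)


def _scatter_in(rng, geom, count, bounds=None):
    """Uniform points inside a geometry via batched rejection sampling."""
    if count == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = bounds or geom.bounds
    out = []
    need = count
    while need > 0:
        m = max(4 * need, 256)
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        keep = points_in_region(xs, ys, geom)
        pts = np.column_stack([xs[keep], ys[keep]])[:need]
        out.append(pts)
        need -= len(pts)
    return np.concatenate(out)


def _disc_points(rng, cx, cy, r, count):
    rad = r * np.sqrt(rng.uniform(0, 1, count))
    th = rng.uniform(0, 2 * np.pi, count)
    return np.column_stack([cx + rad * np.cos(th), cy + rad * np.sin(th)])


def sample_tls_features(
    spec: CohortSpec, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw n TLS: (archetype ids 1-based, depth flags, density matrix).

    Densities are the drawn per-TLS expected values (cells/mm²) after the
    archetype dispersion and the superficial CD4 multiplier.
    """
    arch = rng.choice(5, size=n, p=np.asarray(spec.archetype_weights, float))
    logd = np.asarray(spec.archetype_log_means, float)[arch] + rng.normal(
        0.0, spec.archetype_log_sd, (n, 5)
    )
    superficial = rng.random(n) < spec.frac_superficial
    logd[superficial, 1] += np.log(spec.superficial_cd4_multiplier)
    return arch + 1, superficial, np.exp(logd)


def generate_slide(
    spec: CohortSpec, patient_id: str, seed: int
) -> tuple[pd.DataFrame, RegionSet, GroundTruth]:
    """Generate one slide: cell table, region set and ground truth.

    Deterministic given (spec, patient_id, seed). Cells follow homogeneous
    Poisson processes per compartment at patient-level lognormal densities;
    margin cells are enriched; TLS discs carry archetype-drawn compositions
    and stage-dependent CD21/CD23 positives.
    """
    spec.validate()
    rng = np.random.default_rng(seed)

    # ---- geometry
    W, D = spec.slide_width_um, spec.slide_depth_um
    slide = box(-W / 2, 0.0, W / 2, D)
    mucosa = LineString([(-W / 2, 0.0), (W / 2, 0.0)])
    center = Point(0.0, spec.tumor_center_depth_um)
    tumor = center.buffer(spec.tumor_radius_um, quad_segs=32)
    inner_r = spec.tumor_radius_um * np.sqrt(1.0 - spec.stroma_fraction)
    parenchyma = center.buffer(inner_r, quad_segs=32)
    stroma = tumor.difference(parenchyma)
    margin = tumor.buffer(spec.margin_width_um, quad_segs=64).difference(tumor)
    background = slide.difference(tumor.union(margin))

    regions = RegionSet()
    regions.add(Region("central_tumor", tumor, f"{patient_id}_central_tumor"))
    regions.add(Region("tumor_parenchyma", parenchyma, f"{patient_id}_parenchyma"))
    regions.add(Region("stroma", stroma, f"{patient_id}_stroma"))
    regions.add(Region("margin_band", margin, f"{patient_id}_margin"))
    regions.add(Region("mucosa_line", mucosa, f"{patient_id}_mucosa"))

    # ---- patient-level densities
    tone = rng.normal(0.0, spec.patient_tone_sd)
    coupling = rng.normal(0.0, 1.0)  # latent CD8-vs-FoxP3 axis
    drawn: dict[str, dict[str, float]] = {}
    for comp in ("tumor_parenchyma", "stroma", "background"):
        drawn[comp] = {}
        for ph, (median, sd) in spec.density_log[comp].items():
            if median <= 0:
                drawn[comp][ph] = 0.0
                continue
            shift = tone if ph != "Tumor_cell" else 0.0
            if spec.cd8_foxp3_coupling:
                if ph == "CD8_T":
                    shift += spec.cd8_foxp3_coupling * coupling
                elif ph == "FoxP3_T":
                    shift -= spec.cd8_foxp3_coupling * coupling
            drawn[comp][ph] = float(
                np.exp(np.log(median) + rng.normal(0.0, sd) + shift)
            )
    margin_density = {
        ph: d * spec.margin_enrichment_factor for ph, d in drawn["stroma"].items()
    }
    margin_density["CD8_T"] *= spec.margin_cd8_multiplier

    geoms = {
        "tumor_parenchyma": parenchyma,
        "stroma": stroma,
        "margin_band": margin,
        "background": background,
    }
    densities = dict(drawn)
    densities["margin_band"] = margin_density

    cells: list[dict] = []
    truth_ph: list[str] = []

    def emit(xy: np.ndarray, phenotype: str, cd21: int = 0, cd23: int = 0):
        markers = _MARKER_OF[phenotype]
        for x, y in xy:
            row = {"x_um": x, "y_um": y}
            for m in CORE_MARKERS:
                row[m] = markers.get(m, 0)
            if spec.include_maturation_panel:
                row["CD21"], row["CD23"] = cd21, cd23
            cells.append(row)
            truth_ph.append(phenotype)

    for comp, geom in geoms.items():
        area = geom.area / 1e6
        for ph, dens in densities[comp].items():
            if dens <= 0:
                continue
            count = rng.poisson(dens * area)
            emit(_scatter_in(rng, geom, count), ph)

    # ---- TLS
    rate = np.exp(np.log(spec.tls_rate_median)
                  + rng.normal(0.0, spec.tls_rate_log_sd))
    n_tls = int(rng.poisson(rate))
    arch_ids, superficial, dens_mat = sample_tls_features(spec, n_tls, rng)
    radii = np.exp(np.log(spec.tls_radius_median_um)
                   + rng.normal(0.0, spec.tls_radius_log_sd, n_tls))
    blocked = tumor.union(margin).buffer(100.0)
    placed: list[tuple[float, float, float]] = []
    truth_rows = []
    kept = 0
    for i in range(n_tls):
        r = float(radii[i])
        pos = None
        for _ in range(200):
            x = rng.uniform(-W / 2 + r, W / 2 - r)
            if superficial[i]:
                y = rng.uniform(
                    min(r + 10, spec.superficial_depth_um / 2),
                    max(spec.superficial_depth_um - r, r + 20),
                )
            else:
                y = rng.uniform(spec.superficial_depth_um + 2 * r + 100, D - r)
            disc = Point(x, y).buffer(r, quad_segs=12)
            if disc.intersects(blocked):
                continue
            if any(np.hypot(x - px, y - py) < r + pr + 100
                   for px, py, pr in placed):
                continue
            pos = (x, y)
            break
        if pos is None:
            log.info("slide %s: could not place TLS %d, skipped", patient_id, i)
            continue
        x, y = pos
        placed.append((x, y, r))
        disc = Point(x, y).buffer(r, quad_segs=12)
        area = disc.area / 1e6
        depth_class = "superficial" if superficial[i] else "deep"
        planted_counts = {}
        for j, ph in enumerate(TLS_FEATURES):
            count = int(rng.poisson(dens_mat[i, j] * area))
            planted_counts[ph] = count
            emit(_disc_points(rng, x, y, r, count), ph)
        stage = "unstaged"
        if spec.include_maturation_panel:
            probs = spec.stage_probs[depth_class]
            stage = rng.choice(
                MATURATION_STAGES,
                p=[probs[s] for s in MATURATION_STAGES],
            )
            n_fdc = rng.poisson(15) + 5 if stage in ("PFL", "SFL") else \
                int(rng.binomial(2, 0.2))
            n_gc = rng.poisson(10) + 5 if stage == "SFL" else \
                int(rng.binomial(2, 0.2))
            if n_fdc:
                emit(_disc_points(rng, x, y, r * 0.6, n_fdc), "Other", cd21=1)
            if n_gc:
                emit(_disc_points(rng, x, y, r * 0.5, n_gc), "Other", cd23=1)
        tid = f"{patient_id}_tls{kept}"
        regions.add(Region("tls", disc, tid))
        truth_rows.append(
            {
                "tls_id": tid,
                "archetype": int(arch_ids[i]),
                "depth_class": depth_class,
                "maturation": stage,
                "x_um": x,
                "y_um": y,
                "radius_um": r,
                **{f"true_density_{ph}": dens_mat[i, j]
                   for j, ph in enumerate(TLS_FEATURES)},
                **{f"true_count_{ph}": planted_counts[ph]
                   for ph in TLS_FEATURES},
            }
        )
        kept += 1

    df = pd.DataFrame(cells)
    if df.empty:
        cols = ["x_um", "y_um", *CORE_MARKERS]
        if spec.include_maturation_panel:
            cols += list(OPTIONAL_MARKERS)
        df = pd.DataFrame(columns=cols)
    df.insert(0, "cell_id", [f"{patient_id}_c{i}" for i in range(len(df))])
    df["true_phenotype"] = truth_ph
    for m in CORE_MARKERS + (OPTIONAL_MARKERS if spec.include_maturation_panel
                             else ()):
        df[m] = df[m].astype(int)

    truth = GroundTruth(
        cell_phenotypes=df.set_index("cell_id")["true_phenotype"],
        tls=pd.DataFrame(truth_rows),
        compartment_areas_mm2={
            name: geom.area / 1e6 for name, geom in geoms.items()
        },
    )
    return df, regions, truth


def generate_cohort(
    spec: CohortSpec, seed: int, outdir: str | Path
) -> pd.DataFrame:
    """Generate a cohort: one slide per patient plus a manifest.

    Layout: ``<outdir>/manifest.csv`` and per patient
    ``patients/<pid>/cells.csv``, ``regions.geojson``, ``truth.json``.
    Returns the manifest table.
    """
    from .io import write_cell_table, write_manifest, write_regions

    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outcome_rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), 10**6])
    )
    labels = list(spec.outcome_probs)
    probs = [spec.outcome_probs[o] for o in labels]
    rows = []
    for i in range(spec.n_patients):
        pid = f"P{i + 1:03d}"
        pdir = outdir / "patients" / pid
        pdir.mkdir(parents=True, exist_ok=True)
        slide_spec = spec
        outcome = str(outcome_rng.choice(labels, p=probs))
        if (spec.margin_cd8_no_recurrence_multiplier != 1.0
                and outcome == "no_recurrence"):
            slide_spec = replace(
                spec,
                margin_cd8_multiplier=spec.margin_cd8_multiplier
                * spec.margin_cd8_no_recurrence_multiplier,
            )
        cells, regions, truth = generate_slide(slide_spec, pid,
                                               slide_seed(seed, i))
        write_cell_table(cells, pdir / "cells.csv")
        write_regions(regions, pdir / "regions.geojson")
        with open(pdir / "truth.json", "w") as fh:
            json.dump(
                {
                    "tls": truth.tls.to_dict(orient="records"),
                    "compartment_areas_mm2": truth.compartment_areas_mm2,
                },
                fh,
            )
        rows.append(
            {
                "patient_id": pid,
                "cohort": spec.cohort,
                "outcome": outcome,
                "cells_path": str(pdir / "cells.csv"),
                "regions_path": str(pdir / "regions.geojson"),
            }
        )
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, outdir / "manifest.csv")
    return manifest
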