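"""Cohort report assembly.

Collects the pipeline's per-patient artifacts into one JSON report of group
comparisons: compartment densities by outcome, immune-phenotype
distribution and its recurrence contingency, TLS composition by outcome and
depth, TLS cluster fractions across cohorts, and maturation-stage fractions
by depth. Every p-value is reported raw and carries an explicit
``unadjusted`` flag; no multiplicity correction is applied.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .contexture import phenotype_distribution
from .errors import DependencyError
from .phenotyping import TLS_FEATURES
from .stats import boxplot_summary, fisher_exact_two_sided, mann_whitney_two_sided
from .tls import MATURATION_STAGES

#: Artifact name -> pipeline stage that produces it.
STAGES = {
    "manifest": "simulate/ingest",
    "densities": "quantify",
    "phenotype_calls": "phenotype-call",
    "tls_records": "tls-assign",
    "maturation": "maturation",
}


def _compare(x, y, label_x: str, label_y: str) -> dict | None:
    x = np.asarray(x, float)
    x = x[~np.isnan(x)]
    y = np.asarray(y, float)
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        return None
    gc = mann_whitney_two_sided(x, y)
    return {
        "groups": [label_x, label_y],
        "n": [gc.n1, gc.n2],
        "u": gc.u,
        "p": gc.p,
        "method": f"mann_whitney_{gc.method}",
        "unadjusted": True,
        "summary": {label_x: boxplot_summary(x), label_y: boxplot_summary(y)},
    }


def build_report(
    artifacts: dict[str, str | Path | pd.DataFrame],
    config: AnalysisConfig,
    seed: int | None = None,
) -> dict:
    """Assemble the cohort report from pipeline outputs.

    ``artifacts`` maps artifact names (``manifest``, ``densities``,
    ``phenotype_calls``, ``tls_records``, ``maturation``) to file paths or
    DataFrames. A missing required artifact raises :class:`DependencyError`
    naming the stage that should have produced it.
    """
    tables: dict[str, pd.DataFrame] = {}
    for name, stage in STAGES.items():
        src = artifacts.get(name)
        if src is None:
            raise DependencyError(
                f"missing artifact {name!r}; run the {stage!r} stage first"
            )
        if isinstance(src, pd.DataFrame):
            tables[name] = src
        else:
            path = Path(src)
            if not path.exists():
                raise DependencyError(
                    f"missing artifact {name!r} at {path}; run the "
                    f"{stage!r} stage first"
                )
            tables[name] = pd.read_csv(path)

    manifest = tables["manifest"]
    if manifest.empty:
        raise DependencyError("empty cohort manifest")
    densities = tables["densities"]
    calls = tables["phenotype_calls"]
    records = tables["tls_records"]
    maturation = tables["maturation"]

    outcome = manifest.set_index("patient_id")["outcome"]
    report: dict = {
        "config_hash": config.hash(),
        "config": config.to_dict(),
        "seed": seed,
        "multiple_comparison_adjustment": "none",
        "blocks": {},
    }
    blocks = report["blocks"]

    # -- compartment density overview: margin vs central tumor, per phenotype
    comps = []
    for ph, grp in densities.groupby("phenotype", sort=False):
        margin = grp.loc[grp["compartment"] == "margin_band", "density"]
        tumor = grp.loc[grp["compartment"] == "central_tumor", "density"]
        c = _compare(margin, tumor, "margin_band", "central_tumor")
        if c:
            comps.append({"phenotype": ph, **c})
    blocks["margin_vs_tumor_density"] = comps

    # -- densities by recurrence outcome, per compartment × phenotype
    dens_o = densities.merge(
        outcome.rename("outcome"), left_on="patient_id", right_index=True
    )
    comps = []
    for (comp, ph), grp in dens_o.groupby(["compartment", "phenotype"],
                                          sort=False):
        rec = grp.loc[grp["outcome"] == "recurrence", "density"]
        non = grp.loc[grp["outcome"] == "no_recurrence", "density"]
        c = _compare(rec, non, "recurrence", "no_recurrence")
        if c:
            comps.append({"compartment": comp, "phenotype": ph, **c})
    blocks["density_by_outcome"] = comps

    # -- immune-phenotype distribution + per-label recurrence Fisher tests
    dist = phenotype_distribution(calls["immune_phenotype"].tolist())
    calls_o = calls.merge(
        outcome.rename("outcome"), left_on="patient_id", right_index=True
    )
    fisher = []
    for label in ("inflamed", "excluded", "desert"):
        is_label = calls_o["immune_phenotype"] == label
        is_rec = calls_o["outcome"] == "recurrence"
        table = [
            [int((is_label & is_rec).sum()), int((is_label & ~is_rec).sum())],
            [int((~is_label & is_rec).sum()), int((~is_label & ~is_rec).sum())],
        ]
        if sum(table[0]) and sum(table[1]):
            fisher.append(
                {
                    "phenotype": label,
                    "table": table,
                    "p": fisher_exact_two_sided(table),
                    "method": "fisher_exact",
                    "unadjusted": True,
                }
            )
    blocks["phenotype_distribution"] = dist.to_dict(orient="records")
    blocks["phenotype_recurrence_fisher"] = fisher

    # -- densities across immune-phenotype groups, pairwise
    dens_c = densities.merge(
        calls[["patient_id", "immune_phenotype"]], on="patient_id"
    )
    comps = []
    pairs = [("inflamed", "excluded"), ("inflamed", "desert"),
             ("excluded", "desert")]
    for (comp, ph), grp in dens_c.groupby(["compartment", "phenotype"],
                                          sort=False):
        for a, b in pairs:
            c = _compare(
                grp.loc[grp["immune_phenotype"] == a, "density"],
                grp.loc[grp["immune_phenotype"] == b, "density"], a, b,
            )
            if c:
                comps.append({"compartment": comp, "phenotype": ph, **c})
    blocks["density_by_immune_phenotype"] = comps

    # -- aggregated TLS composition by outcome and by depth class
    rec_o = records.merge(
        outcome.rename("outcome"), left_on="patient_id", right_index=True
    )
    by_outcome, by_depth = [], []
    for ph in TLS_FEATURES:
        col = f"density_{ph}"
        c = _compare(
            rec_o.loc[rec_o["outcome"] == "recurrence", col],
            rec_o.loc[rec_o["outcome"] == "no_recurrence", col],
            "recurrence", "no_recurrence",
        )
        if c:
            by_outcome.append({"phenotype": ph, **c})
        c = _compare(
            records.loc[records["depth_class"] == "superficial", col],
            records.loc[records["depth_class"] == "deep", col],
            "superficial", "deep",
        )
        if c:
            by_depth.append({"phenotype": ph, **c})
    blocks["tls_density_by_outcome"] = by_outcome
    blocks["tls_density_by_depth"] = by_depth

    # -- TLS cluster fractions (area by outcome, count across cohorts)
    area_cmp, frac_cmp = [], []
    if "cluster" in records.columns and records["cluster"].notna().any():
        from .clustering import cluster_summaries

        k = int(records["cluster"].max())
        summ = cluster_summaries(records, manifest, k)
        for c_id, grp in summ.groupby("cluster"):
            c = _compare(
                grp.loc[grp["outcome"] == "recurrence", "area_fraction"],
                grp.loc[grp["outcome"] == "no_recurrence", "area_fraction"],
                "recurrence", "no_recurrence",
            )
            if c:
                area_cmp.append({"cluster": int(c_id), **c})
            grp_cohort = [
                ("untreated", grp.loc[grp["cohort"] == "untreated",
                                      "count_fraction"]),
                ("CR", grp.loc[grp["outcome"] == "CR", "count_fraction"]),
                ("non_CR", grp.loc[grp["outcome"] == "non_CR",
                                   "count_fraction"]),
            ]
            for (la, va), (lb, vb) in [(grp_cohort[0], grp_cohort[1]),
                                       (grp_cohort[0], grp_cohort[2]),
                                       (grp_cohort[1], grp_cohort[2])]:
                c = _compare(va, vb, la, lb)
                if c:
                    frac_cmp.append({"cluster": int(c_id), **c})
    blocks["tls_cluster_area_by_outcome"] = area_cmp
    blocks["tls_cluster_fraction_by_cohort"] = frac_cmp

    # -- maturation fractions by depth class
    mat_cmp = []
    if not maturation.empty:
        for stage in MATURATION_STAGES:
            col = f"frac_{stage}"
            c = _compare(
                maturation.loc[maturation["depth_class"] == "superficial", col],
                maturation.loc[maturation["depth_class"] == "deep", col],
                "superficial", "deep",
            )
            if c:
                mat_cmp.append({"stage": stage, **c})
    blocks["maturation_by_depth"] = mat_cmp

    return report


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
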