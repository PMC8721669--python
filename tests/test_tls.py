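"""TLS detection, composition, maturation staging, depth stratification."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Point, box

from mifquant import (
    AnalysisConfig,
    assign_phenotypes,
    build_tls_records,
    classify_depth,
    detect_tls,
    generate_slide,
    maturation_fractions,
    stage_maturation,
    tls_composition,
)
from mifquant.errors import GeometryError
from conftest import small_spec


def _disc_cells(rng, cx, cy, r, n, b_fraction=0.6, start=0):
    rad = r * np.sqrt(rng.uniform(0, 1, n))
    th = rng.uniform(0, 2 * np.pi, n)
    df = pd.DataFrame(
        {
            "cell_id": [f"d{start + i}" for i in range(n)],
            "x_um": cx + rad * np.cos(th),
            "y_um": cy + rad * np.sin(th),
        }
    )
    n_b = int(round(b_fraction * n))
    df["phenotype"] = ["B_cell"] * n_b + ["CD4_T"] * (n - n_b)
    return df


class TestDetect:
    def test_single_planted_disc(self, rng, config):
        cells = _disc_cells(rng, 0, 0, 120.0, 200)
        polys = detect_tls(cells, config)
        assert len(polys) == 1
        inside = [
            polys[0].covers(Point(x, y))
            for x, y in cells[["x_um", "y_um"]].to_numpy()
        ]
        assert np.mean(inside) >= 0.95

    def test_empty_slide(self, config):
        empty = pd.DataFrame(
            columns=["cell_id", "x_um", "y_um", "phenotype"]
        )
        assert detect_tls(empty, config) == []

    def test_two_discs_merge_when_link_radius_spans_gap(self, rng):
        # edge-to-edge gap of 300 µm between two r=100 µm discs: separate at
        # the default link radius, single-linkage merges once the link radius
        # exceeds the nearest cross-disc point distance (≈ the gap)
        r, gap = 100.0, 300.0
        cells = pd.concat(
            [
                _disc_cells(rng, 0, 0, r, 150),
                _disc_cells(rng, 2 * r + gap, 0, r, 150, start=150),
            ],
            ignore_index=True,
        )
        assert len(detect_tls(cells, AnalysisConfig())) == 2
        merged = detect_tls(
            cells, AnalysisConfig(link_radius_um=gap + 30)
        )
        assert len(merged) == 1

    def test_b_poor_aggregate_rejected(self, rng, config):
        cells = _disc_cells(rng, 0, 0, 120.0, 200, b_fraction=0.1)
        assert detect_tls(cells, config) == []

    def test_recall_precision_on_planted_cohort(self, config):
        """Detection recovers ≥90% of planted aggregates that meet the
        detector's own operating definition (enough lymphocytes, B-rich),
        with ≥90% precision against the planted set."""
        spec = small_spec(tls_rate_median=10.0)
        tp = fn = fp = 0
        for i in range(4):
            cells, regions, truth = generate_slide(spec, f"P{i}", seed=500 + i)
            labeled, _ = assign_phenotypes(cells)
            mask = regions.first("central_tumor").geometry.union(
                regions.first("margin_band").geometry
            )
            detected = detect_tls(labeled, config, exclude=mask)
            lymph_cols = [f"true_count_{p}" for p in
                          ("B_cell", "CD4_T", "CD8_T", "FoxP3_T")]
            planted = truth.tls.copy()
            planted["lymph"] = planted[lymph_cols].sum(axis=1)
            planted["b_frac"] = planted["true_count_B_cell"] / planted["lymph"]
            eligible = planted[
                (planted["lymph"] >= config.min_lymphocytes)
                & (planted["b_frac"] >= config.min_b_fraction)
            ]
            discs = [
                Point(x, y).buffer(r)
                for x, y, r in zip(eligible["x_um"], eligible["y_um"],
                                   eligible["radius_um"])
            ]
            hit = [any(p.intersects(d) for p in detected) for d in discs]
            tp += sum(hit)
            fn += len(hit) - sum(hit)
            all_discs = [
                Point(x, y).buffer(r)
                for x, y, r in zip(planted["x_um"], planted["y_um"],
                                   planted["radius_um"])
            ]
            fp += sum(
                not any(p.intersects(d) for d in all_discs) for p in detected
            )
        assert tp / (tp + fn) >= 0.9
        assert tp / max(tp + fp, 1) >= 0.9


class TestComposition:
    def test_known_density(self, rng):
        # 50 B cells in a square TLS of 0.05 mm² -> 1000 cells/mm²
        tls = box(0, 0, 250, 200)  # 0.05 mm²
        cells = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(50)],
                "x_um": rng.uniform(1, 249, 50),
                "y_um": rng.uniform(1, 199, 50),
                "phenotype": "B_cell",
            }
        )
        dens, area = tls_composition(cells, tls)
        assert area == pytest.approx(0.05)
        assert dens[0] == pytest.approx(1000.0)
        assert dens[4] == 0.0  # no macrophages -> raw zero, no pseudo-count

    def test_zero_area_raises(self):
        degenerate = box(0, 0, 0, 0)
        cells = pd.DataFrame(
            {"cell_id": ["a"], "x_um": [0.0], "y_um": [0.0],
             "phenotype": ["B_cell"]}
        )
        with pytest.raises(GeometryError):
            tls_composition(cells, degenerate)

    def test_matches_brute_force(self, slide):
        cells, regions, _ = slide
        from mifquant.geometry import points_in_region
        from mifquant.phenotyping import TLS_FEATURES

        for region in regions.by_label("tls")[:5]:
            dens, area = tls_composition(cells, region.geometry)
            inside = points_in_region(
                cells["x_um"].to_numpy(), cells["y_um"].to_numpy(),
                region.geometry,
            )
            brute = cells.loc[inside, "phenotype"].value_counts()
            for j, ph in enumerate(TLS_FEATURES):
                assert dens[j] == pytest.approx(brute.get(ph, 0) / area)


class TestMaturation:
    @staticmethod
    def _tls_cells(n_cd21, n_cd23):
        n = 40 + n_cd21 + n_cd23
        df = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(n)],
                "x_um": np.linspace(-50, 50, n),
                "y_um": 0.0,
                "phenotype": "B_cell",
                "CD21": [1] * n_cd21 + [0] * (n - n_cd21),
                "CD23": [0] * (n - n_cd23) + [1] * n_cd23,
            }
        )
        return df

    @pytest.mark.parametrize(
        "n_cd21, n_cd23, expected",
        [
            (0, 0, "Early"),
            (8, 0, "PFL"),
            (8, 8, "SFL"),
            (0, 8, "SFL"),  # GC without FDC: anomalous, staged SFL
        ],
    )
    def test_truth_table(self, n_cd21, n_cd23, expected):
        tls = box(-100, -100, 100, 100)
        assert stage_maturation(self._tls_cells(n_cd21, n_cd23), tls) == \
            expected

    def test_below_threshold_counts_ignored(self):
        tls = box(-100, -100, 100, 100)
        assert stage_maturation(self._tls_cells(4, 4), tls) == "Early"

    def test_unstaged_without_panel(self):
        tls = box(-100, -100, 100, 100)
        cells = self._tls_cells(8, 8).drop(columns=["CD21", "CD23"])
        assert stage_maturation(cells, tls) == "unstaged"


class TestDepth:
    mucosa = LineString([(-5000, 0), (5000, 0)])

    @pytest.mark.parametrize(
        "depth, expected",
        [(200.0, "superficial"), (1000.0, "superficial"), (5000.0, "deep")],
    )
    def test_threshold(self, depth, expected):
        tls = Point(0, depth).buffer(50)
        cls, d = classify_depth(tls, self.mucosa, 1000.0)
        assert cls == expected
        assert d == pytest.approx(depth, abs=1.0)

    def test_missing_mucosa_unstaged(self):
        cls, d = classify_depth(Point(0, 100).buffer(50), None, 1000.0)
        assert cls == "unstaged" and np.isnan(d)


class TestMaturationFractions:
    def _records(self, rows):
        return pd.DataFrame(
            rows, columns=["patient_id", "depth_class", "maturation"]
        )

    def test_simple_fractions(self):
        rec = self._records(
            [("p1", "deep", "Early"), ("p1", "deep", "Early"),
             ("p1", "deep", "SFL")]
        )
        out = maturation_fractions(rec)
        row = out.iloc[0]
        assert (row["frac_Early"], row["frac_PFL"], row["frac_SFL"]) == \
            (2 / 3, 0.0, 1 / 3)

    def test_all_sfl(self):
        rec = self._records([("p1", "deep", "SFL")] * 4)
        assert maturation_fractions(rec).iloc[0]["frac_SFL"] == 1.0

    def test_random_stage_vectors_brute_force(self, rng):
        stages = np.array(["Early", "PFL", "SFL"])
        rows = []
        for p in range(6):
            for _ in range(rng.integers(1, 15)):
                rows.append(
                    (f"p{p}", rng.choice(["superficial", "deep"]),
                     rng.choice(stages))
                )
        rec = self._records(rows)
        out = maturation_fractions(rec)
        for _, r in out.iterrows():
            grp = rec[(rec["patient_id"] == r["patient_id"])
                      & (rec["depth_class"] == r["depth_class"])]
            for s in stages:
                assert r[f"frac_{s}"] == pytest.approx(
                    (grp["maturation"] == s).mean()
                )
            assert r["frac_Early"] + r["frac_PFL"] + r["frac_SFL"] == \
                pytest.approx(1.0)

    def test_unstaged_patients_excluded(self):
        rec = self._records(
            [("p1", "deep", "unstaged"), ("p2", "deep", "PFL")]
        )
        out = maturation_fractions(rec)
        assert list(out["patient_id"]) == ["p2"]


class TestDepthEnrichment:
    def test_superficial_early_enrichment_sign(self):
        """Generator's depth model yields a higher Early fraction in
        superficial than deep TLS (cohort-level expectation)."""
        spec = small_spec(tls_rate_median=12.0)
        frames = []
        cfg = AnalysisConfig()
        for i in range(6):
            cells, regions, _ = generate_slide(spec, f"P{i}", seed=900 + i)
            labeled, _ = assign_phenotypes(cells)
            frames.append(
                build_tls_records(labeled, regions, cfg, patient_id=f"P{i}")
            )
        rec = pd.concat(frames, ignore_index=True)
        sup = rec[rec["depth_class"] == "superficial"]
        deep = rec[rec["depth_class"] == "deep"]
        assert (sup["maturation"] == "Early").mean() > \
            (deep["maturation"] == "Early").mean()
        # superficial CD4 enrichment, same records
        assert sup["density_CD4_T"].median() > deep["density_CD4_T"].median()
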