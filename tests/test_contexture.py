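"""Compartment quantification, tile heterogeneity, T fractions and the
immune-phenotype decision rule."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from mifquant import (
    AnalysisConfig,
    classify_immune_phenotype,
    phenotype_distribution,
    quantify_compartments,
    sample_tiles,
    t_cell_fractions,
    tile_heterogeneity,
)
from mifquant.contexture import get_density
from mifquant.core import Region, RegionSet
from mifquant.errors import InputError, QuantificationError
from mifquant.geometry import points_in_region
from mifquant.phenotyping import PHENOTYPES


def _cells(xy, phenotype):
    df = pd.DataFrame(xy, columns=["x_um", "y_um"])
    df.insert(0, "cell_id", [f"c{i}" for i in range(len(df))])
    df["phenotype"] = phenotype
    return df


def _profile(cd8_tumor, cd8_stroma, cd8_margin=0.0):
    rows = []
    for comp, d in [
        ("tumor_parenchyma", cd8_tumor),
        ("stroma", cd8_stroma),
        ("central_tumor", cd8_tumor + cd8_stroma),
        ("margin_band", cd8_margin),
    ]:
        for ph in PHENOTYPES:
            rows.append(
                {
                    "compartment": comp,
                    "phenotype": ph,
                    "count": 0,
                    "area_mm2": 1.0,
                    "density": d if ph == "CD8_T" else 0.0,
                    "undefined": False,
                }
            )
    return pd.DataFrame(rows)


class TestQuantify:
    def test_simple_density(self):
        # 100 CD8 T cells in a 2 mm² parenchyma -> 50 cells/mm²
        regions = RegionSet()
        par = box(0, 0, 2000, 1000)
        regions.add(Region("central_tumor", box(0, 0, 2000, 2000), "ct"))
        regions.add(Region("tumor_parenchyma", par, "p"))
        regions.add(Region("stroma", box(0, 1000, 2000, 2000), "s"))
        regions.add(Region("margin_band", box(0, -500, 2000, 0), "m"))
        rng = np.random.default_rng(0)
        xy = np.column_stack(
            [rng.uniform(1, 1999, 100), rng.uniform(1, 999, 100)]
        )
        profile = quantify_compartments(_cells(xy, "CD8_T"), regions)
        assert get_density(profile, "tumor_parenchyma", "CD8_T") == \
            pytest.approx(50.0)
        assert get_density(profile, "stroma", "CD8_T") == 0.0

    def test_missing_compartment_named(self, slide):
        cells, _, _ = slide
        with pytest.raises(QuantificationError, match="tumor_parenchyma"):
            quantify_compartments(cells, RegionSet())

    def test_matches_brute_force_membership(self, slide):
        """Counts equal a per-cell point-in-polygon tally on a full slide."""
        cells, regions, _ = slide
        profile = quantify_compartments(cells, regions)
        for comp in ("tumor_parenchyma", "stroma", "margin_band"):
            geom = regions.first(comp).geometry
            inside = points_in_region(
                cells["x_um"].to_numpy(), cells["y_um"].to_numpy(), geom
            )
            brute = cells.loc[inside, "phenotype"].value_counts()
            for ph in PHENOTYPES:
                got = profile.loc[
                    (profile["compartment"] == comp)
                    & (profile["phenotype"] == ph),
                    "count",
                ].iloc[0]
                assert got == brute.get(ph, 0)

    def test_density_scale_equivariance(self, slide):
        """Duplicating every cell doubles densities, leaves fractions
        unchanged."""
        cells, regions, _ = slide
        doubled = pd.concat([cells, cells.assign(
            cell_id=cells["cell_id"] + "_dup")], ignore_index=True)
        p1 = quantify_compartments(cells, regions)
        p2 = quantify_compartments(doubled, regions)
        np.testing.assert_allclose(
            p2["density"].to_numpy(), 2 * p1["density"].to_numpy()
        )
        f1, f2 = t_cell_fractions(p1), t_cell_fractions(p2)
        np.testing.assert_allclose(
            f1["fraction"].astype(float), f2["fraction"].astype(float),
            equal_nan=True,
        )


class TestTiles:
    def test_uniform_slide_tile_mean_near_global(self, rng):
        region = box(0, 0, 8000, 8000)
        density = 400.0  # cells/mm²
        n = rng.poisson(density * 64.0)
        xy = np.column_stack(
            [rng.uniform(0, 8000, n), rng.uniform(0, 8000, n)]
        )
        cells = _cells(xy, "B_cell")
        tiles = sample_tiles(region, 30, 500.0, seed=1)
        table, _ = tile_heterogeneity(cells, tiles)
        b = table[table["phenotype"] == "B_cell"]["density"]
        # mean tile density within 3 SE of the global intensity
        se = np.sqrt(density / (30 * 0.25))
        assert abs(b.mean() - density) < 3 * se

    def test_clustered_slide_more_dispersed(self):
        """IQR/median across tiles is larger for a clustered pattern than a
        uniform one at matched global density (50-replicate medians)."""
        region = box(0, 0, 6000, 6000)
        ratios = {"uniform": [], "clustered": []}
        for rep in range(50):
            r = np.random.default_rng(rep)
            tiles = sample_tiles(region, 25, 500.0, seed=rep)
            n = 2000
            xy_u = np.column_stack(
                [r.uniform(0, 6000, n), r.uniform(0, 6000, n)]
            )
            centers = r.uniform(500, 5500, (8, 2))
            idx = r.integers(0, 8, n)
            xy_c = centers[idx] + r.normal(0, 150, (n, 2))
            for name, xy in (("uniform", xy_u), ("clustered", xy_c)):
                table, summ = tile_heterogeneity(_cells(xy, "B_cell"), tiles)
                row = summ[summ["phenotype"] == "B_cell"].iloc[0]
                med = max(row["median"], 1e-9)
                ratios[name].append(row["iqr"] / med)
        assert np.median(ratios["clustered"]) > np.median(ratios["uniform"])

    def test_single_tile_iqr_zero(self):
        tiles = sample_tiles(box(0, 0, 600, 600), 1, 500.0, seed=0)
        _, summ = tile_heterogeneity(
            _cells(np.array([[100.0, 100.0]]), "B_cell"), tiles
        )
        assert (summ["iqr"] == 0).all()

    def test_zero_tiles_raises(self):
        from mifquant.geometry import TileGrid

        with pytest.raises(InputError):
            tile_heterogeneity(
                _cells(np.array([[0.0, 0.0]]), "B_cell"),
                TileGrid(edge_um=500.0, seed=0, tiles=[]),
            )


class TestFractions:
    def test_simple_fractions(self):
        profile = pd.DataFrame(
            [
                {"compartment": "stroma", "phenotype": "CD8_T", "count": 10},
                {"compartment": "stroma", "phenotype": "FoxP3_T", "count": 5},
                {"compartment": "stroma", "phenotype": "CD4_T", "count": 5},
            ]
        )
        out = t_cell_fractions(profile)
        assert dict(zip(out["phenotype"], out["fraction"])) == {
            "CD8_T": 0.5, "FoxP3_T": 0.25, "CD4_T": 0.25,
        }

    def test_zero_t_flagged_undefined(self):
        profile = pd.DataFrame(
            [
                {"compartment": "stroma", "phenotype": ph, "count": 0}
                for ph in ("CD8_T", "FoxP3_T", "CD4_T")
            ]
        )
        out = t_cell_fractions(profile)
        assert out["undefined"].all()
        assert out["fraction"].isna().all()

    def test_cd8_foxp3_coupling_sign(self):
        """With generator coupling, low-CD8-fraction slides carry a higher
        FoxP3 fraction (directional check)."""
        from conftest import small_spec
        from mifquant import assign_phenotypes, generate_slide

        spec = small_spec(cd8_foxp3_coupling=1.2, tls_rate_median=0.5)
        rows = []
        for i in range(12):
            cells, regions, _ = generate_slide(spec, f"P{i}", seed=100 + i)
            labeled, _ = assign_phenotypes(cells)
            prof = quantify_compartments(labeled, regions)
            fr = t_cell_fractions(prof)
            sel = fr[fr["compartment"] == "central_tumor"].set_index(
                "phenotype")["fraction"]
            rows.append((sel["CD8_T"], sel["FoxP3_T"]))
        rows.sort()
        low = np.mean([f for _, f in rows[:4]])
        high = np.mean([f for _, f in rows[-4:]])
        assert low > high


class TestPhenotypeCall:
    @pytest.mark.parametrize(
        "cd8_tumor, cd8_stroma, cd8_margin, expected",
        [
            (100.0, 20.0, 0.0, "inflamed"),
            (5.0, 200.0, 0.0, "excluded"),
            (0.0, 0.0, 0.0, "desert"),
            (50.0, 0.0, 0.0, "inflamed"),     # threshold closed
            (49.9, 50.0, 0.0, "excluded"),
            (10.0, 10.0, 80.0, "excluded"),   # margin can rescue excluded
            (10.0, 10.0, 10.0, "desert"),
        ],
    )
    def test_decision_rule(self, cd8_tumor, cd8_stroma, cd8_margin, expected):
        call = classify_immune_phenotype(
            _profile(cd8_tumor, cd8_stroma, cd8_margin), AnalysisConfig()
        )
        assert call.label == expected

    def test_margin_toggle(self):
        cfg = AnalysisConfig(use_margin_for_excluded=False)
        call = classify_immune_phenotype(_profile(10.0, 10.0, 80.0), cfg)
        assert call.label == "desert"

    def test_monotone_in_tumor_cd8(self, rng):
        """Raising parenchyma CD8 never moves a call away from inflamed."""
        order = {"desert": 0, "excluded": 0, "inflamed": 1}
        cfg = AnalysisConfig()
        for _ in range(50):
            s, m = rng.uniform(0, 120, 2)
            labels = [
                classify_immune_phenotype(_profile(t, s, m), cfg).label
                for t in np.linspace(0, 150, 16)
            ]
            ranks = [order[la] for la in labels]
            assert ranks == sorted(ranks)


class TestDistribution:
    def test_cohort_percentages(self):
        labels = ["inflamed"] * 13 + ["excluded"] * 10 + ["desert"] * 8
        out = phenotype_distribution(labels)
        assert dict(zip(out["label"], out["pct"])) == {
            "inflamed": 42, "excluded": 32, "desert": 26,
        }

    def test_single_patient(self):
        out = phenotype_distribution(["desert"])
        assert out.set_index("label").loc["desert", "pct"] == 100

    def test_random_counts_match_arithmetic(self, rng):
        for _ in range(25):
            n = rng.integers(1, 60, 3)
            labels = (
                ["inflamed"] * n[0] + ["excluded"] * n[1] + ["desert"] * n[2]
            )
            out = phenotype_distribution(labels).set_index("label")
            total = n.sum()
            for label, c in zip(("inflamed", "excluded", "desert"), n):
                assert out.loc[label, "n"] == c
                assert out.loc[label, "pct"] == int(round(100 * c / total))
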