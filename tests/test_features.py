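"""Feature extraction: regions, area-Voronoi, Delaunay, summaries, scaling."""

import numpy as np
import pandas as pd
import pytest

import histodensity as hd
from conftest import random_label_map
from _oracles import (brute_force_delaunay_degrees, brute_force_eccentricity,
                      brute_force_voronoi, sort_based_summary)


def make_map(labels, mpp=0.5):
    return hd.TissueMap(labels=np.asarray(labels, dtype=np.uint8),
                        microns_per_pixel=mpp, slide_id="t")


class TestExtractRegions:
    def test_no_epithelium_gives_empty_list(self):
        tmap = make_map(np.full((8, 8), 2))
        regions, _ = hd.extract_regions(tmap)
        assert len(regions) == 0

    def test_square_region_area(self):
        labels = np.full((10, 10), 2, dtype=np.uint8)
        labels[2:6, 2:6] = 1  # 16 px at 0.25 um^2/px
        regions, _ = hd.extract_regions(make_map(labels), min_region_area=0.0)
        assert len(regions) == 1
        assert regions.loc[0, "area"] == pytest.approx(4.0)

    def test_rectangle_eccentricity_matches_moment_oracle(self):
        labels = np.full((16, 16), 2, dtype=np.uint8)
        labels[3:13, 5:7] = 1  # 10 x 2 block
        regions, _ = hd.extract_regions(make_map(labels), min_region_area=0.0)
        expect = brute_force_eccentricity(labels == 1)
        assert regions.loc[0, "eccentricity"] == pytest.approx(expect, rel=1e-9)

    def test_min_area_filter(self):
        labels = np.full((16, 16), 2, dtype=np.uint8)
        labels[0, 0] = 1            # 0.25 um^2
        labels[5:9, 5:9] = 1        # 4 um^2
        regions, _ = hd.extract_regions(make_map(labels), min_region_area=1.0)
        assert len(regions) == 1

    def test_diagonal_pixels_are_one_region(self):
        # 8-connectivity joins diagonal neighbours
        labels = np.full((6, 6), 2, dtype=np.uint8)
        labels[1, 1] = labels[2, 2] = 1
        regions, _ = hd.extract_regions(make_map(labels), min_region_area=0.0)
        assert len(regions) == 1


class TestAreaVoronoi:
    def test_single_region_owns_all_tissue(self):
        labels = np.full((12, 12), 3, dtype=np.uint8)
        labels[0, :] = 0
        labels[5:7, 5:7] = 1
        tmap = make_map(labels)
        regions, rlab = hd.extract_regions(tmap, min_region_area=0.0)
        vor = hd.area_voronoi(tmap, rlab)
        assert (vor[labels > 0] == 1).all()
        assert (vor[labels == 0] == 0).all()

    def test_strip_tie_goes_to_lower_label(self):
        # 1x11 tissue strip, single-pixel regions at both ends: the middle
        # pixel is equidistant and must join region 1
        labels = np.zeros((1, 11), dtype=np.uint8)
        labels[0, :] = 2
        labels[0, 0] = 1
        labels[0, 10] = 1
        tmap = make_map(labels)
        regions, rlab = hd.extract_regions(tmap, min_region_area=0.0)
        vor = hd.area_voronoi(tmap, rlab)
        assert (vor[0, :6] == 1).all()
        assert (vor[0, 6:] == 2).all()
        assert int((vor == 1).sum()) == 6
        assert int((vor == 2).sum()) == 5

    def test_matches_brute_force_oracle_on_random_maps(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            tmap = random_label_map(rng, size=64, n_blobs=int(rng.integers(1, 7)))
            regions, rlab = hd.extract_regions(tmap, min_region_area=0.0)
            if len(regions) == 0:
                continue
            vor = hd.area_voronoi(tmap, rlab)
            oracle = brute_force_voronoi(tmap.labels, rlab)
            assert (vor == oracle).all()

    def test_partition_of_tissue(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            tmap = random_label_map(rng, size=48, n_blobs=3)
            regions, rlab = hd.extract_regions(tmap, min_region_area=0.0)
            if len(regions) == 0:
                continue
            vor = hd.area_voronoi(tmap, rlab)
            assert int((vor > 0).sum()) == int(tmap.tissue_mask().sum())

    def test_no_regions_raises(self):
        tmap = make_map(np.full((6, 6), 2))
        _, rlab = hd.extract_regions(tmap)
        with pytest.raises(hd.NoEpitheliumError):
            hd.area_voronoi(tmap, rlab)


class TestVoronoiRatios:
    def test_region_filling_its_zone(self):
        df = pd.DataFrame({"region_label": [1], "area": [7.0],
                           "voronoi_area": [7.0]})
        out = hd.voronoi_ratios(df)
        assert out.loc[0, "ratio_epi_voronoi"] == 1.0
        assert np.isnan(out.loc[0, "ratio_epi_nonepi"])

    def test_arithmetic(self):
        df = pd.DataFrame({"region_label": [1], "area": [10.0],
                           "voronoi_area": [40.0]})
        out = hd.voronoi_ratios(df)
        assert out.loc[0, "ratio_epi_voronoi"] == pytest.approx(0.25)
        assert out.loc[0, "ratio_epi_nonepi"] == pytest.approx(10.0 / 30.0)

    def test_coalescent_mode_raises_fill_ratio(self):
        from histodensity.simulate import PatientState

        cfg = hd.SimulationConfig()
        means = {}
        for mode in ("dispersed", "coalescent"):
            vals = []
            for i in range(8):
                ps = PatientState(
                    patient_id=f"R{i}", index=700 + i, fat_share=0.5,
                    epi_fraction=0.1, local_fat_share=0.5, diagnosis="x",
                    clustering_mode=mode, split="train", true_global_fgv=0.0,
                    true_localized_fgv=0.0, bmi=25.0, menopause="pre")
                vec = hd.extract_features(hd.generate_tissue_map(cfg, ps, i))
                vals.append(vec["ratio_epi_voronoi_mean"])
            means[mode] = np.mean(vals)
        assert means["coalescent"] > means["dispersed"]


class TestDelaunay:
    def test_triangle_degrees(self):
        df = pd.DataFrame({"centroid_row": [0.0, 10.0, 0.0],
                           "centroid_col": [0.0, 0.0, 10.0]})
        out = hd.delaunay_degrees(df)
        assert (out["delaunay_degree"] == 2).all()

    def test_single_region_degree_zero(self):
        df = pd.DataFrame({"centroid_row": [1.0], "centroid_col": [2.0]})
        assert hd.delaunay_degrees(df)["delaunay_degree"].tolist() == [0]

    def test_two_regions(self):
        df = pd.DataFrame({"centroid_row": [0.0, 5.0], "centroid_col": [0.0, 5.0]})
        assert hd.delaunay_degrees(df)["delaunay_degree"].tolist() == [1, 1]

    def test_collinear_chain(self):
        df = pd.DataFrame({"centroid_row": [0.0, 1.0, 2.0, 3.0],
                           "centroid_col": [0.0, 1.0, 2.0, 3.0]})
        assert sorted(hd.delaunay_degrees(df)["delaunay_degree"]) == [1, 1, 2, 2]

    def test_matches_circumcircle_oracle(self):
        rng = np.random.default_rng(23)
        pts = rng.uniform(0, 100, (10, 2))
        df = pd.DataFrame({"centroid_row": pts[:, 0], "centroid_col": pts[:, 1]})
        out = hd.delaunay_degrees(df)
        oracle = brute_force_delaunay_degrees(pts)
        assert out["delaunay_degree"].tolist() == oracle.tolist()

    def test_handshake_lemma(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 50, (15, 2))
        df = pd.DataFrame({"centroid_row": pts[:, 0], "centroid_col": pts[:, 1]})
        from scipy.spatial import Delaunay
        tri = Delaunay(pts)
        edges = set()
        for simplex in tri.simplices:
            for a in range(3):
                for b in range(a + 1, 3):
                    edges.add(tuple(sorted((simplex[a], simplex[b]))))
        degrees = hd.delaunay_degrees(df)["delaunay_degree"]
        assert degrees.sum() == 2 * len(edges)


class TestExtractFeatures:
    def test_all_fat_slide(self):
        vec = hd.extract_features(make_map(np.full((8, 8), 3)))
        assert vec["fat_amount_norm"] == 100.0
        assert vec["stroma_amount_norm"] == 0.0
        assert vec["epi_amount_norm"] == 0.0
        assert vec["n_epi_regions"] == 0
        assert vec["no_epithelium"] == 1.0

    def test_normalized_amount_arithmetic(self):
        labels = np.zeros((40, 40), dtype=np.uint8)  # 1600 px
        labels[:25, :40] = 3                          # 1000 px tissue
        labels[:5, :40] = 2                           # of which 200 px stroma
        labels[0, :50 % 40] = 2
        labels = np.zeros((40, 40), dtype=np.uint8)
        labels.flat[:1000] = 3
        labels.flat[:250] = 2
        vec = hd.extract_features(make_map(labels))
        assert vec["stroma_amount_norm"] == pytest.approx(25.0)

    def test_norms_sum_to_100(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            vec = hd.extract_features(random_label_map(rng), min_region_area=0.0)
            total = (vec["fat_amount_norm"] + vec["stroma_amount_norm"]
                     + vec["epi_amount_norm"])
            assert total == pytest.approx(100.0, abs=1e-6)

    def test_empty_slide_raises(self):
        with pytest.raises(hd.EmptySlideError):
            hd.extract_features(make_map(np.zeros((6, 6))))

    def test_golden_fixture(self, fixture_map, golden_features):
        vec = hd.extract_features(fixture_map,
                                  golden_features["min_region_area"])
        for name, expect in golden_features["features"].items():
            assert vec[name] == pytest.approx(expect, rel=1e-9, abs=1e-12), name

    def test_summary_statistics_match_sort_oracle(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(0, 50, 11)
        from histodensity.features import _summary
        got = _summary(values, "x")
        for stat in ("mean", "median", "sd", "iq", "max"):
            assert got[f"x_{stat}"] == pytest.approx(
                sort_based_summary(values, stat), rel=1e-12)

    def test_stroma_to_fat_relabel_monotonicity(self, fixture_map):
        vec0 = hd.extract_features(fixture_map)
        labels = fixture_map.labels.copy()
        swap = (labels == 2) & (np.arange(labels.size).reshape(labels.shape) % 3 == 0)
        labels[swap] = 3
        vec1 = hd.extract_features(make_map(labels))
        assert vec1["stroma_amount_norm"] < vec0["stroma_amount_norm"]
        total0 = vec0["fat_amount"] + vec0["stroma_amount"] + vec0["epi_amount"]
        total1 = vec1["fat_amount"] + vec1["stroma_amount"] + vec1["epi_amount"]
        assert total1 == pytest.approx(total0)
        for name in hd.FEATURE_NAMES:
            if name.startswith(("epi_", "voronoi", "ratio", "delaunay", "n_epi")):
                assert vec1[name] == pytest.approx(vec0[name], rel=1e-12)

    def test_scale_covariance(self, fixture_map):
        # doubling the pixel scale scales um^2 features by 4 and leaves
        # dimensionless features untouched (threshold scaled to keep the same
        # region set)
        vec1 = hd.extract_features(fixture_map, min_region_area=50.0)
        doubled = hd.TissueMap(labels=fixture_map.labels,
                               microns_per_pixel=1.0, slide_id="x2")
        vec2 = hd.extract_features(doubled, min_region_area=200.0)
        for name in hd.FEATURE_NAMES:
            if "amount" in name and "norm" not in name or \
               name.startswith(("epi_area", "voronoi_area")):
                assert vec2[name] == pytest.approx(4.0 * vec1[name], rel=1e-12)
            else:
                assert vec2[name] == pytest.approx(vec1[name], rel=1e-12)


class TestAggregation:
    def test_single_slide_identity(self, fixture_map):
        vec = hd.extract_features(fixture_map)
        agg = hd.aggregate_patient(pd.DataFrame([vec]))
        pd.testing.assert_series_equal(agg, vec, check_names=False)

    def test_two_slide_median(self):
        df = pd.DataFrame({"stroma_amount_norm": [20.0, 40.0]})
        assert hd.aggregate_patient(df)["stroma_amount_norm"] == 30.0

    def test_median_matches_sort_oracle(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.uniform(0, 10, (3, 5)),
                          columns=list("abcde"))
        agg = hd.aggregate_patient(df)
        for col in df.columns:
            assert agg[col] == pytest.approx(
                sort_based_summary(df[col], "median"))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            hd.aggregate_patient(pd.DataFrame())
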