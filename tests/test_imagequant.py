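"""Unit and property tests for ROI quantification and puncta tallies."""

import numpy as np
import pandas as pd
import pytest

from barrelkit.imagequant import (
    RoiSet,
    aggregate_per_animal,
    assign_puncta,
    contrast_index,
    measure_rois,
    normalize_to_background,
    quantify_section,
    roi_set_from_polygons,
    septa_mean,
    tally_puncta,
)
from barrelkit.synthgen import BarrelImageSpec, simulate_barrel_image
from oracles import nearest_cell_bruteforce, roi_means_pixel_loop


def _mask(shape, sl):
    m = np.zeros(shape, dtype=bool)
    m[sl] = True
    return m


class TestMeasureRois:
    def test_uniform_image(self):
        img = np.full((10, 10), 7.0)
        out = measure_rois(img, [_mask(img.shape, np.s_[2:5, 3:8])])
        assert out.loc[0, "mean"] == pytest.approx(7.0)

    def test_two_by_two_values(self):
        img = np.zeros((4, 4))
        img[1:3, 1:3] = [[1, 2], [3, 4]]
        out = measure_rois(img, [_mask(img.shape, np.s_[1:3, 1:3])])
        assert out.loc[0, "mean"] == pytest.approx(2.5)
        assert out.loc[0, "sum"] == pytest.approx(10.0)
        assert out.loc[0, "area"] == 4

    def test_pixel_loop_oracle_on_random_rois(self):
        rng = np.random.default_rng(12)
        img = rng.normal(size=(64, 64))
        masks = [rng.random((64, 64)) < 0.2 for _ in range(10)]
        out = measure_rois(img, masks)
        for i, (mean, total, area) in enumerate(roi_means_pixel_loop(img, masks)):
            assert out.loc[i, "mean"] == pytest.approx(mean, abs=1e-12)
            assert out.loc[i, "sum"] == pytest.approx(total, abs=1e-12)
            assert out.loc[i, "area"] == area

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            measure_rois(np.ones((5, 5)), [np.zeros((5, 5), dtype=bool)])


class TestSeptaAndContrast:
    def test_worked_example(self):
        assert septa_mean(100.0, 50, [60.0], [20]) == pytest.approx(40 / 30)

    def test_no_barrels_equals_enclosing_mean(self):
        assert septa_mean(100.0, 50, [], []) == pytest.approx(2.0)

    def test_tiling_barrels_rejected(self):
        with pytest.raises(ValueError, match="zero septa area"):
            septa_mean(100.0, 50, [100.0], [50])

    def test_mask_complement_oracle(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(1, 10, size=(40, 40))
        enclosing = _mask(img.shape, np.s_[5:35, 5:35])
        barrels = [
            _mask(img.shape, np.s_[8:14, 8:14]),
            _mask(img.shape, np.s_[20:30, 20:30]),
        ]
        septa_px = enclosing & ~(barrels[0] | barrels[1])
        enc = measure_rois(img, [enclosing]).iloc[0]
        bar = measure_rois(img, barrels)
        got = septa_mean(enc["sum"], enc["area"], bar["sum"], bar["area"])
        assert got == pytest.approx(img[septa_px].mean(), abs=1e-12)

    @pytest.mark.parametrize("b, s, expect", [(3, 1, 0.5), (2, 2, 0.0), (2, 0, 1.0)])
    def test_contrast_examples(self, b, s, expect):
        assert contrast_index(b, s) == pytest.approx(expect)

    def test_contrast_undefined_at_zero_sum(self):
        with pytest.raises(ValueError, match="undefined contrast"):
            contrast_index(0.0, 0.0)

    def test_normalization_examples(self):
        assert normalize_to_background(4.0, [1.0, 2.0, 3.0]) == pytest.approx(2.0)
        assert normalize_to_background(1.7, [1.0]) == pytest.approx(1.7)
        with pytest.raises(ValueError):
            normalize_to_background(1.0, [])
        with pytest.raises(ValueError):
            normalize_to_background(1.0, [0.0])


class TestSectionInvariants:
    def _roiset_and_image(self, seed=0):
        spec = BarrelImageSpec(
            grid_rows=3, grid_cols=3, intensity_barrel=180.0, intensity_septa=90.0,
            intensity_background=12.0, noise_sd=5.0, seed=seed,
        )
        return simulate_barrel_image(spec)

    def test_intensity_conservation(self):
        img, truth = self._roiset_and_image()
        rs = truth.roi_set
        enc = measure_rois(img, [rs.enclosing_roi]).iloc[0]
        bar = measure_rois(img, rs.barrel_rois)
        septa_px = rs.enclosing_roi.copy()
        for m in rs.barrel_rois:
            septa_px &= ~m
        assert enc["sum"] == pytest.approx(img[septa_px].sum() + bar["sum"].sum(), rel=1e-12)

    def test_scale_invariance_of_contrast_and_norms(self):
        img, truth = self._roiset_and_image(3)
        m1 = quantify_section(img, truth.roi_set)
        m2 = quantify_section(3.7 * img, truth.roi_set)
        assert m1.contrast == pytest.approx(m2.contrast, rel=1e-12)
        assert m1.barrel_norm == pytest.approx(m2.barrel_norm, rel=1e-12)
        assert m1.septa_norm == pytest.approx(m2.septa_norm, rel=1e-12)

    def test_background_normalized_intensities_recover_truth(self):
        spec = BarrelImageSpec(
            intensity_barrel=200.0, intensity_septa=100.0, intensity_background=20.0,
            noise_sd=2.0, blur_sigma_px=0.0, seed=9,
        )
        img, truth = simulate_barrel_image(spec)
        m = quantify_section(img, truth.roi_set)
        assert m.barrel_norm == pytest.approx(200 / 20, rel=0.02)
        assert m.septa_norm == pytest.approx(100 / 20, rel=0.02)

    def test_roiset_validation(self):
        shape = (20, 20)
        enclosing = _mask(shape, np.s_[5:15, 5:15])
        inside = _mask(shape, np.s_[6:9, 6:9])
        outside = _mask(shape, np.s_[0:3, 0:3])
        with pytest.raises(ValueError, match="outside the enclosing"):
            RoiSet(barrel_rois=[outside], enclosing_roi=enclosing)
        with pytest.raises(ValueError, match="overlap"):
            RoiSet(barrel_rois=[inside, inside], enclosing_roi=enclosing)
        with pytest.raises(ValueError, match="background ROI overlaps"):
            RoiSet(barrel_rois=[inside], enclosing_roi=enclosing, background_rois=[inside])


class TestAggregate:
    def test_two_sections_average(self):
        df = pd.DataFrame(
            {"animal_id": ["a1", "a1"], "contrast": [0.2, 0.4]}
        )
        out = aggregate_per_animal(df)
        assert out.loc[0, "contrast"] == pytest.approx(0.3)
        assert out.loc[0, "n_sections"] == 2

    def test_single_section_warns(self):
        df = pd.DataFrame({"animal_id": ["a1"], "contrast": [0.5]})
        with pytest.warns(UserWarning, match="two sections"):
            out = aggregate_per_animal(df)
        assert out.loc[0, "contrast"] == pytest.approx(0.5)

    def test_group_by_oracle(self):
        rng = np.random.default_rng(8)
        rows = []
        for a in range(6):
            for s in range(2):
                rows.append(
                    {
                        "animal_id": f"a{a}",
                        "genotype": "Ctl" if a < 3 else "KO",
                        "contrast": rng.uniform(),
                    }
                )
        df = pd.DataFrame(rows)
        out = aggregate_per_animal(df).set_index("animal_id")
        for a in range(6):
            vals = [r["contrast"] for r in rows if r["animal_id"] == f"a{a}"]
            assert out.loc[f"a{a}", "contrast"] == pytest.approx(sum(vals) / len(vals))


class TestPuncta:
    def _cells(self, xy, ids=None):
        ids = ids if ids is not None else list(range(len(xy)))
        return pd.DataFrame(
            {"cell_id": ids, "x": [p[0] for p in xy], "y": [p[1] for p in xy],
             "layer": "L4"}
        )

    def test_punctum_at_centroid(self):
        cells = self._cells([(0, 0), (10, 10)])
        puncta = pd.DataFrame({"x": [10.0], "y": [10.0]})
        assert assign_puncta(cells, puncta)[0] == 1

    def test_equidistant_tie_goes_to_smallest_id(self):
        cells = self._cells([(0, 0), (10, 0)], ids=[7, 3])
        puncta = pd.DataFrame({"x": [5.0], "y": [0.0]})
        assert assign_puncta(cells, puncta)[0] == 3

    def test_bruteforce_oracle_500x50(self):
        rng = np.random.default_rng(31)
        xy = rng.uniform(0, 512, size=(50, 2))
        cells = self._cells([tuple(p) for p in xy])
        pxy = rng.uniform(0, 512, size=(500, 2))
        puncta = pd.DataFrame({"x": pxy[:, 0], "y": pxy[:, 1]})
        got = assign_puncta(cells, puncta)
        expected = nearest_cell_bruteforce(xy, np.arange(50), pxy)
        assert (got == expected).all()

    def test_no_cells_rejected(self):
        with pytest.raises(ValueError, match="no cells"):
            assign_puncta(self._cells([]), pd.DataFrame({"x": [1.0], "y": [1.0]}))

    def test_counts_conserved_and_zero_cells_counted(self):
        cells = self._cells([(0, 0), (100, 100)])
        puncta = pd.DataFrame({"x": [0.0, 1.0, 0.5], "y": [0.0, 0.0, 0.5]})
        assign = assign_puncta(cells, puncta)
        counts, per_image, _ = tally_puncta(cells, assign)
        assert counts.sum() == len(puncta)
        assert sorted(counts) == [0, 3]
        assert per_image["mean_puncta_per_cell"].iloc[0] == pytest.approx(1.5)

    def test_no_puncta_means_zero(self):
        cells = self._cells([(i, 0) for i in range(10)])
        counts, per_image, _ = tally_puncta(cells, np.array([]))
        assert per_image["mean_puncta_per_cell"].iloc[0] == 0.0

    def test_max_distance_cap(self):
        cells = self._cells([(0, 0)])
        puncta = pd.DataFrame({"x": [0.0, 50.0], "y": [0.0, 0.0]})
        out = assign_puncta(cells, puncta, max_distance=10.0)
        assert list(out) == [0, -1]


class TestPolygons:
    def test_square_polygon_rasterizes_to_square(self):
        spec = {
            "barrels": [],
            "enclosing": [(2, 2), (2, 8), (8, 8), (8, 2)],
        }
        rs = roi_set_from_polygons(spec, (12, 12))
        area = int(rs.enclosing_roi.sum())
        assert 25 <= area <= 49  # 6x6-ish square under the pixel-center rule
        assert rs.enclosing_roi[5, 5]
        assert not rs.enclosing_roi[0, 0]
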