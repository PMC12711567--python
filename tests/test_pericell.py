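"""Pericellular quantification: preprocessing rules, classification
contracts, and brute-force pixel oracles on generated scenes."""

import numpy as np
import pandas as pd
import pytest

from mammostroma.pericell import (ImcConfig, MultiplexImage, analyze_scene,
                                  class_positive_fraction,
                                  classify_marker_classes,
                                  compute_tissue_mask,
                                  extract_cell_intensities,
                                  filter_hot_pixels, normalize_channels,
                                  pericellular_intensity)
from mammostroma.synth import SceneSpec, gen_multiplex_scene

from conftest import as_image


def single_channel(arr):
    return MultiplexImage(np.asarray(arr, float)[None], ("X",))


class TestHotPixelFilter:
    @pytest.mark.parametrize("centre,expected", [
        (300.0, 10.0),   # 300 - 10 > 50: replaced by neighbour max
        (55.0, 55.0),    # 45 <= 50: unchanged
        (60.0, 60.0),    # boundary: 50 is not > 50
        (61.0, 10.0),    # 51 > 50: replaced
    ])
    def test_neighbourhood_max_rule(self, centre, expected):
        img = np.full((3, 3), 10.0)
        img[1, 1] = centre
        out = filter_hot_pixels(single_channel(img), 50.0)
        assert out.channels[0, 1, 1] == expected
        mask = np.ones((3, 3), bool)
        mask[1, 1] = False
        np.testing.assert_array_equal(out.channels[0][mask], img[mask])

    def test_uniform_image_unchanged(self):
        img = single_channel(np.full((5, 5), 7.0))
        np.testing.assert_array_equal(
            filter_hot_pixels(img, 50.0).channels, img.channels)

    def test_idempotent(self, rng):
        img = single_channel(rng.uniform(0, 200, (16, 16)))
        once = filter_hot_pixels(img, 50.0)
        twice = filter_hot_pixels(once, 50.0)
        np.testing.assert_array_equal(once.channels, twice.channels)

    def test_scene_hot_pixels_removed(self):
        scene = gen_multiplex_scene(SceneSpec(hot_pixel_count=20, seed=3))
        out = filter_hot_pixels(as_image(scene), 50.0)
        assert out.channels.max() < 100  # spikes of 1000 are gone


class TestNormalize:
    def test_min_max_example(self):
        img = single_channel(np.array([[2.0, 4.0, 6.0]]))
        np.testing.assert_allclose(
            normalize_channels(img).channels[0], [[0.0, 0.5, 1.0]])

    def test_constant_channel_maps_to_zero(self):
        img = single_channel(np.full((4, 4), 3.0))
        assert np.all(normalize_channels(img).channels == 0)

    def test_idempotent_on_nonconstant(self, rng):
        img = single_channel(rng.uniform(0, 9, (8, 8)))
        once = normalize_channels(img)
        np.testing.assert_allclose(normalize_channels(once).channels,
                                   once.channels)


class TestTissueMask:
    def test_all_zero_image_is_all_void(self):
        img = MultiplexImage(np.zeros((2, 8, 8)), ("DNA", "ECAD"))
        assert not compute_tissue_mask(img, ImcConfig()).any()

    def test_recovers_generated_void_fraction(self):
        spec = SceneSpec(void_fraction=0.25, noise_sd=0.0, seed=21)
        scene = gen_multiplex_scene(spec)
        tissue = compute_tissue_mask(normalize_channels(as_image(scene)),
                                     ImcConfig(), scene.label_mask)
        assert (~tissue).mean() == pytest.approx(0.25, abs=0.02)

    def test_cells_are_never_void(self, noisy_scene):
        tissue = compute_tissue_mask(as_image(noisy_scene), ImcConfig(),
                                     noisy_scene.label_mask)
        assert np.all(tissue[noisy_scene.label_mask > 0])


class TestCellIntensities:
    def test_constant_cells_recovered_exactly(self):
        labels = np.zeros((6, 6), int)
        labels[1:3, 1:3] = 1
        labels[4:6, 4:6] = 2
        ch = np.where(labels == 1, 0.3, np.where(labels == 2, 0.7, 0.0))
        cells = extract_cell_intensities(MultiplexImage(ch[None], ("X",)), labels)
        np.testing.assert_allclose(cells["X"], [0.3, 0.7])
        np.testing.assert_allclose(cells["area_px"], [4, 4])

    def test_sum_conservation(self, noisy_scene):
        img = as_image(noisy_scene)
        cells = extract_cell_intensities(img, noisy_scene.label_mask)
        total = (cells["COL6"] * cells["area_px"]).sum()
        masked = img.channel("COL6")[noisy_scene.label_mask > 0].sum()
        assert total == pytest.approx(masked, rel=1e-10)

    def test_matches_pixel_loop_oracle(self, clean_scene):
        img = as_image(clean_scene)
        cells = extract_cell_intensities(img, clean_scene.label_mask)
        sox9 = img.channel("SOX9")
        for _, row in cells.iterrows():
            sel = clean_scene.label_mask == row["label"]
            assert row["SOX9"] == pytest.approx(sox9[sel].mean(), rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            extract_cell_intensities(MultiplexImage(np.zeros((1, 4, 4)), ("X",)),
                                     np.zeros((5, 5), int))


def make_cells(marker_means, ecad=1.0):
    return pd.DataFrame({
        "label": np.arange(1, len(marker_means) + 1),
        "centroid_row": 0.0, "centroid_col": 0.0, "area_px": 1,
        "ECAD": ecad, "SOX9": marker_means,
    })


class TestClassification:
    def test_fixed_threshold_example(self):
        cells = make_cells([0.9, 0.8, 0.2, 0.1, 0.05])
        cfg = ImcConfig(high_strategy="fixed_value", high_param=0.7,
                        epithelial_threshold=0.5)
        out = classify_marker_classes(cells, cfg)
        assert list(out.loc[out.marker_class == "high", "label"]) == [1, 2]
        assert set(out.loc[out.marker_class == "low", "label"]) == {4, 5}

    def test_quantile_strategy_matches_sort_oracle(self, rng):
        means = rng.uniform(0, 1, 10)
        cells = make_cells(means)
        cfg = ImcConfig(high_strategy="quantile", high_param=0.8,
                        epithelial_threshold=0.5)
        out = classify_marker_classes(cells, cfg)
        order = np.argsort(means, kind="stable")
        k = (out.marker_class == "high").sum()
        assert k == (means > np.quantile(means, 0.8)).sum()
        assert set(out.loc[out.marker_class == "low", "label"]) == \
            set(cells["label"].to_numpy()[order[:k]])

    def test_all_below_threshold_yields_empty_classes(self):
        cells = make_cells([0.1, 0.2, 0.3])
        cfg = ImcConfig(high_strategy="fixed_value", high_param=0.9,
                        epithelial_threshold=0.05)
        with pytest.warns(UserWarning):
            out = classify_marker_classes(cells, cfg)
        assert (out.marker_class == "unassigned").all()

    def test_overlapping_classes_error(self):
        cells = make_cells([0.9, 0.8, 0.7])
        cfg = ImcConfig(high_strategy="fixed_value", high_param=0.5,
                        epithelial_threshold=0.1)
        with pytest.raises(ValueError, match="overlap"):
            classify_marker_classes(cells, cfg)

    def test_high_implies_epithelial_and_counts_match(self, noisy_scene):
        cells, _ = analyze_scene(as_image(noisy_scene), noisy_scene.label_mask)
        high = cells[cells.marker_class == "high"]
        low = cells[cells.marker_class == "low"]
        assert len(high) == len(low) > 0
        assert high["epithelial"].all() and low["epithelial"].all()


class TestPericellular:
    def test_matches_brute_force_pixel_loop(self, clean_scene):
        """Independent oracle: global distance grid per cell, excluding all
        labelled and void pixels; must match the windowed implementation."""
        img = as_image(clean_scene)
        cfg = ImcConfig(high_strategy="fixed_value", high_param=0.5)
        cells = extract_cell_intensities(img, clean_scene.label_mask)
        cells = classify_marker_classes(cells, cfg)
        out = pericellular_intensity(img, clean_scene.label_mask,
                                     clean_scene.void_mask, cells, cfg)
        h, w = clean_scene.label_mask.shape
        rr, cc = np.mgrid[0:h, 0:w]
        forbidden = (clean_scene.label_mask > 0) | clean_scene.void_mask
        for _, row in out[out.marker_class.isin(["high", "low"])].iterrows():
            disc = ((rr - row.centroid_row) ** 2 + (cc - row.centroid_col) ** 2
                    <= (cfg.radius_um / img.pixel_size_um) ** 2)
            valid = disc & ~forbidden
            expect = img.channel("COL6")[valid].mean()
            assert row["pericell_COL6"] == pytest.approx(expect, rel=1e-12)
            assert row["valid_pixel_fraction"] == pytest.approx(
                valid.sum() / disc.sum(), rel=1e-12)

    def test_recovers_known_enrichment(self, clean_scene):
        cfg = ImcConfig(high_strategy="fixed_value", high_param=0.5)
        cells, _ = analyze_scene(as_image(clean_scene),
                                 clean_scene.label_mask, cfg)
        a = cells.loc[cells.marker_class == "high", "pericell_COL6"]
        b = cells.loc[cells.marker_class == "low", "pericell_COL6"]
        assert a.mean() == pytest.approx(0.4, abs=1e-9)
        assert b.mean() == pytest.approx(0.2, abs=1e-9)

    def test_void_dominated_cell_is_dropped(self):
        """A cell whose disc is almost entirely void keeps NaN means."""
        labels = np.zeros((40, 40), int)
        labels[20, 20] = 1
        void = np.ones((40, 40), bool)
        void[20, 19:22] = False  # only 3 valid pixels near the cell
        img = MultiplexImage(np.full((1, 40, 40), 0.5), ("COL6",))
        cells = pd.DataFrame({"label": [1], "centroid_row": [20.0],
                              "centroid_col": [20.0], "area_px": [1],
                              "COL6": [0.5], "marker_class": ["high"],
                              "epithelial": [True]})
        out = pericellular_intensity(img, labels, void, cells,
                                     ImcConfig(ecm_channels=("COL6",)))
        assert bool(out.pericell_dropped.iloc[0])
        assert np.isnan(out.pericell_COL6.iloc[0])

    def test_translation_invariance(self):
        """Embedding the same scene at two offsets in a larger void canvas
        leaves every per-cell statistic unchanged."""
        scene = gen_multiplex_scene(SceneSpec(seed=31, noise_sd=0.01,
                                              void_fraction=0.0))
        tables = []
        for dy, dx in ((8, 8), (15, 13)):
            h, w = scene.label_mask.shape
            ch = np.zeros((scene.channels.shape[0], h + 32, w + 32))
            lab = np.zeros((h + 32, w + 32), int)
            void = np.ones((h + 32, w + 32), bool)
            ch[:, dy:dy + h, dx:dx + w] = scene.channels
            lab[dy:dy + h, dx:dx + w] = scene.label_mask
            void[dy:dy + h, dx:dx + w] = scene.void_mask
            img = MultiplexImage(ch, scene.channel_names)
            cfg = ImcConfig()
            cells = extract_cell_intensities(img, lab)
            cells = classify_marker_classes(cells, cfg)
            out = pericellular_intensity(img, lab, void, cells, cfg)
            tables.append(out.sort_values("label").reset_index(drop=True))
        a, b = tables
        for col in ("SOX9", "COL6", "pericell_COL6", "valid_pixel_fraction"):
            np.testing.assert_allclose(a[col], b[col], rtol=0, atol=1e-12)
        assert list(a.marker_class) == list(b.marker_class)


class TestPositiveFraction:
    def test_examples(self):
        cells = pd.DataFrame({"marker_class": ["high"] * 4,
                              "KI67": [0.9, 0.1, 0.2, 0.8]})
        assert class_positive_fraction(cells, "KI67", 0.5, "high") == 0.5
        cells["KI67"] = 0.9
        assert class_positive_fraction(cells, "KI67", 0.5, "high") == 1.0

    def test_empty_class_signalled(self):
        cells = pd.DataFrame({"marker_class": ["low"], "KI67": [0.1]})
        with pytest.raises(ValueError):
            class_positive_fraction(cells, "KI67", 0.5, "high")

    def test_matches_ground_truth_on_scene(self, noisy_scene):
        cells, _ = analyze_scene(as_image(noisy_scene), noisy_scene.label_mask)
        gt = noisy_scene.ground_truth.set_index("label")
        high = cells[cells.marker_class == "high"]
        frac = class_positive_fraction(cells, "raw_KI67", 0.5, "high")
        expect = gt.loc[high.label, "ki67_positive"].mean()
        assert frac == pytest.approx(expect)
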