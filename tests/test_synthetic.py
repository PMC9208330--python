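"""Synthetic flower generator: determinism, label structure, separability."""

import numpy as np
import pandas as pd
import pytest

from chrysid.synthetic import (CultivarSpec, SyntheticDatasetConfig,
                               VariationParams, drift_spec, foreground_fraction,
                               generate_dataset, make_specs,
                               render_flower_image, sample_cultivar_spec)
from chrysid.vocab import COLOR_CLASSES, PETAL_TYPES, LabelVocabulary


class TestCultivarSpecSampling:
    def test_same_index_and_seed_give_identical_spec(self, full_vocab):
        a = sample_cultivar_spec(11, full_vocab, rng_seed=5)
        b = sample_cultivar_spec(11, full_vocab, rng_seed=5)
        assert a == b

    def test_different_seed_changes_morphology_not_labels(self, full_vocab):
        a = sample_cultivar_spec(11, full_vocab, rng_seed=5)
        b = sample_cultivar_spec(11, full_vocab, rng_seed=6)
        assert (a.color_class, a.petal_type, a.flower_type) == \
               (b.color_class, b.petal_type, b.flower_type)
        assert a.base_hsv != b.base_hsv

    def test_stratified_coverage_over_126_specs(self, full_vocab):
        specs = [sample_cultivar_spec(i, full_vocab, 0) for i in range(126)]
        petal_counts = pd.Series([s.petal_type for s in specs]).value_counts()
        assert set(petal_counts.index) == set(PETAL_TYPES)
        assert (petal_counts >= 1).all()
        color_counts = pd.Series([s.color_class for s in specs]).value_counts()
        assert set(color_counts.index) == set(COLOR_CLASSES)
        # 126 / 9 = 14: round-robin assignment is exactly balanced
        assert ((color_counts - 14).abs() <= 1).all()

    def test_empty_vocabulary_level_rejected(self):
        with pytest.raises(ValueError):
            LabelVocabulary(petal_types=[])

    def test_flower_type_matches_petal_family_in_default_vocab(self, full_vocab):
        from chrysid.vocab import flower_types_of_family
        for i in range(30):
            s = sample_cultivar_spec(i, full_vocab, 3)
            assert s.flower_type in {ft.name for ft in
                                     flower_types_of_family(s.petal_type)}


class TestRenderer:
    def test_zero_jitter_renders_are_pixel_identical(self, full_vocab):
        spec = sample_cultivar_spec(0, full_vocab, 0)
        var = VariationParams.none()
        a = render_flower_image(spec, var, rng_seed=9, size=48)
        b = render_flower_image(spec, var, rng_seed=9, size=48)
        np.testing.assert_array_equal(a.image, b.image)

    def test_different_render_seed_changes_pixels_under_jitter(self, full_vocab):
        spec = sample_cultivar_spec(0, full_vocab, 0)
        var = VariationParams.low()
        a = render_flower_image(spec, var, rng_seed=1, size=48)
        b = render_flower_image(spec, var, rng_seed=2, size=48)
        assert (a.image != b.image).any()

    def test_white_flower_is_brighter_than_background(self, full_vocab):
        white = next(sample_cultivar_spec(i, full_vocab, 0) for i in range(9)
                     if sample_cultivar_spec(i, full_vocab, 0).color_class == "white")
        img = render_flower_image(white, VariationParams.none(), 0, 64).image
        background = 0.04 * 255
        assert img.mean() > background + 50

    def test_tubular_covers_less_area_than_flat(self):
        base = dict(petal_count=20, petal_aspect=1.0, disk_frac=0.1,
                    base_hsv=(0.15, 0.9, 0.95))
        flat = CultivarSpec("cv_a", "yellow", "flat", "lotus-like", **base)
        tub = CultivarSpec("cv_b", "yellow", "tubular", "fine-tube", **base)
        var = VariationParams.none()
        f_flat = foreground_fraction(render_flower_image(flat, var, 3, 64).image)
        f_tub = foreground_fraction(render_flower_image(tub, var, 3, 64).image)
        assert f_tub < f_flat

    def test_too_small_size_rejected(self, full_vocab):
        spec = sample_cultivar_spec(0, full_vocab, 0)
        with pytest.raises(ValueError):
            render_flower_image(spec, VariationParams.none(), 0, size=16)

    def test_labels_propagate_from_spec(self, full_vocab):
        spec = sample_cultivar_spec(4, full_vocab, 0)
        img = render_flower_image(spec, VariationParams.low(), 5, 48)
        assert (img.cultivar_id, img.petal_type, img.flower_type) == \
               (spec.cultivar_id, spec.petal_type, spec.flower_type)


class TestDatasetGeneration:
    def test_row_count_is_cultivars_times_images(self, small_dataset):
        assert len(small_dataset) == 6 * 10

    def test_single_image_dataset(self, tmp_path, full_vocab):
        cfg = SyntheticDatasetConfig(n_cultivars=1, images_per_cultivar=1,
                                     image_size=32, seed=3)
        m = generate_dataset(cfg, tmp_path)
        assert len(m) == 1
        spec = make_specs(cfg)[0]
        row = m.df.iloc[0]
        assert (row.cultivar_id, row.petal_type, row.flower_type) == \
               (spec.cultivar_id, spec.petal_type, spec.flower_type)

    def test_regeneration_is_byte_identical(self, tmp_path):
        cfg = SyntheticDatasetConfig(n_cultivars=2, images_per_cultivar=3,
                                     image_size=32, seed=11)
        m1 = generate_dataset(cfg, tmp_path / "a")
        m2 = generate_dataset(cfg, tmp_path / "b")
        lab = ["cultivar_id", "petal_type", "flower_type", "year", "view"]
        pd.testing.assert_frame_equal(m1.df[lab], m2.df[lab])
        b1 = (tmp_path / "a" / "images_2018").glob("*.png")
        b2 = (tmp_path / "b" / "images_2018").glob("*.png")
        for p1, p2 in zip(sorted(b1), sorted(b2)):
            assert p1.read_bytes() == p2.read_bytes()

    def test_label_consistency_within_cultivar(self, small_dataset):
        per = small_dataset.df.groupby("cultivar_id")[["petal_type", "flower_type"]]
        assert (per.nunique() == 1).all().all()

    def test_drift_preserves_labels_but_shifts_pixel_statistics(self, tmp_path):
        base = SyntheticDatasetConfig(n_cultivars=3, images_per_cultivar=4,
                                      image_size=48, seed=21, year_tag="2018")
        drifted = SyntheticDatasetConfig(n_cultivars=3, images_per_cultivar=4,
                                         image_size=48, seed=21, year_tag="2019",
                                         drift_level=0.3)
        m1 = generate_dataset(base, tmp_path)
        m2 = generate_dataset(drifted, tmp_path)
        lab = ["cultivar_id", "petal_type", "flower_type"]
        pd.testing.assert_frame_equal(m1.df[lab], m2.df[lab])

        from PIL import Image
        def mean_rgb_per_cultivar(m):
            out = {}
            for cid, g in m.df.groupby("cultivar_id"):
                arrs = [np.asarray(Image.open(p)).mean(axis=(0, 1))
                        for p in g["path"]]
                out[cid] = np.mean(arrs, axis=0)
            return out
        a, b = mean_rgb_per_cultivar(m1), mean_rgb_per_cultivar(m2)
        dist = sum(np.linalg.norm(a[c] - b[c]) for c in a)
        assert dist > 0

    def test_drift_spec_keeps_labels(self, full_vocab):
        spec = sample_cultivar_spec(2, full_vocab, 0)
        d = drift_spec(spec, 0.5, 99)
        assert (d.cultivar_id, d.petal_type, d.flower_type) == \
               (spec.cultivar_id, spec.petal_type, spec.flower_type)
        assert (d.petal_count, d.petal_aspect, d.disk_frac, d.base_hsv) != \
               (spec.petal_count, spec.petal_aspect, spec.disk_frac, spec.base_hsv)

    def test_voc_sidecar_emitted_when_requested(self, tmp_path):
        cfg = SyntheticDatasetConfig(n_cultivars=1, images_per_cultivar=2,
                                     image_size=32, seed=1, emit_voc=True)
        m = generate_dataset(cfg, tmp_path)
        for p in m.df["path"]:
            assert p.endswith(".png")
            from pathlib import Path
            assert Path(p).with_suffix(".xml").exists()


class TestColorSeparability:
    def test_linear_probe_on_foreground_rgb_separates_nine_colors(self, full_vocab):
        """At zero jitter the 9 color series are linearly separable from
        foreground mean-RGB features (the palette is constructed separable)."""
        from sklearn.linear_model import LogisticRegression

        X, y = [], []
        for i in range(27):  # 3 cultivars per color series
            spec = sample_cultivar_spec(i, full_vocab, 1)
            for s in range(4):
                img = render_flower_image(spec, VariationParams.none(),
                                          rng_seed=1000 * i + s, size=48).image
                fg = img[img.max(axis=-1) > 30]
                X.append(fg.mean(axis=0))
                y.append(spec.color_class)
        X = np.array(X) / 255.0
        y = np.array(y)
        train = np.arange(len(y)) % 4 < 2
        clf = LogisticRegression(max_iter=5000, C=1000.0).fit(X[train], y[train])
        assert clf.score(X[~train], y[~train]) >= 0.95
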