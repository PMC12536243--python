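"""Synthetic-histology generator: partition, determinism, artifacts, brushes."""

import numpy as np
import pytest

from gutseg.image import GROUND_TRUTH_CLASSES
from gutseg.synthetic import (
    AGE_DEFAULTS,
    AGE_GROUPS,
    ArtifactFlags,
    GeneratorConfig,
    generate_cohort,
    generate_tissue_image,
    inject_artifacts,
    sample_annotations,
)


class TestConfig:
    def test_age_defaults_are_monotone(self):
        """Younger animals: more vacuolation, tighter villus packing."""
        vac = [AGE_DEFAULTS[a][0] for a in AGE_GROUPS]
        gap = [AGE_DEFAULTS[a][1] for a in AGE_GROUPS]
        assert vac == sorted(vac, reverse=True)
        assert gap == sorted(gap)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(age_group=30)
        with pytest.raises(ValueError):
            GeneratorConfig(vacuolation_fraction=1.5)
        with pytest.raises(ValueError):
            GeneratorConfig(villus_width_um=-1)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="villus|height"):
            generate_tissue_image(GeneratorConfig(image_size_px=(64, 448)))


class TestGenerate:
    def test_partition_and_background_brightness(self, sample1):
        """Every pixel gets exactly one class; artifact-free background always
        exceeds mean RGB 205, so the tissue threshold is meaningful."""
        image, truth, record = sample1
        lab = truth.label_mask
        assert lab.classes == GROUND_TRUTH_CLASSES
        assert ((lab.data >= 0) & (lab.data < 5)).all()
        assert record.count() == 0
        bg = lab.mask_of("background")
        assert (image.mean_rgb()[bg] > 205).all()

    def test_derived_masks_are_exact_unions(self, sample1):
        _, truth, _ = sample1
        lab = truth.label_mask
        np.testing.assert_array_equal(
            truth.mucosa_mask, lab.mask_of("epithelium") | lab.mask_of("lamina_propria")
        )
        np.testing.assert_array_equal(
            truth.tissue_mask, ~(lab.mask_of("background") | lab.mask_of("lumen_content"))
        )
        assert not (truth.mucosa_mask & lab.mask_of("submucosa_muscularis")).any()

    def test_epithelium_lies_within_band_of_lumen(self, sample1):
        from scipy import ndimage

        _, truth, _ = sample1
        lab = truth.label_mask
        dist = ndimage.distance_transform_edt(~lab.mask_of("background"))
        band_px = truth.epithelial_band_um / lab.pixel_size_um
        assert dist[lab.mask_of("epithelium")].max() <= band_px + 1e-9

    def test_seeded_determinism(self):
        cfg = GeneratorConfig(seed=9)
        a = generate_tissue_image(cfg)
        b = generate_tissue_image(cfg)
        np.testing.assert_array_equal(a[0].pixels, b[0].pixels)
        np.testing.assert_array_equal(a[1].label_mask.data, b[1].label_mask.data)

    def test_vacuolation_fraction_controls_pale_epithelium(self):
        """Raising the vacuolation fraction makes the epithelium paler on
        average (fetal-type enterocytes take up less stain)."""
        means = []
        for frac in (0.0, 0.5):
            img, truth, _ = generate_tissue_image(
                GeneratorConfig(seed=3, vacuolation_fraction=frac)
            )
            means.append(img.mean_rgb()[truth.label_mask.mask_of("epithelium")].mean())
        assert means[1] > means[0] + 10


class TestArtifacts:
    def test_no_flags_is_identity(self, sample1):
        image, truth, _ = sample1
        out, record = inject_artifacts(image, truth, ArtifactFlags(), seed=0)
        assert out is image
        assert record.count() == 0

    def test_luminal_debris_preserves_tissue_area(self):
        cfg_clean = GeneratorConfig(seed=21)
        _, truth_clean, _ = generate_tissue_image(cfg_clean)
        img, truth, record = generate_tissue_image(
            GeneratorConfig(seed=21, artifact_flags=ArtifactFlags(luminal_debris=True))
        )
        assert record.count("luminal_debris") >= 1
        # debris is labeled lumen_content, so ground-truth tissue is unchanged
        assert truth.tissue_mask.sum() == truth_clean.tissue_mask.sum()
        assert truth.label_mask.mask_of("lumen_content").sum() > 0
        # the lumen gained stained (dark) pixels
        debris = truth.label_mask.mask_of("lumen_content")
        assert img.mean_rgb()[debris].mean() < 205

    def test_edema_vessel_is_bright_but_tissue(self):
        img, truth, record = generate_tissue_image(
            GeneratorConfig(seed=22, artifact_flags=ArtifactFlags(edema_vessels=True))
        )
        vessels = [e for e in record.entries if e.kind == "edema_vessel"]
        assert len(vessels) >= 1
        assert vessels[0].area_um2 > 100_000
        # vessel interior: mean RGB above the background cutoff, yet labeled tissue
        cy, cx = vessels[0].row, vessels[0].col
        patch = img.mean_rgb()[cy - 3 : cy + 4, cx - 3 : cx + 4]
        assert patch.mean() > 205
        assert truth.label_mask.data[cy, cx] == truth.label_mask.index_of(
            "submucosa_muscularis"
        )

    def test_crypt_abscesses_recorded_with_area(self):
        _, truth, record = generate_tissue_image(
            GeneratorConfig(seed=23, artifact_flags=ArtifactFlags(crypt_abscesses=True))
        )
        abscesses = [e for e in record.entries if e.kind == "crypt_abscess"]
        assert len(abscesses) >= 1
        for e in abscesses:
            assert e.area_um2 > 0
            # labeled as lumen content: neither epithelium nor lamina propria
            assert truth.label_mask.data[e.row, e.col] == truth.label_mask.index_of(
                "lumen_content"
            )

    def test_alignment_checked(self, sample1):
        image, truth, _ = sample1
        from gutseg.image import CalibratedImage

        small = CalibratedImage(image.pixels[:100, :100], image.pixel_size_um)
        with pytest.raises(ValueError, match="aligned"):
            inject_artifacts(small, truth, ArtifactFlags(luminal_debris=True), 0)


class TestAnnotations:
    def test_strokes_are_pure_and_counted(self, sample1):
        _, truth, _ = sample1
        ann = sample_annotations(
            truth.step3_labels(), ("epithelium", "lamina_propria"), 8, 7.0, seed=1
        )
        assert len(ann) == 16
        lab = truth.step3_labels()
        for stroke in ann.strokes:
            idx = lab.index_of(stroke.class_name)
            assert (lab.data[stroke.rows, stroke.cols] == idx).all()

    def test_zero_strokes(self, sample1):
        _, truth, _ = sample1
        ann = sample_annotations(truth.step3_labels(), ("epithelium",), 0, 7.0, seed=1)
        assert len(ann) == 0

    def test_seeded_reproducibility(self, sample1):
        _, truth, _ = sample1
        a = sample_annotations(truth.step2_labels(), ("mucosa",), 3, 25.0, seed=5)
        b = sample_annotations(truth.step2_labels(), ("mucosa",), 3, 25.0, seed=5)
        for s, t in zip(a.strokes, b.strokes):
            np.testing.assert_array_equal(s.rows, t.rows)

    def test_oversized_brush_rejected(self, sample1):
        _, truth, _ = sample1
        with pytest.raises(ValueError, match="too small"):
            sample_annotations(truth.step3_labels(), ("epithelium",), 2, 300.0, seed=1)

    def test_missing_class_rejected(self, sample1):
        _, truth, _ = sample1
        with pytest.raises((ValueError, KeyError)):
            sample_annotations(truth.step3_labels(), ("lumen_content",), 2, 7.0, seed=1)


class TestCohort:
    def test_counts_and_determinism(self):
        a = generate_cohort(2, seed=11)
        b = generate_cohort(2, seed=11)
        assert len(a) == 10
        assert [s.age_group for s in a] == sorted(
            [age for age in AGE_GROUPS for _ in range(2)]
        )
        np.testing.assert_array_equal(a[3].image.pixels, b[3].image.pixels)

    def test_young_more_vacuolated_than_old(self):
        cohort = generate_cohort(2, seed=12)
        young = np.mean(
            [s.config.resolved().vacuolation_fraction for s in cohort if s.age_group == 4]
        )
        old = np.mean(
            [s.config.resolved().vacuolation_fraction for s in cohort if s.age_group == 67]
        )
        assert young > old

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            generate_cohort(0)
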