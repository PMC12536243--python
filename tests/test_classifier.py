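"""Pixel-classifier training, masked application, and the step hierarchy."""

import numpy as np
import pytest

from gutseg.classifier import (
    apply_classifier,
    run_three_step_pipeline,
    train_classifier,
)
from gutseg.features import STEP3_FEATURES, FeatureConfig
from gutseg.image import AnnotationSet, CalibratedImage, Stroke
from gutseg.tissue import ThresholdConfig

RGB_CFG = FeatureConfig(("R", "G", "B"), ("gaussian", "weighted_deviation"), (1.0,), 3.51)


def separable_sample(seed=0, offset=80.0):
    """Two vertical half-planes separated by an intensity offset >> noise."""
    rng = np.random.default_rng(seed)
    px = np.full((48, 48, 3), 60.0)
    px[:, 24:, :] += offset
    px += rng.normal(0, 1.0, px.shape)
    image = CalibratedImage(np.clip(px, 0, 255).astype(np.uint8), 3.51)
    ann = AnnotationSet(pixel_size_um=3.51)
    rr, cc = np.mgrid[10:40, 4:10]
    ann.strokes.append(Stroke("dark", rr.ravel(), cc.ravel()))
    rr, cc = np.mgrid[10:40, 38:44]
    ann.strokes.append(Stroke("bright", rr.ravel(), cc.ravel()))
    return image, ann


class TestTraining:
    def test_separable_classes_classified_perfectly(self):
        """On a linearly separable construction, held-out pixels far from the
        training strokes are classified with 100% accuracy."""
        image, ann = separable_sample()
        model = train_classifier([(image, ann)], RGB_CFG, ("dark", "bright"), seed=0)
        probe, _ = separable_sample(seed=99)
        labels = apply_classifier(model, probe)
        assert (labels.data[5:-5, 5:20] == 0).all()
        assert (labels.data[5:-5, 28:-5] == 1).all()

    def test_seeded_determinism(self):
        image, ann = separable_sample()
        m1 = train_classifier([(image, ann)], RGB_CFG, ("dark", "bright"), seed=7)
        m2 = train_classifier([(image, ann)], RGB_CFG, ("dark", "bright"), seed=7)
        probe, _ = separable_sample(seed=50, offset=20.0)
        np.testing.assert_array_equal(
            apply_classifier(m1, probe).data, apply_classifier(m2, probe).data
        )

    def test_class_order_symmetry(self):
        """Swapping the declared class order only renames the labels."""
        image, ann = separable_sample()
        m_ab = train_classifier([(image, ann)], RGB_CFG, ("dark", "bright"), seed=3)
        m_ba = train_classifier([(image, ann)], RGB_CFG, ("bright", "dark"), seed=3)
        probe, _ = separable_sample(seed=60)
        la = apply_classifier(m_ab, probe).data
        lb = apply_classifier(m_ba, probe).data
        np.testing.assert_array_equal(la, 1 - lb)

    def test_missing_class_named_in_error(self):
        image, ann = separable_sample()
        with pytest.raises(ValueError, match="stroma"):
            train_classifier([(image, ann)], RGB_CFG, ("dark", "bright", "stroma"))

    def test_single_class_rejected(self):
        image, ann = separable_sample()
        with pytest.raises(ValueError, match="two classes"):
            train_classifier([(image, ann)], RGB_CFG, ("dark",))

    def test_manifest_records_counts(self):
        image, ann = separable_sample()
        model = train_classifier([(image, ann)], RGB_CFG, ("dark", "bright"), seed=1)
        counts = model.manifest["annotated_pixels_per_class"]
        assert counts["dark"] == 30 * 6 and counts["bright"] == 30 * 6
        assert model.manifest["rf_params"]["n_estimators"] == 100

    def test_oob_accuracy_on_separable_data(self):
        """The forest's out-of-bag accuracy on annotated pixels exceeds 0.99
        when the classes are separable by construction."""
        image, ann = separable_sample()
        model = train_classifier(
            [(image, ann)], RGB_CFG, ("dark", "bright"),
            rf_params={"oob_score": True}, seed=0,
        )
        assert model.forest.oob_score_ > 0.99


@pytest.fixture(scope="module")
def model():
    image, ann = separable_sample()
    return train_classifier([(image, ann)], RGB_CFG, ("dark", "bright"), seed=0)


class TestApply:

    def test_empty_restriction_is_fully_unclassified(self, model):
        probe, _ = separable_sample(seed=1)
        out = apply_classifier(model, probe, restrict_mask=np.zeros((48, 48), bool))
        assert (out.data == -1).all()

    def test_masking_contract(self, model):
        probe, _ = separable_sample(seed=2)
        mask = np.zeros((48, 48), dtype=bool)
        mask[:, :10] = True
        out = apply_classifier(model, probe, restrict_mask=mask)
        assert (out.data[~mask] == -1).all()
        assert (out.data[mask] >= 0).all()

    def test_feature_config_mismatch_refused(self, model):
        probe, _ = separable_sample(seed=3)
        with pytest.raises(ValueError, match="mismatch"):
            apply_classifier(model, probe, feature_config=STEP3_FEATURES)

    def test_save_load_round_trip(self, model, tmp_path):
        from gutseg.classifier import TrainedPixelClassifier

        path = tmp_path / "model.joblib"
        model.save(path)
        back = TrainedPixelClassifier.load(path)
        assert back.classes == model.classes
        assert back.feature_config == model.feature_config
        probe, _ = separable_sample(seed=4)
        np.testing.assert_array_equal(
            apply_classifier(back, probe).data, apply_classifier(model, probe).data
        )


class TestPipelineHierarchy:
    def test_containment_and_nesting(self, small_models, validation_sample):
        _, m2, m3 = small_models
        image, truth, _ = validation_sample
        result = run_three_step_pipeline(image, ThresholdConfig(), m2, m3)
        tissue, _ = result.masks["tissue"]
        mucosa, _ = result.masks["mucosa"]
        epi, _ = result.masks["epithelium"]
        lam, _ = result.masks["lamina_propria"]
        assert not (mucosa & ~tissue).any()
        up = np.kron(mucosa, np.ones((2, 2), dtype=bool))[: epi.shape[0], : epi.shape[1]]
        assert not ((epi | lam) & ~up).any()
        a = result.areas_um2
        assert a["epithelium"] + a["lamina_propria"] <= a["mucosa"] * 1.01
        assert a["mucosa"] <= a["tissue"]

    def test_blank_image_yields_zero_areas(self, small_models):
        _, m2, m3 = small_models
        blank = CalibratedImage(np.full((448, 448, 3), 255, dtype=np.uint8), 3.51)
        result = run_three_step_pipeline(blank, ThresholdConfig(), m2, m3)
        assert all(v == 0.0 for v in result.areas_um2.values())
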