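"""Auto-context cascade: sampling, context geometry, training and
application contracts.  The expensive effectiveness checks live in the
acceptance suite; here cascades are trained on tiny phantoms."""

import numpy as np
import pytest

from liverseg.cascade import (
    ClassifierCascade,
    ContextConfig,
    ProbabilityMap,
    TrainingCase,
    apply_cascade,
    context_feature_map,
    context_features,
    load_cascade,
    sample_training_pixels,
    save_cascade,
    train_cascade,
)
from liverseg.glcm import GLCMConfig, appearance_feature_map
from liverseg.boosting import margin_to_prob

TINY_GLCM = GLCMConfig(quant_levels=8, patch_radius=3, offsets=((1, 0), (1, 90)))
TINY_CTX = ContextConfig(radii=(3, 6))


def tiny_cases(n=2, size=64, seed=0):
    """Two-texture images: smooth bright blob on noisy dark background."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    cases = []
    for k in range(n):
        img = 0.3 + 0.05 * rng.standard_normal((size, size))
        mask = np.zeros((size, size), dtype=np.uint8)
        r, c = rng.integers(20, size - 20, size=2)
        rr, cc = np.mgrid[0:size, 0:size]
        mask[(rr - r) ** 2 + (cc - c) ** 2 < 144] = 1
        tex = ndimage.gaussian_filter(rng.standard_normal((size, size)), 2)
        img[mask == 1] = 0.6 + 0.08 * tex[mask == 1]
        cases.append(TrainingCase(image=img, label_map=mask, id=f"tiny{k}"))
    return cases


@pytest.fixture(scope="module")
def tiny_cascade():
    return train_cascade(tiny_cases(), U=1, glcm_config=TINY_GLCM,
                         context_config=TINY_CTX, n_per_class=300, n_rounds=20,
                         rng_seed=3)


class TestSampleTrainingPixels:
    def make_case(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[:, 5:] = 1
        return TrainingCase(image=np.zeros((10, 10)), label_map=mask, id="half")

    def test_balanced_counts(self):
        pix = sample_training_pixels(self.make_case(), 10, rng_seed=0)
        labels = [y for _, y in pix]
        assert labels.count(1) == 10 and labels.count(0) == 10

    def test_deterministic(self):
        a = sample_training_pixels(self.make_case(), 10, rng_seed=4)
        b = sample_training_pixels(self.make_case(), 10, rng_seed=4)
        assert a == b

    def test_small_class_used_whole_with_warning(self, caplog):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[0, :5] = 1  # 5 liver pixels
        case = TrainingCase(image=np.zeros((10, 10)), label_map=mask, id="small")
        with caplog.at_level("WARNING"):
            pix = sample_training_pixels(case, 10, rng_seed=0)
        assert sum(y for _, y in pix) == 5
        assert "small" in caplog.text

    def test_absent_class_rejected(self):
        case = TrainingCase(image=np.zeros((4, 4)),
                            label_map=np.ones((4, 4), dtype=np.uint8), id="allfg")
        with pytest.raises(ValueError, match="allfg"):
            sample_training_pixels(case, 5, rng_seed=0)


class TestContextFeatures:
    def test_uniform_map_constant_features(self):
        pm = ProbabilityMap(probs=np.full((40, 40), 0.7), iteration=0)
        cfg = ContextConfig(radii=(3, 6, 9), include_center=True)
        f = context_features(pm, (20, 20), cfg)
        np.testing.assert_allclose(f, 0.7)

    def test_vector_length_8_rays(self):
        cfg = ContextConfig(radii=(3, 6, 9, 12, 15), include_center=True)
        assert cfg.n_features == 41
        pm = ProbabilityMap(probs=np.full((40, 40), 0.5), iteration=0)
        assert context_features(pm, (20, 20), cfg).shape == (41,)

    def test_corner_rays_leave_image_read_zero(self):
        pm = ProbabilityMap(probs=np.full((10, 10), 0.8), iteration=0)
        cfg = ContextConfig(radii=(3,), include_center=True)
        f = context_features(pm, (0, 0), cfg)
        # rays at 45..225 degrees (counterclockwise, rows downward) leave
        # the image from the top-left corner; 0 (right), 270 (down) and
        # 315 (down-right) stay inside
        offs = cfg.offsets()
        expected = [0.8] + [
            0.8 if (0 <= dr < 10 and 0 <= dc < 10) else 0.0
            for dr, dc in offs[1:]
        ]
        np.testing.assert_allclose(f, expected)
        assert 0.0 in f  # some ray does leave

    def test_map_matches_per_pixel(self, rng):
        pm = ProbabilityMap(probs=rng.random((15, 17)), iteration=0)
        cfg = ContextConfig(radii=(2, 5), include_center=True)
        cmap = context_feature_map(pm, cfg)
        for x in [(0, 0), (7, 8), (14, 16), (0, 16)]:
            np.testing.assert_allclose(cmap[x], context_features(pm, x, cfg))

    def test_outside_map_rejected(self):
        pm = ProbabilityMap(probs=np.zeros((5, 5)), iteration=0)
        with pytest.raises(IndexError):
            context_features(pm, (5, 0), ContextConfig(radii=(1,)))


class TestTrainCascade:
    def test_u0_single_stage(self):
        casc = train_cascade(tiny_cases(), U=0, glcm_config=TINY_GLCM,
                             context_config=TINY_CTX, n_per_class=200, n_rounds=10)
        assert casc.n_iterations == 0
        assert len(casc.stages) == 1
        assert casc.stages[0].n_features == TINY_GLCM.n_features

    def test_stage_feature_lengths(self, tiny_cascade):
        n_app = TINY_GLCM.n_features
        n_ctx = TINY_CTX.n_features
        assert tiny_cascade.stages[0].n_features == n_app
        assert tiny_cascade.stages[1].n_features == n_app + n_ctx

    def test_deterministic(self):
        kw = dict(U=1, glcm_config=TINY_GLCM, context_config=TINY_CTX,
                  n_per_class=150, n_rounds=8, rng_seed=5)
        a = train_cascade(tiny_cases(), **kw)
        b = train_cascade(tiny_cases(), **kw)
        for sa, sb in zip(a.stages, b.stages):
            assert sa.stumps == sb.stumps
            assert sa.weights == sb.weights

    def test_training_cross_entropy_improves_over_stages(self):
        """On a two-texture phantom set the cascade's final stage fits
        the training pixels at least as well as the appearance-only
        stage (mean cross-entropy does not increase)."""
        cases = tiny_cases(n=2, seed=12)
        casc = train_cascade(cases, U=2, glcm_config=TINY_GLCM,
                             context_config=TINY_CTX, n_per_class=300,
                             n_rounds=20, rng_seed=12)
        ces = []
        for case in cases:
            amap = appearance_feature_map(case.image, TINY_GLCM)
            from liverseg.cascade import _stage_map, context_feature_map

            pm = _stage_map(casc.stages[0], amap, 0)
            y = case.label_map.astype(bool)
            stage_ces = []
            eps = 1e-9
            p = np.clip(pm.probs, eps, 1 - eps)
            stage_ces.append(-np.mean(np.where(y, np.log(p), np.log1p(-p))))
            for u, st in enumerate(casc.stages[1:], 1):
                feats = np.concatenate(
                    [amap, context_feature_map(pm, TINY_CTX)], axis=2)
                pm = _stage_map(st, feats, u)
                p = np.clip(pm.probs, eps, 1 - eps)
                stage_ces.append(-np.mean(np.where(y, np.log(p), np.log1p(-p))))
            ces.append(stage_ces)
        mean_ce = np.mean(ces, axis=0)
        assert mean_ce[-1] <= mean_ce[0]

    def test_single_class_case_rejected_with_stage(self):
        bad = TrainingCase(image=np.zeros((64, 64)),
                           label_map=np.zeros((64, 64), dtype=np.uint8), id="empty")
        with pytest.raises(ValueError):
            train_cascade([bad], U=0, glcm_config=TINY_GLCM, n_per_class=50)


class TestApplyCascade:
    def test_u0_equals_stage0_probability(self):
        casc = train_cascade(tiny_cases(), U=0, glcm_config=TINY_GLCM,
                             context_config=TINY_CTX, n_per_class=200, n_rounds=10)
        img = tiny_cases(seed=9)[0].image
        pm = apply_cascade(img, casc)
        amap = appearance_feature_map(img, TINY_GLCM)
        H, W, F = amap.shape
        expect = margin_to_prob(casc.stages[0].margin(amap.reshape(-1, F))).reshape(H, W)
        np.testing.assert_allclose(pm.probs, expect)
        assert pm.iteration == 0

    def test_probabilities_in_unit_interval_every_stage(self, tiny_cascade):
        img = tiny_cases(seed=7)[0].image
        pm = apply_cascade(img, tiny_cascade)
        assert pm.probs.min() >= 0.0 and pm.probs.max() <= 1.0

    def test_infinite_tol_stops_after_trained_stages(self, tiny_cascade):
        img = tiny_cases(seed=7)[0].image
        pm = apply_cascade(img, tiny_cascade, max_extra_iters=5, tol=np.inf)
        pm2 = apply_cascade(img, tiny_cascade, max_extra_iters=0)
        assert pm.iteration == tiny_cascade.n_iterations
        np.testing.assert_array_equal(pm.probs, pm2.probs)

    def test_determinism_of_application(self, tiny_cascade):
        img = tiny_cases(seed=8)[0].image
        a = apply_cascade(img, tiny_cascade)
        b = apply_cascade(img, tiny_cascade)
        np.testing.assert_array_equal(a.probs, b.probs)


class TestSerialization:
    def test_round_trip(self, tiny_cascade, tmp_path):
        path = tmp_path / "cascade.json"
        save_cascade(tiny_cascade, path)
        loaded = load_cascade(path)
        assert loaded.stages == tiny_cascade.stages
        assert loaded.glcm_config == tiny_cascade.glcm_config
        assert loaded.context_config == tiny_cascade.context_config
        img = tiny_cases(seed=6)[0].image
        np.testing.assert_array_equal(
            apply_cascade(img, loaded).probs, apply_cascade(img, tiny_cascade).probs)

    def test_version_mismatch_rejected(self, tiny_cascade, tmp_path):
        import json

        path = tmp_path / "cascade.json"
        save_cascade(tiny_cascade, path)
        doc = json.loads(path.read_text())
        doc["format_version"] = 999
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="version"):
            load_cascade(path)
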