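"""Synthetic slide generator: geometry distributions, rendering, study grid."""

import numpy as np
import pytest

from decmscore.detect import DetectConfig, detect_suspicious_points, to_analysis_channel
from decmscore.morphometry import feret_diameters, measure_object
from decmscore.simulate import (ObjectClassParams, PlacementError, SceneConfig,
                                default_class_params, default_study_config,
                                generate_study, render_slide,
                                sample_object_geometry)


class TestObjectGeometry:
    def test_nucleus_ratio_recovered(self, rng):
        """Measured Feret ratio of sampled nuclei tracks the configured mean."""
        params = ObjectClassParams("nucleus_1", (400.0, 60.0), (3.0, 0.3),
                                   (110.0, 10.0), curvature=0.35)
        ratios = []
        for _ in range(100):
            mask = sample_object_geometry(params, rng)
            feret, minferet = feret_diameters(mask)
            ratios.append(feret / minferet)
        assert np.mean(ratios) == pytest.approx(3.0, rel=0.20)

    def test_dust_is_near_round(self, rng):
        params = default_class_params("he")["dust"]
        ratios = []
        for _ in range(100):
            feret, minferet = feret_diameters(sample_object_geometry(params, rng))
            ratios.append(feret / minferet)
        ratios = np.asarray(ratios)
        assert np.mean((ratios >= 1.0) & (ratios <= 1.5)) >= 0.95

    def test_feret_at_least_minferet(self, rng):
        for label in ("nucleus_1", "dust"):
            params = default_class_params("feulgen")[label]
            for _ in range(20):
                feret, minferet = feret_diameters(sample_object_geometry(params, rng))
                assert feret >= minferet

    def test_unsamplable_area_errors(self, rng):
        params = ObjectClassParams("dust", (-50.0, 1.0), (1.05, 0.01), (60.0, 5.0))
        with pytest.raises(ValueError):
            sample_object_geometry(params, rng)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ObjectClassParams("dust", (100.0, -1.0), (1.05, 0.01), (60.0, 5.0))
        with pytest.raises(ValueError):
            ObjectClassParams("dust", (100.0, 1.0), (0.9, 0.01), (60.0, 5.0))
        with pytest.raises(ValueError):
            ObjectClassParams("dust", (100.0, 1.0), (1.05, 0.01), (300.0, 5.0))


class TestRenderSlide:
    def test_ground_truth_counts_match_config(self, he_slide):
        by_class = {}
        for o in he_slide.objects:
            by_class[o.class_label] = by_class.get(o.class_label, 0) + 1
        assert by_class == he_slide.config.counts

    def test_rendering_is_deterministic(self):
        cfg = SceneConfig(stain="acetocarmine",
                          counts={"nucleus_2": 5, "dust": 5}, rng_seed=42)
        a, b = render_slide(cfg), render_slide(cfg)
        assert np.array_equal(a.image, b.image)
        assert [o.bbox for o in a.objects] == [o.bbox for o in b.objects]

    def test_objects_disjoint_and_in_bounds(self, he_slide):
        h, w = he_slide.image.shape[:2]
        occupancy = np.zeros((h, w), bool)
        for o in he_slide.objects:
            assert o.mask.any()
            full = o.full_mask((h, w))
            assert full.sum() == o.mask.sum()  # within bounds
            assert not (occupancy & full).any()
            occupancy |= full
        assert occupancy.sum() == sum(o.area for o in he_slide.objects)

    def test_dust_darker_than_nuclei_in_brightfield(self, he_slide):
        channel = to_analysis_channel(he_slide.image, "he")
        shape = channel.shape
        grays = {"nucleus": [], "dust": []}
        for o in he_slide.objects:
            kind = "dust" if o.class_label == "dust" else "nucleus"
            grays[kind].append(measure_object(o.full_mask(shape), channel).avg_gray)
        assert np.mean(grays["dust"]) < np.mean(grays["nucleus"])

    def test_dapi_dust_invisible_to_detection(self, dapi_slide):
        """A DAPI scene seeded with 20 dust particles yields zero dust detections."""
        channel = to_analysis_channel(dapi_slide.image, "dapi")
        points = detect_suspicious_points(channel, DetectConfig(stain="dapi"))
        nuclei = dapi_slide.objects_of("nucleus_1", "nucleus_2")
        assert len(dapi_slide.objects_of("dust")) == 20
        assert len(points) == len(nuclei)

    def test_overcrowded_scene_raises_placement_error(self):
        cfg = SceneConfig(stain="he", image_size=(96, 96),
                          counts={"nucleus_1": 60}, placement_retries=10)
        with pytest.raises(PlacementError, match="nucleus_1"):
            render_slide(cfg)


class TestParameterRecovery:
    @pytest.mark.parametrize("stain", ["he", "dapi"])
    def test_measured_means_track_generative_means(self, stain):
        """Generator-to-morphometry closure: area / ratio / gray within 20%."""
        feats = {c: [] for c in ("nucleus_1", "dust")}
        for seed in range(12):
            cfg = SceneConfig(stain=stain, counts={"nucleus_1": 9, "dust": 9},
                              rng_seed=seed)
            slide = render_slide(cfg)
            channel = to_analysis_channel(slide.image, stain)
            for o in slide.objects:
                fv = measure_object(o.full_mask(channel.shape), channel)
                feats[o.class_label].append((fv.area, fv.feret_ratio, fv.avg_gray))
        params = cfg.class_params
        for label, rows in feats.items():
            if stain == "dapi" and label == "dust":
                continue  # invisible by design: nothing to recover
            assert len(rows) >= 100
            measured = np.asarray(rows).mean(axis=0)
            configured = (params[label].area_dist[0],
                          params[label].feret_ratio_dist[0],
                          params[label].gray_dist[0])
            for got, want in zip(measured, configured):
                assert got == pytest.approx(want, rel=0.20)


class TestStudyGrid:
    def test_default_study_is_300_slides(self):
        study = generate_study(default_study_config(master_seed=1))
        assert len(study) == 5 * 4 * 15

    def test_per_slide_seeds_reproducible(self):
        a = generate_study(default_study_config(master_seed=9))
        b = generate_study(default_study_config(master_seed=9))
        assert [s.scene.rng_seed for s in a.specs] == [s.scene.rng_seed for s in b.specs]
        assert [s.scene.counts for s in a.specs] == [s.scene.counts for s in b.specs]
        c = generate_study(default_study_config(master_seed=10))
        assert [s.scene.rng_seed for s in a.specs] != [s.scene.rng_seed for s in c.specs]

    def test_negative_groups_contain_no_nuclei(self):
        study = generate_study(default_study_config(master_seed=2, n_sections=2))
        for spec in study.specs:
            if not spec.is_positive:
                assert spec.scene.counts.get("nucleus_1", 0) == 0
                assert spec.scene.counts.get("nucleus_2", 0) == 0
                slide = study.render(spec)
                assert slide.objects_of("nucleus_1", "nucleus_2") == []
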