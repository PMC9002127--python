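"""Phantom generator: determinism, geometry fidelity, negatives, datasets."""

import json

import numpy as np
import pytest
from scipy.stats import chisquare

from fetalhc.encoding import encode_targets, read_annotations
from fetalhc.geometry import enclosing_box
from fetalhc.inference import decode_detections, output_from_targets
from fetalhc.phantom import (
    PIXEL_SIZE_RANGE_MM,
    PhantomConfig,
    _ring_distance,
    generate_dataset,
    generate_phantom,
    generate_samples,
    make_negative,
)
from fetalhc.ssr import SSRConfig


class TestGeneratePhantom:
    def test_same_seed_is_byte_identical(self):
        cfg = PhantomConfig(seed=5)
        a = generate_phantom(cfg, seed=5)
        b = generate_phantom(cfg, seed=5)
        assert np.array_equal(a.image, b.image)
        assert a.annotation.ellipse == b.annotation.ellipse

    def test_ring_matches_analytic_band(self, clean_phantom):
        # compare at half maximum: the rendered Gaussian ring profile above
        # half its amplitude should coincide with the analytic band of
        # half-width sigma_r * sqrt(2 ln 2)
        sample, cfg = clean_phantom
        e = sample.annotation.ellipse
        d = _ring_distance(e, sample.image.shape)
        sigma_r = cfg.ring_thickness / 2.0
        band = np.abs(d) <= sigma_r * np.sqrt(2 * np.log(2))
        bg = cfg.background_level
        lit = sample.image.astype(float) > bg + (sample.image.max() - bg) / 2.0
        inter = np.count_nonzero(band & lit)
        union = np.count_nonzero(band | lit)
        assert inter / union > 0.95

    def test_gap_fraction_removes_arc_length(self):
        base = PhantomConfig(speckle=0.0, background_texture=0.0, background_level=0.0,
                             gap_fraction=0.0)
        gapped = PhantomConfig(speckle=0.0, background_texture=0.0, background_level=0.0,
                               gap_fraction=0.4)
        counts = []
        for cfg in (base, gapped):
            total = 0
            for seed in range(5):
                img = generate_phantom(cfg, seed=seed).image
                total += np.count_nonzero(img > 40)
            counts.append(total)
        assert counts[1] / counts[0] == pytest.approx(0.6, abs=0.05)

    def test_annotation_within_stated_ranges(self):
        cfg = PhantomConfig(seed=0)
        for seed in range(30):
            s = generate_phantom(cfg, seed=seed)
            e = s.annotation.ellipse
            lo, hi = PIXEL_SIZE_RANGE_MM
            assert lo <= s.annotation.pixel_size_mm <= hi
            assert cfg.semi_axis_range[0] <= e.a <= cfg.semi_axis_range[1]
            assert cfg.eccentricity_range[0] - 1e-9 <= e.b / e.a <= 1.0
            box = enclosing_box(e)
            h, w = cfg.image_size
            assert box.bx - box.w / 2 >= 0 and box.bx + box.w / 2 <= w - 1
            assert box.by - box.h / 2 >= 0 and box.by + box.h / 2 <= h - 1

    def test_angles_uniform_over_range(self):
        cfg = PhantomConfig(seed=1)
        master = np.random.default_rng(1)
        thetas = [generate_phantom(cfg, seed=int(s)).annotation.ellipse.theta
                  for s in master.integers(0, 2**31 - 1, size=1000)]
        counts, _ = np.histogram(thetas, bins=9, range=(0, 180))
        assert chisquare(counts).pvalue > 0.01

    def test_unfittable_config_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(image_size=(64, 64), semi_axis_range=(30.0, 40.0))

    def test_generated_annotations_round_trip_codec(self, rng):
        cfg = PhantomConfig(seed=9)
        for seed in range(20):
            s = generate_phantom(cfg, seed=seed)
            ts = encode_targets(s.annotation, 4, cfg.image_size)
            det = decode_detections(output_from_targets([ts]), SSRConfig())[0].ellipse
            e = s.annotation.ellipse
            assert det.cx == pytest.approx(e.cx, abs=1e-9)
            assert det.a == pytest.approx(e.a, abs=1e-9)
            d = abs(det.theta - e.theta)
            assert min(d, 180 - d) < 0.1


class TestMakeNegative:
    def test_remove_fill_blends_with_background(self, rng):
        cfg = PhantomConfig(seed=3, gap_fraction=0.0)
        pos = generate_phantom(cfg, seed=3)
        neg = make_negative(pos, "remove_fill", rng, cfg)
        e = pos.annotation.ellipse
        d = _ring_distance(e, pos.image.shape)
        former_ring = np.abs(d) <= cfg.ring_thickness
        surround = (np.abs(d) > 4 * cfg.ring_thickness) & (np.abs(d) < 8 * cfg.ring_thickness)
        inside_mean = float(neg.image[former_ring].mean())
        surround_mean = float(neg.image[surround].mean())
        assert abs(inside_mean - surround_mean) / surround_mean < 0.10
        assert neg.annotation.is_negative and neg.annotation.ellipse is None

    def test_random_crop_obeys_iou_rule(self, rng):
        cfg = PhantomConfig(seed=4)
        pos = generate_phantom(cfg, seed=4)
        neg = make_negative(pos, "random_crop", rng, cfg)
        assert neg.image.shape == pos.image.shape
        assert neg.annotation.is_negative

    def test_negative_input_rejected(self, rng):
        cfg = PhantomConfig(seed=5)
        neg = make_negative(generate_phantom(cfg, seed=5), "remove_fill", rng, cfg)
        with pytest.raises(ValueError):
            make_negative(neg, "remove_fill", rng, cfg)

    def test_unknown_mode_rejected(self, rng):
        cfg = PhantomConfig(seed=6)
        with pytest.raises(ValueError):
            make_negative(generate_phantom(cfg, seed=6), "mirror", rng, cfg)


class TestGenerateDataset:
    def test_files_counts_and_flags(self, tmp_path):
        cfg = PhantomConfig(seed=21)
        manifest = generate_dataset(10, 5, cfg, tmp_path / "ds")
        anns = read_annotations(tmp_path / "ds" / "annotations.csv")
        assert len(anns) == 15
        assert sum(a.is_negative for a in anns) == 5
        assert len(manifest["samples"]) == 15
        assert (tmp_path / "ds" / "manifest.json").exists()
        assert len(list((tmp_path / "ds").glob("*.png"))) == 15

    def test_regeneration_is_byte_identical(self, tmp_path):
        cfg = PhantomConfig(seed=22)
        generate_dataset(5, 2, cfg, tmp_path / "a")
        generate_dataset(5, 2, cfg, tmp_path / "b")
        csv_a = (tmp_path / "a" / "annotations.csv").read_bytes()
        csv_b = (tmp_path / "b" / "annotations.csv").read_bytes()
        assert csv_a == csv_b
        img = next((tmp_path / "a").glob("*.png")).name
        assert (tmp_path / "a" / img).read_bytes() == (tmp_path / "b" / img).read_bytes()

    def test_manifest_echoes_config(self, tmp_path):
        cfg = PhantomConfig(seed=23, gap_fraction=0.3)
        generate_dataset(2, 0, cfg, tmp_path / "ds")
        manifest = json.loads((tmp_path / "ds" / "manifest.json").read_text())
        assert manifest["config"]["gap_fraction"] == 0.3
        assert manifest["config"]["seed"] == 23


def test_generate_samples_mixes_negative_modes():
    samples = generate_samples(4, 4, PhantomConfig(seed=31))
    negs = [s for s in samples if s.annotation.is_negative]
    assert len(negs) == 4
    assert any(n.annotation.image_id.endswith("remove_fill") for n in negs)
    assert any(n.annotation.image_id.endswith("random_crop") for n in negs)
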