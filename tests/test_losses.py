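"""Training losses: focal, smooth-L1, gathered regression terms, composition."""

import math

import numpy as np
import pytest

from fetalhc.autodiff import Tensor
from fetalhc.encoding import Annotation, encode_targets
from fetalhc.geometry import Ellipse
from fetalhc.losses import (
    LossBreakdown,
    LossConfig,
    focal_loss,
    focal_loss_logits,
    regression_losses,
    smooth_l1,
    total_loss,
)
from fetalhc.network import DetectionOutput
from fetalhc.ssr import SSRConfig, ssr_encode_reference


class TestFocalLoss:
    def test_single_pixel_positive_branch(self):
        # P = 1, rho = 0.5, N = 1: -(1 - 0.5)^2 ln 0.5
        val = focal_loss(np.array([[0.5]]), np.array([[1.0]]), 1)
        assert val == pytest.approx(-0.25 * math.log(0.5), abs=1e-9)
        assert val == pytest.approx(0.17329, abs=1e-4)

    def test_single_pixel_negative_branch(self):
        # P = 0 so (1-P)^4 = 1, rho = 0.5: -(0.5)^2 ln(1 - 0.5)
        val = focal_loss(np.array([[0.5]]), np.array([[0.0]]), 1)
        assert val == pytest.approx(0.17329, abs=1e-4)

    def test_perfect_prediction_is_tiny(self):
        gt = np.zeros((8, 8))
        gt[3, 4] = 1.0
        assert focal_loss(gt.copy(), gt, 1) < 1e-5

    def test_monotone_improvement(self, rng):
        gt = np.zeros((8, 8))
        gt[3, 4] = 1.0
        worse = np.full_like(gt, 0.4)
        better = gt * 0.9 + 0.05 * worse
        assert focal_loss(better, gt, 1) < focal_loss(worse, gt, 1)
        assert focal_loss(worse, gt, 1) >= 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(np.zeros((2, 2)), np.zeros((3, 3)), 1)

    def test_logit_form_matches_probability_form(self, rng):
        logits = rng.normal(0, 2, size=(2, 1, 6, 6))
        gt = np.zeros((2, 1, 6, 6))
        gt[0, 0, 2, 3] = 1.0
        gt[1, 0, 4, 4] = 1.0
        probs = 1 / (1 + np.exp(-logits))
        a = float(focal_loss_logits(Tensor(logits), gt, 2).data)
        b = focal_loss(probs, gt, 2)
        assert a == pytest.approx(b, rel=1e-5)

    def test_logit_form_gradient_survives_saturation(self):
        z = Tensor(np.array([[-40.0]]), requires_grad=True)  # sigmoid == 0 in float64
        focal_loss_logits(z, np.array([[1.0]]), 1).backward()
        assert np.isfinite(z.grad).all() and z.grad[0, 0] != 0.0


class TestSmoothL1:
    @pytest.mark.parametrize("x,expected", [
        (0.0, 0.0), (0.5, 0.125), (2.0, 1.5), (-2.0, 1.5), (-0.5, 0.125),
    ])
    def test_branch_values(self, x, expected):
        assert smooth_l1(x) == pytest.approx(expected, abs=1e-12)

    def test_continuity_at_transition(self):
        assert smooth_l1(1.0 - 1e-9) == pytest.approx(smooth_l1(1.0 + 1e-9), abs=1e-8)

    def test_gradient_bounded_by_one(self, rng):
        x = Tensor(rng.uniform(-10, 10, size=100), requires_grad=True)
        smooth_l1(x).sum().backward()
        assert np.all(np.abs(x.grad) <= 1.0 + 1e-9)


def _make_output(grid=24, offset=(0.25, 0.75), axes=(10.0, 6.0), theta=34.5, n_images=1):
    """Constant head maps so values at any gathered cell are known."""
    cfg = SSRConfig()
    pred = ssr_encode_reference(theta, cfg)
    probs = np.concatenate(pred.probs)
    return DetectionOutput(
        heatmap=Tensor(np.zeros((n_images, 1, grid, grid))),
        offset=Tensor(np.broadcast_to(np.array(offset)[None, :, None, None],
                                      (n_images, 2, grid, grid)).copy()),
        axes=Tensor(np.broadcast_to(np.array(axes)[None, :, None, None],
                                    (n_images, 2, grid, grid)).copy()),
        ssr_probs=Tensor(np.broadcast_to(probs[None, :, None, None],
                                         (n_images, cfg.total_bins, grid, grid)).copy()),
        ssr_eta=Tensor(np.zeros((n_images, cfg.total_bins, grid, grid))),
        ssr_delta=Tensor(np.zeros((n_images, cfg.n_stages))),
    )


def _target(e: Ellipse):
    ann = Annotation(image_id="t", ellipse=e, pixel_size_mm=0.1)
    return encode_targets(ann, 4, (96, 96))


class TestRegressionLosses:
    def test_zero_residuals_give_zero_terms(self):
        e = Ellipse(cx=41.0, cy=51.0, a=10.0, b=6.0, theta=34.5)
        out = _make_output(offset=(0.25, 0.75), axes=(10.0, 6.0), theta=34.5)
        terms = regression_losses(out, [_target(e)], SSRConfig())
        for name in ("offset", "axes", "angle", "kld"):
            assert float(terms[name].data) == pytest.approx(0.0, abs=1e-6)

    def test_offset_residual_value(self):
        e = Ellipse(cx=40.0, cy=51.0, a=10.0, b=6.0, theta=34.5)  # gt offset (0.0, 0.75)
        out = _make_output(offset=(0.5, 0.75))  # residual (0.5, 0)
        terms = regression_losses(out, [_target(e)], SSRConfig(),
                                  LossConfig(use_kld=False))
        assert float(terms["offset"].data) == pytest.approx(0.125, abs=1e-6)

    def test_axes_residuals_average_over_objects(self):
        # residuals (1, 0) and (0, 2) -> (0.5 + 1.5) / 2 = 1.0
        e1 = Ellipse(cx=41.0, cy=51.0, a=9.0, b=6.0, theta=34.5)
        e2 = Ellipse(cx=41.0, cy=51.0, a=10.0, b=4.0, theta=34.5)
        out = _make_output(axes=(10.0, 6.0), n_images=2)
        terms = regression_losses(out, [_target(e1), _target(e2)], SSRConfig(),
                                  LossConfig(use_kld=False))
        assert float(terms["axes"].data) == pytest.approx(1.0, abs=1e-6)

    def test_negative_only_batch_gives_zeros(self):
        neg = Annotation(image_id="n", ellipse=None, pixel_size_mm=0.1, is_negative=True)
        out = _make_output()
        terms = regression_losses(out, [encode_targets(neg, 4, (96, 96))], SSRConfig())
        assert all(float(t.data) == 0.0 for t in terms.values())

    def test_center_perturbation_raises_offset_and_kld_together(self):
        e = Ellipse(cx=41.0, cy=51.0, a=10.0, b=6.0, theta=34.5)
        base = regression_losses(_make_output(offset=(0.25, 0.75)), [_target(e)], SSRConfig())
        moved = regression_losses(_make_output(offset=(0.85, 0.75)), [_target(e)], SSRConfig())
        assert float(moved["offset"].data) > float(base["offset"].data)
        assert float(moved["kld"].data) > float(base["kld"].data)

    def test_angle_residual_uses_circular_difference(self):
        e = Ellipse(cx=41.0, cy=51.0, a=10.0, b=6.0, theta=179.0)
        out = _make_output(theta=0.5)  # 1.5 degrees away across the wrap
        circ = regression_losses(out, [_target(e)], SSRConfig(),
                                 LossConfig(use_kld=False, circular_angle=True))
        lin = regression_losses(out, [_target(e)], SSRConfig(),
                                LossConfig(use_kld=False, circular_angle=False))
        assert float(circ["angle"].data) == pytest.approx(smooth_l1(1.5), abs=1e-4)
        assert float(lin["angle"].data) > 100.0


class TestTotalLoss:
    def test_sum_of_parts(self):
        parts = LossBreakdown(heat=0.2, offset=0.1, axes=0.1, angle=0.05, kld=0.3, total=0.0)
        assert total_loss(parts) == pytest.approx(0.75)

    def test_all_zero(self):
        parts = LossBreakdown(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        assert total_loss(parts) == 0.0

    def test_nan_rejected_with_term_name(self):
        parts = LossBreakdown(heat=0.2, offset=float("nan"), axes=0.1, angle=0.0,
                              kld=0.0, total=0.0)
        with pytest.raises(FloatingPointError, match="offset"):
            total_loss(parts)
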