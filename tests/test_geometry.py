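"""Oriented-ellipse math: Gaussian embedding, KLD, perimeter, boxes, IOU."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from fetalhc.geometry import (
    AABox,
    Ellipse,
    Gaussian2D,
    ellipse_iou,
    ellipse_to_gaussian,
    enclosing_box,
    head_circumference,
    kld_gaussian,
    kld_loss,
)

from conftest import random_ellipse


def rotate_ellipse(e: Ellipse, phi_deg: float, about=(0.0, 0.0)) -> Ellipse:
    """Rigidly rotate an ellipse by phi degrees (same convention as the embedding)."""
    rad = math.radians(phi_deg)
    c, s = math.cos(rad), math.sin(rad)
    dx, dy = e.cx - about[0], e.cy - about[1]
    return Ellipse(
        cx=about[0] + c * dx - s * dy,
        cy=about[1] + s * dx + c * dy,
        a=e.a, b=e.b, theta=(e.theta + phi_deg) % 180.0,
    )


class TestEllipseType:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            Ellipse(cx=0, cy=0, a=1, b=2, theta=0)  # b > a
        with pytest.raises(ValueError):
            Ellipse(cx=0, cy=0, a=2, b=1, theta=180.0)
        with pytest.raises(ValueError):
            Ellipse(cx=float("nan"), cy=0, a=2, b=1, theta=0)

    def test_membership(self):
        e = Ellipse(cx=0, cy=0, a=3, b=1, theta=0)
        assert e.contains(2.9, 0.0)
        assert not e.contains(0.0, 2.9)


class TestGaussianEmbedding:
    def test_circle_is_isotropic(self):
        g = ellipse_to_gaussian(Ellipse(cx=0, cy=0, a=2, b=2, theta=0))
        assert np.allclose(g.mu, [0, 0])
        assert np.allclose(g.sigma, 4.0 * np.eye(2))

    def test_axis_aligned_eigenstructure(self):
        g = ellipse_to_gaussian(Ellipse(cx=0, cy=0, a=3, b=1, theta=0))
        vals, vecs = np.linalg.eigh(g.sigma)
        assert np.allclose(sorted(vals), [1.0, 9.0], atol=1e-10)
        major = vecs[:, np.argmax(vals)]
        assert abs(abs(major[0]) - 1.0) < 1e-10  # horizontal major axis

    def test_rotation_equivariance(self, rng):
        for _ in range(20):
            e = random_ellipse(rng)
            phi = rng.uniform(0, 180)
            g_rot = ellipse_to_gaussian(rotate_ellipse(e, phi, about=(e.cx, e.cy)))
            rad = math.radians(phi)
            r = np.array([[math.cos(rad), -math.sin(rad)], [math.sin(rad), math.cos(rad)]])
            expected = r @ ellipse_to_gaussian(e).sigma @ r.T
            assert np.allclose(g_rot.sigma, expected, atol=1e-8)

    def test_determinant_is_ab_squared(self, rng):
        for _ in range(50):
            e = random_ellipse(rng)
            g = ellipse_to_gaussian(e)
            assert np.isclose(np.linalg.det(g.sigma), (e.a * e.b) ** 2, rtol=1e-8)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            ellipse_to_gaussian(Ellipse(cx=0, cy=0, a=2, b=0, theta=0))


class TestKLD:
    def test_identity_is_zero(self, rng):
        for _ in range(10):
            e = random_ellipse(rng)
            g = ellipse_to_gaussian(e)
            assert abs(kld_gaussian(g, g)) < 1e-10

    def test_offset_circles_closed_form(self):
        # equal isotropic covariances: KLD = |d|^2 / (2 sigma^2)
        p = Gaussian2D(mu=[2, 0], sigma=4 * np.eye(2))
        t = Gaussian2D(mu=[0, 0], sigma=4 * np.eye(2))
        assert np.isclose(kld_gaussian(p, t), 0.5, atol=1e-12)

    def test_asymmetry(self):
        p = Gaussian2D(mu=[0, 0], sigma=np.diag([9.0, 1.0]))
        t = Gaussian2D(mu=[1, 0], sigma=np.diag([1.0, 1.0]))
        assert kld_gaussian(p, t) != pytest.approx(kld_gaussian(t, p))

    def test_nonnegative(self, rng):
        for _ in range(50):
            p = ellipse_to_gaussian(random_ellipse(rng))
            t = ellipse_to_gaussian(random_ellipse(rng))
            assert kld_gaussian(p, t) >= 0

    def test_rigid_invariance(self, rng):
        for _ in range(10):
            e1, e2 = random_ellipse(rng), random_ellipse(rng)
            phi = rng.uniform(0, 180)
            about = (rng.uniform(-5, 5), rng.uniform(-5, 5))
            d0 = kld_gaussian(ellipse_to_gaussian(e1), ellipse_to_gaussian(e2))
            d1 = kld_gaussian(
                ellipse_to_gaussian(rotate_ellipse(e1, phi, about)),
                ellipse_to_gaussian(rotate_ellipse(e2, phi, about)),
            )
            assert np.isclose(d0, d1, rtol=1e-8, atol=1e-8)


class TestKLDLoss:
    def test_identity_zero(self):
        e = Ellipse(cx=5, cy=5, a=3, b=2, theta=30)
        assert kld_loss(e, e) == pytest.approx(0.0, abs=1e-12)

    def test_offset_circles_value(self):
        p = Ellipse(cx=2, cy=0, a=2, b=2, theta=0)
        t = Ellipse(cx=0, cy=0, a=2, b=2, theta=0)
        assert kld_loss(p, t) == pytest.approx(1 - 1 / (1 + math.log(1.5)), abs=1e-10)

    def test_monotone_to_one(self):
        t = Ellipse(cx=0, cy=0, a=2, b=2, theta=0)
        losses = [kld_loss(Ellipse(cx=d, cy=0, a=2, b=2, theta=0), t)
                  for d in (1, 5, 25, 125, 625)]
        assert all(x < y for x, y in zip(losses, losses[1:]))
        assert losses[-1] < 1.0
        assert losses[-1] > 0.9


class TestHeadCircumference:
    @pytest.mark.parametrize("a,b,expected", [
        (1.0, 1.0, 2 * math.pi),
        (2.0, 1.0, math.pi * (9 - math.sqrt(35))),
        (1.0, 0.0, math.pi * (3 - math.sqrt(3))),
    ])
    def test_closed_form_values(self, a, b, expected):
        assert head_circumference(a, b) == pytest.approx(expected, rel=1e-12)

    def test_against_arc_length_integration(self, rng):
        for _ in range(20):
            a = rng.uniform(1, 50)
            b = a * rng.uniform(0.2, 1.0)
            exact, _ = quad(lambda t: math.hypot(a * math.sin(t), b * math.cos(t)),
                            0, 2 * math.pi, limit=200)
            assert head_circumference(a, b) == pytest.approx(exact, rel=5e-3)

    def test_rejects_bad_axes(self):
        with pytest.raises(ValueError):
            head_circumference(-1.0, 0.5)
        with pytest.raises(ValueError):
            head_circumference(1.0, 2.0)


class TestEnclosingBox:
    @pytest.mark.parametrize("theta,w,h", [
        (0.0, 6.0, 4.0),
        (90.0, 4.0, 6.0),
        (45.0, 2 * math.sqrt(6.5), 2 * math.sqrt(6.5)),
    ])
    def test_known_boxes(self, theta, w, h):
        box = enclosing_box(Ellipse(cx=1, cy=2, a=3, b=2, theta=theta))
        assert (box.bx, box.by) == (1, 2)
        assert box.w == pytest.approx(w, rel=1e-12)
        assert box.h == pytest.approx(h, rel=1e-12)

    def test_containment_is_tight(self, rng):
        t = np.linspace(0, 2 * math.pi, 10000)
        for _ in range(10):
            e = random_ellipse(rng)
            e = Ellipse(cx=0, cy=0, a=e.a, b=e.b, theta=e.theta)
            box = enclosing_box(e)
            psi = math.radians(e.psi_deg)
            bx = e.a * np.cos(t) * math.cos(psi) - e.b * np.sin(t) * math.sin(psi)
            by = e.a * np.cos(t) * math.sin(psi) + e.b * np.sin(t) * math.cos(psi)
            assert np.all(np.abs(bx) <= box.w / 2 + 1e-9)
            assert np.all(np.abs(by) <= box.h / 2 + 1e-9)
            # 1% shrink in either direction must cut off boundary points
            assert np.max(np.abs(bx)) > 0.99 * box.w / 2
            assert np.max(np.abs(by)) > 0.99 * box.h / 2


class TestEllipseIOU:
    def test_identity(self):
        e = Ellipse(cx=10, cy=10, a=5, b=3, theta=30)
        assert ellipse_iou(e, e) == pytest.approx(1.0, abs=1e-9)

    def test_concentric_circles(self):
        e1 = Ellipse(cx=0, cy=0, a=1, b=1, theta=0)
        e2 = Ellipse(cx=0, cy=0, a=2, b=2, theta=0)
        assert ellipse_iou(e1, e2, resolution=16) == pytest.approx(0.25, abs=0.005)

    def test_disjoint(self):
        e1 = Ellipse(cx=0, cy=0, a=2, b=1, theta=0)
        e2 = Ellipse(cx=10, cy=0, a=2, b=1, theta=90)
        assert ellipse_iou(e1, e2) == 0.0

    def test_resolution_convergence(self, rng):
        for _ in range(5):
            e1, e2 = random_ellipse(rng), random_ellipse(rng)
            coarse = ellipse_iou(e1, e2, resolution=4)
            fine = ellipse_iou(e1, e2, resolution=8)
            assert abs(coarse - fine) < 0.005

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            ellipse_iou(Ellipse(cx=0, cy=0, a=1, b=0, theta=0),
                        Ellipse(cx=0, cy=0, a=1, b=1, theta=0))


def test_aabox_requires_positive_extent():
    with pytest.raises(ValueError):
        AABox(bx=0, by=0, w=0, h=1)
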