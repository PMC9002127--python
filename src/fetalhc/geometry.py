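"""Oriented-ellipse mathematics.

The unit of annotation and prediction everywhere in this package is an
oriented ellipse ``(cx, cy, a, b, theta)``: center in image pixel
coordinates (x right, y down, 0-based pixel centers), *semi*-major and
*semi*-minor axis lengths in pixels, and an angle ``theta`` in degrees in
``[0, 180)`` measured between the short axis and the vertical direction.

Because the short axis is perpendicular to the long axis and the vertical
is perpendicular to the horizontal, ``theta`` equals the angle ``psi``
between the *major* axis and the horizontal (+x) direction in the image
frame.  :func:`theta_to_psi` owns this identity; all trigonometric code
below works with ``psi``.

This module provides the Gaussian embedding used by the KLD regression
loss (an oriented ellipse becomes the 2-D Gaussian whose covariance
square root is ``R(psi) @ diag(a, b) @ R(psi).T``), the Kullback-Leibler
divergence between such Gaussians and the bounded loss derived from it,
the Ramanujan closed form for the ellipse perimeter (the head
circumference), the smallest axis-aligned enclosing box, and a rasterized
IOU oracle for rotated ellipses (exact rotated-ellipse overlap has no
convenient closed form, so evaluation uses dense membership tests).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Ellipse",
    "Gaussian2D",
    "AABox",
    "theta_to_psi",
    "ellipse_to_gaussian",
    "kld_gaussian",
    "kld_loss",
    "head_circumference",
    "enclosing_box",
    "ellipse_iou",
]


@dataclass(frozen=True)
class Ellipse:
    """Oriented ellipse: center (px), semi-axes (px), angle (deg in [0, 180))."""

    cx: float
    cy: float
    a: float
    b: float
    theta: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.cx) and math.isfinite(self.cy)):
            raise ValueError("ellipse center must be finite")
        if not (self.a >= self.b >= 0.0):
            raise ValueError(f"require a >= b >= 0, got a={self.a}, b={self.b}")
        if not (0.0 <= self.theta < 180.0):
            raise ValueError(f"theta must lie in [0, 180), got {self.theta}")

    @property
    def psi_deg(self) -> float:
        """Major-axis angle from the +x axis, degrees."""
        return theta_to_psi(self.theta)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized membership test for points (x, y) in pixels."""
        psi = math.radians(self.psi_deg)
        dx = np.asarray(x, dtype=float) - self.cx
        dy = np.asarray(y, dtype=float) - self.cy
        u = dx * math.cos(psi) + dy * math.sin(psi)
        v = -dx * math.sin(psi) + dy * math.cos(psi)
        if self.a == 0.0 or self.b == 0.0:
            return np.zeros(np.broadcast(dx, dy).shape, dtype=bool)
        return (u / self.a) ** 2 + (v / self.b) ** 2 <= 1.0


@dataclass(frozen=True)
class Gaussian2D:
    """2-D Gaussian with mean ``mu`` (px) and SPD covariance ``sigma`` (px^2)."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float).reshape(2)
        sigma = np.asarray(self.sigma, dtype=float).reshape(2, 2)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        if not np.allclose(sigma, sigma.T, atol=1e-9):
            raise ValueError("covariance must be symmetric")
        eigvals = np.linalg.eigvalsh(sigma)
        if np.any(eigvals <= 0):
            raise ValueError(f"covariance must be positive definite, eigvals={eigvals}")


@dataclass(frozen=True)
class AABox:
    """Axis-aligned box: center (px) and full width/height (px)."""

    bx: float
    by: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError("box width and height must be positive")


def theta_to_psi(theta: float) -> float:
    """Map the stored angle (short axis vs. vertical) to the major-axis angle
    from horizontal.

    In the image frame the two measurements coincide numerically, so this
    is the identity; it exists so the convention lives in exactly one
    place.
    """
    return float(theta)


def _rotation(psi_rad: float) -> np.ndarray:
    c, s = math.cos(psi_rad), math.sin(psi_rad)
    return np.array([[c, -s], [s, c]])


def ellipse_to_gaussian(e: Ellipse) -> Gaussian2D:
    """Embed an oriented ellipse as a 2-D Gaussian.

    The covariance square root is ``M = R(psi) @ diag(a, b) @ R(psi).T``
    so that ``sigma = M @ M`` has eigenvalues ``a^2, b^2`` along the
    ellipse axes and ``det(M) = a*b``.

    Raises
    ------
    ValueError
        If the ellipse is degenerate (``b == 0``), since the covariance
        would be singular.
    """
    if e.b <= 0.0:
        raise ValueError("degenerate ellipse (b == 0) has singular covariance")
    psi = math.radians(e.psi_deg)
    r = _rotation(psi)
    m = r @ np.diag([e.a, e.b]) @ r.T
    return Gaussian2D(mu=np.array([e.cx, e.cy]), sigma=m @ m)


def kld_gaussian(p: Gaussian2D, t: Gaussian2D) -> float:
    """Kullback-Leibler divergence D(p || t) between two 2-D Gaussians.

    ``0.5 (mu_p - mu_t)^T S_t^{-1} (mu_p - mu_t) + 0.5 Tr(S_t^{-1} S_p)
    + 0.5 ln(|S_t| / |S_p|) - 1``; nonnegative, zero iff ``p == t``.
    """
    det_t = float(np.linalg.det(t.sigma))
    det_p = float(np.linalg.det(p.sigma))
    if det_t <= 0:
        raise ValueError("target covariance is singular")
    inv_t = np.linalg.inv(t.sigma)
    d = p.mu - t.mu
    term_mu = 0.5 * float(d @ inv_t @ d)
    term_tr = 0.5 * float(np.trace(inv_t @ p.sigma))
    term_ln = 0.5 * math.log(det_t / det_p)
    return term_mu + term_tr + term_ln - 1.0


def kld_loss(p: Ellipse, t: Ellipse) -> float:
    """Bounded regression loss ``1 - 1/(1 + ln(Dkl + 1))`` in ``[0, 1)``.

    ``Dkl`` is the divergence of the predicted ellipse's Gaussian from the
    target's; the log is natural.  Strictly increasing in ``Dkl`` and
    zero iff the ellipses coincide.
    """
    dkl = kld_gaussian(ellipse_to_gaussian(p), ellipse_to_gaussian(t))
    dkl = max(dkl, 0.0)  # guard tiny negative round-off at identity
    return 1.0 - 1.0 / (1.0 + math.log1p(dkl))


def head_circumference(a: float, b: float) -> float:
    """Ellipse perimeter by the Ramanujan approximation.

    ``pi * (3(a+b) - sqrt((3a+b)(a+3b)))`` for *semi*-axes ``a >= b >= 0``.
    Callers convert pixels to millimetres with the pixel size first, so
    passing semi-axes in mm yields the head circumference in mm.
    """
    if a < 0 or b < 0:
        raise ValueError("semi-axes must be nonnegative")
    if b > a:
        raise ValueError("require a >= b")
    return math.pi * (3.0 * (a + b) - math.sqrt((3.0 * a + b) * (a + 3.0 * b)))


def enclosing_box(e: Ellipse) -> AABox:
    """Smallest axis-aligned rectangle containing the ellipse.

    ``w = 2 sqrt(a^2 cos^2 psi + b^2 sin^2 psi)``,
    ``h = 2 sqrt(a^2 sin^2 psi + b^2 cos^2 psi)``; the box center is the
    ellipse center by symmetry.
    """
    psi = math.radians(e.psi_deg)
    c2, s2 = math.cos(psi) ** 2, math.sin(psi) ** 2
    w = 2.0 * math.sqrt(e.a**2 * c2 + e.b**2 * s2)
    h = 2.0 * math.sqrt(e.a**2 * s2 + e.b**2 * c2)
    return AABox(bx=e.cx, by=e.cy, w=w, h=h)


def ellipse_iou(e1: Ellipse, e2: Ellipse, resolution: float = 4.0) -> float:
    """Rasterized intersection-over-union of two oriented ellipses.

    Membership is tested on a regular grid of ``resolution`` cells per
    pixel covering both enclosing boxes.  Rotated-ellipse overlap has no
    practical closed form, so this dense oracle is the package's overlap
    measure for evaluation and for negative-sample screening.

    Parameters
    ----------
    resolution
        Grid cells per pixel along each axis.  Should be high enough that
        each ellipse covers at least ~100 cells.
    """
    if e1.a * e1.b == 0 or e2.a * e2.b == 0:
        raise ValueError("zero-area ellipse has undefined IOU")
    b1, b2 = enclosing_box(e1), enclosing_box(e2)
    x_lo = min(b1.bx - b1.w / 2, b2.bx - b2.w / 2)
    x_hi = max(b1.bx + b1.w / 2, b2.bx + b2.w / 2)
    y_lo = min(b1.by - b1.h / 2, b2.by - b2.h / 2)
    y_hi = max(b1.by + b1.h / 2, b2.by + b2.h / 2)
    step = 1.0 / resolution
    xs = np.arange(x_lo + step / 2, x_hi, step)
    ys = np.arange(y_lo + step / 2, y_hi, step)
    gx, gy = np.meshgrid(xs, ys)
    m1 = e1.contains(gx, gy)
    m2 = e2.contains(gx, gy)
    union = np.count_nonzero(m1 | m2)
    if union == 0:
        return 0.0
    return float(np.count_nonzero(m1 & m2) / union)
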