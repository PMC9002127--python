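"""Data augmentation with consistent transformation of ellipse annotations.

The discrete parameter grids are: rotation in [-30, 30] degrees at a 10
degree interval, isotropic scaling in [0.85, 1.15] at 0.05, gamma in
[0.5, 1.5] at 0.1, and horizontal flipping.  Geometric ops transform the
image about its center and update the annotation in lockstep: rotation
moves the ellipse center and subtracts the rotation angle from theta
(mod 180), scaling multiplies center offsets and semi-axes by the factor
and divides the pixel size by it (so HC in mm is invariant), a flip
mirrors cx and maps theta to 180 - theta, and gamma leaves the
annotation untouched.  The rotation handedness matches
``skimage.transform.rotate`` and is pinned by a mask-overlay test rather
than asserted from convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import replace
from itertools import product

import numpy as np
from skimage import exposure
from skimage.transform import rotate as _sk_rotate
from skimage.transform import rescale as _sk_rescale

from .encoding import Annotation
from .geometry import Ellipse, enclosing_box
from .phantom import PhantomSample

__all__ = ["ROTATION_GRID", "SCALE_GRID", "GAMMA_GRID", "augment", "expand_training_set"]

log = logging.getLogger(__name__)

ROTATION_GRID = tuple(float(x) for x in range(-30, 31, 10))  # 7 values
SCALE_GRID = tuple(round(0.85 + 0.05 * i, 2) for i in range(7))  # 0.85 .. 1.15
GAMMA_GRID = tuple(round(0.5 + 0.1 * i, 1) for i in range(11))  # 0.5 .. 1.5


def _ellipse_in_frame(e: Ellipse, shape: tuple[int, int]) -> bool:
    h, w = shape
    box = enclosing_box(e)
    return (box.bx - box.w / 2 >= 0 and box.bx + box.w / 2 <= w - 1
            and box.by - box.h / 2 >= 0 and box.by + box.h / 2 <= h - 1)


def _rotate_image(img: np.ndarray, phi: float) -> np.ndarray:
    out = _sk_rotate(img.astype(np.float64), phi, center=None, order=1,
                     mode="constant", cval=float(np.median(img)), preserve_range=True)
    return np.clip(out, 0, 255).astype(np.uint8)


def _scale_image(img: np.ndarray, sigma: float) -> np.ndarray:
    h, w = img.shape
    scaled = _sk_rescale(img.astype(np.float64), sigma, order=1, preserve_range=True,
                         anti_aliasing=sigma < 1.0)
    sh, sw = scaled.shape
    out = np.full((h, w), float(np.median(img)))
    # paste/crop so the image center is preserved
    y0 = (sh - h) // 2
    x0 = (sw - w) // 2
    if sigma >= 1.0:
        out = scaled[y0 : y0 + h, x0 : x0 + w]
    else:
        oy, ox = (h - sh) // 2, (w - sw) // 2
        out[oy : oy + sh, ox : ox + sw] = scaled
    return np.clip(out, 0, 255).astype(np.uint8)


def augment(sample: PhantomSample, kind: str, value: float | None = None,
            rng: np.random.Generator | None = None, strict: bool = True) -> PhantomSample:
    """Apply one augmentation; returns a new sample with updated annotation.

    ``kind`` is one of ``rotate``, ``scale``, ``gamma``, ``flip``.  When
    ``value`` is None it is drawn from the corresponding discrete grid
    with ``rng``.  With ``strict`` a transformed ellipse leaving the
    frame raises; otherwise the sample is returned untransformed.
    """
    ann = sample.annotation
    e = ann.ellipse
    img = sample.image
    h, w = img.shape
    cx_img, cy_img = (w - 1) / 2.0, (h - 1) / 2.0

    if kind == "rotate":
        phi = float(value if value is not None else rng.choice(ROTATION_GRID))
        new_img = _rotate_image(img, phi)
        new_e = e
        if e is not None:
            # skimage rotates content counter-clockwise in display coords
            # (y down), i.e. points map by R(-phi) about the image center
            rad = math.radians(phi)
            dx, dy = e.cx - cx_img, e.cy - cy_img
            ncx = cx_img + dx * math.cos(rad) + dy * math.sin(rad)
            ncy = cy_img - dx * math.sin(rad) + dy * math.cos(rad)
            new_e = Ellipse(cx=ncx, cy=ncy, a=e.a, b=e.b, theta=(e.theta - phi) % 180.0)
        new_ann = replace(ann, ellipse=new_e)
    elif kind == "scale":
        sigma = float(value if value is not None else rng.choice(SCALE_GRID))
        new_img = _scale_image(img, sigma)
        new_e = e
        if e is not None:
            # rescale then center-crop/pad: a point at offset d from center maps to sigma*d
            ncx = cx_img + (e.cx - cx_img) * sigma
            ncy = cy_img + (e.cy - cy_img) * sigma
            new_e = Ellipse(cx=ncx, cy=ncy, a=e.a * sigma, b=e.b * sigma, theta=e.theta)
        new_ann = replace(ann, ellipse=new_e, pixel_size_mm=ann.pixel_size_mm / sigma)
    elif kind == "gamma":
        gamma = float(value if value is not None else rng.choice(GAMMA_GRID))
        new_img = (exposure.adjust_gamma(img.astype(np.float64) / 255.0, gamma) * 255.0)
        new_img = np.clip(new_img, 0, 255).astype(np.uint8)
        new_ann = ann
    elif kind == "flip":
        do_flip = bool(value) if value is not None else bool(rng.integers(0, 2))
        if not do_flip:
            return PhantomSample(image=img.copy(), annotation=ann, seed=sample.seed)
        new_img = np.ascontiguousarray(np.fliplr(img))
        new_e = e
        if e is not None:
            new_e = Ellipse(cx=(w - 1) - e.cx, cy=e.cy, a=e.a, b=e.b,
                            theta=(180.0 - e.theta) % 180.0)
        new_ann = replace(ann, ellipse=new_e)
    else:
        raise ValueError(f"unknown augmentation kind {kind!r}")

    if new_ann.ellipse is not None and not _ellipse_in_frame(new_ann.ellipse, (h, w)):
        if strict:
            raise ValueError(f"augmentation {kind}={value} pushed the ellipse out of frame")
        return PhantomSample(image=img.copy(), annotation=ann, seed=sample.seed)
    return PhantomSample(image=new_img, annotation=new_ann, seed=sample.seed)


def expand_training_set(samples: list[PhantomSample],
                        grid: dict[str, list] | None = None,
                        mode: str = "single",
                        rng: np.random.Generator | None = None) -> list[PhantomSample]:
    """Expand a dataset by the discrete augmentation grid.

    ``mode='single'`` applies each (kind, value) pair separately to each
    sample -- expansion factor = total grid size; ``mode='product'``
    composes one value from every kind -- expansion factor = product of
    grid sizes.  Out-of-frame results are skipped and counted.
    """
    if grid is None:
        grid = {"rotate": list(ROTATION_GRID), "scale": list(SCALE_GRID),
                "gamma": list(GAMMA_GRID), "flip": [False, True]}
    if not grid:
        return list(samples)
    out: list[PhantomSample] = []
    skipped = 0
    if mode == "single":
        for s in samples:
            for kind, values in grid.items():
                for v in values:
                    try:
                        out.append(augment(s, kind, v, rng=rng))
                    except ValueError:
                        skipped += 1
    elif mode == "product":
        kinds = list(grid)
        for s in samples:
            for combo in product(*(grid[k] for k in kinds)):
                try:
                    cur = s
                    for kind, v in zip(kinds, combo):
                        cur = augment(cur, kind, v, rng=rng)
                    out.append(cur)
                except ValueError:
                    skipped += 1
    else:
        raise ValueError(f"unknown expansion mode {mode!r}")
    factor = len(out) / max(len(samples), 1)
    log.info("expanded %d samples to %d (factor %.1f, %d skipped out-of-frame)",
             len(samples), len(out), factor, skipped)
    return out
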