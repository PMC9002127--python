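"""Seeded generator of ultrasound-like fetal-skull phantoms.

Each positive phantom is a bright anti-aliased elliptical ring (the skull
cross-section on the trans-thalamic plane) over a smooth low-frequency
background, degraded by multiplicative unit-mean gamma speckle -- the
standard first-order approximation to B-mode ultrasound texture -- and
by contiguous arc dropouts that mimic acoustic shadowing at the skull
poles.  The generating ellipse is the exact ground-truth annotation, and
the pixel size is drawn from the 0.052-0.6 mm range typical of clinical
fetal scans, so head circumferences in mm span a realistic spread.

Negative samples are built two ways: removing the target and filling the
hole with surrounding-background statistics, or randomly cropping a
patch whose overlap with the ground-truth box is below 0.3 IOU and
resizing it to the input size.

Everything is driven by numpy Generators seeded from a master seed, so a
dataset regenerates byte-identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter, zoom

from .encoding import Annotation, write_annotations
from .geometry import Ellipse, enclosing_box

__all__ = ["PhantomConfig", "PhantomSample", "generate_phantom", "make_negative", "generate_dataset"]

PIXEL_SIZE_RANGE_MM = (0.052, 0.6)


@dataclass(frozen=True)
class PhantomConfig:
    image_size: tuple[int, int] = (96, 96)  # (H, W)
    semi_axis_range: tuple[float, float] = (14.0, 30.0)  # semi-major axis, px
    eccentricity_range: tuple[float, float] = (0.6, 1.0)  # b/a
    ring_thickness: float = 3.0  # px, Gaussian cross-section sigma*2
    ring_intensity: tuple[float, float] = (170.0, 30.0)  # (mean, jitter)
    speckle: float = 0.25  # multiplicative noise sd; 0 disables
    gap_fraction: float = 0.2  # fraction of ring arc erased, in [0, 0.5]
    background_texture: float = 25.0  # low-frequency field amplitude; 0 disables
    background_level: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gap_fraction <= 0.5):
            raise ValueError("gap_fraction must lie in [0, 0.5]")
        if self.semi_axis_range[0] > self.semi_axis_range[1]:
            raise ValueError("empty semi-axis range")
        h, w = self.image_size
        margin = self.semi_axis_range[1] + self.ring_thickness + 2
        if 2 * margin >= min(h, w):
            raise ValueError("largest ellipse cannot fit inside the image with the ring margin")


@dataclass
class PhantomSample:
    image: np.ndarray  # uint8 (H, W)
    annotation: Annotation
    seed: int


def _ring_distance(e: Ellipse, shape: tuple[int, int]) -> np.ndarray:
    """Approximate signed pixel distance from each pixel to the ellipse boundary."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    psi = math.radians(e.psi_deg)
    dx, dy = xx - e.cx, yy - e.cy
    u = dx * math.cos(psi) + dy * math.sin(psi)
    v = -dx * math.sin(psi) + dy * math.cos(psi)
    r = np.sqrt((u / e.a) ** 2 + (v / e.b) ** 2)
    # first-order distance: (r - 1) / |grad r|
    grad = np.sqrt((u / e.a**2) ** 2 + (v / e.b**2) ** 2) / np.maximum(r, 1e-9)
    return (r - 1.0) / np.maximum(grad, 1e-9)


def _arc_param_table(e: Ellipse, n: int = 720) -> tuple[np.ndarray, np.ndarray]:
    """Parametric angles and normalized cumulative arc length around the ellipse."""
    t = np.linspace(0.0, 2 * math.pi, n + 1)
    ds = np.sqrt((e.a * np.sin(t)) ** 2 + (e.b * np.cos(t)) ** 2)
    s = np.concatenate([[0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(t))])
    return t, s / s[-1]


def _gap_mask(e: Ellipse, shape: tuple[int, int], gap_fraction: float,
              rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of ring pixels to erase: contiguous arcs by arc length."""
    h, w = shape
    if gap_fraction <= 0:
        return np.zeros(shape, dtype=bool)
    t_tab, s_tab = _arc_param_table(e)
    n_gaps = int(rng.integers(1, 3))
    fracs = np.full(n_gaps, gap_fraction / n_gaps)
    starts = rng.uniform(0.0, 1.0, size=n_gaps)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    psi = math.radians(e.psi_deg)
    dx, dy = xx - e.cx, yy - e.cy
    u = dx * math.cos(psi) + dy * math.sin(psi)
    v = -dx * math.sin(psi) + dy * math.cos(psi)
    phi = np.arctan2(v / e.b, u / e.a) % (2 * math.pi)
    # normalized arc position of every pixel's boundary point
    s_pix = np.interp(phi, t_tab, s_tab)
    mask = np.zeros(shape, dtype=bool)
    for s0, f in zip(starts, fracs):
        s1 = s0 + f
        mask |= ((s_pix >= s0) & (s_pix < s1)) | (s_pix + 1.0 < s1)
    return mask


def _background(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.image_size
    bg = np.full((h, w), cfg.background_level, dtype=np.float64)
    if cfg.background_texture > 0:
        coarse = rng.normal(0.0, 1.0, size=(6, 6))
        field = zoom(coarse, (h / 6, w / 6), order=3)[:h, :w]
        bg += cfg.background_texture * field
    return bg


def _speckle(shape, scale: float, rng: np.random.Generator) -> np.ndarray:
    if scale <= 0:
        return np.ones(shape)
    k = 1.0 / scale**2  # gamma shape; unit mean, sd = scale
    return rng.gamma(k, 1.0 / k, size=shape)


def generate_phantom(cfg: PhantomConfig, rng: np.random.Generator | None = None,
                     seed: int | None = None) -> PhantomSample:
    """Render one positive skull phantom with its exact annotation."""
    if rng is None:
        seed = cfg.seed if seed is None else seed
        rng = np.random.default_rng(seed)
    else:
        seed = -1 if seed is None else seed
    h, w = cfg.image_size
    pixel_size = float(rng.uniform(*PIXEL_SIZE_RANGE_MM))
    a = float(rng.uniform(*cfg.semi_axis_range))
    b = a * float(rng.uniform(*cfg.eccentricity_range))
    theta = float(rng.uniform(0.0, 180.0))
    margin = a + cfg.ring_thickness + 2
    cx = float(rng.uniform(margin, w - 1 - margin))
    cy = float(rng.uniform(margin, h - 1 - margin))
    intensity = float(rng.normal(cfg.ring_intensity[0], cfg.ring_intensity[1]))
    intensity = float(np.clip(intensity, 90.0, 250.0))
    e = Ellipse(cx=cx, cy=cy, a=a, b=b, theta=theta)

    d = _ring_distance(e, (h, w))
    sigma_r = cfg.ring_thickness / 2.0
    ring = intensity * np.exp(-(d**2) / (2.0 * sigma_r**2))
    ring[_gap_mask(e, (h, w), cfg.gap_fraction, rng)] = 0.0

    img = _background(cfg, rng) + ring
    img *= _speckle((h, w), cfg.speckle, rng)
    img = np.clip(img, 0, 255).astype(np.uint8)

    ann = Annotation(image_id=f"phantom_{seed}", ellipse=e, pixel_size_mm=pixel_size)
    return PhantomSample(image=img, annotation=ann, seed=seed)


def make_negative(sample: PhantomSample, mode: str, rng: np.random.Generator,
                  cfg: PhantomConfig | None = None) -> PhantomSample:
    """Turn a positive phantom into a negative sample.

    ``remove_fill`` replaces the ring region with surrounding-background
    statistics; ``random_crop`` extracts a patch whose axis-aligned IOU
    with the ground-truth enclosing box is below 0.3 and resizes it to
    the input size.
    """
    if sample.annotation.is_negative:
        raise ValueError("make_negative requires a positive input sample")
    cfg = cfg or PhantomConfig()
    thick = max(1.0, cfg.ring_thickness)
    e = sample.annotation.ellipse
    img = sample.image.astype(np.float64)
    h, w = img.shape
    if mode == "remove_fill":
        d = _ring_distance(e, (h, w))
        band = np.abs(d) <= 3.0 * thick
        surround = (np.abs(d) > 3.0 * thick) & (np.abs(d) < 9.0 * thick)
        mean = float(img[surround].mean())
        sd = float(img[surround].std())
        fill = rng.normal(mean, sd, size=img.shape)
        fill = gaussian_filter(fill, sigma=1.5)
        out = img.copy()
        out[band] = fill[band]
        out = np.clip(out, 0, 255).astype(np.uint8)
    elif mode == "random_crop":
        from skimage.transform import resize

        box = enclosing_box(e)
        gt = (box.bx - box.w / 2, box.by - box.h / 2, box.bx + box.w / 2, box.by + box.h / 2)
        for _ in range(100):
            ch = int(rng.uniform(0.4, 0.8) * h)
            cw = int(rng.uniform(0.4, 0.8) * w)
            y0 = int(rng.integers(0, h - ch + 1))
            x0 = int(rng.integers(0, w - cw + 1))
            crop = (x0, y0, x0 + cw, y0 + ch)
            if _box_iou(gt, crop) < 0.3:
                patch = img[y0 : y0 + ch, x0 : x0 + cw]
                out = resize(patch, (h, w), order=1, preserve_range=True, anti_aliasing=True)
                out = np.clip(out, 0, 255).astype(np.uint8)
                break
        else:
            raise RuntimeError("random_crop: no window with IOU < 0.3 found in 100 attempts "
                               f"(GT box {gt} in {w}x{h} image)")
    else:
        raise ValueError(f"unknown negative mode {mode!r}")
    ann = Annotation(image_id=sample.annotation.image_id + f"_neg_{mode}", ellipse=None,
                     pixel_size_mm=sample.annotation.pixel_size_mm, is_negative=True)
    return PhantomSample(image=out, annotation=ann, seed=sample.seed)


def _box_iou(b1, b2) -> float:
    ix0, iy0 = max(b1[0], b2[0]), max(b1[1], b2[1])
    ix1, iy1 = min(b1[2], b2[2]), min(b1[3], b2[3])
    inter = max(0.0, ix1 - ix0) * max(0.0, iy1 - iy0)
    a1 = (b1[2] - b1[0]) * (b1[3] - b1[1])
    a2 = (b2[2] - b2[0]) * (b2[3] - b2[1])
    return inter / (a1 + a2 - inter) if inter else 0.0


def generate_samples(n_pos: int, n_neg: int, cfg: PhantomConfig) -> list[PhantomSample]:
    """Generate positives and negatives in memory, deterministically from cfg.seed."""
    master = np.random.default_rng(cfg.seed)
    seeds = master.integers(0, 2**31 - 1, size=n_pos + n_neg)
    samples = [generate_phantom(cfg, seed=int(s)) for s in seeds[:n_pos]]
    for i, s in enumerate(seeds[n_pos:]):
        base = generate_phantom(cfg, seed=int(s))
        mode = "remove_fill" if i % 2 == 0 else "random_crop"
        neg_rng = np.random.default_rng(int(s) + 1)
        samples.append(make_negative(base, mode, neg_rng, cfg))
    return samples


def generate_dataset(n_pos: int, n_neg: int, cfg: PhantomConfig, out_dir: str | Path) -> dict:
    """Write a phantom dataset: PNGs, annotation CSV, and a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = generate_samples(n_pos, n_neg, cfg)
    annotations = []
    entries = []
    for i, s in enumerate(samples):
        ann = s.annotation
        image_id = f"{i:05d}_{'neg' if ann.is_negative else 'pos'}"
        ann = Annotation(image_id=image_id, ellipse=ann.ellipse,
                         pixel_size_mm=ann.pixel_size_mm, is_negative=ann.is_negative)
        fname = f"{image_id}.png"
        Image.fromarray(s.image, mode="L").save(out_dir / fname)
        annotations.append(ann)
        entries.append({"image_id": image_id, "file": fname, "seed": s.seed,
                        "is_negative": ann.is_negative})
    write_annotations(annotations, out_dir / "annotations.csv")
    manifest = {"config": asdict(cfg), "n_pos": n_pos, "n_neg": n_neg, "samples": entries}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
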