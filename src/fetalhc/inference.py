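"""Decoding head maps into scored oriented ellipses and HC measurements.

Detection is keypoint-style: cells that are local maxima of their 3x3
heatmap neighbourhood and exceed the score threshold become candidate
centers (default one per image -- a standard plane contains one head).
Each candidate's center is refined by the sub-pixel offset map, the
semi-axes are read from the axes map at the cell (sorted so a >= b), and
the angle comes from the soft-stagewise decode of the cell's bin
probabilities and shifts together with the image's stage scale
modifiers.  The head circumference follows directly from the decoded
semi-axes and the pixel size -- no segmentation or ellipse-fitting stage
exists anywhere in the path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter

from .geometry import Ellipse, head_circumference
from .network import DetectionOutput, EllipseNet
from .ssr import SSRConfig, decode_angle

__all__ = ["ScoredEllipse", "extract_peaks", "decode_detections", "predict_hc",
           "output_from_targets"]

#: Default detection confidence threshold (conventional for center-point
#: detectors; the value is a package choice recorded in config).
DEFAULT_SCORE_THRESHOLD = 0.3


@dataclass(frozen=True)
class ScoredEllipse:
    """A detection: ellipse (px), heatmap confidence, optional HC in mm."""

    ellipse: Ellipse
    score: float
    hc_mm: float | None = None


def extract_peaks(heatmap: np.ndarray, max_peaks: int = 1,
                  threshold: float = DEFAULT_SCORE_THRESHOLD) -> list[tuple[tuple[int, int], float]]:
    """Local-maximum cells of a heatmap, sorted by score.

    Returns ``[((ix, iy), score), ...]`` for cells that are maxima of
    their 3x3 neighbourhood with score >= threshold, best first,
    truncated to ``max_peaks``.  An empty list is a valid output (a
    negative image).
    """
    heat = np.asarray(heatmap, dtype=float)
    local_max = maximum_filter(heat, size=3, mode="constant")
    mask = (heat >= local_max) & (heat >= threshold)
    ys, xs = np.nonzero(mask)
    scores = heat[ys, xs]
    order = np.argsort(-scores)[:max_peaks]
    return [((int(xs[i]), int(ys[i])), float(scores[i])) for i in order]


def decode_detections(out: DetectionOutput, ssr_cfg: SSRConfig, stride: int = 4,
                      threshold: float = DEFAULT_SCORE_THRESHOLD, max_peaks: int = 1,
                      image_index: int = 0) -> list[ScoredEllipse]:
    """Decode one image's head maps into scored ellipses."""
    heat = np.asarray(out.heatmap.data[image_index, 0], dtype=float)
    offset = np.asarray(out.offset.data[image_index], dtype=float)
    axes = np.asarray(out.axes.data[image_index], dtype=float)
    probs = np.asarray(out.ssr_probs.data[image_index], dtype=float)
    eta = np.asarray(out.ssr_eta.data[image_index], dtype=float)
    delta = np.asarray(out.ssr_delta.data[image_index], dtype=float)

    detections: list[ScoredEllipse] = []
    for (ix, iy), score in extract_peaks(heat, max_peaks=max_peaks, threshold=threshold):
        ox, oy = offset[0, iy, ix], offset[1, iy, ix]
        cx = (ix + ox) * stride
        cy = (iy + oy) * stride
        ax1, ax2 = axes[0, iy, ix], axes[1, iy, ix]
        a, b = (ax1, ax2) if ax1 >= ax2 else (ax2, ax1)
        probs_stages, eta_stages = [], []
        start = 0
        for s_k in ssr_cfg.stages:
            probs_stages.append(probs[start : start + s_k, iy, ix])
            eta_stages.append(eta[start : start + s_k, iy, ix])
            start += s_k
        theta = float(decode_angle(probs_stages, eta_stages, list(delta), ssr_cfg)) % ssr_cfg.v_range
        values = (cx, cy, a, b, theta)
        if not all(np.isfinite(v) for v in values):
            warnings.warn(f"dropping detection with non-finite parameters {values}")
            continue
        detections.append(ScoredEllipse(Ellipse(cx=float(cx), cy=float(cy), a=float(a),
                                                b=float(b), theta=theta), score=score))
    return detections


def output_from_targets(targets, ssr_cfg: SSRConfig | None = None) -> DetectionOutput:
    """Manufacture head maps from encoded targets (an oracle model).

    The returned output decodes back to the annotated ellipses exactly
    (up to SSR angle quantization), which ties the target codec to the
    detection decoder: ``decode(encode(annotation)) == annotation``.
    """
    from .autodiff import Tensor
    from .ssr import ssr_encode_reference

    ssr_cfg = ssr_cfg or SSRConfig()
    n = len(targets)
    hg, wg = targets[0].heatmap.shape
    heat = np.zeros((n, 1, hg, wg))
    offset = np.zeros((n, 2, hg, wg))
    axes = np.full((n, 2, hg, wg), 1.0)
    probs = np.zeros((n, ssr_cfg.total_bins, hg, wg))
    # a uniform-probability background keeps every cell's stages normalized
    start = 0
    for s_k in ssr_cfg.stages:
        probs[:, start : start + s_k] = 1.0 / s_k
        start += s_k
    eta = np.zeros((n, ssr_cfg.total_bins, hg, wg))
    delta = np.zeros((n, ssr_cfg.n_stages))
    for i, t in enumerate(targets):
        heat[i, 0] = t.heatmap
        if t.is_negative:
            continue
        ix, iy = t.center_index
        offset[i, :, iy, ix] = t.offset
        axes[i, :, iy, ix] = t.axes
        onehot = np.concatenate(ssr_encode_reference(t.angle, ssr_cfg).probs)
        probs[i, :, iy, ix] = onehot
    return DetectionOutput(heatmap=Tensor(heat), offset=Tensor(offset), axes=Tensor(axes),
                           ssr_probs=Tensor(probs), ssr_eta=Tensor(eta),
                           ssr_delta=Tensor(delta))


def predict_hc(image: np.ndarray, model: EllipseNet, pixel_size_mm: float,
               threshold: float = DEFAULT_SCORE_THRESHOLD) -> ScoredEllipse | None:
    """Single best detection with head circumference in mm.

    ``image`` is a 2-D grayscale array (uint8 or float in [0, 1]).
    Returns None when no peak clears the threshold ("no head detected").
    """
    if pixel_size_mm <= 0:
        raise ValueError("pixel size must be positive")
    img = np.asarray(image, dtype=np.float32)
    if img.max() > 1.5:
        img = img / 255.0
    model.eval()
    out = model.forward(img[None, None])
    dets = decode_detections(out, model.ssr_cfg, stride=model.cfg.stride, threshold=threshold)
    if not dets:
        return None
    best = dets[0]
    e = best.ellipse
    hc = head_circumference(e.a * pixel_size_mm, e.b * pixel_size_mm)
    return ScoredEllipse(ellipse=e, score=best.score, hc_mm=hc)
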