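"""Training losses and their composition into the total objective.

The objective combines a penalty-reduced ("variant") focal loss on the
center heatmap with smooth-L1 regression of the sub-pixel center offset,
the semi-axes and the soft-stagewise-decoded angle, plus a bounded
Kullback-Leibler regression term that embeds predicted and ground-truth
ellipses as 2-D Gaussians and so couples the center, axes and angle
gradients (improving one parameter re-weights the others).

All regression terms are evaluated only at ground-truth center cells
(one prediction gathered per object); the focal loss sees the whole
heatmap, negatives included.  The total is the unweighted sum of the
five terms; per-term weights and ablation switches (``use_ssr``,
``use_kld``, ``include_axes_in_total``) live in :class:`LossConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, gather_cells
from .encoding import TargetSet
from .network import DetectionOutput
from .ssr import SSRConfig, decode_angle

__all__ = [
    "LossConfig",
    "LossBreakdown",
    "focal_loss",
    "smooth_l1",
    "regression_losses",
    "total_loss",
    "compute_losses",
]

_EPS = 1e-7


@dataclass(frozen=True)
class LossConfig:
    """Loss hyperparameters and ablation switches.

    ``use_ssr=False`` freezes the angle head's dynamic-range terms
    (Delta and eta are hard zeros), degenerating soft-stagewise
    regression to fixed-bin expectation regression; ``use_kld=False``
    drops the Gaussian KLD term, reproducing the smooth-L1-only
    objective.  ``circular_angle`` computes the angle residual on the
    minimal circular difference (the 0/180 wrap); switching it off
    restores a plain linear difference.

    The default weights down-weight the pixel/degree-scale regression
    terms (axes, angle) to 0.05 so they balance the O(1) heatmap focal
    loss, following the keypoint-detection convention for size terms;
    set every weight to 1.0 to recover the plain unweighted sum.
    """

    alpha: float = 2.0
    beta: float = 4.0
    use_ssr: bool = True
    use_kld: bool = True
    include_axes_in_total: bool = True
    circular_angle: bool = True
    weights: dict = field(default_factory=lambda: {
        "heat": 1.0, "offset": 1.0, "axes": 0.05, "angle": 0.05, "kld": 1.0})


@dataclass
class LossBreakdown:
    heat: float
    offset: float
    axes: float
    angle: float
    kld: float
    total: float

    def as_dict(self) -> dict[str, float]:
        return {"heat": self.heat, "offset": self.offset, "axes": self.axes,
                "angle": self.angle, "kld": self.kld, "total": self.total}


def _lift(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def focal_loss(pred, gt, n_objects: int, alpha: float = 2.0, beta: float = 4.0):
    """Penalty-reduced pixelwise focal loss for keypoint heatmaps.

    ``-(1/N) sum_i [P_i = 1] (1-p_i)^a log p_i
              + [P_i < 1] (1-P_i)^b p_i^a log(1-p_i)``
    with N the object count floored at 1.  ``pred`` may be a numpy array
    (returns float) or an autodiff Tensor (returns Tensor).
    """
    was_tensor = isinstance(pred, Tensor)
    p = _lift(pred)
    gt = np.asarray(gt, dtype=p.data.dtype)
    if p.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {gt.shape}")
    p = p.clip(_EPS, 1.0 - _EPS)
    pos = (gt >= 1.0).astype(p.data.dtype)
    neg = 1.0 - pos
    neg_w = (1.0 - gt) ** beta
    term_pos = ((1.0 - p) ** alpha) * p.log() * pos
    term_neg = neg_w * (p**alpha) * (1.0 - p).log() * neg
    loss = -(term_pos + term_neg).sum() * (1.0 / max(n_objects, 1))
    return loss if was_tensor else float(loss.data)


def focal_loss_logits(logits: Tensor, gt: np.ndarray, n_objects: int,
                      alpha: float = 2.0, beta: float = 4.0) -> Tensor:
    """The same variant focal loss, evaluated from pre-sigmoid logits.

    Uses ``log(sigmoid(z)) = -softplus(-z)`` so the gradient survives
    sigmoid saturation in float32 (the probability-space form dies once a
    pixel saturates to exactly 0 or 1).  Used by the training path; the
    probability-space :func:`focal_loss` remains the reference form.
    """
    gt = np.asarray(gt, dtype=logits.data.dtype)
    rho = logits.sigmoid()
    log_rho = -(-logits).softplus()
    log_1m = -logits.softplus()
    pos = (gt >= 1.0).astype(gt.dtype)
    neg_w = ((1.0 - gt) ** beta) * (1.0 - pos)
    term_pos = ((1.0 - rho) ** alpha) * log_rho * pos
    term_neg = neg_w * (rho**alpha) * log_1m
    return -(term_pos + term_neg).sum() * (1.0 / max(n_objects, 1))


def smooth_l1(x):
    """Huber-style smooth L1: ``0.5 x^2`` for |x| < 1, else ``|x| - 0.5``.

    Elementwise; accepts scalars, numpy arrays or autodiff Tensors.
    """
    if isinstance(x, Tensor):
        mask = (np.abs(x.data) < 1.0).astype(x.data.dtype)
        return (x * x * 0.5) * mask + (x.abs() - 0.5) * (1.0 - mask)
    x = np.asarray(x, dtype=float)
    out = np.where(np.abs(x) < 1.0, 0.5 * x**2, np.abs(x) - 0.5)
    return float(out) if out.ndim == 0 else out


def _circular_residual(d: Tensor, period: float = 180.0) -> Tensor:
    """Wrap a difference into (-period/2, period/2]; gradient is 1 a.e."""
    shift = period * np.round(d.data / period)
    return d - shift


def _sigma_elements(a: Tensor, b: Tensor, psi_rad: Tensor):
    """Closed-form entries of Sigma = (R diag(a,b) R^T)^2 for a batch."""
    c, s = psi_rad.cos(), psi_rad.sin()
    m11 = a * c * c + b * s * s
    m22 = a * s * s + b * c * c
    m12 = (a - b) * c * s
    s11 = m11 * m11 + m12 * m12
    s12 = m12 * (m11 + m22)
    s22 = m12 * m12 + m22 * m22
    return s11, s12, s22


def regression_losses(out: DetectionOutput, targets: list[TargetSet],
                      ssr_cfg: SSRConfig, cfg: LossConfig | None = None) -> dict[str, Tensor]:
    """Smooth-L1 and KLD terms gathered at ground-truth center cells.

    ``targets[i]`` corresponds to batch element ``i`` of ``out``.
    Returns a dict of scalar Tensors (offset, axes, angle, kld); all are
    zero Tensors when the batch holds no positive object.
    """
    cfg = cfg or LossConfig()
    pos = [(i, t) for i, t in enumerate(targets) if not t.is_negative]
    zero = Tensor(np.zeros(()))
    if not pos:
        return {"offset": zero, "axes": zero, "angle": zero, "kld": zero}
    n = len(pos)
    stride = pos[0][1].stride
    bi = np.array([i for i, _ in pos])
    xi = np.array([t.center_index[0] for _, t in pos])
    yi = np.array([t.center_index[1] for _, t in pos])
    gt_off = np.array([t.offset for _, t in pos])  # (K, 2)
    gt_axes = np.array([t.axes for _, t in pos])
    gt_theta = np.array([t.angle for _, t in pos])

    p_off = gather_cells(out.offset, bi, yi, xi)  # (K, 2)
    p_axes = gather_cells(out.axes, bi, yi, xi)
    l_off = smooth_l1(p_off - gt_off).sum() * (1.0 / n)
    l_axes = smooth_l1(p_axes - gt_axes).sum() * (1.0 / n)

    # angle via differentiable SSR decode at the center cell
    p_probs = gather_cells(out.ssr_probs, bi, yi, xi)  # (K, total_bins)
    p_eta = gather_cells(out.ssr_eta, bi, yi, xi)
    p_delta = out.ssr_delta[bi]  # (K, n_stages)
    probs_stages, eta_stages, delta_stages = [], [], []
    start = 0
    for k, s_k in enumerate(ssr_cfg.stages):
        probs_stages.append(p_probs[:, start : start + s_k])
        if cfg.use_ssr:
            eta_stages.append(p_eta[:, start : start + s_k])
            delta_stages.append(p_delta[:, k])
        else:
            eta_stages.append(Tensor(np.zeros((n, s_k))))
            delta_stages.append(Tensor(np.zeros(n)))
        start += s_k
    theta_pred = decode_angle(probs_stages, eta_stages, delta_stages, ssr_cfg)  # (K,)
    d_theta = theta_pred - gt_theta
    if cfg.circular_angle:
        d_theta = _circular_residual(d_theta, ssr_cfg.v_range)
    l_angle = smooth_l1(d_theta).sum() * (1.0 / n)

    if cfg.use_kld:
        p_cx = (xi + p_off[:, 0]) * stride
        p_cy = (yi + p_off[:, 1]) * stride
        psi = theta_pred * (math.pi / 180.0)
        s11, s12, s22 = _sigma_elements(p_axes[:, 0], p_axes[:, 1], psi)
        # target Gaussian inverse covariance and log-determinant (constants)
        ti = np.empty((n, 3))
        ld_t = np.empty(n)
        mu_t = np.empty((n, 2))
        for j, (_, t) in enumerate(pos):
            g = t.gt_gaussian
            inv = np.linalg.inv(g.sigma)
            ti[j] = (inv[0, 0], inv[0, 1], inv[1, 1])
            ld_t[j] = math.log(np.linalg.det(g.sigma))
            mu_t[j] = g.mu
        dx = p_cx - mu_t[:, 0]
        dy = p_cy - mu_t[:, 1]
        quad = ti[:, 0] * dx * dx + 2.0 * ti[:, 1] * dx * dy + ti[:, 2] * dy * dy
        trace = ti[:, 0] * s11 + 2.0 * ti[:, 1] * s12 + ti[:, 2] * s22
        det_p = (s11 * s22 - s12 * s12).clip(1e-12, np.inf)
        dkl = quad * 0.5 + trace * 0.5 + (ld_t - det_p.log()) * 0.5 - 1.0
        dkl = dkl.clip(0.0, np.inf)
        l_kld = (1.0 - 1.0 / (1.0 + (dkl + 1.0).log())).sum() * (1.0 / n)
    else:
        l_kld = zero
    return {"offset": l_off, "axes": l_axes, "angle": l_angle, "kld": l_kld}


def total_loss(parts: LossBreakdown) -> float:
    """Unweighted sum of the five terms; rejects non-finite components."""
    for name, v in parts.as_dict().items():
        if name != "total" and not math.isfinite(v):
            raise FloatingPointError(f"loss term '{name}' is not finite: {v}")
    return parts.heat + parts.offset + parts.axes + parts.angle + parts.kld


def compute_losses(out: DetectionOutput, targets: list[TargetSet],
                   ssr_cfg: SSRConfig, cfg: LossConfig | None = None):
    """Full objective for one batch.

    Returns ``(breakdown, total_tensor)`` where ``total_tensor`` is the
    differentiable weighted sum to backpropagate and ``breakdown`` holds
    per-term floats for logging.
    """
    cfg = cfg or LossConfig()
    n_obj = sum(t.n_objects for t in targets)
    gt_heat = np.stack([t.heatmap for t in targets])[:, None]  # (N, 1, Hg, Wg)
    if out.heatmap_logits is not None:
        l_heat = focal_loss_logits(out.heatmap_logits, gt_heat, n_obj, cfg.alpha, cfg.beta)
    else:
        l_heat = focal_loss(out.heatmap, gt_heat, n_obj, cfg.alpha, cfg.beta)
    reg = regression_losses(out, targets, ssr_cfg, cfg)
    w = cfg.weights
    total = l_heat * w["heat"] + reg["offset"] * w["offset"] + reg["angle"] * w["angle"]
    if cfg.include_axes_in_total:
        total = total + reg["axes"] * w["axes"]
    if cfg.use_kld:
        total = total + reg["kld"] * w["kld"]
    parts = LossBreakdown(
        heat=float(l_heat.data),
        offset=float(reg["offset"].data),
        axes=float(reg["axes"].data),
        angle=float(reg["angle"].data),
        kld=float(reg["kld"].data),
        total=float(total.data),
    )
    return parts, total
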