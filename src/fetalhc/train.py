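"""Training loop for the composite detection objective.

The default optimizer is Adam (lr 1e-3, 50-step warmup, gradient-norm
clipping), which equilibrates the very differently scaled heads within
a small epoch budget on CPU; momentum SGD (lr 0.005, momentum 0.9) is
available for full-scale runs.  Targets are encoded once per sample;
each epoch shuffles the sample order, and the per-term loss breakdown
(heatmap focal, center offset, axes, angle, KLD, total) is logged per
epoch so ablation runs can be compared term by term.

Checkpoints are ``.npz`` files holding every parameter and batch-norm
buffer plus a JSON echo of the model and SSR configurations; loading
refuses a checkpoint whose configuration does not match.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .encoding import Annotation, TargetSet, encode_targets
from .losses import LossBreakdown, LossConfig, compute_losses
from .network import EllipseNet, ModelConfig
from .nn import SGD, Adam
from .phantom import PhantomSample
from .ssr import SSRConfig

__all__ = ["TrainConfig", "train_model", "save_checkpoint", "load_checkpoint"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    ``optimizer='adam'`` (lr 1e-3) is the default for desk-scale CPU
    training; ``'sgd'`` selects momentum SGD with lr 0.005 /
    momentum 0.9 defaults, suited to full-scale runs.
    """

    epochs: int = 10
    batch_size: int = 4
    optimizer: str = "adam"
    lr: float | None = None  # None -> per-optimizer default
    momentum: float = 0.9
    weight_decay: float = 1e-4
    clip_norm: float | None = 50.0
    seed: int = 0
    lr_schedule: str = "step"  # "cosine" anneals lr to ~0; "step" uses lr_decay_epochs
    warmup_steps: int = 50  # linear lr ramp over the first optimizer steps
    lr_decay_epochs: tuple[int, ...] = (8,)  # for the step schedule: lr /= 10 at these epochs

    def resolved_lr(self) -> float:
        if self.lr is not None:
            return self.lr
        return 1e-3 if self.optimizer == "adam" else 0.005


def _to_batch(samples: list[PhantomSample]) -> np.ndarray:
    imgs = np.stack([s.image for s in samples]).astype(np.float32) / 255.0
    return imgs[:, None]


def train_model(model: EllipseNet, samples: list[PhantomSample],
                train_cfg: TrainConfig | None = None,
                loss_cfg: LossConfig | None = None) -> list[dict[str, float]]:
    """Optimize the model in place; returns the per-epoch loss history."""
    train_cfg = train_cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig()
    h, w = model.cfg.input_size
    targets = [encode_targets(s.annotation, model.cfg.stride, (h, w)) for s in samples]
    rng = np.random.default_rng(train_cfg.seed)
    if train_cfg.optimizer == "adam":
        opt = Adam(model.parameters(), lr=train_cfg.resolved_lr(),
                   weight_decay=train_cfg.weight_decay, clip_norm=train_cfg.clip_norm)
    elif train_cfg.optimizer == "sgd":
        opt = SGD(model.parameters(), lr=train_cfg.resolved_lr(), momentum=train_cfg.momentum,
                  weight_decay=train_cfg.weight_decay, clip_norm=train_cfg.clip_norm)
    else:
        raise ValueError(f"unknown optimizer {train_cfg.optimizer!r}")
    model.train()
    history: list[dict[str, float]] = []
    n = len(samples)
    base_lr = train_cfg.resolved_lr()
    step_count = 0
    epoch_lr = base_lr
    for epoch in range(train_cfg.epochs):
        if train_cfg.lr_schedule == "cosine":
            epoch_lr = base_lr * 0.5 * (1.0 + np.cos(np.pi * epoch / train_cfg.epochs))
        elif epoch in train_cfg.lr_decay_epochs:
            epoch_lr /= 10.0
        opt.lr = epoch_lr
        order = rng.permutation(n)
        sums: dict[str, float] = {}
        n_batches = 0
        t0 = time.time()
        for start in range(0, n, train_cfg.batch_size):
            if step_count < train_cfg.warmup_steps:
                opt.lr = epoch_lr * (step_count + 1) / train_cfg.warmup_steps
            elif step_count == train_cfg.warmup_steps:
                opt.lr = epoch_lr
            step_count += 1
            idx = order[start : start + train_cfg.batch_size]
            batch = [samples[i] for i in idx]
            batch_t = [targets[i] for i in idx]
            out = model.forward(_to_batch(batch))
            parts, total = compute_losses(out, batch_t, model.ssr_cfg, loss_cfg)
            opt.zero_grad()
            total.backward()
            opt.step()
            for k, v in parts.as_dict().items():
                sums[k] = sums.get(k, 0.0) + v
            n_batches += 1
        means = {k: v / n_batches for k, v in sums.items()}
        means["epoch"] = epoch
        history.append(means)
        log.info(
            "epoch %d | heat %.4f offset %.4f axes %.4f angle %.4f kld %.4f | total %.4f (%.1fs)",
            epoch, means["heat"], means["offset"], means["axes"], means["angle"],
            means["kld"], means["total"], time.time() - t0,
        )
    model.eval()
    return history


def save_checkpoint(model: EllipseNet, path: str | Path) -> None:
    """Write weights, batch-norm buffers and the config echo to an .npz file."""
    arrays = model.state_arrays()
    meta = json.dumps({"model": asdict(model.cfg),
                       "ssr": {"stages": list(model.ssr_cfg.stages),
                               "v_range": model.ssr_cfg.v_range}})
    np.savez(path, *arrays, meta=np.array(meta))


def load_checkpoint(path: str | Path) -> EllipseNet:
    """Rebuild the model a checkpoint describes and load its weights.

    The checkpoint is self-describing; a mismatch between the stored
    configuration and the reconstructed model's state layout is an error.
    """
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        arrays = [data[f"arr_{i}"] for i in range(len(data.files) - 1)]
    model_kwargs = dict(meta["model"])
    model_kwargs["input_size"] = tuple(model_kwargs["input_size"])
    cfg = ModelConfig(**model_kwargs)
    ssr = SSRConfig(stages=tuple(meta["ssr"]["stages"]), v_range=meta["ssr"]["v_range"])
    model = EllipseNet(cfg, ssr)
    model.load_state_arrays(arrays)
    model.eval()
    return model
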