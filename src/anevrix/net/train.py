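"""Adam training loop over sampled patches."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..preprocess import zscore
from .loss import combo_loss, combo_loss_grad
from .unet import NetConfig, UNet3D

__all__ = ["Adam", "TrainReport", "train"]


class Adam:
    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        # params: list of (name, value, grad)
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {n: np.zeros_like(v, dtype=np.float64) for n, v, _ in self.params}
        self.v = {n: np.zeros_like(v, dtype=np.float64) for n, v, _ in self.params}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for name, value, grad in self.params:
            m = self.m[name]
            v = self.v[name]
            m *= self.b1
            m += (1 - self.b1) * grad
            v *= self.b2
            v += (1 - self.b2) * grad.astype(np.float64) ** 2
            value -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(value.dtype)


@dataclass
class TrainReport:
    epoch_losses: list[float]
    best_epoch: int | None
    best_loss: float | None
    checkpoint: str | None
    config: dict


def _save_checkpoint(model: UNet3D, path: Path, epoch: int, loss: float) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    meta = {"epoch": epoch, "loss": loss,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(model.cfg).items()}}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_checkpoint(path: str | Path) -> UNet3D:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg_kwargs = dict(meta["config"])
    cfg_kwargs["filters"] = tuple(cfg_kwargs["filters"])
    model = UNet3D(NetConfig(**cfg_kwargs))
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as st:
        model.load_state_dict(dict(st))
    return model


def train(
    model: UNet3D,
    patches,
    cfg: NetConfig,
    out_dir: str | Path | None = None,
    steps_per_epoch: int | None = None,
) -> TrainReport:
    """Train with Adam on z-scored patches; checkpoint on each improvement."""
    patches = list(patches)
    if not patches:
        raise ValueError("empty patch set")
    rng = np.random.default_rng(cfg.seed)
    xs = np.stack([zscore(p.intensities) for p in patches]).astype(np.float32)
    ys = np.stack([np.asarray(p.label, dtype=np.float32) for p in patches])
    params = list(model.parameters())
    opt = Adam(params, lr=cfg.lr)
    ckpt_path = Path(out_dir) / "checkpoint.npz" if out_dir is not None else None
    losses: list[float] = []
    best_loss, best_epoch = None, None
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(patches))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x, t = xs[idx], ys[idx]
            pred = model.forward(x, training=True)
            loss = combo_loss(pred, t, cfg.alpha, cfg.beta)
            grad = combo_loss_grad(pred, t, cfg.alpha, cfg.beta)
            model.backward(grad.astype(np.float32))
            opt.step()
            epoch_loss += loss
            n_batches += 1
            if steps_per_epoch and n_batches >= steps_per_epoch:
                break
        mean_loss = epoch_loss / max(1, n_batches)
        losses.append(mean_loss)
        if best_loss is None or mean_loss < best_loss:
            best_loss, best_epoch = mean_loss, epoch
            if ckpt_path is not None:
                _save_checkpoint(model, ckpt_path, epoch, mean_loss)
    if cfg.epochs == 0 and ckpt_path is not None:
        _save_checkpoint(model, ckpt_path, -1, float("nan"))
    if out_dir is not None:
        log = Path(out_dir) / "training_log.tsv"
        log.parent.mkdir(parents=True, exist_ok=True)
        log.write_text("epoch\tloss\n" + "".join(
            f"{i}\t{l:.6f}\n" for i, l in enumerate(losses)))
    return TrainReport(
        epoch_losses=losses,
        best_epoch=best_epoch,
        best_loss=best_loss,
        checkpoint=str(ckpt_path) if ckpt_path is not None else None,
        config={k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(cfg).items()},
    )
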