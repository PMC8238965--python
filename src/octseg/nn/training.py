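"""SGD training of the segmentation network.

The optimizer follows the recipe standard for DeepLab-type models:
SGD with momentum 0.9 and weight decay 5e-4, initial learning rate
0.007, decayed by the "poly" schedule

    lr(t) = lr0 * (1 - t / max_iter) ** power      (power defaults to 0.9),

minimizing mean per-pixel cross-entropy. The validation split selects the
checkpoint (best validation F1). All randomness (init, shuffling) flows
from ``TrainConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ..metrics import confusion_counts, metrics_report
from .layers import cross_entropy_grad
from .network import NetConfig, SegNet


@dataclass(frozen=True)
class TrainConfig:
    lr0: float = 0.007
    power: float = 0.9
    momentum: float = 0.9
    weight_decay: float = 5e-4
    epochs: int = 20
    batch_size: int = 8
    seed: int = 0
    class_weights: tuple[float, ...] | None = (1.0, 4.0)

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be > 0")
        if not (0 <= self.momentum < 1):
            raise ValueError("momentum must be in [0, 1)")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")


def poly_lr(iteration: int, max_iter: int, lr0: float, power: float = 0.9) -> float:
    """Polynomially decayed learning rate: lr0 * (1 - t/max_iter)^power."""
    if max_iter <= 0:
        raise ValueError("max_iter must be > 0")
    if not (0 <= iteration <= max_iter):
        raise ValueError("iteration must lie in [0, max_iter]")
    return lr0 * (1.0 - iteration / max_iter) ** power


class TrainingDiverged(RuntimeError):
    pass


def _sgd_step(model: SegNet, lr: float, momentum: float, weight_decay: float):
    for p in model.params():
        g = p.grad
        if weight_decay and p.decay:
            g = g + weight_decay * p.value
        p.velocity = momentum * p.velocity + g
        p.value = p.value - lr * p.velocity
        p.grad = np.zeros_like(p.grad)


def _val_f1(model: SegNet, xs: np.ndarray, ys: np.ndarray) -> float:
    """F1 over pooled validation pixels (cheap, stable for tiny val sets)."""
    tp = fp = fn = tn = 0
    for x, y in zip(xs, ys):
        proba = model.predict_proba(x)
        pred = (proba[..., 1] > 0.5).astype(np.uint8)
        a, b, c, d = confusion_counts(pred, y)
        tp, fp, fn, tn = tp + a, fp + b, fn + c, tn + d
    return metrics_report(tp, fp, fn, tn).f1


def train(
    train_images: np.ndarray,
    train_masks: np.ndarray,
    val_images: np.ndarray,
    val_masks: np.ndarray,
    net_config: NetConfig = NetConfig(),
    train_config: TrainConfig = TrainConfig(),
    verbose: bool = False,
) -> tuple[SegNet, list[dict]]:
    """Fit the network; returns (model with best-validation-F1 weights, history).

    ``train_images``: (N, H, W) float in [0, 1]; ``train_masks``: (N, H, W)
    in {0, 1}. Validation images select the checkpoint.
    """
    if len(train_images) == 0:
        raise ValueError("empty training set")
    tc = train_config
    rng = np.random.default_rng(tc.seed)
    model = SegNet(net_config, seed=int(rng.integers(2**31 - 1)))

    x_tr = np.asarray(train_images, dtype=np.float32)[:, None]
    y_tr = np.asarray(train_masks, dtype=np.int64)
    n = len(x_tr)
    steps_per_epoch = max(1, int(np.ceil(n / tc.batch_size)))
    max_iter = tc.epochs * steps_per_epoch

    history: list[dict] = []
    best = {"f1": -1.0, "state": None}
    it = 0
    for epoch in range(tc.epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(steps_per_epoch):
            idx = order[s * tc.batch_size : (s + 1) * tc.batch_size]
            logits = model.forward(x_tr[idx], training=True)
            loss, grad = cross_entropy_grad(logits, y_tr[idx], tc.class_weights)
            if not np.isfinite(loss):
                raise TrainingDiverged(f"non-finite loss at epoch {epoch}")
            model.backward(grad)
            _sgd_step(model, poly_lr(it, max_iter, tc.lr0, tc.power),
                      tc.momentum, tc.weight_decay)
            it += 1
            losses.append(loss)
        record = {"epoch": epoch, "loss": float(np.mean(losses))}
        if len(val_images):
            record["val_f1"] = _val_f1(model, val_images, val_masks)
            if record["val_f1"] >= best["f1"]:
                best = {"f1": record["val_f1"], "state": model.state_arrays()}
        history.append(record)
        if verbose:
            print(f"epoch {epoch:3d}  loss {record['loss']:.4f}"
                  + (f"  val_f1 {record.get('val_f1', float('nan')):.4f}"
                     if "val_f1" in record else ""))
    if best["state"] is not None:
        model.load_state_arrays(best["state"])
    return model, history


def save_checkpoint(path: str | Path, model: SegNet,
                    history: list[dict] | None = None) -> None:
    path = Path(path)
    cfg = asdict(model.config)
    with open(path, "wb") as fh:  # keep the exact filename (no .npz suffixing)
        np.savez(fh, __config__=np.frombuffer(
            json.dumps(cfg).encode(), dtype=np.uint8), **model.state_arrays())
    if history is not None:
        path.with_suffix(".history.json").write_text(json.dumps(history))


def load_checkpoint(path: str | Path) -> SegNet:
    with np.load(path) as data:
        cfg = json.loads(bytes(data["__config__"]).decode())
        cfg["blocks_per_stage"] = tuple(cfg["blocks_per_stage"])
        cfg["atrous_rates"] = tuple(cfg["atrous_rates"])
        cfg["input_size"] = tuple(cfg["input_size"])
        model = SegNet(NetConfig(**cfg), seed=0)
        model.load_state_arrays({k: data[k] for k in data.files
                                 if k != "__config__"})
    return model
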