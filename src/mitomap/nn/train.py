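"""Training loop: cross-entropy, Adam, stochastic augmentations.

The reference recipe trains with per-pixel cross-entropy over the three
classes, Adam (beta1=0.9, beta2=0.999), learning rate 1e-4 dropped to 1e-5
after epoch 150 for 200 epochs total, batch size 8.  Augmentations —
horizontal/vertical flips, rotations in [-20, 20] degrees, zero-mean
Gaussian noise (sd 0.08) and random crops down to 90% of each side, resized
back — are each applied independently with probability 0.5; geometric
transforms are applied identically to image (bilinear) and label (nearest).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .model import SegmentationNet

__all__ = ["TrainConfig", "augment_pair", "apply_geometric", "train_model",
           "softmax_cross_entropy"]


@dataclass
class TrainConfig:
    epochs: int = 200
    batch_size: int = 8
    lr_initial: float = 1e-4
    lr_late: float = 1e-5
    lr_switch_epoch: int = 150  # lr_late applies after this many epochs
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    augment: bool = True
    aug_probability: float = 0.5
    rotation_deg: float = 20.0
    noise_sd: float = 0.08
    crop_fraction: float = 0.9  # crops down to this fraction of each side
    seed: int = 0

    def learning_rates(self) -> list[float]:
        """Per-epoch learning-rate schedule (1-based epochs)."""
        return [self.lr_initial if e <= self.lr_switch_epoch else self.lr_late
                for e in range(1, self.epochs + 1)]


def augment_pair(image: np.ndarray, label: np.ndarray, rng: np.random.Generator,
                 config: TrainConfig):
    """Stochastically augment one (image, label) pair.

    Returns ``(image, label, applied)`` where ``applied`` records the
    geometric operations so :func:`apply_geometric` can replay them on a
    label map exactly.
    """
    img = image.astype(np.float32)
    lab = label.copy()
    applied: dict = {}
    p = config.aug_probability
    if rng.random() < p:
        img, lab = img[:, ::-1], lab[:, ::-1]
        applied["hflip"] = True
    if rng.random() < p:
        img, lab = img[::-1, :], lab[::-1, :]
        applied["vflip"] = True
    if rng.random() < p:
        angle = float(rng.uniform(-config.rotation_deg, config.rotation_deg))
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="nearest")
        lab = ndimage.rotate(lab, angle, reshape=False, order=0, mode="nearest")
        applied["rotate_deg"] = angle
    if rng.random() < p:
        frac = float(rng.uniform(config.crop_fraction, 1.0))
        h, w = img.shape
        ch, cw = max(1, int(round(frac * h))), max(1, int(round(frac * w)))
        top = int(rng.integers(0, h - ch + 1))
        left = int(rng.integers(0, w - cw + 1))
        crop = (top, left, ch, cw)
        img = _crop_resize(img, crop, (h, w), order=1)
        lab = _crop_resize(lab, crop, (h, w), order=0)
        applied["crop"] = crop
    if rng.random() < p:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape).astype(np.float32)
        applied["noise_sd"] = config.noise_sd
    return np.ascontiguousarray(img), np.ascontiguousarray(lab), applied


def _crop_resize(arr: np.ndarray, crop, out_shape, order: int) -> np.ndarray:
    top, left, ch, cw = crop
    sub = arr[top : top + ch, left : left + cw]
    zoom = (out_shape[0] / ch, out_shape[1] / cw)
    out = ndimage.zoom(sub, zoom, order=order, grid_mode=True, mode="nearest")
    # zoom can be off by one pixel on awkward ratios; crop/pad to be exact
    return out[: out_shape[0], : out_shape[1]]


def apply_geometric(label: np.ndarray, applied: dict) -> np.ndarray:
    """Replay the recorded geometric transforms on a label map (nearest)."""
    lab = label.copy()
    if applied.get("hflip"):
        lab = lab[:, ::-1]
    if applied.get("vflip"):
        lab = lab[::-1, :]
    if "rotate_deg" in applied:
        lab = ndimage.rotate(lab, applied["rotate_deg"], reshape=False, order=0,
                             mode="nearest")
    if "crop" in applied:
        lab = _crop_resize(lab, applied["crop"], label.shape, order=0)
    return np.ascontiguousarray(lab)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean per-pixel cross-entropy and its gradient w.r.t. the logits.

    logits: (N, C, H, W); labels: (N, H, W) ints in [0, C).
    """
    n, c, h, w = logits.shape
    shifted = (logits - logits.max(axis=1, keepdims=True)).astype(np.float64)
    exp = np.exp(shifted)
    denom = exp.sum(axis=1, keepdims=True)
    probs = exp / denom
    idx_n, idx_h, idx_w = np.ogrid[:n, :h, :w]
    # log-sum-exp form: exact even when the true-class probability underflows
    loss = float((np.log(denom[:, 0]) - shifted[idx_n, labels, idx_h, idx_w]).mean())
    grad = probs.copy()
    grad[idx_n, labels, idx_h, idx_w] -= 1.0
    grad /= n * h * w
    return loss, grad.astype(np.float32)


def train_model(model: SegmentationNet, dataset, config: TrainConfig):
    """Train in place; returns ``(model, loss_history)``.

    ``dataset`` is a sequence of ``(image (H, W), label (H, W) in {0,1,2})``
    pairs.  Deterministic for a fixed ``config.seed``.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    n_classes = model.config.n_classes
    for _, lab in dataset:
        bad = np.setdiff1d(np.unique(lab), np.arange(n_classes))
        if bad.size:
            raise ValueError(f"labels outside [0, {n_classes}): {bad.tolist()}")
    rng = np.random.default_rng(config.seed)
    lrs = config.learning_rates()
    history: list[float] = []
    t = 0  # Adam step counter
    for epoch, lr in enumerate(lrs, start=1):
        order = rng.permutation(len(dataset))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            imgs, labs = [], []
            for i in batch:
                img, lab = dataset[i]
                if config.augment:
                    img, lab, _ = augment_pair(np.asarray(img), np.asarray(lab), rng, config)
                imgs.append(np.asarray(img, dtype=np.float32))
                labs.append(np.asarray(lab))
            x = np.stack(imgs)[:, None]
            y = np.stack(labs)
            logits = model.forward(x)
            loss, dlogits = softmax_cross_entropy(logits, y)
            model.zero_grad()
            model.backward(dlogits)
            t += 1
            _adam_step(model, lr, config, t)
            epoch_loss += loss
            n_batches += 1
        history.append(epoch_loss / n_batches)
    return model, history


def _adam_step(model: SegmentationNet, lr: float, config: TrainConfig, t: int):
    b1, b2, eps = config.beta1, config.beta2, config.eps
    for p in model.params():
        p.m = b1 * p.m + (1 - b1) * p.grad
        p.v = b2 * p.v + (1 - b2) * p.grad**2
        m_hat = p.m / (1 - b1**t)
        v_hat = p.v / (1 - b2**t)
        p.value -= lr * m_hat / (np.sqrt(v_hat) + eps)
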