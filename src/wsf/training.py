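"""Training regime: hybrid loss, learning-rate scheduling, loss bookkeeping.

The loss is a weighted sum of per-pixel cross-entropy and soft Dice
(1 - mean per-class Dice coefficient), the standard remedy for the small
foreground fraction of stomatal masks. Optimization uses AdamW at an
initial learning rate of 6e-5 with a 0.8 decay factor, either applied
after every epoch (``epoch_decay``) or when the smoothed validation loss
plateaus (``plateau``, the default). Raw and exponentially smoothed
train/validation losses are recorded per batch, and precision/MIoU on the
validation partition per epoch. Everything is reproducible from the
config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .metrics import evaluate_masks
from .model import WSFModel, predict_mask
from .nn import AdamW

__all__ = ["TrainConfig", "TrainHistory", "hybrid_loss", "lr_at_epoch",
           "smooth_losses", "kfold_split", "train_loop"]


@dataclass(frozen=True)
class TrainConfig:
    initial_lr: float = 6e-5
    lr_decay_factor: float = 0.8
    schedule_mode: str = "plateau"        # or "epoch_decay"
    plateau_patience: int = 5
    batch_size: int = 8
    epochs: int = 200
    k_folds: int | None = None
    loss_weights: tuple[float, float] = (1.0, 1.0)   # (w_ce, w_dice)
    class_weights: tuple[float, ...] | None = None
    smoothing_alpha: float = 0.1
    adam_betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if not (0.0 < self.lr_decay_factor <= 1.0):
            raise ValueError("lr_decay_factor must be in (0, 1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        w_ce, w_dice = self.loss_weights
        if w_ce < 0 or w_dice < 0 or (w_ce == 0 and w_dice == 0):
            raise ValueError("loss weights must be non-negative, not both zero")
        if not (0.0 < self.smoothing_alpha <= 1.0):
            raise ValueError("smoothing_alpha must be in (0, 1]")
        if self.schedule_mode not in ("plateau", "epoch_decay"):
            raise ValueError(f"unknown schedule_mode {self.schedule_mode!r}")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)        # per batch
    val_loss: list[float] = field(default_factory=list)          # per batch
    smoothed_train_loss: list[float] = field(default_factory=list)
    smoothed_val_loss: list[float] = field(default_factory=list)
    epoch_lr: list[float] = field(default_factory=list)
    epoch_precision: list[float] = field(default_factory=list)
    epoch_miou: list[float] = field(default_factory=list)
    epoch_val_loss: list[float] = field(default_factory=list)    # epoch means

    def to_frame(self) -> pd.DataFrame:
        """Per-epoch summary table suitable for CSV logging."""
        return pd.DataFrame({
            "epoch": np.arange(len(self.epoch_lr)),
            "lr": self.epoch_lr,
            "val_loss": self.epoch_val_loss,
            "precision": self.epoch_precision,
            "miou": self.epoch_miou,
        })


def hybrid_loss(logits: Tensor, mask: np.ndarray,
                loss_weights: tuple[float, float] = (1.0, 1.0),
                class_weights=None) -> Tensor:
    """w_ce * cross-entropy + w_dice * (1 - mean soft Dice).

    ``logits`` is (N, K, H, W); ``mask`` integer labels (N, H, W).
    Saturated correct logits drive the loss to zero.
    """
    mask = np.asarray(mask)
    if mask.ndim == 2:
        mask = mask[None]
    n, k, h, w = logits.shape
    if mask.shape != (n, h, w):
        raise ValueError(f"mask shape {mask.shape} does not match logits {(n, h, w)}")
    if mask.max(initial=0) >= k:
        raise ValueError(f"label {mask.max()} >= num_classes {k}")
    w_ce, w_dice = loss_weights

    onehot = np.zeros((n, k, h, w), dtype=np.float32)
    np.put_along_axis(onehot, mask[:, None].astype(np.int64), 1.0, axis=1)
    onehot_t = Tensor(onehot)

    total = Tensor(np.zeros((), dtype=np.float32))
    if w_ce > 0:
        logp = logits.log_softmax(axis=1)
        nll = -(logp * onehot_t).sum(axis=1)          # (N, H, W)
        if class_weights is not None:
            cw = np.asarray(class_weights, dtype=np.float32)
            if cw.shape != (k,):
                raise ValueError("class_weights length must equal num_classes")
            pix_w = Tensor(cw[mask])
            ce = (nll * pix_w).sum() / float(cw[mask].sum())
        else:
            ce = nll.mean()
        total = total + ce * w_ce
    if w_dice > 0:
        probs = logits.softmax(axis=1)
        smooth = 1.0
        inter = (probs * onehot_t).sum(axis=(0, 2, 3))
        denom = probs.sum(axis=(0, 2, 3)) + Tensor(onehot.sum(axis=(0, 2, 3)))
        dice = (inter * 2.0 + smooth) / (denom + smooth)
        total = total + (1.0 - dice.mean()) * w_dice
    return total


def smooth_losses(raw, alpha: float) -> list[float]:
    """Exponential moving average: s0 = x0, st = a*xt + (1-a)*s(t-1)."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    raw = list(raw)
    if not raw:
        raise ValueError("empty loss series")
    out = [float(raw[0])]
    for x in raw[1:]:
        out.append(alpha * float(x) + (1.0 - alpha) * out[-1])
    return out


def lr_at_epoch(config: TrainConfig, epoch: int,
                history: TrainHistory | None = None) -> float:
    """Learning rate in force at the start of ``epoch`` (0-based).

    ``epoch_decay``: initial_lr * factor**epoch. ``plateau``: the factor is
    applied whenever the per-epoch smoothed validation loss has not
    improved for ``plateau_patience`` consecutive epochs (judged on
    ``history.epoch_val_loss`` for epochs before ``epoch``).
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if config.schedule_mode == "epoch_decay":
        return config.initial_lr * config.lr_decay_factor ** epoch
    lr = config.initial_lr
    series = history.epoch_val_loss[:epoch] if history is not None else []
    best = np.inf
    wait = 0
    for v in series:
        if v < best - 1e-12:
            best, wait = v, 0
        else:
            wait += 1
            if wait >= config.plateau_patience:
                lr *= config.lr_decay_factor
                wait = 0
    return lr


def kfold_split(n_or_ids, k: int, seed: int = 0) -> list[list]:
    """Disjoint, exhaustive folds with sizes differing by at most 1."""
    if isinstance(n_or_ids, (int, np.integer)):
        ids = list(range(int(n_or_ids)))
    else:
        ids = list(n_or_ids)
    if k < 2 or k > len(ids):
        raise ValueError("need 2 <= k <= n")
    perm = np.random.default_rng(seed).permutation(len(ids))
    return [[ids[j] for j in perm[i::k]] for i in range(k)]


def _forward_batch(model: WSFModel, images: np.ndarray) -> Tensor:
    return model.forward(images)


def train_loop(model: WSFModel, train_pairs, val_pairs,
               config: TrainConfig) -> TrainHistory:
    """Optimize ``model`` on (image, mask) pairs; returns the history.

    ``train_pairs``/``val_pairs`` are sequences of (H, W, 3) uint8 images
    paired with (H, W) label masks. Validation loss and precision/MIoU
    are computed after every epoch. A NaN training loss aborts, leaving
    the model at its last finite state.
    """
    train_pairs, val_pairs = list(train_pairs), list(val_pairs)
    if not train_pairs or not val_pairs:
        raise ValueError("empty train or validation partition")
    rng = np.random.default_rng(config.seed)
    params = model.parameters()
    opt = AdamW(params, lr=config.initial_lr, betas=config.adam_betas,
                weight_decay=config.weight_decay)
    hist = TrainHistory()
    alpha = config.smoothing_alpha
    last_good = model.state_dict()

    for epoch in range(config.epochs):
        lr = lr_at_epoch(config, epoch, hist)
        opt.lr = lr
        hist.epoch_lr.append(lr)
        order = rng.permutation(len(train_pairs))
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo:lo + config.batch_size]
            imgs = np.stack([train_pairs[i][0] for i in idx])
            masks = np.stack([train_pairs[i][1] for i in idx])
            opt.zero_grad()
            loss = hybrid_loss(model.forward(imgs), masks,
                               config.loss_weights, config.class_weights)
            lval = float(loss.data)
            if not np.isfinite(lval):
                model.load_state_dict(last_good)
                raise FloatingPointError(
                    f"training loss became non-finite at epoch {epoch}; "
                    "model restored to last finite state")
            loss.backward()
            opt.step()
            hist.train_loss.append(lval)
            prev = hist.smoothed_train_loss[-1] if hist.smoothed_train_loss else lval
            hist.smoothed_train_loss.append(
                lval if not hist.smoothed_train_loss else alpha * lval + (1 - alpha) * prev)
        last_good = model.state_dict()

        # validation pass
        epoch_vals = []
        preds, gts = [], []
        for lo in range(0, len(val_pairs), config.batch_size):
            chunk = val_pairs[lo:lo + config.batch_size]
            imgs = np.stack([c[0] for c in chunk])
            masks = np.stack([c[1] for c in chunk])
            logits = model.forward(imgs)
            vloss = float(hybrid_loss(logits, masks, config.loss_weights,
                                      config.class_weights).data)
            hist.val_loss.append(vloss)
            prev = hist.smoothed_val_loss[-1] if hist.smoothed_val_loss else vloss
            hist.smoothed_val_loss.append(
                vloss if not hist.smoothed_val_loss else alpha * vloss + (1 - alpha) * prev)
            epoch_vals.append(vloss)
            for b in range(logits.shape[0]):
                preds.append(predict_mask(logits.data[b].transpose(1, 2, 0)))
                gts.append(masks[b])
        report = evaluate_masks(preds, gts, num_classes=model.config.num_classes)
        hist.epoch_val_loss.append(float(np.mean(epoch_vals)))
        hist.epoch_precision.append(report.precision)
        hist.epoch_miou.append(report.miou)
    return hist
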