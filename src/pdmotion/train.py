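"""Losses and training loops for pretext learning and severity fine-tuning.

The pretext objective is a weighted sum over the three transformation
heads of per-task binary cross-entropy,

    L = sum_t alpha_t * mean_b -[ w_pos * y log P_t + (1 - y) log(1 - P_t) ],

with a configurable positive-class weight compensating the 3:1
negative:positive imbalance that the one-transform-per-sample construction
induces at each head. Severity fine-tuning minimizes the Huber loss
(quadratic within |r| <= delta, linear beyond; delta = 1), robust to the
outlying windows that free-living data produce. Both stages run Adam with
early stopping on validation loss and plateau learning-rate decay, and the
validation split holds out whole subjects so no identity leaks across the
split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import LossConfig, TrainConfig
from .networks import SSLNetwork, RegressionNetwork, WeightsBundle
from .nn import Adam, sigmoid


# ---------------------------------------------------------------------------
# losses


def ssl_loss(y_p: np.ndarray, P: np.ndarray,
             cfg: LossConfig | None = None) -> float:
    """Multi-task weighted binary cross-entropy over transformation heads.

    ``y_p`` is the (B, T) pseudo-label matrix in {0,1}; ``P`` the (B, T)
    head probabilities, clipped to [eps, 1-eps] before the logs.
    """
    cfg = cfg or LossConfig()
    y = np.asarray(y_p, dtype=float)
    P = np.clip(np.asarray(P, dtype=float), cfg.prob_clip_eps,
                1.0 - cfg.prob_clip_eps)
    if y.shape != P.shape:
        raise ValueError(f"shape mismatch: labels {y.shape} vs probs {P.shape}")
    w = cfg.positive_weight
    per_task = -(w * y * np.log(P) + (1.0 - y) * np.log(1.0 - P)).mean(axis=0)
    return float(np.dot(np.asarray(cfg.alphas)[:y.shape[1]], per_task))


def ssl_loss_grad_logits(y_p: np.ndarray, logits: np.ndarray,
                         cfg: LossConfig) -> tuple[float, np.ndarray]:
    """Loss and its gradient w.r.t. the head logits (stable sigmoid+BCE)."""
    P = sigmoid(logits)
    loss = ssl_loss(y_p, P, cfg)
    B = y_p.shape[0]
    alphas = np.asarray(cfg.alphas)[None, :y_p.shape[1]]
    w = cfg.positive_weight
    grad = alphas * ((w * y_p + 1.0 - y_p) * P - w * y_p) / B
    return loss, grad


def huber_loss(y: np.ndarray, y_hat: np.ndarray, delta: float = 1.0) -> float:
    """Batch-mean Huber loss: 0.5 r^2 for |r| <= delta, else delta(|r| - delta/2)."""
    r = np.asarray(y, dtype=float) - np.asarray(y_hat, dtype=float)
    a = np.abs(r)
    quad = a <= delta
    vals = np.where(quad, 0.5 * r * r, delta * (a - 0.5 * delta))
    return float(vals.mean())


def huber_grad(y: np.ndarray, y_hat: np.ndarray, delta: float = 1.0) -> np.ndarray:
    """Gradient of the batch-mean Huber loss w.r.t. ``y_hat``."""
    r = np.asarray(y, dtype=float) - np.asarray(y_hat, dtype=float)
    return -np.clip(r, -delta, delta) / r.size


# ---------------------------------------------------------------------------
# history and loop helpers


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_metric: list = field(default_factory=list)  # per-task acc (SSL) or MAE
    lr: list[float] = field(default_factory=list)
    stop_epoch: int = 0
    best_epoch: int = 0

    def to_dict(self) -> dict:
        return {
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
            "val_metric": self.val_metric,
            "lr": self.lr,
            "stop_epoch": self.stop_epoch,
            "best_epoch": self.best_epoch,
        }


def subject_validation_split(subjects: np.ndarray, val_fraction: float,
                             rng: np.random.Generator,
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Boolean train/val masks holding out whole subjects (>= 1)."""
    uniq = np.unique(subjects.astype(str))
    if len(uniq) < 2:
        # single-subject corpora fall back to a random window split
        n = len(subjects)
        idx = rng.permutation(n)
        n_val = max(1, int(round(val_fraction * n)))
        val = np.zeros(n, dtype=bool)
        val[idx[:n_val]] = True
        return ~val, val
    order = rng.permutation(len(uniq))
    n_val = max(1, int(round(val_fraction * len(uniq))))
    val_subjects = set(uniq[order[:n_val]])
    val = np.isin(subjects.astype(str), list(val_subjects))
    return ~val, val


class _EarlyStop:
    """Early stopping + reduce-on-plateau bookkeeping shared by both loops."""

    def __init__(self, cfg: TrainConfig):
        self.cfg = cfg
        self.best = np.inf
        self.best_epoch = 0
        self.stale = 0
        self.lr_stale = 0

    def update(self, epoch: int, val_loss: float, opt: Adam) -> bool:
        """Returns True when training should stop."""
        if val_loss < self.best - 1e-12:
            self.best = val_loss
            self.best_epoch = epoch
            self.stale = 0
            self.lr_stale = 0
            return False
        self.stale += 1
        self.lr_stale += 1
        if self.lr_stale >= self.cfg.lr_patience:
            opt.lr = max(opt.lr * self.cfg.lr_factor, self.cfg.lr_floor)
            self.lr_stale = 0
        return self.stale >= self.cfg.early_stop_patience


# ---------------------------------------------------------------------------
# pretext pretraining


def pretrain(net: SSLNetwork, x_tr: np.ndarray, x_ts: np.ndarray,
             y_p: np.ndarray, subjects: np.ndarray,
             train_cfg: TrainConfig | None = None,
             loss_cfg: LossConfig | None = None,
             ) -> tuple[WeightsBundle, TrainHistory]:
    """Train the transformation-recognition network; returns best-val weights."""
    train_cfg = train_cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig()
    for t in range(y_p.shape[1]):
        if len(np.unique(y_p[:, t])) < 2:
            raise ValueError(f"task {t} has a single class; dataset degenerate")
    rng = np.random.default_rng(train_cfg.seed)
    net.seed_dropouts(train_cfg.seed + 1)
    tr_mask, val_mask = subject_validation_split(subjects,
                                                 train_cfg.val_fraction, rng)
    tr_idx = np.flatnonzero(tr_mask)
    val_idx = np.flatnonzero(val_mask)
    opt = Adam(net.params(), lr=train_cfg.learning_rate)
    stopper = _EarlyStop(train_cfg)
    hist = TrainHistory()
    best_weights = {n: p.value.copy() for n, p in net.named_params().items()}
    B = train_cfg.batch_size
    for epoch in range(train_cfg.epochs):
        rng.shuffle(tr_idx)
        losses = []
        for s in range(0, len(tr_idx), B):
            b = tr_idx[s:s + B]
            opt.zero_grad()
            logits = net.forward(x_tr[b], x_ts[b], train=True)
            loss, dlog = ssl_loss_grad_logits(y_p[b], logits, loss_cfg)
            net.backward(dlog)
            opt.step()
            losses.append(loss)
        # validation pass
        val_logits = net.forward(x_tr[val_idx], x_ts[val_idx], train=False)
        val_loss = ssl_loss(y_p[val_idx], sigmoid(val_logits), loss_cfg)
        acc = ((sigmoid(val_logits) > 0.5) == (y_p[val_idx] > 0.5)).mean(axis=0)
        hist.train_loss.append(float(np.mean(losses)))
        hist.val_loss.append(float(val_loss))
        hist.val_metric.append([float(a) for a in acc])
        hist.lr.append(float(opt.lr))
        stop = stopper.update(epoch, val_loss, opt)
        if val_loss <= stopper.best:
            best_weights = {n: p.value.copy()
                            for n, p in net.named_params().items()}
        hist.stop_epoch = epoch + 1
        if stop:
            break
    hist.best_epoch = stopper.best_epoch + 1
    for n, p in net.named_params().items():
        p.value[...] = best_weights[n]
    bundle = WeightsBundle.from_network(net, metadata={"stage": "pretext"})
    return bundle, hist


# ---------------------------------------------------------------------------
# supervised fine-tuning / training


def finetune(net: RegressionNetwork, x_r: np.ndarray, x_s: np.ndarray,
             y: np.ndarray, subjects: np.ndarray,
             train_cfg: TrainConfig | None = None,
             loss_cfg: LossConfig | None = None,
             ) -> tuple[WeightsBundle, TrainHistory]:
    """Train the severity regressor with Huber loss; frozen tensors untouched.

    ``y`` carries the round-level clinical score broadcast to each of the
    round's windows (round labels are the only supervision available).
    Works for both transfer-initialized and fully supervised variants.
    """
    train_cfg = train_cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig()
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("no labeled windows to train on")
    rng = np.random.default_rng(train_cfg.seed)
    net.seed_dropouts(train_cfg.seed + 1)
    tr_mask, val_mask = subject_validation_split(subjects,
                                                 train_cfg.val_fraction, rng)
    tr_idx = np.flatnonzero(tr_mask)
    val_idx = np.flatnonzero(val_mask)
    if train_cfg.target_standardize:
        net.target_mean_ = float(y[tr_idx].mean())
        net.target_std_ = float(max(y[tr_idx].std(), 1e-8))
    ys = (y - net.target_mean_) / net.target_std_
    opt = Adam(net.params(), lr=train_cfg.learning_rate)
    stopper = _EarlyStop(train_cfg)
    hist = TrainHistory()
    best_weights = {n: p.value.copy() for n, p in net.named_params().items()}
    delta = loss_cfg.huber_delta
    B = train_cfg.batch_size

    def fwd(idx, train):
        xr = x_r[idx] if net.use_raw else None
        xs = x_s[idx] if net.use_spec else None
        return net.forward(xr, xs, train=train)

    for epoch in range(train_cfg.epochs):
        rng.shuffle(tr_idx)
        losses = []
        for s in range(0, len(tr_idx), B):
            b = tr_idx[s:s + B]
            opt.zero_grad()
            y_hat = fwd(b, True)
            losses.append(huber_loss(ys[b], y_hat, delta))
            net.backward(huber_grad(ys[b], y_hat, delta))
            opt.step()
        y_hat_val = fwd(val_idx, False)
        val_loss = huber_loss(ys[val_idx], y_hat_val, delta)
        val_est = y_hat_val * net.target_std_ + net.target_mean_
        hist.train_loss.append(float(np.mean(losses)))
        hist.val_loss.append(float(val_loss))
        hist.val_metric.append(float(np.abs(y[val_idx] - val_est).mean()))
        hist.lr.append(float(opt.lr))
        stop = stopper.update(epoch, val_loss, opt)
        if val_loss <= stopper.best:
            best_weights = {n: p.value.copy()
                            for n, p in net.named_params().items()}
        hist.stop_epoch = epoch + 1
        if stop:
            break
    hist.best_epoch = stopper.best_epoch + 1
    for n, p in net.named_params().items():
        p.value[...] = best_weights[n]
    bundle = WeightsBundle.from_network(
        net, metadata={"stage": "finetune", "target_mean": net.target_mean_,
                       "target_std": net.target_std_})
    return bundle, hist
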