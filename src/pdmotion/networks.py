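"""Network architectures for pretext-task learning and severity regression.

Two convolutional branches are shared by every model in the family:

* **ConvR** (raw branch): two 1D blocks over the 320x6 window — 64 kernels
  of size 32, max-pool (16, stride 4), dropout 0.1; then 128 kernels of
  size 8, dropout 0.2. Pooled mode ends in global average pooling (128
  features); sequence mode keeps the 77x128 conv time axis for an LSTM.
* **ConvS** (spectrogram branch): two 2D blocks over the 33x43x6 dB image —
  64 kernels 5x5, max-pool 2x2, dropout 0.1; then 128 kernels 3x3, dropout
  0.1. Pooled mode ends in global max pooling; sequence mode averages the
  frequency axis to a 21x128 sequence.

The self-supervised network concatenates both pooled branches and attaches
one 128-unit shared task layer plus sigmoid output per transformation task.
The regression network runs a 128-unit LSTM over each branch sequence,
fuses the last states, and maps dense(256, relu) -> linear scalar. The
seven-variant model family (single/multichannel CNN and CNN-LSTM plus the
self-supervised multichannel CNN-LSTM) reuses these same branch
definitions, so pretext-trained convolutional weights transfer key-for-key.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .config import NetworkConfig
from .nn import (Conv1D, Conv2D, Dense, Dropout, GlobalAvgPool,
                 GlobalMaxPool, LSTM, MaxPool1D, MaxPool2D, Param, ReLU,
                 sigmoid)

MODEL_VARIANTS = (
    "cnn1d",
    "cnn2d",
    "cnn_multi",
    "cnn1d_lstm",
    "cnn2d_lstm",
    "cnn_multi_lstm",
    "mssl_cnn_multi_lstm",
)


# ---------------------------------------------------------------------------
# branches


class RawBranch:
    """ConvR: 1D convolutional branch over (B, 320, 6) raw windows."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        f1, f2 = cfg.conv_r_filters
        k1, k2 = cfg.conv_r_kernels
        self.conv1 = Conv1D(cfg.n_channels, f1, k1, "convR/block1/conv", rng)
        self.relu1 = ReLU()
        self.pool = MaxPool1D(cfg.conv_r_pool, cfg.conv_r_pool_stride)
        self.drop1 = Dropout(cfg.conv_r_dropout[0])
        self.conv2 = Conv1D(f1, f2, k2, "convR/block2/conv", rng)
        self.relu2 = ReLU()
        self.drop2 = Dropout(cfg.conv_r_dropout[1])
        self.gap = GlobalAvgPool()
        self.out_dim = f2
        self.seq_len = (cfg.window_samples - cfg.conv_r_pool) // cfg.conv_r_pool_stride + 1
        self._expected_input = (cfg.window_samples, cfg.n_channels)

    def layers(self):
        return [self.conv1, self.relu1, self.pool, self.drop1,
                self.conv2, self.relu2, self.drop2]

    def params(self):
        return self.conv1.params() + self.conv2.params()

    def forward(self, x, train=False, pooled=True):
        if x.ndim != 3 or x.shape[1:] != self._expected_input:
            raise ValueError(
                f"raw branch expects (B, {self._expected_input[0]}, "
                f"{self._expected_input[1]}), got {x.shape}")
        h = x
        for layer in self.layers():
            h = layer.forward(h, train=train)
        return self.gap.forward(h, train=train) if pooled else h

    def backward(self, d, pooled=True):
        if pooled:
            d = self.gap.backward(d)
        for layer in reversed(self.layers()):
            d = layer.backward(d)
        return d


class SpecBranch:
    """ConvS: 2D convolutional branch over (B, 33, 43, 6) spectrograms."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        f1, f2 = cfg.conv_s_filters
        (k1h, k1w), (k2h, k2w) = cfg.conv_s_kernels
        self.conv1 = Conv2D(cfg.n_channels, f1, (k1h, k1w), "convS/block1/conv", rng)
        self.relu1 = ReLU()
        self.pool = MaxPool2D(cfg.conv_s_pool, cfg.conv_s_pool_stride)
        self.drop1 = Dropout(cfg.conv_s_dropout[0])
        self.conv2 = Conv2D(f1, f2, (k2h, k2w), "convS/block2/conv", rng)
        self.relu2 = ReLU()
        self.drop2 = Dropout(cfg.conv_s_dropout[1])
        self.gmp = GlobalMaxPool()
        self.out_dim = f2
        self.seq_len = cfg.spec_shape[1] // cfg.conv_s_pool
        self._n_freq = cfg.spec_shape[0] // cfg.conv_s_pool
        self._expected_input = (*cfg.spec_shape, cfg.n_channels)

    def layers(self):
        return [self.conv1, self.relu1, self.pool, self.drop1,
                self.conv2, self.relu2, self.drop2]

    def params(self):
        return self.conv1.params() + self.conv2.params()

    def forward(self, x, train=False, pooled=True):
        if x.ndim != 4 or x.shape[1:] != self._expected_input:
            raise ValueError(
                f"spectrogram branch expects (B, {self._expected_input}), "
                f"got {x.shape}")
        h = x
        for layer in self.layers():
            h = layer.forward(h, train=train)
        if pooled:
            return self.gmp.forward(h, train=train)
        # frequency-averaged sequence: (B, F', T', C) -> (B, T', C)
        self._seq_nfreq = h.shape[1]
        return h.mean(axis=1)

    def backward(self, d, pooled=True):
        if pooled:
            d = self.gmp.backward(d)
        else:
            nf = self._seq_nfreq
            d = np.repeat(d[:, None, :, :], nf, axis=1) / nf
        for layer in reversed(self.layers()):
            d = layer.backward(d)
        return d


# ---------------------------------------------------------------------------
# self-supervised (pretext) network


class SSLNetwork:
    """Two pooled branches + one shared 128-unit layer per recognition task.

    ``forward`` returns per-task logits; ``predict_proba`` maps them through
    a sigmoid to the transformation probabilities P_t.
    """

    def __init__(self, cfg: NetworkConfig | None = None, seed: int = 0):
        self.cfg = cfg or NetworkConfig()
        rng = np.random.default_rng(seed)
        self.raw = RawBranch(self.cfg, rng)
        self.spec = SpecBranch(self.cfg, rng)
        feat = self.raw.out_dim + self.spec.out_dim
        self.heads = []
        for t in range(self.cfg.n_tasks):
            dense = Dense(feat, self.cfg.task_head_size, f"task{t}/dense", rng)
            relu = ReLU()
            out = Dense(self.cfg.task_head_size, 1, f"task{t}/out", rng)
            self.heads.append((dense, relu, out))

    def params(self) -> list[Param]:
        ps = self.raw.params() + self.spec.params()
        for dense, _, out in self.heads:
            ps += dense.params() + out.params()
        return ps

    def named_params(self) -> dict[str, Param]:
        return {p.name: p for p in self.params()}

    def seed_dropouts(self, seed: int) -> None:
        ds = [self.raw.drop1, self.raw.drop2, self.spec.drop1, self.spec.drop2]
        for i, d in enumerate(ds):
            d.seed(seed + i)

    def forward(self, x_r, x_s, train=False) -> np.ndarray:
        fr = self.raw.forward(x_r, train=train, pooled=True)
        fs_ = self.spec.forward(x_s, train=train, pooled=True)
        feat = np.concatenate([fr, fs_], axis=1)
        logits = np.empty((x_r.shape[0], self.cfg.n_tasks))
        for t, (dense, relu, out) in enumerate(self.heads):
            h = relu.forward(dense.forward(feat, train), train)
            logits[:, t] = out.forward(h, train)[:, 0]
        return logits

    def predict_proba(self, x_r, x_s) -> np.ndarray:
        return sigmoid(self.forward(x_r, x_s, train=False))

    def backward(self, dlogits: np.ndarray) -> None:
        dfeat = 0.0
        for t, (dense, relu, out) in enumerate(self.heads):
            dh = out.backward(dlogits[:, t:t + 1])
            dfeat = dfeat + dense.backward(relu.backward(dh))
        nr = self.raw.out_dim
        self.raw.backward(dfeat[:, :nr], pooled=True)
        self.spec.backward(dfeat[:, nr:], pooled=True)


# ---------------------------------------------------------------------------
# regression network family


class RegressionNetwork:
    """UPDRS-III estimator; covers all seven model variants.

    Single-input variants reuse the same branch definitions; LSTM variants
    feed each branch's intra-window sequence to a 128-unit LSTM and fuse
    last states, non-LSTM variants fuse pooled branch features directly.
    The output is an unbounded linear unit (clipping to the clinical range
    is a reporting decision, not part of the model).
    """

    def __init__(self, variant: str = "cnn_multi_lstm",
                 cfg: NetworkConfig | None = None, seed: int = 0):
        if variant not in MODEL_VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; "
                             f"choose from {MODEL_VARIANTS}")
        self.variant = variant
        self.cfg = cfg or NetworkConfig()
        self.use_raw = variant not in ("cnn2d", "cnn2d_lstm")
        self.use_spec = variant not in ("cnn1d", "cnn1d_lstm")
        self.use_lstm = variant.endswith("_lstm")
        rng = np.random.default_rng(seed)
        self.raw = RawBranch(self.cfg, rng) if self.use_raw else None
        self.spec = SpecBranch(self.cfg, rng) if self.use_spec else None

        feat = 0
        self.lstm_r = self.lstm_s = None
        self.drop_r = self.drop_s = None
        if self.use_raw:
            if self.use_lstm:
                self.lstm_r = LSTM(self.raw.out_dim, self.cfg.lstm_size,
                                   "lstmR", rng)
                self.drop_r = Dropout(self.cfg.lstm_dropout)
                feat += self.cfg.lstm_size
            else:
                feat += self.raw.out_dim
        if self.use_spec:
            if self.use_lstm:
                self.lstm_s = LSTM(self.spec.out_dim, self.cfg.lstm_size,
                                   "lstmS", rng)
                self.drop_s = Dropout(self.cfg.lstm_dropout)
                feat += self.cfg.lstm_size
            else:
                feat += self.spec.out_dim
        self.fusion = Dense(feat, self.cfg.fusion_dense, "fusion/dense", rng)
        self.fusion_relu = ReLU()
        self.output = Dense(self.cfg.fusion_dense, 1, "output", rng)
        # target scaling fitted during training; identity until then
        self.target_mean_ = 0.0
        self.target_std_ = 1.0

    def params(self) -> list[Param]:
        ps: list[Param] = []
        if self.use_raw:
            ps += self.raw.params()
        if self.use_spec:
            ps += self.spec.params()
        for l in (self.lstm_r, self.lstm_s):
            if l is not None:
                ps += l.params()
        ps += self.fusion.params() + self.output.params()
        return ps

    def named_params(self) -> dict[str, Param]:
        return {p.name: p for p in self.params()}

    def seed_dropouts(self, seed: int) -> None:
        ds = []
        if self.use_raw:
            ds += [self.raw.drop1, self.raw.drop2]
        if self.use_spec:
            ds += [self.spec.drop1, self.spec.drop2]
        ds += [d for d in (self.drop_r, self.drop_s) if d is not None]
        for i, d in enumerate(ds):
            d.seed(seed + i)

    def forward(self, x_r=None, x_s=None, train=False) -> np.ndarray:
        feats = []
        if self.use_raw:
            if x_r is None:
                raise ValueError(f"variant {self.variant} requires raw input x_r")
            h = self.raw.forward(x_r, train=train, pooled=not self.use_lstm)
            if self.use_lstm:
                h = self.drop_r.forward(self.lstm_r.forward(h, train), train)
            feats.append(h)
        elif x_r is not None and x_s is None:
            raise ValueError(f"variant {self.variant} takes spectrogram input only")
        if self.use_spec:
            if x_s is None:
                raise ValueError(f"variant {self.variant} requires spectrogram input x_s")
            h = self.spec.forward(x_s, train=train, pooled=not self.use_lstm)
            if self.use_lstm:
                h = self.drop_s.forward(self.lstm_s.forward(h, train), train)
            feats.append(h)
        elif x_s is not None and x_r is None:
            raise ValueError(f"variant {self.variant} takes raw input only")
        self._split = [f.shape[1] for f in feats]
        feat = np.concatenate(feats, axis=1) if len(feats) > 1 else feats[0]
        h = self.fusion_relu.forward(self.fusion.forward(feat, train), train)
        return self.output.forward(h, train)[:, 0]

    def predict(self, x_r=None, x_s=None) -> np.ndarray:
        """Severity estimates in clinical units (inverts target scaling)."""
        out = self.forward(x_r, x_s, train=False)
        return out * self.target_std_ + self.target_mean_

    def backward(self, dy: np.ndarray) -> None:
        dh = self.output.backward(dy[:, None])
        dfeat = self.fusion.backward(self.fusion_relu.backward(dh))
        chunks = np.split(dfeat, np.cumsum(self._split)[:-1], axis=1)
        i = 0
        if self.use_raw:
            d = chunks[i]; i += 1
            if self.use_lstm:
                d = self.lstm_r.backward(self.drop_r.backward(d))
            self.raw.backward(d, pooled=not self.use_lstm)
        if self.use_spec:
            d = chunks[i]; i += 1
            if self.use_lstm:
                d = self.lstm_s.backward(self.drop_s.backward(d))
            self.spec.backward(d, pooled=not self.use_lstm)


def build_model(variant: str, cfg: NetworkConfig | None = None,
                seed: int = 0) -> RegressionNetwork:
    """Construct one of the seven severity-estimation variants."""
    return RegressionNetwork(variant, cfg, seed)


def count_params(net) -> int:
    return int(sum(p.value.size for p in net.params()))


# ---------------------------------------------------------------------------
# weight bundles and transfer learning


@dataclass
class WeightsBundle:
    """Named parameter tensors with freeze flags and provenance metadata."""

    weights: dict[str, np.ndarray]
    frozen: set[str] = field(default_factory=set)
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_network(cls, net, metadata: dict | None = None) -> "WeightsBundle":
        return cls(
            weights={n: p.value.copy() for n, p in net.named_params().items()},
            frozen={n for n, p in net.named_params().items() if p.frozen},
            metadata=dict(metadata or {}),
        )

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            for name, arr in self.weights.items():
                f.create_dataset(name, data=arr)
            f.attrs["frozen"] = json.dumps(sorted(self.frozen))
            f.attrs["metadata"] = json.dumps(self.metadata, default=str)

    @classmethod
    def load(cls, path) -> "WeightsBundle":
        weights = {}

        def visit(name, obj):
            if isinstance(obj, h5py.Dataset):
                weights[name] = obj[...]

        with h5py.File(path, "r") as f:
            f.visititems(visit)
            frozen = set(json.loads(f.attrs.get("frozen", "[]")))
            metadata = json.loads(f.attrs.get("metadata", "{}"))
        return cls(weights, frozen, metadata)


def conv_block_keys(names, branches=("convR", "convS")) -> set[str]:
    return {n for n in names
            if any(n.startswith(f"{b}/block") for b in branches)}


def transfer_and_freeze(ssl_bundle: WeightsBundle, target: RegressionNetwork,
                        freeze_blocks: set[str] = frozenset({"block1"}),
                        ) -> RegressionNetwork:
    """Copy pretext-trained conv weights into the target net and freeze blocks.

    All convolutional-block parameters present in the target are copied from
    the bundle (a key mismatch raises, listing the missing keys); parameters
    whose block name is in ``freeze_blocks`` are marked frozen so the
    optimizer never updates them. LSTM/dense layers keep their fresh
    initialization.
    """
    named = target.named_params()
    conv_keys = conv_block_keys(named)
    missing = sorted(conv_keys - set(ssl_bundle.weights))
    if missing:
        raise KeyError(f"pretext bundle lacks convolutional keys: {missing}")
    for key in conv_keys:
        src = ssl_bundle.weights[key]
        if src.shape != named[key].value.shape:
            raise ValueError(f"shape mismatch for {key}: "
                             f"{src.shape} vs {named[key].value.shape}")
        named[key].value[...] = src
        if any(f"/{blk}/" in key for blk in freeze_blocks):
            named[key].frozen = True
    return target
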