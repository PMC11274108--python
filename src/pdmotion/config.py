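"""Configuration dataclasses for every pipeline stage.

Defaults mirror the published architecture and training recipe: two-block
convolutional branches (64→128 kernels, sizes 32/8 raw and 5×5/3×3
spectrogram), 128-unit task heads and LSTMs, a 256-unit fusion layer, Adam
at 1e-4 for 35 epochs with batch size 32, Huber δ = 1. All configs
round-trip losslessly through ``to_dict``/``from_dict`` (and YAML via the
CLI) and hash stably for provenance stamping.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field


# Offsets added to the master seed so each stage draws from an independent,
# individually reproducible stream.
STAGE_SEED_OFFSETS = {
    "simulate": 0,
    "preprocess": 1,
    "transforms": 2,
    "pretrain": 3,
    "finetune": 4,
    "evaluate": 5,
}


def stage_seed(master_seed: int, stage: str) -> int:
    return (int(master_seed) + STAGE_SEED_OFFSETS[stage]) % (2 ** 31)


@dataclass
class StftConfig:
    """Spectrogram settings: 1 s Kaiser window, 90% overlap at 64 Hz.

    The nominal hop 64·(1−0.9) = 6.4 samples is fractional; the overlap is
    rounded to 58 samples (hop 6), the closest integer realization.
    """

    win_s: float = 1.0
    overlap_frac: float = 0.9
    kaiser_beta: float = 8.0
    nfft: int = 64
    log_floor_db: float = -80.0
    crop_hz: float | None = None  # optionally crop bins above this frequency

    def __post_init__(self):
        if not 0.0 <= self.overlap_frac < 1.0:
            raise ValueError("overlap_frac must be in [0, 1)")

    def win_samples(self, fs: float) -> int:
        return int(round(self.win_s * fs))

    def hop(self, fs: float) -> int:
        w = self.win_samples(fs)
        hop = w - int(round(self.overlap_frac * w))
        return max(hop, 1)


@dataclass
class FilterConfig:
    low_hz: float = 0.5
    high_hz: float = 15.0
    num_taps: int = 513


@dataclass
class TransformConfig:
    rotation_max_deg: float = 180.0
    permute_segments: int = 4
    warp_knots: int = 4
    warp_sigma: float = 0.2  # fraction of window duration
    rng_seed: int = 0


@dataclass
class NetworkConfig:
    # raw-signal branch (1D)
    conv_r_filters: tuple[int, int] = (64, 128)
    conv_r_kernels: tuple[int, int] = (32, 8)
    conv_r_pool: int = 16
    conv_r_pool_stride: int = 4
    conv_r_dropout: tuple[float, float] = (0.1, 0.2)
    # spectrogram branch (2D)
    conv_s_filters: tuple[int, int] = (64, 128)
    conv_s_kernels: tuple[tuple[int, int], tuple[int, int]] = ((5, 5), (3, 3))
    conv_s_pool: int = 2
    conv_s_pool_stride: int = 2
    conv_s_dropout: tuple[float, float] = (0.1, 0.1)
    # heads and recurrent part
    task_head_size: int = 128
    n_tasks: int = 3
    lstm_size: int = 128
    lstm_dropout: float = 0.1
    fusion_dense: int = 256
    fusion: str = "concat"  # fusion operator for branch outputs
    n_channels: int = 6
    window_samples: int = 320
    spec_shape: tuple[int, int] = (33, 43)

    @classmethod
    def reduced(cls, scale: int = 8) -> "NetworkConfig":
        """A width-reduced configuration for desk-scale experiments."""
        return cls(
            conv_r_filters=(max(4, 64 // scale), max(8, 128 // scale)),
            conv_s_filters=(max(4, 64 // scale), max(8, 128 // scale)),
            task_head_size=max(8, 128 // scale),
            lstm_size=max(8, 128 // scale),
            fusion_dense=max(16, 256 // scale),
        )


@dataclass
class LossConfig:
    alphas: tuple[float, float, float] = (1.0, 1.0, 1.0)
    positive_weight: float = 3.0
    huber_delta: float = 1.0
    prob_clip_eps: float = 1e-7


@dataclass
class TrainConfig:
    epochs: int = 35
    batch_size: int = 32
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    early_stop_patience: int = 10
    lr_factor: float = 0.5
    lr_patience: int = 5
    lr_floor: float = 1e-6
    val_fraction: float = 0.2
    #: z-score regression targets on the training split (inverted at
    #: prediction time) so the Huber delta acts on a unit-variance scale
    target_standardize: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")


#: activities of the structured (group A) protocol with movement-amplitude
#: multipliers relative to unscaled ADL movement
GROUP_A_ACTIVITIES = {
    "ambulation": 1.5,
    "resting": 0.2,
    "cutting_food": 0.8,
    "dressing": 1.0,
    "drinking": 0.7,
    "unpacking_groceries": 1.1,
    "hygiene": 0.9,
}

GROUP_B_ACTIVITIES = {
    "laundry": 1.0,
    "watching_television": 0.3,
    "snacking": 0.6,
    "desk_work": 0.5,
}


@dataclass
class CohortConfig:
    n_subjects: int = 12
    protocol: str = "mixed"  # 'A', 'B' or 'mixed' (≈5/8 structured, as observed)
    round_duration_s: float = 600.0
    session_duration_s: float = 1800.0
    exam_duration_s: float = 20.0
    activity_min_s: float = 15.0
    activity_max_s: float = 60.0
    severity_off_range: tuple[int, int] = (12, 60)
    severity_on_range: tuple[int, int] = (4, 38)
    tremor_f_range: tuple[float, float] = (4.0, 6.0)
    tremor_amp_coeff: float = 25.0   # deg/s at severity 60 above onset
    tremor_onset_threshold: float = 15.0
    ankle_tremor_factor: float = 0.5
    movement_band: tuple[float, float] = (0.5, 3.0)
    movement_amp: float = 30.0       # deg/s RMS at severity 0, unscaled activity
    bradykinesia_slope: float = 0.6
    noise_sigma: float = 2.0
    wearoff_prob: float = 0.25
    fs: float = 64.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.fs != 64.0:
            raise ValueError("only 64 Hz cohorts are supported")
        for lo, hi in (self.severity_off_range, self.severity_on_range,
                       self.tremor_f_range, self.movement_band):
            if lo >= hi:
                raise ValueError("range bounds must be increasing")


@dataclass
class ExperimentConfig:
    variant: str = "mssl_cnn_multi_lstm"
    master_seed: int = 0
    stft: StftConfig = field(default_factory=StftConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    transform: TransformConfig = field(default_factory=TransformConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    #: settings for the pretext stage; falls back to ``train`` when None
    pretrain: TrainConfig | None = None
    loss: LossConfig = field(default_factory=LossConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)

    @classmethod
    def desk_scale(cls, master_seed: int = 0,
                   variant: str = "mssl_cnn_multi_lstm") -> "ExperimentConfig":
        """Width-reduced networks and short rounds sized for one CPU core.

        Fine-tuning runs its full epoch budget (patience = epochs) because
        early stopping on the 1-subject validation split of a small fold is
        noise-driven; the pretext stage trains briefly at a low rate (see
        the methods note on pretext transfer at reduced width).
        """
        return cls(
            variant=variant,
            master_seed=master_seed,
            network=NetworkConfig.reduced(),
            train=TrainConfig(epochs=30, batch_size=16, learning_rate=1e-3,
                              early_stop_patience=30, lr_patience=8),
            pretrain=TrainConfig(epochs=5, batch_size=16, learning_rate=3e-4,
                                 early_stop_patience=5),
            cohort=CohortConfig(n_subjects=8, round_duration_s=90.0,
                                session_duration_s=180.0, exam_duration_s=5.0),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        def build(tp, sub):
            fields = {f.name: f for f in dataclasses.fields(tp)}
            kwargs = {}
            for k, v in sub.items():
                if k not in fields:
                    raise ValueError(f"unknown config key {k!r} for {tp.__name__}")
                ftype = fields[k].type
                if isinstance(v, list):
                    v = tuple(tuple(e) if isinstance(e, list) else e for e in v)
                kwargs[k] = v
            return tp(**kwargs)

        d = dict(d)
        sub_types = {"stft": StftConfig, "filter": FilterConfig,
                     "transform": TransformConfig, "network": NetworkConfig,
                     "train": TrainConfig, "pretrain": TrainConfig,
                     "loss": LossConfig, "cohort": CohortConfig}
        kwargs = {}
        for k, v in d.items():
            if k in sub_types and v is not None:
                kwargs[k] = build(sub_types[k], v)
            else:
                kwargs[k] = v
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]
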