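"""Pretext-task signal transformations and self-supervised dataset assembly.

Three label-free transformations give the network recognition tasks to
learn from: a random 3D rotation of each sensor's axis triplet (emulating
placement variability), a random permutation of contiguous temporal
segments, and a smooth monotone time warp. Each source window contributes
four samples — the untouched original plus one singly-transformed copy per
task — with one-hot pseudo-labels over (rotation, permutation, time-warp),
and every sample's spectrogram is recomputed from its transformed raw
signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial.transform import Rotation

from .config import StftConfig, TransformConfig
from .preprocess import compute_spectrograms

TRANSFORM_NAMES = ("rotation", "permutation", "time_warp")


@dataclass
class SSLSample:
    x_tr: np.ndarray        # (samples, 6) raw window (possibly transformed)
    x_ts: np.ndarray        # (bins, frames, 6) spectrogram of x_tr
    y_p: np.ndarray         # (3,) one-hot over TRANSFORM_NAMES, all-zero if original
    t: int                  # 0 = original, 1..3 = transform id
    subject_id: str = ""


def rotate(window: np.ndarray, rng: np.random.Generator,
           max_deg: float = 180.0) -> np.ndarray:
    """Rotate each sensor's 3-axis triplet by an independent random rotation.

    Axis uniform on the sphere, angle uniform in [-max_deg, max_deg]; the
    per-timestep Euclidean norm of each triplet is preserved.
    """
    window = np.asarray(window, dtype=float)
    n_ch = window.shape[1]
    if n_ch % 3 != 0:
        raise ValueError(f"channel count {n_ch} is not a multiple of 3")
    out = np.empty_like(window)
    for s in range(n_ch // 3):
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        angle = np.deg2rad(rng.uniform(-max_deg, max_deg))
        R = Rotation.from_rotvec(angle * axis).as_matrix()
        out[:, 3 * s:3 * s + 3] = window[:, 3 * s:3 * s + 3] @ R.T
    return out


def permute(window: np.ndarray, n_segments: int,
            rng: np.random.Generator) -> np.ndarray:
    """Split into equal contiguous segments and reorder them randomly.

    The last segment absorbs the division remainder; the identity
    permutation is rejected and resampled so the output order always
    differs from the input order.
    """
    window = np.asarray(window, dtype=float)
    L = window.shape[0]
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    if n_segments > L:
        raise ValueError(f"n_segments {n_segments} exceeds window length {L}")
    base = L // n_segments
    bounds = [i * base for i in range(n_segments)] + [L]
    blocks = [window[bounds[i]:bounds[i + 1]] for i in range(n_segments)]
    while True:
        order = rng.permutation(n_segments)
        if not np.array_equal(order, np.arange(n_segments)):
            break
    return np.concatenate([blocks[i] for i in order], axis=0)


def time_warp(window: np.ndarray, rng: np.random.Generator,
              n_knots: int = 4, sigma: float = 0.2) -> np.ndarray:
    """Resample along a smooth monotone random warping of the time axis.

    A cubic spline through ``n_knots`` interior anchors (perturbed by a
    Gaussian of scale ``sigma`` × window duration) maps output time to
    source time; endpoints are fixed and non-monotone draws are rejected.
    Values are linearly interpolated, so each channel's output stays within
    its input range and the first/last samples are unchanged.
    """
    window = np.asarray(window, dtype=float)
    L = window.shape[0]
    if n_knots < 2:
        raise ValueError("n_knots must be >= 2")
    anchors = np.linspace(0.0, L - 1.0, n_knots + 2)
    for _ in range(1000):
        pert = anchors.copy()
        pert[1:-1] += rng.normal(0.0, sigma * (L - 1), size=n_knots)
        if np.all(np.diff(pert) > 0):
            break
    else:  # pragma: no cover - sigma pathologically large
        pert = anchors
    spline = CubicSpline(anchors, pert)
    src = np.clip(spline(np.arange(L)), 0.0, L - 1.0)
    src[0], src[-1] = 0.0, L - 1.0
    out = np.empty_like(window)
    grid = np.arange(L)
    for c in range(window.shape[1]):
        out[:, c] = np.interp(src, grid, window[:, c])
    return out


def apply_transform(window: np.ndarray, t: int, cfg: TransformConfig,
                    rng: np.random.Generator) -> np.ndarray:
    if t == 0:
        return np.array(window, dtype=float)
    if t == 1:
        return rotate(window, rng, cfg.rotation_max_deg)
    if t == 2:
        return permute(window, cfg.permute_segments, rng)
    if t == 3:
        return time_warp(window, rng, cfg.warp_knots, cfg.warp_sigma)
    raise ValueError(f"unknown transform id {t}")


def build_ssl_dataset(windows: np.ndarray, cfg: TransformConfig,
                      stft_cfg: StftConfig | None = None, fs: float = 64.0,
                      subject_ids: np.ndarray | None = None,
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray,
                                 np.ndarray]:
    """Assemble the self-supervised training set from preprocessed windows.

    For each input window emits 4 samples (original + one per transform)
    with pseudo-labels ``y_p`` in {0,1}^3 (exactly one 1 for transformed
    samples, all zero for originals). Spectrograms are recomputed from each
    sample's raw signal. Output order is shuffled under ``cfg.rng_seed``.

    Returns (x_tr, x_ts, y_p, t, subjects) as stacked arrays.
    """
    windows = np.asarray(windows, dtype=float)
    stft_cfg = stft_cfg or StftConfig()
    n = windows.shape[0]
    if n == 0:
        shp = (0,) + windows.shape[1:]
        return (np.empty(shp), np.empty((0, 0, 0, 0)), np.empty((0, 3)),
                np.empty(0, dtype=int), np.empty(0, dtype=object))
    if subject_ids is None:
        subject_ids = np.array([""] * n, dtype=object)
    rng = np.random.default_rng(cfg.rng_seed)
    x_tr, y_p, t_ids, subs = [], [], [], []
    for i in range(n):
        for t in range(4):
            x_tr.append(apply_transform(windows[i], t, cfg, rng))
            label = np.zeros(3)
            if t > 0:
                label[t - 1] = 1.0
            y_p.append(label)
            t_ids.append(t)
            subs.append(subject_ids[i])
    x_tr = np.stack(x_tr)
    y_p = np.stack(y_p)
    t_ids = np.array(t_ids)
    subs = np.array(subs, dtype=object)
    x_ts = compute_spectrograms(x_tr, stft_cfg, fs)
    order = rng.permutation(len(x_tr))
    return x_tr[order], x_ts[order], y_p[order], t_ids[order], subs[order]


def save_ssl_dataset(path, x_tr, x_ts, y_p, t, subjects) -> None:
    """Persist an assembled SSL dataset (same HDF5 layout as window stores)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("x_r", data=x_tr)
        f.create_dataset("x_s", data=x_ts)
        f.create_dataset("y_p", data=y_p)
        f.create_dataset("t", data=t)
        f.create_dataset("meta/subject", data=np.asarray(subjects, dtype="S"))


def load_ssl_dataset(path):
    import h5py

    with h5py.File(path, "r") as f:
        return (f["x_r"][...], f["x_s"][...], f["y_p"][...], f["t"][...],
                f["meta/subject"][...].astype(str))
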