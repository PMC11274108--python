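"""Leave-one-subject-out evaluation and round-level metric reporting.

Estimates are produced per 5 s window, then averaged within each clinical
round (the unit at which a neurologist assigns a score), and round means
are compared to the clinical scores with Pearson r, R^2, MAE and RMSE.
Grouped reports break the same quantities down by activity or medication
state. All splitting is subject-disjoint: the held-out subject contributes
nothing to training windows, normalization statistics or the early-stopping
validation split, and ``audit_no_leakage`` checks exactly that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import (ExperimentConfig, StftConfig, TrainConfig,
                     TransformConfig, stage_seed)
from .data import WindowSet
from .networks import SSLNetwork, build_model, transfer_and_freeze
from .preprocess import ChannelZScore, SpectrogramMinMax, compute_spectrograms
from .train import finetune, pretrain
from .transforms import build_ssl_dataset


# ---------------------------------------------------------------------------
# splits


def loso_folds(subject_ids) -> list[tuple[list, object]]:
    """One (train_ids, test_id) fold per subject; exhaustive and disjoint."""
    ids = list(subject_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate subject ids")
    if len(ids) < 2:
        raise ValueError("need at least 2 subjects")
    return [([s for s in ids if s != test], test) for test in ids]


def grouped_folds(subject_ids, n_splits: int, seed: int = 0,
                  ) -> list[tuple[list, list]]:
    """Subject-grouped k-fold: each subject held out in exactly one fold."""
    ids = list(subject_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate subject ids")
    if not 2 <= n_splits <= len(ids):
        raise ValueError("n_splits must be in [2, n_subjects]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    chunks = np.array_split(order, n_splits)
    folds = []
    for chunk in chunks:
        test = [ids[i] for i in chunk]
        train = [s for s in ids if s not in set(test)]
        folds.append((train, test))
    return folds


def audit_no_leakage(folds, window_subjects_per_fold) -> bool:
    """Assert subject-disjointness between train and test for every fold.

    ``window_subjects_per_fold`` is a list of (train_window_subjects,
    test_window_subjects) actually used by the experiment (including any
    structure that saw normalization statistics or validation splits).
    Raises on any overlap; returns True when clean.
    """
    for (train_ids, test_ids), (tr_ws, te_ws) in zip(folds,
                                                     window_subjects_per_fold):
        test_set = {test_ids} if np.isscalar(test_ids) or isinstance(
            test_ids, str) else set(test_ids)
        overlap = test_set & set(train_ids)
        if overlap:
            raise AssertionError(f"fold shares subjects {overlap}")
        if set(tr_ws) & test_set:
            raise AssertionError(
                f"test-subject windows leaked into training structures: "
                f"{set(tr_ws) & test_set}")
        if not set(te_ws) <= test_set:
            raise AssertionError("foreign windows in the test set")
    return True


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MetricsReport:
    r: float
    r_pvalue: float
    r2: float
    mae: float
    rmse: float
    n_rounds: int
    group: str | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"r": self.r, "r_pvalue": self.r_pvalue, "r2": self.r2,
             "mae": self.mae, "rmse": self.rmse, "n_rounds": self.n_rounds}
        if self.group is not None:
            d["group"] = self.group
        d.update(self.extras)
        return d


def compute_metrics(y, y_hat, group: str | None = None) -> MetricsReport:
    """Pearson r (two-sided p), R^2 = 1 - SS_res/SS_tot, MAE and RMSE."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.ndim != 1:
        raise ValueError("paired 1-D vectors required")
    n = y.size
    if n < 2:
        return MetricsReport(np.nan, np.nan, np.nan,
                             float(np.abs(y - y_hat).mean()) if n else np.nan,
                             np.nan, n, group, {"flag": "too_few_rounds"})
    mae = float(np.abs(y - y_hat).mean())
    rmse = float(np.sqrt(((y - y_hat) ** 2).mean()))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return MetricsReport(np.nan, np.nan, np.nan, mae, rmse, n, group,
                             {"flag": "zero_variance_targets"})
    r2 = 1.0 - float(((y - y_hat) ** 2).sum()) / ss_tot
    if np.std(y_hat) == 0.0:
        r, p = np.nan, np.nan
    else:
        r, p = stats.pearsonr(y, y_hat)
        if n < 3:
            p = np.nan
    return MetricsReport(float(r), float(p), r2, mae, rmse, n, group)


def round_average(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse window estimates to per-round means paired with clinic scores.

    ``df`` needs columns subject, round, y, y_hat (extra grouping columns
    pass through if constant within round). Rounds with no windows simply
    do not appear.
    """
    keys = ["subject", "round"]
    agg = {"y_hat": "mean", "y": "first"}
    for extra in ("med_state",):
        if extra in df.columns:
            agg[extra] = "first"
    return df.groupby(keys, as_index=False).agg(agg)


def grouped_metrics(df: pd.DataFrame, group_key: str) -> list[MetricsReport]:
    """Round-level metrics per value of ``group_key`` (activity, med_state, ...).

    Window estimates are round-averaged within each group before scoring.
    For medication-state grouping the report also carries the median and
    IQR of per-subject MAE.
    """
    if group_key not in df.columns:
        raise KeyError(f"group key {group_key!r} not in prediction columns")
    reports = []
    for val, sub in df.groupby(group_key):
        rounds = sub.groupby(["subject", "round"], as_index=False).agg(
            {"y_hat": "mean", "y": "first"})
        rep = compute_metrics(rounds["y"], rounds["y_hat"], group=str(val))
        if group_key == "med_state" and len(rounds) >= 2:
            per_subj = rounds.assign(err=(rounds.y - rounds.y_hat).abs()) \
                             .groupby("subject")["err"].mean()
            q1, med, q3 = np.percentile(per_subj, [25, 50, 75])
            rep.extras.update({"subject_mae_median": float(med),
                               "subject_mae_iqr": float(q3 - q1)})
        reports.append(rep)
    return reports


# ---------------------------------------------------------------------------
# experiment driver


@dataclass
class ExperimentResult:
    variant: str
    predictions: pd.DataFrame          # window-level with y, y_hat
    rounds: pd.DataFrame               # round-level means
    pooled: MetricsReport
    per_subject: list[MetricsReport]
    histories: list[dict]
    fold_subjects: list[tuple[list, list]]

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "pooled": self.pooled.to_dict(),
            "per_subject": [m.to_dict() for m in self.per_subject],
            "n_windows": int(len(self.predictions)),
        }


def _prepare_fold(window_set: WindowSet, train_ids: set, test_ids: set,
                  stft_cfg: StftConfig):
    subs = window_set.subjects.astype(str)
    tr_mask = np.isin(subs, list(train_ids))
    te_mask = np.isin(subs, list(test_ids))
    train = window_set.subset(tr_mask)
    test = window_set.subset(te_mask)
    zs = ChannelZScore().fit(train.x_r)
    xs_train_raw = compute_spectrograms(train.x_r, stft_cfg)
    mm = SpectrogramMinMax().fit(xs_train_raw)
    return train, test, zs, mm, xs_train_raw


def run_experiment(window_set: WindowSet, variant: str,
                   cfg: ExperimentConfig | None = None,
                   folds: list[tuple[list, list]] | None = None,
                   ) -> ExperimentResult:
    """Cross-validated training and round-level evaluation of one variant.

    Defaults to leave-one-subject-out folds; pass ``folds`` for grouped
    k-fold at desk scale. The self-supervised variant pretrains on the
    fold's training windows (pretext transformations), transfers the
    convolutional weights with first blocks frozen, then fine-tunes; purely
    supervised variants train directly. Normalization statistics come from
    each fold's training windows only.
    """
    cfg = cfg or ExperimentConfig(variant=variant)
    subjects = list(dict.fromkeys(window_set.subjects.astype(str)))
    if folds is None:
        folds = [(tr, [te]) for tr, te in loso_folds(subjects)]
    preds = []
    histories = []
    fold_subjects = []
    seed0 = stage_seed(cfg.master_seed, "evaluate")
    for k, (train_ids, test_ids) in enumerate(folds):
        fold_seed = (seed0 + 1000 * k) % (2 ** 31)
        train, test, zs, mm, xs_train_raw = _prepare_fold(
            window_set, set(train_ids), set(test_ids), cfg.stft)
        xr_train = zs.transform(train.x_r)
        xs_train = mm.transform(xs_train_raw)
        xr_test = zs.transform(test.x_r)
        xs_test = mm.transform(compute_spectrograms(test.x_r, cfg.stft))
        y_train = train.meta["updrs"].to_numpy(dtype=float)
        tr_subjects = train.subjects.astype(str)

        train_cfg = TrainConfig(**{**cfg.train.__dict__, "seed": fold_seed})
        pre_base = cfg.pretrain if cfg.pretrain is not None else cfg.train
        pre_cfg = TrainConfig(**{**pre_base.__dict__, "seed": fold_seed})
        net_seed = fold_seed + 7

        if variant == "mssl_cnn_multi_lstm":
            t_cfg = TransformConfig(**{**cfg.transform.__dict__,
                                       "rng_seed": fold_seed + 13})
            x_tr, x_ts, y_p, _, ssl_subs = build_ssl_dataset(
                train.x_r, t_cfg, cfg.stft, subject_ids=tr_subjects)
            x_tr = zs.transform(x_tr)
            x_ts = mm.transform(x_ts)
            ssl_net = SSLNetwork(cfg.network, seed=net_seed)
            bundle, hist_p = pretrain(ssl_net, x_tr, x_ts, y_p, ssl_subs,
                                      pre_cfg, cfg.loss)
            histories.append({"stage": "pretrain", "fold": k,
                              **hist_p.to_dict()})
            net = build_model("cnn_multi_lstm", cfg.network, seed=net_seed + 1)
            transfer_and_freeze(bundle, net)
        else:
            net = build_model(variant, cfg.network, seed=net_seed)

        _, hist_f = finetune(net, xr_train, xs_train, y_train, tr_subjects,
                             train_cfg, cfg.loss)
        histories.append({"stage": "finetune", "fold": k, **hist_f.to_dict()})

        y_hat = net.predict(xr_test if net.use_raw else None,
                            xs_test if net.use_spec else None)
        df = test.meta.copy()
        df["y"] = test.meta["updrs"].astype(float)
        df["y_hat"] = y_hat
        df["fold"] = k
        preds.append(df)
        fold_subjects.append((sorted(set(tr_subjects)),
                              sorted(set(test.subjects.astype(str)))))

    predictions = pd.concat(preds, ignore_index=True)
    rounds = round_average(predictions)
    pooled = compute_metrics(rounds["y"], rounds["y_hat"])
    per_subject = [
        compute_metrics(sub["y"], sub["y_hat"], group=str(s))
        for s, sub in rounds.groupby("subject")
    ]
    audit_no_leakage(folds, fold_subjects)
    return ExperimentResult(variant=variant, predictions=predictions,
                            rounds=rounds, pooled=pooled,
                            per_subject=per_subject, histories=histories,
                            fold_subjects=fold_subjects)


def desk_benchmark(master_seed: int,
                   variants=("mssl_cnn_multi_lstm", "cnn_multi_lstm"),
                   n_folds: int = 3) -> dict[str, ExperimentResult]:
    """Simulate a desk-scale cohort and evaluate variants on shared folds.

    The whole chain — cohort synthesis, preprocessing, fold assignment,
    pretraining/fine-tuning — derives from ``master_seed``, so a repeat
    call reproduces results exactly.
    """
    import dataclasses

    from .preprocess import preprocess_cohort
    from .simulate import simulate_cohort

    cfg = ExperimentConfig.desk_scale(master_seed)
    cohort_cfg = dataclasses.replace(cfg.cohort,
                                     seed=stage_seed(master_seed, "simulate"))
    window_set = preprocess_cohort(simulate_cohort(cohort_cfg))
    subjects = sorted(set(window_set.subjects.astype(str)))
    folds = grouped_folds(subjects, n_folds,
                          seed=stage_seed(master_seed, "evaluate"))
    return {v: run_experiment(window_set, v, cfg, folds=folds)
            for v in variants}
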