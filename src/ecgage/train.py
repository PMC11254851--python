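"""Cross-validated training harness: MSE loss, Adam, step-decayed learning
rate, best-on-validation checkpointing, and 10-fold averaging.

Fold rotation: for test fold ``f`` the validation fold is ``(f+1) mod 10`` and
the remaining eight folds train (the archive's published split defines folds
but not the holdout-validation convention, so the rotation is explicit and
configurable via ``val_offset``).  All randomness -- batch order, augmentation,
corruption -- derives from one seed through separate spawned streams, so a
fold run repeats bit-identically.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import augment as aug
from . import corrupt as cor
from .io import CachedCohort
from .models import LayerGraph
from .nn import Adam
from .preprocess import pad_to_grid

N_FOLDS = 10


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    batch_size: int = 96
    lr: float = 0.001
    decay_factor: float = 0.1
    decay_every: int = 80
    val_offset: int = 1
    corrupt_eval: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1 or self.lr <= 0:
            raise ValueError("invalid training configuration")
        if not (0 < self.decay_factor <= 1) or self.decay_every < 1:
            raise ValueError("invalid decay schedule")

    def lr_at(self, epoch: int) -> float:
        """Learning rate for 1-based ``epoch`` (decays every ``decay_every``)."""
        return self.lr * self.decay_factor ** ((epoch - 1) // self.decay_every)


@dataclass
class EvalResult:
    mse: float
    mae: float
    mae_sd: float
    pred_mean: float
    pred_sd: float


@dataclass
class FoldResult:
    fold: int
    best_val_mse: float
    best_epoch: int
    test_mse: float
    test_mae: float
    test_mae_sd: float
    pred_mean: float
    pred_sd: float
    history: list = field(default_factory=list)


def predict(graph: LayerGraph, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
    preds = [graph.forward(X[i:i + batch_size], train=False)
             for i in range(0, len(X), batch_size)]
    return np.concatenate(preds) if preds else np.empty(0)


def evaluate(graph: LayerGraph, X: np.ndarray, ages: np.ndarray,
             batch_size: int = 256) -> EvalResult:
    """MSE, MAE mean +/- SD, and predicted-age mean +/- SD over the records."""
    ages = np.asarray(ages, dtype=np.float64)
    if len(X) != len(ages):
        raise ValueError(f"{len(X)} records but {len(ages)} ages")
    pred = predict(graph, X, batch_size).astype(np.float64)
    err = pred - ages
    abserr = np.abs(err)
    return EvalResult(mse=float(np.mean(err ** 2)),
                      mae=float(abserr_mean := abserr.mean()),
                      mae_sd=float(abserr.std()),
                      pred_mean=float(pred.mean()),
                      pred_sd=float(pred.std()))


def _fit_length(batch: np.ndarray, input_len: int) -> np.ndarray:
    """Pad (never trim) a batch onto the model's grid input length."""
    batch = pad_to_grid(batch)
    L = batch.shape[-1]
    if L > input_len:
        raise ValueError(f"batch length {L} exceeds model input {input_len}")
    if L < input_len:
        batch = np.pad(batch, ((0, 0), (0, 0), (0, input_len - L)))
    return batch


def _eval_inputs(cohort: CachedCohort, idx: np.ndarray, graph: LayerGraph,
                 policy: aug.AugmentPolicy | None) -> np.ndarray:
    X = cohort.signals[idx]
    if policy is not None and policy.scheme == "random_crop":
        w = int(round(policy.crop_seconds * float(cohort.rates[idx[0]])))
        X = X[:, :, :w]  # deterministic first-k crop at evaluation
    return _fit_length(X, graph.input_len)


def _annotations_for(cohort: CachedCohort, idx: np.ndarray) -> list:
    return [cohort.annotations.get(cohort.record_ids[i], []) for i in idx]


def train_fold(graph: LayerGraph, cohort: CachedCohort, fold: int,
               cfg: TrainConfig = TrainConfig(),
               policy: aug.AugmentPolicy | None = None,
               scheme: cor.MaskScheme | None = None,
               seed: int | None = None,
               train_idx: np.ndarray | None = None) -> FoldResult:
    """Train ``graph`` with fold ``fold`` held out as test.

    The best-validation-MSE weights are restored before the test evaluation.
    ``train_idx`` optionally restricts the training records (transfer-learning
    subsets); validation and test splits are never subsampled.
    """
    seed = cfg.seed if seed is None else seed
    folds = np.asarray(cohort.folds)
    present = np.unique(folds)
    if fold not in present:
        raise ValueError(f"fold {fold} not present in cohort folds {present}")
    val_fold = (fold + cfg.val_offset) % N_FOLDS
    test_idx = np.flatnonzero(folds == fold)
    val_idx = np.flatnonzero(folds == val_fold)
    if train_idx is None:
        train_idx = np.flatnonzero((folds != fold) & (folds != val_fold))
    train_idx = np.asarray(train_idx)
    if train_idx.size == 0:
        raise ValueError("empty training split")

    ss = np.random.SeedSequence([seed, fold])
    rng_batch, rng_aug, rng_cor, rng_evalcor = (
        np.random.default_rng(s) for s in ss.spawn(4))

    rate = float(cohort.rates[train_idx[0]])
    ages = cohort.ages
    X_val = _eval_inputs(cohort, val_idx, graph, policy)
    X_test = _eval_inputs(cohort, test_idx, graph, policy)
    if scheme is not None and cfg.corrupt_eval:
        X_val = cor.mask_batch(X_val, _annotations_for(cohort, val_idx),
                               scheme, rng_evalcor)
        X_test = cor.mask_batch(X_test, _annotations_for(cohort, test_idx),
                                scheme, rng_evalcor)

    params = graph.parameters()
    opt = Adam(params, lr=cfg.lr)
    best_state = graph.state_dict()
    best_val = evaluate(graph, X_val, ages[val_idx]).mse
    best_epoch = 0
    history = [{"epoch": 0, "train_mse": np.nan, "val_mse": best_val,
                "lr": cfg.lr_at(1) if cfg.epochs else cfg.lr}]

    for epoch in range(1, cfg.epochs + 1):
        opt.lr = cfg.lr_at(epoch)
        order = rng_batch.permutation(train_idx)
        sq_sum, n_seen = 0.0, 0
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            xb = cohort.signals[idx]
            if scheme is not None:
                xb = cor.mask_batch(xb, _annotations_for(cohort, idx),
                                    scheme, rng_cor)
            if policy is not None:
                xb = aug.apply_policy(xb, policy, rng_aug, rate=rate)
            xb = _fit_length(xb, graph.input_len)
            yb = ages[idx]
            pred = graph.forward(xb, train=True)
            err = pred - yb
            sq_sum += float(np.sum(err ** 2))
            n_seen += len(idx)
            opt.zero_grad()
            graph.backward((2.0 * err / len(idx)).astype(np.float32))
            opt.step()
        val = evaluate(graph, X_val, ages[val_idx]).mse
        history.append({"epoch": epoch, "train_mse": sq_sum / n_seen,
                        "val_mse": val, "lr": opt.lr})
        if val < best_val:
            best_val, best_epoch = val, epoch
            best_state = graph.state_dict()

    graph.load_state_dict(best_state)
    test = evaluate(graph, X_test, ages[test_idx])
    return FoldResult(fold=fold, best_val_mse=float(best_val),
                      best_epoch=best_epoch, test_mse=test.mse,
                      test_mae=test.mae, test_mae_sd=test.mae_sd,
                      pred_mean=test.pred_mean, pred_sd=test.pred_sd,
                      history=history)


def cross_validate(builder, cohort: CachedCohort,
                   cfg: TrainConfig = TrainConfig(),
                   policy: aug.AugmentPolicy | None = None,
                   scheme: cor.MaskScheme | None = None,
                   folds=None) -> tuple[list[FoldResult], dict]:
    """Train one fresh network per fold and average the test metrics.

    ``builder(fold)`` must return a newly initialized :class:`LayerGraph`.
    """
    folds = list(range(N_FOLDS)) if folds is None else list(folds)
    present = set(np.unique(cohort.folds).tolist())
    missing = [f for f in folds if f not in present]
    if missing:
        raise ValueError(f"cohort is missing folds {missing}")
    results = [train_fold(builder(f), cohort, f, cfg, policy, scheme)
               for f in folds]
    mean = {
        "test_mse": float(np.mean([r.test_mse for r in results])),
        "test_mae": float(np.mean([r.test_mae for r in results])),
        "pred_mean": float(np.mean([r.pred_mean for r in results])),
        "pred_sd": float(np.mean([r.pred_sd for r in results])),
    }
    return results, mean
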