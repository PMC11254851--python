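"""Fine-tuning versus scratch-training across shrinking train-set sizes.

Protocol: pretrain on a source population, then for each subset size ``n``
draw ``n`` training records uniformly without replacement from the target
population's training folds and either (a) fine-tune the pretrained network
with everything up to the third residual block frozen, or (b) train an
identically configured network from random initialization.  Both arms share
the target test/validation folds (paired design).  A zero-shot arm (pretrained
weights evaluated untouched on the target) quantifies the raw population gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CachedCohort
from .models import LayerGraph, freeze_scope
from .train import FoldResult, TrainConfig, N_FOLDS, evaluate, train_fold, _eval_inputs


@dataclass(frozen=True)
class SubsetSchedule:
    sizes: tuple[int, ...] = (8000, 4000, 2000, 1000, 500, 250, 125)
    nested: bool = False
    seed: int = 0

    def __post_init__(self):
        if any(s < 1 for s in self.sizes):
            raise ValueError("subset sizes must be positive")


def subsample_train(cohort: CachedCohort, n: int, seed: int,
                    test_fold: int = 0, val_offset: int = 1) -> np.ndarray:
    """Uniformly sample ``n`` training-record indices without replacement."""
    folds = np.asarray(cohort.folds)
    val_fold = (test_fold + val_offset) % N_FOLDS
    pool = np.flatnonzero((folds != test_fold) & (folds != val_fold))
    if n > pool.size:
        raise ValueError(f"requested {n} training records but only "
                         f"{pool.size} are available")
    if n == pool.size:
        return np.sort(pool)
    rng = np.random.default_rng(np.random.SeedSequence([seed, n]))
    return np.sort(rng.choice(pool, size=n, replace=False))


def finetune(pretrained: LayerGraph, cohort: CachedCohort, n: int,
             cfg: TrainConfig, fold: int = 0, seed: int | None = None,
             boundary: str = "through_resblock3") -> FoldResult:
    """Fine-tune a pretrained ResNet1D on ``n`` target records.

    Only the fourth residual block and the scalar output layer are updated;
    frozen batch norms run on their stored statistics.
    """
    freeze_scope(pretrained, boundary)
    idx = subsample_train(cohort, n, seed if seed is not None else cfg.seed,
                          test_fold=fold, val_offset=cfg.val_offset)
    return train_fold(pretrained, cohort, fold, cfg, seed=seed, train_idx=idx)


def regime_curve(builder, source: CachedCohort, target: CachedCohort,
                 schedule: SubsetSchedule, cfg: TrainConfig,
                 pretrain_cfg: TrainConfig | None = None,
                 fold: int = 0, seed: int = 0) -> pd.DataFrame:
    """Fine-tune vs scratch-train test MSE on the target, per subset size.

    ``builder(seed)`` returns a fresh network.  Returns one row per schedule
    size with columns ``n, finetune_mse, finetune_mae, scratch_mse,
    scratch_mae`` plus attrs ``zero_shot_mse`` and ``scratch_full_mse``.
    """
    pretrain_cfg = pretrain_cfg or cfg
    pre = builder(seed)
    pre_result = train_fold(pre, source, fold, pretrain_cfg, seed=seed)
    pre_state = pre.state_dict()

    test_idx = np.flatnonzero(np.asarray(target.folds) == fold)
    X_test = _eval_inputs(target, test_idx, pre, None)
    zero_shot = evaluate(pre, X_test, target.ages[test_idx])

    rows = []
    for n in schedule.sizes:
        ft_net = builder(seed)
        ft_net.load_state_dict(pre_state)
        ft = finetune(ft_net, target, n, cfg, fold=fold, seed=seed)
        sc_net = builder(seed + 1)
        idx = subsample_train(target, n, cfg.seed if seed is None else seed,
                              test_fold=fold, val_offset=cfg.val_offset)
        sc = train_fold(sc_net, target, fold, cfg, seed=seed, train_idx=idx)
        rows.append({"n": n, "finetune_mse": ft.test_mse,
                     "finetune_mae": ft.test_mae,
                     "scratch_mse": sc.test_mse, "scratch_mae": sc.test_mae})
    out = pd.DataFrame(rows)
    out.attrs["zero_shot_mse"] = zero_shot.mse
    out.attrs["pretrain_test_mse"] = pre_result.test_mse
    return out
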