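"""Shared fixtures: synthetic records/cohorts and the two expensive
desk-scale training runs (computed once per session, consumed by several
tests)."""

from __future__ import annotations

import numpy as np
import pytest

from ecgage import io as eio
from ecgage import models, synth, transfer
from ecgage.train import TrainConfig, evaluate, train_fold, _eval_inputs


@pytest.fixture(scope="session")
def default_model():
    return synth.DEFAULT_MODEL


@pytest.fixture(scope="session")
def record500():
    """One annotated 10-s record at 500 Hz (age 50)."""
    return synth.synthesize_record(50.0, rate=500.0, duration=10.0, seed=3,
                                   patient_id="pt_fix", record_id="pt_fixr0")


@pytest.fixture(scope="session")
def small_cohort():
    """40 patients, one 2-s record each at 500 Hz, cached in memory."""
    table, records = synth.generate_cohort(40, 1, rates=(500.0,), seed=7,
                                           duration=2.0)
    return table, records, eio.cache_records(table, records)


@pytest.fixture(scope="session")
def learnability_run():
    """Reduced AttiaNet trained 30 epochs on 2,000 synthetic 2-s/100 Hz
    records (test fold 0): the desk-scale parameter-recovery study."""
    table, records = synth.generate_cohort(2000, 1, rates=(100.0,), seed=11,
                                           duration=2.0)
    cohort = eio.cache_records(table, records)
    graph = models.build_attianet(models.ATTIA_REDUCED, input_len=1024, seed=0)
    result = train_fold(graph, cohort, fold=0, cfg=TrainConfig(epochs=30, seed=0))
    return {"cohort": cohort, "graph": graph, "result": result}


@pytest.fixture(scope="session")
def transfer_runs():
    """Two-population transfer study at desk scale.

    Source population A uses the default age-morphology model; target B has
    +/-20 %-perturbed slopes and a redrawn lead projection.  One ResNet1D
    (reduced) is pretrained on A; ten seeds then pair a fine-tuned arm
    (frozen through residual block 3) against a scratch arm on the same
    125-record target subset, all evaluated on B's held-out test fold.
    """
    n_patients, epochs, smallest = 3000, 12, 125
    table_a, recs_a = synth.generate_cohort(n_patients, 1, rates=(500.0,),
                                            seed=21, duration=2.0)
    cohort_a = eio.cache_records(table_a, recs_a)
    model_b = synth.shifted_model(synth.DEFAULT_MODEL, seed=77)
    table_b, recs_b = synth.generate_cohort(n_patients, 1, rates=(500.0,),
                                            seed=22, duration=2.0, model=model_b)
    cohort_b = eio.cache_records(table_b, recs_b)

    def builder(seed):
        return models.build_resnet1d(models.RESNET_REDUCED, input_len=1024,
                                     seed=seed)

    cfg = TrainConfig(epochs=epochs, seed=100)
    pre = builder(100)
    train_fold(pre, cohort_a, 0, cfg)
    pre_state = pre.state_dict()

    test_idx = np.flatnonzero(np.asarray(cohort_b.folds) == 0)
    X_test = _eval_inputs(cohort_b, test_idx, pre, None)
    zero_shot_mse = evaluate(pre, X_test, cohort_b.ages[test_idx]).mse

    scratch_full = train_fold(builder(101), cohort_b, 0, cfg)

    pairs = []
    for s in range(10):
        ft_net = builder(100)
        ft_net.load_state_dict(pre_state)
        ft = transfer.finetune(ft_net, cohort_b, smallest, cfg, fold=0,
                               seed=200 + s)
        idx = transfer.subsample_train(cohort_b, smallest, 200 + s, test_fold=0)
        sc = train_fold(builder(300 + s), cohort_b, 0, cfg, seed=200 + s,
                        train_idx=idx)
        pairs.append((ft.test_mse, sc.test_mse))
    return {"zero_shot_mse": zero_shot_mse,
            "scratch_full_mse": scratch_full.test_mse,
            "pairs": pairs, "cohort_b": cohort_b, "builder": builder,
            "pre_state": pre_state, "cfg": cfg, "smallest": smallest}
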