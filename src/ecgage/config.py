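"""Run configuration: strict YAML schema, defaults, and experiment templates.

A run config names one of five experiment templates -- ``sampling_rate``,
``duration``, ``augmentation``, ``corruption``, ``transfer`` -- plus the model
family, cohort source (synthetic spec or a WFDB directory), training
hyper-parameters and a seed.  ``run_experiment`` materializes the cohort,
sweeps the template's conditions, and writes one tidy CSV of per-condition
cross-validated metrics plus a JSON-lines provenance log (config hash and all
derived seeds) into the output directory.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import augment as aug
from . import corrupt as cor
from . import io as ecg_io
from . import models, preprocess, synth, transfer
from .train import TrainConfig, cross_validate

EXPERIMENTS = ("sampling_rate", "duration", "augmentation", "corruption",
               "transfer")
MODELS = {
    "attianet": (models.build_attianet, models.ATTIA_DEFAULT),
    "attianet_reduced": (models.build_attianet, models.ATTIA_REDUCED),
    "resnet1d": (models.build_resnet1d, models.RESNET_DEFAULT),
    "resnet1d_reduced": (models.build_resnet1d, models.RESNET_REDUCED),
}

_TRAIN_KEYS = {"epochs", "batch_size", "lr", "decay_factor", "decay_every",
               "val_offset", "corrupt_eval"}
_COHORT_KEYS = {"n_patients", "records_per_patient", "duration_s", "rate",
                "wfdb_dir"}
_AUG_KEYS = {"scheme", "p_apply", "crop_seconds", "crop_per"}
_COR_KEYS = {"kind", "p_lead", "fill"}
_TOP_KEYS = {"experiment", "model", "rates", "durations", "augment", "corrupt",
             "train", "cohort", "output_dir", "seed", "folds", "schedule"}


@dataclass
class RunConfig:
    experiment: str
    model: str = "attianet_reduced"
    rates: tuple = (100.0, 200.0, 300.0, 400.0, 500.0)
    durations: tuple = (2.0, 4.0, 6.0, 8.0, 10.0)
    augment: dict = field(default_factory=dict)
    corrupt: dict = field(default_factory=dict)
    train: TrainConfig = field(default_factory=TrainConfig)
    cohort: dict = field(default_factory=lambda: {
        "n_patients": 200, "records_per_patient": 1,
        "duration_s": 10.0, "rate": 100.0})
    output_dir: str = "runs"
    seed: int = 0
    folds: tuple = tuple(range(10))
    schedule: tuple = (8000, 4000, 2000, 1000, 500, 250, 125)

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}; "
                             f"valid choices: {EXPERIMENTS}")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; "
                             f"valid choices: {tuple(MODELS)}")
        if any(r <= 0 for r in self.rates):
            raise ValueError("sampling rates must be positive")
        if any(d <= 0 for d in self.durations):
            raise ValueError("durations must be positive")

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown keys {sorted(unknown)} in {where}; "
                         f"allowed: {sorted(allowed)}")


def validate_config(path) -> RunConfig:
    """Parse + validate a YAML run config; unknown keys are rejected."""
    raw = yaml.safe_load(pathlib.Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    _check_keys(raw, _TOP_KEYS, "config")
    for key, allowed in (("train", _TRAIN_KEYS), ("cohort", _COHORT_KEYS),
                         ("augment", _AUG_KEYS), ("corrupt", _COR_KEYS)):
        if key in raw:
            _check_keys(raw[key] or {}, allowed, f"config.{key}")
    kwargs = dict(raw)
    if "train" in kwargs:
        kwargs["train"] = TrainConfig(**(kwargs["train"] or {}))
    for key in ("rates", "durations", "folds", "schedule"):
        if key in kwargs:
            kwargs[key] = tuple(float(v) if key in ("rates", "durations")
                                else int(v) for v in kwargs[key])
    cohort = dict(RunConfig.__dataclass_fields__["cohort"].default_factory())
    cohort.update(kwargs.get("cohort") or {})
    cohort["duration_s"] = float(cohort["duration_s"])
    cohort["rate"] = float(cohort["rate"])
    kwargs["cohort"] = cohort
    return RunConfig(**kwargs)


# ---------------------------------------------------------------------------
# experiment execution
# ---------------------------------------------------------------------------

def _make_cohort(cfg: RunConfig, rate: float | None = None,
                 duration: float | None = None,
                 model: synth.AgeMorphologyModel | None = None,
                 seed: int | None = None) -> ecg_io.CachedCohort:
    spec = cfg.cohort
    if spec.get("wfdb_dir"):
        d = pathlib.Path(spec["wfdb_dir"])
        return ecg_io.load_cohort(d / "cohort.csv", d)
    table, records = synth.generate_cohort(
        n_patients=int(spec["n_patients"]),
        records_per_patient=int(spec["records_per_patient"]),
        rates=(rate if rate is not None else spec["rate"],),
        model=model or synth.DEFAULT_MODEL,
        seed=cfg.seed if seed is None else seed,
        duration=duration if duration is not None else spec["duration_s"])
    return ecg_io.cache_records(table, records)


def _builder(cfg: RunConfig, input_len: int):
    build, mconf = MODELS[cfg.model]

    def make(seed_offset: int = 0):
        return build(mconf, input_len=input_len, seed=cfg.seed + seed_offset)
    return make


def _cv(cfg: RunConfig, cohort, input_len, policy=None, scheme=None,
        condition: str = "", outdir: pathlib.Path | None = None) -> dict:
    make = _builder(cfg, input_len)
    results, mean = cross_validate(lambda f: make(f), cohort, cfg.train,
                                   policy=policy, scheme=scheme,
                                   folds=cfg.folds)
    if outdir is not None:
        rows = [{"condition": condition, "fold": r.fold, **h}
                for r in results for h in r.history]
        path = outdir / "fold_logs.csv"
        pd.DataFrame(rows).to_csv(path, mode="a", index=False,
                                  header=not path.exists())
    return mean


def _grid_len(n_samples: int) -> int:
    return -(-n_samples // preprocess.GRID) * preprocess.GRID


def run_experiment(config: RunConfig) -> pd.DataFrame:
    """Execute one experiment template; returns (and writes) the result table."""
    outdir = pathlib.Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / f"{config.experiment}.log.jsonl"
    rows = []

    def log(event: str, **kw):
        with open(log_path, "a") as fh:
            fh.write(json.dumps({"event": event, "config": config.content_hash(),
                                 "seed": config.seed, **kw}) + "\n")

    log("start", experiment=config.experiment)

    if config.experiment == "sampling_rate":
        base = _make_cohort(config, rate=100.0)
        for rate in config.rates:
            cohort = _cohort_at_rate(config, base, rate)
            input_len = _grid_len(int(cohort.lengths.max()))
            mean = _cv(config, cohort, input_len,
                       condition=f"rate_{rate:g}", outdir=outdir)
            rows.append({"rate_hz": rate, **mean})
            log("condition", rate=rate, **mean)

    elif config.experiment == "duration":
        rate = config.cohort["rate"]
        base = _make_cohort(config, rate=rate)
        for dur in config.durations:
            n = int(round(dur * rate))
            sub = _truncate_cohort(base, n)
            mean = _cv(config, sub, _grid_len(n),
                       condition=f"duration_{dur:g}", outdir=outdir)
            rows.append({"duration_s": dur, **mean})
            log("condition", duration=dur, **mean)

    elif config.experiment == "augmentation":
        cohort = _make_cohort(config)
        input_len = _grid_len(int(cohort.lengths.max()))
        schemes = ["none", "flip", "reverse", "flip_reverse", "random_crop"]
        for scheme_name in schemes:
            policy = aug.AugmentPolicy(scheme=scheme_name,
                                       **{k: v for k, v in config.augment.items()
                                          if k != "scheme"})
            ilen = input_len
            if scheme_name == "random_crop":
                rate = float(cohort.rates[0])
                ilen = _grid_len(int(round(policy.crop_seconds * rate)))
            mean = _cv(config, cohort, ilen, policy=policy,
                       condition=scheme_name, outdir=outdir)
            rows.append({"scheme": scheme_name, **mean})
            log("condition", scheme=scheme_name, **mean)

    elif config.experiment == "corruption":
        cohort = _make_cohort(config)
        input_len = _grid_len(int(cohort.lengths.max()))
        for kind in ["none", "PR", "QRS", "QT", "random"]:
            scheme = None if kind == "none" else cor.MaskScheme(
                kind=kind, **{k: v for k, v in config.corrupt.items()
                              if k != "kind"})
            mean = _cv(config, cohort, input_len, scheme=scheme,
                       condition=f"mask_{kind}", outdir=outdir)
            rows.append({"mask": kind, **mean})
            log("condition", mask=kind, **mean)

    elif config.experiment == "transfer":
        source = _make_cohort(config)
        shifted = synth.shifted_model(synth.DEFAULT_MODEL, config.seed + 1)
        target = _make_cohort(config, model=shifted, seed=config.seed + 1)
        input_len = _grid_len(int(source.lengths.max()))
        make = _builder(config, input_len)
        curve = transfer.regime_curve(lambda s: make(s), source, target,
                                      transfer.SubsetSchedule(config.schedule),
                                      config.train, seed=config.seed)
        curve.to_csv(outdir / "transfer.csv", index=False)
        log("done", zero_shot_mse=curve.attrs["zero_shot_mse"])
        return curve

    frame = pd.DataFrame(rows)
    frame.to_csv(outdir / f"{config.experiment}.csv", index=False)
    log("done", n_conditions=len(frame))
    return frame


def _cohort_at_rate(cfg: RunConfig, base: ecg_io.CachedCohort,
                    rate: float) -> ecg_io.CachedCohort:
    """100 Hz native; 500 Hz synthesized natively; intermediates interpolated
    upward from the 100 Hz records."""
    if rate == 100.0:
        return base
    if rate == 500.0:
        return _make_cohort(cfg, rate=500.0)
    dur = cfg.cohort["duration_s"]
    n_new = int(round(dur * rate))
    n_old = int(base.lengths.max())
    t_src = np.arange(n_old) / 100.0
    t_dst = np.arange(n_new) / rate
    from scipy.interpolate import CubicSpline
    sig = CubicSpline(t_src, base.signals[:, :, :n_old], axis=2)(t_dst)
    scale = rate / 100.0
    anns = {rid: [synth.BeatAnnotation(*(int(round(v * scale))
                                         for v in (a.p_onset, a.qrs_onset,
                                                   a.qrs_offset, a.t_offset)))
                  for a in lst]
            for rid, lst in base.annotations.items()}
    return ecg_io.CachedCohort(signals=sig.astype(np.float32),
                               lengths=np.full(len(base), n_new),
                               ages=base.ages, folds=base.folds,
                               record_ids=base.record_ids,
                               patient_ids=base.patient_ids,
                               rates=np.full(len(base), rate),
                               annotations=anns)


def _truncate_cohort(base: ecg_io.CachedCohort, n: int) -> ecg_io.CachedCohort:
    anns = {rid: [a for a in lst if a.t_offset < n]
            for rid, lst in base.annotations.items()}
    return ecg_io.CachedCohort(signals=base.signals[:, :, :n].copy(),
                               lengths=np.minimum(base.lengths, n),
                               ages=base.ages, folds=base.folds,
                               record_ids=base.record_ids,
                               patient_ids=base.patient_ids,
                               rates=base.rates, annotations=anns)
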