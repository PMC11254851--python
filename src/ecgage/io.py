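"""Record and cohort I/O: WFDB files, metadata CSVs, and dense array caches.

Records are stored in the PhysioNet WFDB convention used by clinical resting
ECG archives: a text ``.hea`` header plus a format-16 ``.dat`` signal file
(little-endian int16, samples interleaved across the 12 leads) at a gain of
1,000 ADU/mV, i.e. 16-bit amplitude quantization at 1 µV/LSB.  In-memory
amplitudes are always millivolts; storage is integer microvolts.

For training, a whole cohort is flattened into one contiguous float32 block
(records x 12 x T_max) held in memory -- the preload strategy that keeps
disk I/O out of the epoch loop -- and can be round-tripped through HDF5.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .synth import BeatAnnotation, CohortTable, EcgRecord, N_LEADS

GAIN = 1000.0          # ADU per mV  (1 uV per LSB)
ADC_MAX = 32767        # int16 full scale

LEAD_NAMES = ("I", "II", "III", "aVR", "aVL", "aVF",
              "V1", "V2", "V3", "V4", "V5", "V6")


class SchemaError(ValueError):
    """Raised when on-disk files violate the 12-lead record schema."""


# ---------------------------------------------------------------------------
# WFDB records
# ---------------------------------------------------------------------------

def write_wfdb(record: EcgRecord, path) -> pathlib.Path:
    """Write ``<path>.hea`` + ``<path>.dat`` (WFDB format 16, 1 µV/LSB).

    Rejects amplitudes beyond the 16-bit range (+/-32.767 mV).
    """
    path = pathlib.Path(path)
    peak = float(np.abs(record.signal).max()) if record.signal.size else 0.0
    if peak * GAIN > ADC_MAX:
        raise ValueError(f"amplitude {peak:.3f} mV overflows 16-bit storage "
                         f"at 1 uV/LSB (max 32.767 mV)")
    adu = np.round(record.signal.astype(np.float64) * GAIN).astype(np.int16)
    n = record.n_samples
    name = path.name
    lines = [f"{name} {N_LEADS} {record.rate:g} {n}"]
    checksums = (adu.astype(np.int64).sum(axis=1) & 0xFFFF).astype(np.int64)
    checksums = np.where(checksums >= 0x8000, checksums - 0x10000, checksums)
    for i in range(N_LEADS):
        first = int(adu[i, 0]) if n else 0
        lines.append(f"{name}.dat 16 {GAIN:g}(0)/mV 16 0 {first} "
                     f"{int(checksums[i])} 0 {LEAD_NAMES[i]}")
    lines.append(f"# patient_id: {record.patient_id}")
    lines.append(f"# age: {record.age:.6g}")
    path.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    # format 16: sample-major interleave, little-endian
    adu.T.astype("<i2").tofile(path.with_suffix(".dat"))
    return path


def read_wfdb(path) -> EcgRecord:
    """Read a 12-lead WFDB record written by :func:`write_wfdb`."""
    path = pathlib.Path(path)
    hea = path.with_suffix(".hea")
    dat = path.with_suffix(".dat")
    if not hea.exists():
        raise FileNotFoundError(f"missing header file {hea}")
    if not dat.exists():
        raise FileNotFoundError(f"missing signal file {dat}")
    lines = [ln.strip() for ln in hea.read_text().splitlines() if ln.strip()]
    head = lines[0].split()
    n_sig, rate, n_samples = int(head[1]), float(head[2]), int(head[3])
    if n_sig != N_LEADS:
        raise SchemaError(f"{path.name}: expected {N_LEADS} leads, "
                          f"header declares {n_sig}")
    meta = {"patient_id": "", "age": np.nan}
    for ln in lines:
        if ln.startswith("# patient_id:"):
            meta["patient_id"] = ln.split(":", 1)[1].strip()
        elif ln.startswith("# age:"):
            meta["age"] = float(ln.split(":", 1)[1])
    raw = np.fromfile(dat, dtype="<i2")
    if raw.size != n_sig * n_samples:
        raise SchemaError(f"{path.name}: signal file holds {raw.size} samples, "
                          f"header declares {n_sig * n_samples}")
    signal = raw.reshape(n_samples, n_sig).T.astype(np.float32) / GAIN
    return EcgRecord(signal, rate, n_samples / rate, meta["patient_id"],
                     meta["age"], [], path.name)


# ---------------------------------------------------------------------------
# cohort on disk: metadata CSV + annotation sidecar + per-record WFDB
# ---------------------------------------------------------------------------

def save_cohort(directory, table: CohortTable, records: list) -> pathlib.Path:
    """Write ``cohort.csv``, ``annotations.csv`` and one WFDB pair per record."""
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table.frame.to_csv(directory / "cohort.csv", index=False)
    ann_rows = []
    for rec in records:
        write_wfdb(rec, directory / rec.record_id)
        for b, a in enumerate(rec.annotations):
            ann_rows.append({"record_id": rec.record_id, "beat_idx": b,
                             "p_on": a.p_onset, "qrs_on": a.qrs_onset,
                             "qrs_off": a.qrs_offset, "t_off": a.t_offset})
    pd.DataFrame(ann_rows, columns=["record_id", "beat_idx", "p_on",
                                    "qrs_on", "qrs_off", "t_off"]
                 ).to_csv(directory / "annotations.csv", index=False)
    return directory


def load_annotations(csv_path) -> dict[str, list[BeatAnnotation]]:
    frame = pd.read_csv(csv_path)
    out: dict[str, list[BeatAnnotation]] = {}
    for rid, grp in frame.groupby("record_id", sort=False):
        grp = grp.sort_values("beat_idx")
        out[str(rid)] = [BeatAnnotation(int(r.p_on), int(r.qrs_on),
                                        int(r.qrs_off), int(r.t_off))
                         for r in grp.itertuples()]
    return out


# ---------------------------------------------------------------------------
# dense in-memory cache
# ---------------------------------------------------------------------------

@dataclass
class CachedCohort:
    """Contiguous cohort block for fast epoch iteration.

    ``signals`` is (n_records, 12, T_max); rows beyond ``lengths[i]`` are
    zero padding.  Row order is the (record-id-sorted) metadata order and is
    shared by every aligned vector.
    """

    signals: np.ndarray
    lengths: np.ndarray
    ages: np.ndarray
    folds: np.ndarray
    record_ids: list
    patient_ids: list
    rates: np.ndarray
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        n = self.signals.shape[0]
        if not (len(self.lengths) == len(self.ages) == len(self.folds)
                == len(self.record_ids) == n):
            raise ValueError("cache vectors are not aligned")
        if (self.lengths > self.signals.shape[2]).any():
            raise ValueError("valid length exceeds block width")

    def __len__(self):
        return self.signals.shape[0]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("signals", data=self.signals)
            f.create_dataset("lengths", data=self.lengths)
            f.create_dataset("ages", data=self.ages)
            f.create_dataset("folds", data=self.folds)
            f.create_dataset("rates", data=self.rates)
            ids = np.array(self.record_ids, dtype="S")
            pids = np.array(self.patient_ids, dtype="S")
            f.create_dataset("record_ids", data=ids)
            f.create_dataset("patient_ids", data=pids)

    @classmethod
    def from_hdf5(cls, path) -> "CachedCohort":
        with h5py.File(path, "r") as f:
            return cls(signals=f["signals"][...], lengths=f["lengths"][...],
                       ages=f["ages"][...], folds=f["folds"][...],
                       record_ids=[s.decode() for s in f["record_ids"][...]],
                       patient_ids=[s.decode() for s in f["patient_ids"][...]],
                       rates=f["rates"][...])


def cache_records(table: CohortTable, records: list,
                  annotations: dict | None = None) -> CachedCohort:
    """Build a :class:`CachedCohort` directly from in-memory records."""
    by_id = {r.record_id: r for r in records}
    frame = table.frame.sort_values("record_id").reset_index(drop=True)
    missing = [rid for rid in frame.record_id if rid not in by_id]
    if missing:
        raise KeyError(f"records listed in metadata but not supplied: {missing}")
    recs = [by_id[rid] for rid in frame.record_id]
    t_max = max(r.n_samples for r in recs)
    block = np.zeros((len(recs), N_LEADS, t_max), dtype=np.float32)
    lengths = np.zeros(len(recs), dtype=np.int64)
    for i, r in enumerate(recs):
        block[i, :, :r.n_samples] = r.signal
        lengths[i] = r.n_samples
    ann = annotations if annotations is not None else {
        r.record_id: list(r.annotations) for r in recs}
    return CachedCohort(signals=block, lengths=lengths,
                        ages=frame.age.to_numpy(dtype=np.float64),
                        folds=frame.fold_id.to_numpy(dtype=np.int64),
                        record_ids=list(frame.record_id),
                        patient_ids=list(frame.patient_id),
                        rates=np.array([r.rate for r in recs]),
                        annotations=ann)


def load_cohort(metadata_csv, records_dir) -> CachedCohort:
    """Load a cohort from ``cohort.csv`` + WFDB records into one dense block.

    Content is keyed by record id, so shuffled CSV row order yields an
    identical cache.  A record listed in the metadata but absent on disk
    raises an error naming the record id.
    """
    records_dir = pathlib.Path(records_dir)
    frame = pd.read_csv(metadata_csv, float_precision="round_trip")
    table = CohortTable(frame)
    records = []
    for rid in frame.record_id:
        base = records_dir / str(rid)
        if not base.with_suffix(".hea").exists():
            raise FileNotFoundError(
                f"record {rid!r} listed in metadata but missing on disk "
                f"({base.with_suffix('.hea')})")
        rec = read_wfdb(base)
        records.append(rec)
    ann_csv = records_dir / "annotations.csv"
    annotations = load_annotations(ann_csv) if ann_csv.exists() else {}
    return cache_records(table, records, annotations)
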