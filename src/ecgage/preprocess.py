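"""Acquisition-parameter transforms: resampling, truncation, padding, stretching.

The model input-length convention is *pad-to-grid*: a raw signal is zero-padded
at the end to the next multiple of 1,024 samples, so a 10-s record contributes
1,024 points at 100 Hz and 5,120 at 500 Hz, and a 6-s record at 500 Hz
contributes 3,072.  Intermediate rates (200/300/400 Hz) are always produced by
interpolating the 100 Hz signal upward, never by decimating the 500 Hz one.
"""

from __future__ import annotations

from dataclasses import replace as _dc_replace

import numpy as np
from scipy import signal as sp_signal
from scipy.interpolate import CubicSpline, interp1d

from .synth import BeatAnnotation, EcgRecord

GRID = 1024
INTERP_KINDS = ("linear", "cubic", "fourier")


def _resample(signal: np.ndarray, t_src: np.ndarray, t_dst: np.ndarray,
              kind: str) -> np.ndarray:
    if kind == "cubic":
        return CubicSpline(t_src, signal, axis=1)(t_dst)
    if kind == "linear":
        return interp1d(t_src, signal, axis=1, bounds_error=False,
                        fill_value=(signal[:, 0], signal[:, -1]))(t_dst)
    if kind == "fourier":
        return sp_signal.resample(signal, len(t_dst), axis=1)
    raise ValueError(f"unknown interpolation kind {kind!r}; "
                     f"choose from {INTERP_KINDS}")


def interpolate_rate(record: EcgRecord, target_rate: float,
                     kind: str = "cubic") -> EcgRecord:
    """Resample every lead onto a shared time grid at ``target_rate``.

    Duration is preserved; the new sample count is ``duration * target_rate``.
    Fiducial indices are rescaled to the new grid.
    """
    if target_rate <= 0:
        raise ValueError("target rate must be positive")
    if target_rate == record.rate:
        return record
    n_new = int(round(record.duration * target_rate))
    t_src = np.arange(record.n_samples) / record.rate
    t_dst = np.arange(n_new) / target_rate
    sig = _resample(record.signal.astype(np.float64), t_src, t_dst, kind)
    scale = target_rate / record.rate
    anns = [BeatAnnotation(*(min(int(round(v * scale)), n_new - 1)
                             for v in (a.p_onset, a.qrs_onset,
                                       a.qrs_offset, a.t_offset)))
            for a in record.annotations]
    return EcgRecord(sig.astype(np.float32), target_rate, record.duration,
                     record.patient_id, record.age, anns, record.record_id)


def take_first_seconds(record: EcgRecord, k: float) -> EcgRecord:
    """Keep the first ``k`` seconds of every lead; beats that do not fit
    entirely inside the window are dropped from the annotation list."""
    if not 0 < k <= record.duration:
        raise ValueError(f"k={k} s outside (0, {record.duration:g}] s")
    n = int(round(k * record.rate))
    anns = [a for a in record.annotations if a.t_offset < n]
    return EcgRecord(record.signal[:, :n].copy(), record.rate, k,
                     record.patient_id, record.age, anns, record.record_id)


def pad_to_grid(signal: np.ndarray, grid: int = GRID) -> np.ndarray:
    """Zero-pad the last axis to the next multiple of ``grid`` (idempotent)."""
    signal = np.asarray(signal)
    L = signal.shape[-1]
    if L < 1:
        raise ValueError("cannot pad an empty signal")
    target = -(-L // grid) * grid
    if target == L:
        return signal
    pad = [(0, 0)] * (signal.ndim - 1) + [(0, target - L)]
    return np.pad(signal, pad)


def stretch_to_length(record: EcgRecord, n_points: int,
                      kind: str = "cubic") -> EcgRecord:
    """Interpolate (not pad) the record to exactly ``n_points`` samples.

    Wall-clock duration metadata is preserved; the effective sampling rate
    becomes ``n_points / duration``.
    """
    if n_points < record.n_samples:
        raise ValueError(f"n_points={n_points} below raw length "
                         f"{record.n_samples}; stretching only upsamples")
    if n_points == record.n_samples:
        return record
    t_src = np.arange(record.n_samples) / record.rate
    t_dst = np.linspace(0, t_src[-1], n_points)
    sig = _resample(record.signal.astype(np.float64), t_src, t_dst, kind)
    scale = (n_points - 1) / (record.n_samples - 1)
    anns = [BeatAnnotation(*(min(int(round(v * scale)), n_points - 1)
                             for v in (a.p_onset, a.qrs_onset,
                                       a.qrs_offset, a.t_offset)))
            for a in record.annotations]
    return EcgRecord(sig.astype(np.float32), n_points / record.duration,
                     record.duration, record.patient_id, record.age, anns,
                     record.record_id)
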