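"""Systematic and random per-lead signal corruption (masking).

Feature masks zero out a named fiducial interval -- PR ``[P_on, QRS_on)``,
QRS ``[QRS_on, QRS_off)`` or QT ``[QRS_on, T_off)`` -- in every beat of each
*selected* lead; leads are selected independently with probability
``p_lead`` (default 0.25), which emulates per-electrode faults and forces the
network to use the remaining clean leads.  Random masks remove a window of the
*same* expected length per beat at a uniformly random onset inside the beat
span, so the systematic and random conditions delete equal information and
stay directly comparable.  Unselected leads are returned bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .synth import EcgRecord

KINDS = ("PR", "QRS", "QT", "random")
FILLS = ("zero", "hold", "noise")


@dataclass(frozen=True)
class MaskScheme:
    kind: str = "QRS"
    p_lead: float = 0.25
    fill: str = "zero"
    feature: str | None = None   # length-matching feature for kind='random'
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown mask kind {self.kind!r}; choose from {KINDS}")
        if not 0.0 <= self.p_lead <= 1.0:
            raise ValueError("p_lead must lie in [0, 1]")
        if self.fill not in FILLS:
            raise ValueError(f"unknown fill {self.fill!r}; choose from {FILLS}")

    @property
    def match_feature(self) -> str:
        return self.feature or ("QRS" if self.kind == "random" else self.kind)


def _intervals(annotations, kind: str) -> list[tuple[int, int]]:
    if kind == "PR":
        return [(a.p_onset, a.qrs_onset) for a in annotations]
    if kind == "QRS":
        return [(a.qrs_onset, a.qrs_offset) for a in annotations]
    if kind == "QT":
        return [(a.qrs_onset, a.t_offset) for a in annotations]
    raise ValueError(f"no fiducial interval for kind {kind!r}")


def _require_annotations(record: EcgRecord) -> None:
    if not record.annotations:
        raise ValueError(
            f"record {record.record_id or record.patient_id!r} carries no beat "
            "annotations; masking requires fiducials (delineation of raw "
            "recordings is out of scope)")


def _fill_values(scheme: MaskScheme, lead: np.ndarray, lo: int, hi: int,
                 rng: np.random.Generator) -> np.ndarray:
    if scheme.fill == "zero":
        return np.zeros(hi - lo, dtype=lead.dtype)
    if scheme.fill == "hold":
        return np.full(hi - lo, lead[max(lo - 1, 0)], dtype=lead.dtype)
    sd = float(lead.std()) or 1.0
    return rng.normal(0.0, sd, hi - lo).astype(lead.dtype)


def _select_leads(n_leads: int, p: float, rng: np.random.Generator) -> np.ndarray:
    return rng.random(n_leads) < p


def feature_mask(record: EcgRecord, scheme: MaskScheme,
                 rng: np.random.Generator) -> EcgRecord:
    """Mask the scheme's fiducial interval in every beat of selected leads."""
    _require_annotations(record)
    if scheme.kind == "random":
        return random_mask(record, scheme, rng)
    sig = record.signal.copy()
    chosen = _select_leads(sig.shape[0], scheme.p_lead, rng)
    spans = _intervals(record.annotations, scheme.kind)
    for lead_i in np.flatnonzero(chosen):
        for lo, hi in spans:
            sig[lead_i, lo:hi] = _fill_values(scheme, sig[lead_i], lo, hi, rng)
    out = replace_signal(record, sig)
    return out


def random_mask(record: EcgRecord, scheme: MaskScheme,
                rng: np.random.Generator) -> EcgRecord:
    """Mask a window of the matched feature's mean length per beat, at a
    uniformly random onset within each beat span, in selected leads."""
    _require_annotations(record)
    spans = _intervals(record.annotations, scheme.match_feature)
    w = int(round(float(np.mean([hi - lo for lo, hi in spans]))))
    beat_spans = [(a.p_onset, a.t_offset) for a in record.annotations]
    sig = record.signal.copy()
    chosen = _select_leads(sig.shape[0], scheme.p_lead, rng)
    for lead_i in np.flatnonzero(chosen):
        for b_lo, b_hi in beat_spans:
            top = max(b_hi - w, b_lo)
            start = int(rng.integers(b_lo, top + 1))
            stop = min(start + w, record.n_samples)
            sig[lead_i, start:stop] = _fill_values(scheme, sig[lead_i],
                                                   start, stop, rng)
    return replace_signal(record, sig)


def replace_signal(record: EcgRecord, signal: np.ndarray) -> EcgRecord:
    return EcgRecord(signal, record.rate, record.duration, record.patient_id,
                     record.age, list(record.annotations), record.record_id)


def mask_batch(batch: np.ndarray, annotations: list, scheme: MaskScheme,
               rng: np.random.Generator) -> np.ndarray:
    """Batch-array version used inside the training loop.

    ``annotations[i]`` is the beat-annotation list of record ``i``; fiducial
    indices refer to the unpadded head of each row.  Fresh per-lead selections
    are drawn for every record.
    """
    out = np.array(batch, copy=True)
    for i, anns in enumerate(annotations):
        if not anns:
            raise ValueError(f"batch record {i} has no beat annotations")
        chosen = _select_leads(out.shape[1], scheme.p_lead, rng)
        if not chosen.any():
            continue
        if scheme.kind == "random":
            spans = _intervals(anns, scheme.match_feature)
            w = int(round(float(np.mean([hi - lo for lo, hi in spans]))))
            for lead_i in np.flatnonzero(chosen):
                for a in anns:
                    top = max(a.t_offset - w, a.p_onset)
                    start = int(rng.integers(a.p_onset, top + 1))
                    out[i, lead_i, start:start + w] = 0.0
        else:
            spans = _intervals(anns, scheme.kind)
            for lead_i in np.flatnonzero(chosen):
                for lo, hi in spans:
                    out[i, lead_i, lo:hi] = 0.0
    return out
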