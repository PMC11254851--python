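"""Training-batch augmentation: amplitude flip, time reversal, random crop.

Flip and reverse are applied to a whole batch with probability 0.5 per batch
(the network then sees transformed and original signals with equal likelihood);
random crop is applied with probability 1 and draws a fresh k-second window per
record each epoch.  Every operator acts identically on all 12 leads of a
record, preserving cross-lead temporal alignment; age labels ride along
untouched because record order never changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SCHEMES = ("none", "flip", "reverse", "flip_reverse", "random_crop")


@dataclass(frozen=True)
class AugmentPolicy:
    scheme: str = "none"
    p_apply: float | None = None   # default: 0.5, or 1.0 for random_crop
    crop_seconds: float = 8.0
    crop_per: str = "record"       # or "batch"
    seed: int = 0

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; choose from {SCHEMES}")
        if self.crop_per not in ("record", "batch"):
            raise ValueError("crop_per must be 'record' or 'batch'")
        p = self.probability
        if not 0.0 <= p <= 1.0:
            raise ValueError("p_apply must lie in [0, 1]")

    @property
    def probability(self) -> float:
        if self.p_apply is not None:
            return self.p_apply
        return 1.0 if self.scheme == "random_crop" else 0.5


def flip(batch: np.ndarray) -> np.ndarray:
    """Mirror every amplitude across the zero-volt baseline."""
    return -np.asarray(batch)


def reverse(batch: np.ndarray) -> np.ndarray:
    """Reverse the time axis, identically for all leads of every record."""
    return np.asarray(batch)[..., ::-1]


def random_crop(batch: np.ndarray, k: float, rate: float,
                rng: np.random.Generator, per: str = "record") -> np.ndarray:
    """Extract a k-second window at a uniformly random start offset.

    The offset is drawn in integer samples over ``{0, ..., (D - k) * rate}``
    (D = record duration implied by the batch length); one draw per record,
    or one shared draw per batch with ``per='batch'``.  All 12 leads of a
    record share the offset.
    """
    batch = np.asarray(batch)
    n, _, L = batch.shape
    w = int(round(k * rate))
    if w > L:
        raise ValueError(f"crop of {k} s at {rate:g} Hz ({w} samples) exceeds "
                         f"the record length {L}")
    hi = L - w  # inclusive upper bound of the start offset
    if hi == 0:
        return batch.copy()
    if per == "batch":
        starts = np.full(n, rng.integers(0, hi + 1))
    else:
        starts = rng.integers(0, hi + 1, size=n)
    idx = starts[:, None] + np.arange(w)[None, :]
    return np.take_along_axis(batch, idx[:, None, :], axis=2)


def apply_policy(batch: np.ndarray, policy: AugmentPolicy,
                 rng: np.random.Generator, rate: float | None = None
                 ) -> np.ndarray:
    """Apply a policy to one training batch (one Bernoulli draw per batch)."""
    if policy.scheme == "none" or rng.random() >= policy.probability:
        return np.asarray(batch)
    if policy.scheme == "flip":
        return flip(batch)
    if policy.scheme == "reverse":
        return reverse(batch)
    if policy.scheme == "flip_reverse":
        return reverse(flip(batch))
    if policy.scheme == "random_crop":
        if rate is None:
            raise ValueError("random_crop needs the sampling rate")
        return random_crop(batch, policy.crop_seconds, rate, rng, policy.crop_per)
    raise AssertionError("unreachable")
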