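"""Ploidy from integer segment profiles and genome-doubling calls.

The doubling call uses a strict ``ploidy > threshold`` comparison with a
default threshold of 3; the threshold is configurable because published
descriptions of the cutoff differ between strict and non-strict forms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .profiles_io import SegmentProfile, ValidationError

GD_THRESHOLD = 3.0


@dataclass(frozen=True)
class PloidyCall:
    sample_id: str
    ploidy: float
    gd: bool


def sample_ploidy(profile: SegmentProfile) -> float:
    """Length-weighted mean total copy number across the profile."""
    total_len = sum(s.length for s in profile.segments)
    if total_len == 0:
        raise ValidationError(f"sample {profile.sample_id}: zero total segment length")
    weighted = sum(s.length * s.total for s in profile.segments)
    return weighted / total_len


def call_gd(ploidy: float, threshold: float = GD_THRESHOLD) -> bool:
    if ploidy < 0:
        raise ValidationError("ploidy must be non-negative")
    return ploidy > threshold


def ploidy_calls(profiles: Sequence[SegmentProfile],
                 threshold: float = GD_THRESHOLD) -> list[PloidyCall]:
    calls = []
    for p in profiles:
        pl = sample_ploidy(p)
        calls.append(PloidyCall(p.sample_id, pl, call_gd(pl, threshold)))
    return calls


def ploidy_bimodality(calls: Sequence[PloidyCall]) -> float:
    """Percent of samples with ploidy in [1.5, 2.5] or strictly above 3.5."""
    if not calls:
        raise ValidationError("no ploidy calls")
    n = sum(1 for c in calls if 1.5 <= c.ploidy <= 2.5 or c.ploidy > 3.5)
    return 100.0 * n / len(calls)
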