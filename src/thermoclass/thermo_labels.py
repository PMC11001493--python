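"""Multi-threshold inference logic.

An ascending list of temperature thresholds tiles the real line into n+1
half-open ranges: (-inf, T1), [T1, T2), ..., [Tn, +inf).  Given the ordered
binary calls of the per-threshold classifiers, two labels are assigned:

* the left-hand label scans from the low-temperature end and reports the
  range opened by the last positive call of the *leading* run of 1s;
* the right-hand label scans from the high end and reports the range opened
  by the highest threshold called positive anywhere.

Because the per-threshold classifiers are independent, a non-monotone call
vector is possible; then the two labels differ and the profile is flagged
as a clash.  For monotone (non-increasing) call vectors both labels agree
and name the highest temperature range at which the protein is predicted
to still be stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_THRESHOLDS",
    "EXTENDED_THRESHOLDS",
    "TemperatureRange",
    "PredictionProfile",
    "ranges_from_thresholds",
    "binarize",
    "left_right_labels",
    "enumerate_consistency",
    "profile_from_ensembles",
]

DEFAULT_THRESHOLDS: tuple[float, ...] = (40.0, 45.0, 50.0, 55.0, 60.0, 65.0)
EXTENDED_THRESHOLDS: tuple[float, ...] = DEFAULT_THRESHOLDS + (70.0, 75.0, 80.0)


def _fmt(t: float) -> str:
    return f"{t:g}"


@dataclass(frozen=True)
class TemperatureRange:
    """Half-open temperature interval [lower, upper) in degrees Celsius."""

    lower: float  # -inf for the lowest range
    upper: float  # +inf for the highest range

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"range lower {self.lower} must be < upper {self.upper}")

    @property
    def name(self) -> str:
        if math.isinf(self.lower):
            return f"<{_fmt(self.upper)}"
        if math.isinf(self.upper):
            return f"{_fmt(self.lower)}+"
        return f"[{_fmt(self.lower)},{_fmt(self.upper)})"

    def __str__(self) -> str:
        return self.name


@dataclass
class PredictionProfile:
    """Ordered per-threshold predictions for one query sequence."""

    sequence_id: str
    thresholds: Sequence[float]
    probabilities: Sequence[float]
    binary_calls: Sequence[int]
    left_label: TemperatureRange
    right_label: TemperatureRange
    clash: bool

    def __post_init__(self) -> None:
        n = len(self.thresholds)
        if len(self.probabilities) != n or len(self.binary_calls) != n:
            raise ValueError("probabilities/calls must match threshold count")


def ranges_from_thresholds(thresholds: Sequence[float]) -> list[TemperatureRange]:
    """The n+1 half-open ranges tiling (-inf, inf) given n thresholds."""
    ts = _validated_thresholds(thresholds)
    bounds = [-math.inf, *ts, math.inf]
    return [TemperatureRange(bounds[i], bounds[i + 1]) for i in range(len(ts) + 1)]


def _validated_thresholds(thresholds: Sequence[float]) -> list[float]:
    ts = [float(t) for t in thresholds]
    if not ts:
        raise ValueError("threshold list must be non-empty")
    if any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValueError(f"thresholds must be strictly ascending, got {ts}")
    return ts


def binarize(probabilities: Sequence[float], cutoff: float = 0.5) -> list[int]:
    """Hard calls from probabilities: 1 iff p >= cutoff."""
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff must be in (0,1), got {cutoff}")
    calls = []
    for p in probabilities:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0,1]")
        calls.append(1 if p >= cutoff else 0)
    return calls


def left_right_labels(
    calls: Sequence[int], thresholds: Sequence[float]
) -> tuple[TemperatureRange, TemperatureRange, bool]:
    """Left-hand/right-hand temperature-range labels and the clash flag.

    Let j be the length of the leading run of 1s and m the 1-based index of
    the last 1 anywhere (0 if none).  The left label is the range whose
    lower bound is T_j (the lowest range when j = 0), the right label the
    range whose lower bound is T_m, and clash holds iff j != m.  j <= m
    always, so the left label never exceeds the right one.
    """
    ts = _validated_thresholds(thresholds)
    if len(calls) != len(ts):
        raise ValueError(
            f"{len(calls)} calls for {len(ts)} thresholds"
        )
    for c in calls:
        if c not in (0, 1):
            raise ValueError(f"calls must be 0/1, got {c!r}")
    ranges = ranges_from_thresholds(ts)
    j = 0
    while j < len(calls) and calls[j] == 1:
        j += 1
    m = 0
    for i, c in enumerate(calls, start=1):
        if c == 1:
            m = i
    return ranges[j], ranges[m], j != m


def enumerate_consistency(n_thresholds: int) -> int:
    """Number of clash-free call vectors among all 2^n.

    Exactly the monotone non-increasing vectors qualify, so the count is
    n + 1; this routine computes it by exhaustive enumeration through the
    label logic rather than from the closed form.
    """
    if n_thresholds < 1:
        raise ValueError("n_thresholds must be >= 1")
    thresholds = [float(40 + 5 * i) for i in range(n_thresholds)]
    count = 0
    for calls in product((0, 1), repeat=n_thresholds):
        _, _, clash = left_right_labels(list(calls), thresholds)
        if not clash:
            count += 1
    return count


def profile_from_ensembles(
    ensembles: Sequence, x: np.ndarray, cutoff: float = 0.5
) -> PredictionProfile:
    """Run every threshold ensemble on one embedding and assemble a profile.

    Ensembles must be sorted by strictly ascending threshold (default mode:
    40-65 degrees C; extended mode adds 70, 75, 80).
    """
    from .classifier import ensemble_predict

    if not ensembles:
        raise ValueError("at least one ensemble required")
    thresholds = _validated_thresholds([e.threshold for e in ensembles])
    probs = [float(ensemble_predict(e, x)) for e in ensembles]
    calls = binarize(probs, cutoff)
    left, right, clash = left_right_labels(calls, thresholds)
    seq_id = getattr(x, "sequence_id", "")
    return PredictionProfile(
        sequence_id=seq_id,
        thresholds=thresholds,
        probabilities=probs,
        binary_calls=calls,
        left_label=left,
        right_label=right,
        clash=clash,
    )
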