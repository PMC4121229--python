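"""Significant-outlier scores (MMS) and single-step classification.

MMS ("minimum, maximum, sum") compares the range of a series against its
extreme-deviation sums::

    MMS_max = (a_max - a_min) / (S_n - a_min * n)
    MMS_min = (a_max - a_min) / (a_max * n - S_n)

Both equal ``2/n`` exactly on any nonconstant AP and are invariant under
positive affine maps of the values.  A score strictly above the threshold
``R_w`` implicates the corresponding extreme as a significant outlier; the
min-side score is equivalently the max-side score of the complement series.

The scores use only the multiset of present values plus ``n``; positional
repair of gaps is the business of :mod:`apoutlier.repair`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .series import NO_SIGNAL, IndexedSeries, ScorePair

__all__ = ["MMSVerdict", "VerdictKind", "mms_max", "mms_min", "mms_scores", "mms_classify"]


class VerdictKind(str, enum.Enum):
    NONE = "none"
    MAX_OUTLIER = "max_outlier"
    MIN_OUTLIER = "min_outlier"


@dataclass(frozen=True)
class MMSVerdict:
    kind: VerdictKind
    position: int | None = None
    scores: ScorePair | None = None

    def __bool__(self) -> bool:
        return self.kind is not VerdictKind.NONE


def _extremes(series: IndexedSeries):
    v = series.values
    # ties broken toward the earliest position: argmax/argmin return the
    # first occurrence, and indices are stored sorted.
    imax = int(np.argmax(v))
    imin = int(np.argmin(v))
    return float(v[imax]), float(v[imin]), int(series.indices[imax]), int(series.indices[imin])


def mms_scores(series: IndexedSeries) -> ScorePair:
    """Both MMS scores with the positions of the implicated extremes.

    Returns NO_SIGNAL scores for a constant series (0/0 degeneracy).
    The denominators are accumulated as deviation sums (``sum(a_i - a_min)``
    rather than ``S_n - a_min * n``) to avoid catastrophic cancellation when
    the values sit on a large common offset.
    """
    if series.n < 2:
        raise ValueError("MMS scores require at least 2 elements")
    vmax, vmin, pmax, pmin = _extremes(series)
    if vmax == vmin:
        return ScorePair(NO_SIGNAL, NO_SIGNAL, None, None)
    rng = vmax - vmin
    dev_from_min = float(np.sum(series.values - vmin))  # == S_n - a_min * n
    dev_from_max = float(np.sum(vmax - series.values))  # == a_max * n - S_n
    return ScorePair(rng / dev_from_min, rng / dev_from_max, pmax, pmin)


def mms_max(series: IndexedSeries):
    """Max-side score ``(a_max - a_min) / (S_n - a_min * n)``."""
    return mms_scores(series).score_max


def mms_min(series: IndexedSeries):
    """Min-side score ``(a_max - a_min) / (a_max * n - S_n)``."""
    return mms_scores(series).score_min


def mms_classify(series: IndexedSeries, r_w: float) -> MMSVerdict:
    """Flag the extreme whose score strictly exceeds ``r_w``.

    When both scores exceed the threshold the greater one wins; an exact tie
    resolves to the maximum side (fixed, deterministic).  Equality with the
    threshold is "consistent with the linear border" and does not flag.
    """
    scores = mms_scores(series)
    if scores.degenerate:
        return MMSVerdict(VerdictKind.NONE, scores=scores)
    smax, smin = scores.score_max, scores.score_min
    if smax <= r_w and smin <= r_w:
        return MMSVerdict(VerdictKind.NONE, scores=scores)
    if smax >= smin:
        return MMSVerdict(VerdictKind.MAX_OUTLIER, scores.argmax_position, scores)
    return MMSVerdict(VerdictKind.MIN_OUTLIER, scores.argmin_position, scores)
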