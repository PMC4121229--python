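"""Nonsignificant-outlier scores on the constant-value transform (EMMS).

MMS can only implicate the extremes of a window; a subtle outlier that is
neither the maximum nor the minimum produces "Bad Detection" (the wrong
extreme scores highest).  EMMS sidesteps this by scoring the constant-value
transform ``y_TT`` (absolute residuals around the reference-anchored
mean-slope line) instead of the raw values.  Since ``y_TT >= 0`` with the
reference pinned at 0, the minimum of the transform is identically 0 and the
scores simplify to::

    EMMS_max = max(y_TT) / S_TT
    EMMS_min = max(y_TT) / (max(y_TT) * n - S_TT)

with ``S_TT = sum(y_TT)``.  The greater score above the threshold flags the
element with the largest residual; an exactly collinear window has an
all-zero transform and yields NO_SIGNAL.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .series import NO_SIGNAL, IndexedSeries, ScorePair
from .repair import constant_transform

__all__ = ["EMMSVerdict", "EMMSVerdictKind", "emms_scores", "emms_classify"]

#: Relative floor below which the largest residual is numerical noise from a
#: collinear window rather than signal.  Scaled by the magnitude of the
#: detrended values so it is unit-free.
ZERO_RTOL = 1e-9


class EMMSVerdictKind(str, enum.Enum):
    NONE = "none"
    OUTLIER = "outlier"
    AMBIGUOUS_MIN = "ambiguous_min"


@dataclass(frozen=True)
class EMMSVerdict:
    kind: EMMSVerdictKind
    position: int | None = None
    scores: ScorePair | None = None

    def __bool__(self) -> bool:
        return self.kind is EMMSVerdictKind.OUTLIER


def emms_scores(series: IndexedSeries, reference_position: int | None = None) -> ScorePair:
    """EMMS score pair on the constant-value transform of ``series``.

    NO_SIGNAL when the transform vanishes (window collinear with the
    reference up to floating-point noise): a residual maximum below
    ``ZERO_RTOL`` times the detrended magnitude counts as zero.
    """
    if series.n < 3:
        raise ValueError("EMMS requires at least 3 elements")
    y_tt = constant_transform(series, reference_position)
    m = float(y_tt.max())
    ref_pos = series.reference_index if reference_position is None else int(reference_position)
    scale = float(np.abs(series.values - series.value_at(ref_pos)).max())
    if m <= ZERO_RTOL * max(scale, 1.0):
        return ScorePair(NO_SIGNAL, NO_SIGNAL, None, None)
    s = float(y_tt.sum())
    n = series.n
    argmax = int(series.indices[int(np.argmax(y_tt))])
    # min side implicates no single element: the transform minimum is the
    # reference itself, pinned at 0.
    return ScorePair(m / s, m / (m * n - s), argmax, None)


def emms_classify(
    series: IndexedSeries, r_w: float, reference_position: int | None = None,
    *, ambiguous_min_halts: bool = False,
) -> EMMSVerdict:
    """Classify the largest-residual element against ``r_w``.

    Outliers are present whenever *either* score strictly exceeds the
    threshold, and the element with the greatest transformed value is the
    one implicated: the min side of the pair can never implicate a specific
    removable element (the transform minimum is the reference itself,
    pinned at 0), so a min-side excess counts as evidence that outliers
    remain and the removal target is still the residual argmax.  This
    matters when several comparable deviations flatten the max-side score:
    the min-side score stays high and keeps the removal loop alive.

    With ``ambiguous_min_halts`` a min-side-only excess is instead reported
    as AMBIGUOUS_MIN, a conservative termination signal for callers wanting
    no removal that the max side does not itself support.
    """
    scores = emms_scores(series, reference_position)
    if scores.degenerate:
        return EMMSVerdict(EMMSVerdictKind.NONE, scores=scores)
    smax, smin = scores.score_max, scores.score_min
    if smax <= r_w and smin <= r_w:
        return EMMSVerdict(EMMSVerdictKind.NONE, scores=scores)
    if smin > smax and smax <= r_w and ambiguous_min_halts:
        return EMMSVerdict(EMMSVerdictKind.AMBIGUOUS_MIN, scores=scores)
    return EMMSVerdict(EMMSVerdictKind.OUTLIER, scores.argmax_position, scores)
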