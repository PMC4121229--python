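"""Core series container and the arithmetic-progression-sum primitives.

An outlier-free linear series is a finite arithmetic progression (AP).  For
any AP of ``n`` terms the ratio of the sum of its extreme elements to the sum
of all elements is exactly ``2/n``::

    (a_min + a_max) / S_n == 2 / n

Any departure from ``2/n`` signals contamination, and the direction of the
departure implicates an extreme: a ratio below ``2/n`` implicates the
minimum, a ratio above implicates the maximum.  This module holds the series
container (:class:`IndexedSeries`), the raw ratio (:func:`ap_ratio`), the
widened detection threshold ``R_w = 2(1+k)/n`` (:func:`criterion`), and the
complement transform used to derive the minimum-side score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "NO_SIGNAL",
    "IndexedSeries",
    "CriteriaConfig",
    "ScorePair",
    "ZeroSumError",
    "ZeroIndexSumError",
    "ap_ratio",
    "criterion",
    "complement",
]


class _NoSignal:
    """Sentinel for score ratios whose defining quotient degenerates (0/0).

    Distinct from an exception: a degenerate score means "no outlier is
    detectable in this window" (e.g. a constant series for MMS, an exactly
    collinear window for EMMS), which the iterative pipeline treats as a
    normal stopping condition.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NO_SIGNAL"

    def __bool__(self) -> bool:
        return False


NO_SIGNAL = _NoSignal()


class ZeroSumError(ValueError):
    """Raised when S_n == 0 makes the raw AP ratio undefined."""


class ZeroIndexSumError(ValueError):
    """Raised when the index offsets from the reference sum to zero."""


@dataclass(frozen=True)
class IndexedSeries:
    """An ordered numeric series with explicit positions and missing support.

    Parameters
    ----------
    indices
        Strictly increasing non-negative integer positions ``x_k``.  Gaps are
        allowed and mean "value absent at that position"; ``n`` always counts
        present elements only.
    values
        Real values ``a_k`` aligned with ``indices``.
    missing
        Positions known to be absent (e.g. empty CSV cells).  Purely
        book-keeping for labelling; they must not collide with ``indices``.
    reference_position
        Position of the presumed-nonoutlier anchor element.  ``None`` (the
        default) means "the first present element", re-evaluated dynamically
        by the detection pipeline as elements are removed.
    """

    indices: np.ndarray
    values: np.ndarray
    missing: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    reference_position: int | None = None

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.int64)
        val = np.asarray(self.values, dtype=np.float64)
        mis = np.asarray(self.missing, dtype=np.int64)
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "values", val)
        object.__setattr__(self, "missing", mis)
        if idx.ndim != 1 or val.ndim != 1 or idx.shape != val.shape:
            raise ValueError("indices and values must be aligned 1-d arrays")
        if idx.size and idx.min() < 0:
            raise ValueError("indices must be non-negative")
        if idx.size > 1 and not np.all(np.diff(idx) > 0):
            raise ValueError("indices must be strictly increasing")
        if not np.all(np.isfinite(val)):
            raise ValueError("values must be finite")
        if np.intersect1d(idx, mis).size:
            raise ValueError("missing positions collide with present indices")
        if self.reference_position is not None and self.reference_position not in idx:
            raise ValueError(
                f"reference_position {self.reference_position} is not a present index"
            )

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_values(cls, values: Sequence[float], **kwargs) -> "IndexedSeries":
        """Build a series from contiguous values indexed 0..len-1."""
        values = np.asarray(values, dtype=np.float64)
        return cls(np.arange(values.size, dtype=np.int64), values, **kwargs)

    # -- basic queries ---------------------------------------------------
    @property
    def n(self) -> int:
        """Number of present elements."""
        return int(self.indices.size)

    @property
    def reference_index(self) -> int:
        """The effective reference position (explicit, else first present)."""
        if self.reference_position is not None:
            return int(self.reference_position)
        if self.n == 0:
            raise ValueError("empty series has no reference")
        return int(self.indices[0])

    @property
    def reference_value(self) -> float:
        return float(self.values[np.searchsorted(self.indices, self.reference_index)])

    def value_at(self, position: int) -> float:
        loc = np.searchsorted(self.indices, position)
        if loc >= self.n or self.indices[loc] != position:
            raise KeyError(position)
        return float(self.values[loc])

    def drop(self, positions) -> "IndexedSeries":
        """Return a copy with the given present positions removed."""
        keep = ~np.isin(self.indices, np.asarray(list(positions), dtype=np.int64))
        ref = self.reference_position
        return replace(self, indices=self.indices[keep], values=self.values[keep],
                       reference_position=ref if ref is None or keep[np.searchsorted(self.indices, ref)] else None)


@dataclass(frozen=True)
class CriteriaConfig:
    """Detection thresholds and pipeline switches.

    ``k_mms``/``k_emms`` widen the exact-line indicator ``2/n`` to the linear
    border ``R_w = 2(1+k)/n``; the validation defaults are k=0.5 for the
    significant-outlier (MMS) phase and k=0.01 for the nonsignificant (EMMS)
    phase.  ``guard_endpoints`` enables the contradiction rule for data whose
    first *and* last elements are known nonoutliers: a flag landing on either
    endpoint then terminates detection instead of removing the element.
    """

    k_mms: float = 0.5
    k_emms: float = 0.01
    guard_endpoints: bool = False
    max_iterations: int | None = None
    #: halt the EMMS phase when only the min-side score exceeds the
    #: threshold, instead of continuing to remove the residual argmax
    ambiguous_min_halts: bool = False

    #: k values reported for field (bioprocess sensor) data rather than the
    #: synthetic validation design.
    FIELD_PROFILE = {"k_mms": 0.2, "k_emms": 0.1}

    def __post_init__(self):
        if self.k_mms < 0 or self.k_emms < 0:
            raise ValueError("k weights must be non-negative")
        if self.max_iterations is not None and self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")

    @classmethod
    def field_profile(cls, **overrides) -> "CriteriaConfig":
        kw = dict(cls.FIELD_PROFILE)
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class ScorePair:
    """A (max-side, min-side) score pair with the implicated positions."""

    score_max: float | _NoSignal
    score_min: float | _NoSignal
    argmax_position: int | None = None
    argmin_position: int | None = None

    @property
    def degenerate(self) -> bool:
        return self.score_max is NO_SIGNAL or self.score_min is NO_SIGNAL


def ap_ratio(series: IndexedSeries) -> float:
    """Raw AP ratio ``(a_min + a_max) / S_n``.

    Equals ``2/n`` exactly for any outlier-free AP with positive terms.  Not
    robust to negative values (the sum may vanish); the MMS scores are the
    negative-safe forms.

    Raises
    ------
    ZeroSumError
        If ``S_n == 0``.
    """
    if series.n < 2:
        raise ValueError("ap_ratio requires at least 2 elements")
    s = float(series.values.sum())
    if s == 0.0:
        raise ZeroSumError("series sums to zero; use the MMS scores instead")
    return (float(series.values.min()) + float(series.values.max())) / s


def criterion(n: int, k: float) -> float:
    """Detection threshold ``R_w = 2(1+k)/n``.

    ``k = 0`` is the exact-line indicator ``2/n``; larger ``k`` widens the
    linear border.  ``k`` must satisfy ``k <= n/2 - 1`` so that the threshold
    stays within the score ceiling 1.
    """
    if n < 2:
        raise ValueError("criterion requires n >= 2")
    if k < 0:
        raise ValueError("k must be non-negative")
    if k > n / 2 - 1:
        raise ValueError(
            f"k={k} exceeds n/2 - 1 = {n / 2 - 1} for n={n}; threshold would exceed 1"
        )
    return 2.0 * (1.0 + k) / n


def complement(series: IndexedSeries) -> IndexedSeries:
    """Map every element to ``(a_max + a_min) - a_i``.

    An involution that swaps the roles of the maximum and the minimum while
    representing the same series; it is the derivation route of the min-side
    MMS score.
    """
    if series.n < 1:
        raise ValueError("complement requires at least 1 element")
    pivot = float(series.values.max()) + float(series.values.min())
    return replace(series, values=pivot - series.values)
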