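"""Imputation-free handling of removed and missing elements.

Two complementary strategies, neither of which ever fills a value in:

* **Angular shifting** — after a removal, elements downstream of the gap are
  re-indexed onto a compact axis and their values recomputed so that each
  keeps its original angle to a reference element::

      a_new = a_ref + (a_orig - a_ref) * new_offset / original_offset

  A point on a line through the reference lands exactly on the same line at
  its new offset, so compaction preserves the AP structure the MMS scores
  rely on.  Recalculation always reads the *original* values, never
  previously recalculated ones, which makes the result a function of the
  removed set alone (hence removal-order independent).

* **Constant-value transform** — maps a linear series to the absolute
  residuals around the line through the reference with the mean slope
  ``m = sum(y_k - y_ref) / sum(x_k - x_ref)`` over present elements.  A
  missing position simply contributes nothing to either sum, so the
  transform is inherently missing-value-proof; an outlier-free series maps
  to all zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .series import IndexedSeries, ZeroIndexSumError

__all__ = [
    "RemovalLedger",
    "angular_shift_value",
    "compact_after_removals",
    "constant_transform",
]


def angular_shift_value(
    reference_value: float,
    original_value: float,
    original_offset: int,
    new_offset: int,
) -> float:
    """Value of an element re-seated at ``new_offset`` from the reference.

    Offsets are counted from the reference element; ``new_offset`` is the
    original offset minus the number of removed/missing positions between
    the reference and the element.  Offsets may be negative for elements
    before an interior reference (both offsets then carry the same sign).
    """
    if original_offset == 0:
        raise ValueError("original_offset must be non-zero (element is not the reference)")
    if new_offset == 0:
        raise ValueError("new_offset of 0 would collapse the element onto the reference")
    if abs(new_offset) > abs(original_offset) or new_offset * original_offset < 0:
        raise ValueError("new_offset must lie between the reference and original_offset")
    if new_offset == original_offset:
        return float(original_value)
    # multiply before dividing: exact for integer-valued lines
    return float(reference_value + (original_value - reference_value) * new_offset / original_offset)


@dataclass(frozen=True)
class RemovalLedger:
    """Frozen original series plus the ordered set of removed positions.

    ``removed_positions`` holds removed outliers *and* plays host to initial
    missing positions (a removal automatically creates a missing-data
    environment, so the two are handled identically).  The reference is
    never removable; by default it floats to the first surviving element.
    """

    original_series: IndexedSeries
    removed_positions: frozenset = field(default_factory=frozenset)
    reference_position: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "removed_positions", frozenset(self.removed_positions))
        present = set(self.original_series.indices.tolist())
        if not self.removed_positions <= present:
            raise ValueError("removed_positions must be present in the original series")
        if self.reference_position is not None:
            if self.reference_position not in present:
                raise ValueError("reference_position must be a present index")
            if self.reference_position in self.removed_positions:
                raise ValueError("reference_position must never be removed")

    def remove(self, position: int) -> "RemovalLedger":
        if position == self.reference_position:
            raise ValueError("cannot remove the reference element")
        return RemovalLedger(
            self.original_series,
            self.removed_positions | {position},
            self.reference_position,
        )

    @property
    def surviving_indices(self) -> np.ndarray:
        keep = ~np.isin(
            self.original_series.indices,
            np.fromiter(self.removed_positions, dtype=np.int64, count=len(self.removed_positions)),
        ) if self.removed_positions else np.ones(self.original_series.n, dtype=bool)
        return self.original_series.indices[keep]

    @property
    def effective_reference(self) -> int:
        if self.reference_position is not None:
            return int(self.reference_position)
        surv = self.surviving_indices
        if surv.size == 0:
            raise ValueError("no surviving elements")
        return int(surv[0])


def compact_after_removals(ledger: RemovalLedger) -> tuple[IndexedSeries, np.ndarray]:
    """Angularly recompacted series after the ledger's removals.

    Surviving elements are re-indexed contiguously (0..n_surv-1 in original
    order) and each value recomputed by :func:`angular_shift_value` from its
    *original* value.  The new offset of an element from the reference is
    its original offset minus the number of removed/missing positions in
    between, i.e. its signed survivor rank relative to the reference.

    Returns
    -------
    (compacted, original_indices)
        The compacted series and, aligned with it, the original position of
        every compacted element (for mapping flags back).
    """
    surv = ledger.surviving_indices
    if surv.size < 2:
        raise ValueError("fewer than 2 surviving elements")
    orig = ledger.original_series
    ref_pos = ledger.effective_reference
    ref_val = orig.value_at(ref_pos)

    ref_rank = int(np.searchsorted(surv, ref_pos))
    new_offsets = np.arange(surv.size, dtype=np.int64) - ref_rank
    old_offsets = surv - ref_pos

    values = np.empty(surv.size, dtype=np.float64)
    surv_locs = np.searchsorted(orig.indices, surv)
    orig_vals = orig.values[surv_locs]
    for i in range(surv.size):
        if old_offsets[i] == 0:
            values[i] = ref_val
        else:
            values[i] = angular_shift_value(
                ref_val, float(orig_vals[i]), int(old_offsets[i]), int(new_offsets[i])
            )
    compacted = IndexedSeries(
        np.arange(surv.size, dtype=np.int64), values, reference_position=ref_rank
    )
    return compacted, surv


def constant_transform(series: IndexedSeries, reference_position: int | None = None) -> np.ndarray:
    """Absolute residuals around the reference-anchored mean-slope line.

    For present elements ``(x_k, y_k)`` and reference ``(x_0, y_0)``::

        m    = sum(y_k - y_0) / sum(x_k - x_0)
        y_TT = | (y_k - y_0) - (x_k - x_0) * m |

    The reference maps to exactly 0, the output is everywhere >= 0, and any
    set of points collinear with the reference maps to all zeros regardless
    of the missing pattern.  Adding ``c*x + d`` to the values leaves the
    result unchanged (slope and offset cancel through ``m`` and the
    reference subtraction).

    Raises
    ------
    ZeroIndexSumError
        If the index offsets from the reference sum to zero (degenerate
        slope estimate).
    """
    if series.n < 2:
        raise ValueError("constant transform requires at least 2 elements")
    ref_pos = series.reference_index if reference_position is None else int(reference_position)
    ref_val = series.value_at(ref_pos)
    x_t = (series.indices - ref_pos).astype(np.float64)
    y_t = series.values - ref_val
    gx = float(x_t.sum())
    if gx == 0.0:
        raise ZeroIndexSumError("index offsets from the reference sum to zero")
    m = float(y_t.sum()) / gx
    return np.abs(y_t - x_t * m)
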