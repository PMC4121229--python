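"""The two-phase iterative detection procedure.

Phase 1 (MMS) repeatedly compacts the surviving window by angular shifting
and removes whichever extreme scores above ``R_w = 2(1+k_mms)/n`` — the
significant outliers.  Phase 2 (EMMS) then scores the survivors at their
original positions through the constant-value transform and removes the
largest-residual element while its score exceeds ``2(1+k_emms)/n`` — the
nonsignificant outliers.  No removed value is ever imputed; both thresholds
shrink with the current surviving ``n``.

The reference element is the presumed-nonoutlier anchor.  By default it is
dynamic (always the first surviving element, per the validation protocol);
an explicitly chosen reference is fixed, is never removed, and a flag
landing on it terminates detection as a contradiction.  With
``guard_endpoints`` enabled, a flag on the first or last surviving element
likewise terminates both phases — the "Bad Detection Level" contradiction
rule for data whose endpoints are known clean.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .series import NO_SIGNAL, CriteriaConfig, IndexedSeries, ScorePair, criterion
from .mms import VerdictKind, mms_classify
from .emms import EMMSVerdictKind, emms_classify
from .repair import RemovalLedger, compact_after_removals

__all__ = ["Label", "LabelVector", "DetectionTrace", "TraceRecord", "detect",
           "detect_multi_reference"]


class Label(str, enum.Enum):
    NONOUTLIER = "nonoutlier"
    SIGNIFICANT_OUTLIER = "significant_outlier"
    NONSIGNIFICANT_OUTLIER = "nonsignificant_outlier"
    MISSING = "missing"


class LabelVector(Mapping):
    """Per-position classification covering every original index exactly once."""

    def __init__(self, labels: dict[int, Label]):
        self._labels = dict(sorted(labels.items()))

    def __getitem__(self, position: int) -> Label:
        return self._labels[position]

    def __iter__(self):
        return iter(self._labels)

    def __len__(self):
        return len(self._labels)

    def __eq__(self, other):
        if isinstance(other, LabelVector):
            return self._labels == other._labels
        return NotImplemented

    def positions(self, label: Label) -> list[int]:
        return [p for p, l in self._labels.items() if l is label]

    @property
    def outliers(self) -> list[int]:
        """Positions flagged by either phase."""
        return [p for p, l in self._labels.items()
                if l in (Label.SIGNIFICANT_OUTLIER, Label.NONSIGNIFICANT_OUTLIER)]

    def counts(self) -> dict[str, int]:
        out = {label.value: 0 for label in Label}
        for l in self._labels.values():
            out[l.value] += 1
        return out

    def to_series(self) -> pd.Series:
        return pd.Series({p: l.value for p, l in self._labels.items()}, name="label")

    def __repr__(self):
        c = self.counts()
        return f"LabelVector({', '.join(f'{k}={v}' for k, v in c.items() if v)})"


@dataclass(frozen=True)
class TraceRecord:
    phase: str                      # "mms" | "emms"
    iteration: int
    n: int
    score_max: float | None
    score_min: float | None
    r_w: float | None
    action: str                     # "remove" | "stop"
    position: int | None = None
    termination_reason: str | None = None


class TerminationReason:
    BELOW_THRESHOLD = "below_threshold"
    BAD_DETECTION_ENDPOINT = "bad_detection_endpoint"
    AMBIGUOUS_MIN = "ambiguous_min"
    NO_SIGNAL = "no_signal"
    MAX_ITERATIONS = "max_iterations"
    WINDOW_TOO_SMALL = "window_too_small"


@dataclass
class DetectionTrace:
    """Ordered per-iteration log of scores, thresholds, and removals."""

    records: list[TraceRecord] = field(default_factory=list)
    candidate_summary: list[dict] | None = None

    def append(self, record: TraceRecord):
        self.records.append(record)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    def removals(self, phase: str | None = None) -> list[int]:
        return [r.position for r in self.records
                if r.action == "remove" and (phase is None or r.phase == phase)]

    def termination_reason(self, phase: str) -> str | None:
        for r in reversed(self.records):
            if r.phase == phase and r.termination_reason:
                return r.termination_reason
        return None

    @property
    def bad_detection(self) -> bool:
        return any(r.termination_reason == TerminationReason.BAD_DETECTION_ENDPOINT
                   for r in self.records)


def _score_floats(scores: ScorePair | None):
    if scores is None:
        return None, None
    smax = None if scores.score_max is NO_SIGNAL else float(scores.score_max)
    smin = None if scores.score_min is NO_SIGNAL else float(scores.score_min)
    return smax, smin


def detect(series: IndexedSeries, config: CriteriaConfig | None = None,
           phases: tuple[str, ...] = ("mms", "emms")) -> tuple[LabelVector, DetectionTrace]:
    """Run the full two-phase detection on ``series``.

    Returns the per-position labels (covering present and missing positions)
    and the iteration trace.  ``phases`` restricts the run to a single phase
    for diagnostic use.
    """
    config = config or CriteriaConfig()
    if series.n < 3:
        raise ValueError("detection requires at least 3 present elements")
    max_iter = config.max_iterations if config.max_iterations is not None else series.n

    ledger = RemovalLedger(series, frozenset(), series.reference_position)
    labels: dict[int, Label] = {int(p): Label.MISSING for p in series.missing}
    trace = DetectionTrace()
    fixed_ref = series.reference_position
    aborted = False

    def endpoint_hit(pos: int, surv: np.ndarray) -> bool:
        return config.guard_endpoints and (pos == int(surv[0]) or pos == int(surv[-1]))

    # ---- phase 1: significant outliers via MMS on the compacted window ----
    if "mms" in phases and not aborted:
        for it in range(max_iter + 1):
            surv = ledger.surviving_indices
            n = surv.size
            if n < 3:
                trace.append(TraceRecord("mms", it, n, None, None, None, "stop",
                                         termination_reason=TerminationReason.WINDOW_TOO_SMALL))
                break
            if it == max_iter:
                trace.append(TraceRecord("mms", it, n, None, None, None, "stop",
                                         termination_reason=TerminationReason.MAX_ITERATIONS))
                break
            compacted, originals = compact_after_removals(ledger)
            r_w = criterion(n, config.k_mms)
            verdict = mms_classify(compacted, r_w)
            smax, smin = _score_floats(verdict.scores)
            if verdict.kind is VerdictKind.NONE:
                reason = (TerminationReason.NO_SIGNAL if verdict.scores.degenerate
                          else TerminationReason.BELOW_THRESHOLD)
                trace.append(TraceRecord("mms", it, n, smax, smin, r_w, "stop",
                                         termination_reason=reason))
                break
            pos = int(originals[verdict.position])
            if endpoint_hit(pos, surv) or pos == fixed_ref:
                trace.append(TraceRecord(
                    "mms", it, n, smax, smin, r_w, "stop", pos,
                    TerminationReason.BAD_DETECTION_ENDPOINT))
                aborted = True  # contradiction terminates both phases
                break
            labels[pos] = Label.SIGNIFICANT_OUTLIER
            trace.append(TraceRecord("mms", it, n, smax, smin, r_w, "remove", pos))
            ledger = ledger.remove(pos)

    # ---- phase 2: nonsignificant outliers via EMMS at original indices ----
    if "emms" in phases and not aborted:
        orig = ledger.original_series
        for it in range(max_iter + 1):
            surv = ledger.surviving_indices
            n = surv.size
            if n < 3:
                trace.append(TraceRecord("emms", it, n, None, None, None, "stop",
                                         termination_reason=TerminationReason.WINDOW_TOO_SMALL))
                break
            if it == max_iter:
                trace.append(TraceRecord("emms", it, n, None, None, None, "stop",
                                         termination_reason=TerminationReason.MAX_ITERATIONS))
                break
            locs = np.searchsorted(orig.indices, surv)
            window = IndexedSeries(surv, orig.values[locs],
                                   reference_position=ledger.effective_reference)
            r_w = criterion(n, config.k_emms)
            verdict = emms_classify(window, r_w,
                                    ambiguous_min_halts=config.ambiguous_min_halts)
            smax, smin = _score_floats(verdict.scores)
            if verdict.kind is EMMSVerdictKind.NONE:
                reason = (TerminationReason.NO_SIGNAL if verdict.scores.degenerate
                          else TerminationReason.BELOW_THRESHOLD)
                trace.append(TraceRecord("emms", it, n, smax, smin, r_w, "stop",
                                         termination_reason=reason))
                break
            if verdict.kind is EMMSVerdictKind.AMBIGUOUS_MIN:
                trace.append(TraceRecord("emms", it, n, smax, smin, r_w, "stop",
                                         termination_reason=TerminationReason.AMBIGUOUS_MIN))
                break
            pos = int(verdict.position)
            if endpoint_hit(pos, surv) or pos == fixed_ref:
                trace.append(TraceRecord(
                    "emms", it, n, smax, smin, r_w, "stop", pos,
                    TerminationReason.BAD_DETECTION_ENDPOINT))
                break
            labels[pos] = Label.NONSIGNIFICANT_OUTLIER
            trace.append(TraceRecord("emms", it, n, smax, smin, r_w, "remove", pos))
            ledger = ledger.remove(pos)

    for p in series.indices:
        labels.setdefault(int(p), Label.NONOUTLIER)
    return LabelVector(labels), trace


def detect_multi_reference(
    series: IndexedSeries,
    config: CriteriaConfig | None = None,
    candidate_references: Iterable[int] = (),
) -> tuple[LabelVector, DetectionTrace]:
    """Run :func:`detect` once per candidate reference and keep the best run.

    "Best fitting" prefers runs that terminated cleanly over runs cut short
    by a bad-detection contradiction, then the run labelling the most
    elements NONOUTLIER, then the earliest reference.  The winning trace
    carries a per-candidate summary.
    """
    candidates = [int(c) for c in candidate_references]
    if not candidates:
        raise ValueError("candidate_references must not be empty")
    from dataclasses import replace as _replace

    runs = []
    for ref in candidates:
        s = _replace(series, reference_position=ref)
        labels, trace = detect(s, config)
        runs.append((ref, labels, trace))

    def rank(run):
        ref, labels, trace = run
        n_nonoutlier = len(labels.positions(Label.NONOUTLIER))
        return (trace.bad_detection, -n_nonoutlier, ref)

    best = min(runs, key=rank)
    summary = [
        {
            "reference": ref,
            "nonoutliers": len(labels.positions(Label.NONOUTLIER)),
            "outliers": len(labels.outliers),
            "bad_detection": trace.bad_detection,
        }
        for ref, labels, trace in runs
    ]
    best[2].candidate_summary = summary
    return best[1], best[2]
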