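"""statsmodels-style model/results surface over the detection pipeline."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .series import CriteriaConfig, IndexedSeries
from .pipeline import (DetectionTrace, Label, LabelVector, detect,
                       detect_multi_reference)

__all__ = ["APOutlierModel", "DetectionResults"]


class APOutlierModel:
    """Arithmetic-progression-sum outlier model for a linear series.

    Binds a series to the detection configuration; :meth:`fit` runs the
    two-phase MMS/EMMS procedure and returns a :class:`DetectionResults`.

    Parameters
    ----------
    series
        An :class:`IndexedSeries`, or any 1-d sequence of values (taken to
        be contiguously indexed from 0).
    k_mms, k_emms
        Threshold weights for the significant (MMS) and nonsignificant
        (EMMS) phases; ``R_w = 2(1+k)/n`` at the current window size.
    guard_endpoints
        Enable the bad-detection contradiction rule for data whose first
        and last elements are known nonoutliers.
    reference
        Fixed reference position (presumed nonoutlier).  ``None`` lets the
        reference float to the first surviving element.

    Examples
    --------
    >>> model = APOutlierModel([100, 101, 102, 103, 204])
    >>> res = model.fit()
    >>> res.significant_outliers
    [4]
    """

    def __init__(self, series, *, k_mms: float = 0.5, k_emms: float = 0.01,
                 guard_endpoints: bool = False, reference: int | None = None,
                 max_iterations: int | None = None):
        if not isinstance(series, IndexedSeries):
            series = IndexedSeries.from_values(np.asarray(series, dtype=np.float64))
        if reference is not None:
            series = replace(series, reference_position=int(reference))
        self.series = series
        self.config = CriteriaConfig(k_mms=k_mms, k_emms=k_emms,
                                     guard_endpoints=guard_endpoints,
                                     max_iterations=max_iterations)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, index_column: str = "index",
                       value_column: str = "value", **kwargs) -> "APOutlierModel":
        """Build from a two-column frame; NA values become missing positions."""
        idx = frame[index_column].to_numpy(dtype=np.int64)
        val = frame[value_column].to_numpy(dtype=np.float64)
        present = np.isfinite(val)
        series = IndexedSeries(idx[present], val[present], missing=idx[~present])
        return cls(series, **kwargs)

    def fit(self) -> "DetectionResults":
        labels, trace = detect(self.series, self.config)
        return DetectionResults(self, labels, trace)

    def fit_multi_reference(self, candidate_references) -> "DetectionResults":
        """Fit once per candidate reference and keep the best-fitting run."""
        labels, trace = detect_multi_reference(self.series, self.config,
                                               candidate_references)
        return DetectionResults(self, labels, trace)


class DetectionResults:
    """Labels, trace and diagnostics from a fitted :class:`APOutlierModel`."""

    def __init__(self, model: APOutlierModel, labels: LabelVector,
                 trace: DetectionTrace):
        self.model = model
        self.labels = labels
        self.trace = trace

    # -- flagged positions ------------------------------------------------
    @property
    def significant_outliers(self) -> list[int]:
        return self.labels.positions(Label.SIGNIFICANT_OUTLIER)

    @property
    def nonsignificant_outliers(self) -> list[int]:
        return self.labels.positions(Label.NONSIGNIFICANT_OUTLIER)

    @property
    def nonoutliers(self) -> list[int]:
        return self.labels.positions(Label.NONOUTLIER)

    @property
    def n_iterations(self) -> int:
        return len(self.trace.records)

    def to_frame(self) -> pd.DataFrame:
        """Per-position frame of index, value and label."""
        series = self.model.series
        rows = []
        for pos, label in self.labels.items():
            if label is Label.MISSING:
                value = np.nan
            else:
                value = series.value_at(pos)
            rows.append({"index": pos, "value": value, "label": label.value})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text summary of the run (scores rounded to 3 decimals)."""
        series, config = self.model.series, self.model.config
        c = self.labels.counts()
        lines = [
            "      AP-sum outlier detection results",
            "=" * 46,
            f"No. present elements: {series.n:>6}   missing: {len(series.missing):>5}",
            f"k (MMS): {config.k_mms:>17.3f}   k (EMMS): {config.k_emms:.3f}",
            f"Endpoint guard: {'on' if config.guard_endpoints else 'off':>11}   "
            f"reference: {series.reference_position if series.reference_position is not None else 'dynamic'}",
            "-" * 46,
            f"significant outliers:    {c['significant_outlier']:>6}",
            f"nonsignificant outliers: {c['nonsignificant_outlier']:>6}",
            f"nonoutliers:             {c['nonoutlier']:>6}",
            f"MMS termination:  {self.trace.termination_reason('mms')}",
            f"EMMS termination: {self.trace.termination_reason('emms')}",
        ]
        flagged = [r for r in self.trace.records if r.action == "remove"]
        if flagged:
            lines.append("-" * 46)
            lines.append("phase  iter     n  position    score     R_w")
            for r in flagged:
                score = r.score_max if r.phase == "emms" else max(
                    s for s in (r.score_max, r.score_min) if s is not None)
                lines.append(f"{r.phase:>5} {r.iteration:>5} {r.n:>5} {r.position:>9} "
                             f"{score:>8.3f} {r.r_w:>7.3f}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of the series coloured by label (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.to_frame().dropna(subset=["value"])
        styles = {
            "nonoutlier": dict(marker="s", color="tab:green", label="nonoutlier"),
            "significant_outlier": dict(marker="^", color="tab:red",
                                        label="significant outlier"),
            "nonsignificant_outlier": dict(marker="o", color="tab:orange",
                                           label="nonsignificant outlier"),
        }
        for label, style in styles.items():
            sub = frame[frame["label"] == label]
            if len(sub):
                ax.scatter(sub["index"], sub["value"], **style)
        ax.set_xlabel("index")
        ax.set_ylabel("value")
        ax.legend()
        return ax

    def __repr__(self):
        c = self.labels.counts()
        return (f"<DetectionResults: {c['significant_outlier']} significant, "
                f"{c['nonsignificant_outlier']} nonsignificant, "
                f"{c['nonoutlier']} nonoutliers>")
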