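"""Synthetic linear-series generator and detection-accuracy evaluator.

Emulates the validation design the detector was built for: a base line
``a_k = a_1 + d*k`` (increasing, decreasing or constant), a chosen fraction
of positions replaced by outliers, and optional missing regions.

Two contamination modes:

* ``non_gaussian`` — multiplicative gross errors.  Each outlier value is
  the correct value times a factor of random sign whose magnitude is
  log-uniform on ``factor_range`` (default 1e-2..1e+2), i.e. sensor glitches
  spanning four decades.  These are the significant outliers MMS exists for.
* ``gaussian`` — additive normal perturbations truncated at two standard
  deviations (symmetric, no extreme tail points), sigma defaulting to 5% of
  the base line's value range.  Such contamination produces no significant
  outliers, so the MMS phase is expected to stay inactive and the EMMS phase
  does all the work.

Ground-truth labels accompany every generated series; :func:`evaluate`
computes the four accuracy percentages (correct/false nonoutliers relative
to actual nonoutliers, correct/false outliers relative to actual outliers),
and :func:`run_validation_suite` sweeps the environment grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import CriteriaConfig, IndexedSeries
from .pipeline import Label, LabelVector, detect

__all__ = ["SimulationSpec", "make_series", "evaluate", "run_validation_suite",
           "Metrics"]

TRENDS = ("increasing", "decreasing", "constant")


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic series.

    ``slope``/``intercept`` of ``None`` pick trend-appropriate defaults: an
    increasing line 100 + k, a decreasing line (100 + n - 1) - k, a constant
    line 100 — positive everywhere and bounded away from zero so that a
    multiplicative outlier always actually perturbs the value.
    """

    n: int = 100
    trend: str = "increasing"
    slope: float | None = None
    intercept: float | None = None
    outlier_fraction: float = 0.5
    outlier_mode: str = "non_gaussian"
    factor_range: tuple[float, float] = (1e-2, 1e2)
    gaussian_sigma_fraction: float = 0.05
    protect_reference: bool = True
    missing_regions: tuple[tuple[int, int], ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.trend not in TRENDS:
            raise ValueError(f"trend must be one of {TRENDS}")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must be in [0, 1)")
        if self.outlier_mode not in ("gaussian", "non_gaussian"):
            raise ValueError("outlier_mode must be 'gaussian' or 'non_gaussian'")
        if not (0 < self.factor_range[0] <= self.factor_range[1]):
            raise ValueError("factor_range must be positive and ordered")
        covered = set()
        for start, length in self.missing_regions:
            region = set(range(start, start + length))
            if start < 0 or start + length > self.n or covered & region:
                raise ValueError("missing regions must be disjoint and within [0, n)")
            covered |= region

    @property
    def line_params(self) -> tuple[float, float]:
        """(intercept a_1, slope d) with trend defaults applied."""
        if self.slope is not None and self.intercept is not None:
            return float(self.intercept), float(self.slope)
        defaults = {
            "increasing": (100.0, 1.0),
            "decreasing": (100.0 + (self.n - 1), -1.0),
            "constant": (100.0, 0.0),
        }
        a1, d = defaults[self.trend]
        if self.intercept is not None:
            a1 = float(self.intercept)
        if self.slope is not None:
            d = float(self.slope)
        return a1, d


def make_series(spec: SimulationSpec) -> tuple[IndexedSeries, LabelVector]:
    """Generate one contaminated series plus its ground-truth labels.

    Deterministic under ``spec.seed``.  Outlier positions are drawn
    uniformly among present, non-reference (when protected) positions;
    truth marks every replaced position as an outlier (grade is not
    distinguished in truth) and every missing position as missing.
    """
    rng = np.random.default_rng(spec.seed)
    a1, d = spec.line_params
    base = a1 + d * np.arange(spec.n, dtype=np.float64)

    missing = np.zeros(spec.n, dtype=bool)
    for start, length in spec.missing_regions:
        missing[start:start + length] = True
    present = np.flatnonzero(~missing)
    if present.size == 0:
        raise ValueError("missing regions leave no present elements")

    eligible = present
    if spec.protect_reference:
        eligible = present[present != present[0]]
    # the fraction is a contamination rate of the observed data: missing
    # positions cannot carry an outlier
    n_out = int(np.floor(spec.outlier_fraction * present.size))
    n_out = min(n_out, eligible.size)
    if present.size - n_out < 3:
        raise ValueError("contamination leaves fewer than 3 clean points")
    positions = rng.choice(eligible, size=n_out, replace=False) if n_out else np.empty(0, int)
    positions = np.sort(positions)

    values = base.copy()
    if n_out:
        if spec.outlier_mode == "non_gaussian":
            lo, hi = spec.factor_range
            mags = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), size=n_out)
            signs = rng.choice([-1.0, 1.0], size=n_out)
            values[positions] = values[positions] * signs * mags
        else:
            lo_rng = float(base[present].max() - base[present].min())
            scale = lo_rng if lo_rng > 0 else abs(float(base[present].mean()))
            sigma = spec.gaussian_sigma_fraction * max(scale, 1.0)
            noise = rng.normal(0.0, sigma, size=n_out)
            np.clip(noise, -2.0 * sigma, 2.0 * sigma, out=noise)
            values[positions] = values[positions] + noise

    truth = {}
    outlier_set = set(positions.tolist())
    for p in range(spec.n):
        if missing[p]:
            truth[p] = Label.MISSING
        elif p in outlier_set:
            truth[p] = Label.SIGNIFICANT_OUTLIER
        else:
            truth[p] = Label.NONOUTLIER
    series = IndexedSeries(present.astype(np.int64), values[present],
                           missing=np.flatnonzero(missing).astype(np.int64))
    return series, LabelVector(truth)


@dataclass(frozen=True)
class Metrics:
    """The four validation percentages (NaN when a denominator is empty)."""

    correct_nonoutlier_pct: float
    false_nonoutlier_pct: float
    correct_outlier_pct: float
    false_outlier_pct: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def evaluate(labels: LabelVector, truth: LabelVector) -> Metrics:
    """Detection accuracy of ``labels`` against ground truth.

    Nonoutlier percentages are relative to the number of actual nonoutliers,
    outlier percentages to the total number of actual outliers; significant
    and nonsignificant flags both count as "outlier".  Missing positions are
    excluded.
    """
    if set(labels) != set(truth):
        raise ValueError("label and truth index sets differ")
    is_out = lambda l: l in (Label.SIGNIFICANT_OUTLIER, Label.NONSIGNIFICANT_OUTLIER)
    actual_non = [p for p, l in truth.items() if l is Label.NONOUTLIER]
    actual_out = [p for p, l in truth.items() if is_out(l)]
    correct_non = sum(labels[p] is Label.NONOUTLIER for p in actual_non)
    false_non = sum(labels[p] is Label.NONOUTLIER for p in actual_out)
    correct_out = sum(is_out(labels[p]) for p in actual_out)
    false_out = sum(is_out(labels[p]) for p in actual_non)

    pct = lambda num, den: 100.0 * num / den if den else float("nan")
    return Metrics(
        correct_nonoutlier_pct=pct(correct_non, len(actual_non)),
        false_nonoutlier_pct=pct(false_non, len(actual_non)),
        correct_outlier_pct=pct(correct_out, len(actual_out)),
        false_outlier_pct=pct(false_out, len(actual_out)),
    )


def run_validation_suite(
    config: CriteriaConfig | None = None,
    sizes: tuple[int, ...] = (10, 100, 1000),
    reps: int = 20,
    seed: int = 0,
    trends: tuple[str, ...] = TRENDS,
    modes: tuple[str, ...] = ("non_gaussian", "gaussian"),
    outlier_fraction: float = 0.5,
    missing_regions_for: dict[int, tuple[tuple[int, int], ...]] | None = None,
) -> pd.DataFrame:
    """Sweep the environment grid and report per-cell mean accuracy.

    One row per (trend, mode, size) cell with the mean of the four accuracy
    percentages over ``reps`` replicates plus the mean count of MMS-phase
    removals.  The default configuration is the validation setting: k=0.5
    (MMS), k=0.01 (EMMS), unguarded endpoints, clean dynamic reference.
    """
    config = config or CriteriaConfig()
    master = np.random.default_rng(seed)
    rows = []
    for trend in trends:
        for mode in modes:
            for n in sizes:
                cell = []
                for _ in range(reps):
                    run_seed = int(master.integers(0, 2**31 - 1))
                    regions = ()
                    if missing_regions_for:
                        regions = missing_regions_for.get(n, ())
                    spec = SimulationSpec(
                        n=n, trend=trend, outlier_fraction=outlier_fraction,
                        outlier_mode=mode, missing_regions=regions, seed=run_seed)
                    series, truth = make_series(spec)
                    labels, trace = detect(series, config)
                    metrics = evaluate(labels, truth)
                    cell.append({**metrics.as_dict(),
                                 "mms_removals": len(trace.removals("mms"))})
                frame = pd.DataFrame(cell)
                row = frame.mean().to_dict()
                row.update(trend=trend, mode=mode, n=n, reps=reps)
                rows.append(row)
    cols = ["trend", "mode", "n", "reps", "correct_nonoutlier_pct",
            "false_nonoutlier_pct", "correct_outlier_pct", "false_outlier_pct",
            "mms_removals"]
    return pd.DataFrame(rows)[cols]
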