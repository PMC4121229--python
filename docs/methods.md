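# Methods

## Model and assumptions

The detector treats an outlier-free series as a finite arithmetic
progression (AP): values `a_k = a_1 + d·k` at integer positions `x_k`, i.e.
a straight line of any slope, including constant.  "Outlier" is defined
geometrically: an element outside a *linear border*, a band of width set by
the threshold weight `k` around the line.  For any AP the ratio of the sum
of its extremes to its total sum equals `2/n` identically, which gives a
domain-independent indicator with a floor (`2/n`) and a ceiling (1), so no
standardisation step is needed.  Everything else in the package is a
consequence of making this identity usable on contaminated data with gaps:

* **MMS scores** (`mms.py`).  `MMS_max = (a_max − a_min)/(S_n − a_min·n)`
  and `MMS_min = (a_max − a_min)/(a_max·n − S_n)` restate the ratio in terms
  of minimum, maximum and sum.  Subtracting `a_min` makes them safe for
  negative values; the min-side form is the max-side form of the
  complemented series `(a_max + a_min) − a_i`, which gives the minimum the
  same detection range the maximum enjoys.  Both scores are invariant under
  positive affine maps of the values and use only the multiset of present
  values plus `n`.  A score strictly above `R_w` implicates the
  corresponding extreme as a *significant* outlier; equality is read as
  "consistent with the border".  Implemented as deviation sums
  (`Σ(a_i − a_min)`) rather than `S_n − a_min·n` to avoid catastrophic
  cancellation on large common offsets.
* **Constant-value transform** (`repair.py`).  Anchored at a reference
  element `(x_0, a_0)` presumed clean, the series maps to absolute residuals
  `|(a_k − a_0) − (x_k − x_0)·m|` around the mean-slope line
  `m = Σ(a_k − a_0)/Σ(x_k − x_0)` over present elements.  A line through the
  reference maps to all zeros for *any* missing pattern, which is what makes
  the transform the missing-value-proof route.
* **EMMS scores** (`emms.py`).  The MMS pair applied to the transform.  The
  transform minimum is identically 0 (the reference), so
  `EMMS_max = max(y_TT)/S_TT` and
  `EMMS_min = max(y_TT)/(max(y_TT)·n − S_TT)`.  These catch *nonsignificant*
  outliers — elements that are not extremes of the raw window.  Either score
  exceeding `R_w` is evidence of outliers; the implicated element is always
  the residual argmax, because the min side of the pair points at the
  reference itself, never at a removable element.  (A conservative mode,
  `ambiguous_min_halts`, instead stops the phase when only the min side
  exceeds the threshold.)  EMMS is trusted only after MMS has removed gross
  contamination, since its slope estimate is derived from the data.
* **Angular shifting** (`repair.py`).  After a removal (or across an initial
  gap) surviving elements are re-indexed contiguously and each value is
  recomputed as `a_ref + (a_orig − a_ref)·new_offset/original_offset`,
  preserving its angle to the reference.  Recalculation always reads
  original values, so the compacted series is a pure function of the removed
  *set* (order-independent), and collinear points remain exactly collinear
  (the multiplication is performed before the division so integer-valued
  lines stay exact).  No value is ever imputed.

## The two-phase pipeline

`detect()` runs MMS iteratively on the angularly compacted window
(significant outliers), then EMMS iteratively on the survivors at their
original positions (nonsignificant outliers).  The split follows each
method's own derivation: angular compaction is the repair MMS was designed
around, while the constant-value transform needs no repair at all.  Both
thresholds are evaluated at the current surviving `n`, so they widen as
elements are removed.  Each iteration removes exactly one element;
termination is guaranteed, and a phase aborts gracefully when fewer than
three elements survive.

**Reference handling.**  By default the reference is *dynamic*: the first
surviving element, re-anchored after every removal and therefore removable
itself if implicated (leading gross outliers are handled this way).  A
user-pinned reference is never removed; a flag landing on it is a
contradiction that terminates detection.  `detect_multi_reference()` tries
several candidate references and keeps the best fit — runs ended by a
contradiction rank below clean runs, then the most nonoutlier labels win,
then the earliest reference.

**Endpoint guard.**  When the first *and* last elements are known clean, a
flag on either endpoint reveals that the threshold has crossed the *bad
detection level* — the regime where an interior outlier drags the wrong
extreme over the threshold — and terminates both phases.  The guard is *off*
by default: it presumes endpoint cleanliness the general case cannot offer,
and with heavy contamination an endpoint is as likely an outlier as any
other position.  Enable `guard_endpoints` when the assumption genuinely
holds.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k_mms` | 0.5 | phase-1 border width; threshold `R_w = 2(1+k)/n`, i.e. 1.5× the exact-line ratio |
| `k_emms` | 0.01 | phase-2 border width; 1% above the exact-line ratio |
| `guard_endpoints` | off | bad-detection contradiction rule (see above) |
| `ambiguous_min_halts` | off | stop EMMS when only the min-side score exceeds `R_w` |
| `max_iterations` | `n` | defensive bound; each iteration removes one element |

`k` is unitless and must satisfy `k ≤ n/2 − 1` so the threshold stays within
the score ceiling 1.  The 0.5/0.01 pair is the synthetic-validation setting;
0.2/0.1 (`CriteriaConfig.field_profile()`) is the wider profile for real
sensor data, where exact collinearity never holds and the nonoutlier band
has physical width.

## Synthetic data generator

`simulate.make_series` emulates the validation design: a base line per trend
(increasing `100 + k`, decreasing `(100 + n − 1) − k`, constant `100` —
positive and bounded away from zero, since a base value of 0 would make a
multiplicative outlier a no-op), a contamination fraction applied to the
*present* positions (default 50%, never the reference when protected),
optional missing regions, and two contamination modes:

* `non_gaussian`: multiplicative gross errors, factor sign random and
  magnitude log-uniform on [1e−2, 1e+2] (the sampling law is the package's
  choice; "very small and very large" factors are equally represented on
  the log scale);
* `gaussian`: additive noise truncated at ±2σ, σ = 5% of the base line's
  range (5% of the mean level for constant lines, whose range is zero).
  Truncation implements "no extreme points": this mode models benign,
  symmetric scatter that should leave the significant-outlier phase
  inactive.

The generator does **not** emulate: autocorrelated or heteroscedastic noise,
drift or curvature in the clean signal, clustered/bursty outliers, or
measurement noise on the clean points (clean points are exactly collinear).
Passing validation therefore demonstrates the method's behaviour under its
own stated design — gross multiplicative contamination of an exact line —
not performance on arbitrary real sensor data, where the field profile and a
verified reference element matter.

## Numerical choices

* Scores are plain float64 ratios; deviation-sum forms avoid cancellation.
* A transform maximum below `1e−9 ×` the detrended magnitude counts as zero
  (`NO_SIGNAL`): once only collinear points survive, residuals of order
  1e−13 would otherwise produce arbitrary max/sum ratios and spurious flags.
* Flags use strict `>`; ties among equal extremes resolve to the earliest
  position, and an exact max/min score tie resolves to the max side — both
  arbitrary but deterministic.
* Degenerate inputs raise typed errors: zero total sum for the raw ratio
  (`ZeroSumError`), zero index-offset sum for the transform
  (`ZeroIndexSumError`), `k` outside its admissible range, fewer than 2 (3)
  elements for scoring (detection).

## Known limitations

* **Reference contamination.**  Every guarantee is conditional on a clean
  reference.  With a contaminated reference the method still finds
  significant outliers but misattributes nonsignificant ones; multi-reference
  search mitigates this at linear extra cost.
* **Residual-ramp saturation.**  When several remaining outliers have
  comparable same-sign deviations (e.g. several "value × small factor"
  points collapsing toward zero), the biased slope spreads the absolute
  residuals into a nearly arithmetic ramp; both EMMS scores then converge to
  `~2/n` and the iteration can stop a hair below threshold with outliers
  left, or — more rarely — implicate a clean far-end point first.  At the
  validation settings this affects on the order of 0.1% of elements pooled
  over the sweep; it is a detection limit of the AP-sum statistic itself at
  `k_emms = 0.01`.
* **Gaussian noise on an exactly constant line.**  MMS is scale-free, so
  when *all* perturbed points of a zero-spread baseline happen to draw
  same-sign noise, the noise is significant by the method's own criterion
  and phase 1 activates (the removed points are genuine perturbations, so
  no false flags result).
* **Nonlinearity.**  The model is a single straight line; segmented or
  curved series must be windowed upstream into locally linear pieces.
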