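"""Independent brute-force oracles in exact rational arithmetic.

Deliberately naive, literal transcriptions of the score definitions —
kept free of any apoutlier import so they can arbitrate the package's
implementations.
"""

from fractions import Fraction


def oracle_mms(values):
    """(MMS_max, MMS_min) as exact Fractions, or (None, None) if constant."""
    vals = [Fraction(v) for v in values]
    n = len(vals)
    vmax, vmin = max(vals), min(vals)
    if vmax == vmin:
        return None, None
    s = sum(vals)
    return (
        Fraction(vmax - vmin, s - vmin * n),
        Fraction(vmax - vmin, vmax * n - s),
    )


def oracle_mms_classify(values, r_w):
    """'none' | ('max', pos) | ('min', pos) with earliest-extreme, max-wins ties."""
    smax, smin = oracle_mms(values)
    if smax is None:
        return "none"
    r_w = Fraction(r_w)
    if smax <= r_w and smin <= r_w:
        return "none"
    vals = [Fraction(v) for v in values]
    if smax >= smin:
        return ("max", vals.index(max(vals)))
    return ("min", vals.index(min(vals)))


def oracle_constant_transform(xs, ys, ref=0):
    """Exact |y_T - x_T * m| residuals anchored at element ``ref``."""
    xs = [Fraction(x) for x in xs]
    ys = [Fraction(y) for y in ys]
    x0, y0 = xs[ref], ys[ref]
    xt = [x - x0 for x in xs]
    yt = [y - y0 for y in ys]
    m = Fraction(sum(yt), sum(xt))
    return [abs(a - b * m) for a, b in zip(yt, xt)]


def oracle_emms(xs, ys, ref=0):
    """(EMMS_max, EMMS_min, argmax position-in-list) or None if collinear."""
    y_tt = oracle_constant_transform(xs, ys, ref)
    m = max(y_tt)
    if m == 0:
        return None
    s = sum(y_tt)
    n = len(y_tt)
    return Fraction(m, s), Fraction(m, m * n - s), y_tt.index(m)


def oracle_angular_shift(ref_value, orig_value, orig_offset, new_offset):
    """Exact angular-shift recalculation."""
    return Fraction(ref_value) + (Fraction(orig_value) - Fraction(ref_value)) * Fraction(
        new_offset, orig_offset
    )
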