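"""Hartigan & Hartigan's dip statistic for unimodality.

The dip of a sample is the smallest sup-norm distance between its empirical
CDF and any unimodal CDF (convex on one side of the mode, concave on the
other, an atom at the mode allowed).  It is computed with the classical
greatest-convex-minorant / least-concave-majorant iteration: within the
current candidate modal interval the GCM and LCM of the empirical CDF are
formed, the largest gap between them locates a tighter modal interval, and
the deviations of the ECDF from the GCM (left of it) and the LCM (right of
it) accumulate into the dip.  All bookkeeping is done in count units; the
final value is divided by 2n.

Known anchors: dip({0, 1}) = 1/4; any sample satisfies
1/(2n) <= dip <= 1/4; the statistic is invariant to affine maps of the
sample.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic"]


def _lower_hull(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Indices (into xs) of the lower convex hull, x strictly increasing."""
    hull: list[int] = []
    for i in range(xs.size):
        while len(hull) >= 2:
            i0, i1 = hull[-2], hull[-1]
            # pop i1 if it lies on or above segment (i0, i)
            if ((ys[i1] - ys[i0]) * (xs[i] - xs[i0])
                    >= (ys[i] - ys[i0]) * (xs[i1] - xs[i0])):
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull, dtype=int)


def _upper_hull(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    return _lower_hull(xs, -ys)


def _side_dip(x: np.ndarray, lo: int, hi: int, convex: bool) -> float:
    """Max deviation (counts) of the ECDF from the GCM (convex side) or LCM
    (concave side) of the points in [lo, hi]."""
    if hi <= lo:
        return 0.0
    seg = np.arange(lo, hi + 1)
    xs = x[seg]
    if xs[0] == xs[-1]:
        return 1.0
    if convex:
        first = np.ones(xs.size, dtype=bool)
        first[1:] = xs[1:] > xs[:-1]
        pts = seg[first]
        hull = pts[_lower_hull(x[pts], pts.astype(float))]
        fit = np.interp(xs, x[hull], hull.astype(float))
        return float(np.max((seg + 1) - fit))
    last = np.ones(xs.size, dtype=bool)
    last[:-1] = xs[1:] > xs[:-1]
    pts = seg[last]
    hull = pts[_upper_hull(x[pts], (pts + 1).astype(float))]
    fit = np.interp(xs, x[hull], (hull + 1).astype(float))
    return float(np.max(fit - seg))


def dip_statistic(values) -> float:
    """The dip statistic of a 1-D sample (n >= 2)."""
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise ValueError("dip requires at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("dip requires finite values")
    if x[0] == x[-1]:
        return 1.0 / (2.0 * n)

    low, high = 0, n - 1
    D = 1.0  # count units; dip = D / (2n)

    while True:
        seg = np.arange(low, high + 1)
        xs = x[seg]
        if xs[0] == xs[-1]:
            break
        # distinct-x reduction: the GCM touches the first (lowest-count)
        # occurrence of each value, the LCM the last.
        first = np.ones(xs.size, dtype=bool)
        first[1:] = xs[1:] > xs[:-1]
        last = np.ones(xs.size, dtype=bool)
        last[:-1] = xs[1:] > xs[:-1]

        g_idx = seg[first]                 # GCM candidate points, y = index
        l_idx = seg[last]                  # LCM candidate points, y = index+1
        g_hull = g_idx[_lower_hull(x[g_idx], g_idx.astype(float))]
        l_hull = l_idx[_upper_hull(x[l_idx], (l_idx + 1).astype(float))]

        def G(xq):
            return np.interp(xq, x[g_hull], g_hull.astype(float))

        def L(xq):
            return np.interp(xq, x[l_hull], (l_hull + 1).astype(float))

        # largest gap between LCM and GCM; a PL concave-minus-convex
        # difference attains its max at a hull vertex
        cand = np.concatenate([x[g_hull], x[l_hull]])
        gaps = L(cand) - G(cand)
        imax = int(np.argmax(gaps))
        d = float(gaps[imax])
        if d <= D:
            break
        x_star = cand[imax]

        new_low = int(g_hull[np.searchsorted(x[g_hull], x_star, side="right") - 1])
        j = int(np.searchsorted(x[l_hull], x_star, side="left"))
        j = min(j, l_hull.size - 1)
        new_high = int(l_hull[j])

        # dip of the ECDF against the GCM of the region left of the modal
        # interval (hull recomputed on that region alone) ...
        D_l = _side_dip(x, low, new_low, convex=True)
        # ... and against the LCM of the region right of it
        D_u = _side_dip(x, new_high, high, convex=False)

        D = max(D, D_l, D_u)
        if new_low == low and new_high == high:
            break
        if new_low < low or new_high > high:  # pragma: no cover - safety net
            break
        low, high = new_low, new_high

    return D / (2.0 * n)
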