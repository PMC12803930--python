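"""Small shared statistical primitives (BH step-up, geometric summaries)."""

from __future__ import annotations

import numpy as np

from .errors import DataError

#: Counts below this are clipped before taking logs for geometric means, the
#: convention used by digital-spatial-profiling toolkits so that zero counts
#: do not annihilate the geometric mean.
GEO_CLIP = 0.5


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Sorted q_(i) = min_{j>=i} p_(j) * m / j, capped at 1, mapped back to the
    input order. NaN entries propagate as NaN and do not count toward m.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise DataError("bh_adjust expects a 1-d array of p-values")
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise DataError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(m)
    qv[order] = np.minimum(ranked, 1.0)
    q[ok] = qv
    return q


def geomean(values, clip: float = GEO_CLIP) -> float:
    """Geometric mean with low-count clipping; NaNs are ignored."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        return float("nan")
    if (x < 0).any():
        raise DataError("geometric mean requires nonnegative values")
    return float(np.exp(np.mean(np.log(np.maximum(x, clip)))))


def geosd(values, clip: float = GEO_CLIP) -> float:
    """Geometric standard deviation: exp of the (n-1)-denominator SD of logs."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise DataError("geometric SD requires at least two values")
    return float(np.exp(np.std(np.log(np.maximum(x, clip)), ddof=1)))
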