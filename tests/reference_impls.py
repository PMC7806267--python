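"""Independent reference implementations used as test oracles.

These deliberately use naive explicit loops and a different mechanical route
than the package (per-multiple scans instead of running floor counters,
double loops instead of margin outer products) so that agreement is evidence,
not tautology.
"""

from __future__ import annotations

import numpy as np


def oracle_segment(theta_unwrapped, times, band=30.0, window=2, tol=5.0):
    """Brute-force frame scan of the Rock/Roll segmentation rules.

    Returns (onset, end, rock_duration, roll_duration) with the same
    conventions as ``segment_phases``: onset is the first frame whose
    absolute angle exceeds the band and keeps increasing over the look-ahead
    window; the Roll ends at the last completed half-turn crossing; an
    excursion that returns into the band without crossing is no onset.
    """
    a = [abs(v) for v in theta_unwrapped]
    n = len(a)

    onset = None
    for k in range(n):
        if a[k] <= band:
            continue
        ok = True
        for j in range(k, min(k + window, n - 1)):
            if a[j + 1] < a[j] - tol:
                ok = False
                break
        if ok:
            onset = k
            break

    if onset is None:
        return None, None, float(times[-1] - times[0]), None

    # scan each half-turn multiple independently for its first-arrival frame
    end = None
    m = 1
    while True:
        hit = None
        for k in range(onset, n):
            if a[k] >= 180.0 * m - 1e-9:
                hit = k
                break
        if hit is None:
            break
        end = hit
        m += 1

    if end is None:
        if a[-1] <= band:
            return None, None, float(times[-1] - times[0]), None
        return onset, None, float(times[onset] - times[0]), None
    return onset, end, float(times[onset] - times[0]), float(times[end] - times[onset])


def oracle_chi2(table) -> float:
    """Double-loop Pearson chi-squared statistic."""
    table = np.asarray(table, dtype=float)
    r, c = table.shape
    n = table.sum()
    rows = [table[i].sum() for i in range(r)]
    cols = [table[:, j].sum() for j in range(c)]
    x2 = 0.0
    for i in range(r):
        for j in range(c):
            e = rows[i] * cols[j] / n
            x2 += (table[i, j] - e) ** 2 / e
    return x2


def oracle_bh(pvals):
    """Textbook Benjamini–Hochberg step-up adjusted p-values."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(1.0, p[i] * m / rank)
        running_min = min(running_min, val)
        adj[i] = running_min
    return adj


def oracle_unwrap(theta_wrapped_deg):
    """Cumulative sum of minimal-magnitude per-frame signed rotations."""
    out = [0.0]
    for k in range(1, len(theta_wrapped_deg)):
        d = theta_wrapped_deg[k] - theta_wrapped_deg[k - 1]
        while d > 180.0:
            d -= 360.0
        while d <= -180.0:
            d += 360.0
        out.append(out[-1] + d)
    return np.array(out) - 0.0
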