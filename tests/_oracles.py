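"""Plain-loop reference computations used to cross-check the segmentation."""

import itertools
import math

import numpy as np


def oracle_best_arc(x, min_markers):
    """Exhaustive arc scan with direct mean/variance arithmetic.

    Scans arc lengths ascending and start positions ascending, keeping the
    strictly best statistic, mirroring the tie-break contract of the fast
    implementation but sharing none of its code.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 * min_markers:
        return None
    sd = float(np.std(x))
    if sd == 0.0:
        return None
    best = None
    for k in range(min_markers, n - min_markers + 1):
        for i in range(0, n - k + 1):
            j = i + k
            arc = x[i:j]
            rest = np.concatenate([x[:i], x[j:]])
            t = abs(arc.mean() - rest.mean()) / (sd * math.sqrt(1 / k + 1 / (n - k)))
            if best is None or t > best[2]:
                best = (i, j, t)
    return best


def total_sse(x, changepoints):
    """Within-segment sum of squares for a given changepoint set."""
    bounds = [0, *sorted(changepoints), len(x)]
    sse = 0.0
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = x[a:b]
        sse += float(((seg - seg.mean()) ** 2).sum())
    return sse


def min_sse_changepoints(x, n_changepoints, min_markers):
    """Brute-force minimal-SSE changepoint set of the given size."""
    n = len(x)
    best = None
    for cps in itertools.combinations(range(1, n), n_changepoints):
        bounds = [0, *cps, n]
        if any(b - a < min_markers for a, b in zip(bounds[:-1], bounds[1:])):
            continue
        sse = total_sse(x, cps)
        if best is None or sse < best[1] - 1e-12:
            best = (cps, sse)
    return best
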