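"""Independent brute-force oracles used by the tests.

Deliberately written with plain Python loops and elementary numpy, sharing
no code path with the package's vectorized solvers.
"""

import math

import numpy as np


def flood_fill_components(mask: np.ndarray) -> int:
    """Count 4-connected components by breadth-first flood fill."""
    mask = np.asarray(mask) > 0
    seen = np.zeros_like(mask, dtype=bool)
    n = 0
    h, w = mask.shape
    for si in range(h):
        for sj in range(w):
            if not mask[si, sj] or seen[si, sj]:
                continue
            n += 1
            stack = [(si, sj)]
            seen[si, sj] = True
            while stack:
                i, j = stack.pop()
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    a, b = i + di, j + dj
                    if 0 <= a < h and 0 <= b < w and mask[a, b] and not seen[a, b]:
                        seen[a, b] = True
                        stack.append((a, b))
    return n


def _candidates(belief, spec):
    r = spec.search_radius_deg
    cs = belief.cell_size_deg
    xy = belief.xy
    xmin, ymin = xy.min(axis=0) - r
    xmax, ymax = xy.max(axis=0) + r
    cand = [
        (i * cs, j * cs)
        for j in range(math.floor(ymin / cs), math.ceil(ymax / cs) + 1)
        for i in range(math.floor(xmin / cs), math.ceil(xmax / cs) + 1)
    ]
    cand.append(tuple(spec.start_location))
    return cand


def exhaustive_single(belief, spec, alpha):
    """Best single fixation over the full padded lattice, with the
    (amplitude, row-major) tie-break applied through an explicit sort key."""
    r = spec.search_radius_deg
    sx, sy = spec.start_location
    best = None
    for fx, fy in _candidates(belief, spec):
        cov = np.hypot(belief.xy[:, 0] - fx, belief.xy[:, 1] - fy) < r
        dp = float(belief.p[cov].sum())
        amp = math.hypot(fx - sx, fy - sy)
        key = (-(100.0 * dp - alpha * amp), amp, fy, fx)
        if best is None or key < best[0]:
            best = (key, (fx, fy), dp)
    return best[1], best[2]


def exhaustive_pair(belief, spec, alpha):
    """Best ordered fixation pair by full enumeration (joint objective).

    The tie-break chain mirrors the documented contract: minimal total
    amplitude, then maximal first-fixation coverage (earlier detection),
    then row-major order."""
    r = spec.search_radius_deg
    sx, sy = spec.start_location
    cand = _candidates(belief, spec)
    covs = [
        np.hypot(belief.xy[:, 0] - fx, belief.xy[:, 1] - fy) < r for fx, fy in cand
    ]
    best = None
    for i, f1 in enumerate(cand):
        a1 = math.hypot(f1[0] - sx, f1[1] - sy)
        m1 = float(belief.p[covs[i]].sum())
        for j, f2 in enumerate(cand):
            dp = float(belief.p[covs[i] | covs[j]].sum())
            amp = a1 + math.hypot(f2[0] - f1[0], f2[1] - f1[1])
            key = (-(100.0 * dp - alpha * amp), amp, -m1,
                   f1[1], f1[0], f2[1], f2[0])
            if best is None or key < best[0]:
                best = (key, f1, f2, dp)
    return (best[1], best[2]), best[3]


def exhaustive_greedy(belief, spec, alpha):
    """Greedy two-step policy by enumeration: best single, then best
    incremental second."""
    r = spec.search_radius_deg
    f1, dp1 = exhaustive_single(belief, spec, alpha)
    cov1 = np.hypot(belief.xy[:, 0] - f1[0], belief.xy[:, 1] - f1[1]) < r
    best = None
    for fx, fy in _candidates(belief, spec):
        cov = np.hypot(belief.xy[:, 0] - fx, belief.xy[:, 1] - fy) < r
        inc = float(belief.p[cov & ~cov1].sum())
        amp = math.hypot(fx - f1[0], fy - f1[1])
        key = (-(100.0 * inc - alpha * amp), amp, fy, fx)
        if best is None or key < best[0]:
            best = (key, (fx, fy), inc)
    return (f1, best[1]), dp1 + best[2]


def monte_carlo_area(contains, bound: float, n: int, seed: int = 0) -> float:
    """Monte-Carlo area of a region given a point-membership predicate."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-bound, bound, size=(n, 2))
    frac = np.mean([bool(contains(p)) for p in pts])
    return float(frac * (2 * bound) ** 2)


def hotelling_two_sample(a, b):
    """Direct matrix-formula evaluation of the two-sample T^2 statistic."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = len(a), len(b)
    ma = a.sum(axis=0) / n1
    mb = b.sum(axis=0) / n2
    sa = (a - ma).T @ (a - ma) / (n1 - 1)
    sb = (b - mb).T @ (b - mb) / (n2 - 1)
    sp = ((n1 - 1) * sa + (n2 - 1) * sb) / (n1 + n2 - 2)
    d = ma - mb
    return float(n1 * n2 / (n1 + n2) * d @ np.linalg.inv(sp) @ d)
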