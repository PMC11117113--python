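"""Independent brute-force reference implementations.

Every function here is written as plainly as possible — explicit Python
loops, textbook formulas — and deliberately shares no code with the
package, so each serves as an oracle for the vectorized implementation.
"""

from __future__ import annotations

import math

import numpy as np


def euclidean_distance_matrix(coords: np.ndarray) -> np.ndarray:
    n = len(coords)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s = 0.0
            for k in range(3):
                s += (coords[i, k] - coords[j, k]) ** 2
            out[i, j] = math.sqrt(s)
    return out


def local_order(phases: np.ndarray, dist: np.ndarray, lam: float) -> np.ndarray:
    """Kernel-weighted mean phase vector modulus by explicit double loop."""
    n, T = phases.shape
    R = np.zeros((n, T))
    for node in range(n):
        for t in range(T):
            num = 0j
            den = 0.0
            for p in range(n):
                w = math.exp(-lam * dist[node, p])
                num += w * complex(math.cos(phases[p, t]), math.sin(phases[p, t]))
                den += w
            R[node, t] = abs(num) / den
    return R


def population_std(values: np.ndarray) -> float:
    flat = [float(v) for v in np.ravel(values)]
    m = sum(flat) / len(flat)
    m2 = sum(v * v for v in flat) / len(flat)
    return math.sqrt(m2 - m * m)


def node_std(R: np.ndarray) -> np.ndarray:
    return np.array([population_std(row) for row in R])


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (dx * dy)


def binned_pair_correlation(
    values: np.ndarray, dist: np.ndarray, n_bins: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean pairwise time-correlation per equal-width distance bin."""
    n = values.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    ds = [dist[i, j] for i, j in pairs]
    lo, hi = min(ds), max(ds)
    width = (hi - lo) / n_bins
    sums = [0.0] * n_bins
    counts = [0] * n_bins
    for (i, j), d in zip(pairs, ds):
        b = min(int((d - lo) / width), n_bins - 1) if width > 0 else 0
        sums[b] += pearson(values[i], values[j])
        counts[b] += 1
    centers = np.array([lo + (b + 0.5) * width for b in range(n_bins)])
    means = np.array(
        [sums[b] / counts[b] if counts[b] else np.nan for b in range(n_bins)]
    )
    return centers, means, np.array(counts, dtype=float)


def loglog_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares line of log y on log x via the normal equations."""
    lx = [math.log(v) for v in x]
    ly = [math.log(v) for v in y]
    n = len(lx)
    sx = sum(lx)
    sy = sum(ly)
    sxx = sum(v * v for v in lx)
    sxy = sum(a * b for a, b in zip(lx, ly))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def cascade_flow(R_hi: np.ndarray, R_lo: np.ndarray, dt: int) -> float:
    vals = []
    for node in range(R_hi.shape[0]):
        x = R_hi[node, dt:]
        y = R_lo[node, : R_lo.shape[1] - dt]
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        vals.append(pearson(x, y))
    return sum(vals) / len(vals)


def ks_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Sup-norm between empirical CDFs, scanned over pooled breakpoints."""
    points = sorted(set(list(x) + list(y)))
    best = 0.0
    for p in points:
        fx = sum(1 for v in x if v <= p) / len(x)
        fy = sum(1 for v in y if v <= p) / len(y)
        best = max(best, abs(fx - fy))
    return best


def cohens_d_pooled(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((v - ma) ** 2 for v in a) / (na - 1)
    vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
    sd = math.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    return (ma - mb) / sd


def top_quantile_counts(
    values: np.ndarray, labels: list[str], quantile: float
) -> dict[str, int]:
    """Sort-and-tally attribution of top-quantile nodes to networks."""
    thresh = np.quantile(values, 1 - quantile)
    out: dict[str, int] = {}
    for v, lab in zip(values, labels):
        if v >= thresh:
            out[lab] = out.get(lab, 0) + 1
    return out
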