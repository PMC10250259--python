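"""Independent brute-force reference implementations used as test oracles.

Everything here is written from first principles (quadratic enumeration,
naive agglomeration, exhaustive active sets) and deliberately shares no
code path with the package.
"""

import itertools

import numpy as np


def brute_tau_a(x, y):
    """Kendall tau-a by enumerating all entry pairs."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    m = len(x)
    c = d = 0
    for i in range(m - 1):
        for j in range(i + 1, m):
            s = (x[i] - x[j]) * (y[i] - y[j])
            if s > 0:
                c += 1
            elif s < 0:
                d += 1
    return (c - d) / (m * (m - 1) / 2)


def brute_upgma(square):
    """Naive UPGMA: clusters as index sets, average of original distances.

    Returns the sorted list of merge heights.
    """
    n = square.shape[0]
    clusters = [{i} for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([square[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return heights


def brute_cophenetic(square):
    """Pearson correlation of distances with naive-UPGMA merge heights."""
    n = square.shape[0]
    clusters = [{i} for i in range(n)]
    coph = np.zeros_like(square)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([square[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [clusters[a] | clusters[b]]
    iu = np.triu_indices(n, 1)
    return np.corrcoef(square[iu], coph[iu])[0, 1]


def brute_silhouette(square, labels):
    """Mean silhouette by direct per-point enumeration; singletons score 0."""
    labels = np.asarray(labels)
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            continue
        a = np.mean([square[i, j] for j in own])
        b = min(
            np.mean([square[i, j] for j in range(n) if labels[j] == lab])
            for lab in set(labels) - {labels[i]}
        )
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(np.mean(s))


def brute_bh(pvals, q_level):
    """Step-up BH by scanning all k; adjusted q by the min-over-suffix rule."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k / m * q_level:
            k_star = k
    reject = np.zeros(m, bool)
    reject[order[:k_star]] = True
    q = np.empty(m)
    suffix_min = np.inf
    for rank in range(m, 0, -1):
        suffix_min = min(suffix_min, m * p[order[rank - 1]] / rank)
        q[order[rank - 1]] = min(suffix_min, 1.0)
    return reject, q


def brute_nnls(A, b):
    """Exhaustive active-set NNLS: try every support, keep the best feasible."""
    A, b = np.asarray(A, float), np.asarray(b, float)
    nf = A.shape[1]
    best_w = np.zeros(nf)
    best_r = np.sum(b**2)
    for r in range(1, nf + 1):
        for support in itertools.combinations(range(nf), r):
            sub = A[:, list(support)]
            w_s, *_ = np.linalg.lstsq(sub, b, rcond=None)
            if np.any(w_s < -1e-12):
                continue
            resid = np.sum((sub @ np.clip(w_s, 0, None) - b) ** 2)
            if resid < best_r - 1e-12:
                best_r = resid
                best_w = np.zeros(nf)
                best_w[list(support)] = np.clip(w_s, 0, None)
    return best_w, best_r


def brute_stress1_nonmetric(dis, dist):
    """Kruskal stress-1 with monotone (isotonic) disparities via PAVA."""
    order = np.argsort(dis, kind="stable")
    y = np.asarray(dist, float)[order]
    # pool-adjacent-violators
    vals = list(y)
    wts = [1.0] * len(vals)
    i = 0
    while i < len(vals) - 1:
        if vals[i] > vals[i + 1] + 1e-15:
            merged = (vals[i] * wts[i] + vals[i + 1] * wts[i + 1]) / (wts[i] + wts[i + 1])
            vals[i:i + 2] = [merged]
            wts[i:i + 2] = [wts[i] + wts[i + 1]]
            i = max(i - 1, 0)
        else:
            i += 1
    dhat = np.repeat(vals, [int(w) for w in wts])
    num = np.sum((y - dhat) ** 2)
    den = np.sum(y**2)
    return np.sqrt(num / den) if den > 0 else 0.0
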