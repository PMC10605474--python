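"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: plain Python loops, no shared code with the package.
"""

from __future__ import annotations


def brute_dbscan_1d(points, eps, min_samples):
    """O(n^2) DBSCAN on a 1-D point list.

    Returns (kept_indices, noise_indices): kept = members of any cluster
    (core or border), noise = the rest.
    """
    n = len(points)
    neighbors = [
        [j for j in range(n) if abs(points[i] - points[j]) <= eps] for i in range(n)
    ]
    core = [i for i in range(n) if len(neighbors[i]) >= min_samples]
    core_set = set(core)
    cluster_of = {}
    cluster_id = 0
    for seed in core:
        if seed in cluster_of:
            continue
        stack = [seed]
        cluster_of[seed] = cluster_id
        while stack:
            i = stack.pop()
            if i not in core_set:
                continue  # border points do not expand
            for j in neighbors[i]:
                if j not in cluster_of:
                    cluster_of[j] = cluster_id
                    stack.append(j)
        cluster_id += 1
    kept = sorted(cluster_of)
    noise = sorted(set(range(n)) - set(kept))
    return kept, noise


def brute_k_distance(points, k):
    """Each point's distance to its k-th nearest neighbour, sorted ascending."""
    out = []
    for i, p in enumerate(points):
        dists = sorted(abs(p - q) for j, q in enumerate(points) if j != i)
        out.append(dists[k - 1])
    return sorted(out)


def exhaustive_kneedle_convex_increasing(y, sensitivity=1.0):
    """Exhaustive Kneedle on a convex increasing curve.

    Mirrors the curve into concave-increasing form, scans every difference-
    curve local maximum in order, and returns the original-orientation index
    of the first one whose difference drops by more than S * mean(dx) before
    the next maximum.  Returns None if no knee qualifies.
    """
    n = len(y)
    lo, hi = min(y), max(y)
    if n < 3 or hi == lo:
        return None
    x_n = [i / (n - 1) for i in range(n)]
    y_n = [(v - lo) / (hi - lo) for v in y]
    y_t = [1.0 - y_n[n - 1 - i] for i in range(n)]
    diff = [y_t[i] - x_n[i] for i in range(n)]
    maxima = [
        i for i in range(1, n - 1) if diff[i - 1] < diff[i] and diff[i] >= diff[i + 1]
    ]
    step = sensitivity / (n - 1)
    for idx, m in enumerate(maxima):
        end = maxima[idx + 1] if idx + 1 < len(maxima) else n
        if any(diff[i] < diff[m] - step for i in range(m + 1, end)):
            return n - 1 - m
    return None
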