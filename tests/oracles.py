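"""Brute-force reference implementations used only to check the package.

Everything here works by exhaustive enumeration of simple paths, which
is exact (and affordable) for the tiny digraphs of 4v4 games, and stays
independent of the algorithms in ssgnet.networks.
"""

import numpy as np


def all_simple_paths(a, j, k):
    """All simple directed paths j -> k in binary adjacency a."""
    n = a.shape[0]
    paths = []

    def extend(path):
        last = path[-1]
        if last == k and len(path) > 1:
            paths.append(list(path))
            return
        for nxt in range(n):
            if a[last, nxt] and nxt not in path:
                extend(path + [nxt])

    extend([j])
    return paths


def brute_paths(a):
    """(dist, sigma, sigma_through) by exhaustive path enumeration."""
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    through = np.zeros((n, n, n))
    np.fill_diagonal(dist, 0.0)
    np.fill_diagonal(sigma, 1.0)
    for j in range(n):
        for k in range(n):
            if j == k:
                continue
            paths = all_simple_paths(a, j, k)
            if not paths:
                continue
            best = min(len(p) - 1 for p in paths)
            shortest = [p for p in paths if len(p) - 1 == best]
            dist[j, k] = best
            sigma[j, k] = len(shortest)
            for i in range(n):
                if i in (j, k):
                    continue
                through[i, j, k] = sum(i in p for p in shortest)
    return dist, sigma, through


def brute_closeness(a, i):
    """Paper-convention closeness: unreachable distances count as n."""
    n = a.shape[0]
    dist, _, _ = brute_paths(a)
    d = np.delete(dist[i, :], i)
    if not np.any(np.isfinite(d)):
        return 0.0
    return 1.0 / float(np.where(np.isfinite(d), d, n).sum())


def brute_betweenness(a, i):
    n = a.shape[0]
    _, sigma, through = brute_paths(a)
    total = 0.0
    for j in range(n):
        for k in range(n):
            if i in (j, k) or j == k or sigma[j, k] == 0:
                continue
            total += through[i, j, k] / sigma[j, k]
    return total


def int_to_digraph(code, n=4):
    """Decode an integer into the binary adjacency of an n-node digraph
    (one bit per ordered off-diagonal pair, row-major)."""
    a = np.zeros((n, n), dtype=int)
    bit = 0
    for j in range(n):
        for k in range(n):
            if j == k:
                continue
            a[j, k] = (code >> bit) & 1
            bit += 1
    return a
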