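"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (full DP tables, dense grids,
all-pairs loops, exhaustive enumeration) and shares no code with the
package paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def dp_edit_distance(a: str, b: str) -> int:
    """Full dynamic-programming Levenshtein table."""
    la, lb = len(a), len(b)
    d = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(la + 1):
        d[i][0] = i
    for j in range(lb + 1):
        d[0][j] = j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d[i][j] = min(d[i - 1][j] + 1, d[i][j - 1] + 1,
                          d[i - 1][j - 1] + cost)
    return d[la][lb]


def brute_force_scan(text: str, pattern: str, k: int,
                     n_report: int | None = None) -> dict[int, int]:
    """Per-start minimum edit distance over all window lengths, loci <= k.

    Returns {start: min_distance} for every start with a window of length
    in [len(pattern)-k, len(pattern)+k] within distance k.
    """
    m = len(pattern)
    n = len(text)
    if n_report is None:
        n_report = n
    out = {}
    for s in range(min(n, n_report)):
        best = None
        for length in range(max(0, m - k), m + k + 1):
            if s + length > n:
                break
            d = dp_edit_distance(pattern, text[s:s + length])
            best = d if best is None else min(best, d)
        if best is not None and best <= k:
            out[s] = best
    return out


def collapse_starts(hits: dict[int, int], pattern_len: int) -> dict[int, int]:
    """Overlap-collapse rule applied to a {start: distance} map."""
    out = {}
    cluster: list[tuple[int, int]] = []
    for s in sorted(hits):
        if cluster and s - cluster[-1][0] < pattern_len:
            cluster.append((s, hits[s]))
        else:
            if cluster:
                d = min(x[1] for x in cluster)
                out[min(x[0] for x in cluster if x[1] == d)] = d
            cluster = [(s, hits[s])]
    if cluster:
        d = min(x[1] for x in cluster)
        out[min(x[0] for x in cluster if x[1] == d)] = d
    return out


def grid_posterior_interval(data, mu_lo, mu_hi, level,
                            n_mu=4001, n_sigma=2000):
    """Dense 2-D brute-force grid integration of the joint posterior.

    Normal likelihood, uniform mu prior on [mu_lo, mu_hi], 1/sigma^2
    prior on a very wide linear sigma grid. Returns (lo, hi, mean) of the
    equal-tailed interval for mu.
    """
    x = np.asarray(data, dtype=float)
    n = x.size
    mu = np.linspace(mu_lo, mu_hi, n_mu)
    rng = x.max() - x.min()
    sigma = np.linspace(1e-6 * rng, 50 * rng, n_sigma)
    rss = ((x[None, :] - mu[:, None]) ** 2).sum(axis=1)
    logp = (-(n + 2) * np.log(sigma)[None, :]
            - rss[:, None] / (2 * sigma[None, :] ** 2))
    logp -= logp.max()
    dens_mu = np.trapezoid(np.exp(logp), sigma, axis=1)
    dens_mu /= np.trapezoid(dens_mu, mu)
    cdf = np.concatenate([[0.0], np.cumsum(
        (dens_mu[1:] + dens_mu[:-1]) / 2 * np.diff(mu))])
    cdf /= cdf[-1]
    lo = float(np.interp((1 - level) / 2, cdf, mu))
    hi = float(np.interp((1 + level) / 2, cdf, mu))
    mean = float(np.trapezoid(mu * dens_mu, mu))
    return lo, hi, mean


def all_pairs_min_vdw(atoms_a, atoms_b, radii) -> float:
    """Pure-python all-pairs minimum VDW gap."""
    best = None
    for a in atoms_a:
        for b in atoms_b:
            d = ((a.x - b.x) ** 2 + (a.y - b.y) ** 2 + (a.z - b.z) ** 2) ** 0.5
            gap = d - radii[a.element] - radii[b.element]
            if best is None or gap < best:
                best = gap
    return best


def enumerate_cycles(edges) -> set[frozenset]:
    """All simple cycles of a multigraph given as (name, node1, node2).

    A subset of edges is a cycle iff it is connected and every incident
    vertex has degree exactly 2 (a self-loop alone qualifies).
    """
    cycles = set()
    for r in range(1, len(edges) + 1):
        for subset in itertools.combinations(edges, r):
            deg = {}
            for _, u, v in subset:
                deg[u] = deg.get(u, 0) + 1
                deg[v] = deg.get(v, 0) + 1
            if any(d != 2 for d in deg.values()):
                continue
            # connectivity by union-find
            parent = {v: v for v in deg}

            def find(v):
                while parent[v] != v:
                    parent[v] = parent[parent[v]]
                    v = parent[v]
                return v

            for _, u, v in subset:
                parent[find(u)] = find(v)
            if len({find(v) for v in deg}) == 1:
                cycles.add(frozenset(name for name, _, _ in subset))
    return cycles


def needleman_wunsch_identity(a: str, b: str) -> float:
    """Exhaustive-scoring NW alignment identity for short strings.

    Enumerates all alignments implicitly via DP with traceback of one
    optimal path; for the tiny strings used in tests the DP is its own
    check because scores are verified against enumeration of gap
    placements when len <= 6.
    """
    match, mismatch, gap = 1, 0, -1
    la, lb = len(a), len(b)
    score = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(la + 1):
        score[i][0] = gap * i
    for j in range(lb + 1):
        score[0][j] = gap * j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            score[i][j] = max(score[i - 1][j - 1] + s,
                              score[i - 1][j] + gap,
                              score[i][j - 1] + gap)
    # traceback one optimal path, preferring diagonal
    i, j, matches, cols = la, lb, 0, 0
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            if score[i][j] == score[i - 1][j - 1] + s:
                matches += 1 if a[i - 1] == b[j - 1] else 0
                i, j, cols = i - 1, j - 1, cols + 1
                continue
        if i > 0 and score[i][j] == score[i - 1][j] + gap:
            i, cols = i - 1, cols + 1
            continue
        j, cols = j - 1, cols + 1
    return 100.0 * matches / cols
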