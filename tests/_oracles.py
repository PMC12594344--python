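"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the Viterbi check
enumerates every state path, and the changepoint check runs a plain
unpruned optimal-partitioning dynamic program.
"""
import itertools

import numpy as np


def all_paths_log_likelihood(y, params):
    """Log-likelihood of every 2^n state path (state 1 = donor)."""
    n = len(y)
    paths = np.array(list(itertools.product([0, 1], repeat=n)), dtype=np.int64)
    log_e = np.log([[1 - params.e_r, params.e_r], [1 - params.e_d, params.e_d]])
    log_t = np.log([[1 - params.t, params.t], [params.t, 1 - params.t]])
    log_pi = np.log([1 - params.pi_d, params.pi_d])
    ll = log_pi[paths[:, 0]] + log_e[paths[:, 0], y[0]]
    for i in range(1, n):
        ll += log_t[paths[:, i - 1], paths[:, i]] + log_e[paths[:, i], y[i]]
    return paths, ll


def dp_optimal_partition(values, penalty, minseg):
    """Plain O(n^2) optimal partitioning, no pruning."""
    v = np.asarray(values, dtype=float)
    n = v.size
    INF = float("inf")
    F = [INF] * (n + 1)
    F[0] = -penalty
    prev = [0] * (n + 1)
    for s in range(1, n + 1):
        for t in range(0, s - minseg + 1):
            seg = v[t:s]
            cost = float(((seg - seg.mean()) ** 2).sum())
            val = F[t] + cost + penalty
            if val < F[s]:
                F[s] = val
                prev[s] = t
    cps = []
    s = n
    while s > 0:
        t = prev[s]
        if t > 0:
            cps.append(t)
        s = t
    return sorted(cps), F[n]


def partition_total_cost(values, cps, penalty):
    v = np.asarray(values, dtype=float)
    bounds = [0] + list(cps) + [len(v)]
    cost = -penalty
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = v[a:b]
        cost += float(((seg - seg.mean()) ** 2).sum()) + penalty
    return cost


def random_piecewise_series(rng, n):
    """Noisy piecewise-constant series with 0-2 true changepoints."""
    k = int(rng.integers(0, 3))
    bounds = np.sort(rng.choice(np.arange(1, n), size=k, replace=False)) if k else []
    levels = rng.uniform(0, 1, size=k + 1)
    v = np.empty(n)
    prev_b = 0
    for lev, b in zip(levels, list(bounds) + [n]):
        v[prev_b:b] = lev
        prev_b = b
    return v + rng.normal(0, 0.15, size=n)
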