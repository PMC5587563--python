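"""Independent brute-force oracles for the weighted graph measures.

Triple-loop / exhaustive-enumeration implementations kept deliberately
separate from the package code paths they validate.
"""

import numpy as np


def floyd_warshall_oracle(w):
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def efficiency_oracle(w):
    d = floyd_warshall_oracle(w)
    n = w.shape[0]
    acc = 0.0
    for s in range(n):
        for t in range(n):
            if s != t and np.isfinite(d[s, t]):
                acc += 1.0 / d[s, t]
    return acc / (n * (n - 1))


def clustering_oracle(w, denominator):
    ws = w / w.max()
    n = w.shape[0]
    cv = np.zeros(n)
    for v in range(n):
        acc = 0.0
        for x in range(n):
            for y in range(n):
                acc += (ws[v, x] * ws[v, y] * ws[x, y]) ** (1 / 3)
        k = np.count_nonzero(ws[v]) if denominator == "degree" else ws[v].sum()
        cv[v] = acc / (k * (k - 1)) if k * (k - 1) > 0 else 0.0
    return cv.mean(), cv


def local_efficiency_oracle(w):
    n = w.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nbrs = [x for x in range(n) if w[v, x] > 0]
        if len(nbrs) < 2:
            continue
        idx = [v] + nbrs
        out[v] = efficiency_oracle(w[np.ix_(idx, idx)])
    return out


def set_partitions(items):
    """All partitions of a list (recursive enumeration)."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, subset in enumerate(smaller):
            yield smaller[:i] + [[first] + subset] + smaller[i + 1 :]
        yield [[first]] + smaller


def modularity_of_partition(w, parts):
    total = w.sum()  # 2m for undirected
    q = 0.0
    strengths = w.sum(axis=1)
    for block in parts:
        for i in block:
            for j in block:
                q += w[i, j] - strengths[i] * strengths[j] / total
    return q / total
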