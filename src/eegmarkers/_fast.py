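"""Compiled kernels for the sequence-complexity estimators."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def lz76_phrase_count(s: np.ndarray) -> int:
    """Number of phrases in the exhaustive (1976) Lempel-Ziv parsing.

    A phrase starting at ``i`` is extended while the candidate ``s[i:i+l]``
    occurs somewhere in ``s[0:i+l-1]`` starting before ``i`` (self-overlap
    with the phrase under construction is allowed); the first character
    that breaks reproducibility closes the phrase.  The trailing,
    possibly incomplete phrase counts as one.
    """
    n = len(s)
    if n == 0:
        return 0
    c = 1
    i = 1
    while i < n:
        l = 1
        while i + l <= n:
            found = False
            for j in range(i):
                ok = True
                for k in range(l):
                    if s[j + k] != s[i + k]:
                        ok = False
                        break
                if ok:
                    found = True
                    break
            if not found:
                break
            l += 1
        c += 1
        i += l
    return c


@njit(cache=True)
def ctw_log2_prob(bits: np.ndarray, depth: int) -> float:
    """log2 of the context-tree-weighted probability of a binary string.

    Krichevsky-Trofimov estimators at every node of a context tree of the
    given depth, with the standard half/half weighting between each node's
    own KT estimate and the product of its children.  The initial context
    is zero-padded so all ``len(bits)`` symbols contribute.
    """
    n = len(bits)
    if n == 0:
        return 0.0
    max_nodes = n * (depth + 1) + depth + 2
    child = np.full((max_nodes, 2), -1, dtype=np.int64)
    counts = np.zeros((max_nodes, 2), dtype=np.float64)
    lpe = np.zeros(max_nodes, dtype=np.float64)
    lpw = np.zeros(max_nodes, dtype=np.float64)
    n_nodes = 1  # root = 0
    path = np.empty(depth + 1, dtype=np.int64)
    log_half = -0.6931471805599453

    for t in range(n):
        s = bits[t]
        # walk root -> leaf along the context (most recent symbol first)
        node = 0
        path[0] = 0
        for d in range(1, depth + 1):
            b = bits[t - d] if t - d >= 0 else 0
            nxt = child[node, b]
            if nxt < 0:
                nxt = n_nodes
                n_nodes += 1
                child[node, b] = nxt
            node = nxt
            path[d] = node
        # bottom-up KT + weighting update
        for d in range(depth, -1, -1):
            node = path[d]
            tot = counts[node, 0] + counts[node, 1]
            lpe[node] += np.log((counts[node, s] + 0.5) / (tot + 1.0))
            counts[node, s] += 1.0
            if d == depth:
                lpw[node] = lpe[node]
            else:
                csum = 0.0
                c0 = child[node, 0]
                c1 = child[node, 1]
                if c0 >= 0:
                    csum += lpw[c0]
                if c1 >= 0:
                    csum += lpw[c1]
                a = log_half + lpe[node]
                b2 = log_half + csum
                if a > b2:
                    lpw[node] = a + np.log1p(np.exp(b2 - a))
                else:
                    lpw[node] = b2 + np.log1p(np.exp(a - b2))
    return lpw[0] / 0.6931471805599453


@njit(cache=True)
def fuzzy_pair_sums(x: np.ndarray, r: float) -> (float, float):
    """Sums over template pairs i<j of the sigmoid membership
    ``mu(d) = 1/(1 + exp((d - 0.5)/r))`` for Chebyshev distances of
    embedding dimension m=2 (B) and m=3 (A), delay 1.

    Kept for reference/small inputs; the chunked NumPy path in
    :mod:`eegmarkers.entropy` is used for long segments.
    """
    n = len(x)
    N = n - 2
    A = 0.0
    B = 0.0
    for i in range(N):
        for j in range(i + 1, N):
            d = abs(x[i] - x[j])
            d1 = abs(x[i + 1] - x[j + 1])
            if d1 > d:
                d = d1
            B += 1.0 / (1.0 + np.exp((d - 0.5) / r))
            d2 = abs(x[i + 2] - x[j + 2])
            if d2 > d:
                d = d2
            A += 1.0 / (1.0 + np.exp((d - 0.5) / r))
    return A, B
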