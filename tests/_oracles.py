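"""Brute-force reference implementations used only as test oracles.

Everything here is deliberately independent of the package code paths:
ranks are built by counting comparisons, the test statistics follow the
textbook formulas term by term, and Holm is a literal step-down loop.
"""

from __future__ import annotations

import math


def midranks(values):
    """Rank by counting: rank = (#smaller) + (#equal + 1)/2."""
    return [sum(v < x for v in values) + (sum(v == x for v in values) + 1) / 2.0
            for x in values]


def tie_sum(values):
    out = 0.0
    for v in set(values):
        t = values.count(v) if isinstance(values, list) else \
            int(sum(x == v for x in values))
        out += t ** 3 - t
    return out


def kw_brute(groups):
    """Tie-corrected Kruskal-Wallis H and df from a list of lists."""
    pooled = [x for g in groups for x in g]
    n = len(pooled)
    ranks = midranks(pooled)
    h = 0.0
    pos = 0
    for g in groups:
        r = ranks[pos:pos + len(g)]
        h += sum(r) ** 2 / len(g)
        pos += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    c = 1.0 - tie_sum(pooled) / (n ** 3 - n)
    if c <= 0:
        return 0.0, len(groups) - 1
    return max(h / c, 0.0), len(groups) - 1


def dunn_z_brute(groups, i, j):
    """Dunn Z for groups i vs j on joint mid-ranks."""
    pooled = [x for g in groups for x in g]
    n = len(pooled)
    ranks = midranks(pooled)
    bounds = []
    pos = 0
    for g in groups:
        bounds.append((pos, pos + len(g)))
        pos += len(g)
    ri = ranks[bounds[i][0]:bounds[i][1]]
    rj = ranks[bounds[j][0]:bounds[j][1]]
    var = (n * (n + 1) / 12.0 - tie_sum(pooled) / (12.0 * (n - 1))) * \
        (1.0 / len(ri) + 1.0 / len(rj))
    if var <= 0:
        return 0.0
    return (sum(ri) / len(ri) - sum(rj) / len(rj)) / math.sqrt(var)


def holm_brute(pvals):
    """Literal step-down: repeatedly adjust the smallest remaining p."""
    m = len(pvals)
    indexed = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 0.0
    for step, idx in enumerate(indexed):
        val = (m - step) * pvals[idx]
        running = max(running, val)
        adjusted[idx] = min(running, 1.0)
    return adjusted


def small_instances():
    """Deterministic family of small integer grouped samples.

    All value tuples over {1, 2, 3} of total size 3..6, split into two
    or three groups — heavy ties included by construction.
    """
    import itertools
    for n in range(3, 7):
        for values in itertools.product((1, 2, 3), repeat=n):
            half = n // 2
            yield [list(values[:half]), list(values[half:])]
            if n >= 6:
                third = n // 3
                yield [list(values[:third]),
                       list(values[third:2 * third]),
                       list(values[2 * third:])]
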