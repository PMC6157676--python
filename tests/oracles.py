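"""Independent brute-force oracles used only by the tests.

Deliberately naive implementations — loops and first-principles formulas —
so they share no code path with the package.
"""

from __future__ import annotations

import math


def midranks(values) -> list[float]:
    """Ranks 1..n with ties replaced by the mean of their positions."""
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_spearman(x, y) -> float:
    """Spearman rho = Pearson correlation of midranks, from first principles."""
    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / math.sqrt(vx * vy)
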