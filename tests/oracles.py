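"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: plain-Python affine-gap
alignment over explicit three-state tables, naive identity counting, and
exhaustive enumerations.  Slow but obviously correct on small inputs.
"""

from __future__ import annotations

import itertools
import math

NEG = float("-inf")


def oracle_affine_global(a: str, b: str, score, gap_open: float,
                         gap_extend: float) -> float:
    """Optimal global score; gap of length k costs gap_open + k*gap_extend."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + gap_extend * i)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + gap_extend * j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score(a[i - 1], b[j - 1])
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] - gap_open - gap_extend,
                          X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - gap_open - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open - gap_extend,
                          Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - gap_open - gap_extend)
    return max(M[n][m], X[n][m], Y[n][m])


def oracle_affine_local(a: str, b: str, score, gap_open: float,
                        gap_extend: float) -> float:
    """Optimal local (Smith-Waterman) score under the same gap model."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = NEG
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score(a[i - 1], b[j - 1])
            prev = max(0.0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = s + prev
            best = max(best, M[i][j])
            X[i][j] = max(M[i - 1][j] - gap_open - gap_extend,
                          X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - gap_open - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open - gap_extend,
                          Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - gap_open - gap_extend)
    return best


def oracle_column_identity(aligned_a: str, aligned_b: str,
                           ambiguous: str = "X") -> int:
    """Match count by explicit column walk on a printed alignment."""
    matches = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            continue
        if x == y and x not in ambiguous:
            matches += 1
    return matches


def oracle_accumulation_medians(sets, fn=None):
    """Exhaustive accumulation over all orderings of per-genome cluster
    sets; returns (pan_medians, core_medians) as lists of floats using the
    same linear-interpolation median as numpy's default."""
    import statistics

    G = len(sets)
    pans = []
    cores = []
    for order in itertools.permutations(range(G)):
        pan = set()
        core = None
        prow = []
        crow = []
        for gi in order:
            pan = pan | sets[gi]
            core = set(sets[gi]) if core is None else core & sets[gi]
            prow.append(len(pan))
            crow.append(len(core))
        pans.append(prow)
        cores.append(crow)
    pan_med = [statistics.median(col) for col in zip(*pans)]
    core_med = [statistics.median(col) for col in zip(*cores)]
    return pan_med, core_med


def oracle_spearman(x, y):
    """Spearman rho with average ranks, from first principles."""
    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx)
                    * sum((b - my) ** 2 for b in ry))
    return num / den
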