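"""Independent reference implementations used only as test oracles.

These are deliberately naive and coded separately from the package: a
textbook affine-gap local-alignment dynamic program (Gotoh), and a plain
dense Markov-clustering loop with depth-first cluster read-off. They trade
all performance for obvious correctness.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def gotoh_local_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Optimal local alignment score, affine gaps costing open + L*extend."""
    n, m = len(a), len(b)
    NEG = -10**9
    H = [[0] * (m + 1) for _ in range(n + 1)]  # best ending in match/mismatch or 0
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(
                H[i - 1][j] - gap_open - gap_extend, E[i - 1][j] - gap_extend
            )
            F[i][j] = max(
                H[i][j - 1] - gap_open - gap_extend, F[i][j - 1] - gap_extend
            )
            s = int(_B62[a[i - 1]][b[j - 1]])
            H[i][j] = max(
                0,
                max(H[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1]) + s,
            )
            best = max(best, H[i][j], E[i][j], F[i][j])
    return best


def naive_mcl(
    adjacency: np.ndarray,
    inflation: float = 2.0,
    expansion: int = 2,
    prune: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> list[set[int]]:
    """Plain dense MCL over a symmetric non-negative adjacency matrix.

    Self-loop weight = max incident weight (1 for isolated nodes); clusters
    are read off the converged flow support with a hand-rolled DFS.
    """
    A = np.array(adjacency, dtype=float)
    n = A.shape[0]
    for i in range(n):
        mx = A[:, i].max()
        A[i, i] = mx if mx > 0 else 1.0
    M = A / A.sum(axis=0)
    for _ in range(max_iter):
        prev = M.copy()
        P = M
        for _ in range(expansion - 1):
            P = P @ M
        M = P**inflation
        M[M < prune] = 0.0
        s = M.sum(axis=0)
        s[s == 0] = 1.0
        M = M / s
        if np.max(np.abs(M - prev)) < tol:
            break
    support = (M > prune) | (M > prune).T
    seen = [False] * n
    clusters = []
    for start in range(n):
        if seen[start]:
            continue
        stack = [start]
        comp = set()
        while stack:
            v = stack.pop()
            if seen[v]:
                continue
            seen[v] = True
            comp.add(v)
            for w in range(n):
                if support[v, w] and not seen[w]:
                    stack.append(w)
        clusters.append(comp)
    return clusters
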