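"""Independent brute-force reference implementations.

These deliberately avoid the code paths (and where possible the libraries)
used by the package: textbook formulas, triple loops and Floyd-Warshall
instead of vectorized linear algebra and Dijkstra.
"""

from __future__ import annotations

import math

import numpy as np


def pearson_direct(x, y) -> float:
    """Textbook covariance-formula Pearson correlation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def strength_degree_brute(W: np.ndarray) -> tuple[list[float], list[int]]:
    n = W.shape[0]
    strength = [sum(W[i][j] for j in range(n) if j != i) for i in range(n)]
    degree = [sum(1 for j in range(n) if j != i and W[i][j] > 0) for i in range(n)]
    return strength, degree


def clustering_onnela_brute(W: np.ndarray) -> list[float]:
    """Per-node Onnela weighted clustering by triple enumeration.

    Assumes edge weights are already on the [0, 1] scale (max weight 1)."""
    n = W.shape[0]
    out = []
    for i in range(n):
        neigh = [j for j in range(n) if j != i and W[i][j] > 0]
        k = len(neigh)
        if k < 2:
            out.append(0.0)
            continue
        total = 0.0
        for a in range(len(neigh)):
            for b in range(len(neigh)):
                if a == b:
                    continue
                j, h = neigh[a], neigh[b]
                if W[j][h] > 0:
                    total += (W[i][j] * W[i][h] * W[j][h]) ** (1.0 / 3.0)
        out.append(total / (k * (k - 1)))
    return out


def path_length_floyd(W: np.ndarray) -> tuple[float, float]:
    """Characteristic path length via Floyd-Warshall on lengths 1/weight.

    Returns (mean over reachable ordered pairs, unreachable fraction)."""
    n = W.shape[0]
    INF = float("inf")
    D = [[0.0 if i == j else (1.0 / W[i][j] if W[i][j] > 0 else INF)
          for j in range(n)] for i in range(n)]
    for m in range(n):
        for i in range(n):
            for j in range(n):
                if D[i][m] + D[m][j] < D[i][j]:
                    D[i][j] = D[i][m] + D[m][j]
    finite = [D[i][j] for i in range(n) for j in range(n) if i != j and D[i][j] < INF]
    n_off = n * (n - 1)
    frac_unreachable = 1.0 - len(finite) / n_off
    mean_len = sum(finite) / len(finite) if finite else INF
    return mean_len, frac_unreachable


def rich_club_brute(W: np.ndarray, k: int) -> float | None:
    """phi(k) by explicit subgraph enumeration: density of the induced
    subgraph over nodes of degree > k.  None when undefined."""
    n = W.shape[0]
    degree = [sum(1 for j in range(n) if j != i and W[i][j] > 0) for i in range(n)]
    nodes = [i for i in range(n) if degree[i] > k]
    if len(nodes) < 2:
        return None
    edges = sum(1 for a in range(len(nodes)) for b in range(a + 1, len(nodes))
                if W[nodes[a]][nodes[b]] > 0)
    return 2.0 * edges / (len(nodes) * (len(nodes) - 1))


def mixed_anova_cellmeans(Y: np.ndarray, n_groups: int) -> tuple[float, float, float]:
    """Hand SS-decomposition mixed ANOVA on a subjects x sessions matrix
    (subjects blocked by group, equal sizes), written with explicit loops."""
    n_subj, b = Y.shape
    n_per = n_subj // n_groups
    grand = Y.mean()
    ss_total = ((Y - grand) ** 2).sum()
    subj_mean = Y.mean(axis=1)
    ss_between_subj = b * ((subj_mean - grand) ** 2).sum()
    group_of = np.repeat(np.arange(n_groups), n_per)
    gmean = np.array([Y[group_of == g].mean() for g in range(n_groups)])
    ss_a = n_per * b * ((gmean - grand) ** 2).sum()
    ss_subj = ss_between_subj - ss_a
    smean = Y.mean(axis=0)
    ss_b = n_subj * ((smean - grand) ** 2).sum()
    cell = np.array([[Y[group_of == g][:, j].mean() for j in range(b)]
                     for g in range(n_groups)])
    ss_ab = n_per * sum((cell[g, j] - gmean[g] - smean[j] + grand) ** 2
                        for g in range(n_groups) for j in range(b))
    ss_err = ss_total - ss_between_subj - ss_b - ss_ab
    df_a, df_subj = n_groups - 1, n_groups * (n_per - 1)
    df_b = b - 1
    df_ab, df_err = df_a * df_b, df_subj * df_b
    f_a = (ss_a / df_a) / (ss_subj / df_subj)
    f_b = (ss_b / df_b) / (ss_err / df_err)
    f_ab = (ss_ab / df_ab) / (ss_err / df_err)
    return f_a, f_b, f_ab
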