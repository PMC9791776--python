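"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity from first principles (enumeration, the
defining formula, or pairwise counting) without touching the library code
paths it checks.
"""

from itertools import combinations

import numpy as np
from scipy import stats


def rank_sum_exact_p(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = np.array(x + y)
    n1 = len(x)
    idx = range(len(pooled))

    def u_stat(first_idx):
        first = pooled[list(first_idx)]
        rest = pooled[[i for i in idx if i not in set(first_idx)]]
        return sum(np.sum(a > rest) + 0.5 * np.sum(a == rest) for a in first)

    u_obs = u_stat(range(n1))
    us = np.array([u_stat(c) for c in combinations(idx, n1)])
    p = 2.0 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))
    return min(1.0, p)


def kruskal_h(groups) -> float:
    """Kruskal-Wallis H from the defining rank formula with tie correction."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    ranks = stats.rankdata(pooled)
    n = pooled.size
    start = 0
    h = 0.0
    for g in groups:
        k = len(g)
        h += ranks[start : start + k].sum() ** 2 / k
        start += k
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


def bh_step_up(pvalues) -> np.ndarray:
    """BH adjusted p-values directly from the step-up definition."""
    p = np.asarray(pvalues, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adjusted[i] = running_min
    return adjusted


def pairwise_auc(scores, labels) -> float:
    """AUC as explicit pairwise concordance counting, ties worth 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (pos.size * neg.size)


def greedy_mrmr(disc: np.ndarray, labels: np.ndarray, top_k: int) -> list[int]:
    """Exhaustive greedy mRMR (MID) over pre-discretized features."""
    from sklearn.metrics import mutual_info_score

    n_feat = disc.shape[1]
    relevance = [mutual_info_score(labels, disc[:, j]) for j in range(n_feat)]
    selected: list[int] = []
    while len(selected) < top_k:
        best_j, best_score = None, -np.inf
        for j in range(n_feat):
            if j in selected:
                continue
            if selected:
                red = np.mean([mutual_info_score(disc[:, j], disc[:, s]) for s in selected])
            else:
                red = 0.0
            score = relevance[j] - red
            if score > best_score + 1e-12:
                best_j, best_score = j, score
        selected.append(best_j)
    return selected


def agglomerate(dist: np.ndarray, method: str = "average") -> list[frozenset]:
    """Naive agglomeration: returns the merged cluster at each step."""
    n = dist.shape[0]
    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            pairs = [dist[i, j] for i in clusters[a] for j in clusters[b]]
            d = np.mean(pairs) if method == "average" else np.max(pairs)
            if best is None or d < best[0] - 1e-12:
                best = (d, a, b)
        _, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append(merged)
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return merges
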