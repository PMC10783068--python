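"""Independent brute-force reference implementations used only by tests.

Each function here recomputes a statistic from its textbook definition
with naive loops, deliberately sharing no code with the package.
"""

from __future__ import annotations

import numpy as np


# --- pairwise dissimilarities ---------------------------------------------


def jaccard(x: np.ndarray, y: np.ndarray) -> float:
    a = set(np.flatnonzero(x > 0))
    b = set(np.flatnonzero(y > 0))
    if not a and not b:
        return 0.0
    return 1.0 - len(a & b) / len(a | b)


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    x = x / x.sum()
    y = y / y.sum()
    return float(np.abs(x - y).sum() / (x + y).sum())


def _branches(tree, taxa):
    """(length, tip-descendant set) for every non-root branch."""
    out = []
    for node in tree.traverse(include_self=False):
        tips = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        out.append((node.length or 0.0, tips & set(taxa)))
    return out


def unweighted_unifrac(x, y, tree, taxa) -> float:
    present_x = {taxa[i] for i in np.flatnonzero(x > 0)}
    present_y = {taxa[i] for i in np.flatnonzero(y > 0)}
    unique = shared = 0.0
    for length, tips in _branches(tree, taxa):
        in_x = bool(tips & present_x)
        in_y = bool(tips & present_y)
        if in_x or in_y:
            shared += length
            if in_x != in_y:
                unique += length
    return unique / shared if shared > 0 else 0.0


def weighted_unifrac_normalized(x, y, tree, taxa) -> float:
    px = dict(zip(taxa, x / x.sum()))
    py = dict(zip(taxa, y / y.sum()))
    num = den = 0.0
    for length, tips in _branches(tree, taxa):
        pa = sum(px[t] for t in tips)
        pb = sum(py[t] for t in tips)
        num += length * abs(pa - pb)
        den += length * (pa + pb)
    return num / den if den > 0 else 0.0


# --- graphs ----------------------------------------------------------------


def betweenness_bfs(adj: dict, normalized: bool = True) -> dict:
    """Brandes-free betweenness: enumerate all shortest paths explicitly."""
    nodes = list(adj)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s in nodes:
        for t in nodes:
            if s >= t:
                continue
            paths = _all_shortest_paths(adj, s, t)
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    score[v] += 1.0 / len(paths)
    if normalized and n > 2:
        factor = 2.0 / ((n - 1) * (n - 2))
        score = {v: x * factor for v, x in score.items()}
    return score


def _all_shortest_paths(adj, s, t):
    from collections import deque

    dist = {s: 0}
    queue = deque([s])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    if t not in dist:
        return []
    paths = []

    def walk(v, acc):
        if v == s:
            paths.append([s] + acc)
            return
        for u in adj[v]:
            if dist.get(u, -1) == dist[v] - 1:
                walk(u, [v] + acc)

    walk(t, [])
    return paths


def fragmentation_components(adj: dict) -> float:
    seen, sizes = set(), []
    for start in adj:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adj[u])
        seen |= comp
        sizes.append(len(comp))
    n = sum(sizes)
    if n < 2:
        return 0.0
    return 1.0 - sum(s * (s - 1) for s in sizes) / (n * (n - 1))


# --- phylogenetic statistics ----------------------------------------------


def mntd_naive(present, dist_lookup) -> float:
    vals = []
    for a in present:
        vals.append(min(dist_lookup[a, b] for b in present if b != a))
    return float(np.mean(vals))


# --- ANOVA -----------------------------------------------------------------


def anova_ss_cell_means(y, a, b):
    """Type-I SS of a balanced two-way crossed design via cell means."""
    y = np.asarray(y, dtype=float)
    a = np.asarray(a)
    b = np.asarray(b)
    grand = y.mean()
    levels_a = sorted(set(a.tolist()))
    levels_b = sorted(set(b.tolist()))
    n_per_cell = len(y) / (len(levels_a) * len(levels_b))
    ss_a = sum(
        (y[a == la].mean() - grand) ** 2 * (y[a == la]).size for la in levels_a
    )
    ss_b = sum(
        (y[b == lb].mean() - grand) ** 2 * (y[b == lb]).size for lb in levels_b
    )
    ss_cells = 0.0
    for la in levels_a:
        for lb in levels_b:
            cell = y[(a == la) & (b == lb)]
            ss_cells += cell.size * (cell.mean() - grand) ** 2
    ss_ab = ss_cells - ss_a - ss_b
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_cells
    assert n_per_cell == int(n_per_cell), "oracle requires a balanced design"
    return {
        "A": float(ss_a),
        "B": float(ss_b),
        "AB": float(ss_ab),
        "error": float(ss_err),
        "total": float(ss_total),
    }
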