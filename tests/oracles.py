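"""Independent brute-force reference implementations used only by tests.

Everything here is O(N^2) and written with plain loops/dicts so it shares
no code path with the package implementations it checks.
"""

from collections import Counter

import numpy as np


def pairwise_dist(coords):
    coords = np.asarray(coords, dtype=float)
    return np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))


def knn_window_bruteforce(coords, k, include_self=True):
    """k-cell windows, ties by (distance, index)."""
    d = pairwise_dist(coords)
    n = len(d)
    out = []
    for i in range(n):
        order = sorted(j for j in range(n) if j != i)
        order.sort(key=lambda j: (d[i, j], j))
        if include_self:
            out.append([i] + order[:k - 1])
        else:
            out.append(order[:k])
    return np.array(out)


def window_fractions_bruteforce(coords, labels, k, include_self=True):
    """Per-cell label fraction dicts for the k-cell window."""
    win = knn_window_bruteforce(coords, k, include_self)
    rows = []
    for members in win:
        c = Counter(labels[j] for j in members)
        rows.append({l: c[l] / k for l in c})
    return rows


def clq_bruteforce(coords, types, k):
    """Ordered-pair CLQ dict keyed by (a, b)."""
    d = pairwise_dist(coords)
    n = len(types)
    cats = sorted(set(types))
    counts = {t: sum(1 for x in types if x == t) for t in cats}
    c_sum = {(a, b): 0.0 for a in cats for b in cats}
    for i in range(n):
        order = sorted((j for j in range(n) if j != i), key=lambda j: (d[i, j], j))
        nb = order[:k]
        for b in cats:
            c_sum[(types[i], b)] += sum(1 for j in nb if types[j] == b) / k
    out = {}
    for a in cats:
        for b in cats:
            n_b = counts[b] - 1 if a == b else counts[b]
            denom = n_b / (n - 1)
            if denom <= 0 or counts[a] == 0:
                out[(a, b)] = float("nan")
            else:
                out[(a, b)] = (c_sum[(a, b)] / counts[a]) / denom
    return out


def context_bruteforce(coords, labels, k, threshold, include_self=True):
    """Counter of minimal >=threshold combinations (sorted label tuples)."""
    win = knn_window_bruteforce(coords, k, include_self)
    combos = []
    for members in win:
        c = Counter(labels[j] for j in members)
        ranked = sorted(c.items(), key=lambda kv: (-kv[1], kv[0]))
        total, chosen = 0, []
        for lab, cnt in ranked:
            chosen.append(lab)
            total += cnt
            if total / k >= threshold - 1e-9:
                break
        combos.append(tuple(sorted(chosen)))
    return Counter(combos)


def containment_edges_bruteforce(combos):
    """All (S, T) with S subset of T and |T| = |S| + 1."""
    edges = set()
    for s in combos:
        for t in combos:
            if len(t) == len(s) + 1 and set(s) <= set(t):
                edges.add((s, t))
    return edges


def instances_bruteforce(edges, labels, n_cells, min_cells=3):
    """Same-label components over an explicit cell edge list, plus the
    instance adjacency, via union-find written here."""
    parent = list(range(n_cells))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for u, v in edges:
        if labels[u] == labels[v]:
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[max(ru, rv)] = min(ru, rv)
    comp = {}
    for i in range(n_cells):
        comp.setdefault(find(i), []).append(i)
    kept = {root: cells for root, cells in comp.items() if len(cells) >= min_cells}
    roots = sorted(kept)
    inst_of = {}
    for j, root in enumerate(roots):
        for c in kept[root]:
            inst_of[c] = j
    inst_edges = set()
    for u, v in edges:
        iu, iv = inst_of.get(u), inst_of.get(v)
        if iu is not None and iv is not None and iu != iv:
            inst_edges.add((min(iu, iv), max(iu, iv)))
    inst = [(labels[kept[root][0]], len(kept[root])) for root in roots]
    return inst, inst_edges


def enrichment_bruteforce(upper, lower):
    """dict (u, c) -> fold enrichment via plain tallies."""
    n = len(upper)
    overall = Counter(lower)
    by_u = {}
    for u, c in zip(upper, lower):
        by_u.setdefault(u, Counter())[c] += 1
    out = {}
    for u, cnt in by_u.items():
        n_u = sum(cnt.values())
        for c in overall:
            frac_in = cnt[c] / n_u
            frac_all = overall[c] / n
            out[(u, c)] = frac_in / frac_all
    return out
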