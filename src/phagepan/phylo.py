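"""Distance phylogenetics: p-distances, neighbor joining, patristic
distances, substitution-saturation assessment and DNA-packaging inference
from a tree with strategy-labeled reference leaves."""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._tree import Node, parent_map

PACKAGING_STRATEGIES = (
    "headful", "cos_5prime", "cos_3prime", "short_DTR", "long_DTR", "unknown",
)


def p_distance(a: str, b: str) -> float:
    """Uncorrected distance between two rows of an alignment; columns
    gapped in either row are skipped."""
    if len(a) != len(b):
        raise ValueError("aligned rows must have equal length")
    mism = comp = 0
    for x, y in zip(a.upper(), b.upper()):
        if x == "-" or y == "-":
            continue
        comp += 1
        if x != y:
            mism += 1
    if comp == 0:
        raise ValueError("no comparable columns")
    return mism / comp


def p_distance_matrix(alignment: Mapping[str, str]) -> pd.DataFrame:
    ids = list(alignment)
    D = np.zeros((len(ids), len(ids)))
    for i, j in combinations(range(len(ids)), 2):
        D[i, j] = D[j, i] = p_distance(alignment[ids[i]], alignment[ids[j]])
    return pd.DataFrame(D, index=ids, columns=ids)


def nj_tree(dist: pd.DataFrame) -> Node:
    """Canonical neighbor joining.

    Negative branch-length estimates are clamped to zero with the deficit
    moved to the sister branch. Returns a tree with a trifurcating root
    (arbitrary rooting of the unrooted topology).
    """
    ids = list(dist.index)
    if len(ids) < 3:
        raise ValueError("need at least three taxa")
    D = dist.to_numpy(dtype=float).copy()
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if (D < 0).any() or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric and non-negative")
    nodes: list[Node] = [Node(name=i) for i in ids]
    active = list(range(len(ids)))
    while len(active) > 3:
        n = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(Q), Q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        ai, aj = active[i_], active[j_]
        dij = sub[i_, j_]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2 * (n - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        nodes[ai].length = li
        nodes[aj].length = lj
        new = Node(children=[nodes[ai], nodes[aj]])
        # distances from the new node to remaining taxa
        newrow = np.zeros(D.shape[0] + 1)
        for k in active:
            if k in (ai, aj):
                continue
            newrow[k] = 0.5 * (D[ai, k] + D[aj, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(newrow) - 1] = newrow[:-1]
        D[: len(newrow) - 1, -1] = newrow[:-1]
        nodes.append(new)
        active = [k for k in active if k not in (ai, aj)] + [len(nodes) - 1]
    # join the last three nodes at a trifurcating root
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for k, lk in ((a, la), (b, lb), (c, lc)):
        nodes[k].length = max(lk, 0.0)
    return Node(children=[nodes[a], nodes[b], nodes[c]])


def patristic(tree: Node, a: str, b: str) -> float:
    """Sum of branch lengths along the path between two leaves."""
    if a == b:
        if tree.find_leaf(a) is None:
            raise KeyError(a)
        return 0.0
    parents = parent_map(tree)
    na, nb = tree.find_leaf(a), tree.find_leaf(b)
    if na is None or nb is None:
        raise KeyError(f"leaf not found: {a if na is None else b}")

    def path_up(n):
        out = [n]
        while id(n) in parents:
            n = parents[id(n)]
            out.append(n)
        return out

    pa, pb = path_up(na), path_up(nb)
    ancestors_a = {id(n): k for k, n in enumerate(pa)}
    for n in pb:
        if id(n) in ancestors_a:
            lca = n
            break
    dist = 0.0
    for n in pa:
        if n is lca:
            break
        dist += n.length
    for n in pb:
        if n is lca:
            break
        dist += n.length
    return dist


def patristic_matrix(tree: Node) -> pd.DataFrame:
    ids = sorted(tree.leaves())
    D = np.zeros((len(ids), len(ids)))
    for i, j in combinations(range(len(ids)), 2):
        D[i, j] = D[j, i] = patristic(tree, ids[i], ids[j])
    return pd.DataFrame(D, index=ids, columns=ids)


def saturation_test(
    p_distances: Sequence[float],
    patristic_distances: Sequence[float],
    r2_threshold: float = 0.90,
    alpha: float = 0.05,
) -> tuple[float, float, bool]:
    """Regress p-distance on patristic distance and flag saturation.

    Saturation is declared when the linear fit is poor (R^2 below the
    threshold) or a quadratic term is significantly negative (one-sided
    t-test), i.e. the relationship bends toward a plateau.
    Returns (slope, R^2, saturated).
    """
    p = np.asarray(p_distances, dtype=float)
    d = np.asarray(patristic_distances, dtype=float)
    if p.shape != d.shape or p.ndim != 1:
        raise ValueError("paired vectors required")
    if len(p) < 5:
        raise ValueError("need at least five pairs")
    if np.ptp(d) == 0 or np.ptp(p) == 0:
        raise ValueError("zero-variance input")
    slope, intercept = np.polyfit(d, p, 1)
    resid = p - (slope * d + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((p - p.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot

    X = np.column_stack([np.ones_like(d), d, d**2])
    beta, _, rank, _ = np.linalg.lstsq(X, p, rcond=None)
    quad_sig_neg = False
    dof = len(p) - 3
    if rank == 3 and dof > 0:
        resid2 = p - X @ beta
        sigma2 = float(resid2 @ resid2) / dof
        if sigma2 == 0:
            quad_sig_neg = beta[2] < 0
        else:
            cov = sigma2 * np.linalg.inv(X.T @ X)
            t = beta[2] / np.sqrt(cov[2, 2])
            quad_sig_neg = bool(t < stats.t.ppf(alpha, dof))
    saturated = (r2 < r2_threshold) or quad_sig_neg
    return float(slope), float(r2), saturated


def infer_packaging(
    tree: Node,
    labels: Mapping[str, str],
    queries: Sequence[str],
    max_steps: int = 3,
    radius_factor: float = 1.5,
) -> dict[str, tuple[str, float]]:
    """Assign packaging strategies to query leaves from labeled references.

    Works on the unrooted topology (rooting-invariant). References
    reachable within ``max_steps`` internal nodes of the query are
    eligible; with none, the query is labeled ``unknown`` rather than
    guessed. Among eligible references the query's neighborhood is the
    nearest one in patristic distance plus everything within
    ``radius_factor`` times that distance; the majority label wins, ties
    broken by the nearest labeled leaf. Returns query -> (strategy,
    confidence) where confidence is the majority-label fraction in the
    neighborhood.
    """
    if not labels:
        raise ValueError("no labeled references")
    for lab in labels.values():
        if lab not in PACKAGING_STRATEGIES:
            raise ValueError(f"unknown packaging strategy {lab!r}")
    # unrooted adjacency over all nodes
    adj: dict[int, list[Node]] = {}
    by_id: dict[int, Node] = {}
    for node in tree.walk():
        by_id[id(node)] = node
        adj.setdefault(id(node), [])
        for c in node.children:
            adj[id(node)].append(c)
            adj.setdefault(id(c), []).append(node)

    out: dict[str, tuple[str, float]] = {}
    for q in queries:
        leaf = tree.find_leaf(q)
        if leaf is None:
            raise KeyError(q)
        # BFS depth = number of internal nodes crossed on the path
        depth: dict[int, int] = {id(leaf): 0}
        frontier = [leaf]
        ref_depth: dict[str, int] = {}
        while frontier:
            nxt = []
            for node in frontier:
                for nb in adj[id(node)]:
                    if id(nb) in depth:
                        continue
                    d = depth[id(node)] + (0 if nb.is_leaf else 1)
                    depth[id(nb)] = d
                    if nb.is_leaf and nb.name in labels and nb.name != q:
                        ref_depth[nb.name] = d
                    nxt.append(nb)
            frontier = nxt
        eligible = sorted(r for r, d in ref_depth.items() if d <= max_steps)
        if not eligible:
            out[q] = ("unknown", 0.0)
            continue
        dist = {r: patristic(tree, q, r) for r in eligible}
        dmin = min(dist.values())
        refs_here = sorted(r for r in eligible if dist[r] <= dmin * radius_factor + 1e-12)
        tally: dict[str, int] = {}
        for ref in refs_here:
            tally[labels[ref]] = tally.get(labels[ref], 0) + 1
        top = max(tally.values())
        winners = sorted(s for s, v in tally.items() if v == top)
        if len(winners) == 1:
            strategy = winners[0]
        else:
            cand = [r for r in refs_here if labels[r] in winners]
            cand.sort(key=lambda r: (dist[r], r))
            strategy = labels[cand[0]]
        out[q] = (strategy, top / len(refs_here))
    return out
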