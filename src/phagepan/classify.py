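"""Genome classification from the pan-genome matrix: binary (Jaccard)
distances, deterministic agglomerative clustering, multiscale-bootstrap
AU supports and threshold-based group cutting.

The AU support follows the multiscale-bootstrap recipe: bootstrap the
matrix columns at several resampling scales r, record per-clade recovery
frequencies BP_r, map them through the probit, fit
``z_r = d*sqrt(r) + c/sqrt(r)`` by weighted least squares and report
``AU = 1 - Phi(d - c)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._tree import Node

DEFAULT_SCALES = tuple(round(0.5 + 0.1 * k, 1) for k in range(10))  # 0.5 .. 1.4


def binary_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Jaccard-style binary distance d = (b+c)/(a+b+c) between genome rows.

    a counts clusters present in both genomes, b and c those present in
    exactly one; joint absences are ignored. A pair with a+b+c = 0 gets
    distance 0 (nothing to compare).
    """
    if len(matrix.index) < 2:
        raise ValueError("need at least two genomes")
    X = matrix.to_numpy(dtype=float)
    return pd.DataFrame(
        _binary_distance_array(X), index=matrix.index, columns=matrix.index
    )


def _binary_distance_array(X: np.ndarray) -> np.ndarray:
    a = X @ X.T
    rows = X.sum(axis=1)
    denom = rows[:, None] + rows[None, :] - a
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (denom - a) / denom
    d[denom == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    return d


def hclust(dist: pd.DataFrame, linkage: str = "average") -> Node:
    """Agglomerative clustering with deterministic tie-breaking.

    Among equally close pairs the pair whose (lexicographically smallest
    member, partner's smallest member) sorts first is merged. Supported
    linkages: average (UPGMA), complete, single.
    """
    ids = list(dist.index)
    root = _hclust_nodes(dist.to_numpy(dtype=float), ids, linkage)
    return root


def _hclust_nodes(D: np.ndarray, ids: list[str], linkage: str) -> Node:
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unknown linkage {linkage!r}")
    n = len(ids)
    active = {i: Node(name=ids[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    keys = {i: ids[i] for i in range(n)}  # lexicographically smallest member
    D = D.copy()
    nxt = n
    while len(active) > 1:
        items = sorted(active)
        best = None
        for ii, i in enumerate(items):
            for j in items[ii + 1 :]:
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (D[i, j], pair_key)
                if best is None or cand < best[0:2]:
                    best = (D[i, j], pair_key, i, j)
        d, _, i, j = best
        left, right = sorted((i, j), key=lambda k: keys[k])
        node = Node(children=[active[left], active[right]], height=d)
        # grow the distance matrix with the merged cluster's row
        if nxt >= D.shape[0]:
            D = np.pad(D, ((0, n), (0, n)), constant_values=0.0)
        for k in active:
            if k in (i, j):
                continue
            if linkage == "average":
                val = (sizes[i] * D[i, k] + sizes[j] * D[j, k]) / (sizes[i] + sizes[j])
            elif linkage == "complete":
                val = max(D[i, k], D[j, k])
            else:
                val = min(D[i, k], D[j, k])
            D[nxt, k] = D[k, nxt] = val
        sizes[nxt] = sizes[i] + sizes[j]
        keys[nxt] = min(keys[i], keys[j])
        active[nxt] = node
        del active[i], active[j], sizes[i], sizes[j], keys[i], keys[j]
        nxt += 1
    root = next(iter(active.values()))
    _set_lengths_from_heights(root)
    return root


def _set_lengths_from_heights(root: Node) -> None:
    for node in root.walk():
        for c in node.children:
            c.length = max(node.height - c.height, 0.0)


@dataclass
class ClusterTree:
    root: Node
    scales: tuple[float, ...]
    n_boot: int
    bp_table: dict[frozenset[str], np.ndarray] = field(default_factory=dict)
    degenerate_fit: set[frozenset[str]] = field(default_factory=set)

    def supports(self) -> dict[frozenset[str], tuple[float, float]]:
        return {
            n.leaf_set(): (n.au, n.bp)
            for n in self.root.walk()
            if not n.is_leaf and n.au is not None
        }

    def newick(self) -> str:
        return self.root.newick(
            comment=lambda n: f"au={n.au:.3f},bp={n.bp:.3f}" if n.au is not None else ""
        )


def multiscale_bootstrap(
    matrix: pd.DataFrame,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    n_boot: int = 1000,
    linkage: str = "average",
    seed: int = 0,
) -> ClusterTree:
    """Cluster genomes and attach AU/BP supports to every internal edge."""
    if n_boot < 100:
        import warnings

        warnings.warn("n_boot < 100 gives unstable AU estimates")
    rng = np.random.default_rng(seed)
    ids = list(matrix.index)
    X = matrix.to_numpy(dtype=float)
    n_cols = X.shape[1]

    observed = hclust(binary_distance(matrix), linkage=linkage)
    clades = sorted(observed.clades(), key=lambda s: (len(s), sorted(s)))
    clade_idx = {c: k for k, c in enumerate(clades)}

    counts = np.zeros((len(scales), len(clades)))
    for si, r in enumerate(scales):
        m = max(1, math.ceil(r * n_cols))
        for _ in range(n_boot):
            cols = rng.integers(0, n_cols, size=m)
            Db = _binary_distance_array(X[:, cols])
            tree = _hclust_nodes(Db, ids, linkage)
            for c in tree.clades():
                k = clade_idx.get(c)
                if k is not None:
                    counts[si, k] += 1
    bp = counts / n_boot

    result = ClusterTree(root=observed, scales=tuple(scales), n_boot=n_boot)
    scale_one = int(np.argmin(np.abs(np.array(scales) - 1.0)))
    for node in observed.walk():
        if node.is_leaf:
            continue
        cl = node.leaf_set()
        if cl not in clade_idx:  # root: trivially present in every replicate
            node.au, node.bp = 1.0, 1.0
            continue
        bps = bp[:, clade_idx[cl]]
        result.bp_table[cl] = bps
        node.bp = float(bps[scale_one])
        node.au = _fit_au(bps, np.asarray(scales, dtype=float), n_boot, result, cl)
    return result


def _fit_au(bps: np.ndarray, scales: np.ndarray, n_boot: int,
            result: ClusterTree, clade: frozenset[str]) -> float:
    if np.all(bps == 1.0):
        return 1.0
    if np.all(bps == 0.0):
        return 0.0
    # scales at the bootstrap's resolution floor (within a few counts of 0
    # or n_boot) carry no probit information: a constant near-extreme z has
    # no scale trend and the d/c split becomes arbitrary, wrecking AU for
    # edges recovered in ~every replicate. With fewer than two informative
    # scales the fit is degenerate and AU falls back to BP near scale 1.
    eps = 3.0 / n_boot
    interior = (bps >= eps) & (bps <= 1.0 - eps)
    if interior.sum() < 2:
        result.degenerate_fit.add(clade)
        return float(bps[np.argmin(np.abs(scales - 1.0))])
    bp_c = bps[interior]
    r = scales[interior]
    z = norm.ppf(1.0 - bp_c)
    sq = np.sqrt(r)
    design = np.column_stack([sq, 1.0 / sq])
    # binomial-delta-method weights, as in the multiscale bootstrap
    w = n_boot * norm.pdf(z) ** 2 / (bp_c * (1.0 - bp_c))
    W = np.sqrt(w)
    try:
        coef, *_ = np.linalg.lstsq(design * W[:, None], z * W, rcond=None)
    except np.linalg.LinAlgError:
        result.degenerate_fit.add(clade)
        return float(bps[np.argmin(np.abs(scales - 1.0))])
    d, c = coef
    return float(1.0 - norm.cdf(d - c))


_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
          "XI", "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX"]


def cut_groups(
    tree: ClusterTree, au_threshold: float = 0.95
) -> tuple[dict[str, str], dict[str, str]]:
    """Partition genomes into maximal AU-supported subtrees.

    A subtree whose subtending edge has AU >= threshold becomes a group
    when its parent's edge does not (top-down descent yields exactly the
    maximal such subtrees); leaves are trivially supported, so a tree
    with no supported edge decays into singletons. The root has no
    subtending edge and forms a single group only when every one of its
    direct child edges is supported. Groups are labeled I, II, ... in
    left-to-right leaf order. The second mapping carries sub-labels
    (A/B) for groups whose top split separates two supported internal
    subtrees.
    """
    if not (0 < au_threshold < 1):
        raise ValueError("au_threshold must be in (0, 1)")

    def _supported(node: Node) -> bool:
        if node.is_leaf:
            return True
        return node.au is not None and node.au >= au_threshold

    group_roots: list[Node] = []

    def _collect(node: Node, is_root: bool = False) -> None:
        ok = all(_supported(c) for c in node.children) if is_root else _supported(node)
        if ok:
            group_roots.append(node)
            return
        for c in node.children:
            _collect(c)

    _collect(tree.root, is_root=True)

    labels: dict[str, str] = {}
    sublabels: dict[str, str] = {}
    for k, node in enumerate(group_roots):
        name = _ROMAN[k] if k < len(_ROMAN) else f"G{k + 1}"
        for leaf in node.leaves():
            labels[leaf] = name
        if len(node.children) == 2 and all(
            not c.is_leaf
            and len(c.leaf_set()) >= 2
            and c.au is not None
            and c.au >= au_threshold
            for c in node.children
        ):
            for sub, c in zip("AB", node.children):
                for leaf in c.leaves():
                    sublabels[leaf] = f"{name}-{sub}"
    return labels, sublabels
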