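"""Pan-genome presence/absence matrix, core genomes, shared-core Venn
regions and functional-category tallies."""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .homology import GeneClusterSet

FUNCTIONAL_CATEGORIES = ("A", "B", "C", "D", "E", "F", "L")


def build_matrix(clusters: GeneClusterSet, genomes: Sequence[str]) -> pd.DataFrame:
    """Binary genomes x clusters matrix; cell = 1 iff the cluster has a
    member from that genome. Clusters with no member in ``genomes`` are
    dropped so no all-zero column exists."""
    cols = {}
    for cid in sorted(clusters.clusters):
        present = {g for g, _ in clusters.clusters[cid]}
        col = [1 if g in present else 0 for g in genomes]
        if any(col):
            cols[cid] = col
    return pd.DataFrame(cols, index=list(genomes), dtype=np.int8)


def core_genome(matrix: pd.DataFrame, subset: Iterable[str]) -> set[str]:
    """Clusters present in every genome of ``subset``."""
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    unknown = [g for g in subset if g not in matrix.index]
    if unknown:
        raise KeyError(f"unknown genome ids: {unknown}")
    sub = matrix.loc[subset]
    return set(sub.columns[(sub == 1).all(axis=0)])


def shared_core_venn(
    matrix: pd.DataFrame, groups: Mapping[str, Sequence[str]]
) -> dict[frozenset[str], int]:
    """Exclusive Venn region counts over group core-genomes.

    Region keyed by the subset of groups whose cores contain the cluster;
    counts clusters in every listed group's core and in no other group's
    core. Empty regions are reported as 0.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    cores = {name: core_genome(matrix, ids) for name, ids in groups.items()}
    names = sorted(cores)
    regions: dict[frozenset[str], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(cores[n] for n in combo))
            for other in names:
                if other not in combo:
                    inside -= cores[other]
            regions[frozenset(combo)] = len(inside)
    return regions


def categorize_core(
    cluster_ids: Iterable[str], category_map: Mapping[str, str]
) -> pd.DataFrame:
    """Histogram of functional categories (A-F, L); unassigned -> L."""
    ids = list(cluster_ids)
    counts = {c: 0 for c in FUNCTIONAL_CATEGORIES}
    for cid in ids:
        cat = category_map.get(cid, "L")
        if cat not in counts:
            raise ValueError(f"unknown functional category {cat!r} for {cid}")
        counts[cat] += 1
    total = len(ids)
    rows = [
        {"category": c, "count": n, "fraction": (n / total if total else 0.0)}
        for c, n in counts.items()
        if total > 0
    ]
    return pd.DataFrame(rows, columns=["category", "count", "fraction"])


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="genome_id")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="genome_id")
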