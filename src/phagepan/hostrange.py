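"""Host-range (spot test) analysis: matrix encoding, breadth and lysotype
groups, clustering for heatmaps, covering phage pairs and the
psychrophilic/mesophilic sensitivity split."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .classify import binary_distance, hclust

MAX_EXPONENT = 7
HIGH_ACTIVITY_SCORE = 5  # lysis at >= 1e-4 dilution

# lysotype breadth thresholds on a 65-isolate panel, scaled proportionally
NARROW_MAX = 5      # breadth < 5/65 -> narrow
INTER_LO = 10       # 10/65 .. 30/65 -> intermediate
INTER_HI = 30
BROAD_MIN = 44      # breadth > 44/65 -> broad


class HostRangeError(ValueError):
    pass


@dataclass
class HostRangeMatrix:
    scores: pd.DataFrame           # phages x isolates, ints 0..8
    isolate_meta: pd.DataFrame     # index = isolate ids; subspecies, lifestyle

    def __post_init__(self):
        s = self.scores.to_numpy()
        if ((s < 0) | (s > MAX_EXPONENT + 1)).any():
            raise HostRangeError("scores must lie in 0..8")
        missing = set(self.scores.columns) - set(self.isolate_meta.index)
        if missing:
            raise HostRangeError(f"isolates without metadata: {sorted(missing)}")

    @property
    def phages(self) -> list[str]:
        return list(self.scores.index)

    @property
    def isolates(self) -> list[str]:
        return list(self.scores.columns)

    def sensitivity(self) -> pd.DataFrame:
        return (self.scores > 0).astype(int)

    def activity_class(self) -> pd.DataFrame:
        out = pd.DataFrame("none", index=self.scores.index, columns=self.scores.columns)
        out[self.scores > 0] = "low"
        out[self.scores >= HIGH_ACTIVITY_SCORE] = "high"
        return out


def encode_matrix(raw: pd.DataFrame, isolate_meta: pd.DataFrame) -> HostRangeMatrix:
    """Encode highest-lytic-dilution exponents as ordinal scores.

    Raw cells hold 'none' (no lysis) or an exponent 0..7 meaning lysis at
    dilution 10^-exponent; the score is exponent + 1 so 0 always means
    insensitive.
    """
    def enc(v):
        if isinstance(v, str) and v.strip().lower() == "none":
            return 0
        x = int(v)
        if not (0 <= x <= MAX_EXPONENT):
            raise HostRangeError(f"exponent {x} outside 0..{MAX_EXPONENT}")
        return x + 1

    scores = raw.map(enc).astype(int)
    return HostRangeMatrix(scores=scores, isolate_meta=isolate_meta)


def decode_matrix(matrix: HostRangeMatrix) -> pd.DataFrame:
    """Inverse of :func:`encode_matrix` (scores back to raw exponents)."""
    return matrix.scores.map(lambda s: "none" if s == 0 else str(s - 1))


def breadth(matrix: HostRangeMatrix, phage: str) -> int:
    if phage not in matrix.scores.index:
        raise HostRangeError(f"unknown phage {phage!r}")
    return int((matrix.scores.loc[phage] > 0).sum())


def assign_lysotype_group(b: int, n_isolates: int) -> str:
    """Map a breadth to narrow/intermediate/broad using thresholds scaled
    from the 65-isolate reference panel; values in the gaps between the
    published bands are left unclassified."""
    if not (0 <= b <= n_isolates):
        raise HostRangeError("breadth outside 0..n_isolates")
    frac = b / n_isolates
    if frac < NARROW_MAX / 65:
        return "narrow"
    if INTER_LO / 65 <= frac <= INTER_HI / 65:
        return "intermediate"
    if frac > BROAD_MIN / 65:
        return "broad"
    return "unclassified"


def lysotype_groups(matrix: HostRangeMatrix) -> dict[str, str]:
    n = len(matrix.isolates)
    return {p: assign_lysotype_group(breadth(matrix, p), n) for p in matrix.phages}


def cluster_heatmap(matrix: HostRangeMatrix, linkage: str = "average"):
    """Cluster both axes on binary sensitivity; returns (phage tree,
    isolate tree, matrix reordered to leaf order)."""
    if len(matrix.phages) < 2 or len(matrix.isolates) < 2:
        raise HostRangeError("need at least two phages and two isolates")
    sens = matrix.sensitivity()
    ptree = hclust(binary_distance(sens), linkage=linkage)
    itree = hclust(binary_distance(sens.T), linkage=linkage)
    ordered = matrix.scores.loc[ptree.leaves(), itree.leaves()]
    return ptree, itree, ordered


def covering_pairs(
    matrix: HostRangeMatrix, targets: Sequence[str]
) -> list[tuple[str, str, int]]:
    """Phage pairs whose combined sensitivity covers every target isolate,
    ranked by summed breadth (descending), ties alphabetical."""
    targets = list(targets)
    if not targets:
        raise HostRangeError("target subset must be non-empty")
    sens = matrix.sensitivity()[targets]
    out = []
    for p, q in combinations(sorted(matrix.phages), 2):
        if ((sens.loc[p] > 0) | (sens.loc[q] > 0)).all():
            out.append((p, q, breadth(matrix, p) + breadth(matrix, q)))
    out.sort(key=lambda t: (-t[2], t[0], t[1]))
    return out


def lifestyle_split(matrix: HostRangeMatrix):
    """Sensitivity summary per lifestyle with a Fisher exact test.

    Collapses to a 2x2 table of lifestyle x (sensitive to >= 1 phage)
    over isolates, and lists every mesophilic sensitive (phage, isolate)
    cell as an explicit exception. Returns a dict report.
    """
    meta = matrix.isolate_meta
    lifestyles = meta["lifestyle"]
    if set(lifestyles.unique()) < {"psychrophilic", "mesophilic"}:
        raise HostRangeError("both lifestyles must be present")
    sens = matrix.sensitivity()
    report: dict = {"per_lifestyle": {}, "exceptions": []}
    for ls, isolates in meta.groupby("lifestyle").groups.items():
        block = sens[list(isolates)]
        report["per_lifestyle"][ls] = {
            "n_isolates": len(isolates),
            "fraction_sensitive_cells": float(block.to_numpy().mean()),
        }
    any_sens = sens.sum(axis=0) > 0
    table = np.zeros((2, 2), dtype=int)
    for j, ls in enumerate(("psychrophilic", "mesophilic")):
        ids = lifestyles[lifestyles == ls].index
        table[j, 0] = int(any_sens[ids].sum())
        table[j, 1] = int((~any_sens[ids]).sum())
    _, p = fisher_exact(table, alternative="two-sided")
    report["fisher_table"] = table.tolist()
    report["fisher_p"] = float(p)
    meso = lifestyles[lifestyles == "mesophilic"].index
    for iso in meso:
        for phage in matrix.phages:
            if sens.loc[phage, iso]:
                report["exceptions"].append({"phage": phage, "isolate": iso})
    return report


def read_hostrange_tsv(scores_path, meta_path) -> HostRangeMatrix:
    raw = pd.read_csv(scores_path, sep="\t", index_col=0, dtype=str)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return encode_matrix(raw, meta)
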