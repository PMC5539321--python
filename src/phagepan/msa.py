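"""Internal progressive protein aligner.

Pairwise global alignments (the same BLOSUM62/affine engine used for
homology search) give guide distances; a UPGMA guide tree orders
profile-profile merges scored by mean column substitution score with a
linear gap penalty. Adequate for the low-divergence intra-cluster
alignments this pipeline produces; not a general-purpose MSA tool.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from . import homology
from .classify import hclust

_ALPHABET = "ARNDCQEGHILKMFPSTWYVX-"
_AA_INDEX = {a: i for i, a in enumerate(_ALPHABET)}


def _column_score_matrix(gap_pair_score: float = 0.0) -> np.ndarray:
    blosum = substitution_matrices.load("BLOSUM62")
    S = np.zeros((len(_ALPHABET), len(_ALPHABET)))
    for i, a in enumerate(_ALPHABET):
        for j, b in enumerate(_ALPHABET):
            if a == "-" or b == "-":
                S[i, j] = gap_pair_score
            elif a == "X" or b == "X":
                S[i, j] = 0.0
            else:
                S[i, j] = blosum[a, b]
    return S


_COLSCORE = _column_score_matrix()


def _encode_profile(rows: list[str]) -> np.ndarray:
    L = len(rows[0])
    counts = np.zeros((L, len(_ALPHABET)))
    for row in rows:
        for j, ch in enumerate(row):
            counts[j, _AA_INDEX.get(ch, _AA_INDEX["X"])] += 1
    return counts / len(rows)


def _align_profiles(p1: list[str], p2: list[str], gap: float = -8.0) -> tuple[list[str], list[str]]:
    """Global profile-profile alignment with linear gaps (vectorized NW)."""
    C1, C2 = _encode_profile(p1), _encode_profile(p2)
    M = C1 @ _COLSCORE @ C2.T
    L1, L2 = M.shape
    H = np.empty((L1 + 1, L2 + 1))
    H[0, :] = gap * np.arange(L2 + 1)
    H[:, 0] = gap * np.arange(L1 + 1)
    for i in range(1, L1 + 1):
        cand = np.maximum(H[i - 1, :-1] + M[i - 1], H[i - 1, 1:] + gap)
        # left-gap recurrence via running max of cand[j] - gap*j
        t = np.maximum.accumulate(
            np.concatenate(([H[i, 0]], cand - gap * np.arange(1, L2 + 1)))
        )
        H[i, 1:] = t[1:] + gap * np.arange(1, L2 + 1)
        H[i, 1:] = np.maximum(H[i, 1:], cand)
    # traceback
    i, j = L1, L2
    a1: list[int] = []
    a2: list[int] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0 and np.isclose(H[i, j], H[i - 1, j - 1] + M[i - 1, j - 1]):
            a1.append(i - 1)
            a2.append(j - 1)
            i, j = i - 1, j - 1
        elif i > 0 and np.isclose(H[i, j], H[i - 1, j] + gap):
            a1.append(i - 1)
            a2.append(-1)
            i -= 1
        else:
            a1.append(-1)
            a2.append(j - 1)
            j -= 1
    a1.reverse()
    a2.reverse()
    out1 = ["".join(row[k] if k >= 0 else "-" for k in a1) for row in p1]
    out2 = ["".join(row[k] if k >= 0 else "-" for k in a2) for row in p2]
    return out1, out2


def pairwise_p_distance(a: str, b: str) -> float:
    """p-distance from a global pairwise alignment of two proteins."""
    aligner = homology._make_aligner("global")
    aln = aligner.align(a.upper(), b.upper())[0]
    counts = aln.counts()
    comp = counts.identities + counts.mismatches
    return counts.mismatches / comp if comp else 1.0


def progressive_align(seqs: Mapping[str, str]) -> dict[str, str]:
    """Multiple protein alignment; returns gapped rows keyed like input."""
    ids = list(seqs)
    if len(ids) == 1:
        return dict(seqs)
    if len(ids) == 2:
        p1, p2 = _align_profiles([seqs[ids[0]]], [seqs[ids[1]]])
        return {ids[0]: p1[0], ids[1]: p2[0]}
    D = np.zeros((len(ids), len(ids)))
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            D[i, j] = D[j, i] = pairwise_p_distance(seqs[ids[i]], seqs[ids[j]])
    guide = hclust(pd.DataFrame(D, index=ids, columns=ids), linkage="average")

    def _merge(node) -> dict[str, str]:
        if node.is_leaf:
            return {node.name: seqs[node.name]}
        left = _merge(node.children[0])
        right = _merge(node.children[1])
        lids, rids = list(left), list(right)
        a1, a2 = _align_profiles([left[k] for k in lids], [right[k] for k in rids])
        out = {k: row for k, row in zip(lids, a1)}
        out.update({k: row for k, row in zip(rids, a2)})
        return out

    return _merge(guide)
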