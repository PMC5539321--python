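"""Protein homology: pairwise local alignment, all-vs-all search, BBH graph,
COG-triangle and Markov clustering, clustering intersection, identity matrix
and reference-set screening.

External search binaries are replaced by exact Smith-Waterman (BLOSUM62,
affine gaps 11/1); the cohorts handled here are small enough that exact DP
is affordable. The e-value surrogate is a Karlin-Altschul style estimate
used only as a score threshold, not as a calibrated statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

# gapped BLOSUM62 (open 11, extend 1) Karlin-Altschul parameters
_KA_LAMBDA = 0.267
_KA_K = 0.041

DEFAULT_COVERAGE = 0.75
DEFAULT_EVALUE = 1e-5


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentHit:
    query: str
    subject: str
    score: float
    identity: float
    coverage_q: float
    coverage_s: float
    evalue_like: float


@dataclass
class GeneClusterSet:
    """Disjoint clusters of (genome_id, locus_id) members."""

    clusters: dict[str, frozenset[tuple[str, str]]]
    algorithm: str
    converged: bool = True

    def member_sets(self) -> set[frozenset[tuple[str, str]]]:
        return set(self.clusters.values())

    def __len__(self) -> int:
        return len(self.clusters)


def _make_aligner(mode: str = "local", open_gap: float = 11.0, extend_gap: float = 1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    mat = substitution_matrices.load("BLOSUM62")
    arr = np.array(mat)
    xi = mat.alphabet.index("X")
    arr[xi, :] = 0.0
    arr[:, xi] = 0.0
    aligner.substitution_matrix = substitution_matrices.Array(
        alphabet=mat.alphabet, dims=2, data=arr
    )
    aligner.open_gap_score = -open_gap
    aligner.extend_gap_score = -extend_gap
    return aligner


_LOCAL_ALIGNER = _make_aligner("local")


def evalue_like(score: float, m: int, n: int) -> float:
    return _KA_K * m * n * math.exp(-_KA_LAMBDA * score)


def align_pair(a: str, b: str, query_id: str = "q", subject_id: str = "s",
               search_space: int | None = None) -> AlignmentHit:
    """Smith-Waterman local alignment of two protein sequences.

    Identity is matches over alignment columns (gap columns included, as
    in BLAST); coverage is the aligned span divided by sequence length.
    ``search_space`` overrides n in the e-value surrogate (database size).
    """
    if not a or not b:
        raise AlignmentError("empty protein sequence")
    alns = _LOCAL_ALIGNER.align(a.upper(), b.upper())
    if len(alns) == 0 or alns.score <= 0:
        return AlignmentHit(query_id, subject_id, 0.0, 0.0, 0.0, 0.0, math.inf)
    aln = alns[0]
    counts = aln.counts()
    ncols = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / ncols if ncols else 0.0
    qa, sa = aln.aligned
    span_q = qa[-1][1] - qa[0][0]
    span_s = sa[-1][1] - sa[0][0]
    n = search_space if search_space is not None else len(b)
    return AlignmentHit(
        query=query_id, subject=subject_id, score=float(aln.score),
        identity=identity, coverage_q=span_q / len(a), coverage_s=span_s / len(b),
        evalue_like=evalue_like(aln.score, len(a), n),
    )


def self_scores(proteomes: Sequence) -> dict[tuple[str, str], float]:
    out = {}
    for g in proteomes:
        for locus, aa in g.proteins().items():
            out[(g.id, locus)] = align_pair(aa, aa).score
    return out


def all_vs_all(
    proteomes: Sequence,
    min_coverage: float = DEFAULT_COVERAGE,
    max_evalue: float = DEFAULT_EVALUE,
) -> list[AlignmentHit]:
    """All cross-genome protein pairs passing coverage and score thresholds.

    Hits are emitted in both directions (query->subject and back). Self
    hits are excluded; retrieve self-scores via :func:`self_scores`.
    """
    if len(proteomes) < 2:
        raise ValueError("need at least two genomes")
    seqs: list[tuple[str, str, str]] = []
    for g in proteomes:
        for locus, aa in g.proteins().items():
            seqs.append((g.id, locus, aa))
    total_res = sum(len(s[2]) for s in seqs)
    hits: list[AlignmentHit] = []
    for i in range(len(seqs)):
        gi, li, ai = seqs[i]
        for j in range(i + 1, len(seqs)):
            gj, lj, aj = seqs[j]
            if gi == gj:
                continue
            h = align_pair(ai, aj, f"{gi}:{li}", f"{gj}:{lj}", search_space=total_res)
            if (
                h.score > 0
                and h.coverage_q >= min_coverage
                and h.coverage_s >= min_coverage
                and h.evalue_like <= max_evalue
            ):
                hits.append(h)
                hits.append(
                    AlignmentHit(h.subject, h.query, h.score, h.identity,
                                 h.coverage_s, h.coverage_q, h.evalue_like)
                )
    return hits


def _genome_of(tag: str) -> str:
    return tag.split(":", 1)[0]


def bbh_graph(hits: Iterable[AlignmentHit]) -> set[frozenset[str]]:
    """Bidirectional best hits per genome pair.

    For each query, its best hit into each other genome is the one with
    the highest score, ties broken by higher identity then lexicographic
    subject id. Edge (x, y) exists iff each is the other's best.
    """
    best: dict[tuple[str, str], tuple[float, float, str]] = {}
    for h in hits:
        key = (h.query, _genome_of(h.subject))
        cand = (h.score, h.identity, h.subject)
        cur = best.get(key)
        if cur is None or (cand[0], cand[1], _neg_lex(cand[2])) > (cur[0], cur[1], _neg_lex(cur[2])):
            best[key] = cand
    edges: set[frozenset[str]] = set()
    for (query, _), (_, _, subject) in best.items():
        back = best.get((subject, _genome_of(query)))
        if back is not None and back[2] == query:
            edges.add(frozenset((query, subject)))
    return edges


class _NegLex(str):
    """Inverts lexicographic order so max() prefers the smaller id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def _neg_lex(s: str) -> _NegLex:
    return _NegLex(s)


def _as_member(tag: str) -> tuple[str, str]:
    genome, locus = tag.split(":", 1)
    return genome, locus


def cog_triangles(edges: set[frozenset[str]], all_loci: Iterable[str]) -> GeneClusterSet:
    """COG-style clustering: merge BBH triangles spanning three genomes.

    Triangles sharing an edge are merged transitively; leftover BBH pairs
    with both endpoints unclustered form 2-member clusters; everything
    else is a singleton cluster.
    """
    adj: dict[str, set[str]] = {}
    for e in edges:
        a, b = tuple(e)
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    triangles = []
    nodes = sorted(adj)
    for a in nodes:
        for b in sorted(adj[a]):
            if b <= a:
                continue
            for c in sorted(adj[a] & adj[b]):
                if c <= b:
                    continue
                if len({_genome_of(a), _genome_of(b), _genome_of(c)}) == 3:
                    triangles.append((a, b, c))

    # union-find over triangles keyed by their edges
    parent: dict[str, str] = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    edge_owner: dict[frozenset[str], str] = {}
    for idx, tri in enumerate(triangles):
        tid = f"t{idx}"
        parent.setdefault(tid, tid)
        for e in (frozenset((tri[0], tri[1])), frozenset((tri[0], tri[2])), frozenset((tri[1], tri[2]))):
            if e in edge_owner:
                union(tid, edge_owner[e])
            else:
                edge_owner[e] = tid

    groups: dict[str, set[str]] = {}
    for idx, tri in enumerate(triangles):
        groups.setdefault(find(f"t{idx}"), set()).update(tri)

    clustered: set[str] = set()
    clusters: list[frozenset[tuple[str, str]]] = []
    for members in sorted(groups.values(), key=lambda s: sorted(s)):
        clusters.append(frozenset(_as_member(m) for m in members))
        clustered |= members
    for e in sorted(edges, key=sorted):
        a, b = tuple(e)
        if a not in clustered and b not in clustered:
            clusters.append(frozenset((_as_member(a), _as_member(b))))
            clustered |= {a, b}
    for tag in sorted(set(all_loci)):
        if tag not in clustered:
            clusters.append(frozenset({_as_member(tag)}))
    return GeneClusterSet(
        clusters={f"cog{k:05d}": c for k, c in enumerate(clusters, start=1)},
        algorithm="cog",
    )


def mcl_cluster(
    hits: Iterable[AlignmentHit],
    all_loci: Iterable[str],
    inflation: float = 1.5,
    prune: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 200,
    self_scores: Mapping[str, float] | None = None,
) -> GeneClusterSet:
    """Markov clustering of the normalized similarity graph.

    Expansion = matrix square; inflation = entrywise power + column
    renormalization; entries below ``prune`` are zeroed each round.
    Clusters are connected components of the attractor support.
    ``self_scores`` (locus tag -> self-alignment score) sets the diagonal
    self-loops; without it each node's strongest edge is reused. Real
    self-scores strictly exceed cross-scores of non-identical sequences,
    which is what makes very high inflation shatter everything except
    exact duplicates.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    loci = sorted(set(all_loci))
    index = {t: i for i, t in enumerate(loci)}
    n = len(loci)
    M = np.zeros((n, n))
    for h in hits:
        i, j = index[h.query], index[h.subject]
        M[i, j] = max(M[i, j], h.score)
    M = np.maximum(M, M.T)
    if self_scores is not None:
        for t, i in index.items():
            M[i, i] = self_scores[t]
    else:
        np.fill_diagonal(M, M.max(axis=1, initial=1.0))  # self loops stabilize attractors
    col = M.sum(axis=0)
    col[col == 0] = 1.0
    M = M / col

    converged = False
    for _ in range(max_iter):
        prev = M
        M = M @ M
        M = np.power(M, inflation)
        M[M < prune] = 0.0
        col = M.sum(axis=0)
        col[col == 0] = 1.0
        M = M / col
        if np.abs(M - prev).max() < tol:
            converged = True
            break

    support = M > prune
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n))
    rows, cols = np.nonzero(support)
    g.add_edges_from(zip(rows.tolist(), cols.tolist()))
    comps = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
    clusters = {
        f"mcl{k:05d}": frozenset(_as_member(loci[i]) for i in comp)
        for k, comp in enumerate(comps, start=1)
    }
    return GeneClusterSet(clusters=clusters, algorithm="mcl", converged=converged)


def intersect_clusterings(a: GeneClusterSet, b: GeneClusterSet) -> GeneClusterSet:
    """Clusters whose member sets appear identically in both inputs."""
    common = a.member_sets() & b.member_sets()
    ordered = sorted(common, key=lambda s: sorted(s))
    return GeneClusterSet(
        clusters={f"cl{k:05d}": c for k, c in enumerate(ordered, start=1)},
        algorithm="intersection",
    )


def identity_matrix(proteomes: Sequence, hits: Iterable[AlignmentHit]) -> "pd.DataFrame":
    """Genome-level similarity: mean best-hit score normalized by self-score.

    Entry (i, j) averages, over genome i's proteins, the best hit score
    into genome j divided by the protein's self-score (0 when no hit);
    the result is symmetrized by averaging and has unit diagonal.
    """
    import pandas as pd

    selfs = self_scores(proteomes)
    ids = [g.id for g in proteomes]
    best: dict[tuple[str, str], float] = {}
    for h in hits:
        gq, lq = _as_member(h.query)
        gs = _genome_of(h.subject)
        key = ((gq, lq), gs)
        best[key] = max(best.get(key, 0.0), h.score)
    mat = np.eye(len(ids))
    for i, gi in enumerate(ids):
        prot_keys = [k for k in selfs if k[0] == gi]
        for j, gj in enumerate(ids):
            if i == j:
                continue
            vals = [min(best.get((k, gj), 0.0) / selfs[k], 1.0) for k in prot_keys]
            mat[i, j] = float(np.mean(vals)) if vals else 0.0
    mat = (mat + mat.T) / 2
    return pd.DataFrame(mat, index=ids, columns=ids)


def screen_reference_set(
    proteome,
    references: Mapping[str, str],
    min_identity: float = 0.3,
    min_coverage: float = 0.5,
    low_conf_coverage: float = 0.3,
) -> list[tuple[str, str, str]]:
    """Flag proteome members hitting a reference set (integrase/virulence).

    Verdicts: ``present`` when the best reference hit reaches the identity
    and reference-coverage thresholds; ``low_confidence`` when identity
    passes but reference coverage lands in [low_conf_coverage,
    min_coverage). Returns (locus, best_reference, verdict) tuples.
    """
    if not references:
        raise ValueError("reference set is empty")
    out = []
    for locus, aa in proteome.proteins().items():
        best_hit = None
        best_ref = None
        for ref_id, ref_seq in references.items():
            h = align_pair(aa, ref_seq, locus, ref_id)
            if best_hit is None or h.score > best_hit.score:
                best_hit, best_ref = h, ref_id
        if best_hit is None or best_hit.identity < min_identity:
            continue
        if best_hit.coverage_s >= min_coverage:
            out.append((locus, best_ref, "present"))
        elif best_hit.coverage_s >= low_conf_coverage:
            out.append((locus, best_ref, "low_confidence"))
    return out


def write_clusters_tsv(clusters: GeneClusterSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tgenome_id\tlocus_id\n")
        for cid in sorted(clusters.clusters):
            for genome, locus in sorted(clusters.clusters[cid]):
                fh.write(f"{cid}\t{genome}\t{locus}\n")
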