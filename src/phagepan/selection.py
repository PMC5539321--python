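"""Positive-selection scan: codon-aware alignment, recombination
breakpoint detection by topology incongruence, Nei-Gojobori (1986)
counting dN/dS with Jukes-Cantor correction, a column-resampling
significance test, and SNP effect classification for near-identical
genome pairs.

The likelihood machinery of branch-site selection tests is deliberately
out of scope; the verdict here comes from the counting statistic
T = dN - dS and a centered column-bootstrap null, so published
likelihood-based p-values are not numerically comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from . import msa
from .genome_io import GENETIC_CODE_TABLE, translate
from .phylo import nj_tree, p_distance_matrix

_TABLE = CodonTable.unambiguous_dna_by_id[GENETIC_CODE_TABLE]
_STOPS = set(_TABLE.stop_codons)
_BASES = "ACGT"


class SelectionError(ValueError):
    pass


# ---------------------------------------------------------------- alignment

@dataclass
class CodonAlignment:
    ids: list[str]
    rows: dict[str, str]               # aligned nucleotide rows, len % 3 == 0
    boundaries: list[int] = field(default_factory=list)  # codon-column starts of partitions (excl. 0)

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.rows.values()))) // 3

    def codon_columns(self) -> list[dict[str, str]]:
        out = []
        for k in range(self.n_codons):
            out.append({i: self.rows[i][3 * k : 3 * k + 3] for i in self.ids})
        return out

    def partitions(self) -> list[tuple[int, int]]:
        edges = [0] + sorted(self.boundaries) + [self.n_codons]
        return [(edges[k], edges[k + 1]) for k in range(len(edges) - 1) if edges[k] < edges[k + 1]]


def codon_align(nt_seqs: Mapping[str, str]) -> CodonAlignment:
    """Codon-aware alignment: align translations, back-thread codons.

    Incomplete terminal codons are trimmed; an internal stop raises with
    the offending sequence and codon position.
    """
    if len(nt_seqs) < 2:
        raise SelectionError("need at least two sequences")
    trimmed: dict[str, str] = {}
    prots: dict[str, str] = {}
    for sid, nt in nt_seqs.items():
        nt = nt.upper()
        nt = nt[: len(nt) - len(nt) % 3]
        if nt[-3:] in _STOPS:
            nt = nt[:-3]
        for k in range(0, len(nt), 3):
            if nt[k : k + 3] in _STOPS:
                raise SelectionError(f"internal stop codon in {sid} at codon {k // 3 + 1}")
        trimmed[sid] = nt
        prots[sid] = translate(nt)
    aligned_aa = msa.progressive_align(prots)
    rows = {}
    for sid, aa_row in aligned_aa.items():
        nt = trimmed[sid]
        out = []
        pos = 0
        for ch in aa_row:
            if ch == "-":
                out.append("---")
            else:
                out.append(nt[pos : pos + 3])
                pos += 3
        rows[sid] = "".join(out)
    return CodonAlignment(ids=list(nt_seqs), rows=rows)


# ----------------------------------------------------- breakpoint detection

def _splits(tree) -> frozenset:
    leaves = frozenset(tree.leaves())
    out = set()
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        side = node.leaf_set()
        if 1 < len(side) < len(leaves) - 1:
            out.add(frozenset((side, leaves - side)))
    return frozenset(out)


def detect_breakpoints(
    aln: CodonAlignment, window: int = 60, step: int = 20, persist: int = 2
) -> list[int]:
    """Recombination-breakpoint scan by NJ-topology incongruence.

    Slides a window over codon columns, builds an NJ topology per window
    from nucleotide p-distances, and records a boundary wherever the
    unrooted topology changes and the new topology persists for at least
    ``persist`` windows. Returns sorted codon-column boundaries.
    """
    if len(aln.ids) < 4:
        raise SelectionError("breakpoint detection needs at least four sequences")
    n = aln.n_codons
    if n < window:
        return []
    starts = list(range(0, n - window + 1, step))
    topos = []
    for s in starts:
        sub = {i: aln.rows[i][3 * s : 3 * (s + window)] for i in aln.ids}
        topos.append(_splits(nj_tree(p_distance_matrix(sub))))
    # run-length encode topologies; boundaries between persistent runs
    runs: list[tuple[frozenset, int, int]] = []  # (topology, first window idx, length)
    for k, t in enumerate(topos):
        if runs and runs[-1][0] == t:
            runs[-1] = (t, runs[-1][1], runs[-1][2] + 1)
        else:
            runs.append((t, k, 1))
    boundaries = []
    for prev, cur in zip(runs, runs[1:]):
        if prev[2] >= persist and cur[2] >= persist:
            boundaries.append(starts[cur[1]])
    return sorted(set(b for b in boundaries if 0 < b < n))


# -------------------------------------------------------------------- NG86

from functools import lru_cache


@lru_cache(maxsize=None)
def _syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the three single-nt changes at pos that are synonymous;
    changes producing stops count as nonsynonymous."""
    aa = _TABLE.forward_table[codon]
    syn = 0
    for b in _BASES:
        if b == codon[pos]:
            continue
        mut = codon[:pos] + b + codon[pos + 1 :]
        if mut not in _STOPS and _TABLE.forward_table[mut] == aa:
            syn += 1
    return syn / 3


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) potential sites of one codon."""
    s = sum(_syn_fraction(codon, p) for p in range(3))
    return s, 3.0 - s


@lru_cache(maxsize=None)
def codon_pair_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Observed (synonymous, nonsynonymous) differences between two codons,
    averaged over minimal mutational pathways; pathways through stop
    codons are excluded (all pathways used if every one is blocked)."""
    diff_pos = [p for p in range(3) if c1[p] != c2[p]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0
        blocked = False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if nxt in _STOPS:
                blocked = True
                break
            if _TABLE.forward_table[cur] == _TABLE.forward_table[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            paths.append((sd, nd))
    if not paths:  # every pathway passes through a stop: fall back to all
        for order in permutations(diff_pos):
            cur = c1
            sd = nd = 0
            for p in order:
                nxt = cur[:p] + c2[p] + cur[p + 1 :]
                a1 = _TABLE.forward_table.get(cur)
                a2 = _TABLE.forward_table.get(nxt)
                if a1 is not None and a2 is not None and a1 == a2:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC69 distance; None when p >= 3/4 (saturated)."""
    if p >= 0.75:
        return None
    return abs(-0.75 * math.log(1.0 - 4.0 * p / 3.0))


@dataclass(frozen=True)
class NGResult:
    dn: float | None
    ds: float | None

    @property
    def saturated(self) -> bool:
        return self.dn is None or self.ds is None

    def __iter__(self):
        yield self.dn
        yield self.ds


def _pair_components(row1: str, row2: str):
    """Per-codon-column (S_sites, N_sites, sd, nd) arrays for one pair;
    columns with gaps or ambiguity in either row contribute zeros."""
    n = len(row1) // 3
    S = np.zeros(n)
    N = np.zeros(n)
    SD = np.zeros(n)
    ND = np.zeros(n)
    for k in range(n):
        c1, c2 = row1[3 * k : 3 * k + 3], row2[3 * k : 3 * k + 3]
        if set(c1) - set(_BASES) or set(c2) - set(_BASES):
            continue
        if c1 in _STOPS or c2 in _STOPS:
            continue
        s1, n1 = codon_sites(c1)
        s2, n2 = codon_sites(c2)
        S[k] = (s1 + s2) / 2
        N[k] = (n1 + n2) / 2
        sd, nd = codon_pair_diffs(c1, c2)
        SD[k] = sd
        ND[k] = nd
    return S, N, SD, ND


def ng86_dnds(row1: str, row2: str) -> NGResult:
    """Nei-Gojobori 1986 dN and dS for two aligned codon rows (JC-corrected)."""
    if len(row1) != len(row2) or len(row1) % 3:
        raise SelectionError("rows must be equal length and codon-aligned")
    S, N, SD, ND = _pair_components(row1, row2)
    s_tot, n_tot = S.sum(), N.sum()
    if s_tot == 0 and n_tot == 0:
        raise SelectionError("no comparable codons")
    ps = SD.sum() / s_tot if s_tot > 0 else 0.0
    pn = ND.sum() / n_tot if n_tot > 0 else 0.0
    return NGResult(dn=jukes_cantor(pn), ds=jukes_cantor(ps))


# ----------------------------------------------------------- cluster test

@dataclass
class DnDsResult:
    cluster_id: str
    partition: tuple[int, int]
    dn: float | None
    ds: float | None
    statistic: float | None        # dN - dS
    p_value: float | None
    positively_selected: bool
    saturated: bool = False


def cluster_dnds(
    aln: CodonAlignment,
    cluster_id: str = "cluster",
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[DnDsResult]:
    """Mean pairwise dN - dS per partition with a centered column-bootstrap
    test: codon columns are resampled with replacement, the statistic is
    recentered at the observed value to form the null, and p is the
    fraction of null draws at or above the observed statistic.
    """
    if len(aln.ids) < 2:
        raise SelectionError("need at least two sequences")
    rng = np.random.default_rng(seed)
    pairs = list(combinations(aln.ids, 2))
    comps = {
        (a, b): _pair_components(aln.rows[a], aln.rows[b]) for a, b in pairs
    }
    results = []
    for part in aln.partitions():
        lo, hi = part
        idx = np.arange(lo, hi)

        def statistic(cols: np.ndarray) -> tuple[float | None, float | None, float | None]:
            dns, dss = [], []
            for pair in pairs:
                S, N, SD, ND = comps[pair]
                s_tot = S[cols].sum()
                n_tot = N[cols].sum()
                if s_tot == 0 or n_tot == 0:
                    continue
                dn = jukes_cantor(ND[cols].sum() / n_tot)
                ds = jukes_cantor(SD[cols].sum() / s_tot)
                if dn is None or ds is None:
                    continue
                dns.append(dn)
                dss.append(ds)
            if not dns:
                return None, None, None
            dn_m, ds_m = float(np.mean(dns)), float(np.mean(dss))
            return dn_m, ds_m, dn_m - ds_m

        dn_obs, ds_obs, t_obs = statistic(idx)
        if t_obs is None:
            results.append(
                DnDsResult(cluster_id, part, None, None, None, None, False, saturated=True)
            )
            continue
        t_null = []
        for _ in range(n_boot):
            cols = rng.choice(idx, size=len(idx), replace=True)
            _, _, t_b = statistic(cols)
            if t_b is not None:
                t_null.append(t_b - t_obs)  # center the bootstrap at zero
        if not t_null:
            p = None
            verdict = False
        else:
            p = float(np.mean(np.asarray(t_null) >= t_obs))
            verdict = p < alpha
        results.append(DnDsResult(cluster_id, part, dn_obs, ds_obs, t_obs, p, verdict))
    return results


# -------------------------------------------------------------------- SNPs

@dataclass(frozen=True)
class SnpCall:
    position: int                  # 1-based position in the first genome
    ref: str
    alt: str
    effect: str                    # synonymous | nonsynonymous | intergenic
    locus_id: str | None = None
    codon_change: str | None = None
    aa_change: str | None = None


def classify_snps(genome_a, genome_b, min_identity: float = 0.95):
    """Global alignment of two near-identical genomes; substitutions are
    classified against the first genome's CDS annotations.

    Returns (snps, indels) where indels is a list of (position, length,
    kind) tuples. Refuses dissimilar genomes: below ``min_identity`` a
    whole-genome global alignment is not meaningful.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aln = aligner.align(genome_a.sequence, genome_b.sequence)[0]
    counts = aln.counts()
    ncols = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / ncols if ncols else 0.0
    if identity < min_identity:
        raise SelectionError(
            f"global identity {identity:.3f} < {min_identity}; genomes are too "
            "divergent for SNP calling - use the homology module instead"
        )
    cds_at = {}
    for c in genome_a.cds:
        for pos in range(c.start, c.end + 1):
            cds_at.setdefault(pos, c)

    snps: list[SnpCall] = []
    indels: list[tuple[int, int, str]] = []
    sa, sb = genome_a.sequence, genome_b.sequence
    ia = ib = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        if a0 > ia:
            indels.append((ia + 1, a0 - ia, "deletion_in_b"))
        if b0 > ib:
            indels.append((ia + 1, b0 - ib, "insertion_in_b"))
        for off in range(a1 - a0):
            ra, rb = sa[a0 + off], sb[b0 + off]
            if ra == rb:
                continue
            pos = a0 + off + 1
            cds = cds_at.get(pos)
            if cds is None:
                snps.append(SnpCall(pos, ra, rb, "intergenic"))
                continue
            snps.append(_classify_coding_snp(cds, pos, ra, rb))
        ia, ib = a1, b1
    if ia < len(sa):
        indels.append((ia + 1, len(sa) - ia, "deletion_in_b"))
    if ib < len(sb):
        indels.append((ia + 1, len(sb) - ib, "insertion_in_b"))
    return snps, indels


_COMP = str.maketrans("ACGT", "TGCA")


def _classify_coding_snp(cds, pos: int, ref: str, alt: str) -> SnpCall:
    if cds.strand == "+":
        off = pos - cds.start
        r, a = ref, alt
    else:
        off = cds.end - pos
        r, a = ref.translate(_COMP), alt.translate(_COMP)
    ci = off // 3
    cp = off % 3
    ref_codon = cds.nt_seq[3 * ci : 3 * ci + 3]
    alt_codon = ref_codon[:cp] + a + ref_codon[cp + 1 :]
    aa_ref = translate(ref_codon) or "*"
    aa_alt = translate(alt_codon) or "*"
    effect = "synonymous" if aa_ref == aa_alt else "nonsynonymous"
    return SnpCall(
        pos, ref, alt, effect, locus_id=cds.locus_id,
        codon_change=f"{ref_codon}>{alt_codon}", aa_change=f"{aa_ref}>{aa_alt}",
    )
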