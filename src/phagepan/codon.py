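"""Codon-usage analyses: RSCU vectors, amino-acid composition, PCA of
genome profiles, tRNA/GC association and outlier flagging."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[11]

# synonymous families over the 59 informative sense codons: stops plus the
# single-codon families (ATG, TGG) carry no usage signal and are excluded
SYNONYMOUS_FAMILIES: dict[str, list[str]] = {}
for codon in ("".join(p) for p in product("TCAG", repeat=3)):
    if codon in _TABLE.stop_codons:
        continue
    SYNONYMOUS_FAMILIES.setdefault(_TABLE.forward_table[codon], []).append(codon)
SYNONYMOUS_FAMILIES = {
    aa: sorted(codons) for aa, codons in SYNONYMOUS_FAMILIES.items() if len(codons) > 1
}
RSCU_CODONS = tuple(c for codons in SYNONYMOUS_FAMILIES.values() for c in codons)
AMINO_ACIDS = tuple(sorted(set(_TABLE.forward_table.values())))


class CodonUsageError(ValueError):
    pass


@dataclass
class CodonProfile:
    genome_id: str
    rscu: pd.Series            # indexed by the 59 informative codons
    aa_comp: pd.Series         # indexed by the 20 amino acids, sums to 1
    gc_percent: float
    has_trna: bool
    empty_families: tuple[str, ...] = ()


def _codon_counts(cds_seqs) -> dict[str, int]:
    counts: dict[str, int] = {}
    for nt in cds_seqs:
        nt = nt.upper()
        if len(nt) % 3:
            raise CodonUsageError("CDS length not divisible by 3")
        for i in range(0, len(nt), 3):
            codon = nt[i : i + 3]
            if set(codon) <= set("ACGT"):
                counts[codon] = counts.get(codon, 0) + 1
    return counts


def rscu(cds_seqs) -> tuple[pd.Series, tuple[str, ...]]:
    """Relative synonymous codon usage over concatenated CDSs.

    RSCU of codon c = observed(c) * family_size / family_total. Families
    with no observations get all-zero components and are reported in the
    second return value.
    """
    counts = _codon_counts(cds_seqs)
    if not counts:
        raise CodonUsageError("no valid codons found")
    vals = {}
    empty = []
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        total = sum(counts.get(c, 0) for c in codons)
        if total == 0:
            empty.append(aa)
            for c in codons:
                vals[c] = 0.0
        else:
            k = len(codons)
            for c in codons:
                vals[c] = counts.get(c, 0) * k / total
    return pd.Series(vals).reindex(list(RSCU_CODONS)), tuple(empty)


def aa_composition(cds_seqs) -> pd.Series:
    counts = _codon_counts(cds_seqs)
    if not counts:
        raise CodonUsageError("no valid codons found")
    aa_counts = {aa: 0 for aa in AMINO_ACIDS}
    for codon, n in counts.items():
        aa = _TABLE.forward_table.get(codon)
        if aa is not None:
            aa_counts[aa] += n
    total = sum(aa_counts.values())
    if total == 0:
        raise CodonUsageError("no sense codons found")
    return pd.Series({aa: n / total for aa, n in aa_counts.items()}).reindex(list(AMINO_ACIDS))


def profile_genome(genome) -> CodonProfile:
    seqs = [c.nt_seq for c in genome.cds]
    r, empty = rscu(seqs)
    return CodonProfile(
        genome_id=genome.id,
        rscu=r,
        aa_comp=aa_composition(seqs),
        gc_percent=genome.gc_percent,
        has_trna=genome.trna_count > 0,
        empty_families=empty,
    )


def pca(profiles, on: str = "rscu"):
    """Covariance PCA of genome profiles.

    Returns (scores, loadings, explained_variance_ratio) as DataFrames /
    Series. Columns are centered but not scaled; the sign of each
    component is fixed so its largest-magnitude loading is positive.
    """
    if len(profiles) < 3:
        raise ValueError("need at least three profiles")
    rows = {p.genome_id: getattr(p, on) for p in profiles}
    X = pd.DataFrame(rows).T
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc.to_numpy(), 0.0):
        raise CodonUsageError("zero-variance profile matrix")
    U, S, Vt = np.linalg.svd(Xc.to_numpy(), full_matrices=False)
    # sign convention: largest-magnitude loading positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]
    scores = U * S
    var = S**2 / max(len(X) - 1, 1)
    evr = var / var.sum()
    comp_names = [f"PC{k + 1}" for k in range(len(S))]
    return (
        pd.DataFrame(scores, index=X.index, columns=comp_names),
        pd.DataFrame(Vt, index=comp_names, columns=X.columns),
        pd.Series(evr, index=comp_names),
    )


def trna_gc_association(cohort: pd.DataFrame):
    """Point-biserial r between tRNA presence and GC%, plus perfect
    separation check (max GC of one class below min GC of the other).

    Returns (r, perfectly_separated, threshold). With a single class, r
    is None and separation is trivially True.
    """
    has = cohort["trna_count"] > 0
    gc = cohort["gc_percent"].to_numpy(dtype=float)
    if has.all() or (~has).all():
        return None, True, None
    g1, g0 = gc[has.to_numpy()], gc[~has.to_numpy()]
    r = float(np.corrcoef(has.to_numpy(dtype=float), gc)[0, 1])
    if g1.max() < g0.min():
        return r, True, float((g1.max() + g0.min()) / 2)
    if g0.max() < g1.min():
        return r, True, float((g0.max() + g1.min()) / 2)
    return r, False, None


def flag_outliers(profiles, scores: pd.DataFrame, z_cut: float = 3.0,
                  gc_split: float = 50.0) -> list[str]:
    """Genomes with |robust z| > z_cut on PC1 or PC2 within their GC class.

    Robust z uses median/MAD (scaled); when MAD is 0 but values differ, a
    range-based fallback flags the points away from the median.
    """
    classes: dict[str, list[str]] = {"low": [], "high": []}
    for p in profiles:
        classes["high" if p.gc_percent >= gc_split else "low"].append(p.genome_id)
    flagged: set[str] = set()
    use_cols = [c for c in ("PC1", "PC2") if c in scores.columns]
    for ids in classes.values():
        if len(ids) < 3:
            continue
        for col in use_cols:
            v = scores.loc[ids, col].to_numpy(dtype=float)
            med = np.median(v)
            mad = np.median(np.abs(v - med))
            if mad > 0:
                z = 0.6745 * (v - med) / mad
                for gid, zi in zip(ids, z):
                    if abs(zi) > z_cut:
                        flagged.add(gid)
            else:
                spread = v.max() - v.min()
                if spread > 0:
                    for gid, vi in zip(ids, v):
                        if abs(vi - med) > 0.5 * spread:
                            flagged.add(gid)
    return sorted(flagged)
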