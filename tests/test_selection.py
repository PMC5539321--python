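from itertools import permutations

import numpy as np
import pytest
from Bio.Data import CodonTable

from phagepan import selection as sel
from phagepan.simulate import evolve_codon_sequences

TAB = CodonTable.unambiguous_dna_by_id[11]
STOPS = set(TAB.stop_codons)


class TestCodonAlign:
    def test_identical_gap_free(self):
        aln = sel.codon_align({"a": "ATGAAACCCGGG", "b": "ATGAAACCCGGG"})
        assert aln.rows["a"] == aln.rows["b"] == "ATGAAACCCGGG"

    def test_clean_codon_deletion(self):
        a = "ATGAAATGGCCCGGGTGG"
        b = "ATGAAACCCGGGTGG"  # TGG codon 2 deleted
        aln = sel.codon_align({"a": a, "b": b})
        assert len(aln.rows["a"]) == len(aln.rows["b"]) == 18
        assert aln.rows["b"].count("-") == 3
        # the gap is codon-shaped
        gap_start = aln.rows["b"].index("-")
        assert gap_start % 3 == 0
        assert aln.rows["b"][gap_start : gap_start + 3] == "---"

    def test_internal_stop_rejected(self):
        with pytest.raises(sel.SelectionError, match="internal stop"):
            sel.codon_align({"a": "ATGTAAAAACCC", "b": "ATGAAAAAACCC"})

    def test_needs_two(self):
        with pytest.raises(sel.SelectionError):
            sel.codon_align({"a": "ATGAAA"})


# -------------------------------------------------------------- NG86 oracle

def _aa(codon):
    from Bio.Seq import Seq

    return str(Seq(codon).translate(table=11))


def ng86_oracle(row1, row2):
    """Independent NG86: recursive pathway enumeration + site counting via
    Biopython translation, JC correction applied at the end."""
    s_sites = n_sites = sd = nd = 0.0
    ncomp = 0
    for k in range(0, len(row1), 3):
        c1, c2 = row1[k : k + 3], row2[k : k + 3]
        if set(c1 + c2) - set("ACGT") or c1 in STOPS or c2 in STOPS:
            continue
        ncomp += 1
        for c in (c1, c2):
            s = 0.0
            for pos in range(3):
                for b in "ACGT":
                    if b == c[pos]:
                        continue
                    m = c[:pos] + b + c[pos + 1 :]
                    if m not in STOPS and _aa(m) == _aa(c):
                        s += 1 / 3
            s_sites += s / 2
            n_sites += (3 - s) / 2
        diffs = [p for p in range(3) if c1[p] != c2[p]]
        if not diffs:
            continue
        paths = []
        for order in permutations(diffs):
            cur, s_cnt, n_cnt, ok = c1, 0, 0, True
            for p in order:
                nxt = cur[:p] + c2[p] + cur[p + 1 :]
                if nxt in STOPS:
                    ok = False
                    break
                if _aa(cur) == _aa(nxt):
                    s_cnt += 1
                else:
                    n_cnt += 1
                cur = nxt
            if ok:
                paths.append((s_cnt, n_cnt))
        if not paths:
            for order in permutations(diffs):
                cur, s_cnt, n_cnt = c1, 0, 0
                for p in order:
                    nxt = cur[:p] + c2[p] + cur[p + 1 :]
                    if nxt not in STOPS and cur not in STOPS and _aa(cur) == _aa(nxt):
                        s_cnt += 1
                    else:
                        n_cnt += 1
                    cur = nxt
                paths.append((s_cnt, n_cnt))
        sd += sum(p[0] for p in paths) / len(paths)
        nd += sum(p[1] for p in paths) / len(paths)
    if ncomp == 0:
        raise ValueError("nothing to compare")

    def jc(p):
        if p >= 0.75:
            return None
        return -0.75 * np.log(1 - 4 * p / 3)

    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    return jc(pn), jc(ps)


class TestNg86:
    def test_identical(self):
        assert tuple(sel.ng86_dnds("ATGAAA", "ATGAAA")) == (0.0, 0.0)

    def test_synonymous_only(self):
        dn, ds = sel.ng86_dnds("GCTGCT", "GCCGCT")
        assert dn == 0.0
        assert ds > 0.0

    def test_matches_oracle_on_random_pairs(self):
        rng = np.random.default_rng(99)
        sense = sorted(set(TAB.forward_table))
        for _ in range(50):
            c1 = [sense[rng.integers(len(sense))] for _ in range(10)]
            c2 = []
            for c in c1:
                if rng.random() < 0.4:
                    # mutate 1-2 positions, avoiding stops
                    m = c
                    for _ in range(int(rng.integers(1, 3))):
                        pos = int(rng.integers(3))
                        b = "ACGT"[rng.integers(4)]
                        cand = m[:pos] + b + m[pos + 1 :]
                        if cand not in STOPS:
                            m = cand
                    c2.append(m)
                else:
                    c2.append(c)
            r1, r2 = "".join(c1), "".join(c2)
            got = sel.ng86_dnds(r1, r2)
            exp_dn, exp_ds = ng86_oracle(r1, r2)
            if exp_dn is None:
                assert got.dn is None
            else:
                assert got.dn == pytest.approx(exp_dn, abs=1e-12)
            if exp_ds is None:
                assert got.ds is None
            else:
                assert got.ds == pytest.approx(exp_ds, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a = evolve_codon_sequences(2, 30, 8, seed=1)
        r1, r2 = a["seq1"], a["seq2"]
        assert tuple(sel.ng86_dnds(r1, r2)) == tuple(sel.ng86_dnds(r2, r1))

    def test_saturation_flag(self):
        # maximally divergent codons drive p >= 3/4
        r1 = "AAA" * 20
        r2 = "GGC" * 20
        res = sel.ng86_dnds(r1, r2)
        assert res.saturated

    def test_gapped_columns_skipped(self):
        res = sel.ng86_dnds("---GCTGCAGCG", "GCCGCCGCAGCG")
        assert res.ds > 0
        assert res.dn == 0.0

    def test_monotone_in_planted_substitutions(self):
        ds_prev = dn_prev = -1.0
        for subs in (2, 6, 12):
            seqs = evolve_codon_sequences(2, 100, subs, omega=1.0, seed=7)
            dn, ds = sel.ng86_dnds(seqs["seq1"], seqs["seq2"])
            assert dn + ds >= dn_prev + ds_prev
            dn_prev, ds_prev = dn, ds


class TestDetectBreakpoints:
    def _pair_block(self, topo, n_codons, seed):
        """4-taxon alignment with the given pairing structure."""
        rng = np.random.default_rng(seed)
        anc = evolve_codon_sequences(1, n_codons, 0, seed=seed)["seq1"]

        def mutate(s, n, sd):
            out = evolve_codon_sequences(1, n_codons, n, seed=sd)
            return out

        # two subfamilies from the ancestor, two tips each
        fam1 = evolve_codon_sequences(2, n_codons, 4, seed=seed * 17 + 1)
        fam2 = evolve_codon_sequences(2, n_codons, 4, seed=seed * 17 + 2)
        if topo == "AB|CD":
            return {"A": fam1["seq1"], "B": fam1["seq2"], "C": fam2["seq1"], "D": fam2["seq2"]}
        return {"A": fam1["seq1"], "C": fam1["seq2"], "B": fam2["seq1"], "D": fam2["seq2"]}

    def test_homogeneous_no_breakpoint(self):
        seqs = self._pair_block("AB|CD", 200, seed=3)
        aln = sel.CodonAlignment(ids=list(seqs), rows=seqs)
        assert sel.detect_breakpoints(aln) == []

    def test_concatenated_topologies_one_breakpoint(self):
        left = self._pair_block("AB|CD", 120, seed=5)
        right = self._pair_block("AC|BD", 120, seed=6)
        seqs = {k: left[k] + right[k] for k in "ABCD"}
        aln = sel.CodonAlignment(ids=list(seqs), rows=seqs)
        bps = sel.detect_breakpoints(aln, window=60, step=20)
        assert len(bps) == 1
        # junction at codon 120; window granularity allows +-1 window
        assert abs(bps[0] - 120) <= 20 + 60  # start-of-run resolution

    def test_three_sequences_rejected(self):
        seqs = {"a": "ATG" * 100, "b": "ATG" * 100, "c": "ATG" * 100}
        aln = sel.CodonAlignment(ids=list(seqs), rows=seqs)
        with pytest.raises(sel.SelectionError):
            sel.detect_breakpoints(aln)

    def test_short_alignment_single_partition(self):
        seqs = self._pair_block("AB|CD", 30, seed=4)
        aln = sel.CodonAlignment(ids=list(seqs), rows=seqs)
        assert sel.detect_breakpoints(aln, window=60) == []

    def test_boundaries_sorted_in_range(self):
        left = self._pair_block("AB|CD", 120, seed=8)
        right = self._pair_block("AC|BD", 120, seed=9)
        seqs = {k: left[k] + right[k] for k in "ABCD"}
        aln = sel.CodonAlignment(ids=list(seqs), rows=seqs)
        bps = sel.detect_breakpoints(aln)
        assert bps == sorted(set(bps))
        assert all(0 < b < aln.n_codons for b in bps)


class TestClusterDnds:
    def test_identical_sequences(self):
        seqs = {"a": "ATGAAACCC" * 10, "b": "ATGAAACCC" * 10}
        aln = sel.CodonAlignment(ids=list(seqs), rows=seqs)
        res = sel.cluster_dnds(aln, n_boot=200, seed=0)[0]
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert res.positively_selected is False

    def test_neutral_type_one_error(self):
        hits = 0
        for seed in range(1, 21):
            seqs = evolve_codon_sequences(5, 120, 18, omega=1.0, seed=seed)
            aln = sel.CodonAlignment(ids=list(seqs), rows=seqs)
            res = sel.cluster_dnds(aln, n_boot=500, seed=seed)[0]
            hits += res.positively_selected
        assert hits / 20 <= 0.10

    def test_power_under_nonsynonymous_excess(self):
        hits = 0
        for seed in range(1, 21):
            seqs = evolve_codon_sequences(5, 120, 18, omega=3.0, seed=1000 + seed)
            aln = sel.CodonAlignment(ids=list(seqs), rows=seqs)
            res = sel.cluster_dnds(aln, n_boot=500, seed=seed)[0]
            hits += res.positively_selected
        assert hits / 20 >= 0.80

    def test_partitions_respected(self):
        seqs = evolve_codon_sequences(4, 100, 10, seed=2)
        aln = sel.CodonAlignment(ids=list(seqs), rows=seqs, boundaries=[50])
        res = sel.cluster_dnds(aln, n_boot=100, seed=0)
        assert [r.partition for r in res] == [(0, 50), (50, 100)]


class TestClassifySnps:
    def _genome(self, gid, seq, cds_specs):
        from phagepan.genome_io import CdsRecord, PhageGenome, extract_cds_seq, translate

        cds = []
        for locus, start, end, strand in cds_specs:
            nt = extract_cds_seq(seq, start, end, strand)
            cds.append(CdsRecord(locus, start, end, strand, nt, translate(nt)))
        return PhageGenome(id=gid, sequence=seq, cds=cds)

    def test_identical_genomes(self):
        seq = "CCC" + "ATGAAACCCGGGTTTTAA" + "CCC"
        a = self._genome("a", seq, [("c1", 4, 21, "+")])
        b = self._genome("b", seq, [("c1", 4, 21, "+")])
        snps, indels = sel.classify_snps(a, b)
        assert snps == [] and indels == []

    def test_nonsynonymous_atg_to_gtg(self):
        base = "ATGAAACCCGGGTTT" * 8 + "TAA"
        seq_a = "CCCCCC" + base + "CCCCCC"
        seq_b = "CCCCCC" + "GTG" + base[3:] + "CCCCCC"
        a = self._genome("a", seq_a, [("c1", 7, 6 + len(base), "+")])
        b = self._genome("b", seq_b, [("c1", 7, 6 + len(base), "+")])
        snps, _ = sel.classify_snps(a, b)
        assert len(snps) == 1
        s = snps[0]
        assert s.effect == "nonsynonymous"
        assert s.aa_change == "M>V"

    def test_intergenic_snp(self):
        base = "ATGAAACCCGGGTTT" * 8 + "TAA"
        seq_a = "CCCCCC" + base + "CCCCCC"
        seq_b = "CCCCCC" + base + "CCCCAC"
        a = self._genome("a", seq_a, [("c1", 7, 6 + len(base), "+")])
        b = self._genome("b", seq_b, [("c1", 7, 6 + len(base), "+")])
        snps, _ = sel.classify_snps(a, b)
        assert [s.effect for s in snps] == ["intergenic"]

    def test_minus_strand_classification(self):
        from phagepan.genome_io import reverse_complement

        gene = "ATGAAACCCGGGTTT" * 8 + "TAA"
        seq_a = "CCCCCC" + reverse_complement(gene) + "CCCCCC"
        # synonymous change AAA->AAG (Lys) at codon 2 of the gene
        mutated = gene[:5] + "G" + gene[6:]
        assert mutated[3:6] == "AAG"
        seq_b = "CCCCCC" + reverse_complement(mutated) + "CCCCCC"
        a = self._genome("a", seq_a, [("c1", 7, 6 + len(gene), "-")])
        b = self._genome("b", seq_b, [("c1", 7, 6 + len(gene), "-")])
        snps, _ = sel.classify_snps(a, b)
        assert [s.effect for s in snps] == ["synonymous"]

    def test_divergent_genomes_refused(self):
        rng = np.random.default_rng(0)
        s1 = "".join(rng.choice(list("ACGT"), size=300))
        s2 = "".join(rng.choice(list("ACGT"), size=300))
        a = self._genome("a", s1, [])
        b = self._genome("b", s2, [])
        with pytest.raises(sel.SelectionError, match="too divergent"):
            sel.classify_snps(a, b)
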