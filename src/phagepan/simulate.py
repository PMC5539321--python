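"""Synthetic phage cohorts with planted structure.

Every downstream stage of the pipeline is exercised against cohorts
produced here: planted genome groups with group-specific gene-cluster
repertoires, GC%-targeted codon composition, tRNA presence coupled to the
GC class, packaging-strategy-labeled terminases, lysotype-structured
host ranges and step-like one-step growth curves. The generator records
full ground truth so recovery can be asserted exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .genome_io import CdsRecord, PhageGenome, translate, write_genomes

_TABLE = CodonTable.unambiguous_dna_by_id[11]
_AA_CODONS: dict[str, list[str]] = {}
for _codon in ("".join(p) for p in product("TCAG", repeat=3)):
    if _codon not in _TABLE.stop_codons:
        _AA_CODONS.setdefault(_TABLE.forward_table[_codon], []).append(_codon)
for _aa in _AA_CODONS:
    _AA_CODONS[_aa].sort()
_AMINO_ACIDS = sorted(_AA_CODONS)
_STOP = "TAA"

PACKAGING_CYCLE = ("headful", "cos_5prime", "short_DTR", "long_DTR", "cos_3prime")
LYSOTYPE_CLASSES = ("narrow", "intermediate", "broad")


class SpecError(ValueError):
    pass


@dataclass
class CohortSpec:
    genomes_per_group: tuple[int, ...] = (4, 4, 4)
    core_clusters_per_group: int = 12
    shared_clusters: dict[tuple[int, int], int] = field(default_factory=dict)
    singleton_rate: float = 0.15
    gc_targets: tuple[float, ...] = (0.56, 0.42, 0.40)
    trna_range_low_gc: tuple[int, int] = (10, 25)   # GC below host -> tRNAs
    gc_trna_threshold: float = 0.50
    protein_length: tuple[float, float] = (120.0, 25.0)
    divergence_within_group: float = 0.05
    lysotypes: tuple[str, ...] | None = None        # per phage; cycled from classes if None
    n_isolates: int = 20
    n_mesophilic: int = 3
    mesophilic_exceptions: int = 0                  # sensitive (phage, mesophilic) cells
    growth_params: tuple[tuple[float, float], ...] | None = None  # (burst, latent) per phage
    packaging_per_group: tuple[str, ...] | None = None
    seed: int = 0

    @property
    def n_groups(self) -> int:
        return len(self.genomes_per_group)

    def validate(self) -> None:
        if len(self.gc_targets) != self.n_groups:
            raise SpecError("gc_targets must match the number of groups")
        if any(n <= 0 for n in self.genomes_per_group):
            raise SpecError("groups must be non-empty")
        if not all(0 < g < 1 for g in self.gc_targets):
            raise SpecError("gc_targets must be fractions in (0, 1)")
        if self.singleton_rate < 0:
            raise SpecError("singleton_rate must be >= 0")
        if not (0 <= self.divergence_within_group < 1):
            raise SpecError("divergence must be in [0, 1)")
        for (a, b), k in self.shared_clusters.items():
            if not (0 <= a < self.n_groups and 0 <= b < self.n_groups and a != b):
                raise SpecError(f"bad shared-cluster group pair {(a, b)}")
            if k < 0 or k > self.core_clusters_per_group:
                raise SpecError("shared clusters exceed core size")


@dataclass
class GroundTruth:
    genome_group: dict[str, int]
    cluster_members: dict[str, list[str]]            # cluster -> ["genome:locus", ...]
    packaging: dict[str, str]
    gc_targets: dict[str, float]
    trna_counts: dict[str, int]
    lysotypes: dict[str, str]
    sensitive_isolates: dict[str, list[str]]
    growth_params: dict[str, dict[str, float]]

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True, indent=1, default=list)


# ------------------------------------------------------------ GC-targeted codons

def _codon_weights(beta: float) -> dict[str, np.ndarray]:
    out = {}
    for aa, codons in _AA_CODONS.items():
        gc = np.array([c.count("G") + c.count("C") for c in codons], dtype=float)
        w = np.exp(beta * gc)
        out[aa] = w / w.sum()
    return out


def _expected_gc(beta: float, aa_freq: dict[str, float]) -> float:
    w = _codon_weights(beta)
    num = 0.0
    for aa, f in aa_freq.items():
        codons = _AA_CODONS[aa]
        gc = np.array([c.count("G") + c.count("C") for c in codons], dtype=float)
        num += f * float(w[aa] @ gc) / 3.0
    return num


def solve_gc_beta(target_gc: float, aa_freq: dict[str, float]) -> float:
    """Bisection for the exponential-tilt parameter whose expected coding
    GC equals the target (expected GC is monotone increasing in beta)."""
    lo, hi = -8.0, 8.0
    if not (_expected_gc(lo, aa_freq) < target_gc < _expected_gc(hi, aa_freq)):
        raise SpecError(f"GC target {target_gc} unreachable by codon choice")
    for _ in range(80):
        mid = (lo + hi) / 2
        if _expected_gc(mid, aa_freq) < target_gc:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def back_translate(protein: str, beta: float, rng: np.random.Generator) -> str:
    weights = _codon_weights(beta)
    parts = []
    for aa in protein:
        codons = _AA_CODONS[aa]
        parts.append(codons[rng.choice(len(codons), p=weights[aa])])
    parts.append(_STOP)
    return "".join(parts)


# ------------------------------------------------------------------ proteins

def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_AMINO_ACIDS), size=max(10, length)))


def mutate_protein(protein: str, divergence: float, rng: np.random.Generator) -> str:
    if divergence == 0:
        return protein
    out = list(protein)
    hits = rng.random(len(out)) < divergence
    for k in np.nonzero(hits)[0]:
        choices = [a for a in _AMINO_ACIDS if a != out[k]]
        out[k] = choices[rng.integers(len(choices))]
    return "".join(out)


def _random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _dna_with_gc_count(length: int, n_gc: int, rng: np.random.Generator) -> str:
    """Random DNA with an exact number of G/C bases."""
    n_gc = int(np.clip(n_gc, 0, length))
    bases = [("G", "C")[int(rng.integers(2))] for _ in range(n_gc)]
    bases += [("A", "T")[int(rng.integers(2))] for _ in range(length - n_gc)]
    perm = rng.permutation(length)
    return "".join(bases[k] for k in perm)


# ------------------------------------------------------------------ cohort

def generate_cohort(spec: CohortSpec, outdir: str | Path) -> tuple[dict[str, Path], GroundTruth]:
    """Emit a full synthetic cohort to ``outdir`` and return its ground truth.

    Files: genomes.fasta, annotations.tsv, cohort.tsv, hostrange.tsv,
    isolates.tsv, growth.tsv, terminase.fasta, terminase_refs.fasta,
    ground_truth.json.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    mean_len, sd_len = spec.protein_length
    genome_ids: list[str] = []
    genome_group: dict[str, int] = {}
    for g, n in enumerate(spec.genomes_per_group):
        for k in range(n):
            gid = f"G{g + 1}P{k + 1}"
            genome_ids.append(gid)
            genome_group[gid] = g

    # ancestors: per-group cores, cross-group shared, terminase per group
    ancestors: list[tuple[str, list[str], str]] = []  # (cluster_id, member genomes, protein)
    cid = 0
    for g, _ in enumerate(spec.genomes_per_group):
        members = [i for i in genome_ids if genome_group[i] == g]
        for _ in range(spec.core_clusters_per_group):
            cid += 1
            length = int(rng.normal(mean_len, sd_len))
            ancestors.append((f"cl{cid:04d}", members, random_protein(length, rng)))
    for (a, b), count in sorted(spec.shared_clusters.items()):
        members = [i for i in genome_ids if genome_group[i] in (a, b)]
        for _ in range(count):
            cid += 1
            length = int(rng.normal(mean_len, sd_len))
            ancestors.append((f"cl{cid:04d}", members, random_protein(length, rng)))

    packaging_labels = (
        spec.packaging_per_group
        if spec.packaging_per_group is not None
        else tuple(PACKAGING_CYCLE[g % len(PACKAGING_CYCLE)] for g in range(spec.n_groups))
    )
    terminase_anc = {
        g: random_protein(200, rng) for g in range(spec.n_groups)
    }

    # per-genome proteins
    cluster_members: dict[str, list[str]] = {a[0]: [] for a in ancestors}
    genome_proteins: dict[str, list[tuple[str, str, str]]] = {i: [] for i in genome_ids}
    for cluster_id, members, anc in ancestors:
        for gid in members:
            prot = mutate_protein(anc, spec.divergence_within_group, rng)
            locus = f"{gid}_{cluster_id}"
            genome_proteins[gid].append((locus, prot, cluster_id))
            cluster_members[cluster_id].append(f"{gid}:{locus}")
    n_singletons = int(round(spec.singleton_rate * spec.core_clusters_per_group))
    for gid in genome_ids:
        for s in range(n_singletons):
            cid += 1
            cluster_id = f"cl{cid:04d}"
            length = int(rng.normal(mean_len, sd_len))
            prot = random_protein(length, rng)
            locus = f"{gid}_sing{s + 1}"
            genome_proteins[gid].append((locus, prot, cluster_id))
            cluster_members[cluster_id] = [f"{gid}:{locus}"]
    terminases: dict[str, str] = {}
    for gid in genome_ids:
        term = mutate_protein(
            terminase_anc[genome_group[gid]], spec.divergence_within_group, rng
        )
        terminases[gid] = term

    # genomes: back-translated CDSs at the group GC target, alternating strands
    genomes: list[PhageGenome] = []
    gc_targets: dict[str, float] = {}
    trna_counts: dict[str, int] = {}
    for gid in genome_ids:
        target = spec.gc_targets[genome_group[gid]]
        gc_targets[gid] = target
        prots = genome_proteins[gid]
        aa_counts: dict[str, float] = {}
        for _, prot, _ in prots:
            for aa in prot:
                aa_counts[aa] = aa_counts.get(aa, 0) + 1
        total = sum(aa_counts.values())
        beta = solve_gc_beta(target, {aa: n / total for aa, n in aa_counts.items()})
        cds_nt = [back_translate(prot, beta, rng) for _, prot, _ in prots]
        # spacers compensate codon-sampling noise so the emitted genome GC
        # lands on the target almost exactly
        spacer_len = 60
        n_spacers = len(prots) + 1
        coding_len = sum(len(nt) for nt in cds_nt)
        coding_gc = sum(nt.count("G") + nt.count("C") for nt in cds_nt)
        total_len = coding_len + spacer_len * n_spacers
        gc_needed = int(round(target * total_len)) - coding_gc
        per_spacer = np.full(n_spacers, gc_needed // n_spacers)
        per_spacer[: gc_needed % n_spacers] += 1
        seq_parts: list[str] = []
        cds_records: list[CdsRecord] = []
        pos = 0
        for k, (locus, prot, _) in enumerate(prots):
            spacer = _dna_with_gc_count(spacer_len, int(per_spacer[k]), rng)
            seq_parts.append(spacer)
            pos += len(spacer)
            nt = cds_nt[k]
            strand = "+" if k % 2 == 0 else "-"
            genomic = nt if strand == "+" else _revcomp(nt)
            start = pos + 1
            end = pos + len(nt)
            seq_parts.append(genomic)
            pos = end
            cds_records.append(
                CdsRecord(locus_id=locus, start=start, end=end, strand=strand,
                          nt_seq=nt, aa_seq=translate(nt))
            )
        seq_parts.append(_dna_with_gc_count(spacer_len, int(per_spacer[-1]), rng))
        if target < spec.gc_trna_threshold:
            lo, hi = spec.trna_range_low_gc
            trna = int(rng.integers(lo, hi + 1))
        else:
            trna = 0
        trna_counts[gid] = trna
        genomes.append(
            PhageGenome(id=gid, sequence="".join(seq_parts), cds=cds_records,
                        trna_count=trna)
        )

    # host range
    if spec.lysotypes is not None:
        lysotypes = dict(zip(genome_ids, spec.lysotypes))
    else:
        lysotypes = {
            gid: LYSOTYPE_CLASSES[genome_group[gid] % len(LYSOTYPE_CLASSES)]
            for gid in genome_ids
        }
    isolates = [f"iso{k + 1:02d}" for k in range(spec.n_isolates)]
    meso = isolates[-spec.n_mesophilic :] if spec.n_mesophilic else []
    psychro = [i for i in isolates if i not in meso]
    scale = spec.n_isolates / 65.0
    breadth_bounds = {
        "narrow": (1, max(1, int(np.floor(4 * scale)))),
        "intermediate": (max(1, int(np.ceil(10 * scale))), max(1, int(np.floor(30 * scale)))),
        "broad": (int(np.ceil(45 * scale)), len(psychro)),
    }
    raw = pd.DataFrame("none", index=genome_ids, columns=isolates, dtype=object)
    # phages of one lysotype class draw nested sensitive sets from a
    # class-specific isolate ordering, so host-range patterns cluster by
    # class (breadth alone carries no pattern signal)
    class_order = {
        cls: list(rng.permutation(psychro)) for cls in LYSOTYPE_CLASSES
    }
    sensitive: dict[str, list[str]] = {}
    for gid in genome_ids:
        lo, hi = breadth_bounds[lysotypes[gid]]
        # draw from the central half of the class band: within-class
        # breadth spread stays below the between-class pattern gaps
        lo2, hi2 = lo + (hi - lo) // 4, hi - (hi - lo) // 4
        b = min(int(rng.integers(lo2, hi2 + 1)), len(psychro))
        chosen = class_order[lysotypes[gid]][:b]
        for iso in chosen:
            raw.loc[gid, iso] = str(int(rng.integers(3, 8)))
        sensitive[gid] = sorted(chosen)
    # plant exception cells on phages whose lysotype class survives the
    # extra sensitive isolate (the class bands have gaps between them)
    from .hostrange import assign_lysotype_group

    stable = [
        gid for gid in genome_ids
        if assign_lysotype_group(len(sensitive[gid]) + spec.mesophilic_exceptions,
                                 spec.n_isolates) == lysotypes[gid]
    ] or genome_ids
    for _ in range(spec.mesophilic_exceptions):
        gid = stable[int(rng.integers(len(stable)))]
        iso = meso[int(rng.integers(len(meso)))]
        if raw.loc[gid, iso] == "none":
            raw.loc[gid, iso] = str(int(rng.integers(3, 8)))
            sensitive[gid] = sorted(sensitive[gid] + [iso])
    isolate_meta = pd.DataFrame(
        {
            "isolate_id": isolates,
            "subspecies": ["salmonicida"] * len(psychro) + ["pectinolytica"] * len(meso),
            "lifestyle": ["psychrophilic"] * len(psychro) + ["mesophilic"] * len(meso),
        }
    )

    # growth curves
    growth_params = (
        spec.growth_params
        if spec.growth_params is not None
        else tuple((float(rng.integers(2, 8)), float(rng.integers(140, 151))) for _ in genome_ids)
    )
    growth_rows = []
    gp: dict[str, dict[str, float]] = {}
    for gid, (burst, latent) in zip(genome_ids, growth_params):
        t, titer = generate_growth_curve(
            burst, latent, noise_cv=0.0, seed=int(rng.integers(2**31))
        )
        gp[gid] = {"burst_size": burst, "latent_min": latent}
        for tt, yy in zip(t, titer):
            growth_rows.append({"phage_id": gid, "time_min": tt, "pfu_ml": yy})

    # -------- write files
    paths = {
        "genomes": outdir / "genomes.fasta",
        "annotations": outdir / "annotations.tsv",
        "cohort": outdir / "cohort.tsv",
        "hostrange": outdir / "hostrange.tsv",
        "isolates": outdir / "isolates.tsv",
        "growth": outdir / "growth.tsv",
        "terminase": outdir / "terminase.fasta",
        "terminase_refs": outdir / "terminase_refs.fasta",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_genomes(genomes, paths["genomes"], paths["annotations"])
    cohort_rows = [
        {
            "genome_id": g.id,
            "genome_size_bp": g.length_bp,
            "cds_count": len(g.cds),
            "trna_count": g.trna_count,
            "gc_percent": round(g.gc_percent, 2),
            "integrase": "no",
        }
        for g in genomes
    ]
    pd.DataFrame(cohort_rows).to_csv(paths["cohort"], sep="\t", index=False)
    raw.to_csv(paths["hostrange"], sep="\t", index_label="phage_id")
    isolate_meta.to_csv(paths["isolates"], sep="\t", index=False)
    pd.DataFrame(growth_rows).to_csv(paths["growth"], sep="\t", index=False)
    with open(paths["terminase"], "w") as fh:
        for gid in genome_ids:
            fh.write(f">{gid}\n{terminases[gid]}\n")
    with open(paths["terminase_refs"], "w") as fh:
        for g in range(spec.n_groups):
            for r in range(2):
                ref = mutate_protein(terminase_anc[g], spec.divergence_within_group, rng)
                fh.write(f">ref_g{g + 1}_{r + 1}|{packaging_labels[g]}\n{ref}\n")

    truth = GroundTruth(
        genome_group=genome_group,
        cluster_members=cluster_members,
        packaging={gid: packaging_labels[genome_group[gid]] for gid in genome_ids},
        gc_targets=gc_targets,
        trna_counts=trna_counts,
        lysotypes=lysotypes,
        sensitive_isolates=sensitive,
        growth_params=gp,
    )
    paths["ground_truth"].write_text(truth.to_json())
    return paths, truth


def evolve_codon_sequences(
    n_seqs: int,
    n_codons: int,
    subs_per_seq: int,
    omega: float = 1.0,
    seed: int = 0,
) -> dict[str, str]:
    """Codon sequences diverged independently from one random ancestor.

    Substitutions are proposed as uniform random single-nucleotide changes
    (stop-creating proposals rejected); nonsynonymous proposals are
    accepted with probability min(1, omega) and synonymous ones with
    min(1, 1/omega), so omega > 1 plants a nonsynonymous excess and
    omega = 1 is neutral.
    """
    rng = np.random.default_rng(seed)
    sense = sorted(c for c in _TABLE.forward_table)
    ancestor = [sense[rng.integers(len(sense))] for _ in range(n_codons)]
    p_non = min(1.0, omega)
    p_syn = min(1.0, 1.0 / omega)
    out = {}
    for s in range(n_seqs):
        seq = list(ancestor)
        applied = 0
        while applied < subs_per_seq:
            k = int(rng.integers(n_codons))
            pos = int(rng.integers(3))
            base = "ACGT"[rng.integers(4)]
            codon = seq[k]
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if mut in _TABLE.stop_codons:
                continue
            syn = _TABLE.forward_table[codon] == _TABLE.forward_table[mut]
            accept = p_syn if syn else p_non
            if rng.random() < accept:
                seq[k] = mut
                applied += 1
        out[f"seq{s + 1}"] = "".join(seq)
    return out


_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def generate_growth_curve(
    burst: float,
    latent_min: float,
    sampling_min: tuple[float, float, float] = (0.0, 210.0, 30.0),
    rise_half_width: float = 10.0,
    base_titer: float = 1e4,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Step-like one-step growth curve.

    Pre-burst plateau at ``base_titer``, post-burst plateau at
    ``base_titer * burst``, log-linear rise centered on ``latent_min``.
    The two rise boundary times are included as sample points (regular
    grid points falling inside the rise are dropped), so a noise-free
    curve lets the estimator recover both parameters exactly.
    Noise is multiplicative lognormal with the given CV.
    """
    if burst < 1:
        raise ValueError("burst must be >= 1")
    start, stop, step = sampling_min
    grid = list(np.arange(start, stop + 1e-9, step))
    t_a, t_b = latent_min - rise_half_width, latent_min + rise_half_width
    times = sorted(
        {round(t, 6) for t in grid if t <= t_a or t >= t_b} | ({t_a, t_b} if burst > 1 else set())
    )
    t = np.array(times)
    lo = np.log10(base_titer)
    hi = np.log10(base_titer * burst)
    logy = np.where(
        t <= t_a, lo, np.where(t >= t_b, hi, lo + (hi - lo) * (t - t_a) / (t_b - t_a))
    )
    y = 10.0**logy
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log(1 + noise_cv**2))
        y = y * rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=len(y))
    return t, y
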