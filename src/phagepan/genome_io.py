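"""Reading, writing and basic statistics for phage genomes.

Genomes are represented as :class:`PhageGenome` records holding the raw
sequence plus extracted CDS features. Coordinates are 1-based inclusive
(GenBank convention) on all public interfaces; translation uses the
bacterial genetic code (NCBI table 11).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

GENETIC_CODE_TABLE = 11
START_CODONS = ("ATG", "GTG", "TTG")
DEFAULT_SIZE_BOUNDS = (100_000, 200_000)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class GenomeParseError(ValueError):
    """Malformed input file (names file and offending record)."""


class GenomeValidationError(ValueError):
    """Internally inconsistent genome (e.g. CDS outside the sequence)."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt_seq: str, table: int = GENETIC_CODE_TABLE) -> str:
    """Conceptual translation, trimming the terminal stop if present."""
    aa = str(Seq(nt_seq).translate(table=table))
    return aa[:-1] if aa.endswith("*") else aa


@dataclass(frozen=True)
class CdsRecord:
    """One protein-coding feature with 1-based inclusive coordinates."""

    locus_id: str
    start: int
    end: int
    strand: str
    nt_seq: str
    aa_seq: str
    product: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise GenomeValidationError(f"{self.locus_id}: strand must be '+' or '-'")
        if not (1 <= self.start <= self.end):
            raise GenomeValidationError(f"{self.locus_id}: bad interval {self.start}..{self.end}")


@dataclass
class PhageGenome:
    id: str
    sequence: str
    cds: list[CdsRecord] = field(default_factory=list)
    trna_count: int = 0
    integrase_flag: str = "no"
    family: str | None = None

    def __post_init__(self):
        for c in self.cds:
            if c.end > len(self.sequence):
                raise GenomeValidationError(
                    f"genome {self.id}: CDS {c.locus_id} at {c.start}..{c.end} "
                    f"exceeds sequence length {len(self.sequence)}"
                )

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    @property
    def gc_percent(self) -> float:
        return gc_content(self.sequence)

    def proteins(self) -> dict[str, str]:
        return {c.locus_id: c.aa_seq for c in self.cds}


def gc_content(seq: str) -> float:
    """GC percentage of ``seq``; N bases are excluded entirely."""
    if not seq:
        raise GenomeValidationError("gc_content of empty sequence is undefined")
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    acgt = gc + s.count("A") + s.count("T")
    if acgt == 0:
        raise GenomeValidationError("gc_content undefined: no unambiguous bases")
    return 100.0 * gc / acgt


def extract_cds_seq(sequence: str, start: int, end: int, strand: str) -> str:
    sub = sequence[start - 1 : end]
    return reverse_complement(sub) if strand == "-" else sub


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns genome_id, locus_id, start, end, strand[, product]."""
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "locus_id": str})
    required = {"genome_id", "locus_id", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise GenomeParseError(f"{path}: annotation table missing columns {sorted(missing)}")
    if "product" not in df.columns:
        df["product"] = ""
    return df


def read_genomes(
    fasta_paths: Sequence[str | Path],
    annotation_path: str | Path | None = None,
    fmt: str = "fasta",
    cohort: pd.DataFrame | None = None,
) -> list[PhageGenome]:
    """Load genomes from FASTA (+ optional annotation table) or GenBank files.

    With ``fmt='genbank'`` CDS and tRNA features are taken from each file.
    With ``fmt='fasta'`` CDS features come from ``annotation_path``; tRNA
    counts and integrase flags can be merged in from a ``cohort`` table.
    """
    genomes: list[PhageGenome] = []
    if fmt == "genbank":
        for p in fasta_paths:
            for rec in SeqIO.parse(str(p), "genbank"):
                genomes.append(_genome_from_genbank(rec, p))
    elif fmt == "fasta":
        ann = read_annotation_table(annotation_path) if annotation_path is not None else None
        for p in fasta_paths:
            for rec in SeqIO.parse(str(p), "fasta"):
                seq = str(rec.seq).upper()
                if not seq:
                    raise GenomeParseError(f"{p}: record {rec.id} has an empty sequence")
                cds = []
                if ann is not None:
                    rows = ann[ann["genome_id"] == rec.id]
                    for row in rows.itertuples():
                        start, end = int(row.start), int(row.end)
                        if not (1 <= start <= end <= len(seq)):
                            raise GenomeValidationError(
                                f"{p}: CDS {row.locus_id} at {start}..{end} "
                                f"outside genome {rec.id} (1..{len(seq)})"
                            )
                        nt = extract_cds_seq(seq, start, end, row.strand)
                        cds.append(
                            CdsRecord(
                                locus_id=row.locus_id,
                                start=start,
                                end=end,
                                strand=row.strand,
                                nt_seq=nt,
                                aa_seq=translate(nt),
                                product=str(row.product),
                            )
                        )
                genomes.append(PhageGenome(id=rec.id, sequence=seq, cds=cds))
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if cohort is not None:
        meta = cohort.set_index("genome_id")
        for g in genomes:
            if g.id in meta.index:
                row = meta.loc[g.id]
                g.trna_count = int(row.get("trna_count", g.trna_count))
                g.integrase_flag = str(row.get("integrase", g.integrase_flag))
    return genomes


def _genome_from_genbank(rec, path) -> PhageGenome:
    seq = str(rec.seq).upper()
    cds = []
    trna = 0
    for i, feat in enumerate(rec.features):
        if feat.type == "tRNA":
            trna += 1
        elif feat.type == "CDS":
            start = int(feat.location.start) + 1
            end = int(feat.location.end)
            strand = "-" if feat.location.strand == -1 else "+"
            nt = extract_cds_seq(seq, start, end, strand)
            locus = feat.qualifiers.get("locus_tag", [f"{rec.id}_cds{i}"])[0]
            product = feat.qualifiers.get("product", [""])[0]
            cds.append(
                CdsRecord(
                    locus_id=locus, start=start, end=end, strand=strand,
                    nt_seq=nt, aa_seq=translate(nt), product=product,
                )
            )
    return PhageGenome(id=rec.id, sequence=seq, cds=cds, trna_count=trna)


def write_genomes(genomes: Iterable[PhageGenome], fasta_path: str | Path,
                  annotation_path: str | Path | None = None, width: int = 60) -> None:
    """Write multi-FASTA (wrapped) and optionally the annotation TSV."""
    with open(fasta_path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i : i + width] + "\n")
    if annotation_path is not None:
        rows = [
            {"genome_id": g.id, "locus_id": c.locus_id, "start": c.start,
             "end": c.end, "strand": c.strand, "product": c.product}
            for g in genomes for c in g.cds
        ]
        pd.DataFrame(rows, columns=["genome_id", "locus_id", "start", "end", "strand", "product"]) \
            .to_csv(annotation_path, sep="\t", index=False)


def find_orfs(seq: str, min_aa: int = 30) -> list[CdsRecord]:
    """Naive ORF caller for bare FASTA input.

    Scans both strands for ATG/GTG/TTG..stop open reading frames of at
    least ``min_aa`` codons (table 11) and keeps a non-overlapping subset
    chosen greedily longest-first.
    """
    if min_aa < 10:
        raise ValueError("min_aa must be >= 10")
    stops = CodonTable.unambiguous_dna_by_id[GENETIC_CODE_TABLE].stop_codons
    n = len(seq)
    candidates: list[tuple[int, int, str]] = []  # (start0, end0 exclusive, strand)
    for strand, s in (("+", seq.upper()), ("-", reverse_complement(seq.upper()))):
        for frame in range(3):
            i = frame
            open_at = None
            while i + 3 <= n:
                codon = s[i : i + 3]
                if open_at is None:
                    if codon in START_CODONS:
                        open_at = i
                elif codon in stops:
                    if (i + 3 - open_at) // 3 - 1 >= min_aa:
                        candidates.append((open_at, i + 3, strand))
                    open_at = None
                i += 3
    # map - strand coordinates back to forward strand
    mapped = []
    for a, b, strand in candidates:
        if strand == "+":
            mapped.append((a, b, strand))
        else:
            mapped.append((n - b, n - a, strand))
    mapped.sort(key=lambda t: (-(t[1] - t[0]), t[0], t[2]))
    taken: list[tuple[int, int, str]] = []
    occupied = np.zeros(n, dtype=bool)
    for a, b, strand in mapped:
        if not occupied[a:b].any():
            occupied[a:b] = True
            taken.append((a, b, strand))
    taken.sort()
    out = []
    for k, (a, b, strand) in enumerate(taken, start=1):
        nt = extract_cds_seq(seq, a + 1, b, strand)
        out.append(
            CdsRecord(locus_id=f"orf{k:04d}", start=a + 1, end=b, strand=strand,
                      nt_seq=nt, aa_seq=translate(nt))
        )
    return out


def size_class(length_bp: int, bounds: tuple[int, int] = DEFAULT_SIZE_BOUNDS) -> str:
    if length_bp <= 0:
        raise GenomeValidationError("genome length must be positive")
    if length_bp < bounds[0]:
        return "small"
    if length_bp < bounds[1]:
        return "medium"
    return "large"


def load_cohort_table(path: str | Path | None = None) -> pd.DataFrame:
    """Read a cohort metadata TSV; defaults to the bundled 18-phage table."""
    if path is None:
        path = importlib.resources.files("phagepan.data") / "asal_cohort.tsv"
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    required = {"genome_id", "genome_size_bp", "cds_count", "trna_count", "gc_percent", "integrase"}
    missing = required - set(df.columns)
    if missing:
        raise GenomeParseError(f"{path}: cohort table missing columns {sorted(missing)}")
    df["size_class"] = [size_class(s) for s in df["genome_size_bp"]]
    return df


def summarize_by_class(
    table: pd.DataFrame,
    column: str,
    grouping: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, dict[str, float | int | None]]:
    """Per-group mean / sample SD (n-1) / n for one cohort-table column.

    ``grouping`` maps group name -> genome ids; by default the table's
    ``size_class`` column defines the partition. A singleton group reports
    SD as None (undefined), not zero.
    """
    if grouping is None:
        grouping = {
            cls: list(sub["genome_id"]) for cls, sub in table.groupby("size_class", sort=False)
        }
    indexed = table.set_index("genome_id")
    out: dict[str, dict[str, float | int | None]] = {}
    for name, ids in grouping.items():
        if len(ids) == 0:
            raise ValueError(f"group {name!r} is empty")
        vals = indexed.loc[list(ids), column].to_numpy(dtype=float)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
        out[name] = {"mean": float(np.mean(vals)), "sd": sd, "n": len(vals)}
    return out
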