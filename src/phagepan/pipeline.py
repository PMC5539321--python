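"""End-to-end orchestration: run every analysis stage on one cohort and
emit per-stage outputs plus a deterministic summary JSON."""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, codon, genome_io, growth, homology, hostrange, msa, pangenome, phylo, selection

ALL_STAGES = (
    "io", "homology", "pangenome", "classify", "codon_usage",
    "phylo_packaging", "selection", "host_range", "growth",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    genomes_fasta: str = "genomes.fasta"
    annotations: str = "annotations.tsv"
    cohort: str = "cohort.tsv"
    hostrange: str | None = "hostrange.tsv"
    isolates: str | None = "isolates.tsv"
    growth: str | None = "growth.tsv"
    terminase: str | None = "terminase.fasta"
    terminase_refs: str | None = "terminase_refs.fasta"
    outdir: str = "phagepan_out"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    n_boot: int = 1000
    scales: tuple[float, ...] = classify.DEFAULT_SCALES
    au_threshold: float = 0.95
    mcl_inflation: float = 1.5
    min_coverage: float = homology.DEFAULT_COVERAGE
    selection_n_boot: int = 200
    selection_max_clusters: int = 5
    packaging_max_steps: int = 6
    linkage: str = "average"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        bad = [s for s in cfg.stages if s not in ALL_STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        return cfg


def _round_floats(obj, nd: int = 6):
    if isinstance(obj, float):
        return round(obj, nd)
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, nd) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), nd)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: PipelineConfig, log=None) -> dict:
    """Execute the configured stages in dependency order.

    Returns the summary dict (also written to ``<outdir>/summary.json``).
    Stage outputs are written under ``outdir``; a stage failure raises
    :class:`PipelineError` after flushing the partial summary.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_seed": config.seed, "stages_run": []}
    state: dict = {}

    def _log(msg):
        if log is not None:
            log(msg)

    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](config, state, summary, out)
        except Exception as exc:  # pragma: no cover - error path
            (out / "summary.json").write_text(
                json.dumps(_round_floats(summary), sort_keys=True, indent=1)
            )
            raise PipelineError(stage, exc) from exc
        summary["stages_run"].append(stage)
        _log(f"[{stage}] done in {time.perf_counter() - t0:.1f}s")

    (out / "summary.json").write_text(
        json.dumps(_round_floats(summary), sort_keys=True, indent=1) + "\n"
    )
    return summary


# ------------------------------------------------------------------ stages

def _stage_io(cfg: PipelineConfig, state, summary, out: Path):
    cohort = genome_io.load_cohort_table(cfg.cohort)
    genomes = genome_io.read_genomes(
        [cfg.genomes_fasta], annotation_path=cfg.annotations, cohort=cohort
    )
    state["genomes"] = genomes
    state["cohort"] = cohort
    agg_gc = genome_io.summarize_by_class(cohort, "gc_percent")
    agg_size = genome_io.summarize_by_class(cohort, "genome_size_bp")
    summary["io"] = {
        "n_genomes": len(genomes),
        "total_cds": int(cohort["cds_count"].sum()),
        "size_classes": sorted(cohort["size_class"].unique()),
        "gc_by_class": agg_gc,
        "size_by_class": agg_size,
    }


def _stage_homology(cfg: PipelineConfig, state, summary, out: Path):
    genomes = state["genomes"]
    hits = homology.all_vs_all(genomes, min_coverage=cfg.min_coverage)
    all_loci = [f"{g.id}:{l}" for g in genomes for l in g.proteins()]
    edges = homology.bbh_graph(hits)
    cog = homology.cog_triangles(edges, all_loci)
    mcl = homology.mcl_cluster(hits, all_loci, inflation=cfg.mcl_inflation)
    inter = homology.intersect_clusterings(cog, mcl)
    idm = homology.identity_matrix(genomes, hits)
    idm.to_csv(out / "identity_matrix.tsv", sep="\t")
    homology.write_clusters_tsv(inter, out / "clusters.tsv")
    state["hits"] = hits
    state["clusters"] = inter
    summary["homology"] = {
        "n_hits": len(hits),
        "n_cog_clusters": len(cog),
        "n_mcl_clusters": len(mcl),
        "n_intersection_clusters": len(inter),
    }


def _stage_pangenome(cfg: PipelineConfig, state, summary, out: Path):
    genomes = [g.id for g in state["genomes"]]
    matrix = pangenome.build_matrix(state["clusters"], genomes)
    pangenome.write_matrix_tsv(matrix, out / "pan_matrix.tsv")
    state["matrix"] = matrix
    core_all = pangenome.core_genome(matrix, genomes)
    summary["pangenome"] = {
        "n_clusters": int(matrix.shape[1]),
        "core_all_genomes": sorted(core_all),
    }


def _stage_classify(cfg: PipelineConfig, state, summary, out: Path):
    tree = classify.multiscale_bootstrap(
        state["matrix"], scales=cfg.scales, n_boot=cfg.n_boot,
        linkage=cfg.linkage, seed=cfg.seed,
    )
    groups, subgroups = classify.cut_groups(tree, au_threshold=cfg.au_threshold)
    (out / "tree.nwk").write_text(tree.newick() + "\n")
    pd.DataFrame(
        sorted(groups.items()), columns=["genome_id", "group"]
    ).to_csv(out / "groups.tsv", sep="\t", index=False)
    state["tree"] = tree
    state["groups"] = groups
    summary["classify"] = {
        "groups": dict(sorted(groups.items())),
        "subgroups": dict(sorted(subgroups.items())),
        "n_groups": len(set(groups.values())),
    }


def _stage_codon(cfg: PipelineConfig, state, summary, out: Path):
    profiles = [codon.profile_genome(g) for g in state["genomes"]]
    scores, loadings, evr = codon.pca(profiles, on="rscu")
    scores.to_csv(out / "pca_scores.tsv", sep="\t")
    r, sep, thr = codon.trna_gc_association(state["cohort"])
    outliers = codon.flag_outliers(profiles, scores)
    state["profiles"] = profiles
    summary["codon_usage"] = {
        "pc1_variance": float(evr.iloc[0]),
        "trna_gc_r": r,
        "trna_gc_perfect_separation": bool(sep),
        "trna_gc_threshold": thr,
        "outliers": outliers,
    }


def _stage_phylo(cfg: PipelineConfig, state, summary, out: Path):
    if not cfg.terminase or not cfg.terminase_refs:
        summary["phylo_packaging"] = {"skipped": "no terminase input"}
        return
    from Bio import SeqIO

    queries = {r.id: str(r.seq) for r in SeqIO.parse(cfg.terminase, "fasta")}
    labels = {}
    refs = {}
    for r in SeqIO.parse(cfg.terminase_refs, "fasta"):
        rid, _, strategy = r.id.partition("|")
        refs[rid] = str(r.seq)
        labels[rid] = strategy
    aligned = msa.progressive_align({**queries, **refs})
    pdist = phylo.p_distance_matrix(aligned)
    tree = phylo.nj_tree(pdist)
    (out / "terminase.nwk").write_text(tree.newick() + "\n")
    calls = phylo.infer_packaging(tree, labels, sorted(queries), max_steps=cfg.packaging_max_steps)
    pat = phylo.patristic_matrix(tree)
    ids = list(pat.index)
    ps, pats = [], []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            ps.append(pdist.loc[ids[i], ids[j]])
            pats.append(pat.iloc[i, j])
    slope, r2, saturated = phylo.saturation_test(ps, pats)
    pd.DataFrame(
        [(q, s, c) for q, (s, c) in sorted(calls.items())],
        columns=["phage", "packaging", "confidence"],
    ).to_csv(out / "packaging.tsv", sep="\t", index=False)
    summary["phylo_packaging"] = {
        "calls": {q: s for q, (s, c) in sorted(calls.items())},
        "saturation": {"slope": slope, "r2": r2, "saturated": bool(saturated)},
    }


def _stage_selection(cfg: PipelineConfig, state, summary, out: Path):
    clusters = state["clusters"]
    genomes = {g.id: g for g in state["genomes"]}
    nt_by_locus = {
        (g.id, c.locus_id): c.nt_seq for g in genomes.values() for c in g.cds
    }
    results = []
    eligible = [
        (cid, members) for cid, members in sorted(clusters.clusters.items())
        if len(members) >= 4
    ]
    for cid, members in eligible[: cfg.selection_max_clusters]:
        seqs = {
            f"{gid}:{locus}": nt_by_locus[(gid, locus)]
            for gid, locus in sorted(members)
            if (gid, locus) in nt_by_locus
        }
        if len(seqs) < 4:
            continue
        try:
            aln = selection.codon_align(seqs)
        except selection.SelectionError as exc:
            results.append({"cluster": cid, "error": str(exc)})
            continue
        aln.boundaries = selection.detect_breakpoints(aln)
        for res in selection.cluster_dnds(
            aln, cluster_id=cid, n_boot=cfg.selection_n_boot, seed=cfg.seed
        ):
            results.append(
                {
                    "cluster": cid,
                    "partition": list(res.partition),
                    "dn": res.dn,
                    "ds": res.ds,
                    "p": res.p_value,
                    "positively_selected": res.positively_selected,
                }
            )
    summary["selection"] = {"results": results}


def _stage_hostrange(cfg: PipelineConfig, state, summary, out: Path):
    if not cfg.hostrange or not cfg.isolates:
        summary["host_range"] = {"skipped": "no host-range input"}
        return
    matrix = hostrange.read_hostrange_tsv(cfg.hostrange, cfg.isolates)
    groups = hostrange.lysotype_groups(matrix)
    split = hostrange.lifestyle_split(matrix)
    summary["host_range"] = {
        "breadths": {p: hostrange.breadth(matrix, p) for p in matrix.phages},
        "lysotypes": dict(sorted(groups.items())),
        "lifestyle_split": split,
    }


def _stage_growth(cfg: PipelineConfig, state, summary, out: Path):
    if not cfg.growth:
        summary["growth"] = {"skipped": "no growth input"}
        return
    curves = growth.read_growth_tsv(cfg.growth)
    res = {}
    for pid, curve in sorted(curves.items()):
        est = growth.estimate_burst(curve)
        res[pid] = {
            "burst_size": est.burst_size,
            "latent_min": est.latent_min,
            "flagged": est.flagged,
        }
    summary["growth"] = res


_STAGE_FUNCS = {
    "io": _stage_io,
    "homology": _stage_homology,
    "pangenome": _stage_pangenome,
    "classify": _stage_classify,
    "codon_usage": _stage_codon,
    "phylo_packaging": _stage_phylo,
    "selection": _stage_selection,
    "host_range": _stage_hostrange,
    "growth": _stage_growth,
}
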