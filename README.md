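# phagepan

Comparative genomics of bacteriophage cohorts: pan-genome construction from
all-vs-all protein homology, genome classification with multiscale-bootstrap
AU supports, codon-usage/GC analyses, terminase-based DNA-packaging
inference with saturation assessment, a counting-method positive-selection
scan, host-range lysotyping, and one-step growth kinetics. A
synthetic-cohort generator with full ground truth makes every stage
testable end to end.

## Modules

| module | role |
|---|---|
| `phagepan.genome_io` | FASTA/annotation/GenBank reading, CDS extraction, GC%, size classes, cohort-table aggregates |
| `phagepan.simulate` | synthetic cohorts with planted groups, GC targets, tRNA rule, host ranges, growth curves |
| `phagepan.homology` | Smith–Waterman all-vs-all, BBH graph, COG-triangle + MCL clustering and their intersection, identity matrix, reference screening |
| `phagepan.pangenome` | presence/absence matrix, core genomes, shared-core Venn regions, functional categories |
| `phagepan.classify` | binary distance, deterministic hclust, multiscale-bootstrap AU p-values, AU-threshold group cutting |
| `phagepan.codon` | RSCU, amino-acid composition, covariance PCA, tRNA/GC association, outlier flagging |
| `phagepan.phylo` | p-distances, neighbor joining, patristic distances, saturation test, packaging inference |
| `phagepan.selection` | codon alignment, breakpoint scan, NG86 dN/dS + column-bootstrap test, SNP classification |
| `phagepan.hostrange` | spot-test encoding, breadths/lysotypes, heatmap clustering, covering pairs, lifestyle split |
| `phagepan.growth` | burst size and latent period from one-step growth curves |
| `phagepan.pipeline` / `phagepan.cli` | orchestration and the `phagepan` command |

The per-genome metadata of the 18-phage *Aeromonas salmonicida* cohort
ships as package data (`phagepan/data/asal_cohort.tsv`) and backs the
desk-scale aggregate checks.

## CLI

```bash
# aggregates of the bundled 18-phage table (or any cohort TSV)
phagepan summarize

# generate a synthetic cohort with 3 planted groups
phagepan simulate --outdir cohort/ --seed 1 --groups 3,4,3 --gc 0.56,0.42,0.40

# full pipeline on a cohort directory
phagepan run-all --indir cohort/ --outdir out/ --seed 1 --n-boot 1000
```

`run-all` writes per-stage outputs (`clusters.tsv`, `pan_matrix.tsv`,
`tree.nwk` with AU/BP edge comments, `groups.tsv`, `pca_scores.tsv`,
`packaging.tsv`, …) plus a deterministic `summary.json`. Identical config
and seed give byte-identical summaries. A JSON config file (keys =
`PipelineConfig` fields) can replace the flags via `--config`.

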