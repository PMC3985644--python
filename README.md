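# phylomarkers

Selection and validation of **minimal phylogenetic marker gene sets** from
whole-genome data.

Given per-gene multiple sequence alignments of widespread single-copy genes,
the pipeline:

1. builds a **reference phylogeny** from the concatenation of all genes
   (supermatrix with a partition map);
2. **ranks** each gene by the topological distance (Robinson–Foulds by
   default; normalized RF and nodal distance are alternatives) of its gene
   tree to the reference;
3. concatenates top-ranked genes progressively until the concatenation tree
   reaches a distance cut-off (default 0) — the **initial marker set**;
4. **minimizes** that set by randomized subset sampling (with optional
   restarts and constraining to the initial set) and/or exhaustive subset
   enumeration;
5. **validates** the selected markers on held-out species, both by placing
   one held-out species at a time into the training tree and by
   cross-validating reference vs marker topologies on the hold-out set
   alone.

Upstream of the alignments, an orthology stage reproduces widespread
single-copy gene detection from seed-species BLAST tabular hit tables
(e-value ≤ 1e-5, query coverage > 50 %, single hit per genome, union or
intersection across multiple seeds).

A simulation module generates Yule species trees, gene alignments with
controlled topological discordance (NNI-perturbed gene trees) under an
equal-rates amino-acid model, stratified training/validation splits, and
synthetic hit tables with planted paralogs and losses — so the whole
pipeline is testable with no downloads and planted ground truth.

Built-in tree inference is classical neighbor joining on protein distances
(p or Poisson-corrected), fully deterministic; production runs can delegate
tree building to any external maximum-likelihood engine via a command
template (`tree_build.ExternalEngineBuilder`).

## Command line

A single entry point with subcommands:

```sh
# generate a synthetic benchmark with planted truth
phylomarkers simulate --n-species 24 --n-genes 40 --n-concordant 10 \
    --length-range 2000:2000 --seed 1 --out dataset/

# widespread single-copy genes from BLAST tabular hits
phylomarkers orthologs --hits seedA.hits.tsv --query-lengths seedA.qlens.tsv \
    --seed-species seedA --genomes A,B,C,D --merge-mode union --out groups.tsv

# rank genes against a reference topology
phylomarkers rank --alignments dataset/genes --reference ref.nwk --out ranking.tsv

# select a minimal marker set
phylomarkers select --alignments dataset/genes --measure rf --cutoff 0 \
    --seed 42 --max-iter 100 --out result/

# validate markers on held-out species
phylomarkers validate --markers result/final_set.txt \
    --holdout-alignments holdout/ --mode cross --out validation.json

# topological distances / tree certainty
phylomarkers treedist --measure rf --ref ref.nwk --trees genes/*.nwk --out report.tsv

# full pipeline from one YAML config
phylomarkers run --config pipeline.yaml --out out/
```

Example `pipeline.yaml`:

```yaml
mode: simulated            # or: alignments (+ alignments_dir, tv_split)
seed: 42
simulation:
  n_species: 24
  n_genes: 40
  n_concordant: 10
  gene_length_range: [2000, 2000]
selection:
  measure: rf              # rf | nrf | nodal
  cutoff: 0.0
  max_random_iterations: 100
  restart_rounds: 2
```

`run` writes `reference.nwk`, `ranking.tsv`, `initial_set.txt`,
`final_set.txt`, `trace.tsv`, `validation.json` and a machine-readable
`report.json` under the output directory; identical config + seed produce a
byte-identical report.

## Package layout

| module | contents |
| --- | --- |
| `phylomarkers.phylo_io` | `Tree`, `Alignment`, supermatrix concatenation with partitions, Newick/FASTA/BLAST-tabular IO |
| `phylomarkers.orthology` | single-copy widespread gene filters, multi-seed union/intersection |
| `phylomarkers.tree_build` | protein distances, neighbor joining, external ML engine contract |
| `phylomarkers.tree_compare` | bipartitions, RF / normalized RF, nodal distance, internode & tree certainty |
| `phylomarkers.marker_selection` | ranking, progressive concatenation, random + exhaustive subset search |
| `phylomarkers.validation` | one-species-at-a-time and cross-validation hold-out tests |
| `phylomarkers.simulate` | Yule trees, NNI perturbation, sequence evolution, benchmark + hit-table synthesis |
| `phylomarkers.pipeline` / `phylomarkers.cli` | end-to-end orchestration and the `phylomarkers` CLI |
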