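# fpkmkit

Small-sample group statistics, structure analysis, gene-set enrichment and
cross-species mutability scoring for FPKM expression tables.

The package covers a complete caudate-style transcriptomic workflow on a
gene × sample FPKM matrix with control / AD / PD groups across two
acquisition sessions:

- **`fpkmkit.expression`** — FPKM table and metadata I/O with strict
  validation, expressed-gene filtering, `log2(v + pseudocount)` transform.
- **`fpkmkit.diffexpr`** — per-gene fold changes on raw FPKM group means,
  Mann-Whitney U (exact permutation distribution at combined n ≤ 12
  without ties, normal approximation otherwise), Welch's t, Welch +
  Brown-Forsythe heteroscedastic ANOVA with control-referenced post-hoc
  comparisons, `*`/`**`/`***` star labels at 0.05/0.01/0.005, significant-
  fraction summaries and deterministic p-value/effect-size ranking.
- **`fpkmkit.structure`** — PCA with genes as observations and samples as
  variables (scores on genes, loadings on samples, variance proportions),
  hierarchical clustering of samples with Newick export, and k-cluster
  gene subgroup profiles via a tree cut.
- **`fpkmkit.enrichment`** — weighted Kolmogorov–Smirnov running-sum
  enrichment score with leading edge, gene-sampling permutation null, GMT
  I/O.
- **`fpkmkit.mutability`** — telomere-proximity factor F(i) (< 50 Mb to
  the nearest chromosome end, strict), A+T-content factor F(ii) (> 0.59,
  strict), per-species matching rates, linkage classification at the
  inclusive 50 cM cutoff with 1 cM ≈ 1 Mb scaling, and transcript-size
  conservation flags against a reference panel range.  GFF3 / BED /
  FASTA / TSV input.
- **`fpkmkit.synthetic`** — seeded generators for FPKM matrices with known
  spiked effects and batch structure, genomes with genes at designed
  telomere distances and A+T fractions, and gene-set collections with a
  known enriched set, each with truth records for recovery testing.
- **`fpkmkit.pipeline` / `fpkmkit.cli`** — staged orchestration with a
  YAML config, per-stage checksums in a run manifest, and a JSON + text
  report.

## CLI

```bash
fpkmkit simulate --n-genes 500 --seed 7 --outdir out \
    --spike 0:AD:6.63:down
fpkmkit de --matrix out/fpkm.tsv --metadata out/metadata.tsv \
    --group-b AD --out out/de.tsv
fpkmkit pca --matrix out/fpkm.tsv --outdir out
fpkmkit cluster --matrix out/fpkm.tsv --outdir out --k-gene-clusters 8
fpkmkit enrich --matrix out/fpkm.tsv --metadata out/metadata.tsv \
    --gene-sets sets.gmt --seed 7 --out out/es.tsv
fpkmkit mutability --loci genes.gff3 --chrom-lengths chroms.tsv \
    --fasta genome.fa --outdir out
fpkmkit run config.yaml      # full staged pipeline from a YAML config
fpkmkit report --outdir out  # summarize existing stage outputs
```

Exit codes: 0 success, 2 configuration error, 3 stage error.  Logs go to
stderr only.

A minimal `config.yaml`:

```yaml
outdir: out
seed: 7
stages: [simulate, ingest, diffexpr, structure, enrichment, report]
simulate_options:
  n_genes: 1000
  gene_sets: {n_sets: 10, set_size: 25, enriched_set_fold: 4.0}
enrichment_options: {n_perm: 1000}
```

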