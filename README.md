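# cneloss

Comparative-genomics toolkit for detecting lineage-specific loss of
conserved noncoding elements (CNEs), built around a two-state phylogenetic
HMM and tested end-to-end on synthetic genomes with planted truth.

The pipeline covers:

- **Neutral model fitting** — extraction of fourfold-degenerate (4D) site
  columns from reference CDS annotations and ML fitting of a general
  reversible (GTR) substitution model plus branch lengths by Felsenstein
  pruning (`cneloss.phylo`).
- **Conserved-element calling** — a two-state phylo-HMM (neutral vs a
  rho-scaled conserved model) with per-chromosome rho estimation, Viterbi
  segmentation, exon-sensitivity checks and CNE definition
  (`cneloss.hmm`).
- **Homology search** — self-contained seed-and-extend ungapped local
  search (nucleotide and translated) with collinear HSP chaining; powers
  the CNE rescue search and candidate gene-locus mining
  (`cneloss.search`).
- **Loss calling** — two-stage per-species presence classification
  (alignment coverage ≥ 30%, then homology rescue at E < 1e-10 / ≥ 80%
  identity / ≥ 30% coverage), gap-free syntenic intervals, high-confidence
  unique-loss calls, and ghost-locus scanning between anchor genes
  (`cneloss.loss`).
- **Enrichment** — nearest-TSS assignment within 1 Mb and hypergeometric
  term enrichment with Benjamini–Hochberg FDR (`cneloss.enrich`).
- **Synthetic data** — sequences evolved along a six-taxon tree under the
  GTR model with rho-scaled elements, planted genes (valid ORFs supplying
  4D sites and TSSs), lineage-specific deletions and assembly N-gaps, all
  emitted as standard formats with a truth table (`cneloss.simulate`).
- **Formats** — FASTA / MAF / GFF3 / BED / newick readers and writers with
  a single 0-based half-open coordinate convention (`cneloss.formats`).

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: exhaustive-path
HMM oracles, brute-force pruning oracles, closed-form checks (JC69,
hypergeometric, relative-rate chi-square), simulation recoveries (rho and
branch lengths), chaining oracles, rescue-gate separation, rate-test
type-I calibration, enrichment-null uniformity, and end-to-end loss
recovery on the default fixture.

## CLI

Everything is reachable through one entry point:

```sh
cneloss simulate --out fixtures/ --seed 42        # synthetic data + truth
cneloss fit-neutral --maf fixtures/alignment.maf \
    --gff fixtures/genes.gff3 --tree fixtures/tree.nwk --out model.json
cneloss estimate-rho --maf fixtures/alignment.maf \
    --model model.json --out rho.json
cneloss call-elements --maf fixtures/alignment.maf \
    --model model.json --rho 0.3 --out elements.bed
cneloss classify --cnes cnes.bed --maf fixtures/alignment.maf \
    --genomes fixtures/ --ref Zv9 --out matrix.tsv
cneloss call-losses --matrix matrix.tsv --intervals synteny.tsv \
    --out losses.bed
cneloss enrich --losses losses.bed --gff fixtures/genes.gff3 \
    --terms terms.tsv --out enrichment.tsv
```

or as one reproducible run (simulate → fit → rho → elements → CNEs →
classify → synteny → losses → enrichment, with a checksummed manifest and
`--resume`):

```sh
cneloss run --out run1/ --seed 42
```

The default configuration (six taxa, 500 elements, 50 single-lineage
deletions, 25 planted assembly gaps) is packaged at
`src/cneloss/data/default_config.yaml`.

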