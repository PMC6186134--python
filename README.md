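# panne

Effective population size (Ne), pan-genome, recombination and gene-turnover
analysis for prokaryotic genome collections — with a synthetic-data
generator so the whole pipeline can be validated end-to-end against known
ground truth.

## What it does

Given per-species inputs (codon-aware alignments, a strain tree, a gene
presence/absence matrix, metadata), the pipeline provides:

- **Ortholog families** (`panne.orthologs`): ortholog/paralog calls from
  universal-gene hit tables (median-vs-mean log10 e-value rule), strain QC
  (≥42 of 44 universal orthologs; 4 missing tolerated for *Mycoplasma*),
  near-identical strain dedup (D < 5e-5) and subsampling, best-reciprocal-hit
  family clustering (≥70% identity, ≥80% coverage both ways, transitive
  closure), pan-genome size N_pan, harmonic normalization P = N_pan/α with
  α = Σ_{i=1}^{n−1} 1/i, the 13-most-divergent-strain Ps, and the ≥85% core
  genome with paralog exclusion.
- **Divergence & Ne** (`panne.codon`, `panne.divergence`): NG86 pairwise
  dN/dS with pathway averaging and Jukes–Cantor correction, species means
  over the inclusive 0.1 ≤ dS ≤ 0.3 window, Watterson's θ on strictly
  four-fold degenerate sites, Ne = θ/(2μ), and calibration/inversion of the
  nearly-neutral map dN/dS = Ne·s/(1 − e^(−Ne·s)).
- **Recombination** (`panne.homoplasy`): the h/m homoplasic-allele ratio by
  generalized Fitch/Sankoff parsimony on the strain tree.
- **Gene flux** (`panne.flux`): gain/loss rates by maximum likelihood
  (Poisson-field / infinitely-many-genes model with observability
  correction), ancestral presence posteriors, per-branch gain/loss event
  calls at posterior thresholds 0.2/0.3, turnover T = G/L, per-branch dS/dN
  from marginal ancestral reconstruction on 150 kb core fragments, and the
  per-species Spearman of T vs dS/dN.
- **Comparative statistics** (`panne.compare`): Felsenstein independent
  contrasts, PIC-corrected correlations, |Ne_i − Ne_j| vs phylogenetic
  distance with Mantel permutations, lifestyle Wilcoxon contrasts, PCA and
  the Spearman correlation network.
- **Synthetic data** (`panne.simulate`): seeded coalescent genealogies,
  MG94-like codon evolution with controlled ω and κ, gene-content histories
  with full event logs, recombination tract injection, paralog-contaminated
  hit tables, Brownian traits, and `generate_dataset` which writes complete
  on-disk species datasets plus ground truth.

## CLI

One executable with subcommands:

```bash
panne simulate  --config cfg.json --out data/ --seed 1
panne orthologs --input data/species000/hits.tsv --output calls.tsv
panne pangenome --input data/species000/families.tsv --output pan.tsv
panne divergence --input data/species000/universal.aln.fasta --output div.tsv
panne ne        --input data/species000 --output ne.tsv
panne homoplasy --aln data/species000/universal.aln.fasta \
                --tree data/species000/tree.nwk --output hm.tsv
panne flux      --tree data/species000/tree.nwk \
                --matrix data/species000/families.tsv \
                --core-aln data/species000/core.aln.fasta --output flux.tsv
panne compare   --table traits.tsv --tree species.nwk --output cmp
```

Species directory layout (written by `simulate`, read by `ne`):
`universal.aln.fasta`, `core.aln.fasta`, `tree.nwk`, `families.tsv`,
`metadata.txt` (`key: value` lines), optional `hits.tsv`. All tabular
output is UTF-8 TSV with `NA` for missing values. Commands exit nonzero
with a one-line `category: message` on failure.

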