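# hybdiag

Diagnostic-site hybrid detection from mitochondrial and nuclear sequence
alignments.

Given pre-aligned FASTA files for one mitochondrial and one or more nuclear
loci, plus a sample metadata table assigning each specimen to one of two
parental lineages or to the query (putative hybrid) group, `hybdiag`:

* collapses sequences into haplotypes and emits a variable-site table;
* discovers **fixed interspecific substitutions** (columns monomorphic for
  different unambiguous bases in the two parental groups);
* scores each query for **heterozygosity** at those diagnostic sites (a
  two-base IUPAC code covering exactly the two parental states) and
  classifies it as `f1_consistent`, `parental_A_like`, `parental_B_like`
  or `inconclusive`;
* assigns each query's mitochondrial sequence to the nearest parental
  haplotype, which — by maternal inheritance of mtDNA — identifies the
  **maternal parent** of an F1-consistent hybrid;
* phases **cloned allele sequences** of heterozygous samples into the two
  parental allele groups and checks them against the direct-sequencing
  consensus;
* computes uncorrected **p-distances** (overall and between-group means)
  with a seeded column-bootstrap standard error.

A fully seeded synthetic-data generator produces two-lineage datasets with
planted diagnostic sites, skewed within-lineage haplotype frequencies, F1
hybrids, and per-gene clone sets — together with a machine-readable ground
truth, so the whole pipeline is testable offline. Packaged reference
fixtures (`table2_coi`, `paper_full`) reconstruct a published 30-specimen
test case exactly.

## CLI

```sh
# materialize the packaged reference dataset
hybdiag fixture paper_full --out fx

# run the full analysis
hybdiag run \
    --locus COI=fx/COI.fasta --locus Wg=fx/Wg.fasta \
    --locus RPS5=fx/RPS5.fasta --locus CaATP=fx/CaATP.fasta \
    --mito COI --metadata fx/metadata.tsv --clones fx/clones \
    --seed 1 --out reports \
    --prefix parental_A=Ah --prefix parental_B=Cl --prefix query=AhCl

# simulate a synthetic dataset with ground truth, then score the pipeline
hybdiag simulate --seed 7 --out sim
hybdiag score --data sim
```

`run` writes TSV reports (haplotype table, variable sites, diagnostic
sites, distance statistics, hybrid verdicts, clone phasing) plus the
concatenated nuclear alignment with a 1-based per-locus offset map. Every
report begins with a `# config:` line echoing the resolved configuration;
identical inputs and seeds give byte-identical reports. Options can also be
supplied via `--config config.yaml` (same keys as the flags).

Metadata TSV columns: `sample_id`, `group` (one of `parental_A`,
`parental_B`, `query`), `taxon_label`, `locality`.

## Library use

```python
from hybdiag import (
    read_alignment, read_metadata, collapse_haplotypes,
    find_fixed_differences, zygosity_profile, assign_mito_lineage,
    call_hybrid, phase_clones, mean_p_distance,
)
```

All coordinates are 1-based and inclusive. Sequence comparisons use
pairwise deletion: gaps and ambiguity codes never count as matches or
mismatches, and fixedness is absolute — a single discordant or ambiguous
parental base disqualifies a column as diagnostic.
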