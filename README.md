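# p335

Classification toolkit for lactococcal P335-group bacteriophages.

The package implements the computational side of a P335 phage
classification workflow end to end:

- **genome_io** — FASTA/GenBank/tabular ORF I/O, a simple ORF finder,
  bacterial-code translation and genome statistics.
- **proteome_similarity** — all-against-all Smith–Waterman protein
  comparison (BLOSUM62, affine gaps, Karlin–Altschul E-values) with the
  classification cut-offs E ≤ 1e-4, identity > 50 %, coverage ≥ 50 % of
  both sequences, plus bidirectional-best-hit extraction.
- **mcl_clustering** — from-scratch Markov clustering of the protein
  similarity graph into families, and phage grouping by Dice similarity
  of shared-family profiles.
- **adhesion_typer** — locates the adhesion module (tape measure protein
  through to the lysis cassette), assigns component roles
  (TMP/Dit/Tal/BppU/BppA/BppL/RBP, including fused Tal-RBPs), classifies
  the baseplate architecture by size bands and types the
  receptor-binding protein into sub-groups I–IV, flagging phages whose
  proteome group and RBP sub-group disagree.
- **insilico_pcr** — single-pair and multiplex PCR simulation with the
  seven-pair P335 typing panel (expected products 1002/554/268/412/128/
  784 bp plus an unsized BppU-detecting pair) and the CWPS A/B/C strain
  typing scheme (442/183/686 bp with an 891 bp control).
- **phenotype_stats** — plaque-count titres with exact Poisson CIs,
  efficiency-of-plaquing with censoring-aware calcium-dependence calls
  (≥ 4-log reduction), antibody-neutralisation tiers and host-range ×
  CWPS cross-tabulation.
- **synthetic_data** — generator of fixture phage genomes with planted
  ground truth (sub-group architectures, diverged protein families,
  primer sites at exact spacings, Poisson plaque counts, Bernoulli host
  ranges) so the entire pipeline is testable offline.
- **pipeline / cli** — orchestration and the `p335` command.

## CLI

```sh
# generate a synthetic cohort with truth records
p335 simulate --outdir sim --seed 3 --per-subgroup 2 --chimera

# full classification (grouping + adhesion typing + PCR typing)
p335 classify --genomes sim/genomes.fasta --annotations sim/annotations --out report

# in-silico PCR / batch survey
p335 pcr --genome phage.fasta --panel src/p335/data/p335_primers.yaml
p335 survey --genomes genomes_dir/ --out survey.tsv

# phenotype statistics
p335 eop --plaques plaques.tsv
p335 crosstab --matrix hostrange.tsv --types strain_types.tsv
```

Reference and primer panels ship as editable text files under
`src/p335/data/` (panel FASTA + YAML thresholds, primer YAML).

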