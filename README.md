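# mitobarcode

DNA-barcode diversity statistics and comparative mitogenomics for
insect COI surveys.

Species surveys of insect pests routinely combine two kinds of
mitochondrial evidence: the ~650-bp COI barcode, used to delimit and
identify species through intra- versus interspecific divergence, and
the complete mitogenome, whose composition, codon usage and gene
arrangement place species in a comparative context. The analyses behind
such surveys are usually scattered across half a dozen GUI tools
(diversity estimators, distance calculators, network builders, codon
usage tables, repeat finders), which makes them hard to script and
harder to verify. `mitobarcode` implements the full chain as one tested
Python library with a CLI, plus seeded synthetic-data generators so
every stage can be checked against known ground truth without any
downloads.

## What it computes

**Barcode diversity.** For each species with *n* sequences and
haplotype frequencies *p&#7522;*:

- haplotype number *k* and segregating (polymorphic) site count *S*;
- haplotype diversity *H* = *n*(1 − Σ*p&#7522;*²)/(*n* − 1), with Nei's
  (1987) sampling variance for the reported SD;
- nucleotide diversity π, the mean pairwise proportion of differing
  sites, with a seeded bootstrap SD;
- uncorrected *p*-distances and Kimura 2-parameter distances
  *d* = −½ ln[(1 − 2*P* − *Q*)√(1 − 2*Q*)], where *P* and *Q* are the
  transition and transversion proportions;
- per-species intraspecific maxima and pairwise interspecific ranges,
  with a conspecificity screen (default flag threshold 3%, warning zone
  2–3%) and a barcode-gap check.

**Haplotype networks.** Median-joining networks (Bandelt–Forster–Röhl):
the ε-relaxed minimum spanning network over observed haplotypes,
augmented with quasi-median (Steiner) vectors where they shorten the
network, with obsolete inferred nodes pruned. Exports GML and DOT.

**Clustering and monophyly.** Neighbor-joining trees from K2P matrices
with a column-resampling bootstrap, Newick output with supports, and
per-species monophyly verdicts after rooting on a declared outgroup.
This is a deliberate distance-based surrogate for ML/Bayesian
inference: the monophyly question needs bipartitions, not optimal
branch lengths.

**Mitogenome statistics.** On annotated circular genomes (GenBank
flatfiles): base composition with AT skew = (A − T)/(A + T) and GC skew
= (G − C)/(G + C) per gene and aggregate; start/stop codon
classification under the invertebrate mitochondrial code (table 5),
including incomplete T/TA stops; relative synonymous codon usage
(RSCU); gene overlap and intergenic spacer accounting with circular
closure; Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor correction; and a
deterministic tandem-repeat scan for the AT-rich control region.

**Synthetic data.** Seeded generators for (i) multi-species barcode
sets on a star phylogeny with a planted divergence gap and
transition/transversion bias, and (ii) annotated mitogenomes with the
canonical 37-gene arthropod arrangement (23 majority-strand, 14
minority-strand genes), planted A+T content, codon bias, start/stop
codons, overlaps/spacers and control-region repeats — each with a truth
table listing every planted statistic.

## Worked example

Simulate a three-species barcode survey and run the full report:

```sh
mitobarcode simulate-barcodes --n-species 3 --n-per-species 8 --seed 42 --outdir sim
mitobarcode barcode-report sim/barcodes.fasta \
    --species-map sim/species_map.tsv --bootstrap-reps 200 --seed 42 \
    --outdir report
```

`report/diversity_summary.tsv` then contains:

```
species             n  k  S   H       H_sd    pi        pi_sd
Simulitingis alpha  8  7  20  0.9643  0.0772  0.009980  0.002377
Simulitingis beta   8  8  9   1.0000  0.0625  0.004847  0.000871
Simulitingis gamma  8  8  15  1.0000  0.0625  0.007485  0.001211
```

Species alpha has 7 haplotypes among 8 sequences and 20 polymorphic
sites; *H* near 1 means almost every specimen carries its own
haplotype, while π ≈ 0.010 says two random alpha sequences differ at
about 1% of sites. A monomorphic species (*k* = 1) would print `n.a.`
for *H* and π. The divergence tables show the planted barcode gap —
intraspecific maxima of 0.8–2.0% against interspecific minima above
15%:

```
species             n_pairs  mean  max   flagged  warn_zone
Simulitingis alpha  28       1.01  2.02  False    True
Simulitingis beta   28       0.49  0.80  False    False
Simulitingis gamma  28       0.75  1.41  False    False
```

The run also writes per-species median-joining networks (`*.gml`), the
bootstrap NJ tree (`nj_tree.nwk`), a long-format pairwise distance
table, and a `manifest.json` from which the whole run can be
reproduced. `mitobarcode mito-report genome.gb ...` produces the
corresponding mitogenome tables (composition/skews, codon
classification, RSCU, spacing, repeats, and cross-genome Ka/Ks when
given two or more genomes).

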