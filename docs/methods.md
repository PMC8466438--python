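# Methods

This note records the statistical and algorithmic choices behind
`mitobarcode`: what each estimator assumes, where the design was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Sequence handling and coordinates

All sequences are normalized to uppercase A/C/G/T/N/`-` (U mapped
to T). Internal coordinates are 0-based half-open everywhere;
conversion to the 1-based inclusive convention of GenBank/FASTA happens
only at the file boundary. This makes length arithmetic on circular
genomes unambiguous: a feature spanning the origin is stored with
`end < start` and materialized as `seq[start:] + seq[:end]`. FASTA and
GenBank parsing/writing are delegated to Biopython behind the `seqio`
surface; the genetic code (NCBI table 5, invertebrate mitochondrial,
configurable) comes from `Bio.Data.CodonTable`.

FASTA header dialect: the record id is the first whitespace-delimited
token and the species label is the remainder, unless an explicit
tab-separated id→species mapping file is supplied. Header conventions
vary across repositories, so the mapping file is the authoritative
override.

## Dataset filtering

`filter_barcode_dataset` applies, in order: (1) species-level labels
only (a configurable regex rejects `sp.`, `cf.`, `aff.`, `nr.`
epithets), (2) ungapped length ≥ 500 bp, (3) at least 3 sequences per
species. Each rule's removal count is returned in a report; order is
preserved and an empty result is legal. The declared outgroup bypasses
filtering in the CLI, since it is typically a single sequence.

## Diversity estimators

* **Gap/N policy.** Haplotype collapsing, *S* and π use complete
  deletion (any column containing a gap or N in any sequence is
  excluded); pairwise distances use pairwise deletion. These mirror the
  defaults of the population-genetics tools practitioners use for
  Table-style summaries and distance matrices respectively, and both
  are what the estimators' formulas assume. Undefined distances
  (no comparable site, or a saturated K2P correction) are flagged as
  missing, never silently zeroed.
* **Haplotype diversity.** *H* = *n*(1 − Σp²)/(n − 1). The SD comes
  from Nei's (1987) variance estimator
  V(Ĥ) = 2/[n(n−1)] · {2(n−2)·[Σp³ − (Σp²)²] + Σp² − (Σp²)²}.
  The tests verify *H* against exhaustive pair-discordance counting for
  every haplotype multiset with n ≤ 8, and the SD against a
  10⁵-replicate multinomial bootstrap (agreement within 5%; the
  estimator is a first-order approximation, not an identity).
  A monomorphic sample is reported `n.a.` rather than 0 — with one
  haplotype there is no frequency variation to estimate, and reports
  conventionally print it as not available.
* **Nucleotide diversity.** π is the mean pairwise proportion of
  differing sites over the completely-deleted column set. The SD is a
  seeded nonparametric bootstrap over sequences (default 1000
  replicates). This deliberately differs from the analytic
  total-variance estimator some tools print; the bootstrap makes no
  equilibrium assumptions and its seed is recorded in the run manifest.
* **K2P.** d = −½ ln[(1−2P−Q)·√(1−2Q)]. When the log argument is
  non-positive (saturation) the distance is undefined and flagged.
  Reports state the model of every distance column, because "p-distance
  under the K2P model" is a contradiction in terms: the two metrics are
  both available and never mixed silently. K2P is the default for
  divergence summaries.
* **Conspecificity screen.** Intraspecific maximum distance above 3%
  flags a species; 2–3% is reported as a warning zone. No universal
  threshold exists; both numbers are configurable and echoed in the
  manifest.

## Median-joining networks

The implementation follows the Bandelt–Forster–Röhl scheme with
ε = 0 and uniform site weights (the defaults of the standard network
software): compute the ε-relaxed minimum spanning network (an edge is
feasible iff its endpoints are not connected using strictly shorter
edges minus ε, which at ε = 0 is exactly the union of all MSTs);
for every triplet connected in the MSN, compute column-wise
quasi-medians and add any median that strictly shortens the triplet's
spanning length; iterate to closure (cap 20 rounds, failure on cap);
finally delete inferred nodes whose removal does not lengthen the
network. Determinism comes from processing candidates in lexicographic
sequence order. Only A/C/G/T columns participate — the quasi-median is
undefined for ambiguity codes, and the haplotype collapser has already
excluded such columns.

One subtlety: with distance ties the minimum-spanning *network* keeps
every co-minimal link, so its total edge weight can exceed the weight
of a single spanning tree. The invariant "medians never lengthen the
network" therefore holds for the network's minimum spanning length
(`spanning_length()`), which the tests check against the MST over
observed haplotypes.

## Neighbor-joining, bootstrap and monophyly

NJ is implemented directly (Saitou–Nei Q criterion) rather than called
from a library, for two reasons: ties on Q are broken lexicographically
on node labels so trees are reproducible, and negative branch-length
estimates are clamped to zero with the deficit transferred to the
sibling branch (preserving the pair's path length) and counted in the
result. On additive matrices no clamping occurs and the tree's path
metric reproduces the input exactly — the property the tests verify on
random additive trees.

Bootstrap support resamples alignment columns with replacement,
rebuilds the NJ tree per replicate, and scores each original
bipartition by the percentage of replicates containing it. Replicates
whose resampled matrix contains an undefined distance are redrawn
(bounded at 10× the requested replicates). Monophyly of a tip set,
after rooting on the declared outgroup, is equivalent to the set being
one side of a bipartition of the unrooted tree; singleton sets are
trivially monophyletic.

The package does not implement likelihood or Bayesian tree inference;
NJ with bootstrap is the declared surrogate for the cluster/monophyly
question, which depends on bipartitions rather than on optimal branch
lengths or models.

## Mitogenome statistics

* **Composition and skews.** AT skew = (A−T)/(A+T), GC skew =
  (G−C)/(G+C); a zero denominator yields an undefined (flagged) skew.
  Per-feature reports are computed on the strand-native sequence
  (N-strand features reverse-complemented) by default, with the
  published-strand (J) orientation available, because cross-strand skew
  comparisons need both conventions; the CLI emits both.
* **Start/stop classification.** A CDS whose length is ≡ 2 (mod 3)
  must end in `TA`, ≡ 1 in `T` — the incomplete stops completed to TAA
  by post-transcriptional polyadenylation; any other trailing residue
  is an explicit anomaly, as is a non-stop final codon in a mod-0 CDS.
  Starts are classed canonical ATN versus alternative (e.g. GTG).
  Internal stops are counted, never silently tolerated.
* **RSCU.** count(codon) / mean count over its synonymous family,
  families from table 5, stop codons excluded. Never-observed families
  are undefined (flagged); single-codon families have RSCU ≡ 1 when
  observed. Σ RSCU over a family equals its degeneracy by construction,
  and the tests assert it on random usage tables.
* **Spacing.** Features sorted by start; for each consecutive pair,
  including the circular closure pair (last, first), overlap and spacer
  lengths are computed in exact integer arithmetic. A nested feature is
  well-defined (overlap = inner length) but warned about. Counts,
  totals and means are all printed because "N bp at M locations" is
  ambiguous between a total and a mean.
* **Ka/Ks.** Nei–Gojobori (1986) with Jukes–Cantor correction, the
  default of the common desktop tool for this statistic. Synonymous
  site fractions count mutations to stop codons as nonsynonymous
  (keeping S + N = 3 per codon exactly); multi-hit codons average over
  all substitution orderings with equal weight, excluding pathways
  through stop codons (falling back to scoring all orderings if every
  pathway is blocked). ps or pn ≥ 0.75 returns the uncorrected
  proportion with a saturation flag. The test suite checks the per-pair
  counts against an independent exhaustive enumeration over all
  61 × 61 sense-codon pairs.
* **Tandem repeats.** A deterministic exhaustive scan, not a port of
  the probabilistic repeat finder: for every motif length in
  [20, 300] bp and every start, successive windows (allowing ≤ 10 bp
  spacers) are accepted at ≥ 90% identity to the first copy; seed
  detection is vectorized over all (length, spacer) phases.
  Overlapping descriptions of the same array are reduced by alignment
  score (+1 match, −1 mismatch, so sliding a window off the true phase
  never gains), with smaller motifs preferred on ties. Defaults are
  chosen so control-region repeats in the 150–200 bp motif range are
  detectable.

## Synthetic data

`simulate_barcodes` places species ancestors on a star phylogeny, each
a fixed number of substitutions (`inter_div`, default 40 on a 501-bp
barcode, ~8%) from a random root drawn from an AT-rich base
composition typical of insect COI. Individuals receive
Poisson(`intra_lambda`, default 2) substitutions; transitions are
favoured with probability κ/(κ+2), κ = 4. Defaults are chosen so that
intraspecific divergence stays below ~2% while interspecific divergence
sits near 15%, a planted barcode gap of the magnitude real COI surveys
report. The truth table records every mutation, the realized
segregating sites and the haplotype partition. Limitations: no
coalescent structure (a star phylogeny cannot produce deep
intraspecific clades), substitution-only (sequences are born aligned;
no indel handling is exercised), and no rate variation among sites.
Passing tests therefore demonstrate correctness of the estimators and
the recovery machinery, not robustness to alignment error or NUMT
contamination.

`simulate_mitogenome` lays out the canonical 37-gene arthropod
arrangement (23 genes on the majority strand, 14 on the minority
strand, control region between the small rRNA and the
tRNA-Ile/Gln/Met cluster) with per-gene lengths in the range reported
for lace bug mitogenomes. Protein-coding genes are filled with sense
codons drawn from an AT-biased weight table (so AT-rich codons are
over-represented, RSCU > 1), with planted start codons (defaults
include one alternative GTG start) and stops (complete TAA/TAG or
incomplete TA/T, which shorten the CDS by the mod-3 convention).
Planted overlaps and spacers shift the layout; a PCG–PCG overlap is
rejected because the later gene's codons would overwrite the
earlier's. The genome length target (default 15,209 bp) is hit exactly
by resizing the AT-rich region. The control region is sampled at its
own A+T target with exact base counts (shuffling counted bases rather
than i.i.d. sampling, so planted composition holds for the region and
not just in expectation), and carries a planted repeat array at its 3′
end; the eight bases upstream of the array are forced to mismatch
their images one period downstream, otherwise a window slid off the
planted phase would describe the same array equally well and the
recovered motif length would be ambiguous by construction.
tRNA/rRNA sequences are composition-matched random filler — only their
coordinates, strands and composition matter to the statistics under
test; no secondary structure is emulated.

`mutate_mitogenome` derives a related genome by giving each internal
PCG codon an independent synonymous single-nucleotide change with
probability 0.05 and a nonsynonymous one with probability 0.01 (never
through a stop), planting a strongly purifying Ka/Ks regime; filler
mutates at 0.02 per site. Coordinates are preserved so parent and
derived genomes align gene-by-gene without an aligner.

## Problem sizes and numerics

The test suite and the acceptance script run on deliberately small
problem sizes chosen to exercise every code path while keeping a full
run under a couple of minutes: bootstrap with 100–200 replicates
(1000 remains the CLI default), 20 generator seeds for recovery
properties, 3–4 specimens per species for bootstrap datasets, and one
30-species × 3 dataset for survey-scale clustering. Floating-point
checks use absolute tolerances of 1e-9 for closed-form identities
(K2P, NJ path metrics) and stochastic tolerances of ±1 percentage
point for planted composition and divergence targets, reflecting
binomial sampling noise at the region and alignment lengths used.
Percentages are printed with 1–2 decimals in TSV reports; full
precision lives in the JSON manifest bundle.

## Known limitations

- NUMT (nuclear mitochondrial copy) detection is out of scope; the
  codon classifier's internal-stop and anomaly flags are the only
  guard.
- The median-joining implementation targets barcode-survey-sized
  haplotype sets (tens of haplotypes); its triplet scan is quadratic to
  cubic in node count and is not intended for thousands of haplotypes.
- The tandem-repeat scanner reports perfect and near-perfect arrays;
  highly degenerate repeats below the identity threshold are invisible
  to it.
- Ka/Ks assumes in-frame, stop-free, equal-length coding sequences;
  alignment of diverged genes is upstream of this package.
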