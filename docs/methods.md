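# Methods

## The question the pipeline answers

When two closely related genomes (think *Arabidopsis lyrata* vs
*A. halleri*, ~1 Myr of divergence) are compared copy by copy, which
transposable-element (TE) fragments have been *retained* at the homologous
position in both lineages, and what distinguishes them from the copies that
were deleted from one lineage?  Because most annotated TE copies are short,
degraded fragments, whole-genome alignment and family phylogenies are
unreliable at this scale; the pipeline instead relies on strictly positional
evidence from flanking genes, the one signal that survives heavy TE decay.

## TE orthology by gene anchoring

1. **Gene anchors.**  One-to-one orthologous genes are found by reciprocal
   best protein hits: translated CDS are compared all-vs-all with local
   BLOSUM62 alignments (gap of length L costs 11 + L), and a pair is kept
   iff each protein is the other's best scoring hit with identity >= 85%
   and >= 60% coverage of both sequences.  An exact 6-mer prefilter skips
   pairs that share no word; such pairs cannot be credible best hits.
   Ties are broken by identity, then lexicographic id, so the map is
   deterministic.  Strict one-to-one-ness is preferred over sensitivity
   because every anchor error propagates into TE calls.

2. **Framing.**  Each TE copy is assigned the counterpart region where its
   ortholog must lie: the interval between the orthologs of its nearest
   mapped flanking genes ("framed"), or the ortholog of its host gene when
   the TE overlaps a gene ("inserted"; gene overlap takes precedence, and
   unmapped genes between anchors are ignored).  TEs at scaffold ends, on
   scaffolds without anchors, or in intergenic segments longer than 70 kb in
   either genome are discarded with an explicit reason.  The 70 kb cap is
   applied to the intergenic span, i.e. the sequence actually searched.  A
   counterpart anchor pair that does not delimit a single interval (broken
   synteny) is reported under the `no_ortholog_scaffold` reason.

3. **Calling.**  The TE sequence is searched against the counterpart region
   with a relaxed gapped local alignment (both strands).  Hits passing
   E <= 1e-10 and identity >= 80% are walked best-E-value first; the first
   hit overlapping (>= 1 bp) a counterpart TE annotation decides the call:
   same family-cluster -> orthologous, a different family only ->
   discarded as ambiguous.  A passing hit over unannotated sequence, or no
   passing hit, means non-orthologous.  `require_same_family` can be
   relaxed to accept any overlapping annotation.

### The aligner

The nucleotide aligner is a seed-and-extend affine-gap Smith-Waterman
(match +2, mismatch -3, gap of length L costs 5 + 2L; blastn-like).
Problems under 5x10^5 cells are solved by the full dynamic program, so
scores there are exact; larger searches collect exact 11-mer seeds, cluster
them by diagonal and run the same dynamic program on a padded subject
window.  E-values follow Karlin-Altschul, E = K m n exp(-lambda S), with
lambda solved from the scoring scheme at uniform base composition
(~0.63 for +2/-3) and K = 0.41, the standard value for this scheme; the
search space is the full query x subject product per comparison.  The
heuristic can miss alignments whose identity is so low that no 11-mer
survives (roughly < 75-80% over short stretches); between orthologous
copies at a few percent divergence seeds are effectively guaranteed.  The
E-value calibration is validated empirically: shuffled subjects essentially
never reach E <= 1e-10.

## TE age

Copy age is proxied by percent identity to the family consensus: a
semi-global alignment (free end gaps on the consensus; match +1, mismatch
-1, gap open -5, extend -1) and identity = matches / copy length.  Copies
at or above 90% identity are "young", below are "old"; 90.0 itself counts
as young, and the threshold is a parameter everywhere.  Only old copies
enter retention contrasts: an old copy predates the species split under
neutral divergence, so its absence from one genome is a deletion, whereas a
young copy missing from one genome may simply have inserted after the
split, and its history cannot be polarized.

The assembly-free TE content estimate maps reads to the concatenated
consensus library with the same scoring: exact 9-mer seeds extended
ungapped with an X-drop of 20; a read maps when any extension reaches a
score of 50 (the gapped score can only be higher, so no DP is needed), and
borderline seeds (>= half the threshold) are re-scored with the gapped DP.
The reported fraction is mapped reads / total reads.

## Retention factors

All contrasts compare **old orthologous** vs **old non-orthologous** TEs:

* superfamily representation - per-superfamily 2x2 chi-squared (1 df, no
  continuity correction; expected counts are large in this design and the
  Yates correction is available as a flag);
* length and distance-to-nearest-gene - group means/medians plus a
  two-sided Mann-Whitney test; the percent contrasts are computed the way
  the summary tables print them (length: relative to the deleted group's
  mean; distance: relative to the retained group's mean);
* genic context - >= 1 bp overlap with a gene makes a TE genic, >= 1 bp
  overlap with a CDS exon promotes it to genic-CDS (declared conventions;
  strand is ignored throughout); 1-df genic/non-genic and 2-df
  CDS/non-CDS/intergenic chi-squared tests, with the genome-wide genic
  fraction reported as the baseline;
* siRNA targeting - a TE is siRNA-active iff it has >= 5 uniquely mapped
  reads per million *and* >= 10% of its length covered (both boundaries
  are inclusive and exposed as flags, since published wordings of the rule
  disagree on "more than" vs "at least"); 2x2 chi-squared per genic class;
* methylation - a cytosine is methylated iff its rate is >= 20% in at
  least one of four tissue/treatment conditions; per-TE percent of
  methylated covered cytosines; the four groups (orthology x genic
  context) are compared with Kruskal-Wallis, and pairwise with the
  rank-based Tukey-Kramer procedure (Nemenyi: |mean-rank difference|
  against the studentized range with infinite df; no tie correction).
  With two groups this reduces to a Mann-Whitney test asymptotically;
* expression - TPM (rate = count/length, scaled to 1e6); host-gene TPM for
  genic TEs and nearest-gene TPM for intergenic TEs, Mann-Whitney per
  contrast.  Transcript-to-gene matching is a pluggable mapping (identity
  by default, standing in for a stringent sequence-match rule);
* essentiality proxies - (1) gene-family size = connected-component size of
  the all-vs-all CDS hit graph (E <= 1e-30, query coverage >= 50%), so
  "single copy" means "no passing non-self hit"; single-copy fractions per
  group vs all genes by chi-squared; (2) Ka/Ks for ortholog pairs by the
  Nei-Gojobori (1986) counting method with Jukes-Cantor correction -
  pathway averages over all orderings of within-codon differences,
  excluding pathways through stop codons when any stop-free pathway
  exists; pairs with Ks = 0 are excluded from the ratio and counted;
  codon-model maximum-likelihood estimators are deliberately out of scope,
  so group comparisons of Ka/Ks are property-based rather than tied to
  published means; (3) loss-of-function fractions per group by chi-squared.

Significance codes follow the convention "***" p < 0.001, "**" p < 0.01,
"*" p < 0.05, "." p <= 0.1, "NS" otherwise.

## Mobilome

Segregating non-reference insertions are called from per-accession read
evidence in two passes: discovery requires >= 10 combined discordant+split
reads in at least one accession (candidates of one family within 100 bp on
a scaffold are merged to the best-supported site; the merge window is a
declared convention); genotyping then scores every accession at every
candidate with a relaxed >= 2-read rule, which recovers insertions shared
across accessions that individually miss the discovery bar.  The TSD flag
is reported but never used as a calling criterion.  An optional
per-accession minimum mean-support filter (off by default) mirrors the
practice of dropping low-coverage samples.

## The synthetic genome-pair generator

The generator is first-class, tested code and defines the study conditions
for every stochastic acceptance check.  Defaults: 4 scaffolds x 500 kb per
genome, 150 genes (2-4 exons, 60-200 codons each, introns 80-400 bp),
1,500 ancestral TE copies drawn from a 6-superfamily x 25-families
consensus library (Gypsy 28%, Copia 22%, LINE/MuDR/Helitron 15% each,
SINE 5%, matching the rank order such genomes show), copy lengths
log-normal (median 350 bp), identity to consensus from a two-component
mixture (70% "old" N(80, 5), 30% "young" N(97, 1.5)) producing the
characteristic bimodal age histogram with its antimode near 90%.  Copies
land 70% intergenic / 18% intronic / 12% in CDS; CDS insertions are padded
to a codon boundary and recoded stop-free so host ORFs stay valid.

Each lineage then independently applies: per-TE Bernoulli deletion with
probability 0.30 x 0.3^[genic] (clean excision of the annotated interval;
an optional flank widens deletions), point substitutions at half the 2%
between-species divergence, small (1-10 bp) indels at 2x10^-4 per bp in
feature-free intergenic DNA only, and 50 young (>= 95% identity) intergenic
insertions.  Substitutions that would create a premature stop are reverted
- a crude stand-in for purifying selection that keeps anchors
translatable.  All coordinates are remapped after every edit.  A truth
table records each ancestral copy's fate; a copy retained in both lineages
is expected orthologous, an *old* copy retained in exactly one is expected
non-orthologous, while young lineage-specific survivors and double
deletions are "not interrogated" because their history could not be
polarized from data either.

Side tables are drawn per TE/gene with group effects scaled by `*_contrast`
fields (0 = exchangeable groups, the null): siRNA rpm log-normal with
group-shifted means, per-cytosine methylation rates (Beta mixtures around
group means of 4/23/18/32% patterned on the orthology x genic contrast),
negative-binomial expression counts with lower means for hosts of retained
TEs, and mobilome read evidence in which every true insertion has at least
one carrier with >= 10 supporting reads while background sites never exceed
1 read.

What the generator does **not** emulate - assembly gaps and collapsed
repeats, nested/fragmented annotations from real TE annotators, insertion
mechanics (TSDs, LTR structure), recombination, within-feature indels, CG
content heterogeneity - bounds what green tests mean: they demonstrate the
correctness and calibration of the method's logic under its own stated
assumptions, not its accuracy on real assemblies of uneven completeness.

## Numerical and design choices

* Coordinates are 0-based half-open internally, 1-based inclusive in GFF3.
* All randomness flows from one integer seed through named `numpy`
  Generator streams (ancestor, lineage A, lineage B, side tables), making
  every output byte-reproducible; the run manifest records a hash of the
  semantic configuration (paths and verbosity excluded).
* Orthology evaluation treats "orthologous" as the positive class and
  scores precision/recall over interrogated TEs only; framing discards and
  not-interrogated truth rows are tabulated separately so the confusion
  counts reconcile exactly.
* One genome-A TE may match a counterpart TE that is also matched by
  another copy (many-to-one); the calls record `matched_te_id` so the
  multiplicity is reportable.
* Problem sizes in the test-suite and acceptance checks (e.g. two 2 Mb
  genomes for headline recovery, 1.2 Mb genomes with ~1,100 old copies per
  sheltering replicate, 2,000 reads for the TE-content check) were chosen
  as the smallest scales at which the corresponding statistics are stable.

## Known limitations

* The seed-and-extend heuristic is exact only below the DP cell cap; a
  diverged hit with no exact 11-mer seed can be missed in large segments.
* Karlin-Altschul K is a fixed constant rather than recomputed per scoring
  scheme; E-values are calibrated for thresholding, not for tail-exact
  p-values.
* Ka/Ks uses equal-weight pathway counting (NG86); saturated pairs
  (pS >= 3/4) are reported as undefined.
* The methylation matrix is consumed as given; no smoothing or coverage
  weighting is applied.
* With real annotations the pipeline inherits their fragment structure: it
  never joins or splits TE fragments.
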