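# Methods

This note documents the models, rules and numerical choices behind
`panfam`, and what the synthetic-data tests do and do not demonstrate
about real pan-genome data.

## Occupancy classification

A membership matrix M (orthogroups × genomes, copy counts) is built
from an OrthoFinder-style table restricted to the identified family
genes. Occupancy k(og) is the number of genomes with at least one copy.
Categories with n genomes:

* core: k = n
* soft-core: ⌈0.9 n⌉ ≤ k ≤ n − 1
* private: k = 1 (n > 1)
* dispensable: everything else (2 ≤ k < ⌈0.9 n⌉)

The count-based reading is used because it reproduces the printed
ranges at n = 22 (22; 20–21; 2–19; 1); a percent-of-genomes reading of
"2%–90%" is inconsistent with those ranges. ⌈·⌉ is deliberate:
0.9 × 22 = 19.8 → 20. A single-genome collection is degenerate (every
orthogroup is both core and private); the classifier reports core and
warns.

Saturation curves sample genome orders uniformly (default 100
permutations, seeded, seed recorded); pan(k) is the union and core(k)
the intersection of orthogroup sets over the first k genomes. Pan is
non-decreasing and core non-increasing for every individual
permutation, which the tests assert per-order, not just on means.

## Family identification

Two filters compose (order-independently): at least one domain hit with
independent E-value ≤ 1e-5, and best global protein identity strictly
greater than 50% against the reference set. Identity is computed on a
global alignment with BLOSUM62, affine gaps (open 10, extend 0.5);
the denominator is aligned columns excluding terminal gap columns
(internal gaps count). Because co-optimal alignments can differ between
argument orders, inputs are canonicalized lexicographically, making
identity exactly symmetric. Full-length identity is used (whether the
original threshold applied to full-length or local-hit identity is not
specified anywhere; this choice is the stricter, more reproducible
one).

PSPG typing slides a 44-position weight model along the protein;
typical iff the best window reaches 60% of the maximal attainable
score. The default model is a consensus indicator (weight 1 on the
consensus residue per position) built from a canonical PSPG consensus;
a user-supplied TSV model replaces it. Proteins shorter than the model
width are atypical with a warning, not an error. Group assignment (A–Q)
uses the highest-identity labeled reference with ties broken by the
lexicographically smallest label — a deterministic, testable stand-in
for maximum-likelihood tree placement, which is out of scope.

Family orthogroup naming is descending occupancy, then descending total
copies, then orthogroup id (no published numbering rule exists to
match).

## Duplication typing

Genes are ranked per chromosome by start (ties: end, then id). The
collinearity chainer works per chromosome pair on homolog anchor
pairs: a block is a chain with strictly increasing ranks on one side,
strictly monotone (either direction — antiparallel blocks allowed)
ranks on the other, and adjacent rank gaps ≤ max_gap (default 25) on
both sides; chains shorter than min_block_size (default 5) are
discarded. Chains are found by a longest-chain dynamic program and
extracted greedily (best first, anchors removed, repeat), which is
deterministic. Strict monotonicity on both sides is a simplification
(ties on the second side are disallowed); the exhaustive-search oracle
in the tests checks exactly this published constraint set on anchor
sets of up to 12 anchors.

The cascade assigns exactly one mode per intra-genome candidate pair:
WGD if the pair is an anchor of a collinear block; else TD if on the
same chromosome at rank distance ≤ 1; else PD at rank distance ≤ 10;
else TRD if exactly one gene lies in a collinear block against the
outgroup genome (ancestral locus); else DSD. Candidate pairs are
homolog pairs above a similarity floor (E ≤ 1e-10, identity ≥ 30% on
the tabular input); all thresholds are exposed as parameters. Pairs are
counted as unordered unique pairs; per-gene summaries take the
highest-priority mode across a gene's pairs.

## Ka/Ks (NG86)

Codon alignments are protein-guided: global protein alignment
(BLOSUM62, open 10 / extend 0.5) back-translated codon-wise; codon
columns containing a gap in either sequence are masked (dropped
pairwise, not end-trimmed). Site counts per sense codon come from
enumerating the nine single-nucleotide mutants (changes to stops are
nonsynonymous); observed differences are averaged over all minimal
mutational pathways with equal weight, excluding pathways through stop
codons (all pathways are used in the rare case every one is blocked).
pN and pS are corrected with Jukes–Cantor, d = −(3/4) ln(1 − 4p/3),
undefined at p ≥ 3/4. NA reason codes distinguish Ks = 0, undefined
correction, and empty alignment. NG86 was chosen as the single method
because it is deterministic, closed-form, and checkable against
independent oracles; maximum-likelihood codon models are out of scope.
The implementation agrees with an independent NG86 implementation
(Biopython's `cal_dn_ds`) to 1e-9 on simulated pairs; that
implementation is used only as a test oracle.

Per-orthogroup distributions use all unordered cross-genome gene pairs
(an orthogroup present in two genomes with one gene each contributes
exactly one value; single-genome orthogroups contribute none).

## SV association and promoters

Per-genome SV genotypes are retained only at DP ≥ 20 (inclusive);
records with no remaining carrier are dropped. Presence is
genotype-based: any retained non-reference genotype counts (the source
procedure does not define presence for heterozygotes). An insertion's
affected reference span is its single anchor base (VCF convention); a
deletion spans [pos, pos + ref_len − 1]. A gene's window is its body ±
2 kb (floored at position 1); gene-level presence is 1 iff ≥ 1 retained
SV overlaps the window in that genome.

The association statistic is the Pearson correlation between the binary
presence vector and expression across genomes, with a two-sided t
p-value (n − 2 df) at α = 0.05 and no multiple-testing correction by
default (a Benjamini–Hochberg option would be a one-liner on the output
table; it is off to mirror the original screen). For binary presence
this is the point-biserial correlation, whose p-value is identical to
the equal-variance two-sample t-test comparing the two presence groups
— the tests assert this identity to 1e-10, which reconciles the
correlation screen with per-gene group comparisons.

Promoters are the 2000 bases 5′ of the gene start (strand-aware,
reverse-complemented on the minus strand, truncated with a warning at
contig edges), anchored at the gene feature. Cis-elements are counted
from an IUPAC pattern table on both strands, deduplicated by start
position so palindromes are not double-counted; elements are ranked by
combined abundance, the top 20 retained, and rolled up by
growth/hormone/stress category when the table carries labels. A small
built-in table of common plant cis-elements is provided for
self-contained runs; real analyses should supply their own table.

## Expression

TPM: count / (length in kb) per gene, scaled per sample to sum to 1e6;
all-zero samples stay zero with a warning. Gene length is the
annotation span (for the generator's single-exon models this equals the
exon union). Replicates aggregate by arithmetic mean. Dosage analysis
correlates per-genome family gene counts with log₂(total family
TPM + 1) — total-then-log, with the pseudocount exposed; the
alternative (summing per-gene logs) is a flag away in user code since
the kernel takes arbitrary vectors. The dosage test and the SV
association share one Pearson kernel, so identical inputs give
identical outputs by construction.

## Synthetic pan-genome generator

The generator emulates the study design at desk scale: default 10
genomes × 2 chromosomes, ~30–45 family genes per genome, genes spaced
3 kb apart on synthetic coordinates. Orthogroups are planted per
category with occupancies drawn inside the category's range and copy
counts in a configurable range; all founder proteins derive from a set
of ancestral reference proteins (~8% divergence per orthogroup, small
within-orthogroup divergence), so identification filters behave as on
real data, and two decoy genes with weak domain hits exercise the
filters' reject path.

Duplication events are planted in genome 1 with rank-gap separation
greater than max_gap between event groups, so each planted pair is
unambiguous under the default chainer parameters: WGD pairs form one
parallel cross-chromosome block; TD pairs are rank-adjacent; PD pairs
sit 2–4 ranks apart; TRD pairs put one gene in a run collinear with a
generated outgroup genome; DSD pairs are isolated. Scaffold (filler)
genes that create the rank separation are ordinary private family
genes. Event counts per same-chromosome group must stay below
min_block_size (validated), or the planted anchors would themselves
chain into blocks.

Codon evolution is a single-parameter process: uniform single-
nucleotide proposals (Jukes–Cantor-like), stop-codon proposals
rejected, nonsynonymous acceptances scaled by ω (synonymous by 1/ω for
ω > 1), so the expected dN/dS equals ω and is recoverable by NG86 —
the recovery test (300 codons, branch length 0.3, 100 replicates per ω
∈ {0.2, 1, 2}) finds correctly ordered means with the neutral mean
within ±0.15 of 1.

Expression counts are negative-binomial (mean 50, size 10 by default)
in TPM-like units; a family gene model is expressed in a genome only if
its orthogroup has a member there, which produces a genuine
dosage–count correlation, and ~200 background transcriptome rows keep
TPM normalization realistic. SVs (insertions/deletions, 50–300 bp) are
placed in gene ± 2 kb windows for a configurable fraction, with
per-genome DP values of which a configurable fraction falls below 20 to
exercise filtering. Planted effect SVs shift the negative-binomial mean
additively (+40 by default) in carrier genomes, use balanced carrier
sets (half the non-reference genomes) and always pass the depth filter,
so the planted carrier set is exactly recoverable; effect genes are
drawn from fully occupied orthogroups and kept mutually distant so
windows do not overlap and dilute each other. No effect-size or noise
estimates exist for the real SV–expression relationships, so these
defaults are free parameters chosen once as plausible, not calibrated
to tea data.

Everything is driven by one seeded generator; identical configs and
seeds give byte-identical output files. Chromosome sequences (for
promoter extraction) are generated deterministically per
(seed, genome, chromosome) and carry no relation to the gene CDS —
fine for motif counting, not for alignment-based analyses.

### What the synthetic tests do not show

The generator plants clean, well-separated signals: real collinear
blocks are eroded by local rearrangements, real orthogroup tables
contain paralog-clustering errors, real expression has batch and
library-size structure far beyond a negative binomial, and real SV
genotypes have reference bias. Passing the recovery tests therefore
demonstrates the correctness of the rules and estimators under their own
assumptions, not robustness to assembly or annotation artifacts.

## Problem sizes and runtime

Defaults are sized for seconds-level runs: the default bundle is ~350
genes across 10 genomes; the statistical checks use 1000 genes × 20
genomes (association calibration), 100 replicates × 300 codons per ω
(NG86 recovery), 200 random anchor sets of ≤ 12 anchors (chainer
oracle), and 100 permutations (saturation). These sizes were chosen as
the smallest that make the statistical assertions stable.

## Degenerate inputs and tie-breaks

* Empty hit tables, empty promoter sets, all-zero samples: empty/zero
  results (with warnings where silent zeros could mislead), not errors.
* Constant presence or expression vectors: NA with a reason code.
* Rank ties: broken by end coordinate then gene id; chain extraction
  ties: earliest anchor in sort order wins; group-label ties: smallest
  label; family naming ties: orthogroup id.
* Percent formatting everywhere: decimal half-up to one decimal,
  matching printed tables (e.g. 783/2311 → 33.9).
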