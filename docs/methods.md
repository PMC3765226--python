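# Methods

This note documents the models and procedures `xerotome` implements, the
conventions and defaults it fixes where the underlying analysis left
choices open, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Locus binning and isoform naming

Two contigs belong to the same locus when they share an exact common
substring of at least `min_overlap` (default 200) bases on either
strand; loci are the connected components of this link graph. Matching
is exact: the original analyses used suffix-tree software whose mismatch
tolerance is not documented, so exact matching is adopted as the
reproducible convention. A shared substring of length ≥ L always
contains one of length exactly L, so the implementation links contigs on
strand-canonical windows of length L through a single hash pass; the
test suite cross-checks the resulting partition against a quadratic
dynamic-programming longest-common-substring oracle and against an
independent all-pairs window-set-intersection oracle.

Locus identifiers are assigned `Locus1, Locus2, ...` in order of the
lexicographically smallest member contig id, which makes both the
partition and the naming invariant to input order. Within a locus,
versions are ranked by descending RPKM with ties broken by contig id
("relative abundance" alone cannot order equal values). The precursor
flag is strict: a member is flagged iff its RPKM is strictly below 10%
of the v1 RPKM, so a member at exactly 10% is not flagged and v1 itself
never is (including the degenerate v1-RPKM = 0 case).

RPKM values in contig names are rendered as the shortest positional
decimal that round-trips the float, with at least one fractional digit
("3.45", "100.0"). This makes the naming grammar a bijection between
valid (locus, version, rpkm, precursor) tuples and names, which the test
suite asserts as a property.

## Contamination triage

Origin labels ({plant, contaminant, unknown}) are inputs — in the
original setting they come from homology classifiers, which this package
deliberately does not re-run. The triage rule: plant contigs are
retained, contaminant contigs dropped, and unknowns retained iff
RPKM ≥ threshold, where the threshold is the lower-quartile RPKM of the
labeled plant contigs. The quartile uses linear interpolation between
order statistics (the common default in scientific software; the rule
itself only names "lower quartile") and the boundary is inclusive.
Triage is monotone in the threshold by construction.

## RPKM and unique mappability

RPKM = 10⁹ · c / (N · L_u). Uniquely mappable length L_u is defined on
read-length windows (default 36 nt, the trimming convention for the
expression libraries): the number of windows in a contig whose
strand-canonical sequence occurs exactly once across the entire
reference set; windows containing N are unmappable. This is a stated
surrogate for alignment-based (MAPQ) uniqueness, which cannot be
mirrored exactly without alignments; it agrees with it on error-free
reads. A contig with L_u = 0 has undefined RPKM and is reported as
missing, not zero.

## k-mer discovery curves

Reads are trimmed to 36 nt, scanned as canonical 25-mers (lexicographic
minimum of the k-mer and its reverse complement, since library
strandedness is not modelled), k-mers containing N skipped. The curve
reports, per batch of reads, the fraction of scanned k-mers never seen
in any earlier batch — a per-batch (not cumulative) discovery frequency.
Its expectation is non-increasing only over randomly ordered reads, so
the read simulator shuffles reads across templates as a sequencer
effectively does.

## Proteomes and RBH orthologs

ORFs are stop-to-stop open frames (the conventional default of
six-frame ORF finders): every maximal run of ≥ 30 non-stop codons in
any frame on either strand, with the closing stop codon included in the
CDS span. ATG-initiated semantics are not the default because the
working-set filter below already selects for plausible full-length
proteins. The working set keeps, per locus, the longest + strand ORF of
the v1 isoform with ≥ 76 aa (the 5th percentile of protein lengths in a
broad plant reference set, taken as a constant) and a CDS covering
≥ 50% of the transcript.

The similarity search scores optimal local alignments under BLOSUM62
with BLAST-convention affine gaps (open 11, extend 1; i.e. a gap of
length L costs 11 + L). Search is exhaustive up to 10⁴ query × subject
pairs and 4-mer-seed-filtered beyond; ties go to the lexicographically
smallest subject id, and a configurable raw-score floor (default 40)
suppresses spurious hits — no fidelity to an unstated original threshold
is claimed. Reciprocal best hits are the mutual best pairs of the two
directed searches; the pairing is a partial matching and is symmetric
under swapping the proteomes. Pair identity is identical columns over
alignment columns (gap columns count against identity) of the optimal
local alignment. Tests verify the exhaustive search against an
independent numpy affine-gap Smith-Waterman oracle, and the seeded mode
by planted-ortholog recovery.

Protein-family size comparison consumes a family × species count table
(cluster memberships are an input format, not recomputed) and performs
per-family two-sided rank-sum tests of focal vs reference species with
Benjamini-Hochberg adjustment across families.

## Thermostability score

The score is the fixed linear combination listed in the README over
molar fractions and normalized mean residue surface area. The ASA table
ships with the package (Gly-X-Gly tripeptide areas, Gly = 75 Å² minimum,
Trp = 255 Å² maximum); user tables are accepted but validated against
those bounds. One normalization subtlety is worth flagging prominently:
dividing the raw mean area (range 75–255 Å²) by 180 Å² yields values in
[0.42, 1.42], not the dimensionless [0, 1] range the score expects, so
the implemented mapping is (mean − 75)/180, which satisfies that range
and pins poly-G at −0.4 and poly-W at +0.9. Non-standard residues
(X, B, Z, U) are excluded from all counts and from the ASA mean, with a
warning. The overlapping terms (A inside Tiny/Sml, T inside Sml) are as
defined; the formula is applied verbatim.

## Polymorphism density and TE classes

Variant records are filtered to quality exactly 999 — the saturated
confidence value emitted by the caller — before summarisation. PPK is
1000 · (SNPs + indels)/length per locus, indels counting once regardless
of length; zero-variant loci are included at PPK 0, and the summary is
additive over disjoint variant sets.

TE annotations are classified with precedence full > end-anchored >
internal: `full` iff start ≤ 1 + tol and end ≥ length − tol (tol = 10),
else `five_prime_end` / `three_prime_end` iff exactly one terminus is
reached, else `internal`. An annotation reaching one end while covering
nearly the whole contig is end-anchored, not "near-full" — a documented
precedence choice. Contigs are treated as oriented transcripts (5' of
the contig is the transcript 5'); classification is mirror-invariant
with the end labels swapped.

## Expression clustering

Rows (loci) are z-scaled with the population (n-denominator) standard
deviation (exposed as an option; the choice is irrelevant to K-means up
to a constant factor per row, but fixed for reproducibility);
zero-variance rows become zero rows. K-means uses k-means++
initialization, 10 restarts, a fixed seed and tolerance 1e-6, with
centroids recomputed as the means of the final assignment so the model
is self-consistent. "Least within group sum of squares" is
operationalized as the elbow of the within-SS curve: the interior k
maximizing its second difference over the candidate range (which must
contain ≥ 3 values). Sample-sample correlations are computed on
log10(RPKM + 1) by default because raw-scale correlations are dominated
by a few abundant loci; the transform is exposed as a flag.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions the analyses assume.

- Plant loci: lognormal lengths around 1,000 nt; 60% of loci embed a
  + strand ORF (ATG, stop-free codons, closing stop) covering 60–80% of
  the contig, with codon sampling biased toward the plant GC target
  (0.44) so coding loci do not distort the overall GC distribution.
- Minor isoforms: 30% of loci gain a second contig sharing the major's
  prefix (≥ 200 bp) with a novel tail, at 1–8% of the major's
  abundance — below the precursor threshold by construction.
- Contaminants: an independent i.i.d. model (homology-free by
  construction) at GC = plant + 0.15 by default, with low abundance.
  The planted abundance strata are: labeled plant log10 RPKM ~
  N(1.0, 0.8) (a wide dynamic range), unknown-labeled plant ~
  N(1.5, 0.35) (typical transcripts), contaminants ~ N(−1.0, 0.5)
  (rare) — the separation that abundance triage presupposes when most
  RNA in a sample is from the plant. Because the lower-quartile
  threshold is computed over all labeled plant contigs including
  sub-10% precursor isoforms, a small tail (~2%) of contaminants can
  land above it; triage recovery is therefore scored at the locus (v1)
  level.
- Heterozygosity: per-contig Poisson(rate · length/1000) planted
  variants at quality 999 (defaults 2.07 and 4.39 per kb for the two
  species), SNP:indel 9:1, indels of 1–3 nt, plus a decoy fraction of
  low-quality records.
- TE fragments: mutated slices (10% divergence, so no exact 200-mer is
  shared between insertions) of per-family consensus sequences placed in
  a known coverage class.
- Two species: per-site substitution copies at 5% divergence
  (nucleotide level) or peptide-level mutation for proteome tests.
- Expression gradients: six non-flat archetype shapes along the ordered
  proximal-to-distal axis (monotone up, monotone down, peak at section
  2, peak at 3, valley at 2, valley at 3), all zero-mean unit-variance
  over the four sections; per-locus lognormal baselines and relative
  Gaussian noise (default sd 0.2) that z-scaling removes up to the noise
  itself. A literally flat archetype is not generated: after row
  z-scaling it would be indistinguishable from pure noise and no method
  could recover it. Archetype membership is round-robin, so classes are
  balanced.

Every generator draws from a stream seeded by (config seed, operation
name), so outputs are byte-reproducible and adding an operation never
perturbs existing ones. The generator does not emulate sequencing
error, read-quality structure, strand-specific library artifacts,
paralogy/paleopolyploidy, or isoform structures beyond the single
shared-prefix minor isoform; passing tests therefore demonstrate
correctness of the computations and recoverability of planted structure
under these idealized conditions, not robustness to real-data artifacts.

## Problem sizes and numerical conventions

Tests and the acceptance script run at desk scale: 5,000 loci per
species for PPK recovery, ~500 contigs for binning-oracle equality,
600 loci × 4 sections × 10 seeds for clustering recovery, 50 × 50
proteomes for alignment-oracle equality and 150 planted pairs for RBH
recovery — sizes at which the planted-parameter statistics are stable
and the exhaustive oracles remain tractable. Degenerate inputs follow
the contracts above: empty collections raise errors where a statistic is
undefined (quartile of nothing, correlation of a constant, RPKM at zero
mappable length give NaN/missing rather than 0). All tie-breaks are
lexicographic by identifier — determinism is preferred everywhere to
fidelity to unstated behaviour of the original tooling.

## Known limitations

- Exact-substring binning is stricter than alignment-based overlap
  detection; highly polymorphic allelic contigs that never share a
  200-bp exact block will split into separate loci.
- Window-based unique mappability ignores sequencing error and
  mismatch-tolerant alignment.
- The similarity search's seeded mode can in principle miss a best hit
  that shares no 4-mer with the query; exhaustive mode is used
  automatically at small scale, and seeded mode is validated only for
  the high-identity regime it is intended for.
- The thermostability score is a composition heuristic; it carries no
  structural information, and its agreement with the external ranking
  tool it streamlines is not assessed here.
- The within-SS elbow needs a cluster structure with a sharp knee;
  on weakly structured data the second-difference criterion can be
  unstable.
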