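# Methods

This note documents the models, numerical choices and open design
decisions behind `viropan`, and what the synthetic corpus does and does
not establish about behaviour on real genomes.

## Similarity engine and statistics

Pairwise protein similarity is optimal local alignment under BLOSUM62
with affine gaps (open 11, extend 1), computed by Biopython's C pairwise
aligner; the score is the exact Smith–Waterman optimum (the test suite
checks exact score equality against an independently written brute-force
dynamic program).  Raw scores are converted with Karlin–Altschul
statistics using the standard gapped-BLOSUM62 parameters λ = 0.267,
K = 0.041: bit = (λS − ln K)/ln 2 and E = m·n·2^(−bit) with m the query
length and n the total database residues.  The engine is a pluggable
object (`AlignmentScorer`), so an external search tool could be
substituted without touching the pipeline logic.

The reciprocal-hit graph weights each edge by the pair's bit score
normalized by the smaller of the two self-alignment bit scores (clamped
to 1), so a perfect reciprocal match weighs 1.  Algebraic connectivity is
the second-smallest eigenvalue of the normalized graph Laplacian by
default (an unnormalized variant is a flag); components with λ₂ below
the minimum (default 0.3) are split along the sign pattern of the Fiedler
vector, computed by a dense symmetric eigendecomposition for
determinism, with zero entries assigned to the smaller side.

## Profiles

Group profiles are affine-gap position-specific scoring models, not full
Plan7 profile HMMs.  The contract the pipeline consumes — build from an
MSA, search a database with an e-value, compare two profiles with a
score — is identical, and a profile-HMM engine could be slotted in behind
the same interface.  Details:

* **MSA**: MAFFT (progressive FFT-NS-2), inputs canonically sorted by
  protein id so results do not depend on supply order.
* **Match columns**: ≤ 50 % gaps (the standard profile convention).
* **Frequencies**: position-based (Henikoff) sequence weights; mixture
  with substitution-matrix pseudocounts,
  p_a = (c·f_a + w·g_a)/(c + w) with g_a = Σ_b f_b P(a|b) implied by
  BLOSUM62 and w = 5 by default.  Scores are log₂(p/background), with the
  BLOSUM62 marginal background.
* **Gap penalties**: 6.0 bits open, 0.6 bits extend per column —
  comparable in scale to the strongest single-column match score
  (≈ 4.3 bits), mirroring the open/extend ratio of the pairwise scheme.
* **Search**: optimal local profile-to-sequence alignment over the whole
  database, computed by a numba-compiled kernel (a vectorized numpy
  fallback produces the same scores).
* **E-values**: a Gumbel law fitted by moments to the scores of 200
  composition-preserving shuffled decoys drawn from the database
  (fixed seed 1091, configurable); E(s) = N·P(S ≥ s).  The decoy set is
  pooled over database lengths; at the corpus sizes involved the
  length-dependence of the null is small compared to the decision
  margins, and the calibration is cached per profile.

### Profile-profile score calibration

The column-pair score for comparing two profiles is the co-emission
log-odds log₂(Σ_a p1_a·p2_a / bg_a), aligned locally with affine gaps.
The pipeline's merge threshold of 20 is a convention expressed in the
units of a different tool, so the raw bit score is rescaled once
(×0.5) so that the threshold separates related from unrelated profile
pairs.  Calibration procedure (reproducible from the test suite): build
profiles for all planted families of a simulated corpus, compare the two
halves of each family (related pairs) and all cross-family pairs
(unrelated); on the default corpus related half-pairs score ≥ ≈ 54 and
unrelated pairs ≤ ≈ 12 in the calibrated units, leaving 20 comfortably
between the two populations.

### Membership requires profile coverage

Every decision that brings a protein *into* a group from outside —
stage-2 membership filtering, stage-4 enrichment, the relaxed passes of
stages 5–7, and paralog attachment — additionally requires the
candidate's optimal local alignment to span at least 50 % of the profile
columns.  Genuine members and remote homologs align along most of the
model (observed coverage ≈ 1.0); spurious e-value-borderline hits,
antisense "shadow" ORFs of conserved genes, and short-segment chance
matches cover only ~10 % of the columns.  Two desk-scale effects make
this necessary: at a few hundred database proteins an e-value of 10
admits roughly the best random hit per genome, and a Gumbel tail fitted
from 200 decoys is imprecise exactly at the strict-threshold boundary
(p ≈ 4·10⁻⁵).  The coverage requirement removes both failure modes
without touching the e-value thresholds; proteins already inside a group
(the MSA's own sequences) are exempt, since the check is about external
evidence.

## Pipeline semantics

Decisions the stage descriptions leave open, fixed here:

* **Stage 2** (profile validation): round-1 membership is the profile's
  hit set intersected with the union of all stage-1 clusters; rounds 2–3
  rebuild and re-search, and the whole group is discarded when any
  founding member drops out of the hit list.
* **Stage 3** (share-a-protein merging): candidate pairs are processed in
  ascending group-id order; a merge is executed only when the union keeps
  ≤ 1 protein per genome, otherwise both groups survive and the shared
  protein is resolved to the lexicographically first group (a logged
  conflict).  Merge order matters when conflicts interact, so it is fixed
  for determinism.
* **Stage 4** (enrichment): only proteins not yet assigned to any group
  are eligible additions; the best-scoring hit per uncovered genome is
  added each round.  On a member loss the last good membership is kept
  (the alternative — accepting the shrunken set — would let one bad round
  erase earlier evidence) and the group is flagged.
* **Stage 5** (profile merging): all pairs are scored once with the
  pre-merge profiles and merges applied greedily in descending score
  order; rescoring after each merge would be quadratic in merges and the
  greedy order is deterministic.
* **Stage 6**: the "excluded genomes" searched by translated-genome
  rescue are all genomes missing from the group (configurable).
* **Stage 8** (synteny): only near-complete groups (≥ 70 % genome
  coverage by default) are candidates — positional conservation is only
  evidence of orthology for genes that are otherwise universal, and
  applying slot-rescue to genus-restricted families would adopt whatever
  gene happens to occupy the equivalent position in genera that genuinely
  lack the family.  A candidate is "syntenic" when its member lies within
  ±5 genes (circular order) of an anchor-group member in ≥ 80 % of the
  genomes that carry it.  "Previously reported biological function"
  adoptions are an explicit curated override file (group → protein),
  applied and recorded, never inferred.
* **Paralogs**: proteins outside all groups that score at e ≤ 0.01
  against a group whose slot for their genome is occupied are attached as
  paralog-flagged members; everything else outside groups is a unique
  gene.  The final catalogue partitions every protein exactly once.

## Divergence statistics

* Identity and similarity are percentages of the full global-alignment
  length (gap columns included); similarity adds substitutions with a
  positive BLOSUM62 score, so similarity ≥ identity always.
* The Z-score aligns the natural pair once and the first sequence against
  n composition-preserving shuffles of the second (default n = 297,
  matching the all-isolates set size the statistic is normally used
  with; tests use smaller n).  The standard deviation uses the n−1
  denominator.  A zero decoy deviation yields an undefined sentinel.
* K2P distances exclude sites with a gap or ambiguity in either sequence
  (pairwise deletion), count transitions and transversions without
  weighting, and return an undefined sentinel whenever a logarithm
  argument is non-positive.  Codon alignments are produced by threading
  each protein row of the group MSA back onto its coding sequence (gap →
  gap triplet, stop codon dropped), concatenating groups in ascending
  group-id order.
* Species delimitation is single linkage: pairs below the conspecific
  threshold join; the partition is the connected-component closure; pairs
  inside [low, high] that the closure leaves apart are flagged
  borderline.  The default thresholds 0.015/0.050 substitutions per site
  follow the demarcation convention used for these viruses; both are
  explicit configuration, not inferences.

## Synthetic corpus

The generator emulates the structure the pipeline must resolve, not the
biology of any particular virus family.  Defaults (the study
conditions): 3 genera of 6/5/5 circular genomes, species of 2 isolates
inside each genus, 10 core families, 2 genus-restricted families per
genus, 2.5 unique genes per genome on average, paralog and
annotation-omission rates 0.05, mean gene length 120 aa (desk-scale; long
enough for profile statistics to behave, short enough that a full
pipeline run takes seconds), intergenic spacers ~100 nt, three anchor
families in conserved order, seed 42.

Evolution is simulated on a star-within-star tree (family root → genus
ancestors → species ancestors → isolates), which makes expected pairwise
divergences additive and analytically predictable: within-genus amino
acid divergence 0.1, between-genus 0.8 (expected substitution events per
site; realized identity follows the 20-state Poisson formula
1/20 + 19/20·e^(−20D/19), verified by an alignment-based calibration
test).  Nucleotide sequences track every amino-acid event with a random
codon of the new residue, plus synonymous codon exchanges at 0.5 silent
substitutions per site per unit amino-acid divergence and purely
synonymous divergence (0.004/site) between isolates of one species —
so protein trees and nucleotide trees agree while dS > dN, and the
species structure is only visible at the nucleotide level.  Occasional
1–2-codon indels (rate 0.03 per codon per unit divergence) exercise the
aligner; start codons are never mutated (purifying selection), so every
planted gene remains an ATG-initiated ORF and omitted genes are
recoverable by prediction.

What passing on this corpus does **not** show: behaviour under genome
rearrangement beyond order shuffling, nucleotide composition bias,
overlapping genes, repeat families (e.g. the *bro*-like expansions),
spliced genes, or the annotation heterogeneity of decades of real
GenBank submissions.  The K2P estimator is exercised under its own model
assumptions; real core-gene alignments violate rate homogeneity.

## Numerical choices and degenerate inputs

* Single-node graphs have λ₂ = +∞ (trivially connected); disconnected
  graphs report 0 within 1e-9.
* ORF calls pair every ATG with its next in-frame stop (nested ORFs share
  a stop); circular genomes are scanned on a doubled sequence with calls
  longer than the genome discarded and duplicates collapsed.  Codons
  containing N translate to X; ORFs are not split at N.
* Genes are identified across annotation/prediction by
  (genome, strand, 3'-end) — two coding features sharing a stop codon are
  the same gene even when their annotated starts differ.
* Ties in profile-search output are broken by protein id; group ids are
  assigned from the sorted cluster contents, so results are invariant to
  genome input order.
* The undefined-distance sentinel is NaN throughout; species delimitation
  treats NaN as "greater than the distinct threshold".

## Problem sizes

Default test and acceptance runs use the 16-genome corpus (~235 proteins,
~7.4 kb genomes); a full pipeline run takes ~15 s on one CPU, and the
20-seed recovery battery ~5 minutes.  These sizes were chosen so the
whole validation cycle runs on a laptop; nothing in the implementation is
specific to them, but wall-clock on a 300-genome corpus will be dominated
by the all-vs-all stage (quadratic in total proteins).
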