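# Methods

This note documents the models, defaults and design choices behind
`repclust`, and what the synthetic study conditions do and do not show
about real repertoire data.

## Pair curation

Two antibodies are functionally similar when the Jaccard index of their
epitope residue sets is at least `jaccard_threshold` (default 0.75).
Candidate pairs are formed within antigens only, after restricting to
the `top_antigens` (default 50) antigens with the most assay-positive
epitope entries (ties broken by antigen id — "most well annotated" is
operationalized as entry count, the only metric available here).
Structure/species/scFv/chain filters are applied to pair members after
pairing so that per-pair drop provenance is observable; the retained
set is identical to filtering first. Pairs whose members share an
identical full receptor sequence or an identical CDRH3 are removed as
redundant.

CDRH3 identity between pair members is reported as
1 − L/(len C₁ + len C₂) (sum-of-lengths denominator). The conventional
max-length form 1 − L/max(len) is available via
`levenshtein_denominator="max"`. The sum form is bounded below by 0.5
for equal-length sequences (L ≤ len), so identity thresholds carry a
different meaning under each form; the pair annotation keeps the sum
form, while clonotyping defaults to the max form (below).

Functional clusters — connected components over retained pairs — are a
derived view (`functional_clusters`), not part of curation output.

## Backtranslation

Each heavy chain is aligned (BLOSUM62, affine gaps −11/−1, local mode —
pinned so results are reproducible) against the translations of every
germline V and J nucleotide reference; the best-scoring gene per
segment wins. Covered positions are rebuilt codon by codon: among the
codons encoding the observed amino acid, minimal Hamming distance to
the reference codon wins; ties are broken by maximal substitution
likelihood, and any residual tie deterministically by codon string
(flagged). A k-substitution codon scores the maximum over all k!
mutation orders of the product of per-step trimer likelihoods, with the
context re-derived from the partially mutated sequence after each step.
During left-to-right reconstruction the left context comes from the
already-built sequence and the right context from the yet-unmodified
reference scaffold.

The trimer model is the arithmetic mean, per substitution, over the 16
fivemers that embed the trimer with the mutating base at the fivemer
center; the aggregation is repeated for the start and end base of the
trimer, and the standard deviation over the 16 values is kept per
entry. Positions at a sequence terminus use the start/end sub-tables
(their centered window would cross the terminus).

Junction (CDR3) positions have no reference codon. They are filled with
the highest-frequency human codon per amino acid — a deterministic rule
isolated in one table (`JUNCTION_CODON`). Determinism was preferred
over realism here: junction nucleotides affect no downstream statistic
(SHM rates exclude the junction; clustering operates on amino acids or
structures), but a reproducible byte-identical output does.

Reference ties at the amino-acid level are resolved by fewest total
nucleotide substitutions, then by the higher total substitution
likelihood (sum of per-codon log likelihoods), then by gene name.

## SHM calibration

The corrected rate is n_mutations / covered_len, where covered_len
counts only reference-covered nucleotides — the junction is excluded
because mutations there cannot be identified without an aligned
reference, and leaving it in the denominator would systematically
underestimate the rate. Mutations are substitutions only; the
codon-paired alignment model has no indels.

Tier derivation reduces the nonzero corrected rates to a (low, high)
pair. The default rule splits at the median of the nonzero rates and
takes group means; it is accurate when the two groups are balanced but
drifts when they are not, so a minimal-within-variance split
(`method="variance"`, an exhaustive 1-D two-class split) is also
provided and is what the pipeline uses — under the 36:14 low:high
design mixture the median lands inside the low group. Whether the
reference tiers 5.1%/11.9% are means, medians or modes of an observed
distribution is not derivable here; the package treats them as fixed
defaults (`RateTiers()`) recovered by either rule under clear
separation.

## Synthetic study conditions

The synthetic-data module replaces four external resources:

* **Germlines** — five heavy V, three heavy J, three kappa V, two kappa
  J synthetic segments sharing one region architecture (FR1 25, CDR1 8,
  FR2 17, CDR2 8, FR3 38, FR4 11 aa for the heavy chain). Nucleotide
  sequences encode fixed protein variants with per-gene varied
  synonymous codons, so genes differ at both levels.
* **Fivemer table** — lognormal(σ=0.5) likelihoods with WRC/GYW hotspot
  contexts boosted 3×: enough context structure to make codon choice
  non-trivial without claiming empirical mutabilities.
* **Curated set** — 54 antibodies over five antigens. Epitope sets are
  nested prefixes of per-cluster residue pools, so every pairwise
  Jaccard equals the ratio of the smaller to the larger set size. The
  31 frozen set sizes of the large antigen yield exactly 197 pairs in
  one connected component; ten small clusters add 16, for 213 pairs.
  CDRH3 lengths (frozen) put exactly 20 pairs in the same-length class
  (13 + 7), i.e. 193/213 = 90.61% of pairs differ in some CDR length.
  CDRH3 sequences come in families keyed to the same-length pair
  cliques; light-chain CDRL3 lengths follow a frozen graph coloring so
  that two curated antibodies share the full six-CDR-length tuple *iff*
  they are an annotated same-length pair. This is what makes "no
  curated false positives" a structural property of the fixture for
  every clustering method — a designed regression property, not a
  biological claim. Framework mutations are drawn from the SHM tier
  mixture (an amino-acid substitution costs ≈1.25 nt here, hence the
  1.9 scaling divisor), so calibration on the fixture recovers tiers
  near 5.1%/11.9%.
* **Structures** — synthetic backbone models (N, CA, C) on a smooth
  curve. The framework trace depends only on the CDR-length class, so
  same-class models superpose exactly; CDR atoms carry a 2 Å
  conformation offset per (class, group) template plus per-antibody
  Gaussian noise (default 0.5 Å) and a random rigid motion. Passing
  functional groups makes structural similarity track functional
  grouping — the premise structure-based clustering relies on. With
  0.5 Å noise the expected within-group CDR RMSD is ≈ 0.5·√6 ≈ 1.2 Å,
  straddling the 1.25 Å default cutoff, so the 1.0–2.5 Å sweep shows a
  rising recovery curve while between-group RMSD (≈ 5 Å) keeps groups
  apart at every swept cutoff.

The simulator draws V and J uniformly, junction amino-acid lengths as
9 + Poisson(2.5) clipped at 23 (range 9–23, mode 11), SHM tiers from
the (0.50, 0.36, 0.14) mixture, and per-site substitutions at the tier
rate over V+J-covered nucleotides with target bases proportional to the
trimer likelihoods; substitutions that would create a stop codon fall
back to the next-likeliest base. Kappa light chains are generated and
paired but take no part in clustering (heavy-chain/CDRH3-centric
methods; light chains only contribute CDR lengths to the partition
key). Uniqueness is enforced at the nucleotide level by default
(`uniqueness="aa"` available). The default pipeline simulates 10,436
sequences so the spiked repertoire totals 10,490 unique sequences.

What the fixture does **not** emulate: clonal expansion
(deliberately — the background is naive), indel-driven CDR length
variation within families (so low-identity pairs here are all
cross-length and recoverable by no method, whereas real curated sets
contain same-length low-identity pairs recoverable by chaining),
lambda light chains, sequencing error, and real CDR1/2 length
diversity (all germlines share one architecture, so length partitions
are coarser than in real data). Passing tests therefore demonstrate
correctness of the machinery and the designed properties of the
fixture, not performance on real repertoires.

## Clustering

Clonotyping partitions records by the enabled keys (V call, J call,
optionally CDRH3 length) and single-links records whose CDRH3 identity
meets the cutoff (default 0.80). Single linkage with a flat cutoff is
realized as connected components of the threshold graph via union-find
— exactly equivalent, with no dendrogram construction. Identity uses
the max-length denominator by default (the conventional reading of an
80% identity threshold); the sum form is a setting. CDRH3-length
matching defaults off: same-epitope pairs with differing CDRH3 lengths
exist, and requiring equal length would exclude them. A length-bucket
bound (distance ≥ length difference) prunes pairs that cannot reach
the cutoff before any edit-distance call.

Length-partition clustering keys on the (H1, H2, H3, L1, L2, L3) CDR
length tuple; with an identity cutoff it refines each partition by
single linkage and never merges across partitions.

Structure clustering partitions by CDR-length class, superposes
framework backbone atoms by Kabsch (SVD with a reflection guard, so the
rotation is always proper), and clusters on CDR backbone RMSD. Default
linkage is single, for consistency with the sequence method; average
linkage (scipy hierarchy) is a setting, since the upstream method
family specifies only "agglomerative". Backbone atoms default to
{N, CA, C}; whether light-chain CDR atoms enter the RMSD follows from
the model contents (both chains are included when present).

## Evaluation

A pair is recovered iff both members share a cluster id. Printed
percentages are rounded half-up to two decimals (100·24/213 → 11.27).
Mean cluster size is n_clustered/n_clusters before rounding.
Low-identity recovery restricts to pairs with CDRH3 identity < 0.8
(sum form, as annotated at curation).

The random clustering rate fills the observed cluster-size template
with a uniform random permutation of the items and counts co-clustered
annotated pairs, averaged over 1000 replicates. The closed form
|P| · Σ s(s−1) / (n(n−1)) is computed alongside; it holds for pairs
sharing antibodies by linearity of expectation (the sum over 213
overlapping pairs is not binomial, but each pair's co-clustering
probability is Σ s(s−1)/(n(n−1)) regardless).

Pair confusion counts, over all unordered curated-antibody pairs that
are co-clustered, those in the annotated set (TP) and not (FP);
precision is defined as 1.0 when nothing is co-clustered.

## Problem sizes and numerics

The default pipeline uses 10,436 simulated sequences; structure
clustering runs on the curated set plus an 800-sequence random
subsample (pairwise RMSD within a CDR-length class is quadratic in
class size, and the curated-set comparisons are unaffected by the
subsample size). Tests use smaller repertoires (40–10,000 depending on
the property under test). Monte-Carlo checks compare against closed
forms within 3 standard errors; geometric identities use 1e-8 Å
tolerances. Stage seeds derive deterministically from the global seed
(CRC32 of the stage name mixed in, reduced mod 2³¹), so stages
reproduce in isolation and identical configs give identical artifact
checksums.

## Known limitations

* Local alignment may trim a terminal mismatched residue from germline
  coverage, slightly shrinking the SHM denominator for heavily mutated
  termini.
* The junction fill rule is a stand-in; junction nucleotides should not
  be interpreted biologically.
* The curated fixture's low-identity pairs are all cross-length, so
  chaining-based recovery of low-identity pairs — observed in real
  curated sets — does not occur under the default study conditions.
* Clonotype V/J calls on heavily mutated fixture antibodies can flip to
  a neighbouring germline variant, which can cost a recovered pair (an
  analogue of real gene-assignment error, but not calibrated to it).
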