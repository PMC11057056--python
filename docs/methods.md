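# Methods

This note documents the models, parameter choices and numerical decisions
behind `sawselect`, and what the synthetic validation does and does not
demonstrate about real data.

## Codon substitution model

All likelihood computation and simulation uses a GY94-type codon model on
the 61 sense codons of the standard genetic code; stop codons are excluded
from the state space and the simulator never emits them.  Instantaneous
rates for a single-nucleotide change i → j are

    q_ij = pi_j * kappa^[transition] * omega^[non-synonymous],

zero for multi-nucleotide changes, diagonal set so rows sum to zero.
Codon frequencies default to uniform 1/61 (closed-form anchors for tests);
an F3x4 option is provided.  Each branch's generator is normalized to unit
mean rate **under that branch's own ω mixture**, so a branch length is the
expected number of substitutions per codon averaged over its site classes.

The model is reversible, so the symmetrized generator
`diag(√π) Q diag(1/√π)` admits a symmetric eigendecomposition; transition
matrices for any branch length then cost two 61×61 products.  Decompositions
are cached per (κ, ω), which is what makes maximum-likelihood optimization
affordable: one objective evaluation needs at most three eigendecompositions
regardless of the number of branches.  Likelihoods use Felsenstein pruning
vectorized over site patterns (alignments are pattern-compressed first).

## The branch test

The episodic-selection test is a fixed two-class simplification of the
adaptive branch-site random-effects framework: the branch under test gets
classes (ω₁ ∈ [0,1], weight 1−w) and (ω₂ ∈ [0, 10⁴], weight w), each site
drawing its class independently; background branches share a single free ω.
The null constrains ω₂ ≤ 1.  The statistic 2Δℓ is referred to the boundary
mixture ½χ²(1) + ½χ²(2).  We deliberately do not implement adaptive
ω-class-count selection: at single-gene alignment sizes the two-class model
is the identifiable core of the test.

Fitting is two-stage. Stage 1 estimates κ, a single ω and all branch
lengths per gene under L-BFGS-B in log space (the two root-child edges are
merged into one parameter since only their sum is identifiable under a
reversible model; the sum is split in proportion to the input tree's
lengths).  Stage 2 holds κ and branch lengths fixed and optimizes
(background ω, ω₁, log ω₂, w) per tested branch.  Freeing the test-branch
length in stage 2 was evaluated and changed mixture-weight estimates only
marginally, so the simpler two-stage scheme is kept.

Optimizer policy: up to three starts per model, spent lazily — the first
alternative start is seeded from the null solution, a second from a
high-ω₂ configuration, and further restarts are used only while the nested
inequality ℓ̂_alt ≥ ℓ̂_null is violated.  Convergence tolerance is 1e-10 on
the scaled objective (comfortably below the 1e-6 log-likelihood tolerance
used by the oracle tests); a branch fit that still violates nesting by more
than 1e-3 is flagged non-converged and can never produce a PSG call.  An
ω₂ within 1e-6 of the 10⁴ cap is reported as capped — the signature of
branches with non-synonymous but no synonymous substitutions — and
winsorized to the cap before feature standardization in the clustering
stage, where it would otherwise dominate.

Holm–Bonferroni correction is applied across genes per branch by default
(a per-gene across-branch family is available); the PSG rule is focal
corrected p ≤ 0.05 and no other terminal branch significant.

## Synthetic study conditions

The species tree is the five-taxon chordate phylogeny (coelacanth
outgroup, then ghostshark, catshark, and the skate–sawfish pair).  The
source phylogeny gives divergence times, not substitution branch lengths;
since every split is ancient (roughly 270–420 My), defaults reflect
deep-divergence coding sequence: terminal branches 0.40–0.70 expected
substitutions per codon (longest on the oldest lineages), internal
branches 0.15.  Background selection is purifying (ω = 0.2) with κ = 2.5,
typical of conserved vertebrate coding genes.  Planted episodic selection
uses ω₂ = 9 on 30 % of sites on the sawfish branch.

The generators emulate the *structure* of real inputs — codon alignments
with branch-specific ω mixtures, orthogroups with paralogs/length
outliers/missing taxa, reads realizing an exact depth profile with
splice-junction records, and three-feature PSG tables with planted
clusters.  They do not emulate indel evolution, sequencing error, assembly
artifacts, alignment uncertainty, or among-site rate variation beyond the
ω mixture.  Passing tests therefore demonstrate the statistical and
algorithmic correctness of each stage under its own model assumptions, not
robustness to real-data model violations.

## Validation sizes and observed behavior

* Calibration: 200 null replicates (300 codons) in the test suite; the
  acceptance script uses 150.  The test is conservative — empirical type-I
  error at α = 0.05 is near zero, as expected for a boundary-constrained
  mixture null.
* Power: 50 replicates (500 codons, ω₂ = 9, w = 0.3) in the test suite, 40
  in the acceptance script; unique detection and ±0.15 weight recovery both
  exceed 80 % under the default tree.  At the demo's shorter 200-codon
  alignments power visibly drops after Holm correction — reported, not
  masked.
* Oracle checks: pruning vs. brute-force ancestral-state enumeration on
  three-taxon, ≤ 5-codon cases (agreement ≤ 1e-6); 61×61 substitution
  classification vs. the code table; Holm vs. the direct step-down formula
  on 1000 random vectors; GRAVY/profiles vs. table lookups on 1000 random
  proteins; local-alignment scores vs. a quadratic Gotoh DP.

## Other numerical and design choices

* **Coordinates** are 0-based half-open throughout; SAM input is converted
  on read.  Overlap = ≥ 1 shared base, strand-blind (unstranded libraries).
* **Low-coverage regions** use per-base strict `< threshold` (default 5);
  the `<5 reads` rule is read per-base, not region-mean.
* **Redundancy removal** keeps the longest sequence per ortholog id, ties
  by lexicographically smaller id.
* **Length-outlier filter** computes the group mean once, pre-filter; the
  discard rule is strict (`> 100` aa deviation).  The taxon-coverage filter
  is re-applied after paralog splitting (toggleable).
* **"Closest aligning" ortholog** = highest identical-residue fraction over
  mutually ungapped MSA columns; ties by fewer gapped columns, then id.
* **Profiles**: windowed means with odd windows; edge positions where the
  full window does not fit carry the raw residue value.  Delta profiles
  default to window 1 (per-residue change); profiles are computed on
  ungapped sequences and mapped through the pairwise alignment, replacing
  the manual gap correction of interactive workflows with a reproducible
  index mapping.  Deltas are stored focal − reference with the sign
  convention recorded; skate-oriented output is produced by negation in the
  report writer.
* **Amino-property classes** (hydrophobic / polar-uncharged / basic /
  acidic) are explicit configuration: published figures rarely state their
  partition, so ours is a documented default, not a reconstruction.
* **Enrichment** is a plain one-sided hypergeometric tail with optional
  Benjamini–Hochberg column — deliberately *not* a GO-graph-aware (elim)
  algorithm; term hierarchies are out of scope.
* **Clustering** runs on standardized raw features; PCA is computed for
  visualization.  k is a required choice (default 2 in the pipeline
  config), never selected silently.
* **Ortholog search** uses exact Smith–Waterman (BLOSUM62, open 11 /
  extend 1) with reciprocal-best flags instead of a heuristic seeded
  search: deterministic and exhaustive at curated-panel scale, with scores
  rather than e-values.
* **FPKM** uses total mapped reads in the library as the denominator and
  counts primary alignments only.
* **Degenerate inputs**: empty alignments fail the >20-codon gate; an
  exon-inclusion call with no informative junction reads returns an
  undefined (flagged) fraction; zero-variance features abort
  standardization with the column named.

## Known limitations

Branch lengths and κ are not re-estimated under the alternative model;
synonymous rate variation, multi-nucleotide mutations and indels are not
modelled; the Holm family matching the original gene-level calls is
ambiguous (both options are implemented); enrichment ignores the GO graph;
the pipeline's cache keys on file checksums, not on code versions.
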