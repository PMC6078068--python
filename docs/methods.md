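# Methods

This note documents the models, parameter choices and numerical conventions
behind `txfuse`, and what the packaged synthetic benchmark does and does not
demonstrate.

## Similarity graph and clustering

Homology between pooled contigs is measured on canonical k-mer sets (k = 31 by
default; the canonical form of a k-mer is the lexicographic minimum of itself
and its reverse complement, so similarity is strand-independent).  The score
is **max-containment**, `|K(a) ∩ K(b)| / min(|K(a)|, |K(b)|)`, rather than
Jaccard: transcript pools are full of fragment/parent pairs, and a fragment
must connect to its full-length version with weight ≈ 1 for the
representative-selection step to see them as one group.  Candidate pairs are
proposed through a shared-k-mer inverted index (k-mers occurring in more than
256 contigs are skipped as repeat guards when proposing pairs), so the
quadratic all-vs-all space is never materialised; the resulting edge set is
nevertheless identical to brute-force all-pairs computation, which the test
suite verifies.  Edges below `min_similarity = 0.1` are dropped — well below
genuine homology signal at k = 31, but enough to prune the pair space.

Clustering is classic MCL on the column-stochastic adjacency matrix with
self-loops set to each node's maximum incident edge weight (1.0 for isolated
nodes): alternate expansion (matrix power, e = 2) and inflation (entrywise
power I, then column renormalisation) until the matrix is stable
(`max |ΔM| < 1e-6`, cap 100 iterations; non-convergence yields the current
interpretation with a warning).  **Inflation defaults to 4**: the merging
protocol deliberately over-fragments clusters so that transcript isoforms —
which share large sequence blocks and would collapse at conventional
inflation 2 — tend to stay in separate groups and each keep a representative.
Two numerical details matter:

* Pruning (`1e-5`) is applied to the *renormalised* columns, not the raw
  inflated matrix.  Raw-matrix pruning at inflation 4 annihilates entire
  uniform columns for clusters wider than ~18 nodes ((1/n)⁴ < 10⁻⁵) and
  shatters them into singletons.  With post-normalisation pruning the
  implementation agrees exactly with a dense no-pruning reference on every
  fixture graph in the suite.
* Clusters are extracted per connected component (MCL can never merge
  components), attractors are rows with positive diagonal mass, attractors
  sharing an attracted node form one group, and each node joins its
  highest-mass attractor's group with ties resolved to the lowest group id.
  All remaining ordering ties anywhere in the pipeline break on the smallest
  id, so runs are bit-reproducible.

## Contig scoring

The four components and their composite follow the structure of read-evidence
assembly scoring (fidelity, coverage, pair agreement, per-transcript coverage
plausibility), with this package's own concrete definitions:

* `s_nuc` — Σ matched bases / Σ aligned bases over primary alignments.
* `s_cov` — fraction of contig positions under ≥ 1 primary aligned base.
* `s_ord` — among pairs with both mates primary on the contig, the fraction
  in FR orientation with template length ≤ `insert_mean + 3·insert_sd`
  (250 + 3·50 by default).  When a contig has no same-contig pairs the
  component is neutral (1.0) — short contigs should not be annihilated by an
  undefined quantity.
* `s_seg` — compare a 1-segment vs best 2-segment piecewise-constant model of
  log₂(coverage+1) under a Gaussian likelihood with shared variance.  The
  breakpoint is searched on a decile grid over the middle 80% of positions;
  model complexities are 2 (mean, variance) vs 4 (two means, breakpoint,
  variance); the score is the 1-segment model's BIC weight.  Zero-variance
  fits are floored at SSE = 1e-9·n so the likelihood stays finite — a
  perfectly uniform contig then wins by exactly the parameter penalty, and a
  50×/1× coverage step (a chimera junction) loses decisively.  All-zero
  coverage scores 0 and is flagged unsupported.

`composite = (Π max(component, 0.01))^{1/4}`; the floor keeps a single failed
component from zeroing the product.  The assembly score is the geometric mean
of composites times the pair mapping rate (both mates primary-mapped), and is
therefore bounded by the mapping rate.  Mapping rate counts *pairs*, not
reads; the choice is documented here because tools differ.

Only primary alignments feed the components: multi-mapped reads would
otherwise be double-counted.  Multi-mapping is instead handled at
quantification time (below).

## The bundled mapper

An exact-seed, ungapped mapper sufficient for scoring at benchmark scale:
canonical 31-mers of the contigs are indexed; each read probes four evenly
spaced windows; every seed hit implies one full-length ungapped placement and
the fewest-mismatch placement wins.  Placements must fit inside the contig
(no clipping, no gaps — read errors are substitution-only in the simulator,
so the model is exact there).  The full set of tied best placements is
recorded; the primary is drawn from the tied contigs by a splitmix64 hash of
the pair index (both mates share the hash, so concordant pairs stay on one
copy).  A deterministic hash rather than "always the lowest id" matters in
this pipeline specifically: pooled assemblies contain near-identical copies
of most transcripts, and a lowest-id rule would starve all but one copy of
reads, zeroing their coverage scores and distorting per-assembler
contributions; hashing spreads multireads evenly while keeping every run
byte-reproducible (`tie_break="lowest"` restores the naive rule).

## Quantification and bias stratification

Fragment counting assigns each mapped pair one unit, split equally over the
contigs its mates' best placements tie on (intersection of the two mates' tie
sets when non-empty).  TPM divides by the effective length
`max(length − insert_mean + 1, 1)` and renormalises to 10⁶.  Equal splitting
rather than an EM re-assignment is a deliberate simplification: the outputs
are used ordinally (rank recovery, per-origin medians), and an EM assigner is
a documented extension point.  Expression stratification summarises
log(TPM+1) (natural log) of merged winners per assembler of origin.

## Sketching and embedding

Assemblies are summarised by bottom-s MinHash signatures (s = 5,000 smallest
splitmix64 hashes of canonical 51-mers; the hash constants are fixed in the
source, so signatures are machine-independent).  Jaccard similarity between
two assemblies is estimated by the bottom-s merge estimator
`|bottom_s(A ∪ B) ∩ A ∩ B| / |bottom_s(A ∪ B)|`; at s = 5,000 the sampling
error is ≈ √(J(1−J)/s) < 0.008, and the suite verifies |estimate − exact| ≤
0.05 in ≥ 99% of random set pairs.  Distances 1 − J are embedded with
classical (Torgerson) metric MDS — double-centre −d²/2, eigendecompose, top
coordinates — which is deterministic and exact for Euclidean-realisable
matrices; axis signs are fixed by making each axis's largest-magnitude
coordinate positive.  A non-metric (stress-minimising) MDS would only change
the picture qualitatively and is intentionally not used.

## The synthetic benchmark

`standard_benchmark(seed)` builds: 500 single-isoform genes with log-normal
lengths (median 1,500 bp, σ_log 0.6, min 300 bp) and log-normal expression
(σ_log 1.5, normalised to TPM); 50,000 FR read pairs of 100 bp (the modal
read length of public short-read RNA-seq), insert 250 ± 50 bp, i.i.d.
substitution errors at 1%; and four corrupted assemblies.  Retention of a
transcript is an optional hard low-TPM dropout times a logistic curve in
log(TPM+1) — a smooth curve, not a threshold, because expression-dependent
recovery in real assemblers tapers gradually.  The four canned profiles
induce the orderings the merge is designed to exploit: "trinity" flat ~0.87,
"spades55" mildly low-abundance-biased, "spades75" strongly biased toward
high expression (the k-mer-length effect), "shannon" severely biased with the
fewest contigs.  Retained transcripts are then duplicated (2–8%, second copy
with 0.2% extra edits), fragmented (2–5%, split uniformly in the middle 50%),
used to seed chimeras (0.3–0.4%, concatenation with another retained
transcript), and given 0.1% substitution noise.  Every emitted contig is
traceable to its source transcript(s) via a provenance table.

Two calibration notes.  The retention curves were tuned once so the gene
recovery ordering shannon < spades75 < {spades55 ≈ trinity} holds across
seeds, each single assembly recovers < 90% of genes, and their union ≥ 95%.
Chimera rates are kept low deliberately: a chimera AB legitimately
co-clusters with its sources A and B (its containment to each is ≈ 1), so
every chimera bridges two gene clusters; sparse chimeras keep the planted
gene partition recoverable (ARI ≥ 0.95) while still exercising the
coverage-step diagnostics.  Isoforms are exercised in dedicated fixtures
rather than the benchmark, because inflation 4 intentionally splits isoform
groups, which is the opposite of what a gene-level partition check rewards.

**What the benchmark does not show.**  The generator has no indels, no
sequencing-platform error profile, no coverage bias along transcripts, no
strandedness, and chimeras are clean end-to-end concatenations rather than
partial misjoins.  Passing the suite therefore demonstrates the pipeline's
internal correctness and the direction of its effects (mapping-rate
dominance, duplication reduction, bias recovery) under controlled conditions
— not performance on real libraries, where alignment, repeat structure and
isoform complexity are far harsher.  Problem sizes (500 genes, 50k pairs)
were chosen as the smallest scale at which all distributional checks are
stable across seeds.

## Known limitations

* The mapper is exact-seed and ungapped; indel-bearing reads or contigs
  require an external aligner (any SAM against the pooled ids is accepted).
* Uniform read length is required by the vectorised mapper.
* Score-cutoff optimisation (reporting the best score over contig-filtering
  thresholds) is not implemented; scores are reported unfiltered.
* Residual-redundancy duplication (no ground truth) uses the clustering
  threshold as its similarity cutoff and is a coarser instrument than the
  provenance-based measure.
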