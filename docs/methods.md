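# Methods

## Problem and model

Given a bipartite set of known lncRNA–protein interactions and four
independent lines of protein evidence, the package ranks all unknown
lncRNA–protein pairs. The model has three stages: per-source protein
similarity, similarity network fusion, and path-constrained relevance
scoring on the resulting heterogeneous network.

### Protein similarity networks

Each source yields a symmetric matrix over one protein index with entries
in [0, 1] and unit diagonal (the diagonal is forced to 1 in every source;
self-weights are set separately by the fusion kernels, so this choice only
standardizes the container):

* **Seqs** — Smith–Waterman local alignment under BLOSUM62 with affine gap
  penalties (open 10, extend 1; configurable). These are the conventional
  protein local-alignment defaults; the alignment engine is
  `Bio.Align.PairwiseAligner`. The raw score is normalized by
  `sw(i,j)/√(sw(i,i)·sw(j,j))` and symmetrized by averaging the two
  orientations (a no-op for symmetric substitution matrices). Values are
  clipped into [0, 1]; normalized scores can exceed 1 only in pathological
  asymmetric-scoring configurations. Proteins without sequences get zero
  off-diagonal rows.
* **Go / Pfam** — flat Jaccard overlap of annotation sets. No GO-graph
  propagation or information-content weighting is performed: the similarity
  is the overlap of the annotation sets as given, over all three GO
  ontologies pooled. A pair where either set is empty scores 0 rather than
  an undefined 0/0.
* **String** — confidence/999 (999 is the scale maximum), symmetrized by
  taking the larger score when both edge directions are listed. Unlisted
  pairs are 0.
* **Binary** — the baseline representation: the STRING network thresholded
  at the smallest positive listed score, i.e. edge existence with weight 1.

Identifiers are joined across sources by exact string match after
whitespace stripping (case-sensitive, no accession-version trimming).
Proteins present in the interaction set but absent from a source keep a
zero row in that source and are flagged, letting fusion fill in from the
other sources. lncRNAs with a single known partner are dropped in one
pass, because a held-out edge would leave them with no remaining evidence.

### Similarity network fusion

Each network `W` gives a row-stochastic full kernel
`P(i,j) = W(i,j)/(2·Σ_{k≠i} W(i,k))` off-diagonal with `P(i,i) = ½`
(rows sum to 1 analytically; a row with no off-diagonal mass falls back to
an identity row with a warning), and a local kernel `S` restricted to each
protein's k nearest neighbours, row-normalized over the neighbourhood.
The update diffuses each network through its own kNN graph against the
average of the other networks, then re-applies the full-kernel map so rows
sum to one and the diagonal (½) dominates every off-diagonal entry. The
fused network is the plain average of the diffused kernels, symmetrized as
(P+Pᵀ)/2, rescaled by its largest off-diagonal entry and given a unit
diagonal so downstream code consumes a valid similarity matrix.

Parameter defaults:

* `k` (neighbourhood size): `max(3, n/10)`, capped at n−1 — the
  conventional neighbourhood fraction for this family of methods. With the
  80-protein benchmark this is k = 8.
* `t_max` = 20 sweeps with early stop when the mean maximum entry change
  across networks falls below 1e-6; the diffusion converges within a few
  sweeps on all matrices we generate.
* kNN ties at rank k break to the lower protein index, for determinism.

### HeteSim scoring on the LPP path

The heterogeneous network has lncRNA and protein node types and two
relations (interaction, similarity); lncRNA–lncRNA links are not modelled.
Scoring follows the lncRNA→protein→protein relevance path, split at the
middle protein type: with `A` the row-normalized interaction matrix and
`B` the row-normalized similarity matrix, the score of (l, p) is the
cosine `⟨A(l,:), B(p,:)⟩ / (‖A(l,:)‖·‖B(p,:)‖)` of the two
reach-probability distributions. Choices made here:

* The normalization is read as the product of Euclidean norms (cosine),
  the standard normalized-relevance form; the printed notation
  `√(‖a‖‖b‖)` is ambiguous, so the literal square-root-of-product
  variant is available via `denominator="sqrt"` (it is always ≤ the
  cosine score, since reach distributions have norm ≤ 1).
* The similarity matrix's diagonal is zeroed before row normalization, so
  a protein's reach distribution describes its neighbours rather than
  itself, consistent with the kNN kernels and ordinary random-walk
  practice; `pp_keep_diagonal=True` preserves the alternative.
* A zero reach distribution on either side scores 0.

A slow dictionary-based recursive evaluator (`hetesim_recursive`)
implements the neighbour-enumeration definition directly, with transition
probabilities proportional to edge weights (reducing to the uniform
`1/(|O||I|)` neighbour-pair average on 0/1 relations). It exists as an
independent cross-check of the matrix form and supports only the path
lengths the pipeline uses.

### Evaluation

LOOCV holds out each known edge in turn and re-scores it from the modified
interaction row; unknown pairs are scored once under the full matrix.
Along the LPP path, removing an edge of lncRNA l only changes row l of the
reach matrix, so negatives are unaffected by other lncRNAs' holdouts; a
`strict_negatives` mode verifies this per fold on small fixtures. The
negative set is *all* unknown pairs in the interaction universe (not a
sample), and candidate proteins come from the interaction universe, not
the full proteome. ROC/AUC uses grouped thresholds with trapezoidal
interpolation (ties count ½, equal to the normalized Mann–Whitney
statistic); the curve computation is delegated to scikit-learn and
cross-checked against `scipy.stats.mannwhitneyu` in the tests.

## Synthetic benchmark

The generator plants a block structure: proteins are partitioned into
functional blocks, lncRNAs are assigned to blocks and wired to same-block
proteins with density 0.15 versus 0.01 between blocks (every lncRNA is
guaranteed ≥ 2 partners). Each evidence channel observes the same blocks:
sequences are lightly mutated (10% of sites) copies of a block-ancestral
60-mer; GO/Pfam sets are drawn from block pools with 10% background
contamination; STRING lists all within-block pairs at high confidence
(150–999) plus half of the between-block pairs at low confidence (0–400),
so edge *existence* is noisy while the scores are informative — which is
what separates the weighted String setting from the Binary baseline.

`noise_per_source` is the fraction of proteins whose measurement in a
channel is uninformative (random sequence, background-pool annotations, a
wholesale-garbled STRING row). The unreliable subsets are drawn
independently per channel, so the channels carry complementary
information: a protein corrupted in one source is usually clean in
another, which is precisely the regime where cross-network diffusion
recovers structure that no single network holds. Under uniform per-pair
noise instead, the strongest single channel would dominate and averaging
could only dilute it; the per-protein model is also the more realistic
portrait of heterogeneous databases, whose failure mode is patchy coverage
rather than uniformly noisy entries.

Default study conditions: 80 proteins, 200 lncRNAs, 4 blocks, per-source
noise 0.4, evaluated over 10 generator seeds. At these sizes the full
16-setting sweep over 10 seeds takes a few seconds on one CPU.

What the benchmark does *not* emulate: real identifier schemes, GO DAG
topology and term depth, domain co-occurrence structure, the heavy-tailed
degree distributions of real interaction data, and lncRNA sequence
features (lncRNAs are pure index nodes). Passing the benchmark shows the
pipeline's stages are internally correct and that fusion behaves as
designed under complementary noise; it does not certify performance
numbers on real NPInter/STRING extractions.

An intrinsic ceiling: within a block, HeteSim assigns near-identical
scores to interacting and non-interacting pairs (both reach distributions
concentrate on the block), and between-block positives carry no signal at
all, so even noiseless AUC sits near 0.8 at the default densities rather
than 1.0.

## Numerical choices and degenerate inputs

* Symmetry, range and unit-diagonal invariants are asserted to 1e-9.
* Isolated proteins (zero similarity row) become identity rows in the
  full kernel and zero rows in the local kernel; zero transition-matrix
  rows are left zero and flagged rather than raised.
* The fused matrix is exactly symmetrized before use because the
  diffusion product is only symmetric up to floating-point error.
* lncRNAs with no surviving interactions score 0 everywhere.

## Known limitations

* Paths longer than LPP are not implemented in the production scorer.
* GO semantic similarity is flat Jaccard by design; ontology-aware
  measures (Resnik/Lin) are out of scope.
* The LOOCV negative set grows as L×N; for very large universes a sampled
  negative set would be needed.
* No identifier-mapping services; a pre-mapped TSV is the supported route
  for reconciling database id schemes.
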