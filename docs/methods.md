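# Methods

This note records the modelling and numerical choices behind `fsinet`, the
parameters that matter, what the synthetic data does and does not emulate,
and the package's known limitations.

## Problem setting

Given `m` drugs, `n` target proteins, and a binary matrix `W⁰ ∈ {0,1}^{m×n}`
of known drug–target interactions, the task is to score every unknown
(drug, target) pair so that missing true interactions rank highly. The
setting is extremely imbalanced (real interaction lists cover well under
1% of all pairs) and closed-world: every unknown pair is treated as a
negative during evaluation, on the understanding that some of them are
undiscovered positives — which is precisely what makes high-ranking
"negatives" interesting.

## Similarity kernels

All kernels return a labelled symmetric matrix with values in [0, 1] and a
unit diagonal.

- **Binary-profile indices.** Tanimoto and Jaccard coincide on binary
  vectors (`u·v/(‖u‖²+‖v‖²−u·v)` = |intersection|/|union|); both are kept
  as separately named measures because they arise from different datasets
  in a catalog. Cosine is `u·v/(‖u‖‖v‖)`. Any pair involving an all-zero
  profile is defined as 0 off-diagonal: this is the NaN-free convention
  for entities a dataset simply does not cover, and it composes with the
  catalog-alignment rule below.
- **Inverse shortest path.** Edges below the confidence threshold
  (default 0.5) are dropped; pairwise distances are hop counts
  (breadth-first search — with uniform edge weights Dijkstra reduces to
  BFS, and no principled edge-length scheme exists for confidence scores);
  similarity is `A·e^{−bD}` with defaults `A = 0.9`, `b = 1`. The raw
  transform gives `A` at `D = 0`; the *stored* diagonal is 1, like every
  other measure, and the raw transform stays available as
  `isp_transform`. Unreachable pairs score 0 (the `D → ∞` limit).
- **Neighbourhood overlap.** Each node's binary adjacency vector on the
  filtered graph, compared with Jaccard or cosine.
- **Alignment similarity.** Raw local (Smith–Waterman) or global
  (Needleman–Wunsch) scores `s(a,b)` normalized to
  `s(a,b)/√(s(a,a)·s(b,b))`. Defaults are BLOSUM62 with gap open 10 /
  extend 0.5; a match/mismatch scheme is available for toy alphabets.
  Global scores can be negative, so normalized values are clamped at 0.
  Self-alignment scores must be positive or the input is rejected.
- **Precomputed matrices.** Measures the package does not compute
  internally (e.g. GO semantic similarity) are read from TSV and
  validated (symmetry within 1e−9, values in [0, 1]).

Measure redundancy is diagnosed with Pearson correlations over the strict
upper triangles; constant measures have undefined correlation and are
reported as NaN rather than silently zeroed.

## Integration

`AVG`, `MIN`, `MAX` are elementwise; `SNF` is similarity network fusion.
Multi-matrix integration folds pairwise left to right, so for
order-dependent methods (AVG, SNF) earlier measures are diluted more:
three matrices under AVG yield `A/4 + B/4 + C/2`. The fold order is the
forward-selection acceptance order, which ties the integration semantics
to the search. MIN/MAX are associative and hence order-free.

The SNF step follows the widely used reference implementation of the
fusion algorithm (SNFpy 0.2.2): each view is row-normalized and
symmetrized into a full kernel `P`, restricted to a row-normalized top-K
kernel `S`; each iteration updates `P ← S · (mean of other views) · Sᵀ`,
re-adds the identity, and symmetrizes; after `t` iterations the views are
averaged, row-normalized, and symmetrized with half the identity added.
This differs in normalization detail from the original publication's
`P₀(i,j) = W(i,j)/(2Σ_{k≠i} W(i,k))`, `P₀(i,i) = ½` — the two variants do
not agree numerically, and the reference-implementation variant was chosen
as the de-facto standard. Because the fused output's diagonal is ≈ ½ and
rows sum near 1, `pairwise_combine` rescales off-diagonals by their
maximum and resets the diagonal to 1 so the result obeys similarity-matrix
conventions and can feed the propagation normalization. Defaults
`K = min(20, n−1)`, `t = 20` follow common SNF practice; both are
configurable. A caution established by the test suite: the kNN-restricted
cross-diffusion genuinely reorders off-diagonal entries (Spearman ≈ 0.7
against the input even when fusing a matrix with itself), so SNF preserves
block structure, not fine-grained rankings.

## Propagation

With `W_dd`, `W_tt` degree-normalized as
`w(i,j) ← w(i,j)/√(Σ_k w(i,k) · Σ_k w(k,j))` the update
`W^{i+1} = α·W_dd·W^i·W_tt + (1−α)·W⁰` is a contraction for `α < 1` and
converges to the unique fixed point
`vec(W) = (I − α·W_ttᵀ ⊗ W_dd)^{-1}(1−α)·vec(W⁰)`; the implementation
iterates rather than solving the `mn × mn` system, and the test suite
verifies both routes agree to 1e−8 on small instances.

Numerical choices:

- `α = 0.1` by default — the operating point at which most models peak on
  AUC in decay-factor sweeps; `α = 0` degenerates to returning `W⁰` and is
  allowed for testing.
- Stopping rule: max absolute entry change < 1e−6, cap 1000 iterations
  (at α = 0.1 convergence takes under ten). Non-convergence is flagged on
  the result, not raised — except inside cross-validation, where a
  non-converged fold is an error because its metrics would be
  meaningless.
- Zero row sums (isolated entities) normalize to zero rather than
  raising; such entities neither emit nor receive propagated weight.
- The unit self-similarity diagonal is included in the normalization
  sums. Known interactions therefore keep a score floor of `(1−α)`.

Novel interactions are the unknown pairs sorted by propagated score,
descending, with deterministic lexicographic tie-breaks; per-drug and
per-target restricted views support case-study-style inspection.

## Forward similarity integration

The wrapper search reuses one fold assignment (fixed seed) for every
candidate model, so criterion values are exactly comparable and the whole
search is deterministic given the catalog order, seed, and config. Step 1
scans all (drug, target) measure pairs; later steps score joint, drug-only
and target-only additions and keep the best strictly improving one. Two
deliberate conventions where the procedure is underdetermined:

- Argmax ties break by catalog declaration order (first declared wins);
  among the three addition modes, drug-only beats target-only beats
  joint on exact ties. Rationale: determinism with a preference for the
  smaller model.
- The same-dataset exclusion rule is enforced both in the combination
  enumeration and on greedy candidates: a measure whose dataset tag is
  already represented on its side is skipped. For the standard layout of
  7 drug measures over 4 datasets and 9 target measures over 4 datasets,
  the enumeration admits 53 × 107 = 5,671 valid combinations, which is
  the check that the constraint is wired in correctly.

The search evaluates at most `|AD|·|AT| + Σ_k(|RDk|·|RTk| + |RDk| + |RTk|)`
models; evaluations are memoized within a run.

## Evaluation protocol

Positives and negatives are partitioned into `k` near-equal folds
separately (sizes differ by ≤ 1), so every fold contains both classes.
Per fold, test positives are zeroed in the training `W⁰`, propagation is
run, and metrics are computed on the fold's pairs only. AUC uses the rank
statistic; AUPR uses step-wise (non-interpolated) precision integration.
The thresholded metrics (PRE/REC/F1/ACC/MCC) need a decision threshold
that the propagation score scale does not naturally provide; the default
rule picks the threshold maximizing F1 on the fold, and a fixed numeric
threshold is available. MCC with a zero denominator is defined as 0.

Model comparisons are paired t-tests across the shared folds, one-sided
by default (testing "greater"); Welch's unpaired test is available. The
decay-factor sweep cross-validates each model at each α and credits every
α tied for the maximum, so percentages can exceed 100 in aggregate —
ties are reported, not hidden.

The permutation ablation reassigns a profile dataset's 1-entries to
uniformly random cells without collision, conserving the association
count while destroying structure; comparing the original and permuted
models on shared folds isolates the dataset's contribution.

One protocol property worth knowing: holding out a positive slightly
deflates its drug's and target's training degree, which deflates exactly
that pair's propagated score. On no-signal data this pushes
cross-validated AUC slightly *below* 0.5 (≈ 0.48 at the default synthetic
scale, further down on very small dense networks). This is a property of
the leave-edges-out protocol with degree-driven scores, not a bug; it is
measured, not corrected.

## Synthetic data

The generator plants `C_d` drug classes and `C_t` target classes
(round-robin assignment) and samples interactions from a class-by-class
compatibility matrix. Defaults: 60 drugs × 80 targets, 4 classes per
side, within-block rate 0.22 and background 0.01, giving ≈ 300 positives
(density ≈ 6%) — deliberately two orders of magnitude denser than real
interaction lists so that 10-fold cross-validation has enough positives
per fold at desk scale. Per dataset, entities copy their class prototype
bit with probability equal to the dataset's informativeness and draw
i.i.d. noise otherwise, then suffer a small flip noise (0.02); at
informativeness 0 a dataset is exactly uninformative. The interaction
graph mixes class-consistent edges (confidence ≥ 0.5, surviving the
filter) with background edges of uniform confidence; sequences mutate
from class-ancestor strings with a per-site rate that rises to 1 as
informativeness falls; the "precomputed" matrices blend class blocks with
symmetric uniform noise and are synthetic stand-ins for externally
computed semantic-similarity matrices.

What the generator does *not* emulate: real fingerprint chemistry (bits
are abstract), realistic degree heterogeneity (class blocks make degrees
near-uniform), pair-specific interaction signal (all signal is
class-level, which caps achievable precision near the within-block rate —
with 4 classes AUPR tops out around 4× prevalence; an order-of-magnitude
ratio needs rarer blocks, e.g. 10 classes with background 0.001), and
database idiosyncrasies (identifier collisions, missing records).
Passing tests on this data demonstrate the machinery — kernels,
integration, propagation, selection, protocol — under known ground
truth; they do not certify performance on any real drug–target corpus.

## Problem sizes used in the test suite

Unit and property tests run on matrices of order ≤ 20; pipeline tests use
bundles between 12 × 15 and 60 × 80 entities; the greedy-vs-exhaustive
check uses a 3 + 3 measure catalog (35 valid combinations) at 30 × 36;
null-distribution and selection-frequency checks aggregate 20 generator
seeds. These sizes were chosen so the full suite exercises every code
path in well under a minute while keeping Monte-Carlo margins meaningful.

## Known limitations

- Entities present in the interaction list but absent from a data source
  are kept with zero similarity by default (an `--intersect` flag
  restricts to entities covered by every source instead). Zero-filled
  rows receive no propagation from that measure, which depresses their
  scores relative to fully covered entities.
- The closed-world negative assumption biases all absolute metric values
  downward; metrics are comparative tools here, not calibrated
  probabilities.
- Sequential pairwise SNF is not equivalent to simultaneous M-view SNF;
  the package deliberately implements the sequential variant to match the
  selection-order semantics, and simultaneous fusion of a fixed set can
  be had by calling `snf_fuse` with all matrices at once.
- The alignment kernel is O(p²) pairwise dynamic programming; for
  thousands of long sequences, precompute the matrix once and feed it in
  as a precomputed measure.
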