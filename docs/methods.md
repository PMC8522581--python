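# Methods

## Model

A sample is a point pattern: cell coordinates `coords ∈ ℝ^{N×2}` (arbitrary
planar units; only relative Euclidean distances are ever used) and phenotype
labels from a declared dictionary (default `Epithelial`, `CTL`, `Treg`).
The classifier never sees engineered per-cell features — the phenotype label
is the only node attribute.

**Cell graph.** Each cell is joined to its k nearest other cells; the
directed relation is symmetrized by union, so `A[i,j] = 1` iff either cell
selected the other. The propagation operator is the symmetrically
normalized self-looped adjacency `Ã = D̂^{-1/2}(A+I)D̂^{-1/2}`, whose entries
are `Â[i,j]/√(D̂[i]·D̂[j])`. Union symmetrization is a deliberate choice:
the normalization presupposes a symmetric adjacency, and the union keeps
every "j is a neighbour of i" relation. Ties in distance break by ascending
cell index (stable sort), so construction is bit-reproducible, including
for duplicated coordinates. k is clamped to N−1 for tiny samples; N = 1
degenerates to Ã = [[1]]. Default k = 20 sits between a barely connected
and a complete graph; the graph may still be disconnected, which is logged
but not repaired.

**Network.** An embedding table (V×d) maps labels to node features X₀.
Each of l graph-convolution layers computes `X_{t+1} = σ(Ã X_t W_t)` with
σ = ReLU by default (tanh available). The attention read-out computes raw
scores `α = tanh(X_l)·w`, simplex weights `p = softmax(α)` (max-subtracted
for overflow safety — mathematically identical), and the context vector
`s = X_lᵀ p ∈ ℝᵈ`, whose dimension is independent of N; this is what lets
one network handle samples of any size. A single affine layer maps s to two
logits, softmax to probabilities. The "feed-forward network" head is kept
minimal (one affine layer) since nothing deeper is needed for a
2-dimensional output; depth is configurable.

**Training.** All parameters — embedding, GCN weights, attention vector,
head — are trained jointly by cross-entropy with Adam (lr 10⁻³, β =
0.9/0.999, ε = 10⁻⁸), 100 epochs, one graph per optimization step, epoch
order reshuffled from the same seeded generator that initialized the
parameters (normal, scale 0.1). Gradients are hand-derived reverse-mode
NumPy; `Ã` is kept sparse (CSR), so a step costs O(nnz·d + N·d²). Graphs
are built once per sample and cached across epochs. No class reweighting is
applied in pairwise training — the imbalance problem is handled at the
consensus level, not the loss level. A non-finite loss aborts with a
diagnostic rather than training through overflow. Defaults d = 30, l = 2,
k = 20.

**Consensus.** The C(C,2) pairwise networks (15 for six classes) are
combined by a fixed rule, not a learned meta-classifier. Stage 1 walks a
priority list and returns the first class all of whose pairwise models vote
for it (vote = argmax of the softmax, i.e. threshold 0.5 — no calibration
data exists for anything finer). Stage 2 (no unanimous class) counts
round-robin wins, ties breaking by priority. The default priority (PDAC,
CP, IPMN, IPMN-associated PDAC, PanIN, MCN) puts the classes with the
strongest pairwise classifiers first, which is what makes the unanimity
stage meaningful; the exact published sequencing of the rule is not
specified anywhere, so this concretization is ours and is configurable.
The prediction is a pure function of the 15 binary votes, and the vote
table is always returned for audit.

## Interpretation

The attention weights p rank cells by contribution to the prediction.
`attention_percentile_mask` selects cells with `p ≥ percentile(p, q)`
(linear-interpolation percentile, inclusive threshold — uniform weights at
q = 90 select *all* cells, by design). q = 90 is the visualization default;
q = 50 feeds the enrichment analysis.

**Neighbourhood enrichment.** On a 3-NN graph (same construction as above,
k = 3), the observed undirected edge count between each unordered pair of
cell types (same-type pairs counted once per edge) is compared to its
distribution under uniformly random label permutations with topology fixed.
P-values use the add-one pseudocount `(1 + #{null ≥ obs})/(1 + n_perm)`
(≤ for depletion), which is never zero and exact under exchangeability;
calls use α = 0.05 by default, n_perm = 999. The attention-subset variant
*rebuilds* the 3-NN graph on the selected cells rather than inducing the
full-sample graph — the analysis is about the selected cells' own
neighbourhood structure. Fewer than two selected cells is an error, not a
silent skip.

## Morisita-Horn baseline

The canonical Morisita-Horn similarity
`MH = 2Σxᵢyᵢ / ((λ_x + λ_y)·X·Y)`, `λ_x = Σxᵢ²/X²`, over per-quadrat counts;
dissimilarity = 1 − MH. The image's bounding box is divided into a 10×10
grid (half-open bins, max edges closed); the default pairing is epithelium
vs pooled immune (CTL+Treg) — with three phenotypes a single per-image
index forces a pairing choice, and tumor-vs-immune is the natural one; both
grid and pairing are configurable. An empty group yields NaN (logged), not
an exception. The baseline classifier is a depth-3 impurity-split decision
tree on the scalar feature (scikit-learn, seeded); the shallow depth guards
against overfitting a one-dimensional feature.

## Synthetic cohorts

The generator emulates the qualitative structure of clustered tumor tissue:
per phenotype, a Thomas-style cluster process (uniform parents in the
window, Poisson total counts, isotropic Gaussian offspring scatter). Immune
phenotypes attach to an epithelial parent with probability `mixing ∈ [0,1]`
— the interface coefficient. Classes that differ in mixing differ in the
local label composition of neighbourhoods while keeping identical marginal
abundances, which is precisely the signal a graph classifier can exploit
and a single-number abundance-overlap index cannot.

Defaults, chosen once as a realistic operating point: 1000×1000 window,
expected 400 epithelial / 120 CTL / 80 Treg cells (~600 cells per sample),
8 parents per phenotype, 40-unit scatter. The six-class preset reproduces
the cohort imbalance 56 CP / 41 PanIN / 21 MCN / 89 IPMN / 38
IPMN-associated PDAC / 143 PDAC (388 samples) with mixing spaced over
[0.15, 0.9]. Two planted presets support evaluation: a separable pair
(mixing 0.05 vs 0.95) and an *overlapping* pair whose per-sample mixing is
drawn from the same U(0.3, 0.7) range for both classes, so the scalar
mixing signal carries no class information by construction.

What the generator does **not** emulate: real nuclear segmentation noise,
marker-intensity ambiguity, tissue-scale anatomy (ducts, stroma), cohort
heterogeneity between patients, or biologically calibrated densities.
Passing tests on synthetic cohorts therefore demonstrate the pipeline's
correctness and its sensitivity to spatial-mixing structure, not clinical
performance on real mIF data.

## Evaluation

Stratified 80/20 train/test splits and stratified 5-fold cross-validation
(scikit-learn, seeded); if the smallest class cannot fill the requested
folds the fold count degrades with a warning. AUC is the rank-based
(Mann-Whitney) area with midrank ties. Weighted precision/recall/F1 average
per-class values with weights proportional to true-class support, making
weighted recall identically the accuracy; a class never predicted
contributes precision 0 with a warning (standard zero-division policy).
Cross-validated metrics are reported mean ± sample standard deviation
across folds. Display rounding is 2 decimals (banker's); stored values are
full precision.

## Problem sizes

The test suite and acceptance script run planted cohorts of 40 samples per
class (60 train / 20 test) at ~600 cells per sample for the network, 100
samples per class for the Morisita-Horn chance-level check (the larger test
set narrows the AUC sampling error to ~0.05 so "chance level" is a
measurable statement), 200 samples × 199 permutations for null
calibration of the enrichment p-values, and 28 samples per class over
three classes for the consensus demonstration. These sizes are the
package's chosen study conditions for synthetic validation; the library
itself has no such limits.

## Known limitations

* One graph per optimization step: no mini-batching across graphs.
* CPU-only dense/sparse NumPy; no GPU path.
* The consensus rule's priority stage assumes the priority order reflects
  genuinely stronger pairwise classifiers; with weak models it simply
  falls through to the tournament.
* Coordinates are treated as unitless; if your data mixes µm and pixels
  across samples, normalize upstream.
* The Morisita-Horn feature depends on the quadrat grid; very sparse
  phenotypes make it noisy (NaN when absent entirely).
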