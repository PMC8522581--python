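# cgatnet

Graph-attention classification of multi-type spatial point patterns from
multiplexed tissue images.

Segmented multiplexed immunofluorescence (mIF) histology reduces a tissue
sample to a *point pattern*: one planar coordinate and one phenotype label
per cell (by default `Epithelial`, `CTL`, `Treg` — pancytokeratin+
epithelium, CD3+CD8+ cytotoxic T lymphocytes, FoxP3+ regulatory T cells).
Distinguishing pancreatic disease classes (PDAC, chronic pancreatitis and
the precursor lesions IPMN, MCN, PanIN) from such data is hard because the
discriminating signal is not cell abundance but the *spatial arrangement*
of phenotypes — and single-number spatial indices flatten most of it away.

`cgatnet` classifies whole point patterns with a cell-graph attention
network and ships the surrounding analysis toolkit:

* **Cell graphs** — each cell is connected to its k nearest neighbours
  (Euclidean, union-symmetrized; default k = 20), giving a binary adjacency
  A, its self-looped form Â = A + I, degree D̂, and the propagation operator
  Ã = D̂^(−1/2) Â D̂^(−1/2).
* **The network** — a trainable embedding maps each phenotype label to
  ℝᵈ (d = 30), then l = 2 graph-convolution layers update node features as
  X_{t+1} = σ(Ã X_t W_t). A self-attention read-out
  α = tanh(X_l)w, p = softmax(α), s = X_lᵀ p
  collapses the variable-size node matrix to a fixed d-dimensional context
  vector s, and an affine layer + softmax yields two class probabilities.
  Training is end-to-end cross-entropy with Adam (λ = 10⁻³, 100 epochs,
  one graph per step), implemented in NumPy with hand-written gradients.
* **Multi-class consensus** — for C classes, all C(C,2) one-vs-one networks
  are combined by a rule: return the first class (in a priority order) whose
  pairwise models vote for it unanimously, falling back to a round-robin
  win count with priority tie-break. No extra training is involved.
* **Interpretation** — the attention weights p rank cells by their
  contribution to the prediction; cells above a percentile (90th for
  visualization, 50th for downstream analysis) can be exported or fed to a
  neighbourhood enrichment test.
* **Neighbourhood enrichment** — on a 3-NN graph, observed edge counts per
  cell-type pair are compared with a label-shuffling permutation null;
  pairs are called enriched/depleted with add-one pseudocount p-values.
* **Morisita-Horn baseline** — one scalar spatial-overlap dissimilarity per
  image (quadrat counts of epithelium vs pooled immune cells), classified
  with a depth-3 decision tree; the classical single-number comparator.
* **Synthetic cohorts** — Thomas-style clustered point processes with a
  tunable *interface mixing* coefficient that pulls immune cells onto
  epithelial clusters, plus a six-class preset reproducing a realistic
  cohort imbalance (56/41/21/89/38/143 samples, 388 total).

## Worked example

Train a pairwise classifier on a planted two-class synthetic cohort whose
classes differ only in interface mixing (identical phenotype abundances),
then inspect one sample's attention and its high-attention neighbourhoods:

```python
import cgatnet as cg

specs = cg.separable_pair_specs()          # mixing 0.05 vs 0.95
cohort = cg.generate_cohort(specs, {"interface-low": 12, "interface-high": 12}, seed=0)
labels = [p.disease_class for p in cohort]
tr, te = cg.split_cohort(labels, train_fraction=0.75, seed=0)
model = cg.train_pairwise(
    [cohort[i] for i in tr], ("interface-high", "interface-low"),
    cg.ModelConfig(seed=0), cg.TrainConfig(epochs=40, seed=0),
)
scores = [model.positive_score(cohort[i]) for i in te]
y = [1 if labels[i] == "interface-high" else 0 for i in te]
print(f"final training loss: {model.final_loss:.4f}")
print(f"held-out AUC: {cg.roc_auc(scores, y):.3f}")

probs, att = cg.forward(cohort[0], model.params, model.config)
top = cg.attention_percentile_mask(att, 90)
print(f"P(interface-high) = {probs[1]:.3f}, "
      f"{len(top)}/{cohort[0].n_cells} cells in the top attention decile")
```

prints

```
final training loss: 0.0004
held-out AUC: 1.000
P(interface-high) = 1.000, 65/644 cells in the top attention decile
```

The held-out AUC of 1.0 means the network completely separates the two
planted classes from spatial arrangement alone. Feeding the same sample's
top-50%-attention cells to the neighbourhood permutation test
(`cg.attention_subset_enrichment(cohort[0], att, q=50, n_perm=999, seed=0)`)
yields one enrichment/depletion call per phenotype pair, e.g.

```
Epithelial-Treg: observed 119, null 109.4+/-7.7, z=+1.25, neutral
```

— the observed cross-type edge count, its permutation-null mean ± sd, the
z-score, and the call at α = 0.05.

The same workflow is available from the shell: `cgatnet simulate | train |
predict | explain | baseline | enrich | evaluate` (see `cgatnet --help`).
Per-sample files are plain CSV (`x,y,cell_type`), cohorts are described by
a `path,disease_class` manifest CSV.

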