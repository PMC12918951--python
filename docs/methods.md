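# Methods

`tdpred` implements a hybrid pipeline for predicting whether a small molecule
inhibits TDP-43 aggregation: a directed message-passing neural network (D-MPNN)
supplies learned molecular embeddings, which are concatenated with
physicochemical descriptors and binary biological-target annotations and fed to
a gradient-boosted tree classifier. This note records the model, its
assumptions, the defaults, and the design choices made where the protocol was
genuinely open.

## Molecular standardization

Every molecule passes through a fixed six-step cleanup before any featurization:
explicit-hydrogen removal, metal disconnection, functional-group normalization,
largest-organic-fragment selection, charge neutralization, and tautomer
canonicalization (delegated to RDKit's `MolStandardize`; the contract we rely
on is determinism and idempotence, not a particular tautomer ruleset). A single
aromaticity model (RDKit default perception) is fixed package-wide because
descriptor and fingerprint values depend on it. Molecules that fail parsing or
standardization are logged with a reason and excluded from all counts rather
than silently dropped or repaired.

## Feature families

* **DESCRIPTOR** — the full RDKit descriptor list (~210 values including
  MolLogP, TPSA, ExactMolWt, qed, EState_VSA8, SMR_VSA9). Descriptors are
  min–max scaled to [0, 1]; the scaler is fitted on training rows only (per
  fold during cross-validation, on the full training set for the final model)
  and *clips* out-of-range query rows, since screening compounds may exceed
  training ranges. Constant columns map to 0.
* **FINGERPRINT** — 2,048-bit circular fingerprints of radius 2 (ECFP4). The
  Morgan algorithm is implemented in-package from first principles with the
  standard atom invariants (element, total degree, attached-H count, formal
  charge, ring flag); the hashing pipeline reproduces RDKit's fingerprints bit
  for bit, which the tests assert against RDKit's `MorganGenerator` as an
  independent oracle.
* **TARGET** — binary columns, one per target-annotation identifier in a
  vocabulary built on training rows only; unseen annotations in query
  compounds are ignored and unannotated compounds get all-zero rows.
* **GNN** — D-MPNN embeddings (below).

## The message-passing encoder

Bonds become two directed edges. Edge states start from the source-atom and
bond features, `h0(v→w) = relu(W_in · [x_v ‖ e_vw])`, and are updated `T−1`
times with reverse-edge exclusion:

    m(v→w)  = Σ_{k∈N(v)\{w}} h_t(k→v)
    h_{t+1} = relu(h0(v→w) + W_msg · m(v→w))

Atom embeddings are `relu(W_atom · [x_v ‖ Σ_k h(k→v)])` and the molecule
embedding is their mean, which makes embeddings invariant to atom re-indexing
(tested at 1e-6). The embedding is tapped after the atom mean and **before**
the feed-forward head — it is the only vector whose width equals the message
hidden dimension, matching how the embeddings are consumed downstream. The
head (1–3 relu layers plus a linear output) exists only for training the
encoder with class-weighted binary cross-entropy; the positive-class weight
defaults to N_inactive/N_active of the training partition.

The network is implemented directly on numpy arrays with hand-written
backpropagation and Adam. At the desk scale used throughout (depth 2, hidden
64, 10 epochs, batch 32, learning rate 1e-3) this trains in seconds on one
CPU; gradients are verified against finite differences in the test suite. The
full-scale configuration (depth 3, hidden 1300, FFN 1500×3, dropout 0.3,
learning rate 1e-4, up to 30 epochs) ships as `dmpnn.paper_profile()`.
Training uses early stopping (patience 5) on the validation loss of an
internal scaffold-balanced 80/10/10 split and restores the best-validation
weights. Hyperparameter tuning is an in-process seeded random search over the
published ranges (depth 2–6, hidden 300–2400, FFN layers 1–3, dropout 0.1–0.6,
batch 32/64), scored by validation loss; distributed tuning infrastructure is
deliberately out of scope.

## Splits and leakage discipline

Compounds are clustered by Butina sphere exclusion on Tanimoto distance
(1 − similarity) of ECFP4 fingerprints. The distance cutoff is not part of the
published protocol; the default is **0.4**, a common choice at this bit length,
exposed as `--cluster-cutoff` and recorded in the run manifest. The 80/20
train/test split and the 5 outer CV folds move whole clusters (greedy,
largest-first, seeded tie shuffling), targeting a test size within ±2% and
class fractions within ±3 points of the global rate. Scaffold splits for
encoder training use Bemis–Murcko scaffolds, with all acyclic molecules
sharing one "empty scaffold" bin so the no-straddling invariant stays
meaningful. Ties everywhere break by (count, lowest index) for
reproducibility, and `assert_no_cluster_leakage` re-checks every emitted plan.

## Feature selection

Per training fold, in order: (1) target annotations kept only when present in
≥ 2 training compounds; (2) greedy Pearson-correlation pruning at |r| > 0.8 in
stable column order (the earlier column of a correlated pair survives;
constant columns drop because r is undefined for them); (3) recursive feature
elimination with an XGBoost ranker down to a fixed budget — 400 features for
three-family models, 300 for two, 200 for one. The RFE step removes 5% of the
current columns per iteration (minimum 1, final step truncated to land exactly
on the budget); single-column steps would be needlessly slow at ~3,000
columns. Whether the correlation threshold applies to r or |r| was open; we
use |r| so anticorrelated duplicates are also pruned.

## Classifier and evaluation

XGBoost with `objective=binary:logistic`, `eval_metric=auc`, tuned by seeded
random search (15 draws) over trees 100–400, learning rate log-uniform
0.01–0.2, depth 3–10, column subsample 0.1–0.9, scored by mean average
precision over 3 inner cluster-grouped folds. The final model uses the
componentwise median of the outer-fold winners (lower median for integers,
mode for categoricals) and is evaluated once on the untouched test set.
Metrics: ROC-AUC (tie-aware; cross-checked against a brute-force pairwise
oracle), MCC, F1, precision and balanced accuracy from confusion counts at a
fixed threshold of 0.5 (exposed as a flag; the protocol reports a confusion
matrix without stating one). Zero-denominator conventions: precision/F1 are 0
with no predicted positives, MCC is 0 when a marginal is empty. The booster is
not class-reweighted by default (class weights are an encoder concern); a
`scale_pos_weight` escape hatch exists. A Random-Forest comparator is
available behind the same interface (`BoosterConfig(kind="rf")`) but is not
part of any acceptance check.

The label-shuffle control permutes *training* labels (seeded) before the
entire pipeline — encoder training, feature selection, booster fitting — and
evaluates on untouched test labels. The control uses a fixed booster
configuration rather than re-tuning: under shuffled labels the search has no
signal to exploit, and a fixed configuration keeps the control focused on
leakage rather than search noise.

## Interpretability

* **Shapley values** are computed exactly by the polynomial path-dependent
  tree-traversal algorithm, implemented in-package on the booster's JSON dump
  (with cover statistics). Local accuracy (base value + Σ attributions =
  margin) is asserted at 1e-6 against the full-precision parsed ensemble; the
  booster's own float32 margins agree to single precision. Tree-conditional
  (path-dependent) expectations were chosen because they are exact,
  background-free and oracle-verifiable by subset enumeration.
* **Rationales** are connected substructures found by Monte Carlo tree search:
  the root is the whole molecule, actions delete a peripheral (non-ring) atom
  or a pendant ring while preserving connectivity, and the leaf reward is the
  encoder's predicted activity for the fragment (valences patched with
  implicit hydrogens; fragments re-standardized before scoring). Selection is
  prior-weighted UCT with exploration constant 10; defaults min_atoms 8,
  max_atoms 20, 500 rollouts. These constants follow the conventions of
  rationale extraction for message-passing models and are all exposed as
  flags and logged.
* **Chemical-space maps** use scikit-learn t-SNE on 2,048-bit fingerprints
  with perplexity 50, 1,200 iterations, learning rate 200 and PCA
  initialisation; perplexity auto-reduces with a warning below 3×perplexity
  rows.

## Synthetic data: what it does and does not emulate

The real training corpus (2,776 literature-curated compounds) is not
redistributable, so the generator produces datasets with its *statistical*
shape: ~10.6% actives; activity driven by a planted nitrogen-containing fused
aromatic motif (quinoline core by default) with P(active|motif) = 0.9 and
P(active|no motif) = 0.02 — the motif prevalence is solved from these so the
expected class rate matches; one hub target annotation at 30% in actives vs
3.4% in inactives plus label-independent background annotations at 5%; and
analog series (a base molecule plus single-substituent variants) so
sphere-exclusion clustering and scaffold splits have real work to do.
Molecules come from a fragment grammar (ring scaffolds × linkers ×
substituents), which guarantees chemical validity without a valence-repair
pass.

What it does **not** emulate: the chemical distribution of the real corpus
(natural-product-like complexity, molecular-weight bias), heterogeneous assay
provenance, or correlated annotation structure beyond the single hub. Passing
tests therefore demonstrate that the pipeline's machinery is correct and
leak-free and that it recovers a planted structure–activity relationship;
they do not certify performance numbers on the real chemistry.

## Problem sizes used by the tests and the acceptance script

The test suite runs the full pipeline at n = 400–600 compounds with a
depth-2/hidden-48 encoder; the acceptance script uses n = 2,000 with the
depth-2/hidden-64 desk profile and five label-shuffle repetitions. These sizes
were chosen as the smallest at which the class balance, cluster structure and
planted signal are stable; all of them run on a single CPU.

## Known limitations

* The encoder is a compact numpy implementation; it is not meant for
  full-scale (hidden 1300) training, for which a GPU framework would be the
  right tool. The architecture and training protocol are identical at both
  scales.
* Blood–brain-barrier permeability and prior-testing status are consumed as
  annotation columns; no ADME prediction is performed in-package.
* Path-dependent Shapley values depend on the training distribution through
  node covers; they are exact for the stated value function but differ from
  interventional variants.
* Butina clustering is O(n²) in memory/time over fingerprints; fine for the
  tens of thousands of compounds this pipeline targets, not for millions.
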