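# Methods

This note records the models, conventions and design choices behind
`transportscreen`, and what the synthetic benchmarks do and do not
demonstrate.

## Standardization pipeline

Input SMILES pass through three stages, mirroring standard
structure-curation practice: a validity check (RDKit parse + sanitization),
structural normalization (functional-group conventions, reionization,
implemented with RDKit's `rdMolStandardize.Cleanup`), and salt stripping.
Salt stripping keeps the **largest organic fragment** — largest by heavy-atom
count, ties broken lexicographically on canonical SMILES — and rejects
inputs with no carbon-containing fragment (`no_organic_fragment`). Remaining
charges are neutralized where chemically possible, and the canonical
isomeric SMILES is stored. The pipeline is a fixed point: re-standardizing a
canonical SMILES reproduces it, which is what makes CSV round-trips lossless
and deduplication well-defined.

Deduplication collapses records with identical canonical SMILES and
consistent labels to the first occurrence. Records whose duplicates carry
*conflicting* binary labels are removed entirely — the conservative
resolution, since a compound measured both active and inactive provides no
trustworthy training signal. Stereochemistry is preserved; stereoisomers are
distinct records.

## D-MPNN classifier

The classifier is a directed message-passing network over the molecular
graph, implemented from the update equations on NumPy arrays (forward pass,
backpropagation and the Adam optimizer are all in `dmpnn.py`; the analytic
gradients are verified against central finite differences in the test
suite).

**Featurization.** Atoms: one-hot element (C, N, O, S, F, Cl, Br, I, P, B,
Si + other), degree 0–5, formal charge −2…+2, attached hydrogens 0–4,
aromaticity flag, hybridization (SP…SP3D2 + other), and atomic mass × 0.01
(39 dimensions). Bonds: one-hot order class (single/double/triple/aromatic),
conjugation and ring-membership flags, and one-hot stereo class
(14 dimensions). The exact layout is a documented constant in `dmpnn.py`.

**Message passing.** Each bond contributes two directed edges. The initial
edge state is `h⁰ₑ = ReLU(W_i [x_src ; x_bond])`. For `depth − 1` steps, the
message into edge u→v sums the states of edges entering u **excluding the
reverse edge v→u**, and the state updates residually against the initial
pre-activation: `hₑ ← ReLU(W_i[...] + W_h mₑ)`. Edge states are then pooled
onto atoms (`h_v = ReLU(W_o [x_v ; Σ_{e→v} hₑ])`), averaged over atoms
(mean readout, so molecule size does not change the scale), and passed
through a feed-forward head (`ffn_layers` linear maps with ReLU between,
final layer scalar) and a sigmoid. Because all aggregations are sums or
means, predictions are invariant to the atom ordering of the input SMILES
(asserted to 1e-6 across randomized SMILES renderings).

**Defaults.** depth 3, hidden size 300, two feed-forward layers, ReLU, 30
epochs, 10-member ensembles, batch size 50. The optimizer is Adam
(β₁ = 0.9, β₂ = 0.999) under a warmup/decay schedule: linear warmup from
1e-4 to 1e-3 over two epochs, then exponential decay back to 1e-4 by the
final step — the schedule conventionally paired with this architecture.
Ensemble members use seeds `seed + 0 … seed + k − 1`; the ensemble
probability is the arithmetic mean and the per-query member standard
deviation is reported as a dispersion measure. Class imbalance is not
reweighted; training-set prevalence is stored with the model. The binary
call threshold is 0.5 (ties called active) and configurable. All arithmetic
is float64 and single-threaded BLAS-deterministic: one (dataset, seed) pair
reproduces parameters bit-for-bit.

Degenerate inputs: datasets with fewer than two examples of either class are
rejected (`degenerate labels`); molecules with no heavy atom are rejected at
featurization; single-atom molecules (no edges) are valid and flow through
the readout with an all-zero edge pool.

## Similarity screen

Data-poor endpoints are screened by 2D similarity: Morgan radius-2
fingerprints, 2048 bits (the radius is the method's defining parameter; the
width is a config knob recorded with every model), Tanimoto similarity on
bit sets, and the **MAX** score — the maximum similarity between the query
and any member of the endpoint's reference set, argmax ties broken by
reference order. Two empty fingerprints are defined as similarity 1
(identical empty environments); empty vs non-empty is 0 by the formula. The
screen's quality is measured as ranking power: external compounds are
binarized at ≤ 1 µM active / ≥ 10 µM inactive (records strictly between the
cutoffs dropped), compounds already present in the reference set are
excluded, and the ROC-AUC of the MAX scores is reported. As a *call*, the
profiler uses MAX ≥ 0.5 → active by default; this threshold is explicit in
the registry and echoed in the output because the screen is fundamentally a
ranking method.

## Applicability domain

Every prediction carries an SDC (sum of distance-weighted contributions)
score against the model's training or reference fingerprints:

    SDC = Σ_{i=1..n} exp(−3 · TDᵢ / (1 − TDᵢ)),   TDᵢ = 1 − Tanimoto(query, i)

Each term lies in [0, 1]; a term at TD = 1 contributes exactly 0, the
continuous limit of the expression, which avoids the division by zero. SDC
is monotone non-decreasing in the training set and bounded by n.

No published numeric cutoff exists for "outside the domain", so the package
self-calibrates: the default threshold is the **5th percentile of the
training set's leave-one-out SDC distribution** (each training molecule
scored against the other n − 1). A query scoring below what 95% of the
training set scores against itself is flagged out-of-domain. The percentile
is configurable per model and stored in the model directory with the
fingerprint parameters, so the domain geometry always matches the similarity
geometry.

## Evaluation conventions

Threshold metrics are the exact confusion-table formulas; MCC returns 0 when
any denominator factor vanishes. Balanced accuracy is (sensitivity +
specificity)/2 by construction. ROC-AUC is the trapezoidal area, identical
to the Mann–Whitney concordant-pair probability with half credit for ties
(the convention matters: printed AUCs differ across tie treatments); PR-AUC
is average precision (step-wise interpolation). Curves and areas go through
scikit-learn; the test suite checks them against exhaustive pair-count and
threshold-enumeration oracles.

k-fold assignment is a seeded random partition into near-equal folds without
stratification (a stratified variant is available behind a flag for small or
imbalanced fixtures). The scaffold split groups compounds by Bemis–Murcko
framework (ring systems plus linkers, side chains removed; acyclic molecules
are singleton groups keyed by canonical SMILES) and places groups whole into
the test side, largest first with ties in a seed-shuffled order, until the
requested fraction is reached; the remainder trains. No scaffold ever
appears on both sides; a dataset with a single scaffold raises rather than
leaking.

## Synthetic benchmarks — what they show

The generators assemble molecules from ~15 ring-scaffold templates and ~18
small substituents. In the **motif benchmark**, structural positives carry a
grafted carboxylic acid (`[CX3](=O)[OX2H1]`, attached through a 0–4-atom
linker) and negatives are verified motif-free by substructure match, so the
pre-noise label is exactly recoverable — the generator is its own oracle.
Label noise flips labels, never structures, keeping the Bayes-optimal
separability known. Default conditions: 600 compounds, positive fraction
0.5 (drawn per-compound, so class counts are binomial), noise 0.

The **similarity benchmark** draws the reference set (default 20) and the
external actives (50, potencies log-uniform in 10 nM–1 µM) from one
quinoline scaffold family and the inactives (150, 10–100 µM) from disjoint
families, with no canonical-SMILES overlap between reference and external
sets.

A depth-3 message-passing network can read a carboxylic acid directly from
its local graph neighborhood, so the noise-free motif benchmark is *meant*
to be learned essentially perfectly (scaffold-split and cross-validated
ROC-AUC ≈ 1.0, as the acceptance script recomputes). What passing shows is
that the training loop, splitting, ensembling and evaluation machinery are
wired correctly end-to-end — not that comparable accuracy is reachable on
real transporter data, where labels are noisy, chemistry is broader, and
activity is not a local substructure property. The same caveat applies to
the similarity benchmark: intra-family Tanimoto similarity is high by
construction, so screen AUC ≈ 1.0 validates the scoring path, not
real-world retrieval rates.

## Problem sizes

The acceptance script and test suite run the full-size network (depth 3,
hidden 300, 30 epochs) but size the *protocols* for a desk-scale machine:
the scaffold-split check trains a single ensemble member, and 5-fold
cross-validation uses one member per fold (a 10-member ensemble per fold is
a straightforward configuration change; on the perfectly separable
benchmark it does not change the conclusion). The quick unit tests use a
down-scaled network (hidden 12–16, depth 2, a few epochs) because they
exercise mechanics, not accuracy.

## Validation against real data (recipe, not CI)

With curated per-transporter CSVs (`smiles,activity` with 1 = active) for
the data-rich endpoints:

```sh
transportscreen standardize pgp_inhibitors_raw.csv pgp_inhibitors.csv
transportscreen crossval pgp_inhibitors.csv --k 5 --ensemble-size 10 --seed 0 --out pgp_cv.json
```

Five-fold ensemble ROC-AUCs in the ~0.7–0.9 band are the expected regime
for public transporter inhibition data; exact values depend on the curation
and on framework-level defaults (optimizer details, split RNG) that differ
between implementations, so numeric reproduction of any particular
published table should not be expected.

## Known limitations

- Bit-vector fingerprints only (no count vectors, MACCS or atom pairs); the
  Tanimoto/SDC definitions used here are bit-set definitions.
- No hyperparameter search, regression mode, multitask heads, dropout, or
  uncertainty calibration beyond ensemble dispersion.
- The conflicting-duplicate rule (remove all copies) is a curation decision;
  majority voting is a reasonable alternative the package does not implement.
- The synthetic chemistry does not mimic real transporter SAR,
  physicochemical property distributions, or realistic potency spreads.
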