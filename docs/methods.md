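# Methods

This note documents the modelling decisions behind `ptmgan`: what each stage
computes, which defaults were open choices, and what the synthetic fixtures
do and do not demonstrate.

## Fragment assembly

A candidate site is a lysine with ξ = 8 residues of context on both sides,
giving a window of L = 17. Sites closer than ξ to a terminus are dropped
rather than padded, so every downstream vector has identical layout.
Windows containing non-canonical letters (B, J, O, U, X, Z) are dropped
with a warning.

Redundancy reduction is a greedy keep-first scan in input (file) order: a
window is discarded iff its positional identity to any already-retained
window is ≥ 0.40. Greedy single-linkage was chosen because it is
deterministic given file order and has no tunable state; the retained set
depends on input order, which is therefore part of the provenance of a run.
Annotations from multiple tables that agree on (protein, site, window)
are merged into one record with the union of labels; records whose final
label set is not a singleton are excluded, and classes with fewer than 500
records (configurable) are deleted. Class indices 1..K follow the
lexicographic order of class names.

## Encoding

Nine blocks are concatenated in fixed order; total width 2359 (2036 when no
structural table is supplied).

* **AAindex (238)** — 14 physicochemical scales per residue, z-scored over
  the 20 residues. The default selection (hydrophobicity, hydrophilicity,
  side-chain mass, pI, volume, polarity, polarizability, maximum ASA,
  flexibility, net charge, pK-COOH, pK-NH2, buriedness, refractivity) is a
  documented, replaceable choice: any 14 full-coverage scales can be passed,
  and downstream code only fixes the count.
* **CKSAAP (1200)** — ordered residue pairs at gaps k ∈ {0, 1, 2}. Counts
  are normalized by the number of pair positions (L − 1 − k), so each
  400-wide k-block is a frequency distribution summing to 1; frequencies
  (rather than raw counts) keep the three k-blocks on one scale.
* **PWM (17)** — positional residue frequencies fitted on the training
  fragments of the current fold only, pooled over classes, no pseudocount.
  A per-class PWM variant is conceivable but yields K vectors of length 17
  with no canonical reduction to one, so the pooled form is the default.
* **Reduced alphabet (136)** — groups: acid {D,E}, basic {H,K,R}, aromatic
  {F,W,Y}, amide {N,Q}, small hydroxyl {S,T}, sulfur {C,M}, aliphatic
  {A,G,P} and {I,L,V}.
* **FoldAmyloid-style profile (17)** — mean of a packaged expected
  packing-density scale over a centered window of 5, optionally binarized at
  the conventional cutoff 21.4. The scheme is toggleable; in practice it
  carries almost no class information and grouped importance confirms this.
* **Binary encoding (340)** — plain 20-way one-hot, alphabetical order.
* **PC-/SC-PseAAC (36 / 52)** — pseudo amino-acid composition with
  λ = L − 1 = 16 and weight ω = 0.05. The parallel variant pools
  (hydrophilicity, hydrophobicity, side-chain mass) into mean squared
  property differences per lag; the series variant keeps per-property
  products for (hydrophilicity, hydrophobicity). Both are normalized so the
  36- resp. 52-vector sums to 1. "Side-chain mass" is used for the
  mass-like property conventionally listed in PseAAC property triples.
* **Structure (323)** — 19 channels per residue consumed from a provided
  table (ASA, Q3 and Q8 secondary-structure probabilities, φ/ψ/θ/τ in
  degrees as provided — no sin/cos transform — HSEα-up/down, contact
  number). The package never predicts structure; producing the table is the
  job of an external per-residue predictor.

Encoding is pure: the same fragment and fitted context give bit-identical
vectors. Every column carries (scheme, tag) provenance.

## Correlation screening

The default screen drops features whose |Pearson r| against the numeric
class label (integer index 1..K) exceeds 0.5, after removing zero-variance
columns. The label encoding is arbitrary; a one-vs-rest max-|r| label mode
and a feature–feature redundancy mode (greedy scan in column order) are
provided as first-class alternatives. Masks are fitted on training rows
only, serialized to JSON, and applied unchanged to evaluation folds.

## Conditional adversarial balancing

Deficits are computed against the largest class; for the published
seven-class corpus counts (3114, 1399, 1224, 1147, 1645, 1174, 3185) the
per-class deficits are (71, 1786, 1961, 2038, 1540, 2011, 0), 9407 rows in
total.

One conditional model is trained over all classes (per-class training is a
config switch). Generator and critic are fully-connected NumPy networks —
z(100) + one-hot(K) → 256 → 512 → width with tanh output, and width + K →
512 → 256 → 1 — with leaky-ReLU hidden units. Features are min–max scaled
to [−1, 1] on the real rows; generated rows are inverse-scaled back.

* **CGAN**: sigmoid discriminator, log-loss (the generator minimizes
  E log(1 − D(G(z|y)))), Adam at 2e-4.
* **CWGAN**: the critic's output sigmoid and the logarithms are removed,
  the critic loss is E[D(G(z|y))] − E[D(x|y)], every critic parameter is
  clipped to [−c, c] (c = 0.01) after each of the n_critic = 5 critic steps
  per generator step, and the optimizer is RMSProp.

Production defaults are 50,000 iterations at learning rate 5e-5, the
conventional weight-clipped Wasserstein setting. The scaled-down runs used
throughout the tests and the acceptance script (≤ 500 iterations) use
learning rate 5e-4: at 5e-5 a 500-step run cannot move the weights
appreciably, so the faster rate is the coherent small-budget configuration.
Conditioning batches draw the class uniformly (`balanced_batches`), so
minority conditionals receive as much critic/generator exposure as the
majority; with proportional sampling the generator learns the pooled
distribution long before the minority conditionals.

Diagnostics follow the generative-quality conventions of the field: per
class, the Euclidean distance between the column-means of real and
synthetic rows, and the per-iteration Gloss/Dloss traces. On a two-Gaussian
toy problem the trained conditional generator's mean distance drops from
≈ 6.8 (initialization) to ≈ 0.2, and each class's synthetic mean lands
nearer its own class than the other.

## Classification and evaluation

Random forest, 500 trees, √p features per split, no depth limit, seeded.
The data split is stratified 4/5 : 1/5 with stratified tenfold CV on the
training part (stratification keeps small classes present in every fold;
fold counts and test fraction are configurable). Inside every fold the PWM,
the correlation mask, the GAN and the forest see training rows only;
augmentation happens per fold by default, so no synthetic row ever derives
from an evaluation row, and evaluation rows are never synthetic. CV metrics
are computed on fold-pooled predictions (one confusion matrix over all
validation rows), which weights every sample equally.

Multiclass MCC is the K-category correlation coefficient computed from the
confusion matrix; CEN is confusion entropy with per-class
misclassification probabilities normalized by the class's row + column
mass and logarithm base 2(K − 1), mass-weighted. Degenerate margins return
0 with a warning (MCC) or are excluded (CEN's empty classes). Both are
validated against independent brute-force summation oracles in the tests,
not against any published corpus value. One-vs-rest AUC uses midrank
(Mann–Whitney) tie handling; the DeLong test uses the fast structural
component estimator with a two-sided normal p-value and is checked against
a pairwise-swap permutation oracle.

Grouped importance sums the forest's impurity importances per encoding
scheme; individual features keep their human-readable tags.

## Synthetic fixtures

Each synthetic protein is 23 residues with one annotated central lysine.
Flank residues at informative offsets (−4, −1, +2, +4, +7) take a
class-specific preferred residue with probability `motif_strength`, else a
uniform draw; all other positions are uniform. Structural channels are
class-shifted Gaussians (shift pattern deterministic per class, scaled by
`struct_effect`; probability groups pass through a softmax so Q3/Q8 sum
to 1). `cplm_counts_fixture()` reproduces the seven published class counts
(total 12,888) for balancing-arithmetic checks.

What the fixtures do **not** emulate: proteome-scale homology structure,
realistic amino-acid background frequencies, label noise, multi-label
crosstalk beyond exact-duplicate sites, or the true covariance of real
structural predictors. Passing fixture-based tests therefore demonstrates
the pipeline's mechanics and the direction of the balancing effect, not
real-corpus accuracy.

## Scaled-down study sizes

The imbalanced-corpus experiment uses 600/100/100 samples, motif strength
0.4, structural effect 0.5, the AAindex + PWM + Structure schemes, 3-fold
pooled CV, a 500-iteration CWGAN and 200 trees. These sizes were chosen so
the experiment exhibits the phenomenon of interest — at stronger signal the
fixture saturates (minority recall ≈ 0.9 without any balancing) and there
is no headroom for augmentation to demonstrate anything. Under these
conditions CWGAN balancing raises mean minority-class sensitivity by
+0.03…+0.15 across seeds while majority sensitivity stays at 1.0.

## Known limitations

* Weight-clipped Wasserstein training is brittle at aggressive learning
  rates; the trainer aborts on non-finite losses rather than continuing.
* The NumPy networks are single-threaded; very wide feature spaces
  (> ~3000 columns) make the 512-unit critic the runtime bottleneck.
* The greedy redundancy filter is order-dependent by design; a different
  input ordering yields a (slightly) different retained set.
* DeLong's normal approximation is coarse below ~30 samples per class;
  the permutation comparison in the tests uses 40-sample toys for that
  reason.
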