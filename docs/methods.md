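# Methods

## The model

`dtiknn` predicts binary drug–target interaction (DTI) labels for
(drug, protein) pairs from two feature blocks:

**Target proteins.** A collection of P amino-acid property scales (one
number per residue type per property, e.g. an AAindex1 table) is row
z-scored and summarised by PCA with properties as observations and the 20
residue types as variables, giving `n_pca` orthonormal loading vectors
`AAP^l ∈ R^20` with non-increasing variance fractions. A sequence of length
`Len` is cut into `n_frag` contiguous fragments of `⌊Len/n_frag⌋` residues
from N- to C-terminus (the last fragment absorbs the remainder), the 20
residue types are counted per fragment, and each component scores each
fragment elementwise:

    TP[l, j, n] = AAP^l(n) · count_j(n),   l = 1..n_pca, j = 1..n_frag, n = 1..20

flattened component-major into a vector of length `n_pca × n_frag × 20`
(1400 at the 7-component / 10-fragment defaults). Note the per-fragment
score keeps both the component index l and the residue index n: it is an
elementwise (Hadamard) product, not a scalar contraction — a contraction
could not produce the 1400-dimensional layout the subspace grid relies on.

**Drugs.** A precomputed table of D 1D/2D molecular descriptors (the
canonical input is a descriptor CSV, e.g. a PaDEL-Descriptor export; an
optional RDKit adapter computes a comparable table from SMILES). After
cleaning, descriptors are split *in file order* into `n_pca` contiguous
groups, the first `n_pca − 1` of size `⌊D/n_pca⌋` and the last absorbing
the remainder (with D = 1444 and 7 groups: six of 206, one of 208).

**Pair vectors.** Each labeled pair is the concatenation drug block ∥
protein block, `(D + n_pca·n_frag·20)`-dimensional (2844 at full scale).

**Subspace ensemble.** Every protein component group `Ft_i` is paired with
every drug descriptor group `Fd_j`, giving `n_pca²` feature subspaces (49
at the defaults; 200 + 206 = 406 features each). One kNN classifier is
trained per subspace. The ensemble calls a pair interacting under the
**unanimity** rule — positive iff *all* classifiers vote positive
(default) — or a simple **majority** rule. Unanimity is the intersection of
the member positive-call sets, so it can only remove false positives
relative to any member, at the price of recall.

## The kNN base classifier

* **Distance:** Euclidean, after per-feature min–max scaling fit on the
  training instances only (descriptor scales span orders of magnitude;
  constant features get divisor 1 and collapse to 0).
* **Weighting:** inverse-distance 1/d by default (uniform available). Any
  neighbor at numerically zero distance (d ≤ 1e−12) dominates: the vote
  becomes the majority label among the zero-distance neighbors.
* **Vote:** positive iff the positive weight fraction is strictly > 1/2;
  exact ties break to NEGATIVE (conservative for interaction calls). The
  same convention gives an exactly-half majority vote of the grid → negative.
* **k selection:** per classifier, leave-one-out accuracy over odd
  k ∈ {1, 3, …, k_max}, k_max = 2·⌈√n⌉ + 1 by default (capped at n − 1);
  ties go to the smallest k. Each of the n_pca² classifiers selects its own
  k independently. A fixed shared k can be configured instead.

## The evaluation protocol

* **Negative recoupling:** the candidate pool is the cross product of the
  drugs and targets observed in the positive set, minus the positives;
  negatives are drawn uniformly without replacement until they number
  `ratio` × positives (ratio 2 by default). With the benchmark class sizes
  (2719 / 1372 / 620 / 86 positives) this yields 5438 / 2744 / 1240 / 172
  negatives, 9594 in total.
* **Cross-validation:** stratified 10-fold. Scalers and per-classifier k
  are refit inside each training fold; the property PCA sees no labels and
  no pair information, so it is fit once globally. Pooled confusion counts
  aggregate out-of-fold predictions (each instance tested exactly once);
  per-subspace reports pool each classifier's own out-of-fold votes.
* **Metrics:** Rec = TP/(TP+FN), Prec = TP/(TP+FP),
  Acc = (TP+TN)/(TP+FP+TN+FN), F1 = 2·Prec·Rec/(Prec+Rec),
  MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
  Ratios with a zero denominator are reported as NaN sentinels with an
  explicit warning — except MCC, which uses the standard limit convention
  MCC = 0 for a constant predictor (as scikit-learn does), also warned.
  A constant predictor genuinely has zero correlation with the labels; a
  NaN there would make null-calibration checks unevaluable.

## The synthetic-data generator

`fixtures.FixtureSpec` defaults mirror the full-scale study conditions
where they exist: 7 components, 10 fragments, 1444 descriptors, 544
properties, 1:2 positives:negatives. Dataset size (100 positives → 300
pairs), sequence lengths (80–300), descriptor noise (unit Gaussian) and the
planted effect (3 feature standard deviations) are the package's own
choices: large enough that a signal-bearing 406-feature subspace is
separable, small enough that the whole suite runs in well under a minute
per protocol run.

* **Property tables** are rank-r structure (random P×r times r×20 Gaussian
  factors) plus Gaussian noise (sd 0.05), so a rank-7 table's top 7
  components recover > 95 % of variance after standardization.
* **Sequences** are i.i.d. uniform over the 20-letter alphabet.
* **Labeled pairs** use one distinct drug per pair; the drugs of positive
  pairs have the descriptor columns of one group mean-shifted by
  `effect_size` × sd. The planted rule thus lives in the drug half of the
  designated (i, j) subspace block. A per-pair shift on the *protein* half
  would be inconsistent whenever two pairs share a protein, so protein
  features are left uninformative; consequently every classifier in drug
  column j carries the signal and the (i, j) classifier is the designated
  signal classifier in tests. `signal_subspace=None` shifts all descriptor
  columns instead, producing a globally informative dataset on which the
  unanimity ensemble attains high accuracy — useful for exercising the
  vote rules at the opposite regime.

What passing tests show — and do not show. The fixtures demonstrate the
pipeline's mechanics: exact kNN behavior against brute-force oracles,
leakage-free fold handling, recovery of planted low-rank and subspace
structure, null calibration (pooled MCC ≈ 0 with no effect), and the
unanimity/majority trade-off (unanimity's positive calls are a subset of
majority's; on a single-subspace signal its recall collapses while its
pooled false-positive count stays at zero). They do not emulate real
descriptor distributions, real residue-property correlations, or the
shared-drug/shared-target dependence structure of real interaction
networks, so test performance says nothing quantitative about accuracy on
biological benchmark data.

## Numerical and degenerate-input choices

* Component signs are fixed (largest-|loading| entry positive) so
  serialized models and encodings are byte-stable.
* Property rows with missing values or zero variance are flagged and
  excluded from PCA — excluded, never imputed.
* Descriptors that are non-finite for any drug or constant across drugs
  are dropped before pairing; the drop list is retained.
* Non-standard residues (B, Z, X, U, O, …) are rejected by default; the
  `skip` policy removes them first and fragments the cleaned sequence.
* Remainders (sequence length mod n_frag; D mod n_pca) go to the last
  fragment/group — one fixed, documented convention for both.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); k selection and fold assignment are
  deterministic given the seed, and a saved ensemble bundle reproduces its
  predictions exactly on reload.

## Known limitations

* Exact (brute-force) neighbor search only; fine for the ≤ 10⁴-instance
  datasets this targets, not for larger screens.
* The unanimity rule is extremely conservative when most subspaces are
  uninformative: recall approaches zero and precision becomes vacuous.
  This is a property of the voting design, made visible by the
  single-subspace fixtures.
* The negative-recoupling assumption (unobserved pairs are negative) is
  the benchmark's, not a biological truth; sampled negatives may contain
  undiscovered interactions.
* Per-class descriptor ordering follows the input file; no attempt is made
  to reproduce any particular external descriptor software's column order.
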