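# Methods

## The problem and the model

Plant genomes transcribe several functionally distinct classes of
non-coding RNA — lncRNA, miRNA, pre-miRNA (pre-miR), rRNA, snoRNA, snRNA,
tRNA — plus ordinary mRNA, which this package carries as an explicit
"others" class. The classes differ systematically in sequence composition
and in how stably and unambiguously they fold, so a vector of
sequence-plus-folding descriptors supports supervised discrimination.
`ncrclass` computes a 70-dimensional descriptor per sequence and trains a
one-vs-one multi-class support vector machine with an RBF kernel on it.

The 70 features, in the frozen order the model fingerprint protects:

1. **L** — sequence length (nt).
2. **AU%** — 100·(#A+#U)/L.
3. **MFEI** — minimum folding energy index. With MFE the minimum free
   energy (kcal/mol) of the predicted secondary structure,
   AMFE = MFE·100/L rescales it to a 100-nt sequence and
   MFEI = |AMFE| / GC%. MFEI is reported as a non-negative magnitude: MFE
   is negative while the index is conventionally quoted positive (the
   canonical pre-miRNA hairpin scale is ~0.85). GC% = 0 makes the ratio
   undefined; it is reported as 0 with a warning (an all-AU sequence has
   essentially no stable fold to normalise).
4. **ND** — normalised base-pair distance, (1/L)·Σ_{i<j} p_ij(1−p_ij),
   the ensemble-expected structural distance per base.
5. **Npb** — base-pairing propensity: base pairs in the MFE structure
   divided by L, bounded by 0.5 (at most L/2 pairs). Computed from the MFE
   structure, not the ensemble expectation, which is what makes the 0.5
   ceiling exact.
6. **NQ** — normalised Shannon entropy of the base-pair probability
   distribution, −(1/L)·Σ_{i<j} p_ij·log₂ p_ij with 0·log 0 := 0. Zero
   when a single structure dominates; larger when alternative
   conformations coexist. Log base 2 (bits); the natural-log variant
   differs only by the constant ln 2.
7–70. **R_k** — the 64 overlapping 3-mer rates per 100 nt,
   R_k = 100·count_k/L, triplets ordered lexicographically over
   A < C < G < U. The denominator is L, not the window count L−2, so
   Σ_k R_k = 100·(L−2)/L exactly — a tested identity. (Dividing by L−2
   instead would rescale every rate by L/(L−2); either convention works if
   train and predict agree, and the fingerprint enforces that.)

Here p_ij is the McCaskill equilibrium base-pair probability: the
Boltzmann-weighted fraction of admissible secondary structures in which
bases i and j pair.

## Folding backends

Folding is pluggable behind one interface.

**Thermodynamic backend (production).** An adapter to ViennaRNA: MFE
structure and energy from the standard nearest-neighbour model, p_ij from
its partition function. All feature extraction defaults to this backend.
Sequences above 5,000 nt are still folded but logged, since partition-
function cost grows cubically and real lncRNAs reach tens of kilobases.

**Reference backend (verifiable).** A self-contained model with one energy
per pair type — defaults e_GC = −3, e_AU = −2, e_GU = −1 kcal/mol, no
stacking terms — at kT = 0.6 kcal/mol, minimum hairpin loop of 3 unpaired
bases, nested structures only. Its parts:

* *MFE*: the Nussinov-style recursion
  E(i,j) = min(E(i+1,j), min_k e(i,k)+E(i+1,k−1)+E(k+1,j)). Among
  co-optimal structures the traceback returns the lexicographically
  smallest dot-bracket ('(' sorts before '.'), making outputs
  deterministic and testable.
* *Partition function*: Z(i,j) = Z(i+1,j) + Σ_k q(i,k)·Z(i+1,k−1)·Z(k+1,j)
  with q = exp(−e/kT); the empty structure has weight 1, so Z ≥ 1 always.
* *Pair probabilities*: an outside recursion over enclosing pairs;
  p_ij = q(i,j)·Z(i+1,j−1)·Z_out(i,j)/Z. The outside pass is O(L⁴) in this
  simple form — acceptable because the reference backend exists for
  verification on short sequences, not production folding.
* *Oracle*: exhaustive enumeration of every admissible nested structure
  (guarded to L ≤ 20). The dynamic programs are tested to agree with
  structure-by-structure Boltzmann sums to better than 1e−9 on hundreds of
  random sequences; that agreement is also recomputed by
  `scripts/acceptance.py`.

Lonely pairs are allowed in the reference model (no minimum helix length);
the thermodynamic backend inherits ViennaRNA's defaults. Pseudoknots,
suboptimal sampling and temperature scans are out of scope.

## Curation

Inputs are normalised (uppercase, T→U) and any sequence still containing a
letter outside {A,C,G,U} is rejected outright — masking would silently
distort 3-mer counts. Exact duplicate residue strings are collapsed to the
first occurrence, across the whole input by default (per-subset
deduplication is available by calling `deduplicate` on each subset).
The curation report's counts reconcile exactly:
kept + rejected + duplicates = read.

## Classifier

scikit-learn's SVC provides the K(K−1)/2 pairwise RBF machines; this
package consumes only their raw one-vs-one decision values and implements
voting explicitly so the decision rule is documented: most pairwise wins;
vote ties broken by the larger aggregate signed margin; remaining ties by
class-label order.

* **Operating point**: C = 8, γ = 0.003 by default — the tuned optimum for
  the 70-feature ncRNA problem. γ may be given as the rule "1/n" (1/70),
  the conventional pre-search RBF default.
* **Scaling**: z-scoring is on by default. The features span 0–24,018
  (length) next to 0–0.5 (Npb); unscaled RBF distances would be dominated
  by length alone. `scaling="none"` preserves the literal unscaled
  reading. Scaling statistics come from training rows only and are stored
  in the model; prediction applies exactly the train-time transformation.
* **Grid search**: each (C, γ) cell trains on the same stratified 80/20
  split and is scored by held-out error; argmin with ties to the smallest
  C, then the smallest γ.
* **Persistence**: a versioned joblib archive embedding JSON metadata —
  hyperparameters, class list, per-class training counts and the feature-
  order fingerprint. Loading refuses version mismatches; prediction
  refuses feature tables whose fingerprint differs from the model's.
* Other estimator families (random forests, boosting, a voting ensemble)
  can be compared through the same train/predict seam but are not shipped.

## Evaluation

One confusion matrix (rows true, columns predicted), collapsed one-vs-rest
per class into TP/FN/FP/TN, gives the nine metrics; macro averages are
unweighted means over classes and every report also carries micro-accuracy
(trace/total), so the micro/macro ambiguity is always resolved by label
rather than by guess. Undefined ratios (zero denominators, e.g. a class
absent from the truth) are NaN with a flag and are excluded from macro
averages with a logged warning.

Split protocols: stratified 50/50, 80/20 and 95/5 train/test splits
(largest-remainder allocation makes the overall sizes exact) and
stratified 5-fold cross-validation with non-overlapping test folds.
Classes with a single member cannot be stratified and are kept on the
training side with a warning. All protocols are deterministic per seed,
and partition exactness (disjoint, exhaustive) is property-tested over
random seeds.

`feature_summary` produces per-class mean/median/SD/min/max plus
moment-based skewness and excess kurtosis for any feature column;
zero-variance samples get NaN skewness/kurtosis, flagged not zeroed.

## Synthetic data: what it emulates and what it does not

The fixture generators make every capability testable offline:

* `make_random_seq` — i.i.d. residues at a target AU fraction.
* `make_hairpin` — stem + loop + reverse-complemented stem; folds to at
  least the designed stem pairing, emulating the strong-hairpin character
  of pre-miRNAs.
* `make_class_dataset` — per-class length/AU/hairpin profiles reproducing
  the *directional* contrasts of real ncRNA classes (a ~21-nt miRNA-like
  class, a 200+-nt lncRNA-like class, a strongly paired pre-miR-like
  class), not calibrated per-class moments.
* `make_feature_clusters` — 8 isotropic unit-SD Gaussians in the 70-d
  feature space whose centers are simplex vertices at a requested pairwise
  separation (in within-class SDs), embedded under a seeded random
  rotation. The rotation matters: with z-scoring on, axis-aligned centers
  would inflate the variance of the few informative axes and silently
  shrink the effective separation; rotating spreads the class signal over
  all coordinates, as in real feature tables. Default separation is 10.

Geometry note: at separation s, each class has 7 competitors at distance
s with unit projection noise, so even the Bayes-optimal accuracy is only
about 1 − 7·Φ(−s/2); at s = 5 that is ≈ 0.93–0.96, and the measured 5-fold
macro-F1 of the default SVM is ≈ 0.91. Guaranteed near-perfect recovery
starts around s ≈ 8 (macro-F1 ≥ 0.99 measured); the default of 10 sits
safely inside that regime. On *indistinguishable* classes (s = 0), note
that cross-validation accuracy is systematically *below* chance — the
stratified training fold is anti-correlated with its test fold — so the
chance-level check is run on an independently generated test draw, where
accuracy is 1/K within binomial noise.

Passing these tests shows the pipeline recovers class structure that the
features actually contain; it does not show that real Viridiplantae ncRNA
classes are separable at any particular accuracy — that depends on the
real corpus (hundreds of thousands of RNACentral sequences), which this
package can process but does not ship.

## Scope notes

* Coding/non-coding discrimination is deliberately not performed; inputs
  should be pre-screened with a coding-potential tool, since folding
  measures and 3-mer rates separate ncRNA classes far better than they
  separate mRNA from ncRNA.
* Similarity-based redundancy reduction (e.g. clustering mRNAs at 50%
  identity) is external preprocessing, not part of curation here.
* Only exact-duplicate removal, k = 3 k-mers, and linear structures are
  supported; probability calibration and class weighting are out of scope.

## Problem sizes used in verification

The shipped verification suite uses: 200 random sequences of L ≤ 12 for
the folding-oracle equivalence, 1,000 random sequences of L ∈ [3, 60] for
the feature-algebra invariants (thermodynamic backend), 500 random
confusion-count quadruples for the metric identities, 100-row label sets
over 15 seeds for partition exactness, and 8×50 cluster rows for the
recovery checks — sizes at which the exhaustive oracles are exact and the
whole suite runs in well under a minute.
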