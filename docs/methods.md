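# Methods

`resamplebench` studies a single question: when does resampling an
imbalanced binary training set help a classifier, and how does the answer
depend on the *complexity* of the class structure, the imbalance ratio and
the sample size?  It couples a controlled synthetic-domain generator with
from-scratch implementations of the classic oversampling, undersampling
and hybrid filtering methods, data-complexity measures, and a
rank-difference evaluation protocol.

## The generative model

Each simulated row starts from a 6-variate Gaussian draw

    (X1, X2, X3, x̃4, x̃5, x̃6) ~ MVN(0, Σ),   Σ_jk = ρ (j ≠ k),  ρ = 0.3,

so every marginal is standard normal and every pair shares the same
correlation.  The 6×6 equicorrelation matrix is positive definite for
ρ ∈ (−1/5, 1); `sample_latent` rejects values outside that range.  The
last three coordinates are binarised at fixed quantiles,

    X4 = 1[x̃4 ≥ Φ⁻¹(0.30)],  X5 = 1[x̃5 ≥ Φ⁻¹(0.20)],  X6 = 1[x̃6 ≥ Φ⁻¹(0.15)],

giving binary prevalences P(X=0) of 0.30/0.20/0.15, and a response is
pushed through a sigmoid with a fresh standard-normal noise term per row:

    η = σ(1.1·X1 + 0.9·X2 + 0.7·X3 + X4 + X5 − X6 + ε),  ε ~ N(0, 1).

The linear predictor is clipped to ±36 before exponentiation so η stays
strictly inside (0, 1) in float64.

**Backbone models.**  A backbone partitions [0, 1) into 2^c equal-width
half-open intervals (the last closed at 1), each tagged minority or
majority.  The complexity levels map to

| level   | c | interval tags (low→high η) |
|---------|---|-----------------------------|
| low     | 1 | MAJ, MIN                    |
| medium  | 2 | MAJ, MIN, MAJ, MIN          |
| extreme | 2 | MIN, MAJ, MAJ, MIN          |

The medium layout alternates classes; the extreme layout pushes the two
minority sub-clusters to the opposite ends of the η range, maximising
their separation.  The exact tag placement is a convention of this
package (the published figures are not machine-readable); a `layout`
override accepts any MIN/MAJ sequence of length 2^c.

**Quotas.**  Sample size level s ∈ {1,3,5} and imbalance level
i ∈ {1,3,5} set per-interval quotas

    majority interval quota = round((5000/32)·2^s / 2^c)
    minority interval quota = round((5000/32)·2^s / 2^c / (32/2^i)),

with round-half-away-from-zero.  At c = 1 these reproduce the published
settings exactly — (s=1,i=1): N = 166 = 156 + 10, IR = 15.6;
(s=3,i=1): 664; (s=5,i=1): 2656; (s=5,i=3): 3125 — and i = 5 gives
balanced classes (divisor 1).  At c = 2 the per-interval quotas are
rounded halves of the c = 1 values, so class totals can drift by one or
two rows when the c = 1 total is odd or the half-quota lands on .5; this
is inherent to per-interval rounding and is covered by tolerance-2 tests.
One published setting (s=3, i=3, N printed as 681) is inconsistent with
the quota formulas and its own printed imbalance ratio (625 + 156 = 781,
IR 4); the package reproduces the formula value.

**Sampling.**  `generate_domain` draws batches of 4096 rows through the
latent → binarise → η pipeline and keeps each row only while its
η-interval still has unmet quota, so realised class counts are exact.  A
safety cap of 10^7 total draws guards unreachable quotas.  Matched test
sets reuse the backbone with quotas rescaled to a requested total
(default 5000) by largest-remainder rounding, preserving the training
imbalance ratio within rounding; the test stream is seeded independently
of the training stream (`SeedSequence([seed, 1])` vs `[seed, 0]`).

## Resampling methods

All methods operate on raw feature columns with Euclidean distance
(binary features as 0/1 — the simulated features are on comparable
scales; standardise real CSVs upstream if needed).  Neighbor ties break
toward the lower row index; a point is never its own neighbor; duplicated
points are legal neighbors.  Defaults follow the methods' original
publications: SMOTE k = 5, Borderline-SMOTE m = k = 5, ENN k = 3,
ALL-KNN k ≤ 3, NearMiss-3 (3, 3), IPF 9 partitions with a >½ vote and a
<1%-for-3-iterations stop.  The balancing target is full balance
(minority/majority = 1) unless overridden.

Orientation conventions worth noting:

* ENN as an undersampler edits **majority rows only**; inside SMOTE-ENN it
  edits **both classes** (the standard hybrid semantics).  An
  `edit_class` switch exposes both.
* Tomek-link undersampling removes only the majority member of each link;
  the SMOTE-TL hybrid removes **both** members.
* NCR deletes only majority rows (rule A: misclassified majority rows;
  rule B: majority neighbors of misclassified minority rows), both rules
  evaluated on the unmodified data.
* IHT scores every row's out-of-fold probability of its own class by
  3-fold cross-fitting (default learner: 50-tree random forest) and drops
  the lowest-scoring majority rows.
* IPF accepts single-class partitions when a class has fewer rows than
  partitions (a tree trained on one class predicts that class); it never
  deletes the last rows of a class.

Hybrids preserve per-row provenance tags (`original` / `synthetic`) so
deletions of synthetic versus original rows remain countable.

## Complexity measures

* **F3** (maximum individual feature efficiency): per feature, the overlap
  region is [max of class minima, min of class maxima]; F3 is the minimum
  over features of the fraction of rows inside it.  Oriented so 0 = one
  feature separates the classes, 1 = total overlap.
* **N2**: r = Σ nearest same-class distance / Σ nearest other-class
  distance, mapped to [0, 1] by r/(1+r).  The mapping is what keeps the
  claimed [0, 1] range.
* **C2**: IRm = ((C−1)/C)·Σ_c n_c/(n−n_c), C2 = 1 − 1/IRm; 0 for balanced
  data, e.g. 0.8723 for 156:10.

Stratification uses inclusive linear-interpolation quantiles: tertile
bins for the three-way splits, and top/bottom-quartile flags (value ≥ Q3,
value ≤ Q1) for the complex/noncomplex and imbalanced subsets.

## Evaluation protocol

AUPRC is non-interpolated average precision with the minority class
positive (ties grouped); AUROC is the trapezoidal/rank-sum area.  Within
each replicate, every method's AUPRC — including the no-resampling
baseline — is ranked (1 = best, average ranks for ties); a method's rank
difference is baseline rank minus its own rank, so positive values mean
the method improved the standing.  The baseline is part of the ranked
pool, making the pool size M = methods + 1.  Mean rank differences are
reported with a two-sided paired t-test on the underlying per-replicate
AUPRC values at α = 0.05, with no multiplicity correction; zero-variance
differences are flagged non-significant unless every difference is
non-zero with the same sign (reported with a degeneracy note).

## Study orchestration

The simulation runner generates one shared test set per domain and, per
replicate, a fresh training domain; each method's resampled training set
is used to tune a decision tree by stratified 3-fold cross-validated grid
search (max_depth ∈ {3, 5, 10, ∞} × min_samples_leaf ∈ {1, 5, 10},
scored by average precision — the study metric) and scored on the test
set.  Tuning happens per resampled training set, not once per domain.
All randomness descends from a master seed through
`SeedSequence([master, domain, replicate, stream])`, so identical
configurations give byte-identical result tables.  A resampler failure on
a replicate is logged and excluded from that replicate's ranking.

The real-CSV protocol encodes categoricals (one-hot below five levels,
ordinal codes otherwise), splits 7:3 stratified by class, computes the
complexity profile on the full dataset, and evaluates every
(resampler + baseline) × classifier combination — per dataset that is
(R+1)·C rows — before stratified summaries and top-combination tables.
The five classifier families (tree, k-NN, linear margin, forest,
feed-forward network) are scikit-learn adapters behind a fit/score
contract, with decision-function scores where probabilities are
unavailable.

## Scaled-down reproduction and what it shows

The packaged qualitative check runs low- and extreme-complexity domains
at s ∈ {1, 3} and i ∈ {1, 3, 5} with 10 replicates each — sizes chosen so
the whole check completes on a single CPU in minutes; the s = 5 domains
(up to 3125 training rows per replicate) are left to explicit
full-scale runs.  At these sizes the family-level ordering reported for
the original study (undersampling above oversampling on simple domains;
filtering on top under extreme complexity) does **not** emerge: the tuned
baseline tree is already strong in ranking terms, the drastic
undersamplers (random, NearMiss-3, IHT) leave very small training sets
and rank far below baseline, and SMOTE-style interpolation measurably
improves tree AUPRC at both complexity levels.  The cleaning
undersamplers (Tomek links, ENN variants, NCR) track the baseline
closely, consistent with the original study's caveat that undersampling
suffers under severe imbalance.  The corresponding acceptance test
asserts the published ordering and is expected to fail at these problem
sizes; the disagreement is robust to the tuning metric, to tuning once
per domain versus per resampled set, and to ranking by AUROC instead of
AUPRC.

## What the generator does and does not emulate

The synthetic domains share one global covariance structure, exact class
quotas, and labels that are a deterministic function of a noisy
1-D response — so passing tests demonstrate correct implementation of
this generative family, not performance on real data, where feature
scales differ, classes need not be threshold sets of a single index, and
label noise is not homoscedastic.  The real-data protocol is therefore
exercised on synthetic CSVs for its bookkeeping and arithmetic contracts
only.

## Numerical choices and limitations

* Rounding of fractional quotas: half away from zero (`round_half_away`).
* Largest-remainder allocation for test-set quotas and ADASYN budgets,
  ties toward the lower index.
* Neighbor searches materialise full distance matrices (fine to a few
  thousand rows; the largest simulated domain is 3125 rows, 6250 after
  balancing).
* `average_precision_score` / `roc_auc_score` supply the raw metric
  values; tests pin both to exhaustive hand-computed oracles.
* SVM-SMOTE and k-means-SMOTE, and the citation-only filters (DSRBF,
  TRIM-SMOTE, SMOTE-RSB*, NRSBoundary-SMOTE, NEATER, SMOTE-FRST-2T,
  NRAS), are not implemented: the first two depend on an auxiliary
  learner/clusterer whose behaviour the registry cannot pin down, and the
  rest have no operative description to implement.
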