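# Methods

## Problem and model

`essmir` classifies pre-miRNA hairpins (~60–110 nt) as essential (1) or
non-essential (0) from sequence- and structure-derived features. The
learner is a gradient-boosted ensemble of Gini-criterion classification
trees: the base tree chooses splits minimizing the size-weighted Gini
impurity I(D, α) = Σⱼ (|Dⱼ|/|D|)(1 − Σᵢ pᵢ²), and boosting fits T such
trees stagewise to the gradient of a logistic loss with shrinkage R and
L2 leaf-weight penalty λ. The tree stage delegates to scikit-learn's
`DecisionTreeClassifier(criterion="gini")` and boosting to
`xgboost.XGBClassifier` (exact tree method, single thread, fixed seed);
the impurity formulas are additionally exposed and tested as standalone
functions (`gini_index`, `branch_purity`) to anchor the contract.

Essential = 1 is the positive class everywhere (metrics, ROC, output
files): essentiality detection is the tool's purpose. Probabilities are
the canonical output; hard labels use a fixed 0.5 cutoff.

## Feature encoders

All k-mer-type orderings are lexicographic with A < C < G < U; this fixes
every dimension's identity across encoders, files and models.

* **k-mer** (k ∈ [1,6]): window counts over the l−k+1 windows, normalized
  to frequencies (unit sum).
* **mismatch** (k ∈ [1,6], m ∈ [0,k−1]): per k-mer type, the number of
  windows within Hamming distance m — equivalently Σ_{j≤m} c_{i,j} with
  c_{i,j} the count of windows at exactly j mismatches. Raw counts, not
  normalized.
* **subsequence** (k ∈ [2,4], δ ∈ [0,1]): per type, Σ over ordered index
  tuples p₁<…<p_k spelling the type of δ^span, where a contiguous tuple
  contributes δ⁰ = 1 and a gapped tuple δ^(p_k−p₁+1). Computed by an
  O(l·4^k) dynamic program over decayed prefix sums; an exhaustive tuple
  enumeration is its test oracle. δ = 0 (with 0⁰ := 1) reduces exactly to
  contiguous k-mer counts — a tested degeneracy, like mismatch at m = 0.
* **triplet**: each interior position contributes (paired/unpaired
  pattern of its 3-window, bracket direction collapsed) × center
  nucleotide → 32 bins, normalized by l−2. Computed over the full
  pre-miRNA; variants of this feature in the literature sometimes first
  excise the hairpin stem-loop segment, which we deliberately do not do —
  a documented convention choice, not a free parameter.
* **PseDSSPC** (d ∈ [1,10], λ ∈ [1,20], w ∈ (0,1]): three blocks —
  (1) frequencies of the 10 structural statuses; (2) for each distance
  d′ = 1..d, frequencies of the 100 *ordered* status pairs (i, i+d′),
  normalized by l−d′ (the ordered convention is what yields 100 entries
  per distance); (3) pseudo-energy correlation tiers
  g_k = (1/(l−k)) Σ (e(tᵢ)−e(tᵢ₊ₖ))² for k = 1..λ. Blocks 1–2 are
  divided by Z and block 3 by Z/w with Z = Σ(blocks 1–2) + w·Σ(block 3);
  since block 1 sums to 1 and block 2 to d, Z = 1 + d + w·Σg, and the
  final vector sums to 1. Requires l > max(d, λ).

Mixed scaling (frequencies vs. raw counts) across schemes is harmless for
tree learners, which are monotone-invariant per feature; the convention is
recorded in each matrix's provenance.

### Structures and pseudo-energies

Structures are MFE dot-brackets from ViennaRNA (engine defaults for
temperature and dangles; version recorded via `fold_engine_info`), or
user-supplied dot-bracket files — the latter path makes all structural
features engine-free, which the hairpin fixtures exploit. Pseudoknot
bracket dialects are rejected; the alphabet is exactly `( ) .`.

Per-residue status is the residue itself when unpaired, else the ordered
pair X-Y (X = the residue, Y = its partner). Only the six canonical and
wobble categories are legal; a non-canonical pair in a file-supplied
structure is a hard error (MFE engines never emit them). The status
pseudo-energy e(t) is a configurable 10-entry table. No published value
set exists for it, and the PseDSSPC tiers consume only squared
differences of e along the sequence, so any fixed table gives a
well-defined, reproducible feature; the shipped default is 0 for the four
unpaired statuses and −3 / −2 / −1 for G-C/C-G, A-U/U-A, G-U/U-G
(stabilizing order G-C > A-U > wobble). Supplying a different table via
`PseDsspcEncoder(energy_table=...)` changes only the tier block.

## Evaluation protocols

* **LOOCV**: each sample scored by a model trained on the other n−1; all
  n held-out scores pooled into one ROC and one confusion matrix
  (per-fold ROC is undefined for singleton folds). Features are encoded
  once up front — encoders are strictly per-sequence, so no information
  leaks across folds.
* **Repeated stratified 5-fold** (default 50 reps): repetition r is
  seeded `seed + r`; within a repetition, held-out scores from the 5
  folds are pooled into one report; reports are averaged arithmetically
  across repetitions. Stratification avoids class-empty folds at n ≈ 150.
  The mean is returned as a summary object (mean/std per metric) rather
  than a synthetic `MetricsReport`, so the invariant "metrics recompute
  exactly from stored counts" holds for every report.
* **Metrics**: Acc, Pre, Rec, F1 from thresholded counts; AUROC as the
  Mann–Whitney rank statistic with ties counted 1/2 (pair-counting oracle
  in the tests). Zero-denominator Pre/Rec/F1 are reported as 0 with an
  explicit `undefined` flag, so aggregation never fails.
* **Sequential grid search**: parameters scanned one at a time in a
  stated order, earlier winners frozen, later parameters at defaults;
  ties break toward the first-listed value (list values simplest-first to
  bias toward simpler models). The full (parameter, value, objective)
  trace is returned for audit. The shipped `CALIBRATION_GRIDS` hold the
  standard scan ranges (k = 1..6; m ≤ k−1; subsequence k ∈ {2,3,4},
  δ = 0.1..0.9; d ∈ 1..10, λ ∈ 1..20, w = 0.1..0.9; tree S/D/M; boosting
  T = 50..500 step 10, R = 0.1..0.5 step 0.02, D = 3..10, λ = 0..2 step
  0.1). The mismatch m-grid depends on k, so calibration scans k first at
  m = 0, then m over [0, k_best−1]; the tree M-grid depends on the
  feature dimension n and is resolved at run time. Objective defaults:
  accuracy for tree-stage scans, AUROC for boosting-stage scans.
* Un-scanned learner parameters sit at conventional defaults — trees:
  S = "best", D = 6, M = n; boosting: T = 100, R = 0.3, D = 6, λ = 1 —
  documented here and recorded in provenance rather than claimed optimal.

## Synthetic data

The fixture generators define the conditions under which the pipeline is
exercised:

* `random_rna(length, gc)` — i.i.d. residues, P(G)=P(C)=gc/2.
* `hairpin_rna(stem, loop)` — perfect stem-loops with ground-truth
  structures whose pairs are canonical by construction.
* `planted_motif_dataset` — defaults: 100 positives + 100 negatives,
  lengths uniform in 60–90 nt, GC 0.5, motif GGGCCC overwritten at a
  uniform position in each positive (insertion rate 1), negatives
  guaranteed motif-free by rejection sampling. The scale mimics curated
  mouse pre-miRNA essentiality benchmarks (~170 hairpins of 60–110 nt)
  while keeping LOOCV runs in seconds; the 6-mer motif gives k = 3
  features a learnable but non-trivial signal (boosted LOOCV AUROC ≈
  0.92, not 1.0, since a 6-mer also arises by chance in ~75-window
  backgrounds).

What the planted signal does *not* emulate: miRNA biogenesis signals,
conservation, base composition biases between essential and non-essential
genes, or class imbalance. Passing the end-to-end checks therefore shows
the pipeline can recover a known discriminative sequence signal at
realistic n and l — not that the same performance transfers to real
essentiality labels.

A known property of pooled-score LOOCV on signal-free data: individual
permutation AUROCs scatter widely (roughly 0.3–0.8 at n = 60) and are
slightly pessimistically biased per run (leaving out a positive tilts the
training prior negative), but the mean across permutations centers at
0.5, which is what the null check asserts.

## Numerical and design choices

* All training is a pure function of (X, y, params, seed): XGBoost runs
  single-threaded with `tree_method="exact"`; sklearn trees take an
  explicit `random_state`. CV clones are re-seeded per protocol rule.
* Boundary lengths are legal inputs: l = k (one window), l = 3 (one
  triplet window), l = max(d, λ)+1 (one term in the shortest block).
* Encoders validate parameters at use (k ∈ [1,6], m ∈ [0,k−1],
  δ ∈ [0,1], d ≥ 1, λ ≥ 1, w ∈ (0,1]); batch encoding collects all
  per-sequence failures and aborts the batch, never emitting a partial
  matrix.
* Feature matrices carry provenance (scheme, parameters, dimension);
  models record the provenance they were fitted on and refuse to score a
  matrix with different provenance. Model artifacts embed a schema
  version and library versions and refuse to load on mismatch.
* CLI outputs are written atomically (write-then-rename) and every
  command emits its fully-resolved configuration as JSON next to its
  output.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run entirely on generated
data: oracle-equivalence sweeps use 500 random sequences of length ≤ 12
cycling through the full calibration grids (PseDSSPC cells restricted to
d, λ < 12 as forced by the length cap and the l > max(d, λ)
precondition); end-to-end checks use the n = 200 planted-motif set under
LOOCV and 50×5-fold CV, and a 20-permutation null at n = 60. These sizes
were chosen to keep a full run in minutes on one CPU while leaving the
discrimination and null checks statistically meaningful.

## Known limitations

* Real essentiality benchmarks are small and partly hand-curated; nothing
  here addresses label noise or the strong class imbalance of genome-wide
  application (false positives are expected when ranking a whole genome).
* The pseudo-energy table is a documented convention, not a fitted or
  published quantity; downstream feature values (tier block only) depend
  on it.
* Whether mismatch/subsequence features should be re-normalized before
  training is a convention on which published pipelines vary; raw
  accumulations are used here (monotone-invariant for trees).
* The sequential grid search is greedy by design and can miss jointly
  optimal settings a Cartesian scan would find; that is the protocol's
  definition, not an implementation shortcut.
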