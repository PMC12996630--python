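# Methods

## Problem and model

`dpas` addresses positive-unlabeled peptide prioritization: a curated set of
disease-associated (mutated) peptides exists, but biologically validated
*non*-disease peptides do not, so ordinary binary classifiers cannot be
trained honestly. The package instead models the positive class alone with
one-class learners and scores each peptide by how far it deviates from the
learned positive structure, then fuses that anomaly score with a
feature-importance term into a single ranking score:

    DPAS(i) = alpha * e_i + beta * f_i

where `e_i` is the min–max-normalized anomaly score of peptide *i* (its
normalized reconstruction error for the reconstruction-type models) and
`f_i` is a per-sample importance term (below), both in [0, 1]. `alpha` and
`beta` are user weights, default 0.5 each; only their ratio affects the
ranking.

## Sequence descriptors

Every peptide is upper-cased and restricted to the 20 canonical letters,
then mapped to a fixed-order row of 459 numeric features:

| block | width | definition |
|---|---|---|
| `AAC_*` | 20 | per-letter frequency / length |
| `GRP_*` | 11 | group-wise sums of AAC over an 11-group reduced alphabet |
| `Volume_Measure` | 1 | mean residue volume (Å³) over the sequence |
| `Hydrophobicity_Measure` | 1 | mean Hopp–Woods (1981) hydrophilicity value |
| `PCP_*` | 5 | residue fractions in 5 physicochemical classes (HB/HL/NT/PC/NC) |
| `SER` | 1 | Shannon entropy (bits) of the 20-letter composition |
| `RRI_*` | 20 | count/length for letters occurring ≥ 2 times, else 0 |
| `DPC_*` | 400 | adjacent-pair frequencies / (length − 1), order AA..YY |

An optional binary `MOTIF_*` block is appended on the right: 1 if a
PROSITE-style pattern matches the sequence anywhere (internal scanner), or if
an external MAST-style hit table contains a hit with `evalue <= threshold`
(the significance convention; a `ge` switch reproduces the opposite reading).
Missing motifs stay 0.

Design choices that were genuinely open:

- **Backing tables.** The residue-volume table is the Zamyatnin (1972)
  tabulation and the hydrophobicity table is Hopp–Woods (1981); both ship as
  versioned TSVs with citation headers, are checksum-pinned in the tests, and
  are swappable through the scale-file interface — any 20-row
  `letter<TAB>value` file drops in, so a different volume estimate (e.g.
  Kharakoz's) can replace the default without code changes.
- **Groupings.** The 11-group reduced alphabet (A | C | DE | FWY | G | H |
  ILMV | KR | NQ | P | ST) and the 5-class physicochemical membership
  (positive {K,R,H}, negative {D,E}, hydrophobic {A,C,F,I,L,M,V,W},
  hydrophilic {N,Q,S,T,Y}, neutral {G,P}) are documented package defaults,
  replaceable by user grouping files. No feature depends on which published
  grouping is supplied; only the interpretation of the `GRP_*`/`PCP_*`
  columns does.
- **Entropy.** `SER` is the entropy of the whole-sequence composition (one
  scalar per peptide), the standard reading of residue-level sequence
  entropy; a per-position entropy profile would not be a fixed-width feature.
- **Case.** Lowercase letters (used by some databases to mark substituted
  residues) are preserved on I/O but never interpreted.

Featurization is row-independent, so chunked execution (`--chunks N`)
produces bit-identical matrices to a single pass — chunking exists purely to
bound memory on large inputs.

## Anomaly scoring

Features are z-scored with population statistics (features with sd < 1e-12
map to exactly 0), then reduced by PCA, then scored by one of:

- **one-class SVM** (`linear` or `rbf`, default `rbf`, nu = 0.05): raw score
  = negated decision-function value;
- **isolation forest** (100 trees, contamination `auto`, seeded): raw score
  = negated native `score_samples`;
- **autoencoder**: a symmetric MLP `p → ⌈p/2⌉ → ⌈p/4⌉ → ⌈p/2⌉ → p` with ReLU
  hidden units, trained input→input by Adam for 50 epochs with an MSE
  objective, seeded; raw score = per-sample mean squared reconstruction
  error;
- **pca**: per-sample squared residual after projecting onto the retained
  components (a model-free diagnostic scorer).

Negating the SVM/forest scores gives every model the same direction (higher
= more anomalous), so their min–max-normalized scores are directly
comparable.

**Retained components.** The default is `"auto"`: the smaller of (a) the
smallest k explaining 95% of variance and (b) ⌈√n⌉. The cap matters at
moderate sample sizes: with n of order 10²–10³ against 459 largely
independent descriptor columns the variance spectrum is nearly flat, the
95% rule keeps most directions, and a near-full-rank basis reconstructs
anomalies as faithfully as inliers — reconstruction-type scores then carry
no signal and the forest dilutes across noise directions. Any explicit
integer or variance fraction overrides the rule. The `pca` diagnostic scorer
remains sensitive to this choice on weak-structure data and should be read
as a complement to, not a substitute for, the three model-based scorers.

**Thresholding.** The outlier threshold is the 95th percentile (linear
interpolation between order statistics — the numpy default, documented
because small-n percentiles are otherwise ambiguous) of the normalized
scores of the scored set itself; labels are −1 strictly above the threshold,
+1 otherwise. By construction this flags ~5% of a continuously scored set;
ties can only lower the flagged fraction. A warning fires below 20 samples.
`summarize_scores` reports mean, median, threshold and flagged percentage of
the normalized scores.

## Feature importance and ranking

Attribution is model-agnostic background permutation: feature j's
attribution for sample i is the mean absolute change of sample i's raw
anomaly score over `n_perm` re-scorings in which column j is replaced by a
permutation of itself (the scored set is its own background). A feature the
model ignores, or one constant across the background, gets attribution 0.
Exact Shapley values are deliberately not computed; the permutation
estimator keeps the contract model-agnostic and O(p·n_perm) score calls.

Global importance is the per-feature mean |attribution|. The DPAS importance
term `f_i` averages |attribution| over the top-k globally important features
(default k = 3) and is min–max normalized across samples: a global constant
would shift every DPAS equally and change no rank, so the per-sample
operationalization is what makes the beta term informative. Ranks are dense
(equal DPAS shares a rank), decreasing, with lexicographic sample-id
tie-breaks; `select_top` exports the top-n (default 15) peptides to FASTA
for downstream annotation.

## Synthetic data and validation

`SyntheticSpec` defaults define the package's reference fixture: 100 inliers
and 5 outliers (≈5% contamination, matching the one-class setting), lengths
uniform on 8–15 residues (typical proteolytic-peptide lengths), seed 7.
Inliers draw residues i.i.d. from a natural-abundance-like composition and
carry a planted conserved motif (`[ST]-P`, plant probability 0.8); outliers
draw from a strongly divergent aromatic/cysteine-rich composition
(W/C/H/M/Y/F only). That composition shift is the fixture's documented
effect size: it is large by design so that outlier recovery is a property of
the *method*, not of a marginal signal-to-noise setting. Ground-truth labels
travel in a sidecar TSV and never enter FASTA headers, keeping the scoring
path label-blind.

What the fixture does not emulate: real mutated-peptide sets have positional
(motif/terminal) structure, length–composition coupling, and near-duplicate
families; i.i.d. draws have none of these. Passing the recovery tests
therefore demonstrates correct mechanics and score direction, not field
performance on database-scale data.

**Permutation negatives.** Each feature column is permuted independently
(its own draw from one seeded stream) — per-column marginals survive
exactly; joint structure, e.g. the simplex constraint tying composition
columns, is destroyed. A single shared row permutation would preserve
dependencies and defeat the construction. `run_validation_experiment`
stacks positives with 1:1 permuted negatives (ratio configurable), splits
70/30 stratified, and trains two baselines: an RBF SVM and a compressive MLP
classifier (an encoder stack with a classification head), reporting
per-class precision/recall/F1, accuracy and confusion counts on the held-out
split.

## Numerical conventions and limitations

- Composition vectors sum to 1 within 1e-12; entropy is clamped to
  [0, log2 20] only by arithmetic, never post-hoc.
- Min–max normalization of a constant score vector returns all zeros.
- All stochastic steps (generator, forest, autoencoder, attribution
  permutations, train/test splits) take explicit seeds; identical seed +
  input gives identical output, including byte-identical CLI artifacts.
- Problem sizes in the test suite and acceptance script (fixtures of 10²–10³
  peptides) are chosen so the full reference analysis re-runs in seconds on
  one CPU; all statistics are defined identically at any scale.
- OCSVM's decision function saturates for points far outside the boundary,
  so while planted outliers all score above the inlier median, the single
  top-ranked sample under OCSVM need not be an outlier; the autoencoder is
  the model of choice for DPAS ranking.
- One-class scores are relative to the training distribution: they flag
  atypicality, not disease mechanism, and the percentile threshold fixes the
  flagged fraction rather than estimating a true contamination rate.
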