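# dpas

One-class anomaly scoring and **DPAS** (disease peptide anomaly score)
ranking of peptide sequences.

## The problem

Supervised classifiers for disease-associated peptides need negative
examples, but biologically validated *non*-disease peptides essentially do
not exist; negatives assembled from unrelated peptide categories bias the
model. `dpas` takes the positive-unlabeled route: it learns the structure of
the positive class alone with one-class models, scores each peptide by how
far it deviates from that structure, and fuses the anomaly score with a
feature-importance term into a single prioritization score,

    DPAS = α · (normalized anomaly score) + β · (importance term),

both terms in [0, 1], with user weights α, β (default 0.5 each). It is
aimed at computational biologists prioritizing candidate peptide biomarkers
from positive-only sequence collections.

## What it computes

- **Descriptors (459 columns, fixed order):** amino-acid composition (20),
  an 11-group reduced-alphabet composition (11), mean residue volume and
  mean Hopp–Woods hydrophilicity (1 + 1), five physicochemical class
  fractions (5), composition Shannon entropy (1), repetitive-residue
  information (20), dipeptide composition (400) — plus an optional binary
  motif block from PROSITE-style patterns or a MAST-style E-value hit table.
- **One-class scorers behind one contract** (higher = more anomalous,
  min–max normalized): one-class SVM (negated decision function), isolation
  forest (negated `score_samples`), a compressive MLP autoencoder trained
  input→input for 50 epochs (mean squared reconstruction error), and a PCA
  reconstruction-error diagnostic. Outliers are labelled −1 above the 95th
  percentile of the scored set.
- **Permutation feature attribution** (model-agnostic background
  permutation), the DPAS fusion and ranking, and top-N FASTA export.
- **Validation without real negatives:** synthetic negatives by independent
  per-column permutation of the positive feature matrix (marginals preserved
  exactly, dependencies destroyed), evaluated with SVM and MLP binary
  baselines; plus a seeded synthetic peptide generator with planted
  outliers and motifs.

See `docs/methods.md` for definitions, defaults and limitations.

## Worked example

Simulate the reference fixture (100 inliers from a natural-abundance-like
composition, 5 planted aromatic/cysteine-rich outliers), then run the whole
pipeline:

```sh
dpas simulate --n-inliers 100 --n-outliers 5 --seed 7 \
     --out-fasta pep.fasta --out-truth truth.tsv
dpas featurize pep.fasta --out features.tsv
dpas fit features.tsv --model autoencoder --seed 0 --out-model ae.joblib
dpas score ae.joblib features.tsv --out scores.tsv
dpas summary scores.tsv
```

```
autoencoder  n=105  mean=0.12365  median=0.08038  p95_threshold=0.43756  outliers=5.71%
```

Normalized reconstruction errors cluster low (median 0.08) with a heavy
right tail; the 95th-percentile rule flags 6/105 = 5.71% of samples (the
discreteness of n = 105 puts the flagged fraction one sample above 5%).
Now attribute, fuse and rank:

```sh
dpas importance ae.joblib features.tsv --n-perm 2 --seed 0 --out attr.tsv
dpas rank scores.tsv attr.tsv --alpha 0.5 --beta 0.5 --out rank.tsv
head -4 rank.tsv
```

```
sample_id   normalized_error    importance_term     dpas                rank
pep_0101    1.0                 1.0                 1.0                 1
pep_0103    0.6142266289510984  0.8359202852956121  0.7250734571233552  2
pep_0104    0.5495612075127191  0.6080292330755389  0.578795220294129   3
```

The three top-ranked peptides are all planted outliers (cross-checking
`rank.tsv` against the `truth.tsv` sidecar shows all 5 planted outliers
inside the top 15). Export them for external annotation:

```sh
dpas select rank.tsv pep.fasta -n 15 --out top15.fasta
```

The validation route (`dpas permute-negatives`, `dpas evaluate`, or
`dpas.synth.run_validation_experiment` from Python) trains binary baselines
against column-permutation negatives and reports per-class
precision/recall/F1 with confusion counts.

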