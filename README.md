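# jamupls

Multivariate analysis of binary herbal-formulary data: given a
formula × plant usage matrix (0/1), per-formula efficacy classes, and a
plant × pharmacological-activity annotation, the package relates ingredient
composition to efficacy through

- **PCA biplots** of the plant × efficacy frequency matrix (plants as
  points, efficacy classes as vectors),
- **PLS-DA** (NIPALS PLS2 on a dummy-coded response) predicting efficacy
  class from plant usage, reported as a confusion matrix with per-class and
  overall percent correct,
- a **permutation test** on the PLS-DA coefficients identifying
  main-ingredient plants per efficacy (two-sided on |b|, add-one p-values),
- **N-PLS-DA**, trilinear PLS on the formula × plant × activity tensor,
  with Kronecker-structured weights, deflation-corrected weights, and an
  |w^K| ≥ 0.3 activity-significance rule,
- a **Ward/Euclidean clustergram** of the activity × efficacy significance
  matrix (explicit Lance–Williams linkage, Newick export),
- a **synthetic formulary generator** with planted main plants and
  specific/general activity groups, providing ground truth for recovery
  tests, and
- a **pipeline** runner orchestrating all stages with content-hashed
  output manifests.

Since real formulary databases of this kind are not redistributable, every
stage is exercised on synthetic data with known structure; the published
summary tables of the motivating 3,138-formula dataset ship in
`jamupls.datasets` as fixed reference inputs for the summary utilities.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` contains the heavier simulation-based checks
(permutation calibration, parameter recovery); the full suite takes a few
minutes, everything else runs in seconds.

## Command line

One executable with per-stage subcommands:

```sh
jamupls simulate  --seed 0 --outdir out/                 # synthetic formulary + ground truth
jamupls pca-biplot --usage out/usage.tsv --outdir out/   # eigenvalues, scores, biplot coords
jamupls plsda     --usage out/usage.tsv --components 4 --outdir out/
jamupls permtest  --usage out/usage.tsv --components 4 --n-perm 999 --outdir out/
jamupls npls      --usage out/usage.tsv --activity out/activity.tsv --outdir out/
jamupls clustergram --significance out/activity_significance.tsv --outdir out/
jamupls run-all   --outdir out/ --seed 0                 # all of the above, with manifest
```

All tables are tab-separated text with a header of variable ids and a
first column of observation ids; the usage table carries the efficacy
label in an `efficacy` column. `run-all` also accepts a JSON config
(`--config run.json`) with per-stage parameters.

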