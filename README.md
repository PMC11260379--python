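# ecplsc

Eigenvector-centrality brain networks and Partial Least Squares Correlation
(PLSC) for brain–behavior analysis, with a synthetic-cohort generator for
ground-truth validation.

## The problem

In aging and Alzheimer's-disease research, a recurring question is how
resting-state brain network organisation relates jointly to age, genetic
risk (the APOE ε4 allele), and cognitive symptoms. This package implements
that analysis as a reusable pipeline for anyone with parcellated
resting-state BOLD time series and a phenotype table:

1. **Connectivity** — each subject's regional time series are band-pass
   filtered (0.01–0.15 Hz, zero-phase Butterworth), pairwise Pearson
   correlations form the functional-connectivity (FC) matrix, and the
   eigenvector of its largest eigenvalue scores every region's hub status
   (eigenvector centrality, the best rank-1 symmetric approximation of FC).
2. **Design** — a six-column behavioral matrix
   `Y = [z(age), z(E4), z(sympt), z(age)·z(E4), z(age)·z(sympt), z(E4)·z(sympt)]`,
   with carrier = any E4-containing genotype and symptomatic = MCI or AD.
3. **PLSC** — SVD of the cross-covariance `R = Yᵀ X_z / (n−1)`:
   `R = U diag(s) Vᵀ`, with brain saliences `V`, behavioral saliences `U`,
   permutation p-values on the singular values, bootstrap ratios
   (salience / bootstrap SE, stable if |BR| > 2), and latent scores
   `Lx = X_z V`, `Ly = Y U`.
4. **Aging score** — `Ly^age = Y^age U^age`, the behavior score restricted
   to the age-related columns (age, age×E4, age×symptoms); a per-subject
   measure of how strongly age effects drive the component, reported with
   per-group regression slopes against chronological age.

Because clinical cohorts of this kind cannot be shared, the package ships a
first-class synthetic-cohort generator: phenotype tables with exact
carrier/symptomatic counts, and either feature matrices or full Gaussian
time series with a *planted*, known rank-1 brain–behavior covariance
structure, so every downstream claim can be tested against ground truth.

## Worked example

```bash
python examples/03_plsc_analysis.py
```

plants one strength-5 effect in a default 128-subject cohort with 379
regions and unit feature noise, then fits the full PLSC:

```
singular values: [4.682 1.933 1.687 1.664 1.576 1.38 ]
p-values:        [0.001  0.0939 1.     0.9341 0.958  0.1329]
significant components (sequential, alpha=0.05): 1
|cosine(recovered V1, planted pattern)| = 0.941
regions with |bootstrap ratio| > 2 on component 1: 210
```

The planted component is detected at the permutation floor
(p = 1/1001 ≈ 0.001), none of the noise components reach significance, and
the recovered brain salience points within ~20° of the planted pattern
(|cosine| = 0.94). `examples/01_simulate_cohort.py` and
`examples/02_connectivity_features.py` walk through the cohort generator
and the time-series → centrality pipeline the same way.

## Library and CLI

Everything is importable from `ecplsc` (see the examples for the API
surface: `generate_cohort`, `build_feature_matrix`, `build_design`,
`fit_plsc`, `cohort_summary`, `aging_score_report`, `run_pipeline`). A thin
CLI drives full runs from a YAML config:

```bash
ecplsc simulate --config run.yaml     # synthetic cohort + full analysis
ecplsc fc --ts-dir ts/ --tr 3.0       # time series -> FC matrices only
ecplsc run --config run.yaml          # analysis on existing inputs
ecplsc report --run-dir out/          # summary of a finished run
```

Input modes: `timeseries` (per-subject TSV matrices), `fc` (precomputed FC),
`features` (a subjects × regions CSV), or `simulate`. Every run writes
salience/score/aging-score tables, a `plsc_summary.json`, and a manifest
with content hashes for reproducibility.

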