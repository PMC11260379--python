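"""From parcellated time series to eigenvector-centrality features.

Simulates Gaussian BOLD series for a few subjects whose functional
connectivity carries an age-coupled community, then runs the band-pass
filter (0.01-0.15 Hz) -> Pearson FC -> leading-eigenvector pipeline and
prints where centrality concentrates.
"""

import numpy as np

from ecplsc import (
    CohortSpec,
    FCMatrix,
    PlantedEffect,
    build_feature_matrix,
    generate_cohort,
    generate_timeseries,
)

N_REGIONS = 40
cohort = generate_cohort(CohortSpec(n_subjects=8, n_carriers=3,
                                    n_symptomatic=3, seed=2))

# base connectivity: weak uniform correlation; planted community: the first
# 10 regions, whose internal coupling scales with each subject's age z-score
base = np.full((N_REGIONS, N_REGIONS), 0.1)
np.fill_diagonal(base, 1.0)
v = np.zeros(N_REGIONS)
v[:10] = 1 / np.sqrt(10)
u = np.zeros(6)
u[0] = 1.0  # age column of the behavioral design
effect = PlantedEffect(brain_pattern=v, behavior_pattern=u, strength=1.0)

ts = generate_timeseries(cohort, [effect], FCMatrix(values=base),
                         coupling=0.6, seed=3, n_timepoints=197, tr=3.0)
print(f"{len(ts)} subjects x {ts[0].n_regions} regions x "
      f"{ts[0].n_timepoints} timepoints (TR = {ts[0].tr} s, "
      f"Nyquist = {ts[0].nyquist:.3f} Hz)")

X = build_feature_matrix(ts)  # filter -> FC -> eigenvector centrality
print(f"feature matrix: {X.shape[0]} subjects x {X.shape[1]} centralities")
print("centrality row norms (always 1):",
      np.round(np.linalg.norm(X.values, axis=1), 6)[:4], "...")

# older subjects load the planted community more strongly
ages = cohort["age"].to_numpy()
community = X.values[:, :10].mean(axis=1)
r = np.corrcoef(ages, community)[0, 1]
print(f"corr(age, mean centrality of planted community) = {r:.2f}")
print("positive r: the community's hub status strengthens with age, "
      "exactly what was planted")
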