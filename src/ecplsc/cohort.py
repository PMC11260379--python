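"""Synthetic cohorts with planted brain-behavior covariance structure.

Generates ADNI-like phenotype tables (age, sex, APOE genotype, diagnosis)
and, on top of them, either regional feature matrices directly or full
parcellated time series whose functional connectivity carries a planted
low-rank brain-behavior effect. Every generator is deterministic given its
seed, so downstream stages can be tested against known ground truth.

Defaults mirror the study cohort this emulates: 128 subjects, 54 APOE4
carriers, 52 symptomatic, 379 regions, 197 timepoints at TR = 3 s, age
73.42 +/- 7.59 years.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import FCMatrix, RegionTimeSeries
from .design import build_design
from .errors import ValidationError

# Genotype marginals. Only the binary carrier flag enters the analysis, so
# these just need to be realistic: carriers are mostly E3/E4 with a little
# E4/E4 and the occasional E2/E4; non-carriers mostly E3/E3.
CARRIER_GENOTYPES = (("E3/E4", 0.85), ("E4/E4", 0.10), ("E2/E4", 0.05))
NONCARRIER_GENOTYPES = (("E3/E3", 0.85), ("E2/E3", 0.15))

# Diagnosis mix within each symptom stratum (MCI:AD = 39:13, CN:SMC = 39:37).
SYMPTOMATIC_DIAGNOSES = (("MCI", 39 / 52), ("AD", 13 / 52))
NONSYMPTOMATIC_DIAGNOSES = (("CN", 39 / 76), ("SMC", 37 / 76))

_P_FEMALE = 71 / 128  # F/M = 71/57 in the emulated cohort
_AGE_RANGE = (50.0, 95.0)


@dataclass(frozen=True)
class CohortSpec:
    """Size and composition of a synthetic cohort."""

    n_subjects: int = 128
    n_carriers: int = 54
    n_symptomatic: int = 52
    age_mean: float = 73.42
    age_sd: float = 7.59
    n_regions: int = 379
    n_timepoints: int = 197
    tr: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be at least 1")
        if not 0 <= self.n_carriers <= self.n_subjects:
            raise ValidationError("n_carriers must lie in [0, n_subjects]")
        if not 0 <= self.n_symptomatic <= self.n_subjects:
            raise ValidationError("n_symptomatic must lie in [0, n_subjects]")
        if self.n_regions < 2:
            raise ValidationError("n_regions must be at least 2")
        if self.n_timepoints < 4:
            raise ValidationError("n_timepoints must be at least 4")
        if self.tr <= 0:
            raise ValidationError("tr must be positive")
        if self.age_sd <= 0:
            raise ValidationError("age_sd must be positive")


@dataclass
class PlantedEffect:
    """Ground-truth rank-1 brain-behavior covariance component.

    ``brain_pattern`` (over regions) and ``behavior_pattern`` (over the six
    design columns) are unit-norm; ``strength`` scales the planted singular
    value. Distinct effects must have mutually orthogonal patterns so that
    they map onto distinct SVD components.
    """

    brain_pattern: np.ndarray
    behavior_pattern: np.ndarray
    strength: float

    def __post_init__(self):
        self.brain_pattern = np.asarray(self.brain_pattern, dtype=float)
        self.behavior_pattern = np.asarray(self.behavior_pattern, dtype=float)
        if self.behavior_pattern.shape != (6,):
            raise ValidationError("behavior_pattern must have length 6")
        for name, v in (("brain_pattern", self.brain_pattern),
                        ("behavior_pattern", self.behavior_pattern)):
            if abs(np.linalg.norm(v) - 1.0) > 1e-8:
                raise ValidationError(f"{name} must have unit l2 norm")
        if self.strength < 0:
            raise ValidationError("strength must be nonnegative")


def _check_effects(effects: list[PlantedEffect], n_regions: int) -> None:
    for k, e in enumerate(effects):
        if e.brain_pattern.shape != (n_regions,):
            raise ValidationError(
                f"effect {k}: brain_pattern length {e.brain_pattern.shape[0]} "
                f"does not match n_regions={n_regions}"
            )
    for a in range(len(effects)):
        for b in range(a + 1, len(effects)):
            if abs(effects[a].brain_pattern @ effects[b].brain_pattern) > 1e-8:
                raise ValidationError(f"effects {a},{b}: brain patterns not orthogonal")
            if abs(effects[a].behavior_pattern @ effects[b].behavior_pattern) > 1e-8:
                raise ValidationError(
                    f"effects {a},{b}: behavior patterns not orthogonal"
                )


def random_effect(
    n_regions: int,
    strength: float,
    seed: int,
    orthogonal_to: list[PlantedEffect] | None = None,
) -> PlantedEffect:
    """Draw a random planted effect with unit-norm patterns.

    If ``orthogonal_to`` is given, the new patterns are projected off the
    existing ones (Gram-Schmidt) so that the resulting set stays orthogonal.
    """
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(n_regions)
    u = rng.standard_normal(6)
    for prev in orthogonal_to or []:
        v = v - (v @ prev.brain_pattern) * prev.brain_pattern
        u = u - (u @ prev.behavior_pattern) * prev.behavior_pattern
    return PlantedEffect(
        brain_pattern=v / np.linalg.norm(v),
        behavior_pattern=u / np.linalg.norm(u),
        strength=strength,
    )


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a phenotype table honouring the spec's composition exactly.

    Exactly ``n_carriers`` rows carry an E4 allele and exactly
    ``n_symptomatic`` rows have an MCI or AD diagnosis (the two flags are
    assigned independently). Ages are drawn from a normal distribution
    truncated to [50, 95] years. Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    carrier = np.zeros(n, dtype=bool)
    carrier[rng.choice(n, size=spec.n_carriers, replace=False)] = True
    symptomatic = np.zeros(n, dtype=bool)
    symptomatic[rng.choice(n, size=spec.n_symptomatic, replace=False)] = True

    a, b = (
        (_AGE_RANGE[0] - spec.age_mean) / spec.age_sd,
        (_AGE_RANGE[1] - spec.age_mean) / spec.age_sd,
    )
    ages = stats.truncnorm.rvs(
        a, b, loc=spec.age_mean, scale=spec.age_sd, size=n, random_state=rng
    )

    def draw(table):
        labels, probs = zip(*table)
        return rng.choice(labels, p=probs)

    genotypes = [
        draw(CARRIER_GENOTYPES if c else NONCARRIER_GENOTYPES) for c in carrier
    ]
    diagnoses = [
        draw(SYMPTOMATIC_DIAGNOSES if s else NONSYMPTOMATIC_DIAGNOSES)
        for s in symptomatic
    ]
    sex = np.where(rng.random(n) < _P_FEMALE, "F", "M")

    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "age": np.round(ages, 2),
            "sex": sex,
            "apoe_genotype": genotypes,
            "diagnosis": diagnoses,
        }
    )


def generate_feature_matrix(
    cohort: pd.DataFrame,
    effects: list[PlantedEffect],
    noise_sd: float,
    seed: int,
    baseline: np.ndarray | None = None,
    n_regions: int | None = None,
    region_ids: list | None = None,
) -> pd.DataFrame:
    """Feature-level generator: X = 1 mu^T + sum_k s_k (Y u_k) v_k^T + noise.

    Plants each effect as a rank-1 term linking the behavioral design Y
    (built from the cohort) to the regional features, then adds iid Gaussian
    noise. Useful for testing the PLSC stage in isolation, without the
    time-series and connectivity stages in between.
    """
    if n_regions is None:
        if effects:
            n_regions = effects[0].brain_pattern.shape[0]
        elif baseline is not None:
            n_regions = len(baseline)
        elif region_ids is not None:
            n_regions = len(region_ids)
        else:
            raise ValidationError(
                "n_regions is required when no effects/baseline/region_ids given"
            )
    _check_effects(effects, n_regions)
    if baseline is None:
        baseline = np.zeros(n_regions)
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != (n_regions,):
        raise ValidationError("baseline length does not match n_regions")

    Y = build_design(cohort).values
    rng = np.random.default_rng(seed)
    X = np.tile(baseline, (len(cohort), 1))
    for e in effects:
        X += e.strength * np.outer(Y @ e.behavior_pattern, e.brain_pattern)
    if noise_sd > 0:
        X += rng.normal(0.0, noise_sd, size=X.shape)
    if region_ids is None:
        region_ids = [f"region_{i:03d}" for i in range(n_regions)]
    return pd.DataFrame(X, index=list(cohort["subject_id"]), columns=region_ids)


def _subject_covariance(
    base: np.ndarray, bump: np.ndarray, alpha: float
) -> np.ndarray:
    """Target correlation for one subject: base + alpha * off-diagonal bump.

    The additive rank-1 perturbation can break positive definiteness. When
    it does, the matrix is repaired by projecting the spectrum onto the
    positive cone (eigenvalues floored at 1e-6) and rescaling back to unit
    diagonal; rescaling is a congruence transform, so the result is an
    exact positive-definite correlation matrix in one pass.
    """
    c = base + alpha * bump
    np.fill_diagonal(c, 1.0)
    c = np.clip(c, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    w, q = np.linalg.eigh(c)
    if w[0] <= 1e-8:
        c = (q * np.maximum(w, 1e-6)) @ q.T
        d = np.sqrt(np.diag(c))
        c = c / np.outer(d, d)
        c = (c + c.T) / 2.0
        np.fill_diagonal(c, 1.0)
    return c


def generate_timeseries(
    cohort: pd.DataFrame,
    effects: list[PlantedEffect],
    base_fc: FCMatrix,
    coupling: float,
    seed: int,
    n_timepoints: int = 197,
    tr: float = 3.0,
    return_covariances: bool = False,
) -> list[RegionTimeSeries]:
    """End-to-end generator: Gaussian time series with subject-specific FC.

    Each subject's target covariance is the shared ``base_fc`` plus, per
    planted effect, ``coupling * alpha_i`` times the off-diagonal part of
    ``v_k v_k^T``, where ``alpha_i = (Y u_k)_i`` is that subject's score on
    the effect's behavioral pattern. Series are zero-mean Gaussian draws
    with that covariance, so the sample FC of long series converges to it.
    """
    n_regions = base_fc.n_regions
    _check_effects(effects, n_regions)
    w = np.linalg.eigvalsh(base_fc.values)
    if w[0] < -1e-10:
        raise ValidationError("base_fc must be positive semidefinite")

    Y = build_design(cohort).values if effects else None
    bumps, alphas = [], []
    for e in effects:
        b = np.outer(e.brain_pattern, e.brain_pattern)
        np.fill_diagonal(b, 0.0)
        bumps.append(b)
        alphas.append(Y @ e.behavior_pattern)

    rng = np.random.default_rng(seed)
    out, covs = [], []
    for i, sid in enumerate(cohort["subject_id"]):
        if effects:
            bump = sum(
                coupling * a[i] * b for b, a in zip(bumps, alphas)
            )
            c = _subject_covariance(base_fc.values, bump, 1.0)
        else:
            c = base_fc.values
        covs.append(c)
        try:
            chol = np.linalg.cholesky(c)
        except np.linalg.LinAlgError:
            chol = np.linalg.cholesky(c + 1e-10 * np.eye(n_regions))
        data = chol @ rng.standard_normal((n_regions, n_timepoints))
        out.append(
            RegionTimeSeries(
                data=data, tr=tr, region_ids=list(base_fc.region_ids),
                subject_id=str(sid),
            )
        )
    if return_covariances:
        return out, covs
    return out


def write_cohort(
    cohort: pd.DataFrame,
    out_dir: str | Path,
    timeseries: list[RegionTimeSeries] | None = None,
    sidecar: dict | None = None,
) -> None:
    """Write phenotypes as CSV, optional per-subject TSV matrices, and a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(out / "cohort.csv", index=False)
    if timeseries is not None:
        for ts in timeseries:
            np.savetxt(out / f"{ts.subject_id}_ts.tsv", ts.data, delimiter="\t")
    if sidecar is not None:
        (out / "generation.json").write_text(json.dumps(sidecar, indent=2))


def spec_sidecar(spec: CohortSpec, effects: list[PlantedEffect], seed: int) -> dict:
    """JSON-serializable record of what was generated and how."""
    return {
        "spec": asdict(spec),
        "seed": seed,
        "effects": [
            {
                "strength": e.strength,
                "brain_pattern": e.brain_pattern.tolist(),
                "behavior_pattern": e.behavior_pattern.tolist(),
            }
            for e in effects
        ],
    }
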