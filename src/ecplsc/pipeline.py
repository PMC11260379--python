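"""End-to-end orchestration: config, full runs, cohort and aging-score reports.

``run_pipeline`` drives filter -> FC -> centrality -> design -> PLSC ->
scores/aging scores from a single RunConfig, writing every table, a JSON
summary, and a manifest with content hashes so runs are reproducible.
``cohort_summary`` produces the demographics-style table with
Kruskal-Wallis group comparisons; ``aging_score_report`` emits per-subject
aging scores against chronological age with per-group least-squares slopes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import io as _io
from .cohort import (
    CohortSpec,
    PlantedEffect,
    generate_cohort,
    generate_feature_matrix,
    generate_timeseries,
    random_effect,
    spec_sidecar,
)
from .connectivity import (
    DEFAULT_HIGH_HZ,
    DEFAULT_LOW_HZ,
    FCMatrix,
    build_feature_matrix,
    compute_fc,
    eigenvector_centrality,
)
from .design import build_design, encode_apoe4, encode_symptoms
from .errors import ConfigurationError, ValidationError
from .plsc import (
    DEFAULT_ALPHA,
    DEFAULT_BR_THRESHOLD,
    DEFAULT_N_BOOTSTRAP,
    DEFAULT_N_PERMUTATIONS,
    AgingScore,
    PLSCResult,
    fit_plsc,
)

logger = logging.getLogger(__name__)

_MODES = ("timeseries", "fc", "features", "simulate")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; YAML round-trippable."""

    mode: str = "simulate"
    ts_dir: str | None = None
    fc_dir: str | None = None
    features_path: str | None = None
    phenotypes_path: str | None = None
    atlas_path: str | None = None
    low_hz: float = DEFAULT_LOW_HZ
    high_hz: float = DEFAULT_HIGH_HZ
    n_permutations: int = DEFAULT_N_PERMUTATIONS
    n_bootstrap: int = DEFAULT_N_BOOTSTRAP
    br_threshold: float = DEFAULT_BR_THRESHOLD
    alpha: float = DEFAULT_ALPHA
    seed: int = 0
    output_dir: str = "ecplsc_run"
    # simulate-mode knobs
    cohort: dict = field(default_factory=dict)
    effects: list = field(default_factory=list)
    noise_sd: float = 1.0
    simulate_timeseries: bool = True
    coupling: float = 0.0

    def validate(self) -> None:
        if self.mode not in _MODES:
            raise ConfigurationError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if not (0 < self.low_hz < self.high_hz):
            raise ConfigurationError("need 0 < low_hz < high_hz")
        tr = float(self.cohort.get("tr", CohortSpec().tr))
        if self.mode in ("timeseries", "simulate") and self.high_hz >= 0.5 / tr:
            raise ConfigurationError(
                f"high_hz={self.high_hz} at or above Nyquist {0.5 / tr:.4f} Hz "
                f"for tr={tr} s"
            )
        if self.n_permutations < 1:
            raise ConfigurationError("n_permutations must be >= 1")
        if self.n_bootstrap < 2:
            raise ConfigurationError("n_bootstrap must be >= 2")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.mode != "simulate" and self.phenotypes_path is None:
            raise ConfigurationError(f"mode {self.mode!r} requires phenotypes_path")
        needs = {"timeseries": "ts_dir", "fc": "fc_dir", "features": "features_path"}
        if self.mode in needs and getattr(self, needs[self.mode]) is None:
            raise ConfigurationError(f"mode {self.mode!r} requires {needs[self.mode]}")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


def _build_effects(cfg: RunConfig, n_regions: int) -> list[PlantedEffect]:
    effects: list[PlantedEffect] = []
    for k, spec in enumerate(cfg.effects):
        if "brain_pattern" in spec and "behavior_pattern" in spec:
            effects.append(
                PlantedEffect(
                    brain_pattern=np.asarray(spec["brain_pattern"], float),
                    behavior_pattern=np.asarray(spec["behavior_pattern"], float),
                    strength=float(spec["strength"]),
                )
            )
        else:
            effects.append(
                random_effect(
                    n_regions,
                    float(spec["strength"]),
                    seed=cfg.seed * 1009 + 7 * k + 1,
                    orthogonal_to=effects,
                )
            )
    return effects


def _group_labels(cohort: pd.DataFrame) -> pd.DataFrame:
    out = cohort.copy()
    if "apoe4" not in out.columns:
        out["apoe4"] = [encode_apoe4(g) for g in out["apoe_genotype"]]
    if "symptoms" not in out.columns:
        out["symptoms"] = [encode_symptoms(d) for d in out["diagnosis"]]
    carrier = np.where(out["apoe4"] == 1, "carrier", "noncarrier")
    sympt = np.where(out["symptoms"] == 1, "symptomatic", "nonsymptomatic")
    out["group"] = [f"{c}_{s}" for c, s in zip(carrier, sympt)]
    return out


def cohort_summary(
    cohort: pd.DataFrame, extra_columns: list[str] | None = None
) -> pd.DataFrame:
    """Demographics table with Kruskal-Wallis tests across the four groups.

    For age and any extra continuous measures, reports per-group mean and
    sd for the four carrier x symptom groups plus all subjects, and the
    Kruskal-Wallis p-value across the four groups. Groups with fewer than
    2 members are skipped (warning logged); if every group's values are
    identical the test is degenerate and p is reported as 1.0 by
    convention.
    """
    labelled = _group_labels(cohort)
    variables = ["age"] + list(extra_columns or [])
    group_names = [
        "carrier_symptomatic",
        "carrier_nonsymptomatic",
        "noncarrier_symptomatic",
        "noncarrier_nonsymptomatic",
    ]
    rows = []
    for var in variables:
        if var not in labelled.columns:
            raise ValidationError(f"cohort lacks column {var!r}")
        row = {"variable": var}
        samples = []
        for g in group_names:
            vals = labelled.loc[labelled.group == g, var].to_numpy(float)
            row[f"{g}_n"] = len(vals)
            row[f"{g}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{g}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
            if len(vals) >= 2:
                samples.append(vals)
            else:
                logger.warning("group %s has < 2 members; excluded from test", g)
        allv = labelled[var].to_numpy(float)
        row["all_n"], row["all_mean"], row["all_sd"] = (
            len(allv), allv.mean(), allv.std(ddof=1),
        )
        if len(samples) >= 2:
            if np.ptp(np.concatenate(samples)) == 0:
                # all values identical across groups: no ranking information
                row["kruskal_p"] = 1.0
            else:
                try:
                    p_kw = float(stats.kruskal(*samples).pvalue)
                except ValueError:
                    p_kw = 1.0
                row["kruskal_p"] = 1.0 if np.isnan(p_kw) else p_kw
        else:
            row["kruskal_p"] = np.nan
            logger.warning("Kruskal-Wallis for %s skipped: < 2 usable groups", var)
        rows.append(row)
    return pd.DataFrame(rows)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def aging_score_report(
    scores: list[AgingScore], cohort: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject aging scores vs chronological age, with group slopes.

    Returns a long-format table (subject, component, age, aging_score,
    carrier/symptom flags) and a slopes table with one ordinary
    least-squares fit of aging_score on age per component for each of the
    four carrier x symptom subgroups and the four marginal groups.
    An empty score list yields empty tables.
    """
    labelled = _group_labels(cohort)
    long_rows, slope_rows = [], []
    groupings = {
        "carrier_x_symptom": labelled["group"],
        "carrier": labelled["apoe4"].map({1: "carrier", 0: "noncarrier"}),
        "symptom": labelled["symptoms"].map({1: "symptomatic", 0: "nonsymptomatic"}),
    }
    for sc in scores:
        comp = sc.component_index
        for i, sid in enumerate(labelled["subject_id"]):
            long_rows.append(
                {
                    "subject_id": sid,
                    "component": comp,
                    "age": labelled["age"].iloc[i],
                    "aging_score": sc.values[i],
                    "apoe4": int(labelled["apoe4"].iloc[i]),
                    "symptoms": int(labelled["symptoms"].iloc[i]),
                }
            )
        ages = labelled["age"].to_numpy(float)
        for grouping, labels in groupings.items():
            for level in sorted(labels.unique()):
                mask = (labels == level).to_numpy()
                if mask.sum() < 2 or np.ptp(ages[mask]) == 0:
                    continue
                slope, intercept = _ols_slope(ages[mask], sc.values[mask])
                slope_rows.append(
                    {
                        "component": comp,
                        "grouping": grouping,
                        "level": level,
                        "n": int(mask.sum()),
                        "slope": slope,
                        "intercept": intercept,
                    }
                )
    long_cols = ["subject_id", "component", "age", "aging_score", "apoe4", "symptoms"]
    slope_cols = ["component", "grouping", "level", "n", "slope", "intercept"]
    return (
        pd.DataFrame(long_rows, columns=long_cols),
        pd.DataFrame(slope_rows, columns=slope_cols),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_plsc_outputs(
    result: PLSCResult, out: Path, br_threshold: float, alpha: float
) -> None:
    K = result.n_components
    brain_rows = []
    for k in range(K):
        for i, region in enumerate(result.region_ids):
            brain_rows.append(
                {
                    "region": region,
                    "component": k + 1,
                    "salience": result.V[i, k],
                    "se": result.se_V[i, k],
                    "bootstrap_ratio": result.br_V[i, k],
                    "stable": bool(abs(result.br_V[i, k]) > br_threshold),
                }
            )
    pd.DataFrame(brain_rows).to_csv(out / "saliences_brain.csv", index=False)

    behav_rows = []
    from .design import DESIGN_COLUMNS

    for k in range(K):
        for j, name in enumerate(DESIGN_COLUMNS):
            behav_rows.append(
                {
                    "variable": name,
                    "component": k + 1,
                    "salience": result.U[j, k],
                    "se": result.se_U[j, k],
                    "bootstrap_ratio": result.br_U[j, k],
                    "stable": bool(abs(result.br_U[j, k]) > br_threshold),
                }
            )
    pd.DataFrame(behav_rows).to_csv(out / "saliences_behavior.csv", index=False)

    score_rows = []
    for k in range(K):
        for i, sid in enumerate(result.subject_ids):
            score_rows.append(
                {
                    "subject_id": sid,
                    "component": k + 1,
                    "Lx": result.Lx[i, k],
                    "Ly": result.Ly[i, k],
                    "aging_score": result.aging_scores[k].values[i],
                }
            )
    pd.DataFrame(score_rows).to_csv(out / "scores.csv", index=False)

    summary = {
        "singular_values": result.singular_values.tolist(),
        "p_values": result.p_values.tolist(),
        "significant_components": result.significant_components(alpha),
        "n_significant_sequential": result.n_significant(alpha),
        "config": result.config,
        "n_flagged_se_floor": int(
            (result.floored_U.sum() if result.floored_U is not None else 0)
            + (result.floored_V.sum() if result.floored_V is not None else 0)
        ),
    }
    (out / "plsc_summary.json").write_text(json.dumps(summary, indent=2))


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full run from config; returns the manifest dict.

    Stages: load or simulate inputs, (filter -> FC -> centrality if needed),
    design, PLSC with permutations and bootstrap, score and aging-score
    reports, cohort summary. All outputs land in ``config.output_dir``
    together with ``manifest.json`` (file hashes, seed, config) and
    ``run.log``.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("ecplsc")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    logger.info("run config: %s", asdict(config))

    try:
        region_ids = None
        if config.atlas_path:
            atlas = _io.read_atlas(config.atlas_path)
            region_ids = list(atlas["region_name"])

        stage = "inputs"
        if config.mode == "simulate":
            spec = CohortSpec(**{**config.cohort, "seed": config.seed})
            cohort = generate_cohort(spec)
            effects = _build_effects(config, spec.n_regions)
            if config.simulate_timeseries:
                base = FCMatrix(
                    values=np.eye(spec.n_regions),
                    region_ids=list(region_ids) if region_ids else [],
                )
                ts_list = generate_timeseries(
                    cohort, effects, base, config.coupling,
                    seed=config.seed + 1,
                    n_timepoints=spec.n_timepoints, tr=spec.tr,
                )
                stage = "connectivity"
                X = build_feature_matrix(ts_list, config.low_hz, config.high_hz)
            else:
                X = generate_feature_matrix(
                    cohort, effects, config.noise_sd, seed=config.seed + 1,
                    n_regions=spec.n_regions, region_ids=region_ids,
                )
            cohort.to_csv(out / "cohort.csv", index=False)
            (out / "generation.json").write_text(
                json.dumps(spec_sidecar(spec, effects, config.seed))
            )
        else:
            cohort = pd.read_csv(config.phenotypes_path)
            if config.mode == "timeseries":
                tr = float(config.cohort.get("tr", CohortSpec().tr))
                ts_list = _io.read_timeseries_dir(config.ts_dir, tr, region_ids)
                stage = "connectivity"
                X = build_feature_matrix(ts_list, config.low_hz, config.high_hz)
            elif config.mode == "fc":
                stage = "connectivity"
                rows, sids = [], []
                for p in sorted(Path(config.fc_dir).glob("*_fc.tsv")):
                    fc = _io.read_fc(p, region_ids)
                    rows.append(eigenvector_centrality(fc).values)
                    sids.append(p.name[: -len("_fc.tsv")])
                if not rows:
                    raise ValidationError(f"no *_fc.tsv files in {config.fc_dir}")
                X = pd.DataFrame(
                    np.vstack(rows), index=sids,
                    columns=region_ids or range(rows[0].shape[0]),
                )
            else:
                X = _io.read_feature_matrix(config.features_path)
            x_ids = [str(s) for s in X.index]
            pheno_ids = set(str(s) for s in cohort["subject_id"])
            missing = [s for s in x_ids if s not in pheno_ids]
            if missing:
                raise ValidationError(
                    f"subjects in imaging data but not phenotypes: {missing[:5]}"
                )
            cohort = (
                cohort.set_index(cohort["subject_id"].astype(str))
                .loc[x_ids]
                .reset_index(drop=True)
            )
        timings[stage] = time.perf_counter() - t0

        stage = "features"
        _io.write_feature_matrix(X, out / "features.csv")

        stage = "design"
        t1 = time.perf_counter()
        design = build_design(cohort)
        design.to_frame().to_csv(out / "design.csv", index_label="subject_id")
        timings[stage] = time.perf_counter() - t1

        stage = "plsc"
        t1 = time.perf_counter()
        result = fit_plsc(
            X, design,
            n_permutations=config.n_permutations,
            n_bootstrap=config.n_bootstrap,
            seed=config.seed,
            br_threshold=config.br_threshold,
        )
        timings[stage] = time.perf_counter() - t1

        stage = "reports"
        t1 = time.perf_counter()
        _write_plsc_outputs(result, out, config.br_threshold, config.alpha)
        cohort_summary(cohort).to_csv(out / "cohort_summary.csv", index=False)
        long_df, slopes = aging_score_report(result.aging_scores, cohort)
        long_df.to_csv(out / "aging_scores.csv", index=False)
        slopes.to_csv(out / "aging_score_slopes.csv", index=False)
        result.stable_regions(config.br_threshold).to_csv(
            out / "stable_regions.csv", index=False
        )
        timings[stage] = time.perf_counter() - t1
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        manifest = {
            "status": "failed",
            "failed_stage": stage,
            "error": str(exc),
            "config": asdict(config),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        root.removeHandler(handler)
        handler.close()
        raise

    files = sorted(
        p.name for p in out.iterdir()
        if p.is_file() and p.name not in ("manifest.json", "run.log")
    )
    manifest = {
        "status": "ok",
        "seed": config.seed,
        "config": asdict(config),
        "outputs": {name: _sha256(out / name) for name in files},
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("timings: %s", manifest["timings_s"])
    root.removeHandler(handler)
    handler.close()
    return manifest
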