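"""Partial Least Squares Correlation (PLSC) between brain features and behavior.

The method takes a subjects x regions brain feature matrix X (here,
eigenvector centralities) and a subjects x 6 behavioral design Y, forms the
cross-covariance R = Y_z^T X_z / (n - 1) (both blocks column-standardized,
so R is on a correlation scale), and decomposes it by SVD:

    R = U diag(s) V^T

U holds behavioral saliences (6 x K), V brain saliences (regions x K), and
each singular value s_k expresses the brain-behavior covariance captured by
component k. Component significance is assessed by permuting subject rows
of Y and re-running the SVD; salience stability by bootstrap resampling of
subjects with a Procrustes re-alignment of each resample's saliences onto
the original before accumulating standard errors. Latent scores are
Lx = X_z V and Ly = Y U; the aging score restricts Ly to the age-related
design columns (age, age x APOE4, age x symptoms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes

from .design import AGE_COLUMN_INDICES, AGE_COLUMNS, DESIGN_COLUMNS, BehavioralDesign
from .errors import AlignmentError, ConfigurationError, ValidationError

DEFAULT_N_PERMUTATIONS = 1000
DEFAULT_N_BOOTSTRAP = 1000
DEFAULT_BR_THRESHOLD = 2.0
DEFAULT_ALPHA = 0.05
_SE_FLOOR = 1e-12
_MAX_REDRAWS = 100


def _as_matrix(X, what="X"):
    """Accept a DataFrame or array; return (values, row_ids, col_ids)."""
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(i) for i in X.index], [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"{what} must be 2-D")
    return arr, None, None


def _design_values(Y):
    if isinstance(Y, BehavioralDesign):
        return Y.values, list(Y.subject_ids)
    arr = np.asarray(Y, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("Y must be 2-D")
    return arr, None


def _zscore_columns(X: np.ndarray, col_ids=None) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [col_ids[i] for i in bad[:5]] if col_ids else bad[:5].tolist()
        raise ValidationError(f"constant feature column(s): {names}")
    return (X - X.mean(axis=0)) / sd


def cross_covariance(X, Y, standardize_x: bool = True) -> np.ndarray:
    """Cross-covariance R = Y^T X_z / (n - 1), shape (6, n_regions).

    X columns are z-scored here (sample sd, ddof=1); Y arrives standardized
    from the design stage. With both blocks standardized, entries for the
    three main-effect rows are exactly Pearson correlations between that
    behavioral variable and each region's centrality; interaction rows are
    covariances on the product scale.
    """
    Xv, x_ids, col_ids = _as_matrix(X)
    Yv, y_ids = _design_values(Y)
    if Xv.shape[0] != Yv.shape[0]:
        raise AlignmentError(
            f"X has {Xv.shape[0]} subjects but Y has {Yv.shape[0]}"
        )
    if x_ids is not None and y_ids:
        if x_ids != [str(s) for s in y_ids]:
            raise AlignmentError("subject_ids of X and Y do not match in order")
    n = Xv.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 subjects")
    Xz = _zscore_columns(Xv, col_ids) if standardize_x else Xv
    return Yv.T @ Xz / (n - 1)


def plsc_svd(R: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD of the cross-covariance: R = U diag(s) V^T, K = min(R.shape).

    Singular values are nonincreasing. Sign convention: each component is
    flipped so the largest-|loading| entry of its brain salience (V column)
    is positive, making results reproducible across LAPACK builds.
    """
    R = np.asarray(R, dtype=float)
    if not np.all(np.isfinite(R)):
        raise ValidationError("cross-covariance contains non-finite entries")
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    for k in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            U[:, k] = -U[:, k]
            V[:, k] = -V[:, k]
    return U, s, V


def permutation_test(
    X,
    Y,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | np.random.Generator = 0,
    standardize_x: bool = True,
    scheme: str = "deflate",
) -> np.ndarray:
    """Permutation p-values for the singular values.

    Rows of Y are permuted relative to X and the cross-covariance SVD is
    recomputed per permutation. The add-one estimator
    p_k = (#{s*_k >= s_k} + 1) / (n_permutations + 1) never returns exactly
    zero; its floor is 1/(n_permutations + 1).

    Two reference schemes are available; both give identical p-values for
    component 1.

    ``scheme="deflate"`` (default) tests component k against permuted
    matrices projected off the observed leading k-1 singular subspaces on
    both sides. The observed statistic is unchanged (the projection leaves
    s_k intact), but the permuted reference now measures the largest
    remaining singular value in the same orthogonal complement, which keeps
    components beyond the true rank calibrated.

    ``scheme="simple"`` compares each permuted singular value with the
    observed one of the same rank. This is the most literal reading of
    permutation testing on singular values, but it is anti-conservative
    past the true rank: when strong components exist, the observed rank-k
    value is the *maximum* noise singular value in their complement while
    the permuted reference is only the k-th order statistic of a null
    spectrum.
    """
    if n_permutations < 1:
        raise ConfigurationError("n_permutations must be at least 1")
    if scheme not in ("deflate", "simple"):
        raise ConfigurationError(f"unknown permutation scheme {scheme!r}")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    Xv, _, col_ids = _as_matrix(X)
    Yv, _ = _design_values(Y)
    Xz = _zscore_columns(Xv, col_ids) if standardize_x else Xv
    n = Xv.shape[0]
    R = Yv.T @ Xz / (n - 1)
    U_obs, s_obs, V_obs = plsc_svd(R)
    K = len(s_obs)
    exceed = np.zeros(K)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        Rp = Yv[perm].T @ Xz / (n - 1)
        if scheme == "simple":
            exceed += np.linalg.svd(Rp, compute_uv=False) >= s_obs
        else:
            Rk = Rp
            for k in range(K):
                if k > 0:
                    # project off the observed rank-(k-1) subspaces
                    u, v = U_obs[:, k - 1 : k], V_obs[:, k - 1 : k]
                    Rk = Rk - u @ (u.T @ Rk)
                    Rk = Rk - (Rk @ v) @ v.T
                top = np.linalg.svd(Rk, compute_uv=False)[0]
                exceed[k] += top >= s_obs[k]
    return (exceed + 1.0) / (n_permutations + 1.0)


def bootstrap_stability(
    X,
    Y,
    n_bootstrap: int = DEFAULT_N_BOOTSTRAP,
    seed: int | np.random.Generator = 0,
    standardize_x: bool = True,
):
    """Bootstrap standard errors and ratios for the saliences.

    Subjects are resampled with replacement and the PLSC refit per resample
    (X re-standardized within the resample). Each resample's (U*, V*) is
    aligned to the original (U, V) by a single orthogonal Procrustes
    rotation of the stacked saliences — without it, sign and component-order
    flips across resamples would corrupt the standard errors. The bootstrap
    ratio is the original salience divided by its bootstrap SE; SEs are
    floored at 1e-12 and floored elements flagged.

    Returns
    -------
    dict with keys ``se_U``, ``se_V``, ``br_U``, ``br_V``,
    ``floored_U``, ``floored_V`` (boolean masks where the floor engaged).
    """
    if n_bootstrap < 2:
        raise ConfigurationError("n_bootstrap must be at least 2")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    Xv, _, col_ids = _as_matrix(X)
    Yv, _ = _design_values(Y)
    n = Xv.shape[0]
    U0, _, V0 = plsc_svd(cross_covariance(Xv, Yv, standardize_x))
    M0 = np.vstack([U0, V0])

    U_stack = np.empty((n_bootstrap,) + U0.shape)
    V_stack = np.empty((n_bootstrap,) + V0.shape)
    for b in range(n_bootstrap):
        for attempt in range(_MAX_REDRAWS + 1):
            idx = rng.integers(0, n, size=n)
            Yb = Yv[idx]
            # a resample can make a design column constant (e.g. all carriers)
            if Yb.std(axis=0).min() > 0 and Xv[idx].std(axis=0).min() > 0:
                break
        else:
            raise ValidationError(
                f"bootstrap resample {b}: constant column persisted after "
                f"{_MAX_REDRAWS} redraws"
            )
        Rb = cross_covariance(Xv[idx], Yb, standardize_x)
        Ub, _, Vb = plsc_svd(Rb)
        rot, _ = orthogonal_procrustes(np.vstack([Ub, Vb]), M0)
        U_stack[b] = Ub @ rot
        V_stack[b] = Vb @ rot

    se_U = U_stack.std(axis=0, ddof=1)
    se_V = V_stack.std(axis=0, ddof=1)
    floored_U = se_U < _SE_FLOOR
    floored_V = se_V < _SE_FLOOR
    se_U = np.maximum(se_U, _SE_FLOOR)
    se_V = np.maximum(se_V, _SE_FLOOR)
    return {
        "se_U": se_U,
        "se_V": se_V,
        "br_U": U0 / se_U,
        "br_V": V0 / se_V,
        "floored_U": floored_U,
        "floored_V": floored_V,
    }


def threshold_saliences(
    bootstrap_ratios_V: np.ndarray,
    br_threshold: float = DEFAULT_BR_THRESHOLD,
    region_ids: list | None = None,
    saliences_V: np.ndarray | None = None,
) -> pd.DataFrame:
    """Regions whose |bootstrap ratio| strictly exceeds the threshold.

    |BR| > 2 corresponds approximately to a 95% confidence interval
    excluding zero under a normal approximation. The inequality is strict:
    BR = +2.0 exactly is excluded. The sign of the retained BR says whether
    the region's centrality increases (+) or decreases (-) with the
    component.
    """
    br = np.asarray(bootstrap_ratios_V, dtype=float)
    if br.ndim == 1:
        br = br.reshape(-1, 1)
    n_regions, n_comp = br.shape
    if region_ids is None:
        region_ids = [f"region_{i:03d}" for i in range(n_regions)]
    rows = []
    for k in range(n_comp):
        keep = np.flatnonzero(np.abs(br[:, k]) > br_threshold)
        for i in keep:
            rows.append(
                {
                    "region": region_ids[i],
                    "component": k + 1,
                    "bootstrap_ratio": br[i, k],
                    "sign": "+" if br[i, k] > 0 else "-",
                    "salience": (
                        saliences_V[i, k] if saliences_V is not None else np.nan
                    ),
                }
            )
    return pd.DataFrame(
        rows, columns=["region", "component", "bootstrap_ratio", "sign", "salience"]
    )


def compute_scores(X, Y, U: np.ndarray, V: np.ndarray, standardize_x: bool = True):
    """Latent scores Lx = X_z V (brain) and Ly = Y U (behavior)."""
    Xv, _, col_ids = _as_matrix(X)
    Yv, _ = _design_values(Y)
    Xz = _zscore_columns(Xv, col_ids) if standardize_x else Xv
    return Xz @ V, Yv @ U


@dataclass
class AgingScore:
    """Per-subject age-specific behavior score for one PLS component.

    values_i = sum over c in {age, age x APOE4, age x symptoms} of
    Y[i, c] * U[c, component]: the behavior score Ly restricted to the
    age-related design columns, quantifying how strongly each subject
    expresses the component's age effect.
    """

    values: np.ndarray
    component_index: int
    age_columns: tuple = AGE_COLUMNS


def aging_score(Y, U: np.ndarray, component: int) -> AgingScore:
    """Aging score Ly^age = Y^age U^age for one component (1-based index)."""
    Yv, _ = _design_values(Y)
    if Yv.shape[1] != 6:
        raise ValidationError(
            f"design must have the 6 standard columns {DESIGN_COLUMNS}, "
            f"got {Yv.shape[1]}"
        )
    K = U.shape[1]
    if not 1 <= component <= K:
        raise ConfigurationError(f"component must be in [1, {K}]")
    idx = list(AGE_COLUMN_INDICES)
    vals = Yv[:, idx] @ U[idx, component - 1]
    return AgingScore(values=vals, component_index=component)


@dataclass
class PLSCResult:
    """Full output of one PLSC fit.

    Saliences U (behavior, 6 x K) and V (brain, regions x K) are orthonormal
    column sets; ``singular_values`` are nonincreasing. ``p_values`` come
    from the permutation test, the ``se_*``/``br_*`` blocks from the
    bootstrap, ``Lx``/``Ly`` are the latent scores, and ``aging_scores``
    holds one AgingScore per component.
    """

    singular_values: np.ndarray
    U: np.ndarray
    V: np.ndarray
    p_values: np.ndarray
    se_U: np.ndarray
    se_V: np.ndarray
    br_U: np.ndarray
    br_V: np.ndarray
    Lx: np.ndarray
    Ly: np.ndarray
    aging_scores: list
    region_ids: list
    subject_ids: list
    config: dict = field(default_factory=dict)
    floored_U: np.ndarray | None = None
    floored_V: np.ndarray | None = None

    def __post_init__(self):
        K = len(self.singular_values)
        if np.any(np.diff(self.singular_values) > 1e-12):
            raise ValidationError("singular values must be nonincreasing")
        if np.any(self.singular_values < -1e-12):
            raise ValidationError("singular values must be nonnegative")
        for name, M in (("U", self.U), ("V", self.V)):
            gram = M.T @ M
            if np.abs(gram - np.eye(K)).max() > 1e-8:
                raise ValidationError(f"{name} columns are not orthonormal")
        if np.any(self.p_values <= 0) or np.any(self.p_values > 1):
            raise ValidationError("p-values must lie in (0, 1]")

    @property
    def n_components(self) -> int:
        return len(self.singular_values)

    def significant_components(self, alpha: float = DEFAULT_ALPHA) -> list[int]:
        """1-based indices of components with p < alpha."""
        return [k + 1 for k in range(self.n_components) if self.p_values[k] < alpha]

    def n_significant(
        self, alpha: float = DEFAULT_ALPHA, rule: str = "sequential"
    ) -> int:
        """Number of significant components.

        ``rule="sequential"`` (default) stops at the first rank whose
        p-value reaches alpha — the usual counting rule for nested rank
        tests, where testing rank k presupposes rank >= k. ``rule="marginal"``
        simply counts p < alpha at any rank.
        """
        if rule == "marginal":
            return int((self.p_values < alpha).sum())
        if rule != "sequential":
            raise ConfigurationError(f"unknown counting rule {rule!r}")
        n = 0
        for p in self.p_values:
            if p >= alpha:
                break
            n += 1
        return n

    def stable_regions(self, br_threshold: float = DEFAULT_BR_THRESHOLD) -> pd.DataFrame:
        return threshold_saliences(
            self.br_V, br_threshold, region_ids=self.region_ids, saliences_V=self.V
        )


def fit_plsc(
    X,
    Y,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    n_bootstrap: int = DEFAULT_N_BOOTSTRAP,
    seed: int = 0,
    br_threshold: float = DEFAULT_BR_THRESHOLD,
    standardize_x: bool = True,
    permutation_scheme: str = "deflate",
) -> PLSCResult:
    """Run the full PLSC analysis: SVD, permutations, bootstrap, scores.

    One master seed spawns independent child streams for the permutation
    and bootstrap stages, so changing ``n_bootstrap`` never changes the
    permutation results (and vice versa).
    """
    Xv, x_ids, col_ids = _as_matrix(X)
    Yv, y_ids = _design_values(Y)
    R = cross_covariance(X, Y, standardize_x)
    U, s, V = plsc_svd(R)
    perm_ss, boot_ss = np.random.SeedSequence(seed).spawn(2)
    p = permutation_test(
        Xv, Yv, n_permutations, np.random.default_rng(perm_ss), standardize_x,
        scheme=permutation_scheme,
    )
    boot = bootstrap_stability(
        Xv, Yv, n_bootstrap, np.random.default_rng(boot_ss), standardize_x
    )
    Lx, Ly = compute_scores(Xv, Yv, U, V, standardize_x)
    ages = [aging_score(Yv, U, k + 1) for k in range(len(s))]
    if col_ids is None:
        col_ids = [f"region_{i:03d}" for i in range(Xv.shape[1])]
    if x_ids is None:
        x_ids = y_ids or [f"sub-{i:04d}" for i in range(Xv.shape[0])]
    return PLSCResult(
        singular_values=s,
        U=U,
        V=V,
        p_values=p,
        se_U=boot["se_U"],
        se_V=boot["se_V"],
        br_U=boot["br_U"],
        br_V=boot["br_V"],
        Lx=Lx,
        Ly=Ly,
        aging_scores=ages,
        region_ids=col_ids,
        subject_ids=list(x_ids),
        config={
            "n_permutations": n_permutations,
            "n_bootstrap": n_bootstrap,
            "seed": seed,
            "br_threshold": br_threshold,
            "standardize_x": standardize_x,
            "permutation_scheme": permutation_scheme,
        },
        floored_U=boot["floored_U"],
        floored_V=boot["floored_V"],
    )
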