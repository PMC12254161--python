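"""Best-subset linear discriminant analysis scored by leave-one-out CV.

The exposure condition is the group variable; regressors are the twelve
biomarkers, the nine behavioural-class proportions, or their union. For each
candidate subset an equal-priors LDA is fitted — group means plus the pooled
within-group covariance ``S = W / (N - G)`` — and an observation is assigned
to the group of minimal squared Mahalanobis distance
``(x - m_g)^T S^{-1} (x - m_g)``. Subsets are ranked by the leave-one-out
cross-validated misclassification rate; subsets whose pooled covariance is
numerically singular are recorded and skipped.

LOOCV uses an exact rank-one downdate of the pooled scatter (removing
observation x from group g shrinks W by ``n_g/(n_g-1) (x - m_g)(x - m_g)^T``
and shifts only that group's mean), which is algebraically identical to
refitting every fold from scratch.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "LDAModel",
    "SubsetModelResult",
    "SingularSubsetError",
    "fit_lda",
    "predict",
    "loocv_error",
    "best_subsets_exhaustive",
    "best_subsets_fixed_size",
    "collect_perfect_models",
]

#: Condition-number guard: a pooled covariance whose 2-norm condition
#: estimate exceeds this is treated as singular and the subset skipped.
CONDITION_LIMIT = 1e10


class SingularSubsetError(np.linalg.LinAlgError):
    """Raised when a subset's pooled within-group covariance is singular."""


@dataclass
class FeatureTable:
    """Replicate-level feature table: one row per observation.

    ``groups`` holds the condition label of each observation; ``X`` the named
    regressor columns; ``provenance`` tags each column as 'biomarker' or
    'behaviour' (used when reporting model composition).
    """

    X: pd.DataFrame
    groups: pd.Series
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.X) != len(self.groups):
            raise ValueError("X and groups must align")
        if self.X.columns.duplicated().any():
            raise ValueError("regressor names must be unique")
        if self.X.isna().any().any():
            raise ValueError("missing values in regressors")
        counts = self.groups.value_counts()
        if (counts < 2).any():
            raise ValueError("every group needs at least 2 observations")

    @property
    def n_obs(self) -> int:
        return len(self.X)

    @property
    def group_labels(self) -> list:
        return sorted(self.groups.unique())

    @property
    def n_groups(self) -> int:
        return self.groups.nunique()

    @property
    def rank_bound(self) -> int:
        """Maximal usable subset size, N - G (pooled-covariance d.f.)."""
        return self.n_obs - self.n_groups


@dataclass
class LDAModel:
    """Equal-priors LDA: group means + pooled within-group covariance."""

    subset: tuple[str, ...]
    group_labels: list
    group_means: np.ndarray      # (G, p)
    pooled_cov: np.ndarray       # (p, p), W / (N - G)
    pooled_cov_inv: np.ndarray
    n_per_group: np.ndarray


def _group_stats(X: np.ndarray, g_idx: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Group means and pooled within-group scatter W."""
    p = X.shape[1]
    means = np.empty((len(g_idx), p))
    W = np.zeros((p, p))
    for gi, ix in enumerate(g_idx):
        xg = X[ix]
        means[gi] = xg.mean(axis=0)
        d = xg - means[gi]
        W += d.T @ d
    return means, W


def _safe_inverse(S: np.ndarray) -> np.ndarray:
    if not np.all(np.isfinite(S)):
        raise SingularSubsetError("non-finite pooled covariance")
    if np.linalg.cond(S) > CONDITION_LIMIT:
        raise SingularSubsetError("pooled covariance numerically singular")
    return np.linalg.inv(S)


def fit_lda(table: FeatureTable, subset: tuple[str, ...]) -> LDAModel:
    """Fit equal-priors LDA on the named regressor subset.

    Raises :class:`SingularSubsetError` if the pooled covariance is singular
    or its condition estimate exceeds the guard; ``ValueError`` if the subset
    exceeds the pooled-covariance rank bound N - G.
    """
    subset = tuple(subset)
    missing = [c for c in subset if c not in table.X.columns]
    if missing:
        raise ValueError(f"subset columns not in table: {missing}")
    if len(subset) > table.rank_bound:
        raise ValueError(
            f"subset size {len(subset)} exceeds pooled-covariance rank bound "
            f"N - G = {table.rank_bound}"
        )
    X = table.X[list(subset)].to_numpy(dtype=float)
    labels = table.group_labels
    g_idx = [np.flatnonzero((table.groups == g).to_numpy()) for g in labels]
    means, W = _group_stats(X, g_idx)
    S = W / (table.n_obs - len(labels))
    S_inv = _safe_inverse(S)
    return LDAModel(
        subset=subset,
        group_labels=labels,
        group_means=means,
        pooled_cov=S,
        pooled_cov_inv=S_inv,
        n_per_group=np.array([len(ix) for ix in g_idx]),
    )


def _classify(X: np.ndarray, means: np.ndarray, S_inv: np.ndarray) -> np.ndarray:
    """Group index of minimal squared Mahalanobis distance (ties -> lowest)."""
    d = X[:, None, :] - means[None, :, :]
    d2 = np.einsum("ngp,pq,ngq->ng", d, S_inv, d)
    return np.argmin(d2, axis=1)


def predict(model: LDAModel, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Classify observations by the fitted rule; returns group labels."""
    if isinstance(X, pd.DataFrame):
        X = X[list(model.subset)].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    idx = _classify(X, model.group_means, model.pooled_cov_inv)
    return np.asarray(model.group_labels, dtype=object)[idx]


def loocv_error(table: FeatureTable, subset: tuple[str, ...]) -> tuple[float, np.ndarray]:
    """Leave-one-out misclassification rate of the subset's LDA rule.

    For every observation the group means and pooled covariance are
    recomputed without it (exact downdate) and the held-out point classified.
    Returns ``(error_fraction, predicted_labels)``. Deterministic; distance
    ties break to the lowest group label. Raises
    :class:`SingularSubsetError` if any fold is unfittable.
    """
    subset = tuple(subset)
    X = table.X[list(subset)].to_numpy(dtype=float)
    labels = table.group_labels
    g_of = {g: gi for gi, g in enumerate(labels)}
    y = np.array([g_of[g] for g in table.groups], dtype=int)
    g_idx = [np.flatnonzero(y == gi) for gi in range(len(labels))]
    means, W = _group_stats(X, g_idx)
    N, G = len(X), len(labels)
    n_g = np.array([len(ix) for ix in g_idx], dtype=float)

    pred = np.empty(N, dtype=int)
    for i in range(N):
        gi = y[i]
        x = X[i]
        d = x - means[gi]
        W_i = W - (n_g[gi] / (n_g[gi] - 1.0)) * np.outer(d, d)
        means_i = means.copy()
        means_i[gi] = (n_g[gi] * means[gi] - x) / (n_g[gi] - 1.0)
        S_i = W_i / (N - 1 - G)
        S_inv = _safe_inverse(S_i)
        pred[i] = _classify(x[None, :], means_i, S_inv)[0]
    err = float(np.mean(pred != y))
    return err, np.asarray(labels, dtype=object)[pred]


@dataclass
class SubsetModelResult:
    """One candidate predictor subset and its scores."""

    subset: tuple[str, ...]
    loocv_error: float | None
    n_effects: int
    fitted: LDAModel | None
    status: str                      # 'ok' | 'singular-skipped'
    resubstitution_error: float | None = None
    provenance: dict[str, int] = field(default_factory=dict)

    @property
    def loocv_accuracy(self) -> float | None:
        return None if self.loocv_error is None else 100.0 * (1.0 - self.loocv_error)


def _evaluate_subset(table: FeatureTable, subset: tuple[str, ...]) -> SubsetModelResult:
    prov: dict[str, int] = {}
    for c in subset:
        tag = table.provenance.get(c, "unknown")
        prov[tag] = prov.get(tag, 0) + 1
    try:
        model = fit_lda(table, subset)
        err, _ = loocv_error(table, subset)
    except SingularSubsetError:
        return SubsetModelResult(
            subset=subset, loocv_error=None, n_effects=len(subset),
            fitted=None, status="singular-skipped", provenance=prov,
        )
    resub = float(np.mean(predict(model, table.X) != table.groups.to_numpy()))
    return SubsetModelResult(
        subset=subset, loocv_error=err, n_effects=len(subset),
        fitted=model, status="ok", resubstitution_error=resub, provenance=prov,
    )


def _rank_key(r: SubsetModelResult):
    err = r.loocv_error if r.loocv_error is not None else math.inf
    return (err, r.n_effects, r.subset)


def best_subsets_exhaustive(
    table: FeatureTable, pool: tuple[str, ...]
) -> list[SubsetModelResult]:
    """Evaluate every non-empty subset of the pool by LOOCV error.

    Subsets larger than the rank bound N - G are not generated. Results are
    ranked by error ascending, then size, then lexicographic subset;
    singular-skipped subsets sort last. Pools above 20 regressors are
    refused (use fixed-size searches).
    """
    pool = tuple(pool)
    if len(pool) > 20:
        raise ValueError(
            f"pool of {len(pool)} regressors gives 2^{len(pool)}-1 subsets; "
            "use best_subsets_fixed_size for selected sizes instead"
        )
    kmax = min(len(pool), table.rank_bound)
    results = [
        _evaluate_subset(table, subset)
        for k in range(1, kmax + 1)
        for subset in itertools.combinations(pool, k)
    ]
    return sorted(results, key=_rank_key)


def best_subsets_fixed_size(
    table: FeatureTable, pool: tuple[str, ...], k: int
) -> list[SubsetModelResult]:
    """Evaluate all C(|pool|, k) subsets of exactly k regressors."""
    pool = tuple(pool)
    kmax = min(len(pool), table.rank_bound)
    if not 1 <= k <= kmax:
        raise ValueError(
            f"k = {k} out of range [1, {kmax}]: subsets larger than N - G = "
            f"{table.rank_bound} make the pooled within-group covariance rank deficient"
        )
    results = [_evaluate_subset(table, s) for s in itertools.combinations(pool, k)]
    return sorted(results, key=_rank_key)


def collect_perfect_models(
    results: list[SubsetModelResult] | list[list[SubsetModelResult]],
) -> list[SubsetModelResult]:
    """All evaluated models with zero LOOCV error, de-duplicated by subset."""
    flat: list[SubsetModelResult] = []
    for r in results:
        flat.extend(r if isinstance(r, list) else [r])
    seen = set()
    perfect = []
    for r in sorted(flat, key=_rank_key):
        if r.status == "ok" and r.loocv_error == 0.0:
            key = frozenset(r.subset)
            if key not in seen:
                seen.add(key)
                perfect.append(r)
    return perfect
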