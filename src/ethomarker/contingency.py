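"""Condition x behavioural-class frequency profiling.

Pools the per-frame class labels of all fish into a condition x class
contingency table, tests independence by chi-square, screens the per-cell
chi-square contributions (partial chi-square, equal to the squared Pearson
residual) against a Bonferroni-corrected chi-square(1) critical value, and
decomposes the association by correspondence analysis (SVD of the
standardized residual matrix, total inertia = chi-square / n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "build_profile",
    "chi_square_independence",
    "correspondence_analysis",
    "residual_report",
    "ChiSquareResult",
    "CAResult",
]


@dataclass
class ChiSquareResult:
    """Chi-square independence test with cell-wise residual screening."""

    statistic: float
    df: int
    p: float
    observed: pd.DataFrame
    expected: pd.DataFrame
    pearson_residuals: pd.DataFrame   # (O - E) / sqrt(E)
    partial_chisq: pd.DataFrame       # (O - E)^2 / E
    significant: pd.DataFrame         # partial chi2 >= Bonferroni chi2_1 critical value
    alpha: float
    bonferroni_critical: float


@dataclass
class CAResult:
    """Correspondence analysis of a contingency table."""

    row_masses: pd.Series
    col_masses: pd.Series
    principal_inertias: np.ndarray
    total_inertia: float
    inertia_proportions: np.ndarray
    row_coordinates: pd.DataFrame
    col_coordinates: pd.DataFrame


def build_profile(
    labels_by_fish: dict[str, np.ndarray],
    condition_map: pd.DataFrame,
    level: str = "condition",
    class_names: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Build class-frequency profiles from per-fish frame labels.

    ``level='condition'`` pools fish within condition and returns the
    condition x class table of frame counts (rows ordered by concentration,
    columns in canonical class order). ``level='fish'`` returns each fish's
    9-vector of class *proportions* (rows sum to 1) — the behavioural
    regressors of the discriminant analysis. Fish with zero labelled frames
    are excluded with a warning.
    """
    cmap = condition_map.set_index("fish_id")["condition"]
    if class_names is None:
        all_labels = sorted({l for v in labels_by_fish.values() for l in v})
        class_names = tuple(all_labels)
    counts = {}
    for fish_id, labels in labels_by_fish.items():
        labels = np.asarray(labels, dtype=object)
        if len(labels) == 0:
            warnings.warn(f"fish {fish_id!r} has no valid labelled frames; excluded")
            continue
        if fish_id not in cmap.index:
            raise ValueError(f"fish {fish_id!r} missing from condition map")
        vc = pd.Series(labels).value_counts()
        counts[fish_id] = [int(vc.get(c, 0)) for c in class_names]
    if not counts:
        raise ValueError("no fish with labelled frames")
    per_fish = pd.DataFrame.from_dict(counts, orient="index", columns=list(class_names))
    per_fish.index.name = "fish_id"

    if level == "fish":
        props = per_fish.div(per_fish.sum(axis=1), axis=0)
        props.insert(0, "condition", cmap.loc[props.index].to_numpy())
        return props.sort_values("condition", kind="stable")
    if level == "condition":
        table = per_fish.groupby(cmap.loc[per_fish.index].to_numpy()).sum()
        table.index.name = "condition"
        return table.sort_index()
    raise ValueError(f"level must be 'fish' or 'condition', got {level!r}")


def chi_square_independence(table: pd.DataFrame, alpha: float = 0.05) -> ChiSquareResult:
    """Pearson chi-square test of independence with Bonferroni cell screening.

    Per-cell significance compares the cell's partial chi-square
    ``(O - E)^2 / E`` against the ``1 - alpha / (R * C)`` quantile of the
    chi-square distribution with 1 d.f.; the direction of a flagged deviation
    is the sign of the Pearson residual.
    """
    O = table.to_numpy(dtype=float)
    if np.any(O < 0):
        raise ValueError("counts must be non-negative")
    if np.any(O.sum(axis=1) == 0) or np.any(O.sum(axis=0) == 0):
        raise ValueError("contingency table has a zero row or column margin")
    statistic, p, df, E = stats.chi2_contingency(O, correction=False)
    resid = (O - E) / np.sqrt(E)
    partial = resid**2
    R, C = O.shape
    crit = float(stats.chi2.ppf(1.0 - alpha / (R * C), df=1))
    wrap = lambda a: pd.DataFrame(a, index=table.index, columns=table.columns)
    return ChiSquareResult(
        statistic=float(statistic),
        df=int(df),
        p=float(p),
        observed=wrap(O),
        expected=wrap(E),
        pearson_residuals=wrap(resid),
        partial_chisq=wrap(partial),
        significant=wrap(partial >= crit),
        alpha=alpha,
        bonferroni_critical=crit,
    )


def correspondence_analysis(table: pd.DataFrame, tol: float = 1e-12) -> CAResult:
    """Simple correspondence analysis of a two-way table of counts.

    With correspondence matrix ``P = counts / n`` and margins ``r``, ``c``,
    the standardized residual matrix ``S = Dr^{-1/2} (P - r c^T) Dc^{-1/2}``
    is decomposed by SVD; the squared singular values are the principal
    inertias (summing to chi-square / n) and the mass-scaled singular vectors
    times the singular values give principal coordinates.
    """
    X = table.to_numpy(dtype=float)
    n = X.sum()
    if n <= 0 or np.any(X.sum(axis=1) <= 0) or np.any(X.sum(axis=0) <= 0):
        raise ValueError("table must have positive margins")
    P = X / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    max_dims = min(X.shape) - 1
    keep = s > tol * max(s[0], 1.0) if len(s) else np.array([], dtype=bool)
    s = s[keep][:max_dims]
    U = U[:, keep][:, :max_dims]
    V = Vt[keep, :].T[:, :max_dims]
    inertias = s**2
    total = float(inertias.sum())
    props = inertias / total if total > 0 else np.zeros_like(inertias)
    dims = [f"dim{i + 1}" for i in range(len(s))]
    row_coords = pd.DataFrame(
        (U / np.sqrt(r)[:, None]) * s, index=table.index, columns=dims
    )
    col_coords = pd.DataFrame(
        (V / np.sqrt(c)[:, None]) * s, index=table.columns, columns=dims
    )
    return CAResult(
        row_masses=pd.Series(r, index=table.index),
        col_masses=pd.Series(c, index=table.columns),
        principal_inertias=inertias,
        total_inertia=total,
        inertia_proportions=props,
        row_coordinates=row_coords,
        col_coordinates=col_coords,
    )


def residual_report(result: ChiSquareResult) -> pd.DataFrame:
    """Tidy per-cell residual table: one row per (condition, class).

    Columns: observed and expected counts, Pearson residual (positive =
    over-represented), partial chi-square and the Bonferroni significance
    flag; ordered by condition then class.
    """
    rows = []
    for cond in result.observed.index:
        for cls in result.observed.columns:
            rows.append(
                {
                    "condition": cond,
                    "class": cls,
                    "observed": result.observed.loc[cond, cls],
                    "expected": result.expected.loc[cond, cls],
                    "pearson_residual": result.pearson_residuals.loc[cond, cls],
                    "partial_chisq": result.partial_chisq.loc[cond, cls],
                    "significant": bool(result.significant.loc[cond, cls]),
                }
            )
    return pd.DataFrame(rows)
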