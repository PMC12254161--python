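"""Integrative dose-response index based on squared Mahalanobis distances.

For each zero-error candidate discriminant model, every observation is
scored by its squared Mahalanobis distance to the control-group centroid,
using the model's pooled within-group covariance on the candidate's
regressors. The resulting per-replicate index is an integrated measure of
how far an exposed fish's joint behaviour-biomarker state sits from the
unexposed state. The index is then tested by one-way ANOVA across
conditions and by Dunnett many-to-one comparisons — once against the
control and once against the peak condition — and the shape of the
concentration-index relationship is classified as monotone, plateau, or
non-monotone. The final model is the significant candidate with the most
monotone dose-response.

Dunnett familywise inference draws from the exact joint distribution of the
G-1 correlated t contrasts (seeded Monte-Carlo of max|T|), so the adjusted
p-values control the familywise error without tabulated critical values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .discriminant import FeatureTable, LDAModel, SubsetModelResult, fit_lda

__all__ = [
    "mahalanobis_index",
    "anova_on_index",
    "dunnett_test",
    "classify_dose_response",
    "select_final_model",
    "AnovaResult",
    "DunnettResult",
    "DoseResponseVerdict",
    "ModelSelection",
]


def mahalanobis_index(
    model: LDAModel,
    table: FeatureTable,
    subset: tuple[str, ...] | None = None,
    control: float | str | None = None,
) -> pd.DataFrame:
    """Squared Mahalanobis distance of every observation to the control centroid.

    ``D2_i = (x_i - m_ctl)^T S^{-1} (x_i - m_ctl)`` on the model's regressors,
    with ``S`` the pooled within-group covariance of the full fit. All
    observations are scored, controls included. ``control`` defaults to the
    lowest group label (the 0 µg/L condition).
    """
    subset = tuple(subset) if subset is not None else model.subset
    if subset != model.subset:
        raise ValueError("subset must match the fitted model's regressors")
    labels = model.group_labels
    if control is None:
        control = labels[0]
    if control not in labels:
        raise ValueError(f"control group {control!r} not among groups {labels}")
    m_ctl = model.group_means[labels.index(control)]
    X = table.X[list(subset)].to_numpy(dtype=float)
    d = X - m_ctl
    d2 = np.einsum("ip,pq,iq->i", d, model.pooled_cov_inv, d)
    return pd.DataFrame(
        {
            "observation": np.arange(len(X)),
            "condition": table.groups.to_numpy(),
            "d2": d2,
        }
    )


@dataclass
class AnovaResult:
    F: float
    df: tuple[int, int]
    p: float
    note: str = ""


def anova_on_index(index: pd.DataFrame) -> AnovaResult:
    """One-way fixed-effects ANOVA of the index across conditions."""
    groups = [g["d2"].to_numpy() for _, g in index.groupby("condition")]
    G = len(groups)
    N = len(index)
    if G < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if all(np.ptp(g) == 0 for g in groups) and np.ptp(index["d2"].to_numpy()) == 0:
        return AnovaResult(F=np.nan, df=(G - 1, N - G), p=np.nan,
                           note="all values identical; F undefined (no effect)")
    with np.errstate(invalid="ignore", divide="ignore"):
        F, p = stats.f_oneway(*groups)
    return AnovaResult(F=float(F), df=(G - 1, N - G), p=float(p))


@dataclass
class DunnettResult:
    """Many-to-one comparisons of group means against a reference group."""

    reference: object
    comparisons: pd.DataFrame   # group, mean_diff, t, p_adjusted, significant
    mse: float
    df_error: int
    critical_value: float
    alpha: float
    mc_draws: int
    seed: int


def _dunnett_max_abs_t(
    n_per_group: np.ndarray, ref_index: int, df_error: int,
    mc_draws: int, rng: np.random.Generator, chunk: int = 500_000,
) -> np.ndarray:
    """Monte-Carlo sample of max_i |T_i| for the Dunnett contrast family."""
    G = len(n_per_group)
    others = [i for i in range(G) if i != ref_index]
    inv_n = 1.0 / n_per_group
    se = np.sqrt(inv_n[others] + inv_n[ref_index])
    out = np.empty(mc_draws)
    done = 0
    while done < mc_draws:
        m = min(chunk, mc_draws - done)
        Z = rng.standard_normal((m, G)) * np.sqrt(inv_n)
        s = np.sqrt(rng.chisquare(df_error, size=m) / df_error)
        T = (Z[:, others] - Z[:, [ref_index]]) / (s[:, None] * se[None, :])
        out[done:done + m] = np.abs(T).max(axis=1)
        done += m
    return out


def dunnett_test(
    index: pd.DataFrame,
    reference,
    alpha: float = 0.05,
    mc_draws: int = 200_000,
    seed: int = 0,
    value_col: str = "d2",
) -> DunnettResult:
    """Two-sided Dunnett test of every group against the reference group.

    ``t_i = (mean_i - mean_ref) / sqrt(MSE (1/n_i + 1/n_ref))`` with the
    pooled error variance; the familywise adjusted p-value of each contrast
    is ``P(max_j |T_j| >= |t_i|)`` under the joint null, evaluated by seeded
    Monte-Carlo. Adjusted p-values are floored at the unadjusted two-sided
    t-test p-value (they can never be smaller).
    """
    by_group = {g: v[value_col].to_numpy() for g, v in index.groupby("condition")}
    labels = sorted(by_group)
    if reference not in by_group:
        raise ValueError(f"reference group {reference!r} not present")
    if len(labels) < 2:
        raise ValueError("need at least one non-reference group")
    n = np.array([len(by_group[g]) for g in labels], dtype=float)
    means = np.array([by_group[g].mean() for g in labels])
    N, G = int(n.sum()), len(labels)
    df_error = N - G
    if df_error < 1:
        raise ValueError("no error degrees of freedom")
    sse = sum(((by_group[g] - by_group[g].mean()) ** 2).sum() for g in labels)
    mse = sse / df_error
    ref_i = labels.index(reference)

    rng = np.random.default_rng(seed)
    max_t = _dunnett_max_abs_t(n, ref_i, df_error, mc_draws, rng)
    crit = float(np.quantile(max_t, 1.0 - alpha))

    rows = []
    for gi, g in enumerate(labels):
        if gi == ref_i:
            continue
        se = np.sqrt(mse * (1.0 / n[gi] + 1.0 / n[ref_i]))
        if se == 0:
            t = 0.0 if means[gi] == means[ref_i] else np.inf
        else:
            t = (means[gi] - means[ref_i]) / se
        p_unadj = 2.0 * stats.t.sf(abs(t), df_error)
        p_adj = float(np.mean(max_t >= abs(t)))
        p_adj = min(1.0, max(p_adj, p_unadj))
        rows.append(
            {
                "group": g,
                "mean_diff": means[gi] - means[ref_i],
                "t": t,
                "p_adjusted": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return DunnettResult(
        reference=reference,
        comparisons=pd.DataFrame(rows),
        mse=float(mse),
        df_error=df_error,
        critical_value=crit,
        alpha=alpha,
        mc_draws=mc_draws,
        seed=seed,
    )


@dataclass
class DoseResponseVerdict:
    """Shape classification of the concentration-index relationship."""

    anova: AnovaResult
    pattern: str                # 'monotone' | 'plateau' | 'non-monotone'
    peak_group: object          # condition with the maximal mean index
    monotonicity_score: float   # Kendall tau of concentration order vs group means
    top_dose_significantly_below_peak: bool
    group_means: pd.Series


def classify_dose_response(
    index: pd.DataFrame,
    anova: AnovaResult,
    dunnett_vs_peak: DunnettResult,
) -> DoseResponseVerdict:
    """Classify the dose-response shape of the index.

    The peak is the condition with the maximal mean index. The pattern is
    ``non-monotone`` if any condition above the peak concentration is
    significantly below the peak (Dunnett against the peak); otherwise
    ``plateau`` if the top concentration's mean lies (non-significantly)
    below the peak's; otherwise ``monotone``. The monotonicity score is the
    Kendall rank correlation between concentration order and group means.
    """
    gm = index.groupby("condition")["d2"].mean().sort_index()
    concs = gm.index.to_numpy(dtype=float)
    peak = gm.idxmax()
    tau = stats.kendalltau(concs, gm.to_numpy()).statistic
    comp = dunnett_vs_peak.comparisons.set_index("group")
    above_peak = [g for g in gm.index if g > peak]
    sig_below = False
    for g in above_peak:
        row = comp.loc[g]
        if bool(row["significant"]) and row["mean_diff"] < 0:
            sig_below = True
    top = gm.index[-1]
    if sig_below:
        pattern = "non-monotone"
    elif top != peak and gm.loc[top] < gm.loc[peak]:
        pattern = "plateau"
    else:
        pattern = "monotone"
    return DoseResponseVerdict(
        anova=anova,
        pattern=pattern,
        peak_group=peak,
        monotonicity_score=float(tau),
        top_dose_significantly_below_peak=sig_below,
        group_means=gm,
    )


@dataclass
class ModelSelection:
    """Audit trail of the candidate-model selection pipeline."""

    audit: pd.DataFrame                 # one row per candidate, all scores
    verdicts: list[DoseResponseVerdict]
    chosen: SubsetModelResult | None
    chosen_verdict: DoseResponseVerdict | None


def select_final_model(
    candidates: list[SubsetModelResult],
    table: FeatureTable,
    alpha: float = 0.05,
    mc_draws: int = 200_000,
    seed: int = 0,
    control=None,
) -> ModelSelection:
    """Pick the final integrative model among zero-error candidates.

    For each candidate: compute the Mahalanobis index to the control
    centroid, its one-way ANOVA, Dunnett against the control and against the
    peak condition, and the dose-response verdict. Then (1) keep candidates
    with ANOVA p < alpha, (2) drop non-monotone patterns, (3) rank the rest
    by monotonicity score descending, ANOVA F descending, then fewer
    effects. Candidate input order does not affect the outcome.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    rows, verdicts = [], []
    kw_note = []
    for ci, cand in enumerate(sorted(candidates, key=lambda c: (c.n_effects, c.subset))):
        model = cand.fitted if cand.fitted is not None else fit_lda(table, cand.subset)
        idx = mahalanobis_index(model, table, control=control)
        anova = anova_on_index(idx)
        ctl = model.group_labels[0] if control is None else control
        d_ctl = dunnett_test(idx, ctl, alpha=alpha, mc_draws=mc_draws, seed=seed)
        peak = idx.groupby("condition")["d2"].mean().idxmax()
        if peak == ctl:
            d_peak = d_ctl
        else:
            d_peak = dunnett_test(idx, peak, alpha=alpha, mc_draws=mc_draws, seed=seed)
        verdict = classify_dose_response(idx, anova, d_peak)
        # informational non-parametric cross-check of the index ANOVA
        kw = stats.kruskal(*[g["d2"].to_numpy() for _, g in idx.groupby("condition")])
        verdicts.append(verdict)
        rows.append(
            {
                "subset": ";".join(cand.subset),
                "n_effects": cand.n_effects,
                "loocv_accuracy": cand.loocv_accuracy,
                "anova_F": anova.F,
                "anova_p": anova.p,
                "kruskal_p": float(kw.pvalue),
                "pattern": verdict.pattern,
                "peak_group": verdict.peak_group,
                "monotonicity_score": verdict.monotonicity_score,
                "n_significant_vs_control": int(d_ctl.comparisons["significant"].sum()),
            }
        )
    audit = pd.DataFrame(rows)
    eligible = audit[(audit["anova_p"] < alpha) & (audit["pattern"] != "non-monotone")]
    if eligible.empty:
        warnings.warn("no candidate is both significant and (near-)monotone; none chosen")
        chosen_i = None
    else:
        ranked = eligible.sort_values(
            by=["monotonicity_score", "anova_F", "n_effects"],
            ascending=[False, False, True],
            kind="stable",
        )
        chosen_i = int(ranked.index[0])
    cand_sorted = sorted(candidates, key=lambda c: (c.n_effects, c.subset))
    return ModelSelection(
        audit=audit,
        verdicts=verdicts,
        chosen=None if chosen_i is None else cand_sorted[chosen_i],
        chosen_verdict=None if chosen_i is None else verdicts[chosen_i],
    )
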