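"""Inferential stage: group comparisons, repeated-measures ANOVA with
Greenhouse–Geisser correction, and the log-linear adherence regression.

Conventions
-----------
* Continuous variables compare across three adherence groups with the
  Kruskal–Wallis rank-sum test, and across two groups (the 75%
  sensitivity split) with the Wilcoxon rank-sum (Mann–Whitney) test.
* Categorical variables use Pearson's chi-squared, falling back to an
  exact test whenever any expected cell count is below 5: Fisher's
  exact test for 2x2 tables, otherwise a conditional Monte-Carlo exact
  test with fixed margins (Patefield sampling).
* The regression response is log(long-term adherence); exponentiated
  coefficients are therefore *relative* effects (1.14 = +14% adherence
  per unit).  Two-sided alpha = 0.05 throughout, no multiplicity
  correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg as spla
from scipy import stats as sps
import statsmodels.api as sm

from .types import (
    CollinearityError,
    DayClass,
    DegenerateGroupError,
    DomainError,
    EffectEstimate,
    GroupComparison,
)

__all__ = [
    "compare_by_group",
    "rm_anova_gg",
    "gg_epsilon",
    "prepare_daily_matrix",
    "RegressionSpec",
    "fit_log_linear",
    "sensitivity_split",
    "seasonality_profile",
    "RMAnovaResult",
]


# ---------------------------------------------------------------------------
# group comparisons

def _contingency(values: pd.Series, groups: pd.Series) -> np.ndarray:
    table = pd.crosstab(values, groups)
    return table.to_numpy()


def compare_by_group(
    values: Sequence,
    groups: Sequence,
    variable_kind: str,
    variable: str = "",
    n_resamples: int = 20000,
    random_state: Optional[int] = 0,
) -> GroupComparison:
    """Test whether a per-participant variable differs across groups.

    ``variable_kind`` is ``"continuous"`` or ``"categorical"``.  Raises
    :class:`DegenerateGroupError` when fewer than two non-empty groups
    remain after dropping missing values.
    """
    df = pd.DataFrame({"value": values, "group": groups}).dropna()
    levels = [g for g, sub in df.groupby("group") if len(sub)]
    if len(levels) < 2:
        raise DegenerateGroupError(f"need >=2 non-empty groups, got {len(levels)}")

    if variable_kind == "continuous":
        samples = [df.loc[df["group"] == g, "value"].to_numpy(float) for g in levels]
        if np.ptp(np.concatenate(samples)) == 0:
            # identical values everywhere: no evidence of any difference
            return GroupComparison(variable, "kruskal-wallis", 0.0, 1.0, len(levels))
        if len(levels) == 2:
            stat, p = sps.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
            return GroupComparison(variable, "wilcoxon-rank-sum", float(stat), float(p), 2)
        stat, p = sps.kruskal(*samples)
        return GroupComparison(variable, "kruskal-wallis", float(stat), float(p), len(levels))

    if variable_kind != "categorical":
        raise DomainError(f"unknown variable_kind {variable_kind!r}")

    table = _contingency(df["value"], df["group"])
    if min(table.shape) < 2:
        # a constant categorical variable cannot differ between groups
        return GroupComparison(variable, "chi-squared", 0.0, 1.0, len(levels))
    chi2 = sps.chi2_contingency(table, correction=False)
    if (chi2.expected_freq < 5).any():
        if table.shape == (2, 2):
            res = sps.fisher_exact(table, alternative="two-sided")
            return GroupComparison(
                variable, "fisher-exact", float(res[0]), float(res[1]), len(levels)
            )
        p = _exact_mc_pvalue(table, n_resamples, random_state)
        return GroupComparison(variable, "exact-monte-carlo", float(chi2.statistic), p, len(levels))
    return GroupComparison(
        variable, "chi-squared", float(chi2.statistic), float(chi2.pvalue), len(levels)
    )


def _exact_mc_pvalue(table: np.ndarray, n_resamples: int, random_state) -> float:
    """Conditional exact p for an r x c table via Patefield sampling.

    Samples tables with the observed margins and compares the
    chi-squared statistic; the +1/+1 correction keeps the estimate a
    valid p-value.  Matches R's ``simulate.p.value`` approach.
    """
    rng = np.random.default_rng(random_state)
    row, col = table.sum(axis=1), table.sum(axis=0)
    dist = sps.random_table(row, col)
    draws = dist.rvs(n_resamples, method="patefield", random_state=rng)
    expected = np.outer(row, col) / table.sum()
    obs = ((table - expected) ** 2 / expected).sum()
    sim = ((draws - expected) ** 2 / expected).sum(axis=(1, 2))
    return float((1 + (sim >= obs - 1e-12).sum()) / (n_resamples + 1))


# ---------------------------------------------------------------------------
# repeated-measures ANOVA with Greenhouse–Geisser correction

@dataclass(frozen=True)
class RMAnovaResult:
    """Split-plot (groups x repeated days) ANOVA with sphericity correction.

    ``p_time`` and ``p_interaction`` are Greenhouse–Geisser corrected;
    the between-subject group test does not involve sphericity and is
    reported on uncorrected degrees of freedom.
    """

    n_subjects: int
    n_timepoints: int
    n_groups: int
    epsilon: float
    f_group: float
    df_group: Tuple[float, float]
    p_group: float
    f_time: float
    df_time_gg: Tuple[float, float]
    p_time: float
    f_interaction: float
    df_interaction_gg: Tuple[float, float]
    p_interaction: float


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from a k x k within-subject covariance.

    epsilon = tr(C S C')^2 / ((k-1) * tr((C S C')^2)) with C the
    centering projector; equals 1 under compound symmetry and is
    bounded in [1/(k-1), 1].  For k = 2 it is exactly 1.
    """
    cov = np.asarray(cov, dtype=float)
    k = cov.shape[0]
    if cov.shape != (k, k) or k < 2:
        raise DomainError("covariance must be k x k with k >= 2")
    if k == 2:
        return 1.0
    c = np.eye(k) - np.ones((k, k)) / k
    m = c @ cov @ c
    num = np.trace(m) ** 2
    den = (k - 1) * np.trace(m @ m)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def rm_anova_gg(matrix: np.ndarray, groups: Sequence) -> RMAnovaResult:
    """Groups x repeated-measures ANOVA on a complete subjects x days matrix.

    Parameters
    ----------
    matrix
        Shape (n_subjects, k_timepoints), no missing values (see
        :func:`prepare_daily_matrix` for panel completion).
    groups
        Group label per subject.

    Notes
    -----
    Classical split-plot decomposition: the group effect is tested
    against between-subject variation, time and group x time against
    the within-subject residual with degrees of freedom scaled by the
    Greenhouse–Geisser epsilon estimated from the pooled within-group
    covariance of the repeated measures.
    """
    y = np.asarray(matrix, dtype=float)
    if y.ndim != 2:
        raise DomainError("matrix must be 2-D (subjects x timepoints)")
    n, k = y.shape
    if k < 2:
        raise DomainError("need at least 2 timepoints")
    if np.isnan(y).any():
        raise DomainError("matrix contains missing values; complete the panel first")
    groups = np.asarray(groups)
    if groups.shape[0] != n:
        raise DomainError("groups length must match number of subjects")
    labels, g_idx = np.unique(groups, return_inverse=True)
    g = len(labels)
    if g < 2:
        raise DegenerateGroupError("need >=2 groups")
    n_g = np.bincount(g_idx)
    if (n_g < 2).any():
        raise DegenerateGroupError("every group needs >=2 subjects")

    grand = y.mean()
    subj_mean = y.mean(axis=1)  # (n,)
    time_mean = y.mean(axis=0)  # (k,)
    group_mean = np.array([y[g_idx == j].mean() for j in range(g)])
    cell_mean = np.vstack([y[g_idx == j].mean(axis=0) for j in range(g)])  # (g, k)

    ss_group = k * float(np.sum(n_g * (group_mean - grand) ** 2))
    ss_subj = k * float(np.sum((subj_mean - group_mean[g_idx]) ** 2))
    ss_time = n * float(np.sum((time_mean - grand) ** 2))
    ss_inter = float(
        np.sum(
            n_g[:, None]
            * (cell_mean - group_mean[:, None] - time_mean[None, :] + grand) ** 2
        )
    )
    resid = y - subj_mean[:, None] - cell_mean[g_idx] + group_mean[g_idx][:, None]
    ss_err = float(np.sum(resid**2))

    df_group = (g - 1, n - g)
    df_time = (k - 1, (n - g) * (k - 1))
    df_inter = ((g - 1) * (k - 1), (n - g) * (k - 1))

    ms_group = ss_group / df_group[0]
    ms_subj = ss_subj / df_group[1]
    ms_time = ss_time / df_time[0]
    ms_inter = ss_inter / df_inter[0]
    ms_err = ss_err / df_time[1]

    # pooled within-group covariance of the repeated measures
    pooled = np.zeros((k, k))
    for j in range(g):
        yj = y[g_idx == j]
        pooled += (len(yj) - 1) * np.cov(yj, rowvar=False)
    pooled /= n - g
    eps = gg_epsilon(pooled)

    f_group = ms_group / ms_subj if ms_subj > 0 else np.inf
    p_group = float(sps.f.sf(f_group, *df_group))
    f_time = ms_time / ms_err if ms_err > 0 else np.inf
    f_inter = ms_inter / ms_err if ms_err > 0 else np.inf
    dft = (eps * df_time[0], eps * df_time[1])
    dfi = (eps * df_inter[0], eps * df_inter[1])
    return RMAnovaResult(
        n_subjects=n,
        n_timepoints=k,
        n_groups=g,
        epsilon=eps,
        f_group=float(f_group),
        df_group=df_group,
        p_group=p_group,
        f_time=float(f_time),
        df_time_gg=dft,
        p_time=float(sps.f.sf(f_time, *dft)),
        f_interaction=float(f_inter),
        df_interaction_gg=dfi,
        p_interaction=float(sps.f.sf(f_inter, *dfi)),
    )


def prepare_daily_matrix(
    day_records: pd.DataFrame,
    groups: pd.Series,
    min_coverage: float = 0.8,
    subject_min_coverage: float = 0.8,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Participants x study-days matrix of daily adherence for the ANOVA.

    Dropout and logistics make the panel unbalanced, in three steps:
    study days observed by fewer than ``min_coverage`` of participants
    are dropped; subjects observing fewer than ``subject_min_coverage``
    of the remaining days are removed (listwise); a subject's sparse
    leftover gaps (their own changeover/logistics days) are filled with
    that subject's mean over observed days, which leaves between-
    subject contrasts untouched.  A day is "observed" when it is not a
    logistics-loss or post-withdrawal day; its value is wear_hours / 24.

    Returns ``(matrix, group_labels, study_days)``.
    """
    obs = day_records[
        ~day_records["day_class"].isin(
            [
                DayClass.CHANGEOVER.value,
                DayClass.NPC_NONWEAR.value,
                DayClass.POST_WITHDRAWAL.value,
            ]
        )
    ].copy()
    obs["daily"] = obs["wear_hours"] / 24.0
    wide = obs.pivot_table(index="participant_id", columns="study_day", values="daily")
    coverage = wide.notna().mean(axis=0)
    wide = wide.loc[:, coverage[coverage >= min_coverage].index]
    subject_cov = wide.notna().mean(axis=1)
    wide = wide.loc[subject_cov >= subject_min_coverage]
    wide = wide.apply(lambda row: row.fillna(row.mean()), axis=1)
    wide = wide.loc[wide.index.intersection(groups.index)]
    g = groups.loc[wide.index].to_numpy()
    return wide.to_numpy(), g, wide.columns.to_numpy()


# ---------------------------------------------------------------------------
# log-linear regression

#: default covariate set; names refer to columns built by ``_build_design``
DEFAULT_COVARIATES = (
    "age_per_decade",
    "female_sex",
    "hf_hospitalization",
    "known_af",
    "cardiovascular_comorbidity",
    "crtd_vs_icd",
    "smoking_active",
    "smoking_previous",
    "kccq_clinical",
    "schedule_both",
    "schedule_monthly",
)


@dataclass(frozen=True)
class RegressionSpec:
    """Model specification for the log-linear adherence regression.

    Categorical references are fixed: male, no-HF, no-AF,
    no-comorbidity, ICD, never-smoked, biweekly schedule.
    ``zero_handling`` decides what happens to participants whose
    adherence is exactly zero (log undefined): ``"exclude"`` drops
    them, ``"offset_epsilon"`` replaces 0 with ``epsilon``.
    """

    response: str = "long_term_adherence"
    covariates: Tuple[str, ...] = DEFAULT_COVARIATES
    zero_handling: str = "exclude"
    epsilon: float = 0.005


def _build_design(data: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    cols = {}
    if "age_years" in data:
        cols["age_per_decade"] = data["age_years"] / 10.0
    if "sex" in data:
        cols["female_sex"] = (data["sex"] == "female").astype(float)
    for flag in ("hf_hospitalization", "known_af", "cardiovascular_comorbidity"):
        if flag in data:
            cols[flag] = data[flag].astype(float)
    if "device_type" in data:
        cols["crtd_vs_icd"] = (data["device_type"] == "CRT-D").astype(float)
    if "smoking" in data:
        cols["smoking_active"] = (data["smoking"] == "active").astype(float)
        cols["smoking_previous"] = (data["smoking"] == "previous").astype(float)
    if "kccq_clinical" in data:
        cols["kccq_clinical"] = data["kccq_clinical"].astype(float)
    if "schedule_type" in data:
        cols["schedule_both"] = (data["schedule_type"] == "both").astype(float)
        cols["schedule_monthly"] = (data["schedule_type"] == "monthly").astype(float)
    base = pd.DataFrame(cols, index=data.index)
    design = pd.DataFrame(index=data.index)
    for i, term in enumerate(covariates):
        source = term.rsplit("__dup", 1)[0]  # allow deliberately duplicated terms
        if source in base:
            design[f"{term}" if term not in design else f"{term}_{i}"] = base[source]
        elif term in data:
            design[term] = data[term].astype(float)
        else:
            raise DomainError(f"unknown covariate {term!r}")
    return design


def _check_collinearity(design: pd.DataFrame) -> None:
    x = np.column_stack([np.ones(len(design)), design.to_numpy(float)])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify offending columns via pivoted QR
        _, _, piv = spla.qr(x, pivoting=True)
        bad_idx = sorted(piv[rank:])
        names = ["intercept"] + list(design.columns)
        raise CollinearityError([names[i] for i in bad_idx])


def fit_log_linear(
    summaries: pd.DataFrame,
    profiles: pd.DataFrame,
    spec: RegressionSpec = RegressionSpec(),
) -> List[EffectEstimate]:
    """OLS of log(adherence) on baseline covariates, reported exponentiated.

    Returns one :class:`EffectEstimate` per covariate (the intercept is
    omitted from the report); each estimate is ``exp(beta)`` with a
    95% CI, i.e. the multiplicative change in long-term adherence per
    unit of the covariate.
    """
    data = summaries.merge(profiles, on="participant_id")
    y = data[spec.response].astype(float)
    keep = y.notna()
    if spec.zero_handling == "exclude":
        keep &= y > 0.0
        y = y[keep]
    elif spec.zero_handling == "offset_epsilon":
        y = y[keep].clip(lower=spec.epsilon)
    else:
        raise DomainError(f"unknown zero_handling {spec.zero_handling!r}")
    data = data.loc[keep.index[keep]]

    design = _build_design(data, spec.covariates)
    n_terms = design.shape[1] + 1
    if len(design) < 10 * n_terms:
        raise DomainError(
            f"insufficient sample: {len(design)} participants for {n_terms} terms"
        )
    _check_collinearity(design)
    x = sm.add_constant(design.to_numpy(float))
    model = sm.OLS(np.log(y.to_numpy(float)), x).fit()
    ci = model.conf_int(alpha=0.05)
    out = []
    for j, term in enumerate(design.columns, start=1):
        out.append(
            EffectEstimate(
                term=str(term),
                relative_effect=float(np.exp(model.params[j])),
                ci95=(float(np.exp(ci[j, 0])), float(np.exp(ci[j, 1]))),
                p_value=float(model.pvalues[j]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# sensitivity split and seasonality

#: variables compared across adherence groups in the baseline table
TABLE1_VARIABLES = (
    ("age_years", "continuous"),
    ("sex", "categorical"),
    ("device_type", "categorical"),
    ("known_af", "categorical"),
    ("hf_hospitalization", "categorical"),
    ("cardiovascular_comorbidity", "categorical"),
    ("smoking", "categorical"),
    ("kccq_clinical", "continuous"),
)


def baseline_comparisons(
    summaries: pd.DataFrame,
    profiles: pd.DataFrame,
    group_col: str = "lt_group",
    variables: Sequence[Tuple[str, str]] = TABLE1_VARIABLES,
) -> pd.DataFrame:
    """Baseline-characteristics comparison across adherence groups."""
    data = summaries.merge(profiles, on="participant_id")
    rows = []
    for var, kind in variables:
        res = compare_by_group(data[var], data[group_col], kind, variable=var)
        rows.append(
            {
                "variable": var,
                "test": res.test_name,
                "statistic": res.statistic,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def sensitivity_split(
    summaries: pd.DataFrame,
    profiles: pd.DataFrame,
    threshold: float = 0.75,
    metric: str = "long_term_adherence",
    variables: Sequence[Tuple[str, str]] = TABLE1_VARIABLES,
) -> pd.DataFrame:
    """Two-group (>= threshold vs below) rerun of the baseline comparisons."""
    data = summaries.merge(profiles, on="participant_id")
    adherent = data[metric].fillna(-1.0) >= threshold
    if adherent.all() or (~adherent).all():
        raise DegenerateGroupError(
            f"threshold {threshold} puts all participants on one side"
        )
    labels = np.where(adherent, "adherent", "non_adherent")
    rows = []
    for var, kind in variables:
        res = compare_by_group(data[var], labels, kind, variable=var)
        rows.append(
            {
                "variable": var,
                "test": res.test_name,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n_adherent": int(adherent.sum()),
                "n_non_adherent": int((~adherent).sum()),
            }
        )
    return pd.DataFrame(rows)


def seasonality_profile(day_records: pd.DataFrame) -> pd.Series:
    """Mean daily adherence (wear/24) per calendar month.

    Qualifying days follow the daily-adherence convention (no
    changeover / logistics days, positive wear).  Months with zero
    qualifying days are NaN.
    """
    mask = ~day_records["day_class"].isin(
        [DayClass.CHANGEOVER.value, DayClass.NPC_NONWEAR.value]
    ) & (day_records["wear_hours"] > 0.0)
    qual = day_records.loc[mask].copy()
    months = pd.to_datetime(qual["date"]).dt.month
    profile = (qual["wear_hours"] / 24.0).groupby(months).mean()
    return profile.reindex(range(1, 13)).rename("mean_daily_adherence")
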