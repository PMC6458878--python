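"""Repeated-measure statistics for long-format outcome tables.

The chain mirrors a standard longitudinal questionnaire/EEG analysis:

* random-intercept mixed model per outcome with a fixed timepoint factor,
  tested against the intercept-only null by a maximum-likelihood likelihood
  ratio test (χ² with T−1 df);
* a priori contrasts of t1 against every later timepoint, with t statistics
  based on the within-subject residual standard error (residual df
  N_obs − N_subjects − (T−1), e.g. 69 for 24 subjects × 4 timepoints and 46
  for 24 × 3), one-tailed Bonferroni-corrected p values, and the effect-size
  conversion r = sqrt(t² / (t² + df));
* Tukey single-step post hoc comparisons of all timepoint pairs;
* Pearson correlations between difference scores (t2−t1) with one-tailed p;
* Benjamini–Hochberg step-up adjustment for correlation matrices;
* Cousineau–Morey within-subject standard errors for error bars;
* an age median-split model-comparison control analysis.

Contrast signs follow the convention that "t1−t2" estimates mean(t2) −
mean(t1): a symptom decrease yields a negative t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats


class UnbalancedTableError(ValueError):
    """Outcome table where some subject misses a timepoint."""


@dataclass(frozen=True)
class AnovaResult:
    chi_sq: float
    df: int
    p: float


@dataclass(frozen=True)
class ContrastResult:
    label: str
    t: float
    df: int
    p_one_tailed: float  # uncorrected
    p_one_tailed_bonf: float
    r: float
    estimate: float


def pivot_outcome(table: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Subjects × timepoints matrix for one outcome; errors when unbalanced."""
    sub = table[table["outcome"] == outcome]
    if sub.empty:
        raise KeyError(f"outcome {outcome!r} not in table")
    wide = sub.pivot_table(index="subject", columns="timepoint", values="value",
                           aggfunc="first", sort=True)
    if wide.isna().any().any():
        missing = wide.isna().stack()
        missing = missing[missing].index.tolist()
        raise UnbalancedTableError(f"missing cells for {outcome}: {missing[:5]}")
    counts = sub.groupby(["subject", "timepoint"]).size()
    if (counts > 1).any():
        raise UnbalancedTableError(f"duplicate cells for {outcome}")
    return wide.reindex(sorted(wide.columns), axis=1)


def _anova_decomposition(wide: pd.DataFrame):
    """Balanced two-way decomposition used by contrasts and Tukey tests."""
    x = wide.to_numpy(dtype=float)
    n, T = x.shape
    grand = x.mean()
    subj_means = x.mean(axis=1, keepdims=True)
    time_means = x.mean(axis=0, keepdims=True)
    resid = x - subj_means - time_means + grand
    df_resid = (n - 1) * (T - 1)  # N_obs − N_subjects − (T−1)
    sigma2 = float((resid**2).sum() / df_resid)
    return x, n, T, time_means.ravel(), sigma2, df_resid


def _neg2_loglik_ml(A: float, B: float, n: int, T: int) -> float:
    """−2 × ML log-likelihood of a balanced random-intercept model (profiled).

    ``A`` is the between-subject residual sum of squares T·Σ(r̄_i)² and ``B``
    the within-subject residual SS after the fixed effects are removed.  The
    compound-symmetric covariance has eigenvalues λ = σ² + Tτ² (subject-mean
    direction, MLE A/n) and σ² (within, MLE B/(n(T−1))); when A/n falls below
    the within estimate the τ² ≥ 0 constraint is active and the model
    collapses to iid errors with pooled variance.
    """
    const = n * T * (1.0 + np.log(2.0 * np.pi))
    lam = A / n
    sig2 = B / (n * (T - 1))
    if lam >= sig2:
        if lam <= 0 or sig2 <= 0:
            return -np.inf
        return n * np.log(lam) + n * (T - 1) * np.log(sig2) + const
    pooled = (A + B) / (n * T)
    if pooled <= 0:
        return -np.inf
    return n * T * np.log(pooled) + const


def fit_time_anova(table: pd.DataFrame, outcome: str) -> AnovaResult:
    """Likelihood-ratio test of the timepoint factor in a random-intercept model.

    The full (value ~ timepoint + (1|subject)) and null
    (value ~ 1 + (1|subject)) models are fitted by maximum likelihood and
    compared: χ² = 2(llf_full − llf_null) with df = T − 1.  Because validated
    tables are balanced the profile ML is available in closed form (fitted
    fixed effects are the timepoint means and the variance components follow
    from the between/within decomposition); this matches an iterative
    mixed-model fit to optimizer precision while being immune to boundary
    failures when the subject variance is 0.
    """
    wide = pivot_outcome(table, outcome)
    x = wide.to_numpy(dtype=float)
    n, T = x.shape
    if np.allclose(x.std(), 0.0):
        return AnovaResult(0.0, T - 1, 1.0)
    grand = x.mean()
    subj = x.mean(axis=1, keepdims=True)
    time = x.mean(axis=0, keepdims=True)
    A = float(T * ((subj - grand) ** 2).sum())  # identical under both models
    B_full = float(((x - subj - time + grand) ** 2).sum())
    B_null = float(((x - subj) ** 2).sum())
    chi_sq = max(
        0.0,
        _neg2_loglik_ml(A, B_null, n, T) - _neg2_loglik_ml(A, B_full, n, T),
    )
    df = T - 1
    return AnovaResult(float(chi_sq), df, float(spstats.chi2.sf(chi_sq, df)))


def apriori_contrasts(
    table: pd.DataFrame, outcome: str, direction: str, baseline: str = "t1"
) -> list[ContrastResult]:
    """t1-vs-later contrasts with Bonferroni one-tailed p and effect size r.

    ``direction`` states the a priori hypothesis: "decrease" (scores drop
    after t1; e.g. symptom measures) or "increase" (e.g. the trained
    alpha/delta ratio).  The one-tailed p in that direction is multiplied by
    the number of contrasts (T−1) and capped at 1.
    """
    if direction not in ("decrease", "increase"):
        raise ValueError("direction must be 'decrease' or 'increase'")
    wide = pivot_outcome(table, outcome)
    if baseline not in wide.columns:
        raise KeyError(f"baseline {baseline!r} not among timepoints")
    x, n, T, time_means, sigma2, df_resid = _anova_decomposition(wide)
    cols = list(wide.columns)
    base_idx = cols.index(baseline)
    se = np.sqrt(2.0 * sigma2 / n)
    n_contrasts = T - 1
    out = []
    for j, tp in enumerate(cols):
        if tp == baseline:
            continue
        est = time_means[j] - time_means[base_idx]
        t = est / se
        p_one = spstats.t.cdf(t, df_resid) if direction == "decrease" else spstats.t.sf(t, df_resid)
        out.append(
            ContrastResult(
                label=f"{baseline}-{tp}",
                t=float(t),
                df=df_resid,
                p_one_tailed=float(p_one),
                p_one_tailed_bonf=float(min(1.0, p_one * n_contrasts)),
                r=effect_size_r(t, df_resid),
                estimate=float(est),
            )
        )
    return out


def effect_size_r(t: float, df: int) -> float:
    """Effect size r from a t statistic: r = sqrt(t² / (t² + df))."""
    if df <= 0:
        raise ValueError("df must be positive")
    return float(np.sqrt(t * t / (t * t + df)))


def one_tailed_bonferroni_p(t: float, df: int, n_contrasts: int, direction: str) -> float:
    """Bonferroni-corrected one-tailed p for a contrast t statistic."""
    p_one = spstats.t.cdf(t, df) if direction == "decrease" else spstats.t.sf(t, df)
    return float(min(1.0, p_one * n_contrasts))


def mean_followup_contrast(
    table: pd.DataFrame, outcome: str, direction: str = "decrease"
) -> ContrastResult:
    """t1 versus the mean of all later timepoints (uncorrected one-tailed p).

    Contrast weights are (−1, +1/(T−1), ..., +1/(T−1)) so a score decrease
    after t1 yields a negative t, matching the sign convention of the
    pairwise contrasts.
    """
    wide = pivot_outcome(table, outcome)
    x, n, T, time_means, sigma2, df_resid = _anova_decomposition(wide)
    w = np.full(T, 1.0 / (T - 1))
    w[0] = -1.0
    est = float(w @ time_means)
    se = np.sqrt(sigma2 * (w**2).sum() / n)
    t = est / se
    p_one = spstats.t.cdf(t, df_resid) if direction == "decrease" else spstats.t.sf(t, df_resid)
    return ContrastResult(
        label="t1-mean(t2..)", t=float(t), df=df_resid,
        p_one_tailed=float(p_one), p_one_tailed_bonf=float(p_one),
        r=effect_size_r(t, df_resid), estimate=est,
    )


def tukey_posthoc(table: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """All pairwise timepoint comparisons with single-step Tukey-adjusted p."""
    wide = pivot_outcome(table, outcome)
    x, n, T, time_means, sigma2, df_resid = _anova_decomposition(wide)
    cols = list(wide.columns)
    se = np.sqrt(2.0 * sigma2 / n)
    rows = []
    for i in range(T):
        for j in range(i + 1, T):
            est = time_means[j] - time_means[i]
            t = est / se
            p_unadj = 2.0 * spstats.t.sf(abs(t), df_resid)
            p_adj = float(spstats.studentized_range.sf(abs(t) * np.sqrt(2.0), T, df_resid))
            rows.append(
                {"pair": f"{cols[i]}-{cols[j]}", "estimate": float(est),
                 "t": float(t), "df": df_resid, "p_unadjusted": float(p_unadj),
                 "p_tukey": min(1.0, p_adj)}
            )
    return pd.DataFrame(rows)


def diff_corr(
    behavior_delta: "pd.Series | np.ndarray",
    eeg_delta: "pd.Series | np.ndarray",
    alternative: str = "less",
) -> tuple[float, float, int]:
    """Pearson correlation between paired difference scores.

    Returns (r, one-tailed p in the hypothesized ``alternative`` direction,
    df = n − 2); reported in text as "r(df)".
    """
    x = np.asarray(behavior_delta, dtype=float)
    y = np.asarray(eeg_delta, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("difference scores must be paired 1-d arrays")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("difference scores must be complete cases")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    res = spstats.pearsonr(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue), x.size - 2


def bh_adjust(p_values: "np.ndarray | list") -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def morey_within_se(table: pd.DataFrame, outcome: str) -> pd.Series:
    """Within-subject standard errors per timepoint (Cousineau–Morey).

    Subject means are removed (grand mean restored) before computing the
    per-timepoint SE, and the result is scaled by the bias-correction factor
    sqrt(T / (T − 1)).
    """
    wide = pivot_outcome(table, outcome)
    x = wide.to_numpy(dtype=float)
    n, T = x.shape
    centered = x - x.mean(axis=1, keepdims=True) + x.mean()
    se = centered.std(axis=0, ddof=1) / np.sqrt(n)
    return pd.Series(se * np.sqrt(T / (T - 1)), index=wide.columns, name=outcome)


@dataclass(frozen=True)
class MedianSplitResult:
    median_age: float
    n_young: int
    n_old: int
    chi_sq: float
    df: int
    p: float


def age_median_split_control(
    table: pd.DataFrame, outcome: str, ages: "dict[str, float] | pd.Series"
) -> MedianSplitResult:
    """Median-split age control: does a time × age-group interaction help?

    Subjects at or below the median age form the young group.  The full model
    (time * group, random intercept) is compared against the time-only model
    by an ML likelihood-ratio test with df = (T − 1) + 1.  Both models are
    saturated in their fixed factors, so the profile ML is available in
    closed form from the between/within residual decompositions.
    """
    wide = pivot_outcome(table, outcome)
    ages = pd.Series(ages)
    missing = [s for s in wide.index if s not in ages.index]
    if missing:
        raise KeyError(f"ages missing for subjects: {missing[:5]}")
    med = float(ages.loc[wide.index].median())
    young = (ages.loc[wide.index] <= med).to_numpy()
    x = wide.to_numpy(dtype=float)
    n, T = x.shape
    subj = x.mean(axis=1, keepdims=True)

    # null: fitted = timepoint means
    time = x.mean(axis=0, keepdims=True)
    A_null = float(T * ((subj - x.mean()) ** 2).sum())
    B_null = float(((x - subj - time + x.mean()) ** 2).sum())

    # full: fitted = group x timepoint cell means
    A_full, B_full = 0.0, 0.0
    for g in (young, ~young):
        xg = x[g]
        cell = xg.mean(axis=0, keepdims=True)
        sg = xg.mean(axis=1, keepdims=True)
        A_full += float(T * ((sg - xg.mean()) ** 2).sum())
        B_full += float(((xg - sg - cell + xg.mean()) ** 2).sum())

    chi_sq = max(
        0.0,
        _neg2_loglik_ml(A_null, B_null, n, T)
        - _neg2_loglik_ml(A_full, B_full, n, T),
    )
    df = T
    return MedianSplitResult(
        median_age=med,
        n_young=int(young.sum()),
        n_old=int((~young).sum()),
        chi_sq=float(chi_sq),
        df=df,
        p=float(spstats.chi2.sf(chi_sq, df)),
    )
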