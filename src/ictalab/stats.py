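"""Seizure metrics, survival analysis and group-comparison tests.

Covers the statistics reported around an acute seizure experiment:
per-animal seizure counts/durations/latency, Kaplan-Meier curves and the
Gehan-Breslow-Wilcoxon test for the repeated-injection seizure-threshold
design, exact death-rate comparison, t-tests / one- and two-way ANOVA with
Tukey HSD for band-power tables, and censoring-aware recovery-time
summaries for slice washout experiments (recordings stopped at 60 min;
censored slices enter the summary at the cap).

Raw p-values are reported without multiple-testing correction across
bands, mirroring the per-band unpaired tests convention; the default
significance level is 0.05 (a stricter 0.005 is accepted wherever alpha is
a parameter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

__all__ = [
    "SeizureMetrics",
    "seizure_metrics",
    "km_estimate",
    "gehan_scores",
    "gehan_breslow_wilcoxon",
    "proportion_compare",
    "unpaired_t",
    "one_way_anova",
    "two_way_anova",
    "recovery_table",
]


@dataclass
class SeizureMetrics:
    """Per-animal seizure summary (durations/latency in minutes)."""

    animal_id: str
    count: int
    mean_duration_min: float    # NaN when count == 0
    onset_latency_min: float    # NaN when count == 0


def seizure_metrics(events: list, injection_time: float,
                    animal_id: str = "") -> SeizureMetrics:
    """Count, mean duration and onset latency of one animal's seizures.

    Only events with onset at or after ``injection_time`` (s) count; the
    latency runs from injection to the first detected onset.
    """
    iv = [(e.onset, e.offset) if hasattr(e, "onset") else (e[0], e[1])
          for e in events]
    iv = [(a, b) for a, b in iv if a >= injection_time]
    if not iv:
        return SeizureMetrics(animal_id, 0, np.nan, np.nan)
    durations = [b - a for a, b in iv]
    first = min(a for a, _ in iv)
    return SeizureMetrics(
        animal_id, len(iv), float(np.mean(durations) / 60.0),
        float((first - injection_time) / 60.0))


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit survival estimate.

    ``events`` flags observed endpoints (False = right-censored). Returns
    a step-function table with columns time, survival.
    """
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=np.asarray(events, dtype=bool))
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.values,
                         "survival": sf.iloc[:, 0].values})


def gehan_scores(times: np.ndarray, events: np.ndarray) -> np.ndarray:
    """Gehan's generalized-Wilcoxon score per observation.

    ``U_i`` counts observations that i definitely outlives minus those
    that definitely outlive i, honoring right-censoring: a censored time
    is only known to exceed earlier event times.
    """
    t = np.asarray(times, dtype=float)[:, None]
    d = np.asarray(events, dtype=bool)[:, None]
    # i definitely survives longer than j: t_i > t_j and j was an event,
    # or equal times where j is an event and i is censored
    greater = ((t > t.T) & d.T) | ((t == t.T) & d.T & ~d)
    return (greater.sum(axis=1) - greater.T.sum(axis=1)).astype(float)


def gehan_breslow_wilcoxon(times_a, events_a, times_b, events_b,
                           n_permutations: int | None = None,
                           seed: int = 0) -> dict:
    """Two-group Gehan-Breslow-Wilcoxon test.

    The statistic is the sum of Gehan scores in group A; its permutation
    variance has the closed form ``n_a n_b sum(U^2) / (N (N-1))``, giving
    an asymptotic chi-square(1) p-value. With ``n_permutations`` set, an
    exact-style permutation p-value of the same statistic is also
    computed. The test is symmetric in the group labels.
    """
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    da = np.asarray(events_a, bool)
    db = np.asarray(events_b, bool)
    if ta.size < 2 or tb.size < 2:
        raise ValueError("need at least 2 observations per group")
    if not (da.any() or db.any()):
        raise ValueError("no events in either group; test undefined")
    t = np.concatenate([ta, tb])
    d = np.concatenate([da, db])
    u = gehan_scores(t, d)
    na, n = ta.size, t.size
    w = u[:na].sum()
    var = na * (n - na) * np.sum(u ** 2) / (n * (n - 1))
    if var == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = w ** 2 / var
        p = float(spstats.chi2.sf(chi2, df=1))
    out = {"statistic": float(chi2), "p": p, "w": float(w),
           "variance": float(var)}
    if n_permutations:
        rng = np.random.default_rng(seed)
        # score sums over random subsets of size na
        keys = rng.random((n_permutations, n))
        idx = np.argpartition(keys, na - 1, axis=1)[:, :na]
        w_perm = u[idx].sum(axis=1)
        out["p_permutation"] = float(
            (1 + np.sum(np.abs(w_perm) >= abs(w) - 1e-12))
            / (n_permutations + 1))
    return out


def proportion_compare(k_a: int, n_a: int, k_b: int, n_b: int) -> dict:
    """Two proportions (percent) with a two-sided Fisher exact p-value."""
    for k, n in ((k_a, n_a), (k_b, n_b)):
        if n <= 0:
            raise ValueError("group size must be positive")
        if not 0 <= k <= n:
            raise ValueError("count outside [0, n]")
    _, p = spstats.fisher_exact([[k_a, n_a - k_a], [k_b, n_b - k_b]])
    return {"proportion_a": 100.0 * k_a / n_a,
            "proportion_b": 100.0 * k_b / n_b,
            "p": float(p)}


def unpaired_t(a, b, welch: bool = False) -> dict:
    """Two-sample t-test (Student by default; Welch optional)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    t, p = spstats.ttest_ind(a, b, equal_var=not welch)
    return {"t": float(t), "p": float(p),
            "mean_a": float(a.mean()), "mean_b": float(b.mean()),
            "sem_a": float(spstats.sem(a)), "sem_b": float(spstats.sem(b))}


def one_way_anova(df: pd.DataFrame, value: str = "value",
                  group: str = "group") -> dict:
    """One-way ANOVA with Tukey's HSD pairwise comparisons."""
    groups = [g[value].to_numpy(float) for _, g in df.groupby(group)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    f, p = spstats.f_oneway(*groups)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tk = pairwise_tukeyhsd(df[value].to_numpy(float),
                           df[group].to_numpy(str))
    tukey = pd.DataFrame(tk.summary().data[1:],
                         columns=tk.summary().data[0])
    return {"F": float(f), "p": float(p), "tukey": tukey}


def two_way_anova(df: pd.DataFrame, value: str = "value",
                  factor_a: str = "treatment",
                  factor_b: str = "hemisphere") -> pd.DataFrame:
    """Two-way ANOVA with interaction (type-II sums of squares).

    Returns the ANOVA table with rows for both main effects and the
    interaction.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if df[factor_a].nunique() < 2 or df[factor_b].nunique() < 2:
        raise ValueError("each factor needs at least 2 levels")
    d = df.rename(columns={value: "_y", factor_a: "_fa", factor_b: "_fb"})
    model = smf.ols("_y ~ C(_fa) * C(_fb)", data=d).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table.index = [str(i).replace("_fa", factor_a).replace("_fb", factor_b)
                   for i in table.index]
    return table


def recovery_table(df: pd.DataFrame, cap_min: float = 60.0,
                   value: str = "time_min", group: str = "group",
                   censored: str = "censored") -> dict:
    """Group summary of washout recovery times with censoring at the cap.

    Censored observations enter the mean at ``cap_min`` exactly (an
    all-censored group therefore summarizes to the cap with SEM 0); the
    censored fraction is reported alongside so the convention is visible.
    A one-way ANOVA with Tukey HSD compares the groups on the capped
    values.
    """
    if df.empty or df.groupby(group).size().min() < 1:
        raise ValueError("every group needs at least one observation")
    if (df[value] > cap_min + 1e-9).any():
        raise ValueError(f"recovery time exceeds the {cap_min} min cap")
    d = df.copy()
    d.loc[d[censored].astype(bool), value] = cap_min
    rows = []
    for g, sub in d.groupby(group):
        v = sub[value].to_numpy(float)
        rows.append({
            "group": g, "n": v.size, "mean_min": float(v.mean()),
            "sem_min": float(spstats.sem(v)) if v.size > 1 else 0.0,
            "censored_fraction": float(sub[censored].astype(bool).mean()),
        })
    summary = pd.DataFrame(rows)
    anova = one_way_anova(d.rename(columns={value: "value"}),
                          group=group) if d[group].nunique() >= 2 else None
    return {"summary": summary, "anova": anova}
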