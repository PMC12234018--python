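"""Group comparisons on clinical characteristics, and variance-explained summaries.

For each severity scheme and each clinical characteristic (cognitive ED
symptoms, depression, anxiety, weekly binge frequency, ...), groups are
compared with a one-way ANOVA: classical F when Levene's test does not
reject homogeneity of variance, Welch-corrected F (Satterthwaite degrees of
freedom) when it does.  Effect size is partial eta squared,
SS_effect / (SS_effect + SS_error); for two-group schemes it is derived from
the t statistic, t^2 / (t^2 + df), so schemes with different group counts
summarize on a common scale.

Planned contrasts follow the ordered-severity logic: each group versus the
pool of all higher-severity groups (Helmert family; the K-1 coefficient
vectors sum to zero and are pairwise orthogonal under equal weights).
Cohen's d for a contrast is the difference of the two pooled-side means
divided by their pooled standard deviation.

A characteristic that *defines* a scheme is excluded from that scheme's
comparison (e.g. compensatory frequency for the DSM-5 scheme), and each
comparison uses pairwise deletion: all records nonmissing on that
characteristic and the grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.oneway import anova_oneway

__all__ = [
    "ComparisonResult",
    "ContrastResult",
    "VarianceSummary",
    "levene_test",
    "anova",
    "planned_contrasts",
    "variance_summary",
    "exclusion_of_defining_characteristic",
    "compare_schemes",
    "DEFAULT_CHARACTERISTICS",
    "DEFAULT_EXCLUSIONS",
]

MIN_GROUP_N = 2


@dataclass
class ComparisonResult:
    characteristic: str
    scheme: str
    F_or_t: float
    df: tuple[float, float]
    p: float
    partial_eta_sq: float
    welch_used: bool
    n_per_group: dict


@dataclass
class ContrastResult:
    coefficients: dict
    estimate: float
    se: float
    t: float
    df: float
    p: float
    cohens_d: float
    welch_used: bool


@dataclass
class VarianceSummary:
    per_scheme: dict[str, dict[str, float]]  # scheme -> {min, max, mean, n_characteristics}
    ratios: dict[str, float]  # "a_vs_b" -> mean_a / mean_b


def _group_lists(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    ok = ~pd.isna(values) & ~pd.isna(groups)
    values, groups = values[ok], groups[ok]
    labels = pd.unique(groups)
    data = {g: values[groups == g] for g in labels}
    return data


def levene_test(values, groups, center: str = "mean") -> tuple[float, float]:
    """Levene's homogeneity-of-variance test (center='median' gives
    Brown-Forsythe)."""
    data = _group_lists(values, groups)
    if len(data) < 2:
        raise ValueError("need at least 2 groups")
    for g, x in data.items():
        if len(x) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    if all(np.ptp(x) == 0 for x in data.values()):
        return 0.0, 1.0  # all deviations zero: no evidence against homogeneity
    w, p = stats.levene(*data.values(), center=center)
    return float(w), float(p)


def _ss_decomposition(data: dict) -> tuple[float, float]:
    allv = np.concatenate(list(data.values()))
    grand = allv.mean()
    ss_between = sum(len(x) * (x.mean() - grand) ** 2 for x in data.values())
    ss_within = sum(((x - x.mean()) ** 2).sum() for x in data.values())
    return float(ss_between), float(ss_within)


def anova(values, groups, welch: bool = False, scheme: str = "", characteristic: str = "") -> ComparisonResult:
    """One-way comparison of ``values`` across ``groups``.

    K >= 3: classical F (sums-of-squares) or Welch F; K = 2: pooled or Welch
    t-test, with eta squared = t^2 / (t^2 + df).  Partial eta squared for
    K >= 3 always comes from the classical decomposition.
    """
    data = _group_lists(values, groups)
    if len(data) < 2:
        raise ValueError("need at least 2 groups")
    for g, x in data.items():
        if len(x) == 0:
            raise ValueError(f"group {g!r} is empty")
        if len(x) < MIN_GROUP_N:
            raise ValueError(f"group {g!r} has fewer than {MIN_GROUP_N} values")
    n_per_group = {g: int(len(x)) for g, x in data.items()}
    k = len(data)
    arrays = list(data.values())

    if k == 2:
        a, b = arrays
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        df1 = 1.0
        if welch:
            va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
            df2 = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        else:
            df2 = float(len(a) + len(b) - 2)
        eta = t**2 / (t**2 + df2)
        return ComparisonResult(
            characteristic, scheme, float(t), (df1, float(df2)), float(p), float(eta),
            welch, n_per_group,
        )

    ss_b, ss_w = _ss_decomposition(data)
    eta = ss_b / (ss_b + ss_w) if (ss_b + ss_w) > 0 else 0.0
    if welch:
        res = anova_oneway(arrays, use_var="unequal", welch_correction=True)
        f, p = float(res.statistic), float(res.pvalue)
        df1, df2 = float(res.df_num), float(res.df_denom)
    else:
        n = sum(len(x) for x in arrays)
        df1, df2 = float(k - 1), float(n - k)
        f = (ss_b / df1) / (ss_w / df2) if ss_w > 0 else np.inf
        p = float(stats.f.sf(f, df1, df2))
    return ComparisonResult(
        characteristic, scheme, float(f), (df1, df2), float(p), float(eta), welch, n_per_group
    )


def helmert_contrasts(order: list) -> list[dict]:
    """K-1 'group j versus all higher groups' coefficient vectors.

    Positive weight on the higher-severity pool, so a positive estimate means
    the higher groups score higher.  Pairwise orthogonal under equal weights.
    """
    k = len(order)
    out = []
    for j in range(k - 1):
        coef = {g: 0.0 for g in order}
        coef[order[j]] = -1.0
        for g in order[j + 1:]:
            coef[g] = 1.0 / (k - 1 - j)
        out.append(coef)
    return out


def planned_contrasts(values, groups, scheme_order: list, welch: bool = False) -> list[ContrastResult]:
    """Ordered-severity planned contrasts with Cohen's d.

    ``scheme_order`` lists group labels from lowest to highest severity.
    Classical contrasts use the omnibus MSE with N-K df; Welch contrasts use
    per-group variances with Satterthwaite df.
    """
    data = _group_lists(values, groups)
    order = [g for g in scheme_order if g in data]
    if len(order) < 2:
        raise ValueError("need at least 2 ordered groups with data")
    data = {g: data[g] for g in order}
    means = {g: x.mean() for g, x in data.items()}
    variances = {g: x.var(ddof=1) for g, x in data.items()}
    ns = {g: len(x) for g, x in data.items()}
    n_total = sum(ns.values())
    k = len(order)
    mse = sum(((x - x.mean()) ** 2).sum() for x in data.values()) / (n_total - k)

    results = []
    for coef in helmert_contrasts(order):
        est = sum(coef[g] * means[g] for g in order)
        if welch:
            se2 = sum(coef[g] ** 2 * variances[g] / ns[g] for g in order)
            df = se2**2 / sum(
                (coef[g] ** 2 * variances[g] / ns[g]) ** 2 / (ns[g] - 1) for g in order
            )
        else:
            se2 = mse * sum(coef[g] ** 2 / ns[g] for g in order)
            df = float(n_total - k)
        se = np.sqrt(se2)
        t = est / se if se > 0 else np.inf
        p = 2.0 * float(stats.t.sf(abs(t), df))

        lo_pool = np.concatenate([data[g] for g in order if coef[g] < 0])
        hi_pool = np.concatenate([data[g] for g in order if coef[g] > 0])
        pooled_sd = np.sqrt(
            (
                ((lo_pool - lo_pool.mean()) ** 2).sum()
                + ((hi_pool - hi_pool.mean()) ** 2).sum()
            )
            / (len(lo_pool) + len(hi_pool) - 2)
        )
        d = float((hi_pool.mean() - lo_pool.mean()) / pooled_sd) if pooled_sd > 0 else 0.0
        results.append(
            ContrastResult(coef, float(est), float(se), float(t), float(df), p, d, welch)
        )
    return results


#: scheme -> characteristics used to define it (never compared under it)
DEFAULT_EXCLUSIONS = {
    "semtree": ("overvaluation",),
    "dsm5": ("comp_freq_weekly", "comp_freq_28d"),
    "clinical_overvaluation": ("overvaluation",),
    "purging_count": ("overvaluation",),
}

DEFAULT_CHARACTERISTICS = (
    "overvaluation",
    "comp_freq_weekly",
    "cognitive_ed",
    "depression_total",
    "anxiety_total",
    "binge_weekly",
)

SCHEME_ORDERS = {
    "dsm5": ["subthreshold", "mild", "moderate", "severe", "extreme"],
    "clinical_overvaluation": ["nonclinical", "clinical"],
    "purging_count": ["single", "multiple"],
}


def exclusion_of_defining_characteristic(
    scheme: str, characteristic: str, table: dict | None = None
) -> bool:
    """True when ``characteristic`` defines ``scheme`` and must not be compared."""
    table = table if table is not None else DEFAULT_EXCLUSIONS
    if scheme not in table:
        raise ValueError(f"unknown scheme {scheme!r}")
    return characteristic in table[scheme]


def variance_summary(results: list[ComparisonResult]) -> VarianceSummary:
    """min/max/mean partial eta squared per scheme, plus all pairwise mean ratios."""
    if not results:
        raise ValueError("no comparison results")
    per: dict[str, list[float]] = {}
    for r in results:
        per.setdefault(r.scheme, []).append(r.partial_eta_sq)
    summary = {
        s: {
            "min": float(np.min(v)),
            "max": float(np.max(v)),
            "mean": float(np.mean(v)),
            "n_characteristics": len(v),
        }
        for s, v in per.items()
    }
    ratios = {}
    for a in summary:
        for b in summary:
            if a != b and summary[b]["mean"] > 0:
                ratios[f"{a}_vs_{b}"] = summary[a]["mean"] / summary[b]["mean"]
    return VarianceSummary(per_scheme=summary, ratios=ratios)


def compare_schemes(
    analysis: pd.DataFrame,
    assignments: pd.DataFrame,
    characteristics: tuple[str, ...] = DEFAULT_CHARACTERISTICS,
    schemes: tuple[str, ...] = ("semtree", "dsm5", "clinical_overvaluation", "purging_count"),
    exclusions: dict | None = None,
    levene_alpha: float = 0.05,
) -> tuple[list[ComparisonResult], VarianceSummary]:
    """Run every scheme x characteristic comparison with pairwise deletion.

    Welch correction is applied automatically when Levene's p < ``levene_alpha``.
    Groups smaller than 2 after deletion are dropped from that comparison;
    ``purging_count`` drops the 'none' and ``dsm5`` the 'subthreshold' label
    (outside the scheme's definition).
    """
    df = analysis.merge(assignments, on="id")
    results: list[ComparisonResult] = []
    for scheme in schemes:
        labels = df[scheme]
        if scheme == "purging_count":
            labels = labels.where(labels != "none")
        if scheme == "dsm5":
            labels = labels.where(labels != "subthreshold")
        for char in characteristics:
            if exclusion_of_defining_characteristic(scheme, char, exclusions):
                continue
            vals = df[char]
            ok = vals.notna() & labels.notna()
            v, g = vals[ok].to_numpy(dtype=float), labels[ok].to_numpy(dtype=object)
            counts = pd.Series(g).value_counts()
            keep = counts[counts >= MIN_GROUP_N].index
            sel = pd.Series(g).isin(keep).to_numpy()
            v, g = v[sel], g[sel]
            if len(pd.unique(g)) < 2:
                continue
            _, p_lev = levene_test(v, g)
            res = anova(v, g, welch=p_lev < levene_alpha, scheme=scheme, characteristic=char)
            results.append(res)
    return results, variance_summary(results)
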