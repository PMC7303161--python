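"""Cohort-level statistics: descriptives, age associations, group tests,
stepwise regression and observer-reproducibility metrics.

The analysis plan mirrors standard practice for normal-range imaging
cohorts: mean +/- SD descriptives split by sex with independent-samples
t-tests; Spearman rank correlations of every metric against age; univariate
linear regression followed by forward-conditional (stepwise) multivariate
selection among the univariately significant candidates; Kruskal-Wallis
with Dunn post-hoc pairwise comparisons across age groups (annotated with
significance letters); and Lin's concordance correlation coefficient plus
coefficient-of-variability/bias for intra-/inter-observer agreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ParameterError, StatisticsError

log = logging.getLogger(__name__)

__all__ = [
    "spearman", "ttest_independent", "kruskal_dunn", "DunnResult",
    "forward_conditional_regression", "concordance", "variability_and_bias",
    "CohortResult", "build_report", "reproducibility_report",
]


def spearman(x, y):
    """Spearman rank correlation (mid-ranks for ties) with two-sided p.

    The p-value uses the t approximation t = r sqrt((n-2)/(1-r^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ParameterError("need equal-length series with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatisticsError("rank correlation undefined for constant series")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def ttest_independent(a, b, equal_var: bool = True):
    """Two-sided independent-samples t-test (pooled variance by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise StatisticsError("zero pooled variance")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


@dataclass
class DunnResult:
    """Kruskal-Wallis H with Dunn pairwise post-hoc comparisons."""

    h: float
    p: float
    pairwise_z: dict           # (i, j) -> z
    pairwise_p: dict           # (i, j) -> unadjusted p
    pairwise_p_bonferroni: dict
    letters: list              # per group: significant partners, e.g. "d,e"


def kruskal_dunn(groups: Sequence, alpha: float = 0.05,
                 adjust: Optional[str] = None) -> DunnResult:
    """Tie-corrected Kruskal-Wallis H test with Dunn post-hoc z tests.

    Dunn's statistic compares mean ranks of groups i and j:

        z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))

    with tie correction T = sum(t^3 - t) / (12 (N - 1)).  Each group gets a
    superscript-letter annotation listing the groups (a, b, c, ...) from
    which it differs at p < alpha; ``adjust='bonferroni'`` applies the
    correction before lettering (unadjusted by default).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ParameterError("need at least 3 groups")
    if any(g.size < 2 for g in groups):
        raise ParameterError("each group needs n >= 2")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        k = len(groups)
        empty = {}
        return DunnResult(0.0, 1.0, empty, empty, empty, [""] * k)
    h, p = stats.kruskal(*groups)

    ranks = stats.rankdata(pooled)
    N = pooled.size
    sizes = [g.size for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean()
                  for i in range(len(groups))]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term

    zd, pd_, pb = {}, {}, {}
    k = len(groups)
    n_pairs = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            pij = 2.0 * stats.norm.sf(abs(z))
            zd[(i, j)] = float(z)
            pd_[(i, j)] = float(pij)
            pb[(i, j)] = float(min(1.0, pij * n_pairs))
    use = pb if adjust == "bonferroni" else pd_
    letters = []
    for i in range(k):
        partners = sorted(j for j in range(k) if j != i
                          and use[(min(i, j), max(i, j))] < alpha)
        letters.append(",".join(chr(ord("a") + j) for j in partners))
    return DunnResult(float(h), float(p), zd, pd_, pb, letters)


def forward_conditional_regression(candidates: pd.DataFrame, y,
                                   p_enter: float = 0.05,
                                   p_remove: float = 0.10) -> pd.DataFrame:
    """Forward-conditional (stepwise) OLS variable selection.

    At each step the not-yet-included candidate with the smallest entry
    p-value below ``p_enter`` is added; all included terms are then
    re-tested conditionally and any with p > ``p_remove`` is dropped; the
    loop stops when the model is stable.  Returns a table of the final
    model's coefficients (beta, SE, p); empty (flagged in the log) when no
    candidate qualifies.
    """
    y = np.asarray(y, dtype=float)
    if not isinstance(candidates, pd.DataFrame):
        candidates = pd.DataFrame(np.asarray(candidates))
    if len(candidates) != y.size:
        raise ParameterError("candidate matrix and response lengths differ")
    if y.size <= candidates.shape[1] + 2:
        raise ParameterError("need n > number of candidates + 2")

    included: list = []
    order: list = []
    while True:
        changed = False
        best_p, best_var = np.inf, None
        for var in candidates.columns:
            if var in included:
                continue
            X = sm.add_constant(candidates[included + [var]].to_numpy())
            res = sm.OLS(y, X).fit()
            pv = res.pvalues[-1]
            if pv < best_p:
                best_p, best_var = pv, var
        if best_var is not None and best_p < p_enter:
            included.append(best_var)
            order.append(best_var)
            changed = True
        # conditional removal pass
        while included:
            X = sm.add_constant(candidates[included].to_numpy())
            res = sm.OLS(y, X).fit()
            pvals = res.pvalues[1:]
            worst = int(np.argmax(pvals))
            if pvals[worst] > p_remove:
                dropped = included.pop(worst)
                log.info("stepwise: removed %s (p=%.3f)", dropped, pvals[worst])
                changed = True
            else:
                break
        if not changed:
            break
    if not included:
        log.info("stepwise: no candidate passed entry; empty model")
        return pd.DataFrame(columns=["variable", "beta", "se", "p"])
    X = sm.add_constant(candidates[included].to_numpy())
    res = sm.OLS(y, X).fit()
    log.info("stepwise entry order: %s", order)
    return pd.DataFrame({"variable": included,
                         "beta": res.params[1:], "se": res.bse[1:],
                         "p": res.pvalues[1:]})


def concordance(x, y):
    """Lin's concordance correlation coefficient and its decomposition.

    CCC = 2 cov(x, y) / (var x + var y + (mean x - mean y)^2), with the
    1/n (population) moment convention; precision is the Pearson r and
    accuracy the bias-correction factor CCC / r.
    Returns (ccc, precision, accuracy).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ParameterError("need paired series with n >= 3")
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        raise StatisticsError("CCC undefined for zero-variance series")
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    ccc = 2.0 * sxy / (vx + vy + (x.mean() - y.mean()) ** 2)
    precision = sxy / np.sqrt(vx * vy)
    accuracy = ccc / precision if precision != 0 else np.nan
    return float(ccc), float(precision), float(accuracy)


def variability_and_bias(x, y):
    """Coefficient of variability and mean bias of paired re-measurements.

    bias%% = 100 mean(x - y) / mean((x + y)/2);
    CoV%%  = 100 SD(x - y) / mean((x + y)/2)  (SD with n-1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ParameterError("need paired series with n >= 3")
    level = ((x + y) / 2.0).mean()
    if level == 0:
        raise StatisticsError("zero mean level: CoV undefined")
    d = x - y
    return (float(100.0 * d.std(ddof=1) / level),
            float(100.0 * d.mean() / level))


# ----------------------------------------------------------------- report

@dataclass
class CohortResult:
    """Bundled cohort analysis tables."""

    descriptives: pd.DataFrame
    correlations: pd.DataFrame
    regression: pd.DataFrame
    group_comparison: pd.DataFrame
    group_sizes: list = field(default_factory=list)
    reproducibility: Optional[pd.DataFrame] = None

    def tables(self) -> dict:
        out = {"descriptives": self.descriptives,
               "correlations": self.correlations,
               "regression": self.regression,
               "group_comparison": self.group_comparison}
        if self.reproducibility is not None:
            out["reproducibility"] = self.reproducibility
        return out


def build_report(cohort: pd.DataFrame,
                 metrics: Optional[Sequence[str]] = None,
                 age_col: str = "age_years", sex_col: str = "sex",
                 age_bin_edges: Optional[Sequence[float]] = None,
                 n_age_groups: int = 5,
                 p_enter: float = 0.05, p_remove: float = 0.10
                 ) -> CohortResult:
    """Full cohort analysis: descriptives, correlations, regression, groups.

    ``metrics`` defaults to every numeric column except age and BSA.  Age
    groups come from explicit ``age_bin_edges`` when given, otherwise from
    ``n_age_groups`` equal-count quantile bins.
    """
    if len(cohort) < 3:
        raise ParameterError("cohort needs at least 3 subjects")
    if metrics is None:
        metrics = [c for c in cohort.columns
                   if c not in (age_col, sex_col, "subject_id", "bsa_m2")
                   and np.issubdtype(cohort[c].dtype, np.number)]
    age = cohort[age_col].to_numpy(dtype=float)

    # --- descriptives by sex with t-test ---------------------------------
    rows = []
    sexes = sorted(cohort[sex_col].unique()) if sex_col in cohort else []
    for m in [age_col] + list(metrics):
        vals = cohort[m].to_numpy(dtype=float)
        row = {"metric": m, "mean": vals.mean(), "sd": vals.std(ddof=1)}
        if len(sexes) == 2:
            a = cohort.loc[cohort[sex_col] == sexes[0], m].to_numpy(float)
            b = cohort.loc[cohort[sex_col] == sexes[1], m].to_numpy(float)
            if a.size >= 2 and b.size >= 2:
                row[f"mean_{sexes[0]}"] = a.mean()
                row[f"sd_{sexes[0]}"] = a.std(ddof=1)
                row[f"mean_{sexes[1]}"] = b.mean()
                row[f"sd_{sexes[1]}"] = b.std(ddof=1)
                try:
                    _, row["p_sex"] = ttest_independent(a, b)
                except StatisticsError:
                    row["p_sex"] = np.nan
        rows.append(row)
    descriptives = pd.DataFrame(rows)

    # --- Spearman vs age --------------------------------------------------
    corr_rows = []
    for m in metrics:
        try:
            r, p = spearman(age, cohort[m].to_numpy(float))
        except StatisticsError:
            r, p = np.nan, np.nan
        corr_rows.append({"metric": m, "spearman_r": r, "p": p})
    correlations = pd.DataFrame(corr_rows)

    # --- univariate + forward-conditional multivariate regression --------
    reg_rows = []
    significant = []
    for m in metrics:
        X = sm.add_constant(cohort[[m]].to_numpy(float))
        res = sm.OLS(age, X).fit()
        reg_rows.append({"variable": m, "model": "univariate",
                         "beta": res.params[1], "se": res.bse[1],
                         "p": res.pvalues[1]})
        if res.pvalues[1] < 0.05:
            significant.append(m)
    if significant and len(cohort) > len(significant) + 2:
        multi = forward_conditional_regression(
            cohort[significant], age, p_enter=p_enter, p_remove=p_remove)
        for _, r in multi.iterrows():
            reg_rows.append({"variable": r["variable"], "model": "multivariate",
                             "beta": r["beta"], "se": r["se"], "p": r["p"]})
    regression = pd.DataFrame(reg_rows)

    # --- age-group comparison (Kruskal-Wallis + Dunn letters) ------------
    if age_bin_edges is None:
        qs = np.linspace(0, 1, n_age_groups + 1)
        age_bin_edges = np.quantile(age, qs)
        age_bin_edges[0] -= 1e-9
        age_bin_edges[-1] += 1e-9
    age_bin_edges = np.asarray(age_bin_edges, dtype=float)
    gidx = np.clip(np.searchsorted(age_bin_edges, age, side="right") - 1,
                   0, len(age_bin_edges) - 2)
    group_sizes = [int((gidx == g).sum()) for g in range(len(age_bin_edges) - 1)]
    grp_rows = []
    for m in metrics:
        vals = cohort[m].to_numpy(float)
        groups = [vals[gidx == g] for g in range(len(age_bin_edges) - 1)]
        if any(len(g) < 2 for g in groups):
            log.warning("group comparison for %s skipped: empty stratum", m)
            continue
        dn = kruskal_dunn(groups)
        row = {"metric": m, "H": dn.h, "p": dn.p}
        for g, (gv, letter) in enumerate(zip(groups, dn.letters)):
            q1, q3 = np.percentile(gv, [25, 75])
            row[f"median_g{g + 1}"] = float(np.median(gv))
            row[f"iqr_g{g + 1}"] = float(q3 - q1)
            row[f"sig_g{g + 1}"] = letter
        grp_rows.append(row)
    group_comparison = pd.DataFrame(grp_rows)

    return CohortResult(descriptives, correlations, regression,
                        group_comparison, group_sizes)


def reproducibility_report(pairs: dict) -> pd.DataFrame:
    """Observer-agreement table from ``{metric: (series_1, series_2)}``.

    Reports Lin's CCC with its precision/accuracy decomposition plus the
    coefficient of variability and mean bias per metric, and a simple-mean
    summary row across metrics.
    """
    rows = []
    for name, (x, y) in pairs.items():
        ccc, prec, acc = concordance(x, y)
        cov, bias = variability_and_bias(x, y)
        rows.append({"metric": name, "ccc": ccc, "precision": prec,
                     "accuracy": acc, "cov_pct": cov, "bias_pct": bias})
    df = pd.DataFrame(rows)
    if len(df) > 1:
        summary = df.drop(columns="metric").mean().to_dict()
        summary["metric"] = "average"
        df = pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
    return df
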