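"""Inferential statistics for the factorial ERP/behavioral analysis.

Implements the full set of tests used in the analysis: one-sample and
pooled-variance independent t tests, the uncorrected Pearson chi-square for
a 2x2 table, a mixed (split-plot) ANOVA with one between-subjects factor
and any number of two-level within-subject factors, Greenhouse-Geisser
epsilon, partial eta squared, post hoc observed power from the noncentral F
distribution (ncp = F * df1), and Bonferroni-adjusted pairwise contrasts.

The mixed ANOVA uses the univariate split-plot decomposition in its
orthogonal-contrast form: each within-subject effect is a per-subject
contrast score tested against zero (Type III, unweighted group means, as in
common commercial ANOVA software), its interaction with group is the
between-group ANOVA on the same scores, and the between-subjects main
effect is the ANOVA on subject means. For two-level factors every within
contrast has a single degree of freedom, so sphericity is vacuous and the
Greenhouse-Geisser epsilon is exactly 1; it is still reported and applied
for interface generality.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult", "ChiSquareResult", "MixedAnovaResult",
    "one_sample_t", "independent_t", "chi_square_2x2", "mixed_anova",
    "partial_eta_sq", "observed_power", "bonferroni_pairwise",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float


@dataclass
class MixedAnovaResult:
    """Per-effect table of a mixed ANOVA."""

    table: pd.DataFrame  # effect, F, df1, df2, p, partial_eta_sq, observed_power, gg_epsilon
    n_subjects: int
    dropped_subjects: tuple = ()

    def effect(self, name: str) -> pd.Series:
        row = self.table[self.table["effect"] == name]
        if row.empty:
            raise KeyError(f"no effect named {name!r}")
        return row.iloc[0]


def one_sample_t(values, mu: float = 0.5) -> TTestResult:
    """Two-sided one-sample t test (e.g. 2-AFC proportions against chance)."""
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance: t statistic undefined")
    res = sps.ttest_1samp(x, mu)
    return TTestResult(float(res.statistic), float(x.size - 1), float(res.pvalue))


def independent_t(mean1=None, sd1=None, n1=None, mean2=None, sd2=None, n2=None,
                  x=None, y=None) -> TTestResult:
    """Pooled-variance Student t with df = n1 + n2 - 2.

    Accepts either group summaries (mean/SD/n) or raw vectors ``x``/``y``.
    """
    if x is not None or y is not None:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        mean1, sd1, n1 = x.mean(), x.std(ddof=1), x.size
        mean2, sd2, n2 = y.mean(), y.std(ddof=1), y.size
    if min(n1, n2) < 2:
        raise ValueError("need at least 2 observations per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return TTestResult(float(t), float(df), float(2 * sps.t.sf(abs(t), df)))


def chi_square_2x2(table) -> ChiSquareResult:
    """Pearson chi-square for a 2x2 count table, df = 1, no continuity correction."""
    obs = np.asarray(table, float)
    if obs.shape != (2, 2) or (obs < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    if (obs.sum(0) == 0).any() or (obs.sum(1) == 0).any():
        raise ValueError("zero margin: chi-square undefined")
    expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    return ChiSquareResult(chi2, 1, float(sps.chi2.sf(chi2, 1)))


def partial_eta_sq(F: float, df1: float, df2: float) -> float:
    """Partial eta squared from an F ratio: F*df1 / (F*df1 + df2)."""
    if F < 0:
        raise ValueError("F must be non-negative")
    return F * df1 / (F * df1 + df2)


def observed_power(F: float, df1: float, df2: float, alpha: float = 0.05) -> float:
    """Post hoc power: P(noncentral F(df1, df2, ncp=F*df1) > F_crit(alpha)).

    At F = 0 the noncentral distribution collapses to the central F and the
    power equals alpha.
    """
    if F < 0:
        raise ValueError("F must be non-negative")
    crit = sps.f.isf(alpha, df1, df2)
    if F == 0:
        return alpha
    return float(sps.ncf.sf(crit, df1, df2, F * df1))


# ---------------------------------------------------------------------------
# mixed (split-plot) ANOVA


def _type3_intercept_F(scores: np.ndarray, groups: np.ndarray):
    """Type III test that the unweighted mean of group means is zero."""
    levels = np.unique(groups)
    g = len(levels)
    ns = np.array([(groups == lv).sum() for lv in levels])
    means = np.array([scores[groups == lv].mean() for lv in levels])
    sse = sum(((scores[groups == lv] - m) ** 2).sum()
              for lv, m in zip(levels, means))
    df2 = len(scores) - g
    mse = sse / df2
    u = means.mean()
    var_u = mse * (1.0 / ns).sum() / g ** 2
    F = u ** 2 / var_u if var_u > 0 else np.inf
    return F, 1.0, float(df2)


def _oneway_F(scores: np.ndarray, groups: np.ndarray):
    """One-way between-groups ANOVA on (contrast or mean) scores."""
    levels = np.unique(groups)
    g = len(levels)
    grand = scores.mean()
    ss_b = sum((groups == lv).sum() * (scores[groups == lv].mean() - grand) ** 2
               for lv in levels)
    ss_w = sum(((scores[groups == lv] - scores[groups == lv].mean()) ** 2).sum()
               for lv in levels)
    df1, df2 = g - 1, len(scores) - g
    F = (ss_b / df1) / (ss_w / df2) if ss_w > 0 else np.inf
    return float(F), float(df1), float(df2)


def mixed_anova(data: pd.DataFrame, dv: str, between: str,
                within: tuple[str, ...], subject: str = "subject",
                alpha: float = 0.05) -> MixedAnovaResult:
    """Mixed ANOVA: one between-subjects factor x two-level within factors.

    ``data`` is long-format with one row per subject x within-cell (cells
    are averaged if repeated). Subjects with incomplete within-cells are
    dropped (recorded in ``dropped_subjects``). Each effect row carries F,
    dfs, p, partial eta squared, observed power, and the Greenhouse-Geisser
    epsilon applied to its dfs (exactly 1 for single-df contrasts).
    """
    within = tuple(within)
    levels = {w: sorted(data[w].unique()) for w in within}
    for w, lv in levels.items():
        if len(lv) != 2:
            raise NotImplementedError(
                f"within factor {w!r} has {len(lv)} levels; only two-level "
                "within factors are supported")

    wide = (data.groupby([subject, between, *within])[dv].mean()
            .unstack(list(within)))
    complete = wide.notna().all(axis=1)
    dropped = tuple(s for (s, _g) in wide.index[~complete])
    wide = wide[complete]
    groups = np.array([g for (_s, g) in wide.index])
    if min(np.bincount(pd.factorize(groups)[0])) < 2:
        raise ValueError("need at least 2 complete subjects per group")
    n = wide.shape[0]

    # +1/-1 codes per within factor level, aligned with the wide columns
    cols = list(wide.columns)  # tuples over within levels (or scalar if 1 factor)
    cols = [c if isinstance(c, tuple) else (c,) for c in cols]
    codes = {w: {levels[w][0]: 1.0, levels[w][1]: -1.0} for w in within}
    values = wide.to_numpy()

    rows = []

    def attach(effect, F, df1, df2, eps=1.0):
        p = float(sps.f.sf(F, eps * df1, eps * df2))
        rows.append(dict(effect=effect, F=float(F), df1=df1, df2=df2, p=p,
                         partial_eta_sq=partial_eta_sq(F, df1, df2),
                         observed_power=observed_power(F, df1, df2, alpha),
                         gg_epsilon=eps))

    # between-subjects main effect: ANOVA on subject means
    attach(between, *_oneway_F(values.mean(axis=1), groups))

    # within effects and their interactions with the between factor
    for r in range(1, len(within) + 1):
        for subset in itertools.combinations(within, r):
            coef = np.array([np.prod([codes[w][dict(zip(within, c))[w]]
                                      for w in subset]) for c in cols])
            scores = values @ coef / len(cols)
            name = ":".join(subset)
            attach(name, *_type3_intercept_F(scores, groups))
            F, df1, df2 = _oneway_F(scores, groups)
            attach(f"{name}:{between}", F, df1, df2)

    table = pd.DataFrame(rows)
    return MixedAnovaResult(table, n, dropped)


# ---------------------------------------------------------------------------
# pairwise contrasts


def bonferroni_pairwise(data: pd.DataFrame, dv: str, factor: str,
                        by: tuple[str, ...] = (), subject: str = "subject",
                        paired: bool = False) -> pd.DataFrame:
    """All pairwise level contrasts of ``factor`` within each ``by`` cell.

    Contrasts use an independent pooled t (``paired=False``; e.g. the
    group factor) or a paired t on subject-matched values (``paired=True``;
    within-subject factors). The family is the full set of returned
    contrasts; adjusted p = min(1, m * raw p).
    """
    by = tuple(by)
    cells = (data[list(by)].drop_duplicates().itertuples(index=False)
             if by else [()])
    rows = []
    for cell in cells:
        cell = tuple(cell)
        sub = data
        for col, val in zip(by, cell):
            sub = sub[sub[col] == val]
        lvls = sorted(sub[factor].unique())
        for a, b in itertools.combinations(lvls, 2):
            xa = sub[sub[factor] == a].groupby(subject)[dv].mean()
            xb = sub[sub[factor] == b].groupby(subject)[dv].mean()
            if paired:
                common = xa.index.intersection(xb.index)
                d = (xa[common] - xb[common]).to_numpy()
                res = sps.ttest_1samp(d, 0.0)
                t, df, p = res.statistic, len(d) - 1, res.pvalue
                se = d.std(ddof=1) / np.sqrt(len(d))
            else:
                r = independent_t(x=xa.to_numpy(), y=xb.to_numpy())
                t, df, p = r.t, r.df, r.p
                se = (xa.mean() - xb.mean()) / t if t != 0 else np.nan
            rows.append(dict(**{c: v for c, v in zip(by, cell)},
                             contrast=f"{a} - {b}",
                             mean_1=xa.mean(), mean_2=xb.mean(),
                             se=abs(se) if se == se else np.nan,
                             t=float(t), df=float(df), p_raw=float(p)))
    out = pd.DataFrame(rows)
    m = len(out)
    out["family_size"] = m
    out["p_bonferroni"] = np.minimum(1.0, m * out["p_raw"])
    return out
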