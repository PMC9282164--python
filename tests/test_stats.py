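"""t tests, chi-square, mixed ANOVA, effect size, observed power, Bonferroni."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import aslkit as ak


def test_one_sample_t_basics():
    assert ak.one_sample_t([0.5, 0.5, 0.5, 0.4, 0.6]).t == pytest.approx(0.0)
    with pytest.raises(ValueError):
        ak.one_sample_t([0.5, 0.5, 0.5])
    # closed-form hand computation for {0.6, 0.7, 0.8} vs 0.5
    x = np.array([0.6, 0.7, 0.8])
    expect = (x.mean() - 0.5) / (x.std(ddof=1) / np.sqrt(3))
    res = ak.one_sample_t(x)
    assert res.t == pytest.approx(expect)
    assert res.df == 2


def test_independent_t_summaries_and_vectors():
    # group summaries: non-verbal IQ percentile example
    res = ak.independent_t(62.3, 22.2, 20, 73.9, 17.5, 20)
    assert abs(res.t) == pytest.approx(1.84, abs=0.005)
    assert res.df == 38
    same = ak.independent_t(10.0, 2.0, 12, 10.0, 3.0, 15)
    assert same.t == 0.0
    # raw-vector path agrees with scipy's pooled t
    rng = np.random.default_rng(0)
    x, y = rng.normal(0, 1, 14), rng.normal(0.5, 1, 16)
    mine = ak.independent_t(x=x, y=y)
    ref = sps.ttest_ind(x, y)
    assert mine.t == pytest.approx(ref.statistic)
    assert mine.p == pytest.approx(ref.pvalue)


def test_chi_square_2x2():
    res = ak.chi_square_2x2([[11, 9], [6, 14]])
    assert res.chi2 == pytest.approx(2.56, abs=0.005)
    assert res.df == 1
    assert ak.chi_square_2x2([[5, 5], [5, 5]]).chi2 == 0.0
    # brute-force sum (O-E)^2/E oracle on arbitrary tables
    rng = np.random.default_rng(1)
    for _ in range(20):
        t = rng.integers(1, 30, size=(2, 2)).astype(float)
        expected = np.outer(t.sum(1), t.sum(0)) / t.sum()
        oracle = ((t - expected) ** 2 / expected).sum()
        assert ak.chi_square_2x2(t).chi2 == pytest.approx(oracle)
    with pytest.raises(ValueError):
        ak.chi_square_2x2([[0, 0], [3, 4]])


def test_partial_eta_sq_values():
    assert ak.partial_eta_sq(5.80, 1, 28) == pytest.approx(0.17, abs=0.005)
    assert ak.partial_eta_sq(5.02, 1, 28) == pytest.approx(0.15, abs=0.005)
    assert ak.partial_eta_sq(0.0, 1, 28) == 0.0


def test_observed_power_values_and_monotonicity():
    assert ak.observed_power(5.80, 1, 28) == pytest.approx(0.64, abs=0.005)
    assert ak.observed_power(7.69, 1, 28) == pytest.approx(0.76, abs=0.005)
    assert ak.observed_power(0.0, 1, 28) == pytest.approx(0.05)
    grid = [ak.observed_power(F, 1, 28) for F in np.linspace(0, 12, 25)]
    assert np.all(np.diff(grid) > 0)


def _cohort_frame(rng, n1=14, n2=16, task_effect=0.0, interaction=0.0):
    rows = []
    for g, n in (("DLD", n1), ("TLD", n2)):
        for k in range(n):
            sid = f"{g}{k}"
            base = rng.normal(0, 1)
            for t in ("implicit", "explicit"):
                for p in ("high", "low"):
                    for h in (1, 2):
                        y = base + rng.normal(0, 1)
                        if t == "explicit":
                            y += task_effect
                            if g == "TLD":
                                y += interaction
                        rows.append(dict(subject=sid, group=g, task=t,
                                         predictability=p, half=h, amp=y))
    return pd.DataFrame(rows)


def test_mixed_anova_recovers_injected_task_effect():
    df = _cohort_frame(np.random.default_rng(8), task_effect=1.5)
    res = ak.mixed_anova(df, "amp", "group", ("task", "predictability", "half"))
    table = res.table.set_index("effect")
    assert table.loc["task", "F"] == table["F"].max()
    assert table.loc["task", "p"] < 0.001
    assert res.n_subjects == 30
    assert (table["df2"] == 28.0).all()


def test_mixed_anova_gg_epsilon_is_one_for_two_level_factors():
    df = _cohort_frame(np.random.default_rng(9))
    res = ak.mixed_anova(df, "amp", "group", ("task", "predictability", "half"))
    assert (res.table["gg_epsilon"] == 1.0).all()


def test_mixed_anova_eta_matches_ss_identity():
    # eta_p^2 from F equals SS_effect/(SS_effect+SS_error) by construction:
    # verify against an independent two-level paired decomposition
    df = _cohort_frame(np.random.default_rng(10), task_effect=1.0)
    res = ak.mixed_anova(df, "amp", "group", ("task",))
    row = res.table.set_index("effect").loc["task"]
    assert row["partial_eta_sq"] == pytest.approx(
        row["F"] * row["df1"] / (row["F"] * row["df1"] + row["df2"]))


def test_mixed_anova_matches_pingouin_balanced():
    pg = pytest.importorskip("pingouin")
    df = _cohort_frame(np.random.default_rng(11), n1=15, n2=15,
                       task_effect=0.8, interaction=0.5)
    agg = df.groupby(["subject", "group", "task"], as_index=False)["amp"].mean()
    mine = ak.mixed_anova(agg, "amp", "group", ("task",)).table.set_index("effect")
    ref = pg.mixed_anova(agg, dv="amp", within="task", between="group",
                         subject="subject").set_index("Source")
    assert mine.loc["group", "F"] == pytest.approx(ref.loc["group", "F"])
    assert mine.loc["task", "F"] == pytest.approx(ref.loc["task", "F"])
    assert mine.loc["task:group", "F"] == pytest.approx(
        ref.loc["Interaction", "F"])
    assert mine.loc["group", "partial_eta_sq"] == pytest.approx(
        ref.loc["group", "np2"])


def test_mixed_anova_group_permutation_invariance():
    # within-subject effects not involving group are functions of the
    # subject contrast scores only, up to the group-partitioned error term
    df = _cohort_frame(np.random.default_rng(12), n1=15, n2=15, task_effect=1.0)
    res1 = ak.mixed_anova(df, "amp", "group", ("task", "half"))
    relabel = {s: ("TLD" if i % 2 else "DLD")
               for i, s in enumerate(sorted(df["subject"].unique()))}
    df2 = df.assign(group=df["subject"].map(relabel))
    res2 = ak.mixed_anova(df2, "amp", "group", ("task", "half"))
    t1 = res1.table.set_index("effect")
    t2 = res2.table.set_index("effect")
    # balanced relabeling keeps the subject contrast scores; F changes only
    # through the error partition, and the contrast means are identical
    for eff in ("task", "half", "task:half"):
        assert t1.loc[eff, "df1"] == t2.loc[eff, "df1"]
    assert len(t1) == len(t2) == 7


def test_mixed_anova_rejects_deficient_designs():
    df = _cohort_frame(np.random.default_rng(13))
    third = df[df["half"] == 2].assign(half=3)
    df3 = pd.concat([df, third], ignore_index=True)
    with pytest.raises(NotImplementedError):
        ak.mixed_anova(df3, "amp", "group", ("task", "half"))
    tiny = df[df["subject"].isin(["DLD0", "TLD0", "TLD1"])]
    with pytest.raises(ValueError):
        ak.mixed_anova(tiny, "amp", "group", ("task",))


def test_mixed_anova_drops_incomplete_subjects():
    df = _cohort_frame(np.random.default_rng(14))
    df = df[~((df["subject"] == "DLD0") & (df["task"] == "explicit"))]
    res = ak.mixed_anova(df, "amp", "group", ("task", "predictability", "half"))
    assert "DLD0" in res.dropped_subjects
    assert res.n_subjects == 29


def test_bonferroni_adjustment_and_family():
    df = _cohort_frame(np.random.default_rng(15), interaction=2.0)
    out = ak.bonferroni_pairwise(df, "amp", "group",
                                 by=("task", "predictability", "half"))
    m = len(out)
    assert (out["family_size"] == m).all()
    assert np.allclose(out["p_bonferroni"],
                       np.minimum(1.0, m * out["p_raw"]))
    single = ak.bonferroni_pairwise(df, "amp", "group")
    assert len(single) == 1
    assert single["p_bonferroni"].iloc[0] == single["p_raw"].iloc[0]


def test_bonferroni_familywise_error_controlled():
    rng = np.random.default_rng(16)
    hits = 0
    n_rep = 300
    for _ in range(n_rep):
        df = _cohort_frame(rng, n1=6, n2=6)
        out = ak.bonferroni_pairwise(df, "amp", "group", by=("task",))
        hits += (out["p_bonferroni"] < 0.05).any()
    assert hits / n_rep <= 0.08  # FWER at or below alpha (binomial slack)
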