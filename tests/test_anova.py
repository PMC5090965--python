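"""Mixed three-way (one between-, two within-subject) ANOVA against an
independent R ``aov`` oracle with explicit error strata, plus structural df
identities."""

import json
import subprocess

import numpy as np
import pandas as pd
import pytest

from petlearn import behavior as bh


def make_design(rng, g_sizes=(5, 5, 4), n_task=2, n_rep=4, effects=None):
    effects = effects or {}
    rows = []
    sid = 0
    for gi, size in enumerate(g_sizes):
        for _ in range(size):
            sid += 1
            subj_eff = rng.normal(0, 1)
            for t in range(n_task):
                for r in range(n_rep):
                    y = (rng.normal(0, 1) + subj_eff
                         + effects.get("group", 0.0) * gi
                         + effects.get("task", 0.0) * t
                         + effects.get("repeat", 0.0) * r)
                    rows.append({"subject": f"S{sid}", "group": f"G{gi}",
                                 "task": f"T{t}", "repeat": f"R{r}", "value": y})
    return pd.DataFrame(rows)


R_ORACLE = r"""
suppressMessages(library(jsonlite))
args <- commandArgs(trailingOnly = TRUE)
d <- read.csv(args[1])
out <- list()
for (did in unique(d$design_id)) {
  sub <- d[d$design_id == did, ]
  sub$group <- factor(sub$group); sub$task <- factor(sub$task)
  sub$repeatf <- factor(sub$repeatf); sub$subject <- factor(sub$subject)
  m <- aov(value ~ group * task * repeatf + Error(subject / (task * repeatf)),
           data = sub)
  s <- summary(m)
  strata <- list()
  for (nm in names(s)) {
    tab <- s[[nm]][[1]]
    strata[[nm]] <- data.frame(term = trimws(rownames(tab)), df = tab$Df,
                               ss = tab$`Sum Sq`)
  }
  out[[as.character(did)]] <- strata
}
write_json(out, args[2], digits = NA)
"""


def r_aov_oracle(designs):
    """Independent oracle: R's split-plot aov with explicit error strata."""
    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        big = pd.concat(
            [d.assign(design_id=i).rename(columns={"repeat": "repeatf"})
             for i, d in enumerate(designs)], ignore_index=True)
        big.to_csv(tmp / "designs.csv", index=False)
        (tmp / "oracle.R").write_text(R_ORACLE)
        subprocess.run(["Rscript", str(tmp / "oracle.R"),
                        str(tmp / "designs.csv"), str(tmp / "out.json")],
                       check=True, capture_output=True)
        raw = json.loads((tmp / "out.json").read_text())

    results = []
    for i in range(len(designs)):
        strata = raw[str(i)]
        flat = {}
        for stratum, rows in strata.items():
            terms = {r["term"]: (float(r["ss"]), int(r["df"])) for r in rows}
            res_ss, res_df = terms.pop("Residuals")
            for term, (ss, dfn) in terms.items():
                f = (ss / dfn) / (res_ss / res_df)
                from scipy import stats as st

                flat[term] = (ss, dfn, res_df, f, float(st.f.sf(f, dfn, res_df)))
        results.append(flat)
    return results


R_TO_EFFECT = {
    "group": "GROUP", "task": "TASK", "group:task": "GROUPxTASK",
    "repeatf": "REPEAT", "group:repeatf": "GROUPxREPEAT",
    "task:repeatf": "TASKxREPEAT", "group:task:repeatf": "GROUPxTASKxREPEAT",
}


def test_full_table_matches_r_aov_on_random_designs():
    """SS, df, F and p agree with R's split-plot aov to 6 significant digits
    on 20 random complete designs of varying shape."""
    rng = np.random.default_rng(42)
    shapes = [((5, 5, 4), 2, 4), ((3, 3), 2, 3), ((4, 2, 3), 3, 2),
              ((6, 6), 2, 5)]
    designs = []
    for i in range(20):
        g_sizes, n_task, n_rep = shapes[i % len(shapes)]
        designs.append(make_design(
            rng, g_sizes, n_task, n_rep,
            effects={"group": rng.normal(), "task": rng.normal(),
                     "repeat": rng.normal()}))
    oracles = r_aov_oracle(designs)
    for df, oracle in zip(designs, oracles):
        mine = bh.mixed_anova(df, dv="value", subject="subject",
                              between="group", within=("task", "repeat"),
                              diagnostics=False).set_index("effect")
        assert len(oracle) == 7
        for term, (ss, dfn, dfd, f, p) in oracle.items():
            row = mine.loc[R_TO_EFFECT[term]]
            assert row.ss == pytest.approx(ss, rel=1e-6)
            assert row.df_num == dfn
            assert row.df_den == dfd
            assert row.F == pytest.approx(f, rel=1e-6)
            assert row.p == pytest.approx(p, rel=1e-6, abs=1e-12)


@pytest.mark.parametrize("g_sizes,n_task,n_rep", [
    ((5, 5, 4), 2, 4), ((3, 4), 2, 3), ((2, 2, 2, 2), 3, 5),
])
def test_df_identities_hold_for_any_configuration(g_sizes, n_task, n_rep):
    rng = np.random.default_rng(1)
    df = make_design(rng, g_sizes, n_task, n_rep)
    tab = bh.mixed_anova(df, diagnostics=False).set_index("effect")
    n, g = sum(g_sizes), len(g_sizes)
    assert tab.loc["GROUP", "df_den"] == n - g
    assert tab.loc["TASK", "df_den"] == (n_task - 1) * (n - g)
    assert tab.loc["REPEAT", "df_num"] == n_rep - 1
    assert tab.loc["REPEAT", "df_den"] == (n_rep - 1) * (n - g)


def test_pure_group_offset_gives_zero_within_effects():
    """Identical values in every cell except a constant group offset: all
    within-subject effects have SS = 0 and are reported as F = 0."""
    rows = []
    sid = 0
    for gi, size in enumerate((3, 3)):
        for _ in range(size):
            sid += 1
            for t in range(2):
                for r in range(3):
                    rows.append({"subject": f"S{sid}", "group": f"G{gi}",
                                 "task": f"T{t}", "repeat": f"R{r}",
                                 "value": 10.0 * gi})
    tab = bh.mixed_anova(pd.DataFrame(rows), diagnostics=False).set_index("effect")
    for effect in ("TASK", "REPEAT", "TASKxREPEAT"):
        assert tab.loc[effect, "F"] == 0.0
        assert tab.loc[effect, "p"] == 1.0
    assert tab.loc["GROUP", "F"] > 0 or tab.loc["GROUP", "F"] == np.inf


def test_incomplete_design_rejected():
    rng = np.random.default_rng(2)
    df = make_design(rng, (3, 3), 2, 3).iloc[:-1]
    with pytest.raises(ValueError):
        bh.mixed_anova(df)


def test_diagnostics_include_levene_and_mauchly():
    rng = np.random.default_rng(3)
    df = make_design(rng, (5, 5, 4), 2, 4)
    tab = bh.mixed_anova(df, diagnostics=True)
    diag = tab.attrs["diagnostics"]
    assert "levene" in diag and "mauchly_repeat" in diag
    w, chi2, ddf, p = diag["mauchly_repeat"]
    assert 0 < w <= 1 and ddf == 5  # k=4 levels -> (k-1)k/2 - 1 = 5


def test_mauchly_matches_pingouin_reference():
    """Cross-check the sphericity statistic against an independent package."""
    pytest.importorskip("pingouin")
    import pingouin as pg

    rng = np.random.default_rng(4)
    df = make_design(rng, (8,), 2, 4)
    tab = bh.mixed_anova(df, diagnostics=True)
    w, chi2, ddf, p = tab.attrs["diagnostics"]["mauchly_repeat"]
    sub = df.groupby(["subject", "repeat"])["value"].mean().reset_index()
    spher = pg.sphericity(sub, dv="value", subject="subject", within="repeat")
    assert w == pytest.approx(spher.W, rel=1e-6)
    assert p == pytest.approx(spher.pval, rel=1e-6)


def test_fisher_lsd_reproduces_two_group_t():
    from scipy import stats as st

    a = np.array([1.0, 2.0, 3.0, 4.0])
    b = np.array([2.0, 4.0, 5.0, 6.0])
    mse = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / 6
    lsd = bh.fisher_lsd(pd.Series({"a": a.mean(), "b": b.mean()}),
                        pd.Series({"a": 4, "b": 4}), mse, 6)
    t_ref, p_ref = st.ttest_ind(a, b, equal_var=True)
    assert lsd.t.iloc[0] == pytest.approx(t_ref)
    assert lsd.p.iloc[0] == pytest.approx(p_ref)
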