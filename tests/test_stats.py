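"""Median split, mixed factorial ANOVA, pairwise tests, and correlations.

The ANOVA is checked two independent ways: a brute-force textbook
sums-of-squares oracle written with plain loops over cell means, and R's
``aov`` with an ``Error(subject/(task*cond))`` stratum specification.
"""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import singacc as sa
from singacc.errors import DesignError, DomainError, InsufficientDataError
from singacc.stats import (
    mixed_anova,
    nf_hf_equivalence,
    pairwise_by_condition,
    partial_correlation,
    partial_r_formula,
    pearson,
)


def _records(avgs):
    return [
        sa.ParticipantRecord(f"P{i}", bais_v=a, bais_c=a, years_performing=1.0,
                             years_theory=1.0)
        for i, a in enumerate(avgs)
    ]


class TestMedianSplit:
    def test_even_split(self):
        recs, med = sa.median_split(_records([1, 2, 3, 4]))
        assert med == pytest.approx(2.5)
        groups = {r.participant_id: r.bais_group for r in recs}
        assert groups == {"P0": "low", "P1": "low", "P2": "high", "P3": "high"}

    def test_reported_median_value(self):
        """A cohort whose BAIS averages straddle 5.02 reports that threshold."""
        recs, med = sa.median_split(_records([4.5, 5.0, 5.04, 6.0]))
        assert med == pytest.approx(5.02)

    def test_tie_at_median_goes_low(self):
        recs, _ = sa.median_split(_records([4.0, 5.0, 6.0]))
        assert {r.bais_avg: r.bais_group for r in recs}[5.0] == "low"

    def test_degenerate_split_rejected(self):
        with pytest.raises(DesignError):
            sa.median_split(_records([5.0, 5.0, 5.0]))


def _random_design(rng, a=2, n=3, b=2, c=3, effect=0.0):
    rows = []
    for gi in range(a):
        for s in range(n):
            sid = f"g{gi}s{s}"
            subj_eff = rng.normal(0, 0.5)
            for t in range(b):
                for k in range(c):
                    rows.append(
                        dict(participant_id=sid, bais_group=f"g{gi}",
                             task=f"t{t}", condition=f"c{k}",
                             value=rng.normal(gi * effect + subj_eff, 1.0))
                    )
    return pd.DataFrame(rows)


def brute_force_mixed_anova(df):
    """Textbook cell-means SS partition for the equal-n mixed design."""
    groups = sorted(df.bais_group.unique())
    tasks = sorted(df.task.unique())
    conds = sorted(df.condition.unique())
    subjects = sorted(df.participant_id.unique())
    g_of = {s: df[df.participant_id == s].bais_group.iloc[0] for s in subjects}
    a, b, c = len(groups), len(tasks), len(conds)
    n = len(subjects) // a
    N = len(subjects)

    def m(**sel):
        sub = df
        for k, v in sel.items():
            sub = sub[sub[k] == v]
        return sub.value.mean()

    M = df.value.mean()
    ss = {}
    ss["A"] = n * b * c * sum((m(bais_group=g) - M) ** 2 for g in groups)
    ss["S"] = b * c * sum(
        (m(participant_id=s) - m(bais_group=g_of[s])) ** 2 for s in subjects
    )
    ss["T"] = N * c * sum((m(task=t) - M) ** 2 for t in tasks)
    ss["AT"] = n * c * sum(
        (m(bais_group=g, task=t) - m(bais_group=g) - m(task=t) + M) ** 2
        for g in groups for t in tasks
    )
    ss["TS"] = c * sum(
        (m(participant_id=s, task=t) - m(participant_id=s)
         - m(bais_group=g_of[s], task=t) + m(bais_group=g_of[s])) ** 2
        for s in subjects for t in tasks
    )
    ss["C"] = N * b * sum((m(condition=k) - M) ** 2 for k in conds)
    ss["AC"] = n * b * sum(
        (m(bais_group=g, condition=k) - m(bais_group=g) - m(condition=k) + M) ** 2
        for g in groups for k in conds
    )
    ss["CS"] = b * sum(
        (m(participant_id=s, condition=k) - m(participant_id=s)
         - m(bais_group=g_of[s], condition=k) + m(bais_group=g_of[s])) ** 2
        for s in subjects for k in conds
    )
    ss["TC"] = n * a * sum(
        (m(task=t, condition=k) - m(task=t) - m(condition=k) + M) ** 2
        for t in tasks for k in conds
    )
    ss["ATC"] = n * sum(
        (m(bais_group=g, task=t, condition=k) - m(bais_group=g, task=t)
         - m(bais_group=g, condition=k) - m(task=t, condition=k)
         + m(bais_group=g) + m(task=t) + m(condition=k) - M) ** 2
        for g in groups for t in tasks for k in conds
    )
    ss["resid"] = sum(
        (row.value
         - m(participant_id=row.participant_id, task=row.task)
         - m(participant_id=row.participant_id, condition=row.condition)
         - m(bais_group=g_of[row.participant_id], task=row.task,
             condition=row.condition)
         + m(participant_id=row.participant_id)
         + m(bais_group=g_of[row.participant_id], task=row.task)
         + m(bais_group=g_of[row.participant_id], condition=row.condition)
         - m(bais_group=g_of[row.participant_id])) ** 2
        for row in df.itertuples()
    )
    f = {
        "A": (ss["A"] / (a - 1)) / (ss["S"] / (N - a)),
        "T": (ss["T"] / (b - 1)) / (ss["TS"] / ((N - a) * (b - 1))),
        "AT": (ss["AT"] / ((a - 1) * (b - 1))) / (ss["TS"] / ((N - a) * (b - 1))),
        "C": (ss["C"] / (c - 1)) / (ss["CS"] / ((N - a) * (c - 1))),
        "AC": (ss["AC"] / ((a - 1) * (c - 1))) / (ss["CS"] / ((N - a) * (c - 1))),
        "TC": (ss["TC"] / ((b - 1) * (c - 1)))
        / (ss["resid"] / ((N - a) * (b - 1) * (c - 1))),
        "ATC": (ss["ATC"] / ((a - 1) * (b - 1) * (c - 1)))
        / (ss["resid"] / ((N - a) * (b - 1) * (c - 1))),
    }
    return ss, f


ORACLE_MAP = {
    "A": "bais_group", "T": "task", "AT": "bais_group*task",
    "C": "condition", "AC": "bais_group*condition",
    "TC": "task*condition", "ATC": "bais_group*task*condition",
}


class TestMixedAnova:
    @pytest.mark.parametrize("dims", [(2, 2, 2, 2), (2, 3, 2, 3), (3, 2, 3, 3)])
    def test_matches_brute_force_oracle(self, rng, dims):
        a, n, b, c = dims
        df = _random_design(rng, a=a, n=n, b=b, c=c, effect=0.4)
        res = mixed_anova(df)
        ss_o, f_o = brute_force_mixed_anova(df)
        for key, name in ORACLE_MAP.items():
            assert res.effect(name)["F"] == pytest.approx(f_o[key], abs=1e-8), name
            assert res.effect(name)["ss"] == pytest.approx(ss_o[key], abs=1e-8)

    def test_ss_conservation_per_stratum(self, rng):
        df = _random_design(rng, a=2, n=4, b=3, c=2, effect=0.3)
        res = mixed_anova(df)
        tab = res.table.set_index("effect")["ss"]
        assert (tab["bais_group"] + tab["subjects(bais_group)"]
                == pytest.approx(res.strata["between"], rel=1e-8))
        assert (tab["task"] + tab["bais_group*task"] + tab["task*subjects"]
                == pytest.approx(res.strata["task"], rel=1e-8))
        assert (tab["condition"] + tab["bais_group*condition"]
                + tab["condition*subjects"]
                == pytest.approx(res.strata["condition"], rel=1e-8))
        assert (tab["task*condition"] + tab["bais_group*task*condition"]
                + tab["task*condition*subjects"]
                == pytest.approx(res.strata["task*condition"], rel=1e-8))
        assert tab.sum() == pytest.approx(
            ((df.value - df.value.mean()) ** 2).sum(), rel=1e-8
        )

    def test_all_identical_values_flagged(self):
        df = _random_design(np.random.default_rng(0), a=2, n=2, b=2, c=2)
        df["value"] = 1.0
        res = mixed_anova(df)
        assert (res.table[res.table.error_term != ""]["F"] == 0).all()
        assert res.flags

    def test_greenhouse_geisser_epsilon_matches_pingouin(self, rng):
        """Per-stratum GG epsilon agrees with pingouin on the group-centered
        collapsed data; 2-level factors have epsilon exactly 1."""
        pg = pytest.importorskip("pingouin")
        from singacc.stats import _gg_epsilons

        df = _random_design(rng, a=2, n=6, b=3, c=4)
        # induce a sphericity violation: scale conditions differently
        scale = df["condition"].map({"c0": 0.5, "c1": 1.0, "c2": 2.0, "c3": 3.0})
        df["value"] = df["value"] * scale
        eps = _gg_epsilons(df, "value", "participant_id", "bais_group",
                           ("task", "condition"))
        grp = df.drop_duplicates("participant_id").set_index(
            "participant_id")["bais_group"]
        for factor in ("task", "condition"):
            coll = df.groupby(["participant_id", factor], as_index=False
                              ).value.mean()
            wide = coll.pivot(index="participant_id", columns=factor,
                              values="value")
            cent = (wide - wide.groupby(grp).transform("mean")).reset_index(
            ).melt(id_vars="participant_id", value_name="v")
            theirs = float(pg.epsilon(cent, subject="participant_id",
                                      within=factor, dv="v", correction="gg"))
            assert eps[factor] == pytest.approx(theirs, abs=1e-10)
        res = mixed_anova(df, sphericity="greenhouse-geisser")
        row = res.effect("condition")
        assert row["eps"] < 1.0 and row["p_gg"] >= row["p"]
        # a 2-level within factor is always spherical
        df2 = _random_design(rng, a=2, n=4, b=2, c=3)
        eps2 = _gg_epsilons(df2, "value", "participant_id", "bais_group",
                            ("task", "condition"))
        assert eps2["task"] == pytest.approx(1.0)

    def test_missing_cell_rejected(self, rng):
        df = _random_design(rng).iloc[:-1]
        with pytest.raises(DesignError, match="missing"):
            mixed_anova(df)

    def test_duplicate_cell_rejected(self, rng):
        df = _random_design(rng)
        df = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(DesignError):
            mixed_anova(df)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="R not available for the cross-check")
    def test_matches_r_aov(self, rng, tmp_path):
        """Independent oracle: R's aov with Error(subject/(task*condition))."""
        df = _random_design(rng, a=2, n=4, b=2, c=3, effect=0.5)
        data = tmp_path / "d.csv"
        out = tmp_path / "out.csv"
        df.to_csv(data, index=False)
        script = tmp_path / "aov.R"
        script.write_text(
            f"""
d <- read.csv('{data}')
for (col in c('participant_id','bais_group','task','condition'))
  d[[col]] <- factor(d[[col]])
a <- aov(value ~ bais_group*task*condition +
         Error(participant_id/(task*condition)), data=d)
s <- summary(a)
out <- data.frame()
for (str in s) {{
  t <- as.data.frame(str[[1]]); t$term <- trimws(rownames(t))
  out <- rbind(out, t)
}}
write.csv(out, '{out}', row.names=FALSE)
"""
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        r_tab = pd.read_csv(out).set_index("term")
        res = mixed_anova(df)
        pairs = {
            "bais_group": "bais_group", "task": "task",
            "bais_group:task": "bais_group*task", "condition": "condition",
            "bais_group:condition": "bais_group*condition",
            "task:condition": "task*condition",
            "bais_group:task:condition": "bais_group*task*condition",
        }
        for r_name, name in pairs.items():
            assert res.effect(name)["F"] == pytest.approx(
                r_tab.loc[r_name, "F value"], rel=1e-8
            ), name


class TestPairwise:
    def _frame(self, hi, lo, cond="PS_WHOLE"):
        rows = [dict(condition=cond, bais_group="high", v=x) for x in hi]
        rows += [dict(condition=cond, bais_group="low", v=x) for x in lo]
        return pd.DataFrame(rows)

    def test_identical_groups_t_zero(self):
        res = pairwise_by_condition(self._frame([1, 2, 3], [1, 2, 3]), dv="v")
        row = res.table.iloc[0]
        assert row.t == pytest.approx(0.0) and row.p_raw == pytest.approx(1.0)

    def test_textbook_t(self):
        res = pairwise_by_condition(self._frame([1, 2, 3], [4, 5, 6]), dv="v")
        row = res.table.iloc[0]
        # pooled SD = 1, SE = sqrt(2/3), t = -3/SE
        assert row.t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-10)
        assert row.df == 4

    def test_bonferroni_definition(self):
        df = pd.concat([
            self._frame([1.0, 2.0, 3.1], [3.0, 4.0, 5.0], cond="A"),
            self._frame([1.0, 2.0, 3.0], [2.0, 3.0, 4.5], cond="B"),
        ])
        res = pairwise_by_condition(df, dv="v", conditions=["A", "B"])
        assert res.family_size == 2
        assert np.allclose(res.table.p_bonf,
                           np.minimum(1.0, 2 * res.table.p_raw))

    def test_empty_group_rejected(self):
        df = self._frame([1, 2, 3], [])
        with pytest.raises(InsufficientDataError):
            pairwise_by_condition(df, dv="v", conditions=["PS_WHOLE"])


class TestCorrelations:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson(x, x).r == pytest.approx(1.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        r = pearson(x, y).r
        manual = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert r == pytest.approx(manual, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DomainError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_partial_formula_worked_example(self):
        assert partial_r_formula(0.6, 0.5, 0.5) == pytest.approx(0.4667, abs=1e-4)

    def test_partial_formula_vs_residual_regression(self, rng):
        """The two definitions agree to 1e-10 on random trivariate data."""
        for _ in range(30):
            z = rng.normal(size=60)
            x = 0.4 * z + rng.normal(size=60)
            y = -0.3 * z + rng.normal(size=60)
            r_resid = partial_correlation(x, y, z).r
            r_form = partial_r_formula(
                pearson(x, y).r, pearson(x, z).r, pearson(y, z).r
            )
            assert r_resid == pytest.approx(r_form, abs=1e-10)

    def test_uncorrelated_control_returns_full_r(self, rng):
        """With a control orthogonal to x and y, partial r equals full r."""
        x = rng.normal(size=50)
        y = 0.6 * x + rng.normal(size=50)
        z = rng.normal(size=50)
        # orthogonalize z against x and y in-sample
        d = np.column_stack([np.ones(50), x, y])
        z = z - d @ np.linalg.lstsq(d, z, rcond=None)[0]
        assert partial_correlation(x, y, z).r == pytest.approx(
            pearson(x, y).r, abs=1e-10
        )

    def test_empty_control_set_equals_full(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        res = partial_correlation(x, y)
        assert res.kind == "full" and res.r == pytest.approx(pearson(x, y).r)

    def test_control_equal_to_x_degenerate(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        with pytest.raises(DomainError):
            partial_correlation(x, y, x)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        z = rng.normal(size=45)
        x = 0.5 * z + rng.normal(size=45)
        y = 0.5 * z + rng.normal(size=45)
        ours = partial_correlation(x, y, z)
        theirs = pg.partial_corr(pd.DataFrame(dict(x=x, y=y, z=z)),
                                 x="x", y="y", covar="z")
        assert ours.r == pytest.approx(float(theirs["r"].iloc[0]), abs=1e-10)
        assert ours.p == pytest.approx(float(theirs["p_val"].iloc[0]), abs=1e-8)


class TestNfHfEquivalence:
    def _measures(self, delta=0.0):
        rows = []
        for pid in ("P1", "P2", "P3"):
            for task in ("Normal", "Toggled"):
                base = hash((pid, task)) % 7 + 5.0
                rows.append(dict(participant_id=pid, task=task, condition="NF",
                                 trd=0.4, cv=base))
                rows.append(dict(participant_id=pid, task=task, condition="HF",
                                 trd=0.4, cv=base + delta))
        return pd.DataFrame(rows)

    def test_identical_controls_t_zero(self):
        tab = nf_hf_equivalence(self._measures()).set_index("measure")
        assert tab.loc["cv", "t"] == 0.0 and tab.loc["cv", "p"] == 1.0

    def test_systematic_offset_detected(self):
        tab = nf_hf_equivalence(self._measures(delta=2.0)).set_index("measure")
        assert tab.loc["cv", "p"] < 0.01

    def test_missing_pair_rejected(self):
        df = self._measures().iloc[:-1]
        with pytest.raises(DesignError):
            nf_hf_equivalence(df)
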