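"""Split-plot ANOVA engine: df structure, F values, error strata."""

import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from licksupp.anova import DesignSpec, MixedAnova, paired_t, rm_anova, welch_t
from licksupp.events import ValidationError
from conftest import make_balanced, naive_split_plot


def _effects_by_name(results):
    return {r.effect: r for r in results}


class TestDegreesOfFreedom:
    def test_full_extinction_design(self, rng):
        """2 groups x 16 subjects, within Session(2) x Trial(18) x CS(2)."""
        df = make_balanced(16, {"session": [1, 2],
                                "trial": list(range(1, 19)),
                                "window": ["pre_cs", "cs"]}, rng)
        res = _effects_by_name(rm_anova(df, _design(df, ("session", "trial",
                                                         "window"))))
        assert (res["Group"].df_num, res["Group"].df_den) == (1, 30)
        assert (res["Trial"].df_num, res["Trial"].df_den) == (17, 510)
        assert (res["Session"].df_num, res["Session"].df_den) == (1, 30)
        assert (res["CS"].df_num, res["CS"].df_den) == (1, 30)
        assert (res["Session × CS"].df_num, res["Session × CS"].df_den) == (1, 30)
        assert (res["Group × Trial"].df_num,
                res["Group × Trial"].df_den) == (17, 510)
        assert len(res) == 15

    def test_memory_design(self, rng):
        """2 groups x 16 subjects, within Session(3) x CS(2)."""
        df = make_balanced(16, {"session": ["a", "b", "c"],
                                "window": ["pre_cs", "cs"]}, rng)
        res = _effects_by_name(rm_anova(df, _design(df, ("session", "window"))))
        assert (res["Group × Session"].df_num,
                res["Group × Session"].df_den) == (2, 60)
        assert (res["Session"].df_num, res["Session"].df_den) == (2, 60)
        assert (res["CS"].df_num, res["CS"].df_den) == (1, 30)
        assert len(res) == 7  # Group, Session, CS + 4 interactions


def _design(df, within, display=None):
    return DesignSpec(
        between="group", between_levels=tuple(sorted(df["group"].unique())),
        within={w: tuple(sorted(df[w].unique())) for w in within},
        display=dict(display or {"window": "CS"}))


class TestFStatistics:
    def test_single_within_factor_equals_paired_t_squared(self, rng):
        """With one 2-level within factor and no between factor, the
        within F is the square of the paired t on the level difference
        (classical identity)."""
        df = make_balanced(8, {"w": ["lo", "hi"]}, rng, groups=("A",))
        res = _effects_by_name(rm_anova(df, _design(df, ("w",), display={})))
        lo = df[df.w == "lo"].sort_values("subject")["value"].to_numpy()
        hi = df[df.w == "hi"].sort_values("subject")["value"].to_numpy()
        t, dof, _ = paired_t(hi, lo)
        assert res["W"].F == pytest.approx(t ** 2, rel=1e-10)
        assert res["W"].df_den == dof

    def test_within_design_matches_statsmodels_anova_rm(self, rng):
        """Independent oracle for the purely within decomposition."""
        pytest.importorskip("statsmodels")
        from statsmodels.stats.anova import AnovaRM
        df = make_balanced(6, {"w1": ["x", "y"], "w2": [1, 2, 3]}, rng,
                           groups=("A",))
        sm = AnovaRM(df, depvar="value", subject="subject",
                     within=["w1", "w2"]).fit().anova_table
        res = _effects_by_name(rm_anova(df, _design(df, ("w1", "w2"),
                                                    display={})))
        for rname, mine in (("w1", "W1"), ("w2", "W2"), ("w1:w2", "W1 × W2")):
            assert res[mine].F == pytest.approx(sm.loc[rname, "F Value"],
                                                rel=1e-8)
            assert res[mine].df_num == sm.loc[rname, "Num DF"]
            assert res[mine].df_den == sm.loc[rname, "Den DF"]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_naive_cell_mean_oracle(self, seed):
        """Random 2-group x 2x3 within datasets: every SS, df and F matches
        the loop-based textbook formulas, and the SS decompose the total."""
        r = np.random.default_rng(seed)
        df = make_balanced(4, {"w1": ["x", "y"], "w2": [1, 2, 3]}, r)
        res = rm_anova(df, _design(df, ("w1", "w2"), display={}))
        oracle = naive_split_plot(df, within=("w1", "w2"))
        key = {"Group": ("group",), "W1": ("group", "w1")[1:],
               "W2": ("w2",), "Group × W1": ("group", "w1"),
               "Group × W2": ("group", "w2"), "W1 × W2": ("w1", "w2"),
               "Group × W1 × W2": ("group", "w1", "w2")}
        by_name = _effects_by_name(res)
        ss_sum = 0.0
        for name, cols in key.items():
            ss, dfn, dfe, F = oracle[cols]
            assert by_name[name].ss == pytest.approx(ss, rel=1e-9, abs=1e-12)
            assert by_name[name].df_num == dfn
            assert by_name[name].df_den == dfe
            assert by_name[name].F == pytest.approx(F, rel=1e-9)
            ss_sum += ss
        # SS conservation: effects + error strata = total
        strata = {tuple(sorted(set(c) - {"group"})): r_.ss_error
                  for c, r_ in zip(key.values(), [by_name[n] for n in key])}
        total = ((df["value"] - df["value"].mean()) ** 2).sum()
        assert ss_sum + sum(strata.values()) == pytest.approx(total, rel=1e-8)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="R not available")
    def test_matches_r_aov_error_strata(self, rng, tmp_path):
        """Independent oracle: R's aov with Error(subject/(w1*w2))."""
        df = make_balanced(4, {"w1": ["x", "y"], "w2": [1, 2, 3]}, rng)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = f"""
        d <- read.csv("{csv}")
        for (c in c("subject","group","w1","w2")) d[[c]] <- factor(d[[c]])
        m <- aov(value ~ group*w1*w2 + Error(subject/(w1*w2)), data=d)
        s <- summary(m)
        for (stratum in s) {{
          tab <- stratum[[1]]
          for (i in seq_len(nrow(tab))) {{
            f <- tab[i, "F value"]
            if (!is.na(f)) cat(trimws(rownames(tab)[i]), f, "\\n")
          }}
        }}
        """
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True).stdout
        r_f = {}
        for line in out.strip().splitlines():
            parts = line.split()
            r_f[" ".join(parts[:-1])] = float(parts[-1])
        res = _effects_by_name(rm_anova(df, _design(df, ("w1", "w2"),
                                                    display={})))
        mapping = {"group": "Group", "w1": "W1", "w2": "W2",
                   "group:w1": "Group × W1", "group:w2": "Group × W2",
                   "w1:w2": "W1 × W2", "group:w1:w2": "Group × W1 × W2"}
        assert len(r_f) == 7
        for rname, f in r_f.items():
            assert res[mapping[rname]].F == pytest.approx(f, rel=1e-5)


class TestValidation:
    def test_missing_cell_rejected(self, rng):
        df = make_balanced(3, {"w": [1, 2]}, rng)
        with pytest.raises(ValidationError, match="missing"):
            rm_anova(df.iloc[:-1], _design(df, ("w",)))

    def test_duplicate_cell_rejected(self, rng):
        df = make_balanced(3, {"w": [1, 2]}, rng)
        dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValidationError, match="duplicated"):
            rm_anova(dup, _design(df, ("w",)))

    def test_unequal_groups_rejected(self, rng):
        df = make_balanced(3, {"w": [1, 2]}, rng)
        df = df[df.subject != "A0"]
        with pytest.raises(ValidationError, match="equal sizes"):
            rm_anova(df, _design(df, ("w",)))


class TestTTests:
    def test_paired_identical_is_null(self):
        t, df, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_paired_df_is_n_minus_1(self, rng):
        x = rng.normal(size=32)
        y = x + rng.normal(size=32)
        t, df, p = paired_t(x, y)
        assert df == 31
        t2, p2 = stats.ttest_rel(x, y)[:2]
        assert t == pytest.approx(t2) and p == pytest.approx(p2)

    def test_paired_zero_variance_sentinel(self):
        with pytest.warns(UserWarning, match="zero variance"):
            t, df, p = paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_welch_matches_hand_satterthwaite(self):
        """Hand computation of the Welch statistic and df."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 4.0, 9.0, 11.0])
        v1, v2 = x.var(ddof=1), y.var(ddof=1)
        n1, n2 = len(x), len(y)
        se2 = v1 / n1 + v2 / n2
        t_hand = (x.mean() - y.mean()) / np.sqrt(se2)
        df_hand = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1)
                              + (v2 / n2) ** 2 / (n2 - 1))
        t, df, p = welch_t(x, y)
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert df == pytest.approx(df_hand, rel=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), df_hand),
                                  rel=1e-12)
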