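"""t tests, split-plot ANOVA and Bonferroni adjustment against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lickometry import (
    bonferroni_adjust,
    bonferroni_pairwise,
    format_p,
    mixed_anova,
    paired_t,
    rm_anova,
    t_p_two_tailed,
    unpaired_t,
)


class TestTP:
    def test_zero_t_gives_one(self):
        assert t_p_two_tailed(0.0, 7) == pytest.approx(1.0)

    def test_matches_scipy_on_grid(self):
        for t in (0.5, 1.2, 2.9, 4.4):
            for df in (3, 7, 14, 22):
                assert t_p_two_tailed(t, df) == pytest.approx(
                    2 * sps.t.sf(t, df), rel=1e-12
                )

    def test_sign_invariance(self):
        assert t_p_two_tailed(-2.5, 9) == t_p_two_tailed(2.5, 9)

    def test_monotone_decreasing_in_abs_t(self):
        ps = [t_p_two_tailed(t, 7) for t in np.linspace(0.1, 6.0, 40)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_increasing_in_df_for_fixed_t(self):
        ps = [t_p_two_tailed(2.5, df) for df in range(2, 40)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_df_below_one_rejected(self):
        with pytest.raises(ValueError):
            t_p_two_tailed(1.0, 0.5)

    def test_display_floor(self):
        assert format_p(0.0004) == "<0.001"
        assert format_p(0.0062) == "0.006"


class TestPairedT:
    def test_zero_variance_guard(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t([2, 3, 4, 5], [1, 2, 3, 4])

    def test_identical_vectors_zero_variance(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_equal_means_unequal_values(self):
        res = paired_t([1.0, 3.0], [3.0, 1.0])
        assert res.t == pytest.approx(0.0)
        assert res.p_two_tailed == pytest.approx(1.0)

    def test_matches_direct_formula_and_scipy(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            res = paired_t(x, y)
            d = x - y
            t_direct = d.mean() / (d.std(ddof=1) / math.sqrt(8))
            assert res.t == pytest.approx(t_direct, abs=1e-10)
            ref = sps.ttest_rel(x, y)
            assert res.t == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p_two_tailed == pytest.approx(ref.pvalue, abs=1e-12)
            assert res.df == 7

    def test_unpaired_matches_scipy(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=10), rng.normal(1.0, 2.0, size=12)
        for welch in (False, True):
            res = unpaired_t(x, y, welch=welch)
            ref = sps.ttest_ind(x, y, equal_var=not welch)
            assert res.t == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p_two_tailed == pytest.approx(ref.pvalue, abs=1e-12)


def _balanced_data(rng, g=3, n=8, l=4, group_effect=0.0):
    rows = []
    for gi in range(g):
        for si in range(n):
            subj = f"g{gi}s{si}"
            subj_re = rng.normal(0, 1.0)
            for li in range(l):
                rows.append(
                    {
                        "subject": subj,
                        "group": f"g{gi}",
                        "level": f"l{li}",
                        "value": rng.normal(0, 1.0)
                        + subj_re
                        + group_effect * gi
                        + 0.3 * li,
                    }
                )
    return pd.DataFrame(rows)


def anova_ss_by_projection(df):
    """Independent oracle: sequential least-squares on explicit dummy design
    matrices.  Each effect's SS is the drop in residual SS when its columns
    join the model (orthogonal for a balanced design)."""
    y = df["value"].to_numpy(dtype=float)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    one = np.ones((len(df), 1))
    G = pd.get_dummies(df["group"]).to_numpy(dtype=float)
    S = pd.get_dummies(df["subject"]).to_numpy(dtype=float)
    L = pd.get_dummies(df["level"]).to_numpy(dtype=float)
    GL = pd.get_dummies(df["group"] + ":" + df["level"]).to_numpy(dtype=float)
    SL = pd.get_dummies(df["subject"] + ":" + df["level"]).to_numpy(dtype=float)

    models = [
        one,
        np.hstack([one, G]),
        np.hstack([one, G, S]),
        np.hstack([one, G, S, L]),
        np.hstack([one, G, S, L, GL]),
        np.hstack([one, G, S, L, GL, SL]),
    ]
    r = [rss(X) for X in models]
    return {
        "group": r[0] - r[1],
        "subjects_within_group": r[1] - r[2],
        "level": r[2] - r[3],
        "group:level": r[3] - r[4],
        "level_x_subjects_within_group": r[4] - r[5],
    }


class TestMixedAnova:
    def test_matches_projection_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            df = _balanced_data(rng, group_effect=0.5)
            table = mixed_anova(df).set_index("effect")
            oracle = anova_ss_by_projection(df)
            for effect, ss in oracle.items():
                assert table.loc[effect, "ss"] == pytest.approx(ss, abs=1e-8)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(13)
        df = _balanced_data(rng, group_effect=0.7)
        ours = mixed_anova(df).set_index("effect")
        ref = pingouin.mixed_anova(
            data=df, dv="value", within="level", between="group", subject="subject"
        ).set_index("Source")
        assert ours.loc["group", "F"] == pytest.approx(ref.loc["group", "F"], rel=1e-6)
        assert ours.loc["level", "F"] == pytest.approx(ref.loc["level", "F"], rel=1e-6)
        assert ours.loc["group:level", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-6
        )
        assert ours.loc["group", "p"] == pytest.approx(
            ref.loc["group", "p_unc"], rel=1e-6
        )

    def test_ss_conservation(self):
        rng = np.random.default_rng(14)
        df = _balanced_data(rng)
        table = mixed_anova(df)
        assert table["ss"].sum() == pytest.approx(table.attrs["ss_total"], rel=1e-10)
        # dfs partition the total
        assert table["df"].sum() == len(df) - 1

    def test_constant_data_flagged(self):
        rows = [
            {"subject": f"g{g}s{s}", "group": f"g{g}", "level": f"l{li}", "value": 5.0}
            for g in range(2)
            for s in range(3)
            for li in range(2)
        ]
        table = mixed_anova(pd.DataFrame(rows))
        assert (table["ss"] == 0).all()
        assert table["F"].dropna().empty

    def test_parallel_profiles_have_zero_interaction(self):
        # group means differ, within-level pattern identical: interaction SS = 0
        rows = []
        for g, offset in enumerate((0.0, 2.0, 5.0)):
            for s in range(4):
                for li, lv in enumerate((1.0, 3.0)):
                    rows.append(
                        {
                            "subject": f"g{g}s{s}",
                            "group": f"g{g}",
                            "level": f"l{li}",
                            "value": offset + lv,
                        }
                    )
        table = mixed_anova(pd.DataFrame(rows)).set_index("effect")
        assert table.loc["group:level", "ss"] == pytest.approx(0.0, abs=1e-12)

    def test_unbalanced_design_rejected(self):
        rng = np.random.default_rng(15)
        df = _balanced_data(rng).iloc[:-1]
        with pytest.raises(ValueError, match="balanced|complete"):
            mixed_anova(df)

    def test_rm_anova_matches_statsmodels(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(16)
        rows = [
            {"subject": f"s{s}", "level": f"l{li}", "value": rng.normal() + 0.4 * li}
            for s in range(8)
            for li in range(3)
        ]
        df = pd.DataFrame(rows)
        ours = rm_anova(df).set_index("effect")
        ref = AnovaRM(df, "value", "subject", within=["level"]).fit()
        assert ours.loc["level", "F"] == pytest.approx(
            float(ref.anova_table["F Value"].iloc[0]), rel=1e-8
        )


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,family,expected", [(0.01, 5, 0.05), (0.5, 3, 1.0), (0.2, 1, 0.2)]
    )
    def test_adjustment(self, p, family, expected):
        assert bonferroni_adjust(p, family) == pytest.approx(expected)

    def test_pairwise_family_documented(self):
        rng = np.random.default_rng(17)
        df = _balanced_data(rng, g=3, n=6, l=2, group_effect=1.0)
        table = bonferroni_pairwise(df)
        assert (table["family_size"] == 6).all()  # 3 pairs x 2 levels
        assert np.all(table["p_adjusted"] >= table["p_raw"] - 1e-15)
        assert np.all(table["p_adjusted"] <= 1.0)
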