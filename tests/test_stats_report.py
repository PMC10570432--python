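"""Statistics battery tests with independent oracles.

The Mann-Whitney p-value is checked against brute-force enumeration of all
group labelings; the mixed ANOVA against a hand-rolled split-plot
sum-of-squares decomposition; the t tests against the textbook formulas.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pvligt import (
    effect_size_r,
    group_t_tests,
    mann_whitney,
    net_score_anova,
    render_report,
    spearman,
)
from pvligt.stats_report import (
    block_net_score_table,
    bonferroni,
    net_scores_long,
    parameter_comparison_table,
    severity_correlation_table,
)


# -- independent oracles --------------------------------------------------


def enumerate_mw_p(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all labelings."""
    x, y = list(x), list(y)
    pooled = x + y
    n1, n = len(x), len(x) + len(y)
    mu = len(x) * len(y) / 2.0

    def u1_of(idx):
        ranks = stats.rankdata(pooled)
        return sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2.0

    obs = abs(u1_of(range(n1)) - mu)
    count = total = 0
    for idx in itertools.combinations(range(n), n1):
        total += 1
        if abs(u1_of(idx) - mu) >= obs - 1e-9:
            count += 1
    return count / total


def splitplot_anova_oracle(scores, groups):
    """F and partial eta^2 for a balanced two-group repeated-measures design,
    from the raw sum-of-squares decomposition."""
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    n, b = scores.shape
    grand = scores.mean()
    labels = pd.unique(groups)
    subj_mean = scores.mean(axis=1)
    block_mean = scores.mean(axis=0)
    ss_between_subj = b * ((subj_mean - grand) ** 2).sum()
    ss_group = sum(
        b * (groups == g).sum() * (scores[groups == g].mean() - grand) ** 2
        for g in labels
    )
    ss_subj = ss_between_subj - ss_group
    ss_block = n * ((block_mean - grand) ** 2).sum()
    ss_inter = sum(
        (groups == g).sum()
        * (scores[groups == g, j].mean() - scores[groups == g].mean()
           - block_mean[j] + grand) ** 2
        for g in labels
        for j in range(b)
    )
    ss_within = ((scores - subj_mean[:, None]) ** 2).sum()
    ss_err = ss_within - ss_block - ss_inter
    df_group, df_subj = len(labels) - 1, n - len(labels)
    df_block = b - 1
    df_inter = df_group * df_block
    df_err = df_block * df_subj
    out = {
        "group": ((ss_group / df_group) / (ss_subj / df_subj),
                  ss_group / (ss_group + ss_subj)),
        "block": ((ss_block / df_block) / (ss_err / df_err),
                  ss_block / (ss_block + ss_err)),
        "interaction": ((ss_inter / df_inter) / (ss_err / df_err),
                        ss_inter / (ss_inter + ss_err)),
    }
    return out


# -- Mann-Whitney ---------------------------------------------------------


class TestMannWhitney:
    def test_balanced_symmetric_case(self):
        res = mann_whitney([1.0, 4.0], [2.0, 3.0])
        assert res.u == res.u1 == res.u2 == 2.0  # n1*n2/2

    def test_u_complement_identity(self, rng):
        for _ in range(10):
            x = rng.normal(size=rng.integers(3, 15))
            y = rng.normal(size=rng.integers(3, 15))
            res = mann_whitney(x, y)
            assert res.u1 + res.u2 == pytest.approx(len(x) * len(y))
            assert 0 <= res.u <= len(x) * len(y)

    def test_printed_effect_sizes_from_z(self):
        # effect sizes as published: r = |Z| / sqrt(94)
        assert effect_size_r(5.033, 94) == pytest.approx(0.52, abs=0.005)
        assert effect_size_r(3.936, 94) == pytest.approx(0.41, abs=0.005)
        assert effect_size_r(2.034, 94) == pytest.approx(0.21, abs=0.005)

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_small_sample_p_matches_enumeration(self, n, rng):
        for rep in range(3):
            x = rng.normal(size=n)
            y = rng.normal(loc=0.8, size=n)
            res = mann_whitney(x, y)  # auto -> exact path here
            assert res.method == "exact"
            assert res.p == pytest.approx(enumerate_mw_p(x, y), abs=0.02)

    def test_asymptotic_approaches_exact_at_moderate_n(self, rng):
        # the documented quality of the continuity-corrected normal Z
        x = rng.normal(size=8)
        y = rng.normal(loc=1.0, size=8)
        exact = mann_whitney(x, y, method="exact").p
        asym = mann_whitney(x, y, method="asymptotic").p
        assert asym == pytest.approx(exact, abs=0.03)

    def test_tie_correction_matches_scipy(self, rng):
        x = np.round(rng.normal(size=25), 1)
        y = np.round(rng.normal(0.5, size=25), 1)
        res = mann_whitney(x, y, method="asymptotic")
        ref = stats.mannwhitneyu(x, y, method="asymptotic")
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_one_sided_alternatives(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(loc=1.0, size=30)
        less = mann_whitney(x, y, alternative="less", method="asymptotic")
        greater = mann_whitney(x, y, alternative="greater", method="asymptotic")
        assert less.p < 0.05 < greater.p

    def test_degenerate_all_identical(self):
        res = mann_whitney([1.0, 1.0, 1.0], [1.0, 1.0])
        assert res.degenerate
        assert math.isnan(res.z) and math.isnan(res.p)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            mann_whitney([], [1.0])


class TestSpearman:
    def test_perfect_monotone(self):
        res = spearman([1, 2, 3, 5], [10, 20, 21, 40])
        assert res.rho == pytest.approx(1.0)

    def test_perfect_antimonotone(self):
        res = spearman([1, 2, 3, 5], [40, 21, 20, 10])
        assert res.rho == pytest.approx(-1.0)

    def test_hand_computed_rank_formula(self):
        res = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.rho == pytest.approx(0.6)

    def test_zero_rank_variance_degenerate(self):
        res = spearman([1, 1, 1], [2, 3, 4])
        assert res.degenerate

    def test_length_validation(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])


class TestTTests:
    def test_identical_samples_t_zero(self):
        t, _, _ = group_t_tests([1.0, 2, 3], [1.0, 2, 3])
        assert t == pytest.approx(0.0)

    def test_equal_variances_student_equals_welch(self):
        x, y = [1.0, 2, 3, 4], [2.0, 3, 4, 5]
        ts, _, _ = group_t_tests(x, y, welch=False)
        tw, _, _ = group_t_tests(x, y, welch=True)
        assert ts == pytest.approx(tw)

    def test_textbook_formula_oracle(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(loc=0.4, scale=1.8, size=17)
        n1, n2 = len(x), len(y)
        v1, v2 = x.var(ddof=1), y.var(ddof=1)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        t_student = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        t_welch = (x.mean() - y.mean()) / math.sqrt(v1 / n1 + v2 / n2)
        df_welch = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
        ts, dfs, _ = group_t_tests(x, y, welch=False)
        tw, dfw, _ = group_t_tests(x, y, welch=True)
        assert ts == pytest.approx(t_student, abs=1e-10)
        assert dfs == n1 + n2 - 2
        assert tw == pytest.approx(t_welch, abs=1e-10)
        assert dfw == pytest.approx(df_welch, abs=1e-8)

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            group_t_tests([1.0], [1.0, 2.0])


class TestBonferroni:
    def test_min_one_times_m(self):
        p = np.array([0.01, 0.2, 0.5])
        adj = bonferroni(p)
        assert np.allclose(adj, [0.03, 0.6, 1.0])
        assert (adj >= p).all()


class TestNetScoreAnova:
    @staticmethod
    def _long(scores, groups):
        return net_scores_long(scores, groups)

    def test_identical_groups_no_group_effect(self, rng):
        base = rng.normal(size=(6, 5))
        scores = np.vstack([base, base])
        groups = ["OCD"] * 6 + ["HC"] * 6
        table = net_score_anova(self._long(scores, groups))
        f_group = table.anova.loc[table.anova["Source"] == "group", "F"].iloc[0]
        assert f_group == pytest.approx(0.0, abs=1e-10)

    def test_constant_blocks_no_within_effect(self, rng):
        subj = rng.normal(size=12)
        scores = np.tile(subj[:, None], (1, 5))
        groups = ["OCD"] * 6 + ["HC"] * 6
        table = net_score_anova(self._long(scores, groups))
        f_block = table.anova.loc[table.anova["Source"] == "block", "F"].iloc[0]
        assert f_block == pytest.approx(0.0, abs=1e-10)

    def test_matches_sum_of_squares_oracle(self, rng):
        scores = rng.normal(size=(16, 5)) + rng.normal(size=(16, 1))
        groups = ["OCD"] * 8 + ["HC"] * 8
        table = net_score_anova(self._long(scores, groups))
        oracle = splitplot_anova_oracle(scores, groups)
        aov = table.anova.set_index("Source")
        for source, key in [("group", "group"), ("block", "block"),
                            ("Interaction", "interaction")]:
            f_ref, np2_ref = oracle[key]
            assert aov.loc[source, "F"] == pytest.approx(f_ref, abs=1e-8)
            assert aov.loc[source, "np2"] == pytest.approx(np2_ref, abs=1e-8)

    def test_simple_effects_and_posthoc_shapes(self, rng):
        scores = rng.normal(size=(10, 5))
        groups = ["OCD"] * 5 + ["HC"] * 5
        table = net_score_anova(self._long(scores, groups))
        assert len(table.simple_group_by_block) == 5
        assert set(table.simple_block_by_group["group"]) == {"OCD", "HC"}
        # 5 blocks -> 10 pairwise comparisons, Bonferroni >= raw
        ph = table.posthoc_blocks
        assert len(ph) == 10
        assert (ph["p_corr"] >= ph["p_unc"] - 1e-12).all()

    def test_unbalanced_rejected(self, rng):
        data = self._long(rng.normal(size=(4, 5)), ["OCD"] * 2 + ["HC"] * 2)
        with pytest.raises(ValueError, match="unbalanced"):
            net_score_anova(data.iloc[:-1])


class TestRenderReport:
    @staticmethod
    def _fixture(rng, n=8):
        est = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(2 * n)],
                "alpha": rng.uniform(0.1, 0.4, 2 * n),
                "lam": rng.uniform(0.1, 1.0, 2 * n),
                "A": np.r_[rng.uniform(0.1, 0.4, n), rng.uniform(0.4, 0.8, n)],
                "c": rng.uniform(0.2, 1.0, 2 * n),
                "loglik": rng.normal(-120, 5, 2 * n),
            }
        )
        meta = pd.DataFrame(
            {
                "subject_id": est["subject_id"],
                "group": ["OCD"] * n + ["HC"] * n,
                "severity": np.r_[rng.integers(5, 20, n), np.zeros(n, dtype=int)],
            }
        )
        return est, meta

    def test_tables_render_and_write(self, rng, tmp_path):
        est, meta = self._fixture(rng)
        tables = render_report(est, meta, out_dir=tmp_path)
        assert set(tables) >= {"parameters", "severity_correlations"}
        assert (tmp_path / "parameters.csv").exists()
        assert (tmp_path / "report.txt").exists()
        # recency row: patient-like mean below control-like mean by design
        row = tables["parameters"].set_index("parameter").loc["A"]
        ocd_mean = float(row["OCD"].split(" ")[0])
        hc_mean = float(row["HC"].split(" ")[0])
        assert ocd_mean < hc_mean

    def test_single_subject_groups_flag_na(self, rng):
        est, meta = self._fixture(rng, n=1)
        tables = render_report(est, meta)
        assert "NA" in tables["parameters"]["OCD"].iloc[0]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no fitted subjects"):
            render_report(pd.DataFrame(), pd.DataFrame({"subject_id": [], "group": []}))

    def test_missing_labels_rejected(self, rng):
        est, meta = self._fixture(rng)
        with pytest.raises(KeyError, match="without labels"):
            parameter_comparison_table(est, meta.set_index("subject_id")["group"].iloc[:3])

    def test_block_table_includes_total(self, rng):
        data = net_scores_long(rng.normal(size=(6, 5)), ["OCD"] * 3 + ["HC"] * 3)
        tab = block_net_score_table(data)
        assert list(tab["block"]) == ["1", "2", "3", "4", "5", "total"]

    def test_severity_table_missing_subject_rejected(self, rng):
        est, meta = self._fixture(rng)
        sev = meta.set_index("subject_id")["severity"].iloc[:3]
        with pytest.raises(KeyError, match="severity"):
            severity_correlation_table(est, sev)
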