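"""Normalization, fold change, moderated/plain ANOVA testing, BH control."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import fibermap as fm

GROUPS = {"m1": "mut", "m2": "mut", "c1": "ctl", "c2": "ctl"}
DESIGN = pd.DataFrame({"sample": list(GROUPS), "line": list(GROUPS.values())})


def _counts(rows):
    return pd.DataFrame(rows, columns=list(GROUPS), index=[f"g{i}" for i in range(len(rows))])


class TestNormalize:
    def test_equal_libraries_preserve_ratios(self):
        counts = _counts([[10, 10, 20, 20], [30, 30, 60, 60]])
        cpm = fm.normalize(counts)
        ratio = cpm.iloc[1] / cpm.iloc[0]
        assert np.allclose(ratio, 3.0)

    def test_double_library_size_is_equalized(self):
        counts = _counts([[10, 20, 10, 10], [30, 60, 30, 30]])
        cpm = fm.normalize(counts)
        assert np.allclose(cpm.loc["g0"], cpm.loc["g0", "m1"])

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError, match="library"):
            fm.normalize(_counts([[0, 1, 1, 1]]))


class TestFoldChange:
    def test_ratio_of_pseudocounted_means(self):
        cpm = _counts([[1790, 1790, 10, 10]]).astype(float)
        fc = fm.fold_change(cpm, DESIGN, "mut", "ctl")
        assert fc["g0"] == pytest.approx(1791 / 11, rel=1e-9)
        assert fc["g0"] == pytest.approx(179, rel=0.1)

    def test_identical_means_give_one(self):
        cpm = _counts([[5.0, 7.0, 6.0, 6.0]])
        assert fm.fold_change(cpm, DESIGN, "mut", "ctl")["g0"] == pytest.approx(1.0)

    def test_all_zero_gene_has_fold_one(self):
        cpm = _counts([[0, 0, 0, 0]]).astype(float)
        assert fm.fold_change(cpm, DESIGN, "mut", "ctl")["g0"] == 1.0

    def test_missing_line_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            fm.fold_change(_counts([[1, 1, 1, 1]]), DESIGN, "mut", "nope")


class TestTestDeg:
    def test_plain_anova_equals_pooled_t_test(self, rng):
        """Without moderation the two-line ANOVA p is the pooled t-test p."""
        cpm = pd.DataFrame(
            rng.lognormal(3, 1, size=(50, 4)), columns=list(GROUPS)
        )
        res = fm.test_deg(cpm, DESIGN, moderation=False)
        logs = np.log2(cpm.to_numpy() + 1)
        t_p = stats.ttest_ind(logs[:, :2], logs[:, 2:], axis=1, equal_var=True).pvalue
        assert np.allclose(res["p_value"].to_numpy(), t_p, atol=1e-10)

    def test_constant_gene_reported_untested(self):
        cpm = _counts([[5, 5, 5, 5], [1, 2, 30, 40]]).astype(float)
        res = fm.test_deg(cpm, DESIGN)
        assert not res.loc["g0", "tested"]
        assert np.isnan(res.loc["g0", "p_value"])
        assert res.loc["g0", "q_value"] == 1.0
        assert not res.loc["g0", "significant"]

    def test_significance_needs_both_fdr_and_fold(self):
        counts, design = fm.simulate_counts(
            500, GROUPS, [("gene_0001", "mut", 179.0)], dispersion=0.02, seed=4
        )
        res = fm.test_deg(fm.normalize(counts), design)
        assert bool(res.loc["gene_0001", "significant"])
        flagged = res[res["significant"]]
        assert (np.abs(np.log2(flagged["fold_change"])) >= 1).all()
        assert (flagged["q_value"] < 0.05).all()

    def test_q_values_monotone_in_p(self):
        counts, design = fm.simulate_counts(300, GROUPS, [], dispersion=0.05, seed=6)
        res = fm.test_deg(fm.normalize(counts), design)
        sub = res[res["tested"]].sort_values("p_value")
        assert (np.diff(sub["q_value"].to_numpy()) >= -1e-12).all()

    def test_single_replicate_line_rejected(self):
        design = pd.DataFrame(
            {"sample": ["m1", "c1", "c2"], "line": ["mut", "ctl", "ctl"]}
        )
        with pytest.raises(ValueError, match="replicates"):
            fm.test_deg(_counts([[1, 1, 1, 1]])[["m1", "c1", "c2"]], design)


class TestBenjaminiHochberg:
    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=60))
    def test_matches_brute_force_step_up(self, pvals):
        """q-values agree with a from-scratch sort/step-up/min-accumulate BH."""
        p = np.asarray(pvals)
        m = len(p)
        order = np.argsort(p)
        stepped = p[order] * m / np.arange(1, m + 1)
        brute = np.minimum.accumulate(stepped[::-1])[::-1]
        brute_q = np.empty(m)
        brute_q[order] = np.minimum(brute, 1.0)

        from statsmodels.stats.multitest import multipletests

        ours = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, brute_q, atol=1e-12)


class TestSummarizePathway:
    def test_empty_map_gives_empty_summary(self):
        res = pd.DataFrame(
            {"fold_change": [2.0], "significant": [True]}, index=["g0"]
        )
        assert len(fm.summarize_pathway(res, {})) == 0

    def test_counts_planted_up_genes(self):
        res = pd.DataFrame(
            {
                "fold_change": [10.0, 0.1, 3.0, 1.0],
                "significant": [True, True, False, False],
            },
            index=["g0", "g1", "g2", "g3"],
        )
        out = fm.summarize_pathway(
            res, {"g0": "flavonoid", "g1": "flavonoid", "g2": "flavonoid"}
        )
        row = out.set_index("pathway").loc["flavonoid"]
        assert (row["n_up"], row["n_down"]) == (1, 1)
        assert row["median_fold_change"] == pytest.approx(3.0)

    def test_stronger_line_has_larger_pathway_fold(self):
        """Two mutant lines planted at 179x vs 756x order correctly per pathway."""
        groups = {
            "a1": "sa", "a2": "sa", "b1": "mc", "b2": "mc", "t1": "tm", "t2": "tm",
        }
        planted = [("gene_0001", "sa", 179.0), ("gene_0001", "mc", 756.0)]
        counts, design = fm.simulate_counts(300, groups, planted, dispersion=0.02, seed=9)
        cpm = fm.normalize(counts)
        fc_sa = fm.fold_change(cpm, design, "sa", "tm")
        fc_mc = fm.fold_change(cpm, design, "mc", "tm")
        assert fc_mc["gene_0001"] > fc_sa["gene_0001"] > 10
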