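import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tfhscreen as tfs
from tfhscreen.stats import (
    classify_hits,
    control_pseudogenes,
    gene_table,
    rra_gene_test,
    rra_score,
)


class TestGuideL2fc:
    @pytest.mark.parametrize(
        "num,den,pc,expected",
        [
            (100, 100, 0.5, 0.0),
            (200, 100, 0.0, 1.0),
            (0, 1000, 0.5, math.log2(0.5 / 1000.5)),
        ],
    )
    def test_examples(self, num, den, pc, expected):
        assert tfs.guide_l2fc(num, den, pc) == pytest.approx(expected,
                                                             abs=1e-12)

    def test_zero_inputs_need_pseudocount(self):
        with pytest.raises(ValueError):
            tfs.guide_l2fc(0.0, 100.0, 0.0)

    @given(num=st.floats(0.1, 1e6), den=st.floats(0.1, 1e6),
           pc=st.floats(0.01, 10))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, num, den, pc):
        assert tfs.guide_l2fc(num, den, pc) == pytest.approx(
            -tfs.guide_l2fc(den, num, pc), abs=1e-9)


def _brute_force_hierarchy(df: pd.DataFrame) -> float:
    """Independent nested-loop computation of the replicate hierarchy."""
    exp_means = []
    for _, exp_df in df.groupby("experiment_id"):
        mouse_means = []
        for _, mouse_df in exp_df.groupby("mouse_id"):
            vals = mouse_df["value"].dropna()
            if len(vals):
                mouse_means.append(sum(vals) / len(vals))
        if mouse_means:
            exp_means.append(sum(mouse_means) / len(mouse_means))
    return sum(exp_means) / len(exp_means)


class TestHierarchicalAverage:
    def test_unbalanced_experiments_weight_equally(self):
        df = pd.DataFrame({
            "experiment_id": ["e1", "e1", "e2"],
            "mouse_id": ["m1", "m2", "m3"],
            "value": [1.0, 3.0, 5.0],
        })
        overall, exp_means = tfs.hierarchical_average(df)
        assert overall == 3.5  # not the pooled mean 3.0
        assert dict(exp_means) == {"e1": 2.0, "e2": 5.0}

    def test_single_value_identity(self):
        df = pd.DataFrame({"experiment_id": ["e1"], "mouse_id": ["m1"],
                           "value": [2.7]})
        assert tfs.hierarchical_average(df)[0] == 2.7

    def test_constant_values_constant_at_all_levels(self):
        df = pd.DataFrame({
            "experiment_id": ["e1"] * 3 + ["e2"] * 2,
            "mouse_id": ["m1", "m2", "m3", "m4", "m5"],
            "value": [1.5] * 5,
        })
        overall, exp_means = tfs.hierarchical_average(df)
        assert overall == 1.5 and (exp_means == 1.5).all()

    def test_all_missing_raises(self):
        df = pd.DataFrame({"experiment_id": ["e1"], "mouse_id": ["m1"],
                           "value": [np.nan]})
        with pytest.raises(ValueError):
            tfs.hierarchical_average(df)

    def test_matches_brute_force_on_random_data(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = rng.integers(2, 30)
            df = pd.DataFrame({
                "experiment_id": rng.choice(["e1", "e2", "e3"], n),
                "mouse_id": rng.choice(["m1", "m2", "m3", "m4"], n),
                "value": rng.normal(size=n),
            })
            assert tfs.hierarchical_average(df)[0] == pytest.approx(
                _brute_force_hierarchy(df), abs=1e-12)


class TestGeneSummary:
    def test_hand_example(self):
        mean, sem = tfs.gene_summary(np.array([1.0, 2.0, 3.0]))
        assert mean == 2.0
        assert sem == pytest.approx(1.0 / math.sqrt(3))

    def test_single_guide_sem_absent(self):
        mean, sem = tfs.gene_summary(np.array([4.2]))
        assert mean == 4.2 and np.isnan(sem)

    def test_equal_guides_zero_sem(self):
        assert tfs.gene_summary(np.array([1.0, 1.0, 1.0]))[1] == 0.0


class TestControlZscore:
    def test_centering_and_scale(self):
        ctrl = pd.Series([0.0, 1.0, -1.0, 2.0, -2.0])
        genes = pd.Series({"A": ctrl.mean(), "B": 2.0})
        z = tfs.control_zscore(genes, ctrl)
        assert z["A"] == 0.0
        assert z["B"] == pytest.approx((2.0 - ctrl.mean()) / ctrl.std(ddof=1))

    def test_shift_invariance(self):
        ctrl = pd.Series([0.1, 0.5, -0.3, 0.8])
        genes = pd.Series({"A": 1.0, "B": -0.2})
        z1 = tfs.control_zscore(genes, ctrl)
        z2 = tfs.control_zscore(genes + 3.0, ctrl + 3.0)
        assert np.allclose(z1, z2)

    def test_controls_standardize_to_unit_scale(self):
        ctrl = pd.Series([0.3, -0.7, 1.2, 0.1, -0.4])
        z = tfs.control_zscore(ctrl, ctrl)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_degenerate_controls_rejected(self):
        with pytest.raises(ValueError):
            tfs.control_zscore(pd.Series({"A": 1.0}), pd.Series([0.5, 0.5]))
        with pytest.raises(ValueError):
            tfs.control_zscore(pd.Series({"A": 1.0}), pd.Series([0.5]))


def _beta_tail_oracle(x: float, j: int, k: int) -> float:
    """P(Beta(j, k-j+1) <= x) by the binomial order-statistic identity:
    the probability that at least j of k uniforms fall below x."""
    return sum(math.comb(k, i) * x**i * (1 - x) ** (k - i)
               for i in range(j, k + 1))


def _rra_oracle(ranks, n_total, alpha):
    rs = sorted(r / n_total for r in ranks)
    k = len(rs)
    scores = [_beta_tail_oracle(r, j, k)
              for j, r in enumerate(rs, start=1) if r < alpha]
    return min(scores) if scores else 1.0


class TestRRA:
    def test_score_matches_order_statistic_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            n = int(rng.integers(4, 50))
            k = int(rng.integers(1, min(6, n)))
            ranks = rng.choice(np.arange(1, n + 1), size=k, replace=False)
            alpha = float(rng.choice([0.1, 0.25, 0.5, 1.0]))
            assert rra_score(ranks / n, alpha) == pytest.approx(
                _rra_oracle(ranks, n, alpha), abs=1e-12)

    def test_no_guides_inside_alpha_scores_one(self):
        assert rra_score(np.array([0.6, 0.8]), alpha=0.25) == 1.0

    def test_top_ranked_gene_has_smallest_score(self, small_library):
        # one gene's guides occupy the best ranks -> minimal score screenwide
        rng = np.random.default_rng(5)
        vals = pd.Series(rng.normal(0, 0.1, len(small_library)),
                         index=small_library.guide_ids)
        target = small_library.genes[0]
        tids = [g.guide_id for g in small_library
                if g.gene_symbol == target]
        vals[tids] = -10.0
        res = rra_gene_test(vals, small_library, "depleted", n_perm=500,
                            seed=1)
        assert res.loc[target, "rra_score"] == res["rra_score"].min()
        assert res.loc[target, "fdr"] == res["fdr"].min()

    def test_permuted_labels_give_calibrated_pvalues(self, pid_like_library):
        """Exchangeable guide values -> calibrated permutation p-values.

        The score distribution has a structural atom at 1 (genes with no
        guide inside the alpha window), so uniformity is checked on the
        pooled continuous lower region that drives FDR, plus the
        empirical exceedance fractions at working thresholds.
        """
        from scipy.stats import kstest

        pvals = []
        for rep in range(5):
            rng = np.random.default_rng(31 + rep)
            vals = pd.Series(rng.normal(size=len(pid_like_library)),
                             index=pid_like_library.guide_ids)
            res = rra_gene_test(vals, pid_like_library, "depleted",
                                n_perm=10_000, seed=7 + rep)
            pvals.append(res["p_value"])
        p = pd.concat(pvals)
        assert abs((p <= 0.05).mean() - 0.05) < 0.04
        assert abs((p <= 0.25).mean() - 0.25) < 0.08
        low = p[p < 0.7] / 0.7
        assert kstest(low, "uniform").pvalue > 0.001

    def test_bh_fdr_monotone_in_p_ranking(self, small_library):
        rng = np.random.default_rng(7)
        vals = pd.Series(rng.normal(size=len(small_library)),
                         index=small_library.guide_ids)
        res = rra_gene_test(vals, small_library, "depleted", n_perm=1000,
                            seed=3)
        ordered = res.sort_values("p_value")
        assert (ordered["fdr"].diff().dropna() >= -1e-12).all()

    def test_missing_values_take_worst_rank(self, small_library):
        rng = np.random.default_rng(9)
        vals = pd.Series(rng.normal(size=len(small_library)),
                         index=small_library.guide_ids)
        target = small_library.genes[0]
        tids = [g.guide_id for g in small_library if g.gene_symbol == target]
        vals[tids] = np.nan
        res = rra_gene_test(vals, small_library, "depleted", n_perm=200,
                            seed=4)
        assert res.loc[target, "rra_score"] == 1.0

    def test_control_fallback_warns(self):
        lib = tfs.build_library(["A", "B", "C"], 3, 0, seed=1)
        vals = pd.Series(np.arange(9, dtype=float), index=lib.guide_ids)
        with pytest.warns(UserWarning, match="control"):
            rra_gene_test(vals, lib, "depleted", n_perm=100, seed=5,
                          null_pool="controls")

    def test_null_pool_selection(self, pid_like_library):
        # 20 controls with 5 guides/gene is below the stability cutoff:
        # auto must fall back to the all-guide pool
        rng = np.random.default_rng(3)
        vals = pd.Series(rng.normal(size=len(pid_like_library)),
                         index=pid_like_library.guide_ids)
        auto = rra_gene_test(vals, pid_like_library, "depleted", n_perm=500,
                             seed=6, null_pool="auto")
        allg = rra_gene_test(vals, pid_like_library, "depleted", n_perm=500,
                             seed=6, null_pool="all")
        ctrl = rra_gene_test(vals, pid_like_library, "depleted", n_perm=500,
                             seed=6, null_pool="controls")
        assert auto["p_value"].equals(allg["p_value"])
        assert not auto["p_value"].equals(ctrl["p_value"])


class TestClassifyHits:
    @pytest.mark.parametrize(
        "tfh,th1,expected",
        [
            (-3.0, -3.0, "required_for_expansion"),
            (3.0, 3.0, "inhibits_expansion"),
            (-2.0, 0.2, "required_for_Tfh"),
            (0.2, -2.0, "required_for_Th1"),
            (0.0, 0.0, "neutral"),
            (-0.5, -0.5, "neutral"),  # inside both thresholds
        ],
    )
    def test_quadrants(self, tfh, th1, expected):
        out = classify_hits(pd.Series({"g": tfh}), pd.Series({"g": th1}),
                            depletion_threshold=-1.0,
                            enrichment_threshold=1.0)
        assert out["g"] == expected

    def test_threshold_validation(self):
        s = pd.Series({"g": 0.0})
        with pytest.raises(ValueError):
            classify_hits(s, s, depletion_threshold=1.0)


class TestControlPseudogenes:
    def test_grouping_respects_guides_per_gene(self, small_library):
        groups = control_pseudogenes(small_library)
        assert len(groups) == 3  # 12 controls / 4 per pseudo-gene
        assert all(len(ids) == 4 for ids in groups.values())
        all_ids = [i for ids in groups.values() for i in ids]
        assert all_ids == small_library.control_ids


class TestComparisons:
    def test_tfh_vs_th1_pairs_within_mouse(self, neutral_screen):
        table, _, cfg = neutral_screen
        reps = tfs.compute_comparison(table, "Tfh_vs_Th1")
        # one replicate per guide per mouse
        per_guide = reps.groupby("guide_id").size()
        assert (per_guide == cfg.n_mice * cfg.n_experiments).all()

    def test_culture_vs_plasmid_one_per_experiment(self, neutral_screen):
        table, _, cfg = neutral_screen
        reps = tfs.compute_comparison(table, "culture_vs_plasmid")
        per_guide = reps.groupby("guide_id").size()
        assert (per_guide == cfg.n_experiments).all()

    def test_neutral_truth_l2fc_centered_at_zero(self, neutral_screen,
                                                 pid_like_library):
        table, _, _ = neutral_screen
        gmeans = tfs.guide_overall_means(
            tfs.compute_comparison(table, "Tfh_vs_Th1"))
        genes = gene_table(gmeans, pid_like_library)
        mean = genes["mean_l2fc"].mean()
        sem = genes["mean_l2fc"].std(ddof=1) / np.sqrt(len(genes))
        assert abs(mean) < 4 * sem + 0.05


class TestAnalyzeScreen:
    def test_planted_effect_ranks_and_classifies(self, pid_like_library):
        truth = tfs.ScreenTruth.neutral(pid_like_library)
        planted = pid_like_library.genes[:4]
        for g in planted:
            truth.tfh_logit_shift[g] = -2.0
        cfg = tfs.ScreenConfig(seed=13)
        table = tfs.simulate_screen(pid_like_library, truth, cfg)
        genes = tfs.analyze_screen(table, pid_like_library, n_perm=1000,
                                   seed=5)
        top = genes.sort_values("mean_l2fc").head(6).index
        assert set(planted) <= set(top)
        assert (genes.loc[planted, "fdr"] < 0.25).all()
        assert (genes.loc[planted, "category"] == "required_for_Tfh").all()
        assert (genes.loc[planted, "zscore"] < -2).all()
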