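"""Unit and oracle tests for the bulk differential-expression engine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import tarsig
from tarsig.bulkde import (
    BulkCountMatrix,
    ContrastSpec,
    bh_adjust,
    filter_low_expression,
    log_cpm,
    moderated_de,
    tmm_factors,
)

from conftest import make_design


def toy_matrix(counts: np.ndarray, n_reps: int = 3) -> BulkCountMatrix:
    design = make_design(n_reps)
    genes = [f"g{i}" for i in range(counts.shape[0])]
    return BulkCountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=design.index),
        design=design,
    )


class TestValidation:
    def test_rejects_negative_and_non_integer_counts(self):
        design = make_design(1)
        good = np.ones((2, 4), dtype=int)
        for bad in (-good, good * 0.5):
            with pytest.raises(ValueError):
                BulkCountMatrix(
                    counts=pd.DataFrame(bad, index=["a", "b"], columns=design.index),
                    design=design,
                )

    def test_rejects_duplicate_gene_ids(self):
        design = make_design(1)
        with pytest.raises(ValueError, match="duplicate gene"):
            BulkCountMatrix(
                counts=pd.DataFrame(
                    np.ones((2, 4), dtype=int), index=["a", "a"], columns=design.index
                ),
                design=design,
            )


class TestFilterLowExpression:
    def test_matches_hand_enumerated_rule_on_toy(self):
        # smallest design cell has 3 samples -> need count >= 10 in >= 3
        # samples and a row total >= 15
        counts = np.array([
            [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],      # all-zero: drop
            [12, 12, 12, 0, 0, 0, 0, 0, 0, 0, 0, 0],   # 3 samples >=10, total 36: keep
            [12, 12, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],    # only 2 samples >=10: drop
            [9, 9, 9, 9, 9, 9, 9, 9, 9, 9, 9, 9],      # never reaches 10: drop
            [20, 20, 20, 20, 20, 20, 20, 20, 20, 20, 20, 20],  # keep
            [14, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],     # total 14 < 15: drop
        ])
        m = toy_matrix(counts)
        kept = set(filter_low_expression(m).gene_ids)

        def brute(row):
            return (sum(c >= 10 for c in row) >= 3) and (sum(row) >= 15)

        expected = {f"g{i}" for i, row in enumerate(counts) if brute(row)}
        assert kept == expected == {"g1", "g4"}

    def test_all_zero_gene_removed_and_saturated_gene_kept(self):
        counts = np.zeros((2, 12), dtype=int)
        counts[1] = 50
        kept = set(filter_low_expression(toy_matrix(counts)).gene_ids)
        assert kept == {"g1"}

    def test_warns_when_everything_is_filtered(self):
        counts = np.ones((2, 12), dtype=int)
        with pytest.warns(UserWarning, match="all genes removed"):
            out = filter_low_expression(toy_matrix(counts))
        assert out.counts.shape[0] == 0


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([5, 10, 200, 3, 50, 80, 7, 1000])
        counts = np.tile(col[:, None], (1, 4))
        f = tmm_factors(toy_matrix(counts, n_reps=1))
        assert np.allclose(f.factors, 1.0, atol=1e-12)

    def test_depth_scaling_is_invisible_to_tmm(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 500, size=8)
        counts = np.column_stack([base, 3 * base, base, 3 * base])
        f = tmm_factors(toy_matrix(counts, n_reps=1))
        assert np.allclose(f.factors, 1.0, atol=1e-12)

    def test_matches_brute_force_trimmed_weighted_mean(self):
        """Two-sample 8-gene toy vs an independent plain-Python oracle."""
        counts = np.array(
            [[100, 80], [200, 210], [300, 290], [50, 55],
             [400, 380], [120, 1500], [60, 65], [900, 880]]
        )
        design = pd.DataFrame(
            {"genotype": ["WT", "WT"], "treatment": ["vehicle", "TPA"],
             "replicate": [1, 1]},
            index=["s1", "s2"],
        )
        m = BulkCountMatrix(
            counts=pd.DataFrame(counts, index=[f"g{i}" for i in range(8)],
                                columns=design.index),
            design=design,
        )
        f = tmm_factors(m)
        ref = int(f.reference_sample == "s1")  # index of the *other* sample
        obs_col, ref_col = (1, 0) if f.reference_sample == "s1" else (0, 1)

        n_obs = counts[:, obs_col].sum()
        n_ref = counts[:, ref_col].sum()
        entries = []
        for y_obs, y_ref in counts[:, [obs_col, ref_col]]:
            p_obs, p_ref = y_obs / n_obs, y_ref / n_ref
            m_val = np.log2(p_obs / p_ref)
            a_val = 0.5 * np.log2(p_obs * p_ref)
            w = (n_obs - y_obs) / (n_obs * y_obs) + (n_ref - y_ref) / (n_ref * y_ref)
            entries.append((m_val, a_val, w))
        n = len(entries)
        m_sorted = sorted(e[0] for e in entries)
        a_sorted = sorted(e[1] for e in entries)
        lo_m = int(np.floor(n * 0.30))          # keep ranks lo_m+1 .. n-lo_m
        lo_a = int(np.floor(n * 0.05))
        m_keep = set()
        for i, (m_val, a_val, _) in enumerate(entries):
            rank_m = m_sorted.index(m_val) + 1
            rank_a = a_sorted.index(a_val) + 1
            if lo_m + 1 <= rank_m <= n - lo_m and lo_a + 1 <= rank_a <= n - lo_a:
                m_keep.add(i)
        num = sum(entries[i][0] / entries[i][2] for i in m_keep)
        den = sum(1.0 / entries[i][2] for i in m_keep)
        expected_obs = 2.0 ** (num / den)
        # geometric-mean rescaling over {1, expected_obs}
        scale = np.sqrt(expected_obs)
        expected = {obs_col: expected_obs / scale, ref_col: 1.0 / scale}
        assert f.factors.iloc[obs_col] == pytest.approx(expected[obs_col], abs=1e-9)
        assert f.factors.iloc[ref_col] == pytest.approx(expected[ref_col], abs=1e-9)
        del ref

    def test_gene_order_permutation_invariance_and_unit_geomean(self):
        rng = np.random.default_rng(3)
        counts = rng.negative_binomial(2, 0.01, size=(300, 12))
        m = toy_matrix(counts)
        f1 = tmm_factors(m).factors
        perm = rng.permutation(300)
        m2 = BulkCountMatrix(counts=m.counts.iloc[perm], design=m.design)
        f2 = tmm_factors(m2).factors
        assert np.allclose(f1, f2)
        assert np.log(f1.to_numpy()).mean() == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_sample_gets_unit_factor_with_warning(self):
        counts = np.array([[10, 0, 10], [20, 0, 25], [0, 30, 0], [0, 40, 0]])
        design = pd.DataFrame(
            {"genotype": ["WT"] * 3, "treatment": ["vehicle", "TPA", "TPA"],
             "replicate": [1, 1, 2]},
            index=["s1", "s2", "s3"],
        )
        m = BulkCountMatrix(
            counts=pd.DataFrame(counts, index=list("abcd"), columns=design.index),
            design=design,
        )
        with pytest.warns(UserWarning, match="no positive genes"):
            tmm_factors(m)


class TestLogCPM:
    def test_closed_form_value_for_zero_count(self):
        # count 0, libsize 1e6, factor 1, prior 0.5:
        # log2(0.5 / (1e6 + 1) * 1e6) ~= -1.0000014
        counts = np.zeros((2, 12), dtype=int)
        counts[1] = 1_000_000 // 2  # two genes summing to 1e6 per sample
        counts[0, 0] = 0
        counts[1, :] = 1_000_000
        m = toy_matrix(counts)
        value = log_cpm(m).iloc[0, 0]
        assert value == pytest.approx(np.log2(0.5 / (1e6 + 1) * 1e6), abs=1e-9)
        assert value == pytest.approx(-1.0000014, abs=1e-6)

    def test_depth_doubling_leaves_logcpm_nearly_unchanged(self):
        # ratio invariance up to the pseudo-count: exact as counts grow
        rng = np.random.default_rng(1)
        counts = rng.integers(100, 2000, size=(50, 12))
        a = log_cpm(toy_matrix(counts))
        b = log_cpm(toy_matrix(2 * counts))
        assert np.abs(a.to_numpy() - b.to_numpy()).max() < 0.01

    def test_monotone_in_count_within_sample(self):
        counts = np.array([[0], [1], [5], [500]]).repeat(12, axis=1)
        values = log_cpm(toy_matrix(counts)).iloc[:, 0].to_numpy()
        assert np.all(np.diff(values) > 0)


class TestModeratedDE:
    def test_flat_gene_has_zero_t_and_p_one(self):
        rng = np.random.default_rng(2)
        logcpm = pd.DataFrame(
            rng.normal(size=(40, 12)),
            index=[f"g{i}" for i in range(40)],
            columns=make_design().index,
        )
        logcpm.iloc[0] = 5.0  # identical in both groups
        de = moderated_de(logcpm, make_design(), ContrastSpec("wt", "WT"))
        assert de.loc["g0", "log_fc"] == 0.0
        assert de.loc["g0", "t"] == 0.0
        assert de.loc["g0", "p_value"] == pytest.approx(1.0)

    def test_zero_prior_df_reduces_to_ordinary_pooled_t(self):
        """With d0=0 the moderated statistic is the classical two-sample t."""
        rng = np.random.default_rng(5)
        design = make_design()
        logcpm = pd.DataFrame(
            rng.normal(size=(5, 12)), index=[f"g{i}" for i in range(5)],
            columns=design.index,
        )
        de = moderated_de(logcpm, design, ContrastSpec("wt", "WT"), prior_df=0.0)
        in_t = (design["genotype"] == "WT") & (design["treatment"] == "TPA")
        in_r = (design["genotype"] == "WT") & (design["treatment"] == "vehicle")
        for gene in logcpm.index:
            x1 = logcpm.loc[gene, in_t.to_numpy()].to_numpy()
            x2 = logcpm.loc[gene, in_r.to_numpy()].to_numpy()
            ref = stats.ttest_ind(x1, x2, equal_var=True)
            assert de.loc[gene, "t"] == pytest.approx(ref.statistic, abs=1e-10)
            assert de.loc[gene, "p_value"] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_prior_df_matches_hand_computed_t(self):
        # 2 vs 2 toy computed by hand: means 4 and 1, pooled var
        # ((1-0)^2*... ) -> s_p^2 = (0.5^2*2 + 0.5^2*2)/2 = ... use exact values
        design = make_design(2).loc[lambda d: d["genotype"] == "WT"]
        logcpm = pd.DataFrame(
            [[1.0, 2.0, 4.0, 5.0]], index=["g0"],
            columns=design.index,  # vehicle r1, r2 then TPA r1, r2
        )
        de = moderated_de(logcpm, design, ContrastSpec("wt", "WT"), prior_df=0.0)
        # logFC = mean(4,5) - mean(1,2) = 3; s^2 = (0.5 + 0.5)/2 = 0.5
        # t = 3 / sqrt(0.5 * (1/2 + 1/2)) = 3 / sqrt(0.5) = 4.2426...
        assert de.loc["g0", "log_fc"] == pytest.approx(3.0)
        assert de.loc["g0", "t"] == pytest.approx(3.0 / np.sqrt(0.5), abs=1e-12)

    def test_location_shift_invariance(self):
        rng = np.random.default_rng(6)
        design = make_design()
        logcpm = pd.DataFrame(
            rng.normal(size=(30, 12)), index=[f"g{i}" for i in range(30)],
            columns=design.index,
        )
        shifted = logcpm.copy()
        shifted.iloc[7] += 100.0
        a = moderated_de(logcpm, design, ContrastSpec("wt", "WT"))
        b = moderated_de(shifted, design, ContrastSpec("wt", "WT"))
        assert b.loc["g7", "t"] == pytest.approx(a.loc["g7", "t"], abs=1e-9)
        assert b.loc["g7", "p_value"] == pytest.approx(a.loc["g7", "p_value"], abs=1e-9)

    def test_single_replicate_cell_requires_explicit_flag(self):
        design = make_design(1)
        logcpm = pd.DataFrame(
            np.random.default_rng(0).normal(size=(4, 4)),
            index=list("abcd"), columns=design.index,
        )
        with pytest.raises(ValueError, match="fold_change_only"):
            moderated_de(logcpm, design, ContrastSpec("wt", "WT"))
        table = moderated_de(
            logcpm, design, ContrastSpec("wt", "WT"), fold_change_only=True
        )
        assert table["t"].isna().all() and table["log_fc"].notna().all()

    def test_variance_shrinkage_pulls_toward_prior(self):
        """Genes with extreme sample variances get less extreme moderated t
        than ordinary t (the empirical-Bayes effect)."""
        rng = np.random.default_rng(9)
        design = make_design()
        logcpm = pd.DataFrame(
            rng.normal(size=(200, 12)), index=[f"g{i}" for i in range(200)],
            columns=design.index,
        )
        mod = moderated_de(logcpm, design, ContrastSpec("wt", "WT"))
        ord_ = moderated_de(logcpm, design, ContrastSpec("wt", "WT"), prior_df=0.0)
        # the most extreme ordinary statistics shrink
        worst = ord_["t"].abs().nlargest(10).index
        assert (mod.loc[worst, "t"].abs() <= ord_.loc[worst, "t"].abs() + 1e-9).all()


class TestBHAdjust:
    def test_single_p_is_identity(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_hand_evaluated_step_up(self):
        out = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_rejects_nan(self):
        with pytest.raises(ValueError, match="NaN"):
            bh_adjust(np.array([0.1, np.nan]))

    @staticmethod
    def brute_force(p):
        """O(n^2) min-over-tail oracle, plain Python."""
        n = len(p)
        order = sorted(range(n), key=lambda i: p[i])
        q = [0.0] * n
        for pos in range(n):
            tail = min(p[order[k]] * n / (k + 1) for k in range(pos, n))
            q[order[pos]] = min(1.0, tail)
        return q

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=100))
    def test_matches_brute_force_oracle(self, p):
        assert np.allclose(bh_adjust(np.array(p)), self.brute_force(p), atol=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=50))
    def test_monotone_in_raw_p_rank_and_dominates_raw(self, p):
        p_arr = np.array(p)
        q = bh_adjust(p_arr)
        assert (q >= p_arr - 1e-15).all()
        order = np.argsort(p_arr, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_agrees_with_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(4)
        p = rng.uniform(size=200)
        ref = statsmodels.multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), ref, atol=1e-12)


class TestParameterRecovery:
    def test_planted_wt_effects_recovered(self, recovery_sim):
        """16-fold planted WT-only effects are called at FC>8, adj p<0.01."""
        m, truth = recovery_sim
        filtered = filter_low_expression(m)
        logcpm = log_cpm(filtered, tmm_factors(filtered))
        de = moderated_de(logcpm, filtered.design, ContrastSpec("wt", "WT"))
        called = tarsig.call_regulated(de)
        true_up = truth.genes_of_class("wt_only_up") | truth.genes_of_class("shared_up")
        sens = len(called & true_up) / len(true_up)
        fdr = len(called - true_up) / max(len(called), 1)
        assert sens >= 0.90
        assert fdr <= 0.05

    def test_null_simulation_calls_nothing(self):
        params = tarsig.BulkSimParams(
            effect_wt_only=1.0, effect_shared=1.0, effect_ko_only=1.0,
            effect_down=1.0, seed=21,
        )
        m, _ = tarsig.generate_bulk_counts(params)
        filtered = filter_low_expression(m)
        logcpm = log_cpm(filtered, tmm_factors(filtered))
        de = moderated_de(logcpm, filtered.design, ContrastSpec("wt", "WT"))
        assert len(tarsig.call_regulated(de)) == 0
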