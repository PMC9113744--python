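import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

import thermatlas as ta
from thermatlas.io_formats import CountMatrix
from thermatlas.normalization_de import (
    _exact_pvalue,
    bh_adjust,
    call_de,
    compute_cpm,
    de_table,
    estimate_dispersion,
    exact_test,
    filter_analysis_genes,
    flag_expressed,
)
from thermatlas.synthetic_data import SimConfig, simulate_null


def binomial_conditional_oracle(s_obs: int, t: int, n_a: int, n_b: int) -> Fraction:
    """Exact-rational conditional binomial p-value by full enumeration.

    Under dispersion 0 with equalized libraries, the split of the conditioned
    total t between groups is Binomial(t, n_a / (n_a + n_b)); the two-sided p
    sums the probabilities of all splits no more likely than the observed.
    """
    weights = [
        math.comb(t, s) * n_a**s * n_b ** (t - s) for s in range(t + 1)
    ]
    obs = weights[s_obs]
    total = sum(weights)
    return Fraction(sum(w for w in weights if w <= obs), total)


class TestCpmAndFilters:
    def test_cpm_hand_oracle_and_column_sums(self):
        cm = CountMatrix(["g1", "g2", "g3"], ["a", "b"], [[1, 0], [3, 5], [6, 5]])
        cpm = compute_cpm(cm)
        assert np.allclose(cpm.sum(axis=0), 1e6)
        assert cpm.loc["g2", "a"] == pytest.approx(3 / 10 * 1e6)
        assert cpm.loc["g1", "b"] == 0.0

    def test_cpm_single_gene_library(self):
        cm = CountMatrix(["g1", "g2"], ["a"], [[7], [0]])
        cpm = compute_cpm(cm)
        assert cpm.loc["g1", "a"] == pytest.approx(1e6)

    def test_cpm_zero_library_names_sample(self):
        cm = CountMatrix(["g1"], ["a", "b"], [[3, 0]])
        with pytest.raises(ValueError, match="b"):
            compute_cpm(cm)

    def test_logcpm_filter_matches_brute_force(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(0, 60, size=(50, 6)),
            index=[f"g{i}" for i in range(50)],
            columns=list("abcdef"),
        )
        counts.iloc[0] = 0
        groups = {"ctrl": ["a", "b", "c"], "treat": ["d", "e", "f"]}
        cpm = compute_cpm(counts)
        mask = filter_analysis_genes(cpm, groups, "logcpm_positive")
        for g in counts.index:
            expect = all(
                (cpm.loc[g, ss] > 1).sum() >= len(ss) / 2 for ss in groups.values()
            )
            assert mask[g] == expect
        assert not mask["g0"]

    def test_flag_expressed_threshold_boundary(self):
        cm = CountMatrix(
            ["g1", "g2"], ["a", "b", "c", "d"], [[4, 4, 0, 0], [5, 0, 0, 0]]
        )
        groups = {"T1": ["a", "b"], "T2": ["c", "d"]}
        flags = flag_expressed(cm, groups, min_count=5)
        assert not flags.loc["g1", "T1"]  # max 4 < 5
        assert flags.loc["g2", "T1"]  # single sample at exactly 5
        assert not flags.loc["g2", "T2"]

    def test_flag_expressed_matches_brute_force(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            rng.integers(0, 8, size=(30, 6)),
            index=[f"g{i}" for i in range(30)],
            columns=list("abcdef"),
        )
        groups = {"T1": ["a", "b", "c"], "T2": ["d", "e", "f"]}
        flags = flag_expressed(df, groups, min_count=5)
        for g in df.index:
            for t, ss in groups.items():
                assert flags.loc[g, t] == (df.loc[g, ss].max() >= 5)

    def test_unknown_rule_is_error(self):
        with pytest.raises(ValueError, match="unknown filter rule"):
            filter_analysis_genes(pd.DataFrame(), {}, rule="nope")


class TestDispersion:
    def test_poisson_data_yields_near_zero(self):
        cfg = SimConfig(
            n_tissues=1, n_genes=2000, temperatures=(10.0, 22.0),
            n_samples_per_group=5, pool_size=1, dispersion=1e-13,
            lib_size_mean=200_000, lib_size_cv=0.0, seed=2,
            frac_tissue_exclusive=0.0,
        )
        cm, sheet = simulate_null(cfg)
        groups = {
            str(t): list(g.sample_id) for t, g in sheet.groupby("temperature_c")
        }
        est = estimate_dispersion(cm, groups)
        assert est.common < 0.01

    def test_nb_dispersion_recovered(self):
        cfg = SimConfig(
            n_tissues=1, n_genes=2000, temperatures=(10.0, 22.0),
            n_samples_per_group=5, pool_size=1, dispersion=0.2,
            lib_size_mean=200_000, seed=2, frac_tissue_exclusive=0.0,
        )
        cm, sheet = simulate_null(cfg)
        groups = {
            str(t): list(g.sample_id) for t, g in sheet.groupby("temperature_c")
        }
        est = estimate_dispersion(cm, groups)
        assert 0.15 <= est.common <= 0.25

    def test_single_sample_groups_unidentifiable(self):
        cm = CountMatrix(["g1"], ["a", "b"], [[3, 5]])
        with pytest.raises(ValueError, match=">= 2 samples"):
            estimate_dispersion(cm, {"x": ["a"], "y": ["b"]})


class TestExactTest:
    def test_identical_group_totals_give_zero_lfc_p_one(self):
        cm = CountMatrix(
            ["g1"], ["a", "b", "c", "d"], [[10, 10, 10, 10]]
        )
        res = exact_test(cm, ["a", "b"], ["c", "d"], 0.0)
        assert res.loc["g1", "log2fc"] == 0.0
        assert res.loc["g1", "p_value"] == pytest.approx(1.0)

    @pytest.mark.parametrize("n_a,n_b", [(2, 2), (3, 2)])
    def test_phi_zero_equals_enumeration_oracle(self, n_a, n_b):
        # sweep over conditioned totals and observed splits
        for t in [1, 2, 3, 5, 10, 17, 40]:
            for s in range(t + 1):
                mine = _exact_pvalue(s, t, n_a, n_b, 0.0)
                oracle = float(binomial_conditional_oracle(s, t, n_a, n_b))
                assert mine == pytest.approx(oracle, rel=1e-9), (t, s)

    def test_end_to_end_equal_libraries_matches_oracle(self):
        # equal library sizes: pseudo-counts are the raw counts and the
        # public API reproduces the enumeration oracle
        cm = CountMatrix(
            ["g1", "g2"],
            ["a", "b", "c", "d"],
            [[7, 3, 1, 1], [13, 17, 19, 19]],  # equal column sums (20)
        )
        res = exact_test(cm, ["a", "b"], ["c", "d"], 0.0)
        for gene in ("g1", "g2"):
            sa = cm.to_frame().loc[gene, ["a", "b"]].sum()
            t = cm.to_frame().loc[gene].sum()
            oracle = float(binomial_conditional_oracle(int(sa), int(t), 2, 2))
            assert res.loc[gene, "p_value"] == pytest.approx(oracle, rel=1e-9)

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            rng.negative_binomial(10, 0.1, size=(40, 6)),
            index=[f"g{i}" for i in range(40)],
            columns=list("abcdef"),
        )
        fwd = exact_test(df, ["a", "b", "c"], ["d", "e", "f"], 0.1)
        rev = exact_test(df, ["d", "e", "f"], ["a", "b", "c"], 0.1)
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["p_value"], rev["p_value"])

    def test_overlapping_groups_rejected(self):
        cm = CountMatrix(["g1"], ["a", "b"], [[1, 2]])
        with pytest.raises(ValueError, match="overlap"):
            exact_test(cm, ["a"], ["a", "b"], 0.0)

    def test_null_nb_simulation_calibrated(self):
        cfg = SimConfig(
            n_tissues=1, n_genes=1500, temperatures=(10.0, 22.0),
            n_samples_per_group=5, pool_size=1, dispersion=0.1,
            lib_size_mean=150_000, seed=9, frac_tissue_exclusive=0.0,
        )
        cm, sheet = simulate_null(cfg)
        ctrl = list(sheet.loc[sheet.temperature_c == 22.0, "sample_id"])
        trt = list(sheet.loc[sheet.temperature_c == 10.0, "sample_id"])
        est = estimate_dispersion(cm, {"c": ctrl, "t": trt})
        res = exact_test(cm, ctrl, trt, est.common)
        nz = cm.to_frame().sum(axis=1) > 0
        rate = (res.loc[nz, "p_value"] <= 0.05).mean()
        n = int(nz.sum())
        half = 2.576 * math.sqrt(0.05 * 0.95 / n)
        assert 0.05 - half <= rate <= 0.05 + half


class TestCalling:
    def test_fc_boundary_uses_1_5_fold(self):
        table = pd.DataFrame(
            {
                "log2fc": [0.58, math.log2(1.5), -2.0, 1.0],
                "p_value": [0.01, 0.01, 0.001, 0.2],
                "mean_logcpm": 5.0,
            },
            index=["a", "b", "c", "d"],
        )
        out = call_de(table)
        assert out.loc["a", "call"] == "ns"  # 0.58 < log2 1.5
        assert out.loc["b", "call"] == "up"
        assert out.loc["c", "call"] == "down"
        assert out.loc["d", "call"] == "ns"  # p too large

    def test_call_counts_match_brute_force(self):
        rng = np.random.default_rng(7)
        table = pd.DataFrame(
            {
                "log2fc": rng.normal(0, 1.2, 200),
                "p_value": rng.uniform(0, 1, 200),
                "mean_logcpm": 5.0,
            },
            index=[f"g{i}" for i in range(200)],
        )
        table.iloc[:10, table.columns.get_loc("p_value")] = np.nan
        out = call_de(table)
        cut = math.log2(1.5)
        for g, row in out.iterrows():
            if np.isnan(row["p_value"]):
                expect = "untested"
            elif row["p_value"] <= 0.05 and row["log2fc"] >= cut:
                expect = "up"
            elif row["p_value"] <= 0.05 and row["log2fc"] <= -cut:
                expect = "down"
            else:
                expect = "ns"
            assert row["call"] == expect
        summary = out["call"].value_counts()
        assert summary.sum() == 200  # partition property

    def test_bh_adjustment_reduces_calls(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame(
            {
                "log2fc": rng.normal(0, 2, 300),
                "p_value": rng.uniform(0, 1, 300),
                "mean_logcpm": 5.0,
            },
            index=[f"g{i}" for i in range(300)],
        )
        raw = call_de(table, adjust="none")
        adj = call_de(table, adjust="bh")
        n_raw = (raw["call"] != "ns").sum()
        n_adj = (adj["call"] != "ns").sum()
        assert n_adj <= n_raw

    def test_bh_matches_reference_formula(self):
        p = pd.Series([0.01, 0.02, 0.03, 0.5, 1.0])
        q = bh_adjust(p)
        # hand-computed step-up values
        assert np.allclose(q, [0.05, 0.05, 0.05, 0.625, 1.0])


class TestDeTablePipeline:
    def test_partition_and_untested_semantics(self, toy):
        cm, sheet, _ = toy
        det = de_table(cm, sheet, "iBAT", 10.0)
        s = det.summary()
        assert sum(s.values()) == cm.shape[0]
        untested = det.table[det.table["call"] == "untested"]
        assert untested["p_value"].isna().all()

    def test_contrast_set_shares_control(self, toy_contrasts):
        cs = toy_contrasts[10.0]
        ctrls = {det.control_temp for det in cs}
        assert ctrls == {22.0}
        assert set(cs.tissues()) == {"iBAT", "ingSAT", "Liver"}
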