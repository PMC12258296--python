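"""NB Wald engine, shrinkage, BH/BY adjustment and DEG calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import concordx as cx


def _counts(array, groups, index=None):
    frame = pd.DataFrame(
        np.asarray(array), index=index or [f"g{i}" for i in range(len(array))],
        columns=[f"s{i}" for i in range(len(groups))],
    )
    return cx.CountMatrix(frame), list(groups)


class TestNbWaldDge:
    def test_flat_gene_is_exact_null(self):
        cm, groups = _counts([[20] * 6, [7] * 6], "AAABBB")
        res = cx.nb_wald_dge(cm, groups=groups)
        assert res.table["lfc_raw"].abs().max() < 1e-10
        assert np.allclose(res.table["p"], 1.0)

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(5)
        cm, groups = _counts(rng.poisson(60, size=(40, 8)), "AAAABBBB")
        fwd = cx.nb_wald_dge(cm, groups=groups)
        rev = cx.nb_wald_dge(cm, groups=[{"A": "B", "B": "A"}[g] for g in groups])
        assert np.allclose(fwd.table["lfc_raw"], -rev.table["lfc_raw"], atol=1e-8)
        assert np.allclose(fwd.table["p"], rev.table["p"], atol=1e-8)

    def test_all_zero_gene_undefined_and_excluded_from_m(self):
        cm, groups = _counts([[0] * 6, [30, 28, 31, 55, 60, 57]], "AAABBB")
        res = cx.nb_wald_dge(cm, groups=groups)
        assert np.isnan(res.table.loc["g0", "p"])
        assert np.isnan(res.table.loc["g0", "padj_by"])
        # single defined test: padj equals p (c(1) = 1)
        assert res.table.loc["g1", "padj_by"] == pytest.approx(res.table.loc["g1", "p"])

    def test_effect_recovery(self):
        """True lfc=2 at mu=500, n=10 vs 10: estimate lands within +-0.3."""
        rng_seeds = range(40)
        hits = 0
        for seed in rng_seeds:
            truth = cx.TrueExpression(
                gene_ids=("g",),
                baseline_log2=np.array([np.log2(500.0)]),
                lfc_true=np.array([2.0]),
                is_de=np.array([True]),
                sample_ids=tuple(f"s{i}" for i in range(20)),
                group_of_sample=tuple("A" * 10 + "B" * 10),
                bio_log2=np.zeros((1, 20)),
            )
            params = cx.PlatformParams(dispersion=0.05, library_size_log2_sd=0,
                                       capture_log2_sd=0, noise_log2_sd=0)
            cm = cx.simulate_platform(truth, params, seed=seed)
            res = cx.nb_wald_dge(cm, groups=list(truth.group_of_sample))
            if abs(res.table["lfc_raw"].iloc[0] - 2.0) <= 0.3:
                hits += 1
        assert hits >= 0.95 * len(list(rng_seeds))

    def test_poisson_consistency(self):
        """At phi ~ 0 and large counts the Wald fit matches a Poisson GLM."""
        import statsmodels.api as statsmodels

        rng = np.random.default_rng(9)
        y = rng.poisson([2000] * 5 + [4000] * 5, size=(30, 10))
        cm, groups = _counts(y, "AAAAABBBBB")
        res = cx.nb_wald_dge(cm, groups=groups)
        x = np.column_stack([np.ones(10), np.array([0] * 5 + [1] * 5)])
        for i in range(5):
            fit = statsmodels.GLM(y[i], x, family=statsmodels.families.Poisson()).fit()
            assert res.table["lfc_raw"].iloc[i] == pytest.approx(
                fit.params[1] / np.log(2), abs=5e-3
            )

    def test_type_i_error_calibration(self):
        """Null simulation: raw p <= 0.05 fraction within 3 binomial SEs."""
        truth = cx.simulate_truth(2000, (5, 5), de_fraction=0.0, bio_log2_sd=0.0, seed=11)
        params = cx.PlatformParams(dispersion=0.2, library_size_log2_sd=0.25,
                                   capture_log2_sd=0.0, noise_log2_sd=0.0)
        cm = cx.simulate_platform(truth, params, seed=111)
        sf = cx.dge_size_factors(cm, "rle")
        res = cx.nb_wald_dge(cm, groups=list(truth.group_of_sample), size_factors=sf)
        p = res.table["p"].dropna()
        frac = float((p <= 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / len(p))
        assert abs(frac - 0.05) <= 3 * se

    def test_group_errors(self):
        cm, _ = _counts([[5] * 4], "AABB")
        with pytest.raises(cx.ValidationError):
            cx.nb_wald_dge(cm, groups=["A", "A", "A", "A"])
        with pytest.raises(cx.ValidationError):
            cx.nb_wald_dge(cm, groups=["A", "B", "C", "A"])


class TestShrinkage:
    def _result(self, lfc, se):
        tab = pd.DataFrame(
            {"base_mean": 10.0, "lfc_raw": lfc, "lfc_shrunk": np.nan,
             "se": se, "p": 0.5, "padj_bh": 0.5, "padj_by": 0.5, "dispersion": 0.1},
            index=[f"g{i}" for i in range(len(lfc))],
        )
        return cx.DGEResult(tab, "A", "B")

    def test_conjugate_posterior_mean(self):
        res = cx.shrink_lfc(self._result([2.0], [1.0]), prior_sd=1.0)
        assert res.table["lfc_shrunk"].iloc[0] == pytest.approx(1.0)

    def test_flat_and_point_prior_limits(self):
        res = self._result([2.0, -1.5], [0.5, 1.0])
        wide = cx.shrink_lfc(res, prior_sd=1e9)
        assert np.allclose(wide.table["lfc_shrunk"], wide.table["lfc_raw"], rtol=1e-6)
        narrow = cx.shrink_lfc(res, prior_sd=1e-6)
        assert np.all(np.abs(narrow.table["lfc_shrunk"]) < 1e-6)
        with pytest.raises(cx.ValidationError):
            cx.shrink_lfc(res, prior_sd=-1.0)

    def test_shrinks_toward_zero_monotonically_in_se(self):
        lfc = [2.0] * 5
        se = [0.1, 0.5, 1.0, 2.0, 5.0]
        res = cx.shrink_lfc(self._result(lfc, se), prior_sd=1.0)
        shrunk = res.table["lfc_shrunk"].to_numpy()
        assert np.all(np.abs(shrunk) <= np.abs(lfc))
        assert np.all(np.diff(shrunk) < 0)  # more se, more shrinkage
        assert np.all(np.sign(shrunk) == np.sign(lfc))


class TestAdjustPvalues:
    def test_single_p(self):
        assert cx.adjust_pvalues([0.03], "BH")[0] == pytest.approx(0.03)
        assert cx.adjust_pvalues([0.03], "BY")[0] == pytest.approx(0.03)

    def test_hand_computed_vector(self):
        p = [0.01, 0.02, 0.03, 0.04]
        assert np.allclose(cx.adjust_pvalues(p, "BH"), 0.04)
        assert np.allclose(cx.adjust_pvalues(p, "BY"), 25 / 12 * 0.04)

    def test_matches_statsmodels(self, rng):
        import statsmodels.stats.multitest as statsmodels

        p = rng.uniform(size=200)
        for method, key in (("BH", "fdr_bh"), ("BY", "fdr_by")):
            mine = cx.adjust_pvalues(p, method)
            ref = statsmodels.multipletests(p, method=key)[1]
            assert np.allclose(mine, ref, atol=1e-12)

    def test_nan_passthrough_does_not_count(self):
        p = [0.01, np.nan, 0.04]
        out = cx.adjust_pvalues(p, "BH")
        assert np.isnan(out[1])
        # m=2: adjusted = [min(0.01*2/1, 0.04*2/2), 0.04]
        assert out[0] == pytest.approx(0.02)
        assert out[2] == pytest.approx(0.04)

    def test_invalid_p_rejected(self):
        with pytest.raises(cx.ValidationError):
            cx.adjust_pvalues([1.2], "BH")

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50))
    def test_by_never_below_bh(self, p):
        bh = cx.adjust_pvalues(p, "BH")
        by = cx.adjust_pvalues(p, "BY")
        assert np.all(by >= bh - 1e-15)
        assert np.all(by >= np.asarray(p) - 1e-15)


class TestCallDegs:
    def _result(self, rows):
        tab = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))])
        tab["base_mean"], tab["se"], tab["p"], tab["dispersion"] = 10.0, 0.2, 0.01, 0.1
        tab["lfc_shrunk"] = tab["lfc_raw"]
        tab["padj_bh"] = tab["padj_by"]
        return cx.DGEResult(tab, "A", "B")

    def test_inclusive_boundaries_and_gates(self):
        res = self._result(
            [
                {"lfc_raw": 1.0, "padj_by": 0.05},   # DEG, up (both boundaries)
                {"lfc_raw": 0.5, "padj_by": 0.001},  # fails fold-change gate
                {"lfc_raw": -2.0, "padj_by": 0.2},   # fails significance gate
                {"lfc_raw": -1.0, "padj_by": 0.05},  # DEG, down
            ]
        )
        degs = cx.call_degs(res, cx.DGEThresholds())
        assert list(degs.index) == ["g0", "g3"]
        assert degs.loc["g0", "direction"] == "up"
        assert degs.loc["g3", "direction"] == "down"

    def test_by_more_conservative_than_bh_on_simulated_runs(self):
        for seed in (1, 2):
            cfg = cx.default_config("hga_vs_agasac", n_genes=800, n_endogenous=150,
                                    n_housekeeping=10, n_missing=2, seed=seed)
            study = cx.simulate_paired_study(cfg)
            sf = cx.dge_size_factors(study.seq_counts, "rle")
            res = cx.shrink_lfc(cx.nb_wald_dge(study.seq_counts, size_factors=sf))
            n_by = len(cx.call_degs(res, cx.DGEThresholds(adjust="BY")))
            n_bh = len(cx.call_degs(res, cx.DGEThresholds(adjust="BH")))
            assert n_by <= n_bh
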