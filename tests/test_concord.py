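"""Annotation overlap, log2FC concordance, direction classes, Venn/Jaccard."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import concordx as cx
from concordx.concord import DIRECTION_LABELS


def make_result(rows: pd.DataFrame) -> cx.DGEResult:
    tab = rows.copy()
    tab["base_mean"] = tab.get("base_mean", 50.0)
    tab["se"] = tab.get("se", 0.3)
    tab["p"] = tab.get("p", tab["padj_by"])
    tab["padj_bh"] = tab.get("padj_bh", tab["padj_by"])
    tab["dispersion"] = 0.1
    if "lfc_shrunk" not in tab.columns:
        tab["lfc_shrunk"] = tab["lfc_raw"]
    return cx.DGEResult(tab, "A", "B")


def paired_tables(n_both=3, n_a_only=2, n_b_only=2, n_ns=4, seed=0):
    """Two DGE tables realizing known direction-class counts."""
    rng = np.random.default_rng(seed)
    rows_a, rows_b, idx = [], [], []

    def add(kind, i):
        sig = {"lfc_raw": 1.5 + rng.random(), "padj_by": 0.01}
        down = {"lfc_raw": -1.5 - rng.random(), "padj_by": 0.01}
        ns = {"lfc_raw": rng.uniform(-0.5, 0.5), "padj_by": 0.6}
        if kind == "both":
            a = b = down if i % 2 else sig
        elif kind == "a_only":
            a, b = sig, ns
        elif kind == "b_only":
            a, b = ns, down
        else:
            a, b = ns, dict(ns)
        rows_a.append(dict(a))
        rows_b.append(dict(b))
        idx.append(f"{kind}_{i}")

    for kind, n in (("both", n_both), ("a_only", n_a_only), ("b_only", n_b_only), ("ns", n_ns)):
        for i in range(n):
            add(kind, i)
    a = make_result(pd.DataFrame(rows_a, index=idx))
    b = make_result(pd.DataFrame(rows_b, index=idx))
    return a, b


class TestAnnotationOverlap:
    def test_subset_panel_full_overlap(self):
        rep = cx.annotation_overlap(["a", "b"], ["a", "b", "c"])
        assert rep.pct_found == 100.0 and rep.missing_ids == []

    def test_missing_ids_sorted_and_counted(self):
        rep = cx.annotation_overlap(["z", "a", "m"], ["a"])
        assert rep.missing_ids == ["m", "z"]
        assert rep.n_found + rep.n_missing == rep.n_panel

    def test_duplicate_or_empty_rejected(self):
        with pytest.raises(cx.ValidationError):
            cx.annotation_overlap([], ["a"])
        with pytest.raises(cx.ValidationError):
            cx.annotation_overlap(["a", "a"], ["a"])

    @pytest.mark.parametrize(
        "pct,display", [(100 * 821 / 830, 98.9), (100 * 790 / 800, 98.75), (100 * 9 / 830, 1.1)]
    )
    def test_percentage_display_rule(self, pct, display):
        assert cx.format_percentage(pct) == display


class TestLfcConcordance:
    def test_identity_and_negation(self):
        a, b = paired_tables()
        p, s, genes = cx.lfc_concordance(a, a)
        assert p == pytest.approx(1.0) and s == pytest.approx(1.0)
        neg = make_result(a.table.assign(lfc_raw=-a.table["lfc_raw"],
                                         lfc_shrunk=-a.table["lfc_shrunk"]))
        p, s, _ = cx.lfc_concordance(a, neg)
        assert p == pytest.approx(-1.0) and s == pytest.approx(-1.0)

    def test_toy_table_matches_direct_formulas(self):
        lfc_a = np.array([0.5, -1.2, 2.0, 0.1, -0.7, 1.4])
        lfc_b = np.array([0.7, -1.0, 1.4, -0.2, -0.9, 1.9])
        a = make_result(pd.DataFrame({"lfc_raw": lfc_a, "padj_by": 0.5},
                                     index=list("abcdef")))
        b = make_result(pd.DataFrame({"lfc_raw": lfc_b, "padj_by": 0.5},
                                     index=list("abcdef")))
        p, s, genes = cx.lfc_concordance(a, b)
        ca = lfc_a - lfc_a.mean()
        cb = lfc_b - lfc_b.mean()
        pearson = (ca * cb).sum() / np.sqrt((ca**2).sum() * (cb**2).sum())
        assert p == pytest.approx(pearson, abs=1e-12)
        assert s == pytest.approx(cx.spearman(lfc_a, lfc_b), abs=1e-12)
        assert len(genes) == 6

    def test_undefined_genes_excluded(self):
        a, b = paired_tables()
        a.table.loc["both_0", "lfc_raw"] = np.nan
        _, _, genes = cx.lfc_concordance(a, b)
        assert "both_0" not in genes


class TestClassifyDirections:
    def test_semantics(self):
        a = make_result(pd.DataFrame(
            {"lfc_raw": [-1.5, 1.4, 0.2], "padj_by": [0.01, 0.02, 0.9]},
            index=["g1", "g2", "g3"]))
        b = make_result(pd.DataFrame(
            {"lfc_raw": [-2.0, 0.3, -0.4], "padj_by": [0.001, 0.40, 0.7]},
            index=["g1", "g2", "g3"]))
        classes = cx.classify_directions(a, b)
        assert classes.labels["g1"] == "both_down"
        assert classes.labels["g2"] == "a_only_up"
        assert classes.labels["g3"] == "not_significant"

    def test_opposite_class_exists(self):
        a = make_result(pd.DataFrame({"lfc_raw": [2.0], "padj_by": [0.01]}, index=["g"]))
        b = make_result(pd.DataFrame({"lfc_raw": [-2.0], "padj_by": [0.01]}, index=["g"]))
        assert cx.classify_directions(a, b).labels["g"] == "opposite"

    def test_partition_and_swap_symmetry(self):
        a, b = paired_tables(5, 3, 4, 7, seed=3)
        fwd = cx.classify_directions(a, b)
        assert sum(fwd.tallies.values()) == fwd.n_genes == 19
        assert set(fwd.tallies) == set(DIRECTION_LABELS)
        rev = cx.classify_directions(b, a)
        assert rev.tallies["a_only_up"] == fwd.tallies["b_only_up"]
        assert rev.tallies["a_only_down"] == fwd.tallies["b_only_down"]
        assert rev.tallies["both_up"] == fwd.tallies["both_up"]

    def test_tallies_reconcile_with_call_degs(self):
        a, b = paired_tables(6, 2, 5, 9, seed=4)
        classes = cx.classify_directions(a, b)
        degs_a = set(cx.call_degs(a).index)
        degs_b = set(cx.call_degs(b).index)
        t = classes.tallies
        assert t["both_up"] + t["both_down"] + t["opposite"] == len(degs_a & degs_b)
        assert t["a_only_up"] + t["a_only_down"] == len(degs_a - degs_b)
        assert t["b_only_up"] + t["b_only_down"] == len(degs_b - degs_a)


class TestJaccard:
    def test_printed_set_sizes(self):
        a = {f"x{i}" for i in range(182)}
        b = set(list(a)[:120]) | {f"y{i}" for i in range(50)}
        assert len(b) == 170
        assert cx.jaccard(a, b) == pytest.approx(120 / 232, abs=1e-12)
        assert round(cx.jaccard(a, b), 2) == 0.52

    def test_empty_conventions(self):
        assert cx.jaccard(set(), {f"g{i}" for i in range(89)}) == 0.0
        assert cx.jaccard(set(), set()) == 0.0
        assert cx.jaccard({"a"}, {"a"}) == 1.0

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.sets(st.integers(0, 30)), st.sets(st.integers(0, 30)))
    def test_symmetry_and_bounds(self, a, b):
        j = cx.jaccard(a, b)
        assert 0.0 <= j <= 1.0
        assert j == cx.jaccard(b, a)
        assert (j == 1.0) == (a == b and len(a) > 0)


class TestBuildReport:
    def _panel_for(self, genes, missing=()):
        return cx.PanelDefinition(endogenous=list(genes),
                                  missing_from_annotation=list(missing))

    def test_identical_results(self):
        a, b = paired_tables(4, 0, 0, 5, seed=1)
        panel = self._panel_for(a.gene_ids)
        rep = cx.build_report(a, a, panel, annotation=a.gene_ids)
        assert rep.jaccard == 1.0
        t = rep.classes.tallies
        assert t["a_only_up"] == t["b_only_up"] == t["opposite"] == 0
        assert t["both_up"] + t["both_down"] == 4

    def test_partition_sums_to_shared_genes(self):
        a, b = paired_tables(3, 2, 2, 6, seed=2)
        panel = self._panel_for(a.gene_ids, missing=["ns_0"])
        rep = cx.build_report(a, b, panel, annotation=[g for g in a.gene_ids if g != "ns_0"])
        assert sum(rep.classes.tallies.values()) == rep.n_shared_genes == 12
        assert rep.venn["a_only"] + rep.venn["both"] == len(rep.degs_a)
        assert rep.venn["b_only"] + rep.venn["both"] == len(rep.degs_b)

    def test_signal_beats_noise_on_jaccard(self):
        def run(de_fraction, seed):
            cfg = cx.default_config(
                "hga_vs_agasac", n_genes=900, n_endogenous=200, n_housekeeping=10,
                n_missing=2, de_fraction=de_fraction, lfc_sd=2.0, seed=seed)
            study = cx.simulate_paired_study(cfg)
            res = {}
            for name, cm, method in (
                ("panel", study.panel_counts.subset_genes(study.panel.content_genes), "rle"),
                ("seq", study.seq_counts, "rle"),
            ):
                sf = cx.dge_size_factors(cm, method)
                res[name] = cx.shrink_lfc(cx.nb_wald_dge(cm, size_factors=sf))
            rep = cx.build_report(res["panel"], res["seq"], study.panel,
                                  annotation=study.seq_counts.gene_ids)
            return rep.jaccard

        # strong shared DE signal vs a pure-noise study at fixed seeds
        assert run(0.25, seed=7) > run(0.0, seed=7)
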