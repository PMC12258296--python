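"""Cross-platform concordance of differential-expression results.

Given per-gene DGE tables from the two platforms this module reports:
how much of the panel is present in the sequencing annotation at all
(:func:`annotation_overlap`); how well the log2 fold changes agree
(:func:`lfc_concordance`); a per-gene direction classification (both
platforms significant and concordant, significant on one side only,
opposite, or not significant); and the Venn counts and Jaccard index of
the two DEG sets.  :func:`build_report` assembles everything for one
biological comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import PanelDefinition, ValidationError
from .correlate import _pearson, spearman
from .dge import DGEResult, DGEThresholds, call_degs

__all__ = [
    "OverlapReport",
    "DirectionClass",
    "ConcordanceReport",
    "annotation_overlap",
    "lfc_concordance",
    "classify_directions",
    "jaccard",
    "build_report",
    "format_percentage",
]

DIRECTION_LABELS = (
    "both_down",
    "both_up",
    "a_only_down",
    "a_only_up",
    "b_only_down",
    "b_only_up",
    "opposite",
    "not_significant",
)


def format_percentage(pct: float) -> float:
    """Round a percentage for reporting: one decimal by default, two kept
    when the value is exact at two decimals but not at one (e.g. 98.75)."""
    r2 = round(pct, 2)
    r1 = round(pct, 1)
    if r2 == pct and r1 != pct:
        return r2
    return r1


@dataclass
class OverlapReport:
    """Panel genes found in / missing from the sequencing annotation."""

    n_panel: int
    n_found: int
    missing_ids: list[str]

    @property
    def n_missing(self) -> int:
        return self.n_panel - self.n_found

    @property
    def pct_found(self) -> float:
        return 100.0 * self.n_found / self.n_panel

    @property
    def pct_missing(self) -> float:
        return 100.0 * self.n_missing / self.n_panel

    def to_dict(self) -> dict:
        return {
            "n_panel": self.n_panel,
            "n_found": self.n_found,
            "n_missing": self.n_missing,
            "pct_found": self.pct_found,
            "pct_found_display": format_percentage(self.pct_found),
            "pct_missing": self.pct_missing,
            "pct_missing_display": format_percentage(self.pct_missing),
            "missing_ids": list(self.missing_ids),
        }


def annotation_overlap(panel_genes, annotation_genes) -> OverlapReport:
    """Which panel genes exist in the annotation; missing IDs sorted."""
    panel_genes = list(panel_genes)
    if not panel_genes:
        raise ValidationError("panel gene list is empty")
    if len(set(panel_genes)) != len(panel_genes):
        raise ValidationError("duplicate IDs in panel gene list")
    annotation = set(annotation_genes)
    if len(annotation) != len(list(annotation_genes)):
        raise ValidationError("duplicate IDs in annotation gene list")
    missing = sorted(g for g in panel_genes if g not in annotation)
    return OverlapReport(
        n_panel=len(panel_genes),
        n_found=len(panel_genes) - len(missing),
        missing_ids=missing,
    )


def _shared_defined(res_a: DGEResult, res_b: DGEResult, col: str) -> pd.DataFrame:
    shared = [g for g in res_a.gene_ids if g in set(res_b.gene_ids)]
    a = res_a.table.loc[shared, col]
    b = res_b.table.loc[shared, col]
    ok = a.notna() & b.notna()
    return pd.DataFrame({"a": a[ok], "b": b[ok]})


def lfc_concordance(
    res_a: DGEResult, res_b: DGEResult, use_shrunk: bool = False
) -> tuple[float, float, list[str]]:
    """Pearson and Spearman correlation of the two platforms' log2 fold
    changes over the shared genes with defined estimates (the gene set
    used is returned as the third element)."""
    col = "lfc_shrunk" if use_shrunk else "lfc_raw"
    pairs = _shared_defined(res_a, res_b, col)
    if len(pairs) < 3:
        raise ValidationError(f"only {len(pairs)} shared genes with defined {col}")
    a = pairs["a"].to_numpy()
    b = pairs["b"].to_numpy()
    return _pearson(a, b), spearman(a, b), list(pairs.index)


@dataclass
class DirectionClass:
    """Per-gene direction labels and their tallies (a partition)."""

    labels: pd.Series
    tallies: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = self.labels.value_counts().to_dict()
        self.tallies = {lab: int(counts.get(lab, 0)) for lab in DIRECTION_LABELS}

    @property
    def n_genes(self) -> int:
        return int(len(self.labels))


def _significant(table: pd.DataFrame, thresholds: DGEThresholds, lfc_col: str, padj_col: str):
    lfc = table[lfc_col]
    padj = table[padj_col]
    sig = (padj <= thresholds.alpha) & (np.abs(lfc) >= thresholds.lfc_cut)
    return sig.fillna(False), lfc


def classify_directions(
    res_a: DGEResult,
    res_b: DGEResult,
    thresholds: DGEThresholds | None = None,
    use_shrunk: bool = True,
) -> DirectionClass:
    """Label every shared gene with defined statistics on both platforms.

    both_{up,down}: significant on both platforms, same sign; x_only_*:
    significant on exactly one platform, direction by that platform's
    sign; opposite: significant on both with opposite signs; otherwise
    not_significant.
    """
    thresholds = thresholds or DGEThresholds()
    lfc_col = "lfc_shrunk" if use_shrunk else "lfc_raw"
    padj_col = "padj_by" if thresholds.adjust.upper() == "BY" else "padj_bh"
    shared = [g for g in res_a.gene_ids if g in set(res_b.gene_ids)]
    ta = res_a.table.loc[shared]
    tb = res_b.table.loc[shared]
    ok = (
        ta[lfc_col].notna()
        & ta[padj_col].notna()
        & tb[lfc_col].notna()
        & tb[padj_col].notna()
    )
    ta, tb = ta[ok], tb[ok]
    sig_a, lfc_a = _significant(ta, thresholds, lfc_col, padj_col)
    sig_b, lfc_b = _significant(tb, thresholds, lfc_col, padj_col)
    up_a = lfc_a > 0
    up_b = lfc_b > 0
    labels = pd.Series("not_significant", index=ta.index, dtype=object)
    both = sig_a & sig_b
    labels[both & up_a & up_b] = "both_up"
    labels[both & ~up_a & ~up_b] = "both_down"
    labels[both & (up_a != up_b)] = "opposite"
    only_a = sig_a & ~sig_b
    labels[only_a & up_a] = "a_only_up"
    labels[only_a & ~up_a] = "a_only_down"
    only_b = sig_b & ~sig_a
    labels[only_b & up_b] = "b_only_up"
    labels[only_b & ~up_b] = "b_only_down"
    return DirectionClass(labels=labels)


def jaccard(set_a, set_b) -> float:
    """|A intersect B| / |A union B|; 0 when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


@dataclass
class ConcordanceReport:
    """Everything about one biological comparison across the platforms."""

    overlap: OverlapReport
    lfc_pearson_raw: float
    lfc_spearman_raw: float
    lfc_pearson_shrunk: float
    lfc_spearman_shrunk: float
    classes: DirectionClass
    venn: dict[str, int]
    jaccard: float
    degs_a: list[str]
    degs_b: list[str]
    n_shared_genes: int

    def to_dict(self) -> dict:
        return {
            "overlap": self.overlap.to_dict(),
            "lfc_correlation": {
                "pearson_raw": self.lfc_pearson_raw,
                "spearman_raw": self.lfc_spearman_raw,
                "pearson_shrunk": self.lfc_pearson_shrunk,
                "spearman_shrunk": self.lfc_spearman_shrunk,
            },
            "direction_classes": dict(self.classes.tallies),
            "n_classified_genes": self.classes.n_genes,
            "venn": dict(self.venn),
            "jaccard": self.jaccard,
            "jaccard_2dp": round(self.jaccard, 2),
            "n_deg_a": len(self.degs_a),
            "n_deg_b": len(self.degs_b),
            "n_shared_genes": self.n_shared_genes,
        }


def build_report(
    res_a: DGEResult,
    res_b: DGEResult,
    panel: PanelDefinition,
    annotation,
    thresholds: DGEThresholds | None = None,
    use_shrunk_for_classes: bool = True,
) -> ConcordanceReport:
    """Assemble the full concordance record for one comparison.

    Panel genes absent from the annotation are excluded before every
    cross-platform computation; ``res_a`` plays the panel role and
    ``res_b`` the sequencing role.
    """
    thresholds = thresholds or DGEThresholds()
    overlap = annotation_overlap(panel.content_genes, annotation)
    missing = set(overlap.missing_ids)
    shared = [
        g
        for g in res_a.gene_ids
        if g in set(res_b.gene_ids) and g not in missing
    ]
    if len(shared) < 3:
        raise ValidationError("fewer than 3 shared annotated genes")
    sub_a = DGEResult(res_a.table.loc[shared].copy(), res_a.baseline, res_a.contrast)
    sub_b = DGEResult(res_b.table.loc[shared].copy(), res_b.baseline, res_b.contrast)
    p_raw, s_raw, _ = lfc_concordance(sub_a, sub_b, use_shrunk=False)
    have_shrunk = sub_a.table["lfc_shrunk"].notna().any() and sub_b.table["lfc_shrunk"].notna().any()
    if have_shrunk:
        p_sh, s_sh, _ = lfc_concordance(sub_a, sub_b, use_shrunk=True)
    else:
        p_sh = s_sh = float("nan")
    classes = classify_directions(
        sub_a, sub_b, thresholds, use_shrunk=use_shrunk_for_classes and have_shrunk
    )
    degs_a = call_degs(sub_a, thresholds, use_shrunk=use_shrunk_for_classes and have_shrunk)
    degs_b = call_degs(sub_b, thresholds, use_shrunk=use_shrunk_for_classes and have_shrunk)
    set_a = set(degs_a.index)
    set_b = set(degs_b.index)
    venn = {
        "a_only": len(set_a - set_b),
        "b_only": len(set_b - set_a),
        "both": len(set_a & set_b),
    }
    return ConcordanceReport(
        overlap=overlap,
        lfc_pearson_raw=p_raw,
        lfc_spearman_raw=s_raw,
        lfc_pearson_shrunk=p_sh,
        lfc_spearman_shrunk=s_sh,
        classes=classes,
        venn=venn,
        jaccard=jaccard(set_a, set_b),
        degs_a=sorted(set_a),
        degs_b=sorted(set_b),
        n_shared_genes=len(shared),
    )
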