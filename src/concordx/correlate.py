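"""Cross-platform correlation profiles.

Two axes are profiled.  Sample-wise: for each matched sample, the
correlation across the shared genes between the two platforms (how
similar is one sample's expression profile on both instruments).
Gene-wise: for each shared gene, the correlation of its counts across the
matched samples (how reproducibly does one gene move).  Coefficients are
Pearson, Pearson on log2(count + pseudocount) ("pearson_log", robust to
count outliers) and Spearman with mid-ranks for ties.

Gene-wise coefficients are additionally summarized within nested
expression strata (all genes, top 90%, top 50% by mean log expression)
because cross-platform agreement grows with expression strength.
Correlation strengths are labelled with the medical-field convention:
>= 0.8 very strong, 0.6-0.8 moderately strong, 0.3-0.6 fair, < 0.3 poor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import CountMatrix, ValidationError
from .normalize import NormalizedMatrix

__all__ = [
    "CorrelationSet",
    "StrataSpec",
    "BoxSummary",
    "pearson_log",
    "spearman",
    "correlation_profile",
    "strata_correlations",
    "classify_strength",
    "summarize_box",
]

COEFFICIENTS = ("pearson", "pearson_log", "spearman")


@dataclass
class BoxSummary:
    """Tukey box-plot summary: quartiles, 1.5x-IQR whiskers, outliers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float]
    n: int

    def to_dict(self) -> dict:
        return {
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "whisker_low": self.whisker_low,
            "whisker_high": self.whisker_high,
            "outliers": list(self.outliers),
            "n": self.n,
        }


@dataclass
class CorrelationSet:
    """Per-sample or per-gene coefficients under one (coefficient,
    normalization) pairing; undefined entries are NaN with a reason."""

    axis: str
    coefficient: str
    normalization: str
    ids: list[str]
    r: np.ndarray
    pseudocount: float | None = None
    reasons: dict[str, str] = field(default_factory=dict)

    @property
    def defined(self) -> np.ndarray:
        return self.r[~np.isnan(self.r)]

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.r).sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.r, index=self.ids, name=f"{self.coefficient}_{self.normalization}")

    def summary(self) -> BoxSummary:
        return summarize_box(self.r)


@dataclass
class StrataSpec:
    """Nested expression strata defined by quantiles of mean log expression."""

    quantiles: tuple[float, float] = (0.10, 0.50)
    labels: tuple[str, str, str] = ("all", "top90", "top50")
    basis_platform: str = "panel"

    def __post_init__(self) -> None:
        if not (0.0 < self.quantiles[0] < self.quantiles[1] < 1.0):
            raise ValidationError("strata quantiles must be strictly increasing in (0, 1)")


def _as_vectors(x, y, min_len: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < min_len:
        raise ValidationError(f"need 1-D vectors of length >= {min_len}")
    return x, y


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))


def pearson_log(x, y, pseudocount: float = 1.0) -> float:
    """Pearson correlation of log2(x + pseudocount) vs log2(y + pseudocount).

    Returns NaN (undefined) when either transformed vector is constant.
    """
    x, y = _as_vectors(x, y)
    if pseudocount < 0 or not np.isfinite(pseudocount):
        raise ValidationError("pseudocount must be a finite nonnegative real")
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("pearson_log expects nonnegative inputs")
    return _pearson(np.log2(x + pseudocount), np.log2(y + pseudocount))


def spearman(x, y) -> float:
    """Spearman rank correlation with mid-ranks for ties; NaN if constant."""
    x, y = _as_vectors(x, y)
    return _pearson(rankdata(x), rankdata(y))


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((ac**2).sum(axis=1))
    sb = np.sqrt((bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ac * bc).sum(axis=1) / (sa * sb)
    r = np.where((sa == 0) | (sb == 0), np.nan, r)
    return np.clip(r, -1.0, 1.0)


def _values(m) -> pd.DataFrame:
    if isinstance(m, NormalizedMatrix):
        return m.values
    if isinstance(m, CountMatrix):
        return m.counts.astype(float)
    if isinstance(m, pd.DataFrame):
        return m.astype(float)
    raise ValidationError(f"cannot extract values from {type(m).__name__}")


def correlation_profile(
    a,
    b,
    axis: str,
    coefficient: str,
    pseudocount: float = 1.0,
    normalization: str = "",
) -> CorrelationSet:
    """One coefficient per shared sample (axis='sample', across the shared
    genes) or per shared gene (axis='gene', across the shared samples).

    The gene universe is the intersection of the two matrices' gene IDs;
    genes absent from either side (e.g. panel genes missing from the
    sequencing annotation) are excluded up front.  Units with zero
    variance on either side yield NaN with a reason, and are excluded
    from (but counted alongside) downstream summaries.
    """
    if axis not in ("sample", "gene"):
        raise ValidationError(f"axis must be 'sample' or 'gene', got {axis!r}")
    if coefficient not in COEFFICIENTS:
        raise ValidationError(f"unknown coefficient {coefficient!r}")
    va, vb = _values(a), _values(b)
    genes = [g for g in va.index if g in set(vb.index)]
    samples = [s for s in va.columns if s in set(vb.columns)]
    if axis == "sample" and len(genes) < 3:
        raise ValidationError(f"only {len(genes)} shared genes; need >= 3")
    if axis == "gene" and len(samples) < 3:
        raise ValidationError(f"only {len(samples)} shared samples; need >= 3")
    if not samples or not genes:
        raise ValidationError("matrices share no samples or no genes")
    ma = va.loc[genes, samples].to_numpy()
    mb = vb.loc[genes, samples].to_numpy()
    if axis == "sample":
        ma, mb = ma.T, mb.T
        ids = samples
    else:
        ids = genes
    if coefficient == "pearson_log":
        if (ma < 0).any() or (mb < 0).any():
            raise ValidationError("pearson_log expects nonnegative values")
        ma = np.log2(ma + pseudocount)
        mb = np.log2(mb + pseudocount)
    elif coefficient == "spearman":
        ma = rankdata(ma, axis=1)
        mb = rankdata(mb, axis=1)
    r = _rowwise_pearson(ma, mb)
    reasons = {
        ids[i]: "zero variance on at least one platform"
        for i in np.flatnonzero(np.isnan(r))
    }
    return CorrelationSet(
        axis=axis,
        coefficient=coefficient,
        normalization=normalization,
        ids=ids,
        r=r,
        pseudocount=pseudocount if coefficient == "pearson_log" else None,
        reasons=reasons,
    )


def strata_correlations(
    gene_set: CorrelationSet,
    mean_expr: pd.Series,
    spec: StrataSpec | None = None,
) -> dict[str, BoxSummary]:
    """Box summaries of gene-wise coefficients in nested expression strata.

    Thresholds are quantiles of ``mean_expr`` (default 10th and 50th
    percentiles, giving the top-90% and top-50% gene sets); every stratum
    is computed on defined coefficients only.
    """
    if gene_set.axis != "gene":
        raise ValidationError("strata require a gene-wise correlation set")
    spec = spec or StrataSpec()
    missing = [g for g in gene_set.ids if g not in mean_expr.index]
    if missing:
        raise ValidationError(f"mean_expr lacks genes: {missing[:10]}")
    expr = mean_expr.loc[gene_set.ids].to_numpy(dtype=float)
    thresholds = np.quantile(expr, spec.quantiles)
    r = gene_set.r
    out: dict[str, BoxSummary] = {}
    masks = (
        np.ones_like(expr, dtype=bool),
        expr >= thresholds[0],
        expr >= thresholds[1],
    )
    for label, mask in zip(spec.labels, masks):
        vals = r[mask]
        if vals.size == 0 or np.isnan(vals).all():
            raise ValidationError(f"stratum {label!r} has no defined coefficients")
        out[label] = summarize_box(vals)
    return out


def classify_strength(r: float) -> str:
    """Strength label of a correlation coefficient (applied to |r|)."""
    if np.isnan(r):
        return "undefined"
    if not (-1.0 <= r <= 1.0):
        raise ValidationError(f"correlation {r} outside [-1, 1]")
    a = abs(r)
    if a >= 0.8:
        return "very strong"
    if a >= 0.6:
        return "moderately strong"
    if a >= 0.3:
        return "fair"
    return "poor"


def summarize_box(values) -> BoxSummary:
    """Median/quartiles (linear interpolation), 1.5x-IQR whiskers, outliers."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValidationError("no defined values to summarize")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = np.sort(v[(v < lo_fence) | (v > hi_fence)])
    return BoxSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=[float(x) for x in outliers],
        n=int(v.size),
    )
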