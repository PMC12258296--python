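"""Two-group negative-binomial differential expression.

A deliberately compact engine: per-gene NB log-link GLM with a group
indicator, fit by iteratively reweighted least squares at a moment-based
dispersion estimate, a Wald test on the group coefficient, normal-prior
log2-fold-change shrinkage, and Benjamini-Hochberg / Benjamini-Yekutieli
step-up adjustment.  It approximates the behaviour of the heavyweight NB
DGE tools (no empirical-Bayes dispersion moderation, no adaptive
shrinkage priors) while keeping every numerical step explicit.

Model for gene g, sample s with size factor f_s and group indicator x_s:

    K_gs ~ NB(mu_gs, phi_g),   log mu_gs = log f_s + b0_g + b1_g * x_s

lfc_raw = b1 / ln 2 (log2 fold change, group B vs baseline A); the Wald
p-value uses a t reference with n - 2 degrees of freedom, the usual
small-sample guard when the dispersion is itself estimated per gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix, ValidationError
from .normalize import ScaleFactors

__all__ = [
    "DGEThresholds",
    "DGEResult",
    "nb_wald_dge",
    "shrink_lfc",
    "adjust_pvalues",
    "call_degs",
]

LN2 = float(np.log(2.0))
DISPERSION_FLOOR = 1e-8
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100


@dataclass(frozen=True)
class DGEThresholds:
    """Significance gates: |log2FC| >= lfc_cut AND padj <= alpha (inclusive)."""

    lfc_cut: float = 1.0
    alpha: float = 0.05
    adjust: str = "BY"

    def __post_init__(self) -> None:
        if self.lfc_cut <= 0:
            raise ValidationError("lfc_cut must be > 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must be in (0, 1)")
        if self.adjust.upper() not in ("BH", "BY"):
            raise ValidationError("adjust must be 'BH' or 'BY'")


@dataclass
class DGEResult:
    """Per-gene DGE table (base mean, raw/shrunken log2FC, SE, p, padj)."""

    table: pd.DataFrame
    baseline: str
    contrast: str

    REQUIRED = ("base_mean", "lfc_raw", "se", "p")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValidationError(f"DGE table lacks column {col!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def defined(self) -> pd.DataFrame:
        return self.table[self.table["p"].notna()]


def _validate_groups(counts: CountMatrix, groups, baseline=None) -> tuple[np.ndarray, str, str]:
    if groups is None:
        if counts.sample_meta is None or "group" not in counts.sample_meta.columns:
            raise ValidationError("no group labels given and none in sample_meta")
        groups = counts.sample_meta["group"]
    groups = pd.Series(list(groups), index=counts.counts.columns)
    labels = sorted(set(groups), key=str)
    if len(labels) != 2:
        raise ValidationError(f"need exactly two group labels, got {labels}")
    if baseline is not None:
        if baseline not in labels:
            raise ValidationError(f"baseline {baseline!r} not among labels {labels}")
        labels = [baseline] + [lab for lab in labels if lab != baseline]
    baseline, contrast = labels
    n_a = int((groups == baseline).sum())
    n_b = int((groups == contrast).sum())
    if n_a < 2 or n_b < 2:
        raise ValidationError("each group needs at least two samples")
    return (groups == contrast).to_numpy(), str(baseline), str(contrast)


def _size_factor_vector(size_factors, counts: CountMatrix) -> np.ndarray:
    if size_factors is None:
        return np.ones(counts.n_samples)
    if isinstance(size_factors, ScaleFactors):
        size_factors = size_factors.factors
    sf = pd.Series(size_factors)
    missing = [s for s in counts.counts.columns if s not in sf.index]
    if missing:
        raise ValidationError(f"size factors missing for samples: {missing[:10]}")
    vals = sf.loc[counts.counts.columns].to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
        raise ValidationError("size factors must be positive and finite")
    return vals


def _moment_dispersion(z: np.ndarray, is_b: np.ndarray) -> np.ndarray:
    """Pooled within-group method-of-moments estimate of phi per gene."""
    num = np.zeros(z.shape[0])
    den = np.zeros(z.shape[0])
    for mask in (~is_b, is_b):
        zk = z[:, mask]
        nk = mask.sum()
        m = zk.mean(axis=1)
        v = zk.var(axis=1, ddof=1)
        num += (nk - 1) * (v - m)
        den += (nk - 1) * m**2
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(den > 0, num / den, 0.0)
    return np.clip(phi, DISPERSION_FLOOR, None)


def nb_wald_dge(
    counts: CountMatrix,
    groups=None,
    size_factors=None,
    baseline=None,
) -> DGEResult:
    """Fit the per-gene two-group NB GLM and Wald-test the group effect.

    Group labels default to the ``group`` column of ``sample_meta``; the
    baseline is the lexicographically first label unless given
    explicitly.  Genes with all-zero
    counts get undefined statistics and are excluded from the adjustment
    denominators.  Returns BH- and BY-adjusted p-values alongside the raw
    Wald p.
    """
    is_b, baseline, contrast = _validate_groups(counts, groups, baseline)
    sf = _size_factor_vector(size_factors, counts)
    y = counts.counts.to_numpy(dtype=float)
    n_genes, n_samples = y.shape
    off = np.log(sf)
    z = y / sf

    all_zero = (y == 0).all(axis=1)
    phi = _moment_dispersion(z, is_b)

    m_a = z[:, ~is_b].mean(axis=1)
    m_b = z[:, is_b].mean(axis=1)
    with np.errstate(divide="ignore"):
        b0 = np.log(np.maximum(m_a, 1e-8))
        b1 = np.log(np.maximum(m_b, 1e-8)) - b0

    x = is_b.astype(float)
    sw = swx = swz = swxz = np.zeros(n_genes)
    for _ in range(IRLS_MAX_ITER):
        eta = np.clip(off[None, :] + b0[:, None] + b1[:, None] * x[None, :], -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + phi[:, None] * mu)
        work = (eta - off[None, :]) + (y - mu) / mu
        sw = w.sum(axis=1)
        swx = (w * x[None, :]).sum(axis=1)
        swz = (w * work).sum(axis=1)
        swxz = (w * x[None, :] * work).sum(axis=1)
        det = sw * swx - swx**2  # x binary: sum(w x^2) = sum(w x)
        with np.errstate(invalid="ignore", divide="ignore"):
            nb0 = (swx * swz - swx * swxz) / det
            nb1 = (sw * swxz - swx * swz) / det
        nb0 = np.where(np.isfinite(nb0), nb0, b0)
        nb1 = np.where(np.isfinite(nb1), nb1, b1)
        nb0 = np.clip(nb0, -30.0, 30.0)
        nb1 = np.clip(nb1, -60.0, 60.0)
        delta = np.maximum(np.abs(nb0 - b0), np.abs(nb1 - b1))
        b0, b1 = nb0, nb1
        if np.all(delta < IRLS_TOL):
            break

    with np.errstate(invalid="ignore", divide="ignore"):
        var_b1 = sw / det
    se_ln = np.sqrt(np.where(var_b1 > 0, var_b1, np.nan))
    df = n_samples - 2
    with np.errstate(invalid="ignore"):
        wald = b1 / se_ln
    p = 2.0 * stats.t.sf(np.abs(wald), df=df)
    base_mean = z.mean(axis=1)

    lfc_raw = b1 / LN2
    se = se_ln / LN2
    for arr in (lfc_raw, se, p):
        arr[all_zero] = np.nan
    phi_out = phi.copy()
    phi_out[all_zero] = np.nan

    table = pd.DataFrame(
        {
            "base_mean": base_mean,
            "lfc_raw": lfc_raw,
            "lfc_shrunk": np.nan,
            "se": se,
            "p": p,
            "padj_bh": adjust_pvalues(p, "BH"),
            "padj_by": adjust_pvalues(p, "BY"),
            "dispersion": phi_out,
        },
        index=counts.counts.index,
    )
    return DGEResult(table=table, baseline=baseline, contrast=contrast)


def shrink_lfc(result: DGEResult, prior_sd="auto", auto_quantile: float = 0.90) -> DGEResult:
    """Normal-prior posterior-mean shrinkage of the log2 fold changes.

    lfc_shrunk = lfc_raw * prior_sd^2 / (prior_sd^2 + se^2): genes with
    large standard errors (little information, low counts) shrink most.
    ``prior_sd='auto'`` uses the ``auto_quantile`` upper quantile of
    |lfc_raw| over genes with defined estimates.
    """
    tab = result.table.copy()
    defined = tab["lfc_raw"].notna() & tab["se"].notna()
    if prior_sd == "auto":
        if not defined.any():
            raise ValidationError("no defined estimates to derive the prior from")
        prior = float(np.quantile(np.abs(tab.loc[defined, "lfc_raw"]), auto_quantile))
        prior = max(prior, 1e-6)
    else:
        prior = float(prior_sd)
        if not np.isfinite(prior) or prior <= 0:
            raise ValidationError(f"prior_sd must be > 0, got {prior_sd}")
    w = prior**2 / (prior**2 + tab["se"] ** 2)
    tab["lfc_shrunk"] = tab["lfc_raw"] * w
    return DGEResult(table=tab, baseline=result.baseline, contrast=result.contrast)


def _harmonic(m: int) -> float:
    return float(np.sum(1.0 / np.arange(1, m + 1)))


def adjust_pvalues(p, method: str) -> np.ndarray:
    """BH or BY step-up adjustment; NaN entries pass through and do not
    count toward the number of tests."""
    method = method.upper()
    if method not in ("BH", "BY"):
        raise ValidationError(f"method must be 'BH' or 'BY', got {method!r}")
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    defined = ~np.isnan(p)
    vals = p[defined]
    if ((vals < 0) | (vals > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = vals.size
    if m == 0:
        return out
    order = np.argsort(vals, kind="stable")
    ranked = vals[order] * m / np.arange(1, m + 1)
    if method == "BY":
        ranked = ranked * _harmonic(m)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[defined] = restored
    return out


def call_degs(
    result: DGEResult,
    thresholds: DGEThresholds | None = None,
    use_shrunk: bool = True,
) -> pd.DataFrame:
    """Genes passing both gates, with per-gene direction ('up'/'down').

    Thresholds are inclusive: padj <= alpha and lfc <= -cut or >= cut.
    """
    thresholds = thresholds or DGEThresholds()
    lfc_col = "lfc_shrunk" if use_shrunk else "lfc_raw"
    padj_col = "padj_by" if thresholds.adjust.upper() == "BY" else "padj_bh"
    tab = result.table
    if padj_col not in tab.columns:
        raise ValidationError(f"result lacks {padj_col!r}")
    if use_shrunk and tab[lfc_col].isna().all() and tab["lfc_raw"].notna().any():
        raise ValidationError("lfc_shrunk not computed; run shrink_lfc first")
    lfc = tab[lfc_col]
    padj = tab[padj_col]
    sig = (padj <= thresholds.alpha) & (
        (lfc <= -thresholds.lfc_cut) | (lfc >= thresholds.lfc_cut)
    )
    sig = sig.fillna(False)
    out = tab.loc[sig, [lfc_col, padj_col]].copy()
    out.columns = ["lfc", "padj"]
    out["direction"] = np.where(out["lfc"] >= thresholds.lfc_cut, "up", "down")
    return out
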