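"""Count normalization: CPM, TMM, RLE and two-step panel normalization.

All four schemes are per-sample rescalings — for every sample the
normalized values are a positive scalar multiple of the raw counts — so
within-sample gene ranks (and hence sample-wise Spearman correlations
against another platform) are invariant to the choice of method.

TMM follows the original trimmed-mean-of-M-values definition (reference
sample by upper-quartile closeness, 30% M-trim / 5% A-trim, delta-method
inverse-variance weights, geometric-mean centering).  RLE is the
median-of-ratios estimator against a geometric-mean pseudo-reference.
The panel scheme is the hybridization-panel convention: a positive-control
scaling step followed by a housekeeping-gene content step, flagging (not
dropping) samples whose factor leaves a plausibility window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import CountMatrix, PanelDefinition, ValidationError

__all__ = [
    "ScaleFactors",
    "NormalizedMatrix",
    "cpm_normalize",
    "tmm_factors",
    "rle_factors",
    "panel_two_step_normalize",
    "normalize_counts",
    "dge_size_factors",
]


@dataclass
class ScaleFactors:
    """Per-sample scaling factors of one normalization method.

    The numeric meaning of ``factors`` follows the method's own
    convention: CPM stores the per-sample divisor ``libsize / 1e6``, TMM
    the multiplicative factor on the library size (geometric mean 1), RLE
    the median-of-ratios size factor (a divisor), and the panel steps the
    multiplier applied to counts.
    """

    method: str
    factors: pd.Series
    flags: pd.Series | None = None
    reasons: dict[str, str] = field(default_factory=dict)
    details: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.factors.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            bad = self.factors.index[~(np.isfinite(vals) & (vals > 0))].tolist()
            raise ValidationError(f"non-positive or non-finite factors for samples {bad[:10]}")
        if self.flags is None:
            self.flags = pd.Series(False, index=self.factors.index)


@dataclass
class NormalizedMatrix:
    """Gene × sample matrix of normalized (nonnegative real) values."""

    values: pd.DataFrame
    method: str
    factors_used: ScaleFactors | None = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_genes(self, genes) -> "NormalizedMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing[:10]}")
        return NormalizedMatrix(self.values.loc[list(genes)].copy(), self.method, self.factors_used)


def _lib_sizes(counts: CountMatrix) -> pd.Series:
    lib = counts.library_sizes()
    zero = lib.index[lib == 0].tolist()
    if zero:
        raise ValidationError(f"samples with zero library size: {zero}")
    return lib


def cpm_normalize(counts: CountMatrix) -> NormalizedMatrix:
    """Counts per million: value = count / library_size * 1e6."""
    lib = _lib_sizes(counts)
    factors = ScaleFactors("CPM", lib / 1e6)
    values = counts.counts.div(factors.factors, axis=1)
    return NormalizedMatrix(values, "cpm", factors)


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Trimmed weighted mean of M-values of one sample against the reference."""
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        raise ValidationError("sample shares no co-expressed genes with the reference")
    o = obs[ok] / n_obs
    r = ref[ok] / n_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # delta-method (binomial) variance of M
    v = (n_obs - obs[ok]) / (n_obs * obs[ok]) + (n_ref - ref[ok]) / (n_ref * ref[ok])
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    with np.errstate(divide="ignore"):
        f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> ScaleFactors:
    """Trimmed-mean-of-M-values factors; their product is 1."""
    if counts.n_samples < 2:
        raise ValidationError("TMM needs at least two samples")
    x = counts.counts.to_numpy(dtype=float)
    if (x.sum(axis=0) == 0).any():
        _lib_sizes(counts)  # raises with the offending sample names
    lib = x.sum(axis=0)
    uq = np.quantile(x / lib * 1e6, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    f = np.array(
        [
            _tmm_pair(x[:, s], x[:, ref_idx], lib[s], lib[ref_idx], trim_m, trim_a)
            for s in range(x.shape[1])
        ]
    )
    f = f / np.exp(np.mean(np.log(f)))
    return ScaleFactors("TMM", pd.Series(f, index=counts.counts.columns))


def rle_factors(counts: CountMatrix) -> ScaleFactors:
    """Relative-log-expression (median-of-ratios) size factors.

    The pseudo-reference for each gene is its geometric mean across
    samples; genes with a zero count in any sample are excluded.
    """
    x = counts.counts.to_numpy(dtype=float)
    usable = (x > 0).all(axis=1)
    if not usable.any():
        raise ValidationError("no gene has nonzero counts in every sample")
    xu = x[usable]
    ref = np.exp(np.log(xu).mean(axis=1))
    factors = np.median(xu / ref[:, None], axis=0)
    return ScaleFactors("RLE", pd.Series(factors, index=counts.counts.columns))


def _geomeans(frame: pd.DataFrame, genes: list[str], what: str) -> pd.Series:
    sub = frame.loc[genes].to_numpy(dtype=float)
    all_zero = (sub <= 0).all(axis=0)
    if all_zero.any():
        bad = frame.columns[all_zero].tolist()
        raise ValidationError(f"samples with all-zero {what}: {bad}")
    with np.errstate(divide="ignore"):
        logs = np.where(sub > 0, np.log(np.where(sub > 0, sub, 1.0)), np.nan)
    gm = np.exp(np.nanmean(logs, axis=0))
    return pd.Series(gm, index=frame.columns)


def _panel_step(
    frame: pd.DataFrame, genes: list[str], flag_range: tuple[float, float], method: str, what: str
) -> tuple[pd.DataFrame, ScaleFactors]:
    gm = _geomeans(frame, genes, what)
    factors = gm.mean() / gm
    lo, hi = flag_range
    flags = (factors < lo) | (factors > hi)
    reasons = {
        s: f"{what} factor {factors[s]:.4g} outside [{lo}, {hi}]"
        for s in factors.index[flags]
    }
    sf = ScaleFactors(method, factors, flags=flags, reasons=reasons)
    return frame.mul(factors, axis=1), sf


def panel_two_step_normalize(
    counts: CountMatrix,
    panel: PanelDefinition,
    pos_flag_range: tuple[float, float] = (0.3, 3.0),
    hk_flag_range: tuple[float, float] = (0.1, 10.0),
) -> NormalizedMatrix:
    """Positive-control then housekeeping normalization of panel counts.

    Each step scales sample ``s`` by (mean over samples of the geometric
    mean of the step's probes) / (geometric mean of those probes in
    ``s``).  Samples whose factor falls outside the flag range are
    flagged, never dropped.
    """
    pos = [g for g in panel.pos_controls if g in counts.counts.index]
    hk = [g for g in panel.housekeeping if g in counts.counts.index]
    if not pos:
        raise ValidationError("no positive-control probes present in the count matrix")
    if not hk:
        raise ValidationError("no housekeeping genes present in the count matrix")
    step1_values, pos_sf = _panel_step(
        counts.counts.astype(float), pos, pos_flag_range, "PANEL_POS", "positive controls"
    )
    step2_values, hk_sf = _panel_step(step1_values, hk, hk_flag_range, "PANEL_HK", "housekeepers")
    combined = pos_sf.factors * hk_sf.factors
    flags = pos_sf.flags | hk_sf.flags
    reasons = {**pos_sf.reasons}
    for s, r in hk_sf.reasons.items():
        reasons[s] = f"{reasons[s]}; {r}" if s in reasons else r
    details = pd.DataFrame({"pos_factor": pos_sf.factors, "hk_factor": hk_sf.factors})
    sf = ScaleFactors("PANEL", combined, flags=flags, reasons=reasons, details=details)
    return NormalizedMatrix(step2_values, "panel", sf)


def normalize_counts(
    counts: CountMatrix, method: str, panel: PanelDefinition | None = None
) -> NormalizedMatrix:
    """Dispatch: ``none``, ``cpm``, ``tmm``, ``rle`` or ``panel``.

    TMM and RLE values are reported on the counts-per-million scale of
    the method's effective library size so the three sequencing-side
    schemes are directly comparable.
    """
    method = method.lower()
    if method == "none":
        return NormalizedMatrix(counts.counts.astype(float), "none", None)
    if method == "cpm":
        return cpm_normalize(counts)
    if method == "tmm":
        sf = tmm_factors(counts)
        lib = _lib_sizes(counts)
        eff = lib * sf.factors
        values = counts.counts.div(eff / 1e6, axis=1)
        return NormalizedMatrix(values, "tmm", sf)
    if method == "rle":
        sf = rle_factors(counts)
        values = counts.counts.div(sf.factors, axis=1)
        return NormalizedMatrix(values, "rle", sf)
    if method == "panel":
        if panel is None:
            raise ValidationError("panel normalization requires a PanelDefinition")
        return panel_two_step_normalize(counts, panel)
    raise ValidationError(f"unknown normalization method {method!r}")


def dge_size_factors(counts: CountMatrix, method: str = "rle", panel: PanelDefinition | None = None) -> pd.Series:
    """Per-sample divisors (geometric mean 1) for the NB DGE engine."""
    method = method.lower()
    if method == "rle":
        return rle_factors(counts).factors
    if method == "cpm":
        lib = _lib_sizes(counts).astype(float)
        return lib / np.exp(np.mean(np.log(lib)))
    if method == "tmm":
        lib = _lib_sizes(counts).astype(float)
        eff = lib * tmm_factors(counts).factors
        return eff / np.exp(np.mean(np.log(eff)))
    if method == "panel":
        if panel is None:
            raise ValidationError("panel size factors require a PanelDefinition")
        mult = panel_two_step_normalize(counts, panel).factors_used.factors
        inv = 1.0 / mult
        return inv / np.exp(np.mean(np.log(inv)))
    if method == "none":
        return pd.Series(1.0, index=counts.counts.columns)
    raise ValidationError(f"unknown size-factor method {method!r}")
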