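"""Synthetic paired-platform expression studies with known ground truth.

The generator emulates a two-group tumor contrast measured twice on the
same samples: once with a whole-transcriptome 3'-tag counting platform
("seq") and once with a fixed ~800-gene hybridization panel ("panel").
Both platforms observe the same latent per-gene expression; each adds its
own systematic per-gene capture efficiency, per-sample depth, optional
per-observation log-normal noise, and negative-binomial counting noise.

Counts for gene g in sample s are drawn NB(mu, phi) with

    mu_gs = 2 ** (baseline_g + lfc_g * [s in group B]
                  + capture_g + depth_s + eps_gs)

and variance mu + phi * mu**2.  Setting ``sampling="expected"`` replaces
the NB draw by round(mu), the noise-free limit used for exactness checks.

The default parameter values define the simulated study conditions: two
designs mirroring the real contrasts (an entity contrast with group sizes
15 vs 10 and a stage contrast with 5 vs 5), a panel of 780-810 endogenous
probes plus 20 housekeeping genes of which ~1% are absent from the
sequencing annotation, and moderate platform noise (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix, PanelDefinition, ValidationError

__all__ = [
    "TrueExpression",
    "PlatformParams",
    "SimConfig",
    "PairedStudy",
    "simulate_truth",
    "simulate_platform",
    "build_panel",
    "simulate_paired_study",
    "default_config",
]

#: Fixed mean counts of the synthetic positive-control probes (spanning
#: four orders of magnitude, mimicking a hybridization-panel titration).
POS_CONTROL_MEANS = (8.0, 80.0, 800.0, 8000.0, 80000.0, 0.8)
#: Mean count of negative-control probes (background; Poisson).
NEG_CONTROL_MEAN = 2.0


@dataclass(frozen=True)
class TrueExpression:
    """Latent truth behind one simulated two-group study.

    ``bio_log2`` is the per-gene, per-sample biological deviation from
    the group mean (log2 scale).  It is part of the *truth*, i.e. shared
    by every platform that observes the study — this shared latent
    variation is what gives genes reproducible cross-platform behaviour
    across samples; platform-specific noise then dilutes it.
    """

    gene_ids: tuple[str, ...]
    baseline_log2: np.ndarray
    lfc_true: np.ndarray
    is_de: np.ndarray
    sample_ids: tuple[str, ...]
    group_of_sample: tuple[str, ...]
    bio_log2: np.ndarray | None = None

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "baseline_log2": self.baseline_log2,
                "lfc_true": self.lfc_true,
                "is_de": self.is_de,
            },
            index=pd.Index(self.gene_ids, name="gene_id"),
        )


@dataclass(frozen=True)
class PlatformParams:
    """Noise model of one measurement platform.

    dispersion
        NB dispersion phi >= 0; count variance is mu + phi * mu**2.
    library_size_log2_sd
        SD of the per-sample sequencing-depth / lane effect (log2 scale).
    capture_log2_sd
        SD of the per-gene platform-specific capture efficiency (log2),
        drawn once per platform — systematic probe / 3'-bias differences.
    noise_log2_sd
        SD of per-observation extra log-normal noise (log2 scale).
    panel_subset
        Optional gene restriction (the panel's probe targets).
    sampling
        "nb" draws NB counts; "expected" returns round(mu) (noise-free
        limit for exactness checks).
    """

    dispersion: float = 0.1
    library_size_log2_sd: float = 0.25
    capture_log2_sd: float = 0.5
    noise_log2_sd: float = 0.25
    panel_subset: tuple[str, ...] | None = None
    sampling: str = "nb"

    def __post_init__(self) -> None:
        for name in ("dispersion", "library_size_log2_sd", "capture_log2_sd", "noise_log2_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v}")
        if self.sampling not in ("nb", "expected"):
            raise ValidationError(f"sampling must be 'nb' or 'expected', got {self.sampling!r}")


@dataclass(frozen=True)
class PairedStudy:
    """One in-silico study: the same samples measured on both platforms."""

    seq_counts: CountMatrix
    panel_counts: CountMatrix
    panel: PanelDefinition
    truth: TrueExpression
    seed: int

    def __post_init__(self) -> None:
        if self.seq_counts.sample_ids != self.panel_counts.sample_ids:
            raise ValidationError("platform matrices must share sample IDs in order")


def _check_finite(**kwargs) -> None:
    for name, v in kwargs.items():
        if not np.isfinite(v):
            raise ValidationError(f"{name} must be finite, got {v}")


def simulate_truth(
    n_genes: int,
    n_per_group: tuple[int, int],
    de_fraction: float,
    lfc_sd: float = 1.5,
    baseline_mean_log2: float = 5.0,
    baseline_sd_log2: float = 2.5,
    bio_log2_sd: float = 1.0,
    seed: int = 0,
) -> TrueExpression:
    """Draw the latent truth of a two-group study.

    Exactly ``round(de_fraction * n_genes)`` genes are differentially
    expressed; their true log2 fold changes (group B vs baseline group A)
    come from a zero-mean normal with SD ``lfc_sd``, all other genes have
    a true fold change of exactly zero.  ``bio_log2_sd`` controls the
    shared per-sample biological variation around each gene's group mean
    (0 gives a deterministic latent profile).
    """
    _check_finite(
        de_fraction=de_fraction,
        lfc_sd=lfc_sd,
        baseline_mean_log2=baseline_mean_log2,
        baseline_sd_log2=baseline_sd_log2,
        bio_log2_sd=bio_log2_sd,
    )
    if bio_log2_sd < 0:
        raise ValidationError("bio_log2_sd must be >= 0")
    if not (0.0 <= de_fraction <= 1.0):
        raise ValidationError(f"de_fraction must be in [0, 1], got {de_fraction}")
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    n_a, n_b = int(n_per_group[0]), int(n_per_group[1])
    if n_a < 2 or n_b < 2:
        raise ValidationError("both group sizes must be >= 2")
    if lfc_sd <= 0 or baseline_sd_log2 <= 0:
        raise ValidationError("lfc_sd and baseline_sd_log2 must be > 0")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    width = max(6, len(str(n_genes)))
    gene_ids = tuple(f"G{i:0{width}d}" for i in range(1, n_genes + 1))
    baseline = rng.normal(baseline_mean_log2, baseline_sd_log2, size=n_genes)
    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    is_de = np.zeros(n_genes, dtype=bool)
    is_de[de_idx] = True
    lfc = np.zeros(n_genes)
    lfc[de_idx] = rng.normal(0.0, lfc_sd, size=n_de)
    n = n_a + n_b
    sample_ids = tuple(f"S{i:02d}" for i in range(1, n + 1))
    groups = tuple(["A"] * n_a + ["B"] * n_b)
    bio = (
        rng.normal(0.0, bio_log2_sd, size=(n_genes, n))
        if bio_log2_sd > 0
        else np.zeros((n_genes, n))
    )
    return TrueExpression(gene_ids, baseline, lfc, is_de, sample_ids, groups, bio)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Gamma-Poisson mixture: mean mu, variance mu + phi * mu**2."""
    if phi == 0.0:
        return rng.poisson(mu)
    shape = 1.0 / phi
    lam = rng.gamma(shape, scale=mu * phi)
    return rng.poisson(lam)


def simulate_platform(
    truth: TrueExpression,
    params: PlatformParams,
    seed: int,
    platform: str = "platform",
    depth_log2: np.ndarray | None = None,
) -> CountMatrix:
    """Observe the latent truth through one platform's noise model.

    ``depth_log2`` lets a caller fix the per-sample depth effects (used by
    :func:`simulate_paired_study` so control probes share the endogenous
    probes' lane effect); when omitted they are drawn from the params.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    gene_ids = list(truth.gene_ids)
    if params.panel_subset is not None:
        unknown = set(params.panel_subset) - set(gene_ids)
        if unknown:
            raise ValidationError(f"panel_subset genes not in truth: {sorted(unknown)[:10]}")
    # draw in full-gene space for reproducibility, subset afterwards
    g = truth.n_genes
    s = truth.n_samples
    is_b = np.array([grp == "B" for grp in truth.group_of_sample])
    capture = (
        rng.normal(0.0, params.capture_log2_sd, size=g)
        if params.capture_log2_sd > 0
        else np.zeros(g)
    )
    if depth_log2 is None:
        depth_log2 = (
            rng.normal(0.0, params.library_size_log2_sd, size=s)
            if params.library_size_log2_sd > 0
            else np.zeros(s)
        )
    else:
        depth_log2 = np.asarray(depth_log2, dtype=float)
        if depth_log2.shape != (s,):
            raise ValidationError("depth_log2 has wrong length")
    eps = (
        rng.normal(0.0, params.noise_log2_sd, size=(g, s))
        if params.noise_log2_sd > 0
        else np.zeros((g, s))
    )
    bio = truth.bio_log2 if truth.bio_log2 is not None else 0.0
    log2_mu = (
        truth.baseline_log2[:, None]
        + truth.lfc_true[:, None] * is_b[None, :]
        + bio
        + capture[:, None]
        + depth_log2[None, :]
        + eps
    )
    mu = np.exp2(log2_mu)
    if params.sampling == "expected":
        counts = np.round(mu).astype(np.int64)
    else:
        counts = _nb_draw(rng, mu, params.dispersion).astype(np.int64)
    frame = pd.DataFrame(counts, index=gene_ids, columns=list(truth.sample_ids))
    if params.panel_subset is not None:
        frame = frame.loc[list(params.panel_subset)]
    meta = pd.DataFrame(
        {"group": list(truth.group_of_sample), "depth_log2": depth_log2},
        index=list(truth.sample_ids),
    )
    return CountMatrix(frame, platform=platform, sample_meta=meta)


def build_panel(
    truth: TrueExpression,
    n_endogenous: int = 780,
    n_housekeeping: int = 20,
    n_pos_controls: int = 6,
    n_neg_controls: int = 8,
    n_missing: int = 9,
    seed: int = 0,
) -> PanelDefinition:
    """Sample a fixed panel from the simulated transcriptome.

    Housekeeping genes are drawn from non-DE genes only (stably expressed
    by construction); control probes get synthetic IDs outside the
    transcriptome; ``n_missing`` endogenous genes are marked absent from
    the sequencing annotation.
    """
    if n_endogenous + n_housekeeping > truth.n_genes:
        raise ValidationError(
            f"panel of {n_endogenous}+{n_housekeeping} genes exceeds "
            f"transcriptome of {truth.n_genes}"
        )
    if n_missing > n_endogenous:
        raise ValidationError("n_missing cannot exceed n_endogenous")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = np.array(truth.gene_ids)
    non_de = genes[~truth.is_de]
    if n_housekeeping > non_de.size:
        raise ValidationError(
            f"need {n_housekeeping} non-DE genes for housekeeping, have {non_de.size}"
        )
    housekeeping = rng.choice(non_de, size=n_housekeeping, replace=False)
    rest = genes[~np.isin(genes, housekeeping)]
    endogenous = rng.choice(rest, size=n_endogenous, replace=False)
    missing = rng.choice(endogenous, size=n_missing, replace=False)
    pos = [f"POS_{chr(ord('A') + i)}" for i in range(n_pos_controls)]
    neg = [f"NEG_{chr(ord('A') + i)}" for i in range(n_neg_controls)]
    return PanelDefinition(
        endogenous=sorted(endogenous.tolist()),
        housekeeping=sorted(housekeeping.tolist()),
        pos_controls=pos,
        neg_controls=neg,
        missing_from_annotation=sorted(missing.tolist()),
    )


@dataclass(frozen=True)
class SimConfig:
    """Complete description of one simulated paired-platform study."""

    name: str = "hga_vs_agasac"
    n_genes: int = 12000
    n_per_group: tuple[int, int] = (15, 10)
    de_fraction: float = 0.10
    lfc_sd: float = 1.5
    baseline_mean_log2: float = 5.0
    baseline_sd_log2: float = 2.5
    bio_log2_sd: float = 1.0
    n_endogenous: int = 810
    n_housekeeping: int = 20
    n_pos_controls: int = 6
    n_neg_controls: int = 8
    n_missing: int = 9
    seq_params: PlatformParams = field(default_factory=lambda: PlatformParams(dispersion=0.2))
    panel_params: PlatformParams = field(default_factory=lambda: PlatformParams(dispersion=0.1))
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("seq_params", "panel_params"):
            if key in d and isinstance(d[key], dict):
                d[key] = PlatformParams(**d[key])
        if "n_per_group" in d:
            d["n_per_group"] = tuple(d["n_per_group"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_per_group"] = list(self.n_per_group)
        for key in ("seq_params", "panel_params"):
            if d[key].get("panel_subset") is not None:
                d[key]["panel_subset"] = list(d[key]["panel_subset"])
        return d


def default_config(name: str = "hga_vs_agasac", **overrides) -> SimConfig:
    """Built-in study designs.

    ``hga_vs_agasac`` — entity contrast, group sizes 15 (baseline) vs 10,
    830-probe panel content (810 endogenous + 20 housekeeping), 9 genes
    missing from the annotation.
    ``cch_early_vs_late`` — stage contrast, 5 vs 5, 800-probe content,
    10 missing, weaker biology (lower DE fraction and effect spread).
    """
    if name == "hga_vs_agasac":
        base = SimConfig(name=name)
    elif name == "cch_early_vs_late":
        base = SimConfig(
            name=name,
            n_per_group=(5, 5),
            de_fraction=0.04,
            lfc_sd=1.0,
            n_endogenous=780,
            n_missing=10,
        )
    else:
        raise ValidationError(f"unknown study design {name!r}")
    return dataclasses.replace(base, **overrides) if overrides else base


def simulate_paired_study(config: SimConfig) -> PairedStudy:
    """Draw one full study: shared truth, two platform observations.

    A single master seed deterministically spawns per-component child
    seeds (truth, panel design, each platform, QC metrics), so studies are
    bitwise reproducible.  The sequencing matrix covers the annotated
    transcriptome — i.e. every simulated gene *except* the panel genes
    flagged missing from the annotation — while the panel matrix carries
    all panel probes including those missing genes plus the control
    probes, mirroring how a probe can exist on a panel yet be absent from
    a genome annotation.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    truth = simulate_truth(
        config.n_genes,
        config.n_per_group,
        config.de_fraction,
        config.lfc_sd,
        config.baseline_mean_log2,
        config.baseline_sd_log2,
        config.bio_log2_sd,
        seed=seeds[0],
    )
    panel = build_panel(
        truth,
        n_endogenous=config.n_endogenous,
        n_housekeeping=config.n_housekeeping,
        n_pos_controls=config.n_pos_controls,
        n_neg_controls=config.n_neg_controls,
        n_missing=config.n_missing,
        seed=seeds[1],
    )
    missing = set(panel.missing_from_annotation)
    annotated = tuple(g for g in truth.gene_ids if g not in missing)
    seq_params = dataclasses.replace(config.seq_params, panel_subset=annotated)
    seq_counts = simulate_platform(truth, seq_params, seed=seeds[2], platform="seq")

    panel_targets = tuple(panel.content_genes)
    panel_params = dataclasses.replace(config.panel_params, panel_subset=panel_targets)
    rng_depth = np.random.default_rng(np.random.SeedSequence(seeds[3]))
    lane = (
        rng_depth.normal(0.0, config.panel_params.library_size_log2_sd, size=truth.n_samples)
        if config.panel_params.library_size_log2_sd > 0
        else np.zeros(truth.n_samples)
    )
    panel_counts = simulate_platform(
        truth, panel_params, seed=seeds[3], platform="panel", depth_log2=lane
    )
    # control probes share the lane effect of the endogenous probes
    rng_ctrl = np.random.default_rng(np.random.SeedSequence(seeds[4]))
    ctrl_rows = {}
    for name, mean in zip(panel.pos_controls, POS_CONTROL_MEANS):
        ctrl_rows[name] = rng_ctrl.poisson(mean * np.exp2(lane))
    for name in panel.neg_controls:
        ctrl_rows[name] = rng_ctrl.poisson(NEG_CONTROL_MEAN, size=truth.n_samples)
    ctrl = pd.DataFrame.from_dict(ctrl_rows, orient="index")
    ctrl.columns = list(truth.sample_ids)
    full_panel = pd.concat([panel_counts.counts, ctrl.astype(np.int64)])

    # synthetic QC metrics: RQN and DV200 in the range the gates accept
    rng_qc = np.random.default_rng(np.random.SeedSequence(seeds[5]))
    meta = pd.DataFrame(
        {
            "group": list(truth.group_of_sample),
            "rqn": np.round(rng_qc.uniform(5.0, 9.0, size=truth.n_samples), 1),
            "dv200": np.round(rng_qc.uniform(66.0, 95.0, size=truth.n_samples), 1),
        },
        index=list(truth.sample_ids),
    )
    seq_cm = CountMatrix(seq_counts.counts, platform="seq", sample_meta=meta.copy())
    panel_cm = CountMatrix(full_panel, platform="panel", sample_meta=meta.copy())
    return PairedStudy(seq_cm, panel_cm, panel, truth, config.seed)
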