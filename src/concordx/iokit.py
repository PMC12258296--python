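"""Readers, writers, sample QC gates, configuration and the pipeline.

File formats are deliberately plain: TSV count matrices (gene IDs in the
first column, sample IDs in the header), a TSV panel table, YAML/JSON
configuration, and the line-oriented RCC dialect exported by
hybridization-panel instruments (read-only, plus a fixture writer for
round-trip tests).  Readers reject malformed input instead of coercing
it — no silent NaN ever enters a count matrix.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .concord import build_report
from .containers import CountMatrix, PanelDefinition, ValidationError
from .correlate import StrataSpec, correlation_profile, strata_correlations
from .dge import DGEResult, DGEThresholds, call_degs, nb_wald_dge, shrink_lfc
from .normalize import dge_size_factors, normalize_counts, panel_two_step_normalize
from .simdata import SimConfig, default_config, simulate_paired_study

__all__ = [
    "sample_qc",
    "read_counts",
    "write_counts",
    "read_panel",
    "write_panel",
    "read_rcc",
    "write_rcc_fixture",
    "load_config",
    "run_pipeline",
]

RQN_GATE = 4.0
DV200_GATE = 64.5


def sample_qc(records: pd.DataFrame) -> pd.DataFrame:
    """Apply the FFPE RNA-quality gates and quality classification.

    A sample is kept iff RQN > 4 and DV200 > 64.5 (both strict).  DV200
    classes follow the sequencing-vendor convention: > 70 high, 50-70
    medium (both band edges inclusive to medium), < 50 low.
    """
    required = {"rqn", "dv200"}
    missing_cols = required - set(records.columns)
    if missing_cols:
        raise ValidationError(f"QC table lacks columns: {sorted(missing_cols)}")
    bad = records.index[records[["rqn", "dv200"]].isna().any(axis=1)].tolist()
    if bad:
        raise ValidationError(f"samples with missing QC fields: {bad}")
    out = records.copy()
    dv = out["dv200"].astype(float)
    if ((dv < 0) | (dv > 100)).any():
        bad = out.index[(dv < 0) | (dv > 100)].tolist()
        raise ValidationError(f"DV200 outside [0, 100] for samples: {bad}")
    out["keep"] = (out["rqn"].astype(float) > RQN_GATE) & (dv > DV200_GATE)
    out["dv200_class"] = np.where(dv > 70.0, "high", np.where(dv >= 50.0, "medium", "low"))
    return out


def read_counts(path, platform: str = "") -> CountMatrix:
    """Read a TSV count matrix; malformed input raises a descriptive error."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.columns.size == 0:
        raise ValidationError(f"{path}: no sample columns found")
    if frame.isna().any().any():
        loc = frame.stack(future_stack=True)
        loc = loc[loc.isna()]
        g, s = loc.index[0]
        raise ValidationError(f"{path}: missing/ragged value at gene {g!r}, sample {s!r}")
    try:
        return CountMatrix(frame, platform=platform)
    except ValidationError as err:
        raise ValidationError(f"{path}: {err}") from err


def write_counts(matrix: CountMatrix, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_panel(path) -> PanelDefinition:
    frame = pd.read_csv(Path(path), sep="\t", index_col=0)
    return PanelDefinition.from_frame(frame)


def write_panel(panel: PanelDefinition, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    panel.to_frame().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# RCC dialect (read-only + fixture writer)

_RCC_CLASS_MAP = {
    "Endogenous": "Endogenous",
    "Housekeeping": "Housekeeping",
    "Positive": "Positive",
    "Negative": "Negative",
}


def read_rcc(path) -> tuple[pd.Series, dict[str, str], dict[str, dict[str, str]]]:
    """Parse one RCC file.

    Returns (counts keyed by probe name, probe code classes, section
    metadata).  The dialect is line-oriented sections ``<Name> ...
    </Name>`` with CSV rows; ``Code_Summary`` rows are
    ``CodeClass,Name,Accession,Count``.
    """
    path = Path(path)
    text = path.read_text()
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("</"):
            name = line[2:-1]
            if current != name:
                raise ValidationError(f"{path}:{lineno}: unexpected closing tag {line}")
            current = None
        elif line.startswith("<"):
            if current is not None:
                raise ValidationError(
                    f"{path}:{lineno}: section {current!r} not closed before {line}"
                )
            current = line[1:-1]
            sections[current] = []
        else:
            if current is None:
                raise ValidationError(f"{path}:{lineno}: data outside any section")
            sections[current].append(line)
    if current is not None:
        raise ValidationError(f"{path}: truncated section {current!r}")
    if "Code_Summary" not in sections:
        raise ValidationError(f"{path}: missing Code_Summary section")

    meta: dict[str, dict[str, str]] = {}
    for sec in ("Header", "Sample_Attributes", "Lane_Attributes"):
        meta[sec] = {}
        for row in sections.get(sec, []):
            key, _, value = row.partition(",")
            meta[sec][key] = value

    rows = sections["Code_Summary"]
    if not rows or rows[0].split(",")[:2] != ["CodeClass", "Name"]:
        raise ValidationError(f"{path}: Code_Summary lacks its header row")
    counts: dict[str, int] = {}
    classes: dict[str, str] = {}
    for row in rows[1:]:
        parts = row.split(",")
        if len(parts) != 4:
            raise ValidationError(f"{path}: malformed Code_Summary row: {row!r}")
        code_class, name, _accession, count = parts
        if code_class not in _RCC_CLASS_MAP:
            raise ValidationError(f"{path}: unknown CodeClass {code_class!r}")
        try:
            value = int(count)
        except ValueError:
            raise ValidationError(
                f"{path}: non-integer Count {count!r} for probe {name!r}"
            ) from None
        if value < 0:
            raise ValidationError(f"{path}: negative Count for probe {name!r}")
        if name in counts:
            raise ValidationError(f"{path}: duplicate probe name {name!r}")
        counts[name] = value
        classes[name] = _RCC_CLASS_MAP[code_class]
    sample_id = meta["Sample_Attributes"].get("ID", path.stem)
    series = pd.Series(counts, name=sample_id, dtype=np.int64)
    return series, classes, meta


def write_rcc_fixture(
    path,
    sample_id: str,
    counts: pd.Series,
    classes: dict[str, str],
    lane_id: int = 1,
) -> None:
    """Emit an RCC file the reader round-trips (test fixture generator)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        "<Header>",
        "FileVersion,1.7",
        f"SoftwareVersion,{__version__}",
        "</Header>",
        "<Sample_Attributes>",
        f"ID,{sample_id}",
        "Owner,",
        "</Sample_Attributes>",
        "<Lane_Attributes>",
        f"ID,{lane_id}",
        "</Lane_Attributes>",
        "<Code_Summary>",
        "CodeClass,Name,Accession,Count",
    ]
    for name, value in counts.items():
        lines.append(f"{classes[name]},{name},NA,{int(value)}")
    lines.append("</Code_Summary>")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Configuration and pipeline

DEFAULT_PIPELINE = {
    "study": "hga_vs_agasac",
    "simulate": {},
    "normalizations": ["none", "cpm", "tmm", "rle"],
    "correlation": {"pseudocount": 1.0, "strata_quantiles": [0.10, 0.50]},
    "dge": {"lfc_cut": 1.0, "alpha": 0.05, "adjust": "BY", "shrink": "auto"},
}

KNOWN_NORMALIZATIONS = ("none", "cpm", "tmm", "rle")


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return cfg


def _merge_config(config: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_PIPELINE))
    for key, value in (config or {}).items():
        if key not in cfg:
            raise ValidationError(f"unknown pipeline config key {key!r}")
        if isinstance(value, dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    for norm in cfg["normalizations"]:
        if norm not in KNOWN_NORMALIZATIONS:
            raise ValidationError(f"unknown normalization name {norm!r}")
    return cfg


def _config_hash(cfg: dict, seed: int) -> str:
    payload = json.dumps({"config": cfg, "seed": seed}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _dge_for(counts: CountMatrix, sf, cfg_dge: dict) -> DGEResult:
    res = nb_wald_dge(counts, size_factors=sf)
    shrink = cfg_dge.get("shrink", "auto")
    if shrink is not None and shrink != "off":
        res = shrink_lfc(res, prior_sd=shrink)
    return res


def run_pipeline(config: dict | None = None, out_dir=None, seed: int = 0) -> dict:
    """Simulate one paired-platform study and run every downstream stage.

    simulate -> QC -> normalize (all requested sequencing-side methods,
    panel two-step on the panel side) -> sample- and gene-wise
    correlations per normalization -> expression strata -> per-platform
    DGE -> concordance report.  When ``out_dir`` is given every artifact
    is written (TSV matrices, DGE tables, report and manifest JSON).
    Identical config + seed gives byte-identical outputs.
    """
    cfg = _merge_config(config)
    sim_kwargs = dict(cfg["simulate"])
    sim_cfg = default_config(cfg["study"], **sim_kwargs, seed=seed)
    study = simulate_paired_study(sim_cfg)

    qc = sample_qc(study.seq_counts.sample_meta)
    kept = qc.index[qc["keep"]].tolist()
    if len(kept) < 4:
        raise ValidationError("fewer than 4 samples pass QC")

    panel = study.panel
    panel_norm = panel_two_step_normalize(study.panel_counts, panel)
    shared_genes = [
        g for g in panel.content_genes
        if g not in set(panel.missing_from_annotation) and g in set(study.seq_counts.gene_ids)
    ]
    panel_shared = panel_norm.subset_genes(shared_genes)

    pseudo = float(cfg["correlation"]["pseudocount"])
    quantiles = tuple(cfg["correlation"]["strata_quantiles"])
    correlations: dict[str, dict] = {"samplewise": {}, "genewise": {}}
    corr_sets = {}
    for norm in cfg["normalizations"]:
        seq_norm = normalize_counts(study.seq_counts, norm)
        seq_shared = seq_norm.subset_genes(shared_genes) if norm != "none" else seq_norm
        correlations["samplewise"][norm] = {}
        correlations["genewise"][norm] = {}
        for coef in ("pearson_log", "spearman"):
            cs = correlation_profile(
                panel_shared, seq_shared, "sample", coef, pseudo, normalization=norm
            )
            correlations["samplewise"][norm][coef] = cs.summary().to_dict()
        for coef in ("pearson", "spearman"):
            cs = correlation_profile(
                panel_shared, seq_shared, "gene", coef, pseudo, normalization=norm
            )
            corr_sets[(norm, coef)] = cs
            correlations["genewise"][norm][coef] = cs.summary().to_dict()

    # expression strata on the TMM (or first available) gene-wise sets
    strata_norm = "tmm" if "tmm" in cfg["normalizations"] else cfg["normalizations"][0]
    seq_tmm = normalize_counts(study.seq_counts, strata_norm).subset_genes(shared_genes)
    strata: dict[str, dict] = {}
    for basis, mat in (("panel", panel_shared.values), ("seq", seq_tmm.values)):
        mean_expr = pd.Series(
            np.log2(mat + 1.0).mean(axis=1), index=mat.index
        )
        strata[basis] = {}
        for coef in ("pearson", "spearman"):
            spec = StrataSpec(quantiles=quantiles, basis_platform=basis)
            boxes = strata_correlations(corr_sets[(strata_norm, coef)], mean_expr, spec)
            strata[basis][coef] = {k: v.to_dict() for k, v in boxes.items()}

    cfg_dge = cfg["dge"]
    thresholds = DGEThresholds(
        lfc_cut=float(cfg_dge["lfc_cut"]),
        alpha=float(cfg_dge["alpha"]),
        adjust=str(cfg_dge["adjust"]),
    )
    seq_sf = dge_size_factors(study.seq_counts, "rle")
    res_seq = _dge_for(study.seq_counts, seq_sf, cfg_dge)
    panel_content = study.panel_counts.subset_genes(panel.content_genes)
    panel_sf = dge_size_factors(study.panel_counts, "panel", panel)
    res_panel = _dge_for(panel_content, panel_sf, cfg_dge)

    report = build_report(
        res_panel,
        res_seq,
        panel,
        annotation=study.seq_counts.gene_ids,
        thresholds=thresholds,
    )
    degs_seq = call_degs(res_seq, thresholds)
    degs_panel = call_degs(res_panel, thresholds)

    result = {
        "study": sim_cfg.name,
        "seed": seed,
        "config_hash": _config_hash(cfg, seed),
        "version": __version__,
        "qc": {
            "kept": kept,
            "excluded": qc.index[~qc["keep"]].tolist(),
            "dv200_classes": qc["dv200_class"].value_counts().to_dict(),
        },
        "n_shared_genes": len(shared_genes),
        "correlations": correlations,
        "strata": strata,
        "dge": {
            "panel": {
                "n_deg": int(len(degs_panel)),
                "n_up": int((degs_panel["direction"] == "up").sum()),
                "n_down": int((degs_panel["direction"] == "down").sum()),
            },
            "seq": {
                "n_deg": int(len(degs_seq)),
                "n_up": int((degs_seq["direction"] == "up").sum()),
                "n_down": int((degs_seq["direction"] == "down").sum()),
            },
        },
        "concordance": report.to_dict(),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_counts(study.seq_counts, out / "seq_counts.tsv")
        write_counts(study.panel_counts, out / "panel_counts.tsv")
        write_panel(panel, out / "panel.tsv")
        study.truth.to_frame().to_csv(out / "truth.tsv", sep="\t")
        qc.to_csv(out / "sample_qc.tsv", sep="\t", index_label="sample_id")
        res_seq.table.to_csv(out / "dge_seq.tsv", sep="\t", index_label="gene_id")
        res_panel.table.to_csv(out / "dge_panel.tsv", sep="\t", index_label="gene_id")
        (out / "report.json").write_text(json.dumps(result, indent=2, sort_keys=True))
        manifest = {
            "version": __version__,
            "seed": seed,
            "config": cfg,
            "config_hash": result["config_hash"],
            "sim_config": sim_cfg.to_dict(),
            "outputs": sorted(
                p.name for p in out.iterdir() if p.name != "manifest.json"
            ),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return result
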