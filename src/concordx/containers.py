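"""Core data containers shared by every pipeline stage.

The unit of exchange is a gene-by-sample matrix of nonnegative integer
counts (:class:`CountMatrix`) plus a :class:`PanelDefinition` describing
which genes belong to a fixed hybridization panel and how each probe is
classified (endogenous target, housekeeping gene, positive or negative
control) and which panel genes are absent from the sequencing annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ValidationError", "CountMatrix", "PanelDefinition"]


class ValidationError(ValueError):
    """An input matrix or table violates its structural contract."""


def _duplicates(index: pd.Index) -> list:
    return index[index.duplicated()].unique().tolist()


@dataclass
class CountMatrix:
    """Gene × sample matrix of nonnegative integer counts.

    Parameters
    ----------
    counts
        DataFrame with gene IDs as index and sample IDs as columns.
        Values must be nonnegative integers (integral floats are cast).
    platform
        Free-text tag identifying the measurement platform.
    sample_meta
        Optional per-sample metadata (group label, RQN, DV200, ...);
        its index must equal the count matrix columns.
    """

    counts: pd.DataFrame
    platform: str = ""
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        dup = _duplicates(self.counts.index)
        if dup:
            raise ValidationError(f"duplicate gene IDs: {dup[:10]}")
        dup = _duplicates(self.counts.columns)
        if dup:
            raise ValidationError(f"duplicate sample IDs: {dup[:10]}")
        arr = self.counts.to_numpy()
        if arr.size and np.issubdtype(arr.dtype, np.floating):
            if np.isnan(arr).any():
                g, s = np.argwhere(np.isnan(arr))[0]
                raise ValidationError(
                    f"missing count at gene {self.counts.index[g]!r}, "
                    f"sample {self.counts.columns[s]!r}"
                )
            if not np.array_equal(arr, np.round(arr)):
                g, s = np.argwhere(arr != np.round(arr))[0]
                raise ValidationError(
                    f"non-integer count {arr[g, s]} at gene "
                    f"{self.counts.index[g]!r}, sample {self.counts.columns[s]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        elif arr.size and not np.issubdtype(arr.dtype, np.integer):
            raise ValidationError(f"counts must be integers, got dtype {arr.dtype}")
        if arr.size and (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count {arr[g, s]} at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        if self.sample_meta is not None:
            if list(self.sample_meta.index) != list(self.counts.columns):
                raise ValidationError(
                    "sample_meta index does not match count matrix columns"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_genes(self, genes) -> "CountMatrix":
        """Restrict to ``genes`` (order preserved); unknown IDs are an error."""
        missing = [g for g in genes if g not in self.counts.index]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing[:10]}")
        return CountMatrix(
            self.counts.loc[list(genes)].copy(),
            platform=self.platform,
            sample_meta=None if self.sample_meta is None else self.sample_meta.copy(),
        )

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.platform == other.platform
            and self.counts.equals(other.counts)
            and (
                (self.sample_meta is None and other.sample_meta is None)
                or (
                    self.sample_meta is not None
                    and other.sample_meta is not None
                    and self.sample_meta.equals(other.sample_meta)
                )
            )
        )


#: CodeClass labels used in panel tables and RCC files.
CODE_CLASSES = ("Endogenous", "Housekeeping", "Positive", "Negative")


@dataclass
class PanelDefinition:
    """Probe classes of a fixed hybridization panel.

    ``missing_from_annotation`` lists endogenous panel genes that are not
    present in the sequencing annotation and therefore can never be
    compared across platforms.
    """

    endogenous: list[str]
    housekeeping: list[str] = field(default_factory=list)
    pos_controls: list[str] = field(default_factory=list)
    neg_controls: list[str] = field(default_factory=list)
    missing_from_annotation: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        groups = {
            "endogenous": self.endogenous,
            "housekeeping": self.housekeeping,
            "pos_controls": self.pos_controls,
            "neg_controls": self.neg_controls,
        }
        seen: dict[str, str] = {}
        for name, ids in groups.items():
            if len(set(ids)) != len(ids):
                raise ValidationError(f"duplicate IDs within {name}")
            for g in ids:
                if g in seen:
                    raise ValidationError(
                        f"gene {g!r} appears in both {seen[g]} and {name}"
                    )
                seen[g] = name
        bad = set(self.missing_from_annotation) - set(self.endogenous)
        if bad:
            raise ValidationError(
                f"missing_from_annotation not a subset of endogenous: {sorted(bad)[:10]}"
            )

    @property
    def content_genes(self) -> list[str]:
        """Biological panel genes (endogenous + housekeeping), no controls."""
        return list(self.endogenous) + list(self.housekeeping)

    @property
    def all_probes(self) -> list[str]:
        return self.content_genes + list(self.pos_controls) + list(self.neg_controls)

    def code_class(self, gene: str) -> str:
        if gene in self.endogenous:
            return "Endogenous"
        if gene in self.housekeeping:
            return "Housekeeping"
        if gene in self.pos_controls:
            return "Positive"
        if gene in self.neg_controls:
            return "Negative"
        raise KeyError(gene)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        missing = set(self.missing_from_annotation)
        for g in self.all_probes:
            rows.append(
                {
                    "gene_id": g,
                    "code_class": self.code_class(g),
                    "in_annotation": g not in missing,
                }
            )
        return pd.DataFrame(rows).set_index("gene_id")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PanelDefinition":
        frame = frame.copy()
        if "code_class" not in frame.columns:
            raise ValidationError("panel table lacks a 'code_class' column")
        if "in_annotation" not in frame.columns:
            frame["in_annotation"] = True
        by_class: dict[str, list[str]] = {c: [] for c in CODE_CLASSES}
        for gene, row in frame.iterrows():
            cc = str(row["code_class"])
            if cc not in by_class:
                raise ValidationError(f"unknown code_class {cc!r} for gene {gene!r}")
            by_class[cc].append(str(gene))
        missing = [
            str(g)
            for g, row in frame.iterrows()
            if not bool(row["in_annotation"]) and row["code_class"] == "Endogenous"
        ]
        return cls(
            endogenous=by_class["Endogenous"],
            housekeeping=by_class["Housekeeping"],
            pos_controls=by_class["Positive"],
            neg_controls=by_class["Negative"],
            missing_from_annotation=missing,
        )
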