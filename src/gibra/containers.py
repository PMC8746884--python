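"""Core data containers for the gut-immune-brain axis pipeline.

The central object is :class:`TaxaCountTable`, a samples x taxa integer count
matrix at one taxonomic rank, with semicolon-ranked lineage strings as column
labels (e.g. ``"Firmicutes;Ruminococcaceae;Oscillospira"``).  Mixed host
features (microbial relative abundances, immune-cell percentages, brain
monoamine levels) live in :class:`FeatureMatrix` together with a binary
behaviour label vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TaxaCountTable",
    "FeatureMatrix",
    "ScfaConcentrationTable",
    "MAJOR_ACIDS",
    "MINOR_ACIDS",
]

#: constituent acids of the total-SCFA column
MAJOR_ACIDS = ("acetate", "propionate", "butyrate")
MINOR_ACIDS = ("valerate", "iso-butyrate", "iso-valerate")


def terminal_label(lineage: str) -> str:
    """Last rank of a semicolon-separated lineage string, whitespace-normalised."""
    return " ".join(lineage.split(";")[-1].split())


class TaxaCountTable:
    """Integer count matrix, samples (rows) x taxa (columns), at one rank.

    Parameters
    ----------
    counts
        DataFrame with unique sample index and unique lineage-string columns;
        entries must be finite and >= 0.
    level
        Taxonomic rank tag, e.g. ``"genus"`` or ``"phylum"``.
    sqrt_transformed
        State flag set by :func:`gibra.ordination.sqrt_transform`; guards
        against applying the transform twice.
    """

    def __init__(self, counts: pd.DataFrame, level: str = "genus",
                 sqrt_transformed: bool = False):
        counts = counts.copy()
        if counts.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate taxon labels")
        arr = counts.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)) or (arr < 0).any():
            raise ValueError("counts must be finite and non-negative")
        self.counts = counts
        self.level = level
        self.sqrt_transformed = sqrt_transformed

    # -- basic views ------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_labels(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def terminal_labels(self) -> list[str]:
        return [terminal_label(c) for c in self.counts.columns]

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (rows sum to 1)."""
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            raise ValueError("sample with zero total count")
        return self.counts.div(totals, axis=0)

    # -- rank aggregation -------------------------------------------------
    def aggregate_to_phylum(self) -> "TaxaCountTable":
        """Column-sum the table to its first lineage rank (the phylum)."""
        phyla = [c.split(";")[0].strip() for c in self.counts.columns]
        agg = self.counts.T.groupby(pd.Index(phyla, name="phylum"), sort=True).sum().T
        return TaxaCountTable(agg, level="phylum")

    # -- I/O (taxa rows x sample columns, lineage string first) -----------
    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.T
        out.index.name = "lineage"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, level: str = "genus") -> "TaxaCountTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.T, level=level)

    def copy(self) -> "TaxaCountTable":
        return TaxaCountTable(self.counts, level=self.level,
                              sqrt_transformed=self.sqrt_transformed)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, m = self.counts.shape
        return f"<TaxaCountTable {n} samples x {m} taxa, level={self.level!r}>"


@dataclass
class FeatureMatrix:
    """Samples x mixed continuous features, plus a binary behaviour label.

    ``provenance`` tags each feature with its source block:
    ``microbiota``, ``immune_MLN``, ``immune_spleen``, ``monoamine_AM``,
    ``monoamine_PFC``, ``monoamine_DH`` or ``diversity``.
    """

    values: pd.DataFrame
    provenance: dict[str, str]
    labels: pd.Series | None = None
    label_definition: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate feature names")
        missing = set(self.values.columns) - set(self.provenance)
        if missing:
            raise ValueError(f"features without provenance tag: {sorted(missing)[:5]}")
        if self.labels is not None:
            self.labels = self.labels.reindex(self.values.index)
            uniq = set(pd.unique(self.labels.dropna()))
            if not uniq <= {0, 1}:
                raise ValueError("labels must be binary 0/1")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def drop_constant(self) -> tuple["FeatureMatrix", list[str]]:
        """Remove zero-variance features (they carry no ranking information)."""
        std = self.values.std(axis=0, ddof=0)
        dropped = list(std.index[std == 0])
        kept = self.values.drop(columns=dropped)
        prov = {k: v for k, v in self.provenance.items() if k in kept.columns}
        return FeatureMatrix(kept, prov, self.labels, self.label_definition), dropped

    def to_csv(self, path: str | Path) -> None:
        """Write values as CSV plus a sidecar ``<path>.provenance.json``."""
        path = Path(path)
        out = self.values.copy()
        if self.labels is not None:
            out["label"] = self.labels
        out.to_csv(path, float_format="%.10g")
        sidecar = {"provenance": self.provenance,
                   "label_definition": self.label_definition}
        Path(str(path) + ".provenance.json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        df = pd.read_csv(path, index_col=0)
        labels = None
        if "label" in df.columns:
            labels = df.pop("label").astype(int)
        sidecar_path = Path(str(path) + ".provenance.json")
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            prov = sidecar["provenance"]
            label_def = sidecar.get("label_definition", {})
        else:
            prov = {c: "unknown" for c in df.columns}
            label_def = {}
        return cls(df, prov, labels, label_def)


class ScfaConcentrationTable:
    """Per-sample short- and branched-chain fatty acid concentrations (mM/kg).

    The derived ``total SCFA`` column is always the row sum of the constituent
    acids actually present in the table.
    """

    def __init__(self, concentrations: pd.DataFrame):
        arr = concentrations.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValueError("concentrations must be non-negative")
        self.concentrations = concentrations.copy()

    @property
    def acids(self) -> list[str]:
        return list(self.concentrations.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.concentrations.index)

    def total(self) -> pd.Series:
        """Total SCFA = sum of all constituent acid columns."""
        return self.concentrations.sum(axis=1).rename("total SCFA")

    def with_total(self) -> pd.DataFrame:
        df = self.concentrations.copy()
        df["total SCFA"] = self.total()
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.with_total().to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScfaConcentrationTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.drop(columns=[c for c in df.columns if c == "total SCFA"])
        return cls(df)
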