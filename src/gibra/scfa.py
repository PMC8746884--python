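"""Inferred SCFA-producer taxa model and fatty-acid group comparisons.

The producer model is a literature-derived mapping from genera to the
short-chain fatty acid they chiefly produce (acetate, propionate, butyrate).
A sample's producer-category value is simply the summed percent relative
abundance of the matched genera — no pathway inference, no abundance
weighting.  Bracketed and unbracketed Ruminococcus are distinct Greengenes
labels and are kept distinct here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .containers import TaxaCountTable, terminal_label, MAJOR_ACIDS, MINOR_ACIDS
from .diversity import (DEFAULT_COMPARISONS, GroupComparisonResult,
                        compare_groups_parametric_gate)

__all__ = [
    "ScfaProducerSets",
    "default_producer_sets",
    "producer_abundance",
    "compare_scfa",
    "BCFA_SET",
]

log = logging.getLogger(__name__)

#: valerate is grouped with the branched-chain acids in reporting
BCFA_SET = tuple(MINOR_ACIDS)

_DEFAULT_SETS: dict[str, list[str]] = {
    "acetate": ["Ruminococcaceae Unclassified", "Lactobacillus", "Ruminococcus",
                "Parabacteroidetes", "Dorea", "Streptococcus", "Bifidobacterium"],
    "propionate": ["Bacteroides", "Akkermansia", "Turicibacter", "Prevotella"],
    "butyrate": ["Lachnospiraceae Unclassified", "[Ruminococcus]", "Oscillospira",
                 "Lachnospiraceae Other", "Coprococcus", "Roseburia",
                 "Anaerofustis", "Butyrivibrio", "Anaerostipes", "Anaerotruncus"],
}

#: printed spelling -> Greengenes spelling; the printed key stays the default
DEFAULT_ALIASES: dict[str, str] = {"Parabacteroidetes": "Parabacteroides"}


@dataclass
class ScfaProducerSets:
    """Ordered genus lists per producer category, with an optional alias map."""

    sets: dict[str, list[str]]
    aliases: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ALIASES))

    def __post_init__(self):
        for cat, genera in self.sets.items():
            cleaned = [" ".join(g.split()) for g in genera]
            if len(set(cleaned)) != len(cleaned):
                raise ValueError(f"duplicate genus within category {cat!r}")
            self.sets[cat] = cleaned

    def candidates(self, category: str) -> list[str]:
        """Genus labels to try for a category: canonical names plus aliases."""
        out = []
        for g in self.sets[category]:
            out.append(g)
            if g in self.aliases:
                out.append(self.aliases[g])
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScfaProducerSets":
        data = yaml.safe_load(Path(path).read_text())
        return cls(sets={k: list(v) for k, v in data["sets"].items()},
                   aliases=dict(data.get("aliases", DEFAULT_ALIASES)))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(
            {"sets": self.sets, "aliases": self.aliases}, sort_keys=True))


def default_producer_sets() -> ScfaProducerSets:
    """The default acetate/propionate/butyrate producer genus lists."""
    return ScfaProducerSets(sets={k: list(v) for k, v in _DEFAULT_SETS.items()})


def producer_abundance(rel_table: pd.DataFrame | TaxaCountTable,
                       sets: ScfaProducerSets | None = None) -> pd.DataFrame:
    """Percent relative abundance of each producer category per sample.

    Genus matching is exact on the whitespace-normalised terminal lineage
    label; unmatched genera are logged, not fatal.  A category with no match
    yields zeros with a warning.
    """
    if isinstance(rel_table, TaxaCountTable):
        rel_table = rel_table.relative_abundance()
    sets = sets or default_producer_sets()
    terminal = {" ".join(terminal_label(c).split()): c for c in rel_table.columns}
    cols = {}
    for cat in sets.sets:
        matched, seen = [], set()
        for g in sets.candidates(cat):
            if g in terminal and terminal[g] not in seen:
                matched.append(terminal[g])
                seen.add(terminal[g])
        unmatched = [g for g in sets.sets[cat]
                     if g not in terminal and sets.aliases.get(g) not in terminal]
        if unmatched:
            log.info("category %s: unmatched genera %s", cat, unmatched)
        if not matched:
            log.warning("category %s matched no genus; reporting zeros", cat)
            cols[cat] = 0.0
        else:
            cols[cat] = rel_table[matched].sum(axis=1) * 100.0
    return pd.DataFrame(cols, index=rel_table.index)


def compare_scfa(values: pd.DataFrame, metadata: pd.DataFrame,
                 comparisons=DEFAULT_COMPARISONS,
                 group_col: str = "diet") -> dict[str, GroupComparisonResult]:
    """Normality-gated group comparison per acid / producer category column.

    Delegates to the shared Shapiro-gated test over the study's selected
    diet pairs; one report per column.
    """
    groups = metadata.loc[values.index, group_col]
    return {col: compare_groups_parametric_gate(values[col].to_numpy(),
                                                groups.to_numpy(), comparisons)
            for col in values.columns}
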