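"""End-to-end pipeline: simulate/load -> rarefy -> alpha -> beta -> taxa ->
SCFA -> feature selection, with a reproducibility manifest.

One master seed drives every stage through named substreams, so identical
configuration + seed reproduces every output file byte for byte; the
manifest records the per-stage seeds, the analysis decisions in force, and
a SHA-256 digest of every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import FeatureMatrix, ScfaConcentrationTable, TaxaCountTable
from .diversity import (DEFAULT_COMPARISONS, alpha_diversity,
                        differential_abundance, fb_ratio, rarefy)
from .ordination import (bray_curtis, nmds, pairwise_anosim, sqrt_transform,
                         taxa_vectors)
from .refs import RefsConfig, RefsModel, binarize_marbles, binarize_openfield, \
    direction_table
from .scfa import ScfaProducerSets, compare_scfa, default_producer_sets, \
    producer_abundance
from .synthetic import SyntheticConfig, simulate

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGES = ("simulate", "rarefy", "beta", "nmds", "refs_marbles",
           "refs_openfield")


@dataclass
class PipelineConfig:
    """Run configuration; either a simulate block or explicit input paths."""

    outdir: str | Path = "gibra_out"
    seed: int = 0
    simulate: SyntheticConfig | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    depth: int = 45_000
    permutations: int = 999
    abundance_filter: float = 0.01
    taxa_vector_threshold: float = 0.6
    comparisons: tuple = DEFAULT_COMPARISONS
    nmds_restarts: int = 20
    producer_sets: ScfaProducerSets | None = None
    refs: RefsConfig = field(default_factory=RefsConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {"outdir", "seed", "depth", "permutations", "abundance_filter",
                 "taxa_vector_threshold", "comparisons", "nmds_restarts",
                 "simulate", "inputs", "refs", "producer_sets"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls()
        for key in ("outdir", "seed", "depth", "permutations",
                    "abundance_filter", "taxa_vector_threshold",
                    "nmds_restarts"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "comparisons" in raw:
            cfg.comparisons = tuple(tuple(p) for p in raw["comparisons"])
        if "simulate" in raw:
            sim = raw["simulate"] or {}
            cfg.simulate = SyntheticConfig(**sim)
        if "inputs" in raw:
            cfg.inputs = dict(raw["inputs"])
        if "refs" in raw:
            cfg.refs = RefsConfig(**{k: (tuple(v) if k == "families" else v)
                                     for k, v in (raw["refs"] or {}).items()})
        if "producer_sets" in raw and raw["producer_sets"]:
            cfg.producer_sets = ScfaProducerSets.from_yaml(raw["producer_sets"])
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.simulate is None and not self.inputs:
            # default: simulate under the standard study conditions
            self.simulate = SyntheticConfig()
        if self.simulate is None:
            required = {"genus_counts", "metadata", "features", "behaviour"}
            missing = [k for k in required if k not in self.inputs]
            if missing:
                raise ValueError(f"missing input paths: {missing}")
            for key, path in self.inputs.items():
                if not Path(path).exists():
                    raise ValueError(f"input path does not exist: {key}={path}")
        if self.depth <= 0:
            raise ValueError("rarefaction depth must be positive")
        self.refs.validate()


def _stage_seeds(master: int) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(len(_STAGES))
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(_STAGES, children)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(cfg: PipelineConfig):
    genus = TaxaCountTable.from_tsv(cfg.inputs["genus_counts"], level="genus")
    meta = pd.read_csv(cfg.inputs["metadata"], sep="\t", index_col=0)
    if "diet" not in meta.columns:
        raise ValueError("metadata is missing required column 'diet'")
    features = FeatureMatrix.from_csv(cfg.inputs["features"])
    behaviour = pd.read_csv(cfg.inputs["behaviour"], sep="\t", index_col=0)
    scfa = (ScfaConcentrationTable.from_tsv(cfg.inputs["scfa"])
            if "scfa" in cfg.inputs else None)
    return genus, meta, scfa, features, behaviour


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the manifest (also written as JSON)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    sets = config.producer_sets or default_producer_sets()
    files: dict[str, Path] = {}

    def save_df(name: str, df: pd.DataFrame, **kw):
        path = outdir / name
        df.to_csv(path, float_format="%.10g", **kw)
        files[name] = path

    def save_json(name: str, obj):
        path = outdir / name
        path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))
        files[name] = path

    # -- stage 1: data ----------------------------------------------------
    if config.simulate is not None:
        dataset = simulate(config.simulate, seed=seeds["simulate"])
        for name, path in dataset.write(outdir / "simulated").items():
            files[f"simulated/{path.name}"] = path
        genus, meta, scfa_tab = dataset.genus_counts, dataset.metadata, dataset.scfa
        features, behaviour = dataset.features, dataset.behaviour
    else:
        genus, meta, scfa_tab, features, behaviour = _load_inputs(config)
    if "diet" not in meta.columns:
        raise ValueError("metadata is missing required column 'diet'")

    # -- stage 2: rarefaction + alpha ------------------------------------
    rarefied = rarefy(genus, config.depth, seeds["rarefy"])
    meta = meta.loc[rarefied.sample_ids]
    alpha = alpha_diversity(rarefied, meta, config.comparisons)
    save_df("alpha_diversity.csv", alpha.per_sample)
    save_json("alpha_tests.json",
              {k: v.to_dict() for k, v in alpha.tests.items()})

    phylum = rarefied.aggregate_to_phylum()
    save_df("fb_ratio.csv", fb_ratio(phylum).to_frame())

    # -- stage 3: beta diversity -----------------------------------------
    rel = rarefied.relative_abundance()
    sq = sqrt_transform(rel)
    dm = bray_curtis(sq)
    save_df("bray_curtis.csv",
            pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)))
    ano = pairwise_anosim(dm, meta, config.comparisons,
                          permutations=config.permutations,
                          seed=seeds["beta"])
    save_df("anosim.csv", ano.table(), index=False)
    ordi = nmds(dm, restarts=config.nmds_restarts, seed=seeds["nmds"])
    vectors = taxa_vectors(sq, ordi.coordinates, config.taxa_vector_threshold)
    coords = ordi.coordinates.copy()
    coords["stress"] = ordi.stress
    save_df("nmds_coordinates.csv", coords)
    save_df("nmds_taxa_vectors.csv", vectors, index=False)

    # -- stage 4: differential abundance ---------------------------------
    da = differential_abundance(rel, meta["diet"].to_numpy(),
                                config.abundance_filter,
                                comparisons=config.comparisons)
    save_df("differential_abundance.csv", da.table)

    # -- stage 5: SCFA producer model ------------------------------------
    producers = producer_abundance(rel, sets)
    save_df("scfa_producers.csv", producers)
    scfa_reports = {f"producer:{k}": v.to_dict() for k, v in
                    compare_scfa(producers, meta, config.comparisons).items()}
    if scfa_tab is not None:
        conc = scfa_tab.with_total().loc[producers.index]
        scfa_reports.update({f"concentration:{k}": v.to_dict() for k, v in
                             compare_scfa(conc, meta, config.comparisons).items()})
    save_json("scfa_tests.json", scfa_reports)

    # -- stage 6: REFS on both behaviour labels --------------------------
    behaviour = behaviour.loc[features.values.index]
    refs_out = {}
    for tag, col, binarize, orientation in (
            ("marbles", "marbles_buried", binarize_marbles, "label1_vs_label0"),
            ("openfield", "centre_entries", binarize_openfield,
             "label0_vs_label1")):
        y = binarize(behaviour[col].to_numpy())
        if len(set(y)) < 2:
            log.warning("behaviour %s has a single label class; REFS skipped",
                        tag)
            continue
        model = RefsModel(features.values, y, config.refs)
        res = model.fit(seed=seeds[f"refs_{tag}"])
        save_df(f"refs_{tag}_accuracy_curve.csv", res.accuracy_curve,
                index=False)
        save_df(f"refs_{tag}_roc.csv", res.roc_points, index=False)
        arrows = direction_table(features.values, y, res.best_signature,
                                 orientation=orientation)
        save_df(f"refs_{tag}_directions.csv", arrows, index=False)
        refs_out[tag] = {
            "best_size": res.best_size,
            "best_accuracy": res.best_accuracy,
            "best_signature": res.best_signature,
            "best_family": res.best_family,
            "auc_mean": res.auc_mean,
            "auc_sd": res.auc_sd,
        }
    save_json("refs_summary.json", refs_out)

    # -- manifest ---------------------------------------------------------
    manifest = {
        "gibra_version": __version__,
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "depth": config.depth,
        "permutations": config.permutations,
        "abundance_filter": config.abundance_filter,
        "comparisons": [list(p) for p in config.comparisons],
        "decisions": {
            "shannon_base": "e",
            "evenness": "pielou",
            "rarefaction": "without replacement, single draw",
            "abundance_filter_scope": "grand mean over all samples",
            "anosim_p": "(1+hits)/(1+permutations), midranks",
            "pairwise_anosim_p": "unadjusted",
            "ordination_input": "sqrt-transformed relative abundance",
            "refs_retention": "ceil(0.8*m)",
            "refs_fine_tail": config.refs.fine_tail,
        },
        "artifacts": {name: _sha256(path) for name, path in sorted(files.items())},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
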