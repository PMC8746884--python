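"""Synthetic multi-modal gut-immune-brain datasets.

Emulates a four-arm mouse diet study (control, scGOS:lcFOS prebiotic,
n-3 PUFA, combination; 8/10/10/10 animals = 38 samples) measured at three
levels: caecal 16S genus counts, caecal SCFA/BCFA concentrations coupled to
producer-genus abundance, and host features (mesenteric-lymph-node and spleen
T-cell percentages, regional brain monoamine levels) that drive two
behavioural counts (marbles buried out of 20, open-field centre entries).

Genus counts follow a Dirichlet-multinomial: each diet group has a fixed
composition obtained by applying planted log-fold shifts to a long-tailed
baseline profile, and per-sample compositions are drawn around it with a
concentration parameter capturing the overdispersion typical of 16S data.
A truth record stores every planted effect so downstream selection and
testing stages can be scored against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (FeatureMatrix, ScfaConcentrationTable,
                         TaxaCountTable, terminal_label)

__all__ = [
    "DIET_GROUPS",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_counts",
    "generate_scfa",
    "generate_host_and_behaviour",
    "simulate",
]

DIET_GROUPS = ("control", "scGOS:lcFOS", "n-3 PUFA", "combination")

# ---------------------------------------------------------------------------
# Fixed genus catalogue: (phylum, family, genus, baseline weight).
# 60 genera over 9 phyla; weights form a long-tailed mouse-caecal profile
# dominated by S24-7 and Lachnospiraceae and are renormalised at use.
# ---------------------------------------------------------------------------
GENUS_CATALOGUE: list[tuple[str, str, str, float]] = [
    # Bacteroidetes
    ("Bacteroidetes", "S24-7", "S24-7 Unclassified", 0.220),
    ("Bacteroidetes", "Bacteroidaceae", "Bacteroides", 0.030),
    ("Bacteroidetes", "Prevotellaceae", "Prevotella", 0.010),
    ("Bacteroidetes", "Porphyromonadaceae", "Parabacteroidetes", 0.008),
    ("Bacteroidetes", "Rikenellaceae", "Rikenellaceae Unclassified", 0.012),
    ("Bacteroidetes", "Odoribacteraceae", "Odoribacter", 0.006),
    ("Bacteroidetes", "Rikenellaceae", "Alistipes", 0.004),
    ("Bacteroidetes", "Paraprevotellaceae", "Paraprevotella", 0.002),
    ("Bacteroidetes", "Bacteroidales", "Bacteroidales Unclassified", 0.010),
    # Firmicutes
    ("Firmicutes", "Lachnospiraceae", "Lachnospiraceae Unclassified", 0.130),
    ("Firmicutes", "Ruminococcaceae", "Ruminococcaceae Unclassified", 0.090),
    ("Firmicutes", "Clostridiales", "Clostridiales Unclassified", 0.060),
    ("Firmicutes", "Ruminococcaceae", "Oscillospira", 0.050),
    ("Firmicutes", "Lactobacillaceae", "Lactobacillus", 0.040),
    ("Firmicutes", "Erysipelotrichaceae", "Allobaculum", 0.030),
    ("Firmicutes", "Lachnospiraceae", "Lachnospiraceae Other", 0.025),
    ("Firmicutes", "Turicibacteraceae", "Turicibacter", 0.020),
    ("Firmicutes", "Ruminococcaceae", "Ruminococcus", 0.015),
    ("Firmicutes", "Lachnospiraceae", "[Ruminococcus]", 0.012),
    ("Firmicutes", "Lachnospiraceae", "Coprococcus", 0.010),
    ("Firmicutes", "Clostridiaceae", "Clostridium", 0.008),
    ("Firmicutes", "Lachnospiraceae", "Dorea", 0.006),
    ("Firmicutes", "Lachnospiraceae", "Blautia", 0.006),
    ("Firmicutes", "Lachnospiraceae", "Roseburia", 0.005),
    ("Firmicutes", "Ruminococcaceae", "Ruminococcaceae Other", 0.005),
    ("Firmicutes", "Dehalobacteriaceae", "Dehalobacterium", 0.004),
    ("Firmicutes", "Ruminococcaceae", "Faecalibacterium", 0.003),
    ("Firmicutes", "Erysipelotrichaceae", "Erysipelotrichaceae Unclassified", 0.003),
    ("Firmicutes", "Clostridiaceae", "SMB53", 0.002),
    ("Firmicutes", "Streptococcaceae", "Streptococcus", 0.002),
    ("Firmicutes", "Christensenellaceae", "Christensenellaceae Unclassified", 0.002),
    ("Firmicutes", "Lachnospiraceae", "Anaerostipes", 0.0015),
    ("Firmicutes", "Ruminococcaceae", "Anaerotruncus", 0.0015),
    ("Firmicutes", "Mogibacteriaceae", "Mogibacteriaceae Unclassified", 0.0015),
    ("Firmicutes", "Eubacteriaceae", "Anaerofustis", 0.001),
    ("Firmicutes", "Lachnospiraceae", "Butyrivibrio", 0.001),
    ("Firmicutes", "Erysipelotrichaceae", "Coprobacillus", 0.001),
    ("Firmicutes", "Clostridiaceae", "Candidatus Arthromitus", 0.001),
    ("Firmicutes", "Peptococcaceae", "rc4-4", 0.001),
    ("Firmicutes", "Peptostreptococcaceae", "Peptostreptococcaceae Unclassified", 0.001),
    ("Firmicutes", "Lachnospiraceae", "Lachnospira", 0.001),
    ("Firmicutes", "Staphylococcaceae", "Staphylococcus", 0.0005),
    ("Firmicutes", "Enterococcaceae", "Enterococcus", 0.0005),
    ("Firmicutes", "Veillonellaceae", "Veillonella", 0.0004),
    ("Firmicutes", "Leuconostocaceae", "Leuconostoc", 0.0003),
    # Actinobacteria
    ("Actinobacteria", "Bifidobacteriaceae", "Bifidobacterium", 0.005),
    ("Actinobacteria", "Coriobacteriaceae", "Adlercreutzia", 0.004),
    ("Actinobacteria", "Coriobacteriaceae", "Collinsella", 0.001),
    ("Actinobacteria", "Coriobacteriaceae", "Coriobacteriaceae Unclassified", 0.001),
    # Verrucomicrobia
    ("Verrucomicrobia", "Verrucomicrobiaceae", "Akkermansia", 0.020),
    # Proteobacteria
    ("Proteobacteria", "Alcaligenaceae", "Sutterella", 0.004),
    ("Proteobacteria", "Desulfovibrionaceae", "Desulfovibrio", 0.003),
    ("Proteobacteria", "Helicobacteraceae", "Helicobacter", 0.002),
    ("Proteobacteria", "Desulfovibrionaceae", "Bilophila", 0.001),
    ("Proteobacteria", "Enterobacteriaceae", "Enterobacteriaceae Unclassified", 0.001),
    # Cyanobacteria
    ("Cyanobacteria", "YS2", "Cyanobacteria 4C0d-2 Unclassified", 0.003),
    # Tenericutes
    ("Tenericutes", "Anaeroplasmataceae", "Anaeroplasma", 0.001),
    ("Tenericutes", "Mycoplasmataceae", "Mycoplasma", 0.0003),
    # Deferribacteres
    ("Deferribacteres", "Deferribacteraceae", "Mucispirillum", 0.002),
    # TM7
    ("TM7", "F16", "TM7-3 Unclassified", 0.001),
]

#: diet-specific natural-log-fold shifts on baseline proportions, by genus.
#: Directions follow the eight genera the study reports as differential:
#: prebiotic and combination diets raise Allobaculum/S24-7 and deplete
#: Oscillospira; the fish-oil diet raises Turicibacter/Akkermansia and
#: Rikenellaceae; the combination additionally depletes Ruminococcaceae and
#: Lachnospiraceae unclassified and shows the strongest Akkermansia bloom.
DEFAULT_PLANTED_GENUS_EFFECTS: dict[str, dict[str, float]] = {
    "Allobaculum": {"scGOS:lcFOS": 1.0, "combination": 1.0},
    "S24-7 Unclassified": {"scGOS:lcFOS": 0.7, "combination": 0.7},
    "Oscillospira": {"scGOS:lcFOS": -1.0, "combination": -1.0},
    "Ruminococcaceae Unclassified": {"combination": -1.0},
    "Turicibacter": {"n-3 PUFA": 1.0},
    "Akkermansia": {"n-3 PUFA": 1.0, "combination": 2.0},
    "Lachnospiraceae Unclassified": {"combination": -0.7},
    "Rikenellaceae Unclassified": {"n-3 PUFA": 1.0},
}

#: acid -> (intercept mM/kg, slope mM/kg per unit producer relative
#: abundance, Gaussian noise sd mM/kg)
DEFAULT_SCFA_COUPLING: dict[str, tuple[float, float, float]] = {
    "acetate": (15.0, 150.0, 4.0),
    "propionate": (1.0, 60.0, 0.8),
    "butyrate": (1.0, 25.0, 1.0),
}

#: minor (branched-chain + valerate) acids: name -> (mean mM/kg, noise sd)
DEFAULT_MINOR_ACIDS: dict[str, tuple[float, float]] = {
    "valerate": (0.5, 0.12),
    "iso-butyrate": (0.6, 0.15),
    "iso-valerate": (0.7, 0.18),
}

# host feature block: (name, provenance tag, mean, sd)
_IMMUNE = [
    ("activated CD4 cells (%)", 12.0, 2.5),
    ("Th1 cells (%)", 8.0, 1.8),
    ("Th2 cells (%)", 4.0, 1.0),
    ("Th17 cells (%)", 2.5, 0.6),
    ("activated Th2 cells (%)", 1.5, 0.4),
]
_MONOAMINES = {
    "AM": [("noradrenaline (nmol/g)", 2.4, 0.5),
           ("dopamine (nmol/g)", 1.1, 0.3),
           ("serotonin (nmol/g)", 3.2, 0.6),
           ("5-HIAA (nmol/g)", 1.8, 0.4),
           ("tryptophan (nmol/g)", 18.0, 3.0)],
    "PFC": [("noradrenaline (nmol/g)", 1.9, 0.4),
            ("dopamine (nmol/g)", 0.9, 0.25),
            ("serotonin (nmol/g)", 2.6, 0.5),
            ("5-HIAA (nmol/g)", 1.2, 0.3),
            ("tryptophan (nmol/g)", 16.0, 2.5),
            ("HVA (nmol/g)", 0.7, 0.2)],
    "DH": [("noradrenaline (nmol/g)", 2.1, 0.45),
           ("dopamine (nmol/g)", 0.4, 0.12),
           ("serotonin (nmol/g)", 2.9, 0.55),
           ("5-HIAA (nmol/g)", 1.5, 0.35),
           ("tryptophan (nmol/g)", 17.0, 2.8)],
}


def default_host_features() -> list[tuple[str, str, float, float]]:
    """26 host features: MLN + spleen T-cell panels and regional monoamines."""
    feats = []
    for organ, tag in (("MLN", "immune_MLN"), ("spleen", "immune_spleen")):
        for name, mean, sd in _IMMUNE:
            feats.append((f"{organ}: {name}", tag, mean, sd))
    for region, panel in _MONOAMINES.items():
        for name, mean, sd in panel:
            feats.append((f"{region}: {name}", f"monoamine_{region}", mean, sd))
    return feats


#: group shifts (in units of feature sd) for a few host features, echoing
#: the reported immune/monoamine group effects; everything else is null.
DEFAULT_HOST_GROUP_SHIFTS: dict[str, dict[str, float]] = {
    "MLN: activated CD4 cells (%)": {"n-3 PUFA": 0.9},
    "AM: serotonin (nmol/g)": {"combination": 0.8},
    "AM: 5-HIAA (nmol/g)": {"combination": 0.8},
}

#: behaviour drivers: feature name -> sign of its effect on the latent
#: behaviour propensity (marbles: toward burying more; open field: toward
#: entering the centre more)
DEFAULT_MARBLE_FEATURES: dict[str, int] = {
    "Adlercreutzia": 1,
    "DH: tryptophan (nmol/g)": 1,
    "Dehalobacterium": -1,
    "MLN: Th17 cells (%)": -1,
    "spleen: activated Th2 cells (%)": -1,
}
DEFAULT_OPENFIELD_FEATURES: dict[str, int] = {
    "Odoribacter": 1,
    "Turicibacter": 1,
    "Oscillospira": -1,
    "PFC: 5-HIAA (nmol/g)": 1,
    "Ruminococcus": -1,
}


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults reproduce the design the analyses assume: 38 animals in four
    diet arms, ~45-60k reads/sample, 87 total features (60 genus relative
    abundances + 26 host features + Shannon diversity), eight planted
    diet-specific genus shifts, SCFA concentrations coupled to producer
    abundance, and behaviour counts driven by five planted features each.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"control": 8, "scGOS:lcFOS": 10,
                                 "n-3 PUFA": 10, "combination": 10})
    library_size_range: tuple[int, int] = (45_000, 60_000)
    dm_concentration: float = 150.0
    planted_genus_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(e) for g, e
                                 in DEFAULT_PLANTED_GENUS_EFFECTS.items()})
    scfa_coupling: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SCFA_COUPLING))
    minor_acids: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MINOR_ACIDS))
    host_features: list[tuple[str, str, float, float]] = field(
        default_factory=default_host_features)
    host_group_shifts: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v
                                 in DEFAULT_HOST_GROUP_SHIFTS.items()})
    marble_features: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MARBLE_FEATURES))
    openfield_features: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_OPENFIELD_FEATURES))
    #: per-feature coefficient on the standardised scale of the latent
    #: behaviour propensity (calibrated once so a single planted feature
    #: discriminates the binarised label with AUC around 0.8)
    behaviour_effect_size: float = 1.2
    #: loading of the shared per-animal behaviour factor on each planted
    #: feature (log-fold units for genera, sd units for host features);
    #: models the gut-brain covariation that makes each planted feature
    #: individually informative
    behaviour_latent_loading: float = 0.7
    litters_per_group: int = 3
    n_marbles: int = 20
    openfield_rate: float = 9.5

    def validate(self) -> None:
        if not self.n_per_group or any(n <= 0 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be strictly positive")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("library size range must be positive and ordered")
        if self.dm_concentration <= 0:
            raise ValueError("Dirichlet concentration must be positive")
        genera = {g for _, _, g, _ in GENUS_CATALOGUE}
        for genus, shifts in self.planted_genus_effects.items():
            if genus not in genera:
                raise ValueError(f"planted genus not in taxa list: {genus!r}")
            for grp in shifts:
                if grp not in self.n_per_group:
                    raise ValueError(f"unknown diet group in planted effect: {grp!r}")
        for acid, (_, slope, sd) in self.scfa_coupling.items():
            if slope < 0 or sd < 0:
                raise ValueError(f"negative slope/noise sd for {acid}")
        for signs in (self.marble_features, self.openfield_features):
            for feat, s in signs.items():
                if s not in (-1, 1):
                    raise ValueError(f"effect sign must be -1/+1: {feat!r}")
        if not np.isfinite(self.behaviour_effect_size):
            raise ValueError("behaviour effect size must be finite")
        if self.n_marbles <= 0 or self.openfield_rate <= 0:
            raise ValueError("behaviour count parameters must be positive")


@dataclass
class SyntheticDataset:
    """One generated study: count tables, metadata, SCFA, features, truth."""

    genus_counts: TaxaCountTable
    phylum_counts: TaxaCountTable
    metadata: pd.DataFrame
    scfa: ScfaConcentrationTable
    features: FeatureMatrix
    behaviour: pd.DataFrame
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Export all tables as TSV/CSV/JSON; returns the file map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files = {
            "genus_counts": outdir / "genus_counts.tsv",
            "phylum_counts": outdir / "phylum_counts.tsv",
            "metadata": outdir / "metadata.tsv",
            "scfa": outdir / "scfa.tsv",
            "features": outdir / "features.csv",
            "behaviour": outdir / "behaviour.tsv",
            "truth": outdir / "truth.json",
        }
        self.genus_counts.to_tsv(files["genus_counts"])
        self.phylum_counts.to_tsv(files["phylum_counts"])
        self.metadata.to_csv(files["metadata"], sep="\t")
        self.scfa.to_tsv(files["scfa"])
        self.features.to_csv(files["features"])
        self.behaviour.to_csv(files["behaviour"], sep="\t")
        files["truth"].write_text(json.dumps(self.truth, indent=1, sort_keys=True))
        return files


# ---------------------------------------------------------------------------
# generation stages
# ---------------------------------------------------------------------------

def _lineages() -> list[str]:
    return [f"{p};{f};{g}" for p, f, g, _ in GENUS_CATALOGUE]


def baseline_proportions() -> np.ndarray:
    w = np.array([w for _, _, _, w in GENUS_CATALOGUE], dtype=float)
    return w / w.sum()


def group_compositions(config: SyntheticConfig) -> dict[str, np.ndarray]:
    """Planted log-fold shifts applied to the baseline, renormalised."""
    base = baseline_proportions()
    genera = [g for _, _, g, _ in GENUS_CATALOGUE]
    comps = {}
    for grp in config.n_per_group:
        logp = np.log(base)
        for genus, shifts in config.planted_genus_effects.items():
            if grp in shifts:
                logp[genera.index(genus)] += shifts[grp]
        p = np.exp(logp)
        comps[grp] = p / p.sum()
    return comps


def generate_counts(config: SyntheticConfig, rng: np.random.Generator,
                    sample_log_shifts: dict[str, np.ndarray] | None = None,
                    ) -> tuple[TaxaCountTable, pd.DataFrame]:
    """Dirichlet-multinomial genus counts plus sample metadata.

    Per sample: draw a library size uniformly from the configured range,
    draw a composition from Dirichlet(concentration x group composition),
    then counts from a multinomial at that composition.  Litter ids are
    assigned round-robin within each diet group.  ``sample_log_shifts``
    optionally adds per-sample log-fold shifts (genus -> length-n vector in
    generation order) on top of the group composition — used to couple
    behaviour-planted genera to the shared behaviour factor.
    """
    config.validate()
    comps = group_compositions(config)
    genera = [g for _, _, g, _ in GENUS_CATALOGUE]
    rows, diets, litters, ids = [], [], [], []
    i = 0
    for grp, n in config.n_per_group.items():
        base = comps[grp]
        for k in range(n):
            p_grp = base
            if sample_log_shifts:
                logp = np.log(base).copy()
                for genus, vec in sample_log_shifts.items():
                    logp[genera.index(genus)] += vec[i]
                p_grp = np.exp(logp)
                p_grp = p_grp / p_grp.sum()
            i += 1
            alpha = config.dm_concentration * p_grp
            lib = int(rng.integers(config.library_size_range[0],
                                   config.library_size_range[1] + 1))
            p = rng.dirichlet(alpha)
            rows.append(rng.multinomial(lib, p))
            diets.append(grp)
            litters.append(f"{grp}/L{k % config.litters_per_group + 1}")
            ids.append(f"S{i:02d}")
    counts = pd.DataFrame(np.asarray(rows), index=ids, columns=_lineages())
    counts.index.name = "sample"
    meta = pd.DataFrame({"diet": diets, "litter": litters}, index=ids)
    meta.index.name = "sample"
    return TaxaCountTable(counts, level="genus"), meta


def generate_scfa(counts: TaxaCountTable, producer_sets: dict[str, list[str]],
                  config: SyntheticConfig,
                  rng: np.random.Generator) -> ScfaConcentrationTable:
    """SCFA concentrations linearly coupled to producer-category abundance.

    concentration = intercept + slope * (category relative abundance)
    + Gaussian noise, truncated at zero.  Minor acids (valerate and the
    branched-chain acids) are uncoupled intercept + noise.
    """
    config.validate()
    rel = counts.relative_abundance()
    terminal = {terminal_label(c): c for c in rel.columns}
    cols = {}
    for acid, (intercept, slope, sd) in config.scfa_coupling.items():
        members = [terminal[g] for g in producer_sets.get(acid, []) if g in terminal]
        abundance = rel[members].sum(axis=1).to_numpy() if members else 0.0
        conc = intercept + slope * abundance + rng.normal(0.0, sd, len(rel))
        cols[acid] = np.clip(conc, 0.0, None)
    for acid, (mean, sd) in config.minor_acids.items():
        cols[acid] = np.clip(mean + rng.normal(0.0, sd, len(rel)), 0.0, None)
    df = pd.DataFrame(cols, index=rel.index)
    df.index.name = "sample"
    return ScfaConcentrationTable(df)


def _shannon_nats(row: np.ndarray) -> float:
    p = row[row > 0] / row.sum()
    return float(-(p * np.log(p)).sum())


def generate_host_and_behaviour(counts: TaxaCountTable, config: SyntheticConfig,
                                rng: np.random.Generator,
                                metadata: pd.DataFrame | None = None,
                                host_latent: dict[str, np.ndarray] | None = None,
                                ) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Host feature block and planted-feature-driven behaviour counts.

    Host features are per-group Gaussians, optionally shifted (in sd units)
    by the shared behaviour factor for planted features.  Marbles buried ~
    Binomial(20, p) with logit(p) a signed sum of the standardised planted
    features; open-field centre entries ~ Poisson(lambda) with the analogous
    log link.
    """
    config.validate()
    rel = counts.relative_abundance()
    rel.columns = [terminal_label(c) for c in rel.columns]
    n = len(rel)

    host_cols, prov = {}, {}
    for name, tag, mean, sd in config.host_features:
        shift = np.zeros(n)
        if metadata is not None and name in config.host_group_shifts:
            for grp, delta in config.host_group_shifts[name].items():
                shift += np.where(metadata["diet"].to_numpy() == grp, delta * sd, 0.0)
        if host_latent and name in host_latent:
            shift = shift + sd * host_latent[name]
        host_cols[name] = np.clip(mean + shift + rng.normal(0.0, sd, n), 0.0, None)
        prov[name] = tag
    host = pd.DataFrame(host_cols, index=rel.index)

    shannon = counts.counts.apply(lambda r: _shannon_nats(r.to_numpy()), axis=1)
    values = pd.concat([rel, host, shannon.rename("Shannon index (genus)")], axis=1)
    for c in rel.columns:
        prov[c] = "microbiota"
    prov["Shannon index (genus)"] = "diversity"

    def latent(signs: dict[str, int]) -> np.ndarray:
        eta = np.zeros(n)
        for feat, sign in signs.items():
            if feat not in values.columns:
                raise ValueError(f"planted behaviour feature absent: {feat!r}")
            col = values[feat].to_numpy()
            sd = col.std(ddof=0)
            if sd == 0:
                raise ValueError(f"planted behaviour feature constant: {feat!r}")
            eta += sign * config.behaviour_effect_size * (col - col.mean()) / sd
        return eta

    p_marble = 1.0 / (1.0 + np.exp(-latent(config.marble_features)))
    marbles = rng.binomial(config.n_marbles, p_marble)
    k = max(len(config.openfield_features), 1)
    lam = config.openfield_rate * np.exp(
        0.45 * latent(config.openfield_features) / np.sqrt(k))
    entries = rng.poisson(lam)
    behaviour = pd.DataFrame({"marbles_buried": marbles,
                              "centre_entries": entries}, index=rel.index)
    behaviour.index.name = "sample"
    fm = FeatureMatrix(values, prov)
    return fm, behaviour


def simulate(config: SyntheticConfig | None = None, seed: int = 0) -> SyntheticDataset:
    """Generate one complete study under `config` (defaults = study design).

    All randomness flows from `seed` through named substreams, so a fixed
    seed yields byte-identical tables on export.
    """
    from .scfa import default_producer_sets  # local import avoids a cycle

    config = config or SyntheticConfig()
    config.validate()
    ss = np.random.SeedSequence(seed)
    rng_counts, rng_scfa, rng_host, rng_latent = (
        np.random.default_rng(s) for s in ss.spawn(4))

    # shared per-animal behaviour factors couple every planted feature of a
    # behaviour, so each is individually informative about the label
    n_total = sum(config.n_per_group.values())
    genera = {g for _, _, g, _ in GENUS_CATALOGUE}
    lam = config.behaviour_latent_loading
    genus_shifts: dict[str, np.ndarray] = {}
    host_shifts: dict[str, np.ndarray] = {}
    for signs in (config.marble_features, config.openfield_features):
        u = rng_latent.normal(size=n_total)
        for feat, sign in signs.items():
            vec = sign * lam * u
            if feat in genera:
                genus_shifts[feat] = genus_shifts.get(feat, 0.0) + vec
            else:
                host_shifts[feat] = host_shifts.get(feat, 0.0) + vec

    genus, meta = generate_counts(config, rng_counts, genus_shifts or None)
    phylum = genus.aggregate_to_phylum()
    scfa = generate_scfa(genus, default_producer_sets().sets, config, rng_scfa)
    features, behaviour = generate_host_and_behaviour(
        genus, config, rng_host, meta, host_shifts or None)

    truth = {
        "planted_genus_effects": {g: dict(e) for g, e
                                  in config.planted_genus_effects.items()},
        "marble_features": dict(config.marble_features),
        "openfield_features": dict(config.openfield_features),
        "behaviour_effect_size": config.behaviour_effect_size,
        "group_compositions": {g: dict(zip([t for _, _, t, _ in GENUS_CATALOGUE],
                                           map(float, comp)))
                               for g, comp in group_compositions(config).items()},
        "seed": seed,
    }
    return SyntheticDataset(genus, phylum, meta, scfa, features, behaviour, truth)
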