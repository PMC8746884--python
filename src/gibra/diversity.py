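"""Within-sample community statistics.

Implements the per-sample battery run on rarefied genus tables: Shannon
diversity (natural log), Pielou evenness, richness, the phylum-level
Firmicutes-to-Bacteroidetes ratio, normality-gated group comparisons
(Shapiro-Wilk deciding between one-way ANOVA + Sidak and Kruskal-Wallis +
Dunn over a selected pair list), and genus-level differential abundance with
a 1% mean-abundance filter and Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import TaxaCountTable

__all__ = [
    "DEFAULT_COMPARISONS",
    "rarefy",
    "shannon",
    "evenness",
    "richness",
    "alpha_diversity",
    "fb_ratio",
    "compare_groups_parametric_gate",
    "differential_abundance",
    "GroupComparisonResult",
    "AlphaDiversityResult",
    "DifferentialAbundanceResult",
]

#: the study's selected pairs: control vs each diet, each single diet vs
#: the combination diet
DEFAULT_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("control", "scGOS:lcFOS"),
    ("control", "n-3 PUFA"),
    ("control", "combination"),
    ("scGOS:lcFOS", "combination"),
    ("n-3 PUFA", "combination"),
)


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def rarefy(table: TaxaCountTable, depth: int, seed: int) -> TaxaCountTable:
    """Subsample each sample to `depth` reads uniformly without replacement.

    Samples with fewer than `depth` total reads are dropped with a warning.
    Sampling is exact multivariate hypergeometric (one draw per sample).
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    totals = table.sample_sums()
    keep = totals[totals >= depth].index
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} sample(s) below depth {depth}: "
                      f"{dropped}", stacklevel=2)
    if len(keep) == 0:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    rng = np.random.default_rng(seed)
    sub = np.empty((len(keep), len(table.taxon_labels)), dtype=np.int64)
    mat = table.counts.loc[keep].to_numpy(dtype=np.int64)
    for i, row in enumerate(mat):
        sub[i] = rng.multivariate_hypergeometric(row, depth)
    out = pd.DataFrame(sub, index=keep, columns=table.counts.columns)
    out.index.name = table.counts.index.name
    return TaxaCountTable(out, level=table.level)


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def shannon(counts_row: np.ndarray) -> float:
    """Shannon index H = -sum p_i ln p_i (nats) over non-zero taxa."""
    row = np.asarray(counts_row, dtype=float)
    if row.sum() <= 0:
        raise ValueError("all-zero count row")
    p = row[row > 0] / row.sum()
    return float(-(p * np.log(p)).sum())


def richness(counts_row: np.ndarray) -> int:
    """Number of taxa with non-zero counts."""
    return int(np.count_nonzero(np.asarray(counts_row)))


def evenness(counts_row: np.ndarray) -> float:
    """Pielou J = H / ln S; NaN (undefined) when fewer than two taxa."""
    s = richness(counts_row)
    if s <= 1:
        return float("nan")
    return shannon(counts_row) / np.log(s)


@dataclass
class GroupComparisonResult:
    """Report of one normality-gated multi-group comparison."""

    branch: str                      # "anova_sidak" or "kruskal_dunn"
    shapiro_p: dict[str, float]
    statistic: float
    p_value: float
    pairwise: pd.DataFrame           # pair, statistic, p_raw, p_adjusted
    degenerate: bool = False
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"branch": self.branch, "statistic": self.statistic,
                "p_value": self.p_value, "degenerate": self.degenerate,
                "shapiro_p": self.shapiro_p,
                "pairwise": self.pairwise.to_dict(orient="records"),
                "notes": self.notes}


def _sidak(p: np.ndarray, m: int) -> np.ndarray:
    return 1.0 - (1.0 - np.asarray(p, dtype=float)) ** m


def _anova_sidak(series: pd.Series, groups: pd.Series,
                 comparisons) -> tuple[float, float, pd.DataFrame]:
    names = list(dict.fromkeys(groups))
    arrays = {g: series[groups == g].to_numpy(dtype=float) for g in names}
    f, p = stats.f_oneway(*arrays.values())
    # pooled within-group variance (ANOVA mean square error)
    n_total = sum(len(a) for a in arrays.values())
    dfe = n_total - len(arrays)
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / dfe
    rows = []
    for a, b in comparisons:
        xa, xb = arrays[a], arrays[b]
        se = np.sqrt(mse * (1 / len(xa) + 1 / len(xb)))
        t = (xa.mean() - xb.mean()) / se if se > 0 else 0.0
        praw = 2 * stats.t.sf(abs(t), dfe)
        rows.append((f"{a} vs {b}", t, praw))
    pw = pd.DataFrame(rows, columns=["pair", "statistic", "p_raw"])
    pw["p_adjusted"] = _sidak(pw["p_raw"].to_numpy(), len(comparisons))
    return float(f), float(p), pw


def _dunn(series: pd.Series, groups: pd.Series,
          comparisons) -> tuple[float, float, pd.DataFrame]:
    names = list(dict.fromkeys(groups))
    x = series.to_numpy(dtype=float)
    g = groups.to_numpy()
    h, p = stats.kruskal(*[x[g == name] for name in names])
    ranks = stats.rankdata(x)
    n = len(x)
    # tie correction for the rank-variance term
    _, tie_counts = np.unique(x, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    mean_rank = {name: ranks[g == name].mean() for name in names}
    size = {name: int((g == name).sum()) for name in names}
    rows = []
    for a, b in comparisons:
        se = np.sqrt(var_base * (1 / size[a] + 1 / size[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        praw = 2 * stats.norm.sf(abs(z))
        rows.append((f"{a} vs {b}", z, praw))
    pw = pd.DataFrame(rows, columns=["pair", "statistic", "p_raw"])
    pw["p_adjusted"] = _sidak(pw["p_raw"].to_numpy(), len(comparisons))
    return float(h), float(p), pw


def compare_groups_parametric_gate(values, groups, comparisons=None,
                                   alpha: float = 0.05) -> GroupComparisonResult:
    """Shapiro-gated group test over a selected pair list.

    Each group is Shapiro-Wilk tested at ``alpha``; if every group looks
    normal the parametric branch runs (one-way ANOVA, Sidak-adjusted pooled-t
    pairwise comparisons), otherwise the non-parametric branch runs
    (Kruskal-Wallis, Dunn z pairwise with Sidak-style adjustment).  Only the
    requested pairs are compared and the Sidak exponent is their count.
    """
    series = pd.Series(np.asarray(values, dtype=float))
    groups = pd.Series(np.asarray(groups), index=series.index)
    mask = series.notna()
    series, groups = series[mask], groups[mask]
    names = list(dict.fromkeys(groups))
    if len(names) < 2 or any((groups == g).sum() < 2 for g in names):
        raise ValueError("need >=2 groups with >=2 observations each")
    if comparisons is None:
        comparisons = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    comparisons = [c for c in comparisons if c[0] in names and c[1] in names]

    if series.nunique() == 1:
        pw = pd.DataFrame({"pair": [f"{a} vs {b}" for a, b in comparisons],
                           "statistic": 0.0, "p_raw": 1.0, "p_adjusted": 1.0})
        return GroupComparisonResult("degenerate", {g: 1.0 for g in names},
                                     0.0, 1.0, pw, degenerate=True)

    shapiro_p = {}
    for g in names:
        arr = series[groups == g].to_numpy()
        if np.ptp(arr) == 0:
            shapiro_p[g] = 0.0    # constant within group: treat as non-normal
        else:
            shapiro_p[g] = float(stats.shapiro(arr).pvalue)
    if all(p > alpha for p in shapiro_p.values()):
        stat, p, pw = _anova_sidak(series, groups, comparisons)
        branch = "anova_sidak"
    else:
        stat, p, pw = _dunn(series, groups, comparisons)
        branch = "kruskal_dunn"
    return GroupComparisonResult(branch, shapiro_p, stat, p, pw,
                                 notes={"alpha_gate": alpha,
                                        "n_comparisons": len(comparisons)})


@dataclass
class AlphaDiversityResult:
    """Per-sample diversity indices with group summaries and gated tests."""

    per_sample: pd.DataFrame          # shannon, evenness, richness
    group_summary: pd.DataFrame | None
    tests: dict[str, GroupComparisonResult]
    notes: dict = field(default_factory=dict)


def alpha_diversity(table: TaxaCountTable, metadata: pd.DataFrame | None = None,
                    comparisons=DEFAULT_COMPARISONS,
                    sqrt_for_stats: bool = True) -> AlphaDiversityResult:
    """Shannon (nats), Pielou evenness and richness per sample.

    Group tests run on square-root-transformed index values (the convention
    used for these summaries; raw values are reported alongside).  Samples
    with undefined evenness (a single observed taxon) are excluded from the
    evenness summary and test.
    """
    mat = table.counts.to_numpy(dtype=float)
    per = pd.DataFrame({
        "shannon": [shannon(r) for r in mat],
        "evenness": [evenness(r) for r in mat],
        "richness": [richness(r) for r in mat],
    }, index=table.counts.index)
    tests, summary = {}, None
    if metadata is not None:
        diet = metadata.loc[per.index, "diet"]
        summary = per.groupby(diet).agg(["mean", "sem"])
        for col in per.columns:
            vals = np.sqrt(per[col]) if sqrt_for_stats else per[col]
            tests[col] = compare_groups_parametric_gate(
                vals.to_numpy(), diet.to_numpy(), comparisons)
    return AlphaDiversityResult(per, summary, tests,
                                notes={"shannon_base": "e",
                                       "evenness": "pielou",
                                       "sqrt_for_stats": sqrt_for_stats})


# ---------------------------------------------------------------------------
# Firmicutes / Bacteroidetes ratio
# ---------------------------------------------------------------------------

def fb_ratio(phylum_table: TaxaCountTable) -> pd.Series:
    """Per-sample Firmicutes-to-Bacteroidetes relative-abundance ratio.

    Returns +inf where the Bacteroidetes count is zero (flagged for
    exclusion from downstream transforms).
    """
    def _find(name: str) -> str:
        hits = [c for c in phylum_table.taxon_labels
                if name in c.split(";")[0].strip().lower()]
        if not hits:
            raise ValueError(f"phylum label absent: {name}")
        return hits[0]

    firm = phylum_table.counts[_find("firmicutes")].to_numpy(dtype=float)
    bact = phylum_table.counts[_find("bacteroidetes")].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(bact > 0, firm / np.where(bact > 0, bact, 1.0), np.inf)
    return pd.Series(ratio, index=phylum_table.counts.index, name="fb_ratio")


# ---------------------------------------------------------------------------
# differential abundance
# ---------------------------------------------------------------------------

@dataclass
class DifferentialAbundanceResult:
    """Genus-level Kruskal-Wallis with 1% filter and BH-FDR control."""

    table: pd.DataFrame               # mean_abundance, removed, H, p, p_fdr, significant
    posthoc: dict[str, pd.DataFrame]
    alpha: float
    min_mean_abundance: float

    @property
    def significant(self) -> list[str]:
        t = self.table
        return list(t.index[t["significant"].fillna(False)])


def differential_abundance(rel_table: pd.DataFrame, groups,
                           min_mean_abundance: float = 0.01,
                           alpha: float = 0.05,
                           comparisons=DEFAULT_COMPARISONS,
                           posthoc_on_significant: bool = True,
                           ) -> DifferentialAbundanceResult:
    """Per-genus Kruskal-Wallis across diet groups on relative abundances.

    Genera whose grand-mean relative abundance across all samples is below
    ``min_mean_abundance`` are flagged removed and not tested.  BH step-up
    adjustment runs across the retained genera; significance is FDR-P <
    ``alpha``.  Optionally a Dunn post hoc over the selected pairs is run
    for each significant genus.
    """
    sums = rel_table.sum(axis=1).to_numpy()
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("relative-abundance rows must sum to 1")
    groups = pd.Series(np.asarray(groups), index=rel_table.index)
    names = list(dict.fromkeys(groups))

    mean_ab = rel_table.mean(axis=0)
    removed = mean_ab < min_mean_abundance
    retained = list(mean_ab.index[~removed])
    if not retained:
        raise ValueError("no genus survives the abundance filter")

    h_vals, p_vals = [], []
    for genus in retained:
        x = rel_table[genus]
        arrays = [x[groups == g].to_numpy(dtype=float) for g in names]
        if np.ptp(np.concatenate(arrays)) == 0:
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*arrays)
        h_vals.append(float(h))
        p_vals.append(float(p))
    _, p_fdr, _, _ = multipletests(p_vals, method="fdr_bh")

    out = pd.DataFrame({"mean_abundance": mean_ab,
                        "removed": removed})
    out["H"] = pd.Series(h_vals, index=retained)
    out["p"] = pd.Series(p_vals, index=retained)
    out["p_fdr"] = pd.Series(p_fdr, index=retained)
    out["significant"] = out["p_fdr"] < alpha

    posthoc: dict[str, pd.DataFrame] = {}
    if posthoc_on_significant:
        for genus in out.index[out["significant"].fillna(False)]:
            _, _, pw = _dunn(rel_table[genus], groups, comparisons)
            posthoc[genus] = pw
    return DifferentialAbundanceResult(out, posthoc, alpha, min_mean_abundance)
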