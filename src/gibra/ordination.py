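"""Between-sample community structure.

Bray-Curtis dissimilarities on square-root-transformed genus relative
abundances, rank-based ANOSIM with permutation p-values (global and for the
study's five pairwise diet comparisons), non-metric multidimensional scaling
(SMACOF iterations with monotone regression, Kruskal stress-1), and the
Pearson taxa-vector overlay retaining taxa with combined |r| > 0.6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "sqrt_transform",
    "bray_curtis",
    "anosim",
    "pairwise_anosim",
    "AnosimResult",
    "nmds",
    "OrdinationResult",
    "taxa_vectors",
]


def sqrt_transform(rel_table: pd.DataFrame) -> pd.DataFrame:
    """Element-wise square root, applied exactly once.

    The returned frame carries ``attrs["sqrt_transformed"] = True``; passing
    an already-transformed frame raises, so the transform cannot silently be
    applied twice.
    """
    if rel_table.attrs.get("sqrt_transformed"):
        raise ValueError("table is already square-root transformed")
    if (rel_table.to_numpy() < 0).any():
        raise ValueError("negative entries cannot be square-root transformed")
    out = np.sqrt(rel_table)
    out.attrs["sqrt_transformed"] = True
    return out


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity BC(x,y) = sum|x-y| / sum(x+y)."""
    if len(table) < 2:
        raise ValueError("need at least two samples")
    mat = table.to_numpy(dtype=float)
    if (mat.sum(axis=1) == 0).any():
        raise ValueError("all-zero sample row: Bray-Curtis undefined")
    cond = pdist(mat, metric="braycurtis")
    return DistanceMatrix(squareform(cond), ids=[str(i) for i in table.index])


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

@dataclass
class AnosimResult:
    """Global and pairwise analysis-of-similarities statistics."""

    grouping: str
    r: float
    p_value: float
    permutations: int
    n: int
    pairwise: pd.DataFrame | None = None   # pair, n, R, p
    notes: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        """Comparison / n / Global R / p-Value rows (global row first)."""
        rows = [("global", self.n, self.r, self.p_value)]
        if self.pairwise is not None:
            rows += [tuple(r) for r in
                     self.pairwise[["pair", "n", "R", "p"]].itertuples(index=False)]
        return pd.DataFrame(rows, columns=["Comparison", "n", "Global R", "p-Value"])


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = ranks.size
    return float((ranks[~within].mean() - ranks[within].mean()) / (m / 2.0))


def anosim(dm: DistanceMatrix, grouping, permutations: int = 999,
           seed: int = 0) -> AnosimResult:
    """Rank-based ANOSIM R with a label-permutation test.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    midranks over all M = n(n-1)/2 pairwise dissimilarities.  The p-value
    uses the (1 + #{permuted R >= observed}) / (1 + permutations) estimator,
    so the smallest attainable p at 999 permutations is 0.001.
    """
    labels = np.asarray(list(grouping))
    n = dm.shape[0]
    if len(labels) != n:
        raise ValueError("grouping length must match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("need >=2 groups with >=2 members each")
    if permutations < 99:
        raise ValueError("use at least 99 permutations")

    iu, ju = np.triu_indices(n, k=1)
    ranks = stats.rankdata(dm.data[iu, ju])
    within = labels[iu] == labels[ju]
    observed = _anosim_r(ranks, within)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        lp = labels[rng.permutation(n)]
        if _anosim_r(ranks, lp[iu] == lp[ju]) >= observed:
            hits += 1
    p = (1 + hits) / (1 + permutations)
    return AnosimResult("grouping", observed, p, permutations, n)


def pairwise_anosim(dm: DistanceMatrix, metadata: pd.DataFrame,
                    pairs, group_col: str = "diet", permutations: int = 999,
                    seed: int = 0) -> AnosimResult:
    """Global ANOSIM plus one sub-matrix ANOSIM per requested group pair.

    Pairwise p-values are reported unadjusted.
    """
    groups = metadata.loc[list(dm.ids), group_col]
    global_res = anosim(dm, groups.to_numpy(), permutations, seed)
    rows = []
    ss = np.random.SeedSequence(seed).spawn(len(pairs))
    for (a, b), sub_ss in zip(pairs, ss):
        ids = [i for i in dm.ids if groups[i] in (a, b)]
        sub = dm.filter(ids)
        res = anosim(sub, groups[ids].to_numpy(), permutations,
                     int(sub_ss.generate_state(1)[0] % (2**31)))
        rows.append((f"{a} vs {b}", len(ids), res.r, res.p_value))
    global_res.pairwise = pd.DataFrame(rows, columns=["pair", "n", "R", "p"])
    return global_res


# ---------------------------------------------------------------------------
# non-metric MDS
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """2-D nMDS embedding with Kruskal stress-1 and its iteration trace."""

    coordinates: pd.DataFrame         # sample x (axis1, axis2)
    stress: float
    stress_trace: list[float]
    restarts_used: int
    converged: bool
    taxa_vectors: pd.DataFrame | None = None


def _kruskal_stress(dist_cond: np.ndarray, disparities: np.ndarray) -> float:
    denom = (dist_cond ** 2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dist_cond - disparities) ** 2).sum() / denom))


def _nmds_single(d: np.ndarray, x0: np.ndarray, max_iter: int,
                 tol: float) -> tuple[np.ndarray, float, list[float], bool]:
    """One SMACOF run: isotonic disparities then Guttman transform.

    An update is accepted only while stress-1 does not increase, so the
    recorded trace is non-increasing by construction.
    """
    n = x0.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    order = np.argsort(d, kind="stable")
    iso = IsotonicRegression(increasing=True)
    x = x0.copy()
    e = pdist(x)
    dhat = np.empty_like(e)
    dhat[order] = iso.fit_transform(np.arange(d.size), e[order])
    trace = [_kruskal_stress(e, dhat)]
    converged = False
    for _ in range(max_iter):
        # Guttman transform with current disparities
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(e > 0, dhat / e, 0.0)
        b = np.zeros((n, n))
        b[iu, ju] = -ratio
        b[ju, iu] = -ratio
        b[np.diag_indices(n)] = -b.sum(axis=1)
        x_new = b @ x / n
        e_new = pdist(x_new)
        dhat_new = np.empty_like(e_new)
        dhat_new[order] = iso.fit_transform(np.arange(d.size), e_new[order])
        stress_new = _kruskal_stress(e_new, dhat_new)
        if stress_new > trace[-1] + 1e-12:
            converged = True       # no downhill step left
            break
        x, e, dhat = x_new, e_new, dhat_new
        improvement = trace[-1] - stress_new
        trace.append(stress_new)
        if improvement < tol * max(trace[-1], 1e-12):
            converged = True
            break
    return x, trace[-1], trace, converged


def _classical_mds(dmat: np.ndarray, dims: int) -> np.ndarray:
    n = dmat.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dmat ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:dims]
    comp = vecs[:, idx] * np.sqrt(np.clip(vals[idx], 0, None))
    return comp


def nmds(dm: DistanceMatrix, dims: int = 2, restarts: int = 20,
         max_iter: int = 300, tol: float = 1e-6, seed: int = 0) -> OrdinationResult:
    """Best-of-restarts non-metric MDS minimising Kruskal stress-1.

    Runs one metric-scaling-initialised SMACOF run plus ``restarts``
    random-start runs and keeps the lowest-stress solution.
    """
    d = squareform(dm.data, checks=False)
    n = dm.shape[0]
    rng = np.random.default_rng(seed)
    inits = [_classical_mds(dm.data, dims)]
    scale = max(d.max(), 1e-12)
    inits += [rng.normal(0, scale, size=(n, dims)) for _ in range(restarts)]

    best = None
    for x0 in inits:
        x, stress, trace, conv = _nmds_single(d, x0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (x, stress, trace, conv)
    x, stress, trace, conv = best
    coords = pd.DataFrame(x, index=list(dm.ids),
                          columns=[f"axis{k+1}" for k in range(dims)])
    return OrdinationResult(coords, stress, trace, restarts, conv)


def taxa_vectors(rel_table: pd.DataFrame, coords: pd.DataFrame,
                 threshold: float = 0.6) -> pd.DataFrame:
    """Pearson correlation of each taxon with the ordination axes.

    Combined r = sqrt(r1^2 + r2^2); taxa exceeding ``threshold`` are
    retained.  Zero-variance taxa are skipped.
    """
    common = [s for s in coords.index if s in rel_table.index]
    tab = rel_table.loc[common]
    axes = coords.loc[common]
    rows = []
    for taxon in tab.columns:
        x = tab[taxon].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            continue
        rs = [float(stats.pearsonr(x, axes[a]).statistic) for a in axes.columns]
        combined = float(np.sqrt(np.sum(np.square(rs))))
        if combined > threshold:
            rows.append((taxon, *rs, combined))
    cols = ["taxon"] + [f"r_{a}" for a in axes.columns] + ["r_combined"]
    return pd.DataFrame(rows, columns=cols).sort_values(
        "r_combined", ascending=False, ignore_index=True)
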