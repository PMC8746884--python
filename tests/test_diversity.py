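"""Rarefaction, alpha diversity, gated tests and differential abundance."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from gibra import TaxaCountTable
from gibra.diversity import (compare_groups_parametric_gate,
                             differential_abundance, evenness, fb_ratio,
                             rarefy, richness, shannon)

from conftest import null_config


def _table(mat, samples=None, taxa=None, level="genus"):
    mat = np.asarray(mat)
    samples = samples or [f"s{i}" for i in range(mat.shape[0])]
    taxa = taxa or [f"P{j};F{j};g{j}" for j in range(mat.shape[1])]
    return TaxaCountTable(pd.DataFrame(mat, index=samples, columns=taxa),
                          level=level)


# -- rarefaction ------------------------------------------------------------

def test_rarefy_at_exact_depth_returns_sample_unchanged():
    t = _table([[60, 40], [30, 80]])
    out = rarefy(t, 100, seed=0)
    assert (out.counts.loc["s0"] == [60, 40]).all()
    assert out.sample_sums().eq(100).all()


def test_rarefy_matches_hypergeometric_expectation():
    """Two-taxon sample (9000, 1000) at depth 100: per-taxon mean over 1000
    seeded draws within 3 SE of the hypergeometric expectation (90, 10)."""
    t = _table([[9000, 1000]])
    draws = np.array([rarefy(t, 100, seed=s).counts.iloc[0].to_numpy()
                      for s in range(1000)])
    n, k, depth = 10_000, 9000, 100
    expect = depth * k / n
    var = depth * (k / n) * (1 - k / n) * (n - depth) / (n - 1)
    se = math.sqrt(var / 1000)
    assert abs(draws[:, 0].mean() - expect) < 3 * se


def test_rarefy_drops_shallow_samples_with_warning():
    t = _table([[60, 40], [10, 20]])
    with pytest.warns(UserWarning, match="below depth"):
        out = rarefy(t, 50, seed=0)
    assert out.sample_ids == ["s0"]


def test_rarefy_rejects_bad_depth():
    t = _table([[10, 10]])
    with pytest.raises(ValueError):
        rarefy(t, 0, seed=0)
    with pytest.raises(ValueError, match="no sample"):
        rarefy(t, 1000, seed=0)


# -- alpha diversity --------------------------------------------------------

@pytest.mark.parametrize("row,expected", [
    ([100, 0, 0], 0.0),
    ([25, 25, 25, 25], math.log(4)),
])
def test_shannon_known_values(row, expected):
    assert shannon(np.array(row)) == pytest.approx(expected, abs=1e-12)


def test_shannon_evenness_match_brute_force_oracle(rng):
    """1000 random count rows agree with direct-summation oracles to 1e-12."""
    for _ in range(1000):
        row = rng.integers(0, 50, size=10)
        if row.sum() == 0:
            row[0] = 1
        p = row[row > 0] / row.sum()
        h_oracle = -sum(pi * math.log(pi) for pi in p)
        assert shannon(row) == pytest.approx(h_oracle, abs=1e-12)
        s = int((row > 0).sum())
        if s > 1:
            assert evenness(row) == pytest.approx(h_oracle / math.log(s),
                                                  abs=1e-12)


def test_shannon_agrees_with_skbio():
    from skbio.diversity.alpha import shannon as skb_shannon
    row = np.array([5, 0, 12, 3, 30])
    assert shannon(row) == pytest.approx(skb_shannon(row, base=math.e),
                                         abs=1e-12)


def test_evenness_uniform_is_one():
    for s in (2, 5, 9):
        assert evenness(np.full(s, 7)) == pytest.approx(1.0, abs=1e-12)


def test_evenness_two_taxon_99_1():
    h = -(0.99 * math.log(0.99) + 0.01 * math.log(0.01))
    assert evenness(np.array([99, 1])) == pytest.approx(h / math.log(2),
                                                        abs=1e-12)


def test_evenness_single_taxon_is_undefined():
    assert math.isnan(evenness(np.array([10, 0, 0])))


def test_shannon_rejects_empty_row():
    with pytest.raises(ValueError):
        shannon(np.zeros(3))


def test_shannon_bounded_by_log_richness(dataset):
    for row in dataset.genus_counts.counts.to_numpy():
        h = shannon(row)
        assert 0 <= h <= math.log(richness(row)) + 1e-12


# -- F/B ratio --------------------------------------------------------------

def test_fb_ratio_hand_values():
    t = _table([[600, 300, 100], [100, 100, 0]],
               taxa=["Firmicutes", "Bacteroidetes", "Actinobacteria"],
               level="phylum")
    r = fb_ratio(t)
    assert r["s0"] == pytest.approx(2.0)
    assert r["s1"] == pytest.approx(1.0)


def test_fb_ratio_zero_bacteroidetes_is_infinite():
    t = _table([[10, 0]], taxa=["Firmicutes", "Bacteroidetes"], level="phylum")
    assert np.isinf(fb_ratio(t)["s0"])


def test_fb_ratio_requires_both_phyla():
    t = _table([[10, 5]], taxa=["Firmicutes", "Actinobacteria"], level="phylum")
    with pytest.raises(ValueError, match="bacteroidetes"):
        fb_ratio(t)


# -- gated group comparison -------------------------------------------------

def test_single_comparison_sidak_equals_raw(rng):
    values = np.concatenate([rng.normal(0, 1, 10), rng.normal(0, 1, 10)])
    groups = ["a"] * 10 + ["b"] * 10
    res = compare_groups_parametric_gate(values, groups, [("a", "b")])
    assert res.pairwise["p_adjusted"].iloc[0] == pytest.approx(
        res.pairwise["p_raw"].iloc[0], rel=1e-12)


def test_null_rejection_rate_is_calibrated(rng):
    """Identical group distributions: the global test rejects at ~alpha over
    500 simulated datasets (binomial 99% bounds)."""
    rejections = 0
    n_rep = 500
    for _ in range(n_rep):
        values = rng.normal(0, 1, 40)
        groups = np.repeat(list("abcd"), 10)
        res = compare_groups_parametric_gate(values, groups)
        rejections += res.p_value < 0.05
    rate = rejections / n_rep
    half_width = 2.576 * math.sqrt(0.05 * 0.95 / n_rep)
    assert abs(rate - 0.05) < half_width + 1e-9


def test_three_sd_shift_detected(rng):
    hits = 0
    n_rep = 200
    for _ in range(n_rep):
        values = np.concatenate([rng.normal(0, 1, 10), rng.normal(3, 1, 10)])
        groups = ["a"] * 10 + ["b"] * 10
        res = compare_groups_parametric_gate(values, groups, [("a", "b")])
        hits += res.pairwise["p_adjusted"].iloc[0] < 0.05
    assert hits >= 0.95 * n_rep


def test_gate_selects_nonparametric_branch_for_skewed_data(rng):
    values = np.concatenate([rng.lognormal(0, 2.5, 25) for _ in range(2)])
    groups = ["a"] * 25 + ["b"] * 25
    res = compare_groups_parametric_gate(values, groups)
    assert res.branch == "kruskal_dunn"


def test_degenerate_input_flagged():
    res = compare_groups_parametric_gate([1.0] * 8, ["a"] * 4 + ["b"] * 4)
    assert res.degenerate


# -- differential abundance -------------------------------------------------

def test_low_abundance_genus_filtered(rel_table, dataset):
    res = differential_abundance(rel_table, dataset.metadata["diet"])
    low = res.table[res.table["mean_abundance"] < 0.01]
    assert low["removed"].all()
    assert low["p"].isna().all()


def test_bh_adjustment_never_below_raw(rel_table, dataset):
    res = differential_abundance(rel_table, dataset.metadata["diet"])
    tested = res.table.dropna(subset=["p"])
    assert (tested["p_fdr"] >= tested["p"] - 1e-12).all()


def test_bh_step_up_oracle():
    """BH on (0.01, 0.02, 0.03, 0.04), m=4 -> all adjusted to 0.04."""
    _, adj, _, _ = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")
    assert np.allclose(adj, 0.04)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=2,
                max_size=20))
def test_bh_matches_step_up_brute_force(pvals):
    """BH equals the explicit step-up construction on arbitrary p-vectors."""
    m = len(pvals)
    order = np.argsort(pvals)
    sorted_p = np.asarray(pvals)[order]
    stepped = np.minimum.accumulate((sorted_p * m / np.arange(1, m + 1))[::-1])[::-1]
    oracle = np.empty(m)
    oracle[order] = np.minimum(stepped, 1.0)
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    assert np.allclose(adj, oracle, atol=1e-12)


def test_null_groups_yield_few_discoveries():
    from gibra import simulate
    from gibra.diversity import rarefy as _rarefy
    fracs = []
    for seed in range(8):
        ds = simulate(null_config(), seed=seed)
        rel = _rarefy(ds.genus_counts, 45_000, seed=seed).relative_abundance()
        res = differential_abundance(rel, ds.metadata["diet"])
        tested = res.table.dropna(subset=["p"])
        fracs.append(len(res.significant) / len(tested))
    assert np.mean(fracs) <= 0.05


def test_all_filtered_raises():
    rel = pd.DataFrame(np.full((6, 4), 0.25),
                       index=[f"s{i}" for i in range(6)],
                       columns=list("wxyz"))
    with pytest.raises(ValueError, match="filter"):
        differential_abundance(rel, ["a"] * 3 + ["b"] * 3,
                               min_mean_abundance=0.5)
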