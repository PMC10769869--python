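import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from chromarch import (
    CircularGenome,
    SegmentSet,
    chip_enrichment,
    classify_gene_groups,
    decile_sets,
    distance_to_nearest_origin,
    expression_domain_test,
    fisher_partition_test,
    lfc_table,
    mfa_normalize,
    rpksp,
    window_spikein_normalize,
)


# -------------------------------------------------------- classify_gene_groups
@pytest.mark.parametrize(
    "product,expected",
    [
        ("hypothetical protein", {"hypothetical"}),
        ("ABC transporter permease", {"membrane"}),
        ("DNA polymerase II", {"nucleic_acid"}),
        ("16S rRNA methylase", {"nucleic_acid"}),
        ("flagellar assembly protein", {"membrane"}),
        ("unknown widget", set()),
    ],
)
def test_keyword_classification(product, expected):
    genes = pd.DataFrame({"id": ["g"], "product": [product]})
    out = classify_gene_groups(genes)
    got = {
        tag
        for tag in ("hypothetical", "membrane", "nucleic_acid", "ribosomal")
        if out.loc[0, tag]
    }
    assert got == expected


def test_id_list_groups():
    genes = pd.DataFrame({"id": ["r1", "x", "go1"], "product": [""] * 3})
    out = classify_gene_groups(genes, ribosomal_ids=["r1"], go_0090304_ids=["go1"])
    assert out.loc[0, "ribosomal"] and not out.loc[1, "ribosomal"]
    assert out.loc[2, "nucleic_acid"]


def test_tags_not_mutually_exclusive():
    genes = pd.DataFrame({"id": ["g"], "product": ["hypothetical DNA transporter"]})
    out = classify_gene_groups(genes)
    assert bool(out.loc[0, "hypothetical"] and out.loc[0, "membrane"] and out.loc[0, "nucleic_acid"])


# ------------------------------------------------------------------------ rpksp
def test_rpksp_formula():
    # all spike-in rpk = 2, gene rpk = 10 -> rpksp = 5
    out = rpksp([10], [1000], [2, 4], [1000, 2000])
    assert out.spike_in_parameter == 2.0
    assert out.table.loc[0, "rpksp"] == 5.0


def test_rpksp_depth_invariance():
    a = rpksp([10, 30], [1000, 1500], [2, 4], [1000, 2000])
    b = rpksp([20, 60], [1000, 1500], [4, 8], [1000, 2000])
    assert np.allclose(a.table["rpksp"], b.table["rpksp"])


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.floats(0.1, 100.0))
def test_rpksp_invariant_under_any_joint_depth_factor(factor):
    counts = np.array([5.0, 17.0, 40.0])
    lens = np.array([800.0, 1200.0, 3000.0])
    sp_counts = np.array([3.0, 9.0])
    sp_lens = np.array([1000.0, 1500.0])
    a = rpksp(counts, lens, sp_counts, sp_lens)
    b = rpksp(counts * factor, lens, sp_counts * factor, sp_lens)
    assert np.allclose(a.table["rpksp"], b.table["rpksp"])


def test_rpksp_mixed_toy_table_hand_computed():
    out = rpksp([6, 12], [2000, 3000], [10, 30], [1000, 3000])
    # spike-in rpks: 10, 10 -> parameter 10; gene rpks: 3, 4
    assert out.spike_in_parameter == 10.0
    assert list(out.table["rpksp"]) == [0.3, 0.4]


def test_rpksp_zero_spikein_rejected():
    with pytest.raises(ValueError):
        rpksp([1], [1000], [], [])
    with pytest.raises(ValueError):
        rpksp([1], [1000], [0], [1000])


def test_window_level_normalization():
    out = window_spikein_normalize([10, 20], [4, 6])
    assert np.allclose(out, [2.0, 4.0])


# -------------------------------------------------------------------- lfc_table
def test_lfc_doubling_and_identity():
    a = rpksp([20, 40], [1000, 1000], [2], [1000])
    b = rpksp([10, 20], [1000, 1000], [2], [1000])
    out = lfc_table(a, b)
    assert np.allclose(out["lfc"], 1.0)
    assert np.allclose(lfc_table(a, a)["lfc"], 0.0)


def test_lfc_zero_masked_and_gene_set_mismatch():
    a = rpksp([0, 10], [1000, 1000], [2], [1000], gene_ids=["g1", "g2"])
    b = rpksp([5, 10], [1000, 1000], [2], [1000], gene_ids=["g1", "g2"])
    out = lfc_table(a, b)
    assert np.isnan(out["lfc"][0]) and np.isfinite(out["lfc"][1])
    c = rpksp([5], [1000], [2], [1000], gene_ids=["other"])
    with pytest.raises(ValueError):
        lfc_table(a, c)


# -------------------------------------------------------- expression_domain_test
def _expr_for(values, ids):
    return rpksp(values, [1000] * len(values), [1], [1000], gene_ids=ids)


def test_wilcoxon_exact_small_sample():
    g = CircularGenome(100_000, 1000)
    segs = SegmentSet([(0, 40)], "HEID", g)
    genes = pd.DataFrame(
        {
            "id": [f"g{k}" for k in range(6)],
            "start": [1000, 5000, 10_000, 60_000, 70_000, 80_000],
            "end": [2000, 6000, 11_000, 61_000, 71_000, 81_000],
        }
    )
    expr = _expr_for([1, 2, 3, 10, 20, 30], list(genes["id"]))
    out = expression_domain_test(expr, genes, segs)
    assert np.isclose(out["p"], 0.1)  # exact two-sided rank-sum, 20 orderings
    assert out["median_inside"] == 2.0 and out["median_outside"] == 20.0


def test_wilcoxon_identical_sets_p_one():
    g = CircularGenome(100_000, 1000)
    segs = SegmentSet([(0, 40)], "HEID", g)
    genes = pd.DataFrame(
        {
            "id": [f"g{k}" for k in range(4)],
            "start": [1000, 5000, 60_000, 70_000],
            "end": [2000, 6000, 61_000, 71_000],
        }
    )
    expr = _expr_for([7, 7, 7, 7], list(genes["id"]))
    out = expression_domain_test(expr, genes, segs)
    assert out["p"] == 1.0


def test_wilcoxon_requires_both_classes():
    g = CircularGenome(100_000, 1000)
    segs = SegmentSet([(0, 40)], "HEID", g)
    genes = pd.DataFrame(
        {"id": ["a", "b"], "start": [1000, 2000], "end": [1500, 2500]}
    )
    with pytest.raises(ValueError):
        expression_domain_test(_expr_for([1, 2], ["a", "b"]), genes, segs)


# --------------------------------------------------------- fisher_partition_test
def test_fisher_no_association_p_one():
    out = fisher_partition_test(5, 5, 5, 5)
    assert out["p"] == 1.0


def _fisher_enumeration_oracle(a, b, c, d):
    """Two-sided exact p by explicit hypergeometric enumeration."""
    n1, n2, m1 = a + b, c + d, a + c
    N = n1 + n2
    lo, hi = max(0, m1 - n2), min(m1, n1)
    pmf = {k: stats.hypergeom.pmf(k, N, n1, m1) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9))


def test_fisher_matches_enumeration_on_small_tables(rng):
    for _ in range(25):
        a, b, c, d = rng.integers(0, 12, size=4)
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            continue
        out = fisher_partition_test(int(a), int(b), int(c), int(d))
        assert np.isclose(out["p"], _fisher_enumeration_oracle(a, b, c, d), atol=1e-9)


def test_fisher_zero_margin_rejected():
    with pytest.raises(ValueError):
        fisher_partition_test(0, 0, 3, 4)


# ------------------------------------------------------------------ decile_sets
def test_deciles_of_100_distinct_values():
    expr = _expr_for(list(range(1, 101)), [f"g{k}" for k in range(100)])
    out = decile_sets(expr)
    assert len(out["top"]) == 10 and len(out["bottom"]) == 10
    assert out["top"].isdisjoint(out["bottom"])


def test_deciles_all_equal_flagged():
    expr = _expr_for([5] * 20, [f"g{k}" for k in range(20)])
    out = decile_sets(expr)
    assert len(out["top"]) == 20 and len(out["bottom"]) == 20
    assert "degenerate_all_equal" in out["flags"]


def test_deciles_include_ties_at_cut():
    vals = [1, 2, 3, 4, 5, 6, 7, 8, 9, 9, 9, 9]
    expr = _expr_for(vals, [f"g{k}" for k in range(12)])
    out = decile_sets(expr)
    # all four genes tied at the top value are included
    assert len(out["top"]) == 4


# ------------------------------------------------- distance_to_nearest_origin
def test_origin_distance_midpoints():
    g = CircularGenome(1000, 100, origins_bp=(0, 500))
    genes = pd.DataFrame(
        {"id": ["far", "at"], "start": [700, 495], "end": [800, 505]}
    )
    expr = _expr_for([1.0, 2.0], ["far", "at"])
    out = distance_to_nearest_origin(genes, expr, g)
    assert out["distance_bp"][0] == 250.0
    assert out["distance_bp"][1] == 0.0


def test_origin_distance_correlation_matches_direct():
    g = CircularGenome(100_000, 1000, origins_bp=(0,))
    starts = np.array([5000, 20_000, 42_000, 60_000, 90_000])
    genes = pd.DataFrame({"id": [f"g{k}" for k in range(5)], "start": starts, "end": starts + 1000})
    vals = [10.0, 6.0, 2.0, 3.0, 9.0]
    expr = _expr_for(vals, list(genes["id"]))
    out = distance_to_nearest_origin(genes, expr, g)
    r_ref, p_ref = stats.pearsonr(out["distance_bp"], vals)
    assert np.isclose(out["r"], r_ref) and np.isclose(out["p"], p_ref)


def test_origin_distance_requires_origin():
    g = CircularGenome(1000, 100)
    genes = pd.DataFrame({"id": ["a"], "start": [0], "end": [100]})
    with pytest.raises(ValueError):
        distance_to_nearest_origin(genes, _expr_for([1.0], ["a"]), g)


# ---------------------------------------------------------------- mfa_normalize
def test_mfa_counts_linear_in_gc_become_constant(rng):
    gc = rng.uniform(0.3, 0.7, size=200)
    counts = 50 + 80 * gc
    out = mfa_normalize(counts, gc)
    assert np.allclose(out["normalized"], counts.mean())


def test_mfa_zero_slope_is_identity(rng):
    gc = np.array([0.4, 0.5, 0.6] * 10)
    counts = np.tile([10.0, 10.0, 10.0], 10)
    out = mfa_normalize(counts, gc)
    assert np.allclose(out["normalized"], counts)


def test_mfa_matches_ols_oracle_and_preserves_mean(rng):
    gc = rng.uniform(0.2, 0.8, size=300)
    counts = rng.poisson(100 * (1 + 0.8 * (gc - gc.mean()))).astype(float)
    out = mfa_normalize(counts, gc)
    slope, intercept = np.polyfit(gc, counts, 1)
    oracle = counts - ((intercept + slope * gc) - counts.mean())
    assert np.allclose(out["normalized"], oracle)
    assert np.isclose(out["normalized"].mean(), counts.mean())
    post_slope = np.polyfit(gc, out["normalized"], 1)[0]
    assert abs(post_slope) < 1e-9


def test_mfa_constant_gc_flagged(rng):
    counts = rng.poisson(100, size=50).astype(float)
    out = mfa_normalize(counts, np.full(50, 0.5))
    assert "constant_gc" in out["flags"]
    assert np.allclose(out["normalized"], counts)


# -------------------------------------------------------------- chip_enrichment
def test_chip_proportional_to_input_is_flat(rng):
    inp = rng.poisson(100, size=80).astype(float) + 1
    chip = 3.0 * inp
    out = chip_enrichment([chip], [inp])
    assert np.allclose(out, 1.0)


def test_chip_replicates_averaged_and_zero_input_masked():
    chip1 = np.array([10.0, 10.0, 0.0])
    inp1 = np.array([10.0, 10.0, 0.0])
    chip2 = np.array([30.0, 10.0, 0.0])
    inp2 = np.array([10.0, 30.0, 0.0])
    out = chip_enrichment([chip1, chip2], [inp1, inp2])
    # replicate 1: totals 20/20 -> enrichment 1, 1; replicate 2: chip frac .75,.25 input .25,.75
    assert np.allclose(out[:2], [(1 + 3.0) / 2, (1 + 1 / 3.0) / 2])
    assert np.isnan(out[2])


def test_chip_single_replicate_hand_computed():
    out = chip_enrichment([[8.0, 2.0]], [[5.0, 5.0]])
    assert np.allclose(out, [1.6, 0.4])
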