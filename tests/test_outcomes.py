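"""Outcome classification, GCR correction, HC-II imputation, contingency tests."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from birkit.errors import InputError
from birkit.outcomes import (
    GcrEstimate,
    PhenotypeCounts,
    RepairClass,
    classify_colony,
    compare_distributions,
    decompose_outcomes,
    estimate_gcr_fraction,
)


@pytest.mark.parametrize(
    ("ade", "leu", "expected"),
    [
        ("plus", "minus", RepairClass.ADE_PLUS_LEU_MINUS),
        ("plus", "plus", RepairClass.GC),
        ("minus_red", "minus", RepairClass.CL),
        ("minus_white", "minus", RepairClass.HC_I),
        ("minus_red", "plus", RepairClass.OTHER),
        ("minus_white", "plus", RepairClass.OTHER),
    ],
)
def test_classify_colony_marker_logic(ade, leu, expected):
    assert classify_colony(ade, leu) is expected


def test_classify_colony_rejects_unknown_tokens():
    with pytest.raises(InputError, match="ade"):
        classify_colony("bright", "minus")
    with pytest.raises(InputError, match="leu"):
        classify_colony("plus", "auxotroph")


@pytest.mark.parametrize(
    ("k", "n", "fraction", "percent"),
    [(10, 23, 10 / 23, 43), (1, 30, 1 / 30, 3), (0, 25, 0.0, 0)],
)
def test_gcr_fraction_matches_karyotyping_counts(k, n, fraction, percent):
    est = estimate_gcr_fraction(k, n)
    assert est.fraction == pytest.approx(fraction, abs=1e-12)
    assert est.percent == percent
    assert 0.0 <= est.ci_low <= est.fraction <= est.ci_high <= 1.0
    if k == 0:
        assert est.ci_low == 0.0


def test_gcr_interval_is_exact_binomial():
    # Clopper-Pearson endpoints satisfy the defining tail equations.
    est = estimate_gcr_fraction(10, 23)
    assert stats.binom.sf(9, 23, est.ci_low) == pytest.approx(0.025, abs=1e-9)
    assert stats.binom.cdf(10, 23, est.ci_high) == pytest.approx(0.025, abs=1e-9)


def test_gcr_rejects_bad_counts():
    with pytest.raises(InputError):
        estimate_gcr_fraction(5, 0)
    with pytest.raises(InputError):
        estimate_gcr_fraction(10, 5)


def test_decompose_hand_worked_example():
    counts = PhenotypeCounts(100, 5, 20, 10, 0)
    dec = decompose_outcomes(counts, 0.30)
    assert dec.counts["gcr"] == pytest.approx(30.0)
    assert dec.counts["hc_ii"] == 10.0
    assert dec.counts["bir"] == pytest.approx(60.0)
    assert dec.denominator == 135
    assert dec.frequencies["bir"] == pytest.approx(60 / 135)
    assert dec.flags == ()


def test_decompose_no_corrections_passes_pool_through():
    counts = PhenotypeCounts(40, 3, 7, 0, 0)
    dec = decompose_outcomes(counts, 0.0)
    assert dec.counts["bir"] == 40.0 and dec.counts["gcr"] == 0.0


def test_decompose_floors_negative_bir_and_flags():
    counts = PhenotypeCounts(10, 0, 0, 20, 0)
    dec = decompose_outcomes(counts, 0.5)
    assert dec.counts["bir"] == 0.0
    assert any(f.startswith("bir_floored") for f in dec.flags)
    # conservation including the recorded deficit
    deficit = float(dec.flags[0].split("=")[1])
    assert dec.counts["gcr"] + dec.counts["hc_ii"] - deficit == pytest.approx(10.0)


@given(
    pool=st.integers(0, 500),
    gc=st.integers(0, 200),
    cl=st.integers(0, 200),
    hc1=st.integers(0, 200),
    other=st.integers(0, 50),
    frac=st.floats(0, 1),
)
def test_decompose_conserves_counts_and_normalizes(pool, gc, cl, hc1, other, frac):
    counts = PhenotypeCounts(pool, gc, cl, hc1, other)
    if counts.total == 0:
        return
    dec = decompose_outcomes(counts, frac)
    if not dec.flags:
        assert dec.counts["gcr"] + dec.counts["hc_ii"] + dec.counts["bir"] == pytest.approx(
            pool, abs=1e-9
        )
        assert sum(dec.frequencies.values()) == pytest.approx(1.0, abs=1e-9)
    assert all(0.0 <= f <= 1.0 + 1e-12 for f in dec.frequencies.values())


@given(
    pool=st.integers(1, 300),
    gc=st.integers(0, 100),
    cl=st.integers(0, 100),
    hc1=st.integers(0, 100),
    scale=st.integers(2, 7),
)
def test_decompose_is_scale_equivariant(pool, gc, cl, hc1, scale):
    frac = 0.25
    a = decompose_outcomes(PhenotypeCounts(pool, gc, cl, hc1, 0), frac)
    b = decompose_outcomes(
        PhenotypeCounts(pool * scale, gc * scale, cl * scale, hc1 * scale, 0), frac
    )
    for cls in a.counts:
        assert b.counts[cls] == pytest.approx(scale * a.counts[cls], rel=1e-12)
        assert b.frequencies[cls] == pytest.approx(a.frequencies[cls], rel=1e-12)


def test_identical_proportions_give_zero_chi_square():
    a = PhenotypeCounts(50, 10, 20, 15, 5)
    b = PhenotypeCounts(100, 20, 40, 30, 10)
    res = compare_distributions(a, b)
    assert res.method == "chi_square_homogeneity"
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.pvalue == pytest.approx(1.0)


def fisher_two_sided_oracle(table):
    """Enumerate all 2x2 tables with the observed margins under the
    hypergeometric null and sum the probabilities <= the observed one."""
    (a, b), (c, d) = table
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = stats.hypergeom(n, col1, row1)
    p_obs = rv.pmf(a)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = rv.pmf(k)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


def test_fisher_matches_hypergeometric_enumeration():
    table = [[10, 13], [1, 29]]
    res = compare_distributions(*table)
    assert res.method == "fisher_exact"
    assert res.pvalue == pytest.approx(fisher_two_sided_oracle(table), abs=1e-10)


def test_chi_square_invariant_to_class_permutation():
    a = np.array([50, 10, 20, 15, 5])
    b = np.array([30, 25, 10, 40, 2])
    base = compare_distributions(a, b).statistic
    perm = np.array([3, 0, 4, 1, 2])
    assert compare_distributions(a[perm], b[perm]).statistic == pytest.approx(base)


def test_compare_rejects_degenerate_tables():
    with pytest.raises(InputError):
        compare_distributions([0, 0, 0], [0, 0, 0])
    with pytest.raises(InputError):
        compare_distributions(PhenotypeCounts(1, 0, 0, 0, 0), PhenotypeCounts(2, 0, 0, 0, 0))


def test_phenotype_counts_validation_and_total():
    with pytest.raises(InputError):
        PhenotypeCounts(-1, 0, 0, 0, 0)
    c = PhenotypeCounts(1, 2, 3, 4, 5)
    assert c.total == 15


def test_from_table_aggregates_by_phenotype():
    import pandas as pd

    df = pd.DataFrame(
        {
            "strain": ["s"] * 5,
            "ade_phenotype": ["plus", "plus", "minus_red", "minus_white", "plus"],
            "leu_phenotype": ["minus", "plus", "minus", "minus", "minus"],
            "count": [10, 2, 3, 4, 5],
        }
    )
    c = PhenotypeCounts.from_table(df, label="s")
    assert (c.n_ade_plus_leu_minus, c.n_ade_plus_leu_plus) == (15, 2)
    assert (c.n_ade_red_leu_minus, c.n_ade_white_leu_minus) == (3, 4)


def test_gcr_estimate_dataclass_is_consistent():
    est = GcrEstimate(n_rearranged=1, n_tested=30, fraction=1 / 30, ci_low=0.0, ci_high=0.2)
    assert math.isclose(est.fraction, est.n_rearranged / est.n_tested)
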