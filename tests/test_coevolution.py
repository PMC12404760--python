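"""MI estimation, the permutation null, BH correction and summaries."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import coevmi as cv
from coevmi.coevolution import (
    InsufficientDataError,
    UndefinedEntropyError,
    _rank_key,
    mutual_information,
)


# -- entropy ---------------------------------------------------------------

@pytest.mark.parametrize(
    "column, expected",
    [
        ("AAAA", 0.0),
        ("ACDE", 2.0),
        ("AACD", 1.5),  # -(0.5 log2 0.5 + 2 * 0.25 log2 0.25)
        ("AA-A", 0.0),  # gap rows excluded
    ],
)
def test_column_entropy_examples(column, expected):
    assert cv.column_entropy(column) == pytest.approx(expected, abs=1e-12)


def test_all_gap_column_has_no_entropy():
    with pytest.raises(UndefinedEntropyError):
        cv.column_entropy("----")


# -- mutual information ----------------------------------------------------

@pytest.mark.parametrize(
    "a, b, mi",
    [
        ("ACDE", "ACDE", 2.0),  # MI(X, X) = H(X)
        ("ACAC", "DDEE", 0.0),  # independent plug-in counts
        ("AACC", "DDEE", 1.0),  # perfectly coupled balanced binary columns
        ("AAAA", "DDEE", 0.0),  # constant column
    ],
)
def test_mutual_information_examples(a, b, mi):
    got, n_eff = cv.mutual_information(a, b)
    assert got == pytest.approx(mi, abs=1e-12)
    assert n_eff == 4


def test_mi_pairwise_gap_policy():
    # row 3 gapped in b, row 5 'X' in a: both dropped jointly
    mi, n_eff = cv.mutual_information("AACCX", "DD-EE")
    ref, _ = cv.mutual_information("AAC", "DDE")
    assert n_eff == 3 and mi == pytest.approx(ref)


def test_mi_insufficient_rows():
    with pytest.raises(InsufficientDataError):
        cv.mutual_information("A---", "-DDD")


@given(
    st.lists(
        st.tuples(st.sampled_from("ACDEF"), st.sampled_from("KLMNP")),
        min_size=2,
        max_size=30,
    )
)
def test_mi_bounded_by_min_entropy(pairs):
    a = [x for x, _ in pairs]
    b = [y for _, y in pairs]
    mi, _ = cv.mutual_information(a, b)
    assert -1e-12 <= mi <= min(cv.column_entropy(a), cv.column_entropy(b)) + 1e-9


# -- grid ------------------------------------------------------------------

def test_grid_matches_per_pair_oracle(small_complex):
    paired = cv.pair_by_species(
        small_complex.alignments["A"], small_complex.alignments["B"]
    )
    grid = cv.mi_grid(paired)
    assert grid.mi.shape == (len(paired.cols_a), len(paired.cols_b))
    for i in range(grid.mi.shape[0]):
        for j in range(grid.mi.shape[1]):
            mi, n_eff = mutual_information(paired.matrix_a[:, i], paired.matrix_b[:, j])
            assert grid.mi[i, j] == pytest.approx(mi, abs=1e-9)
            assert grid.n_eff[i, j] == n_eff


def test_grid_diagonal_is_entropy(small_complex):
    a = small_complex.alignments["A"]
    paired = cv.pair_by_species(a, cv.OrthologAlignment("A2", a.rows))
    grid = cv.mi_grid(paired)
    for i in range(len(paired.cols_a)):
        col = paired.matrix_a[:, i]
        h = cv.column_entropy(col[col != "-"])
        # diagonal MI equals the entropy of the gap-free subset of the column
        sub = col[(col != "-") & (col != "X")]
        assert grid.mi[i, i] == pytest.approx(cv.column_entropy(sub), abs=1e-9)


def test_grid_symmetric_under_swap(small_complex):
    a, b = small_complex.alignments["A"], small_complex.alignments["B"]
    g_ab = cv.mi_grid(cv.pair_by_species(a, b))
    g_ba = cv.mi_grid(cv.pair_by_species(b, a))
    np.testing.assert_allclose(g_ab.mi, g_ba.mi.T, atol=1e-9)


def test_grid_flags_missing_pairs():
    rows_a = [("S1", "A-"), ("S2", "C-"), ("S3", "AA")]
    rows_b = [("S1", "DD"), ("S2", "-E"), ("S3", "D-")]
    paired = cv.pair_by_species(
        cv.OrthologAlignment("A", rows_a), cv.OrthologAlignment("B", rows_b), 0.99
    )
    grid = cv.mi_grid(paired)
    # columns A2/B2 share no jointly non-gap row -> flagged missing, not a crash
    assert np.isnan(grid.mi[1, 1])
    p = cv.permutation_pvalues(paired, grid, n_perm=19, seed=0)
    assert np.isnan(p[1, 1])


# -- permutation p-values --------------------------------------------------

def test_constant_column_gives_p_one():
    rows_a = [(f"S{i}", c) for i, c in enumerate("ACDEF")]
    rows_b = [(f"S{i}", "L") for i in range(5)]
    paired = cv.pair_by_species(
        cv.OrthologAlignment("A", rows_a), cv.OrthologAlignment("B", rows_b)
    )
    p = cv.permutation_pvalues(paired, n_perm=49, seed=1)
    assert p[0, 0] == 1.0


def test_exhaustive_matches_brute_force_enumeration():
    rng = np.random.default_rng(4)
    rows_a = [(f"S{i}", "".join(rng.choice(list("ACDE"), 3))) for i in range(4)]
    rows_b = [(f"S{i}", "".join(rng.choice(list("KLMN"), 3))) for i in range(4)]
    paired = cv.pair_by_species(
        cv.OrthologAlignment("A", rows_a), cv.OrthologAlignment("B", rows_b), 0.99
    )
    grid = cv.mi_grid(paired)
    p = cv.permutation_pvalues(paired, grid, exhaustive=True)
    n_fact = math.factorial(4)
    for i in range(3):
        for j in range(3):
            obs, _ = mutual_information(paired.matrix_a[:, i], paired.matrix_b[:, j])
            count = sum(
                mutual_information(
                    paired.matrix_a[:, i], paired.matrix_b[list(perm), j]
                )[0]
                >= obs - 1e-12
                for perm in itertools.permutations(range(4))
            )
            assert p[i, j] == pytest.approx(count / n_fact, abs=1e-12)


def test_pvalue_floor_is_add_one():
    spec = cv.SimulationSpec(
        n_species=150,
        proteins=[("A", 1), ("B", 1)],
        planted_pairs=[cv.PlantedPair("A", 1, "B", 1, 1.0)],
        substitution_prob=0.4,
        seed=8,
    )
    cx = cv.simulate_complex(spec)
    paired = cv.pair_by_species(cx.alignments["A"], cx.alignments["B"])
    p = cv.permutation_pvalues(paired, n_perm=99, seed=0)
    assert p[0, 0] == pytest.approx(1 / 100)


def test_permutation_seed_reproducible(small_complex):
    paired = cv.pair_by_species(
        small_complex.alignments["A"], small_complex.alignments["B"]
    )
    p1 = cv.permutation_pvalues(paired, n_perm=29, seed=3)
    p2 = cv.permutation_pvalues(paired, n_perm=29, seed=3)
    np.testing.assert_array_equal(p1, p2)


def test_n_perm_validation(small_complex):
    paired = cv.pair_by_species(
        small_complex.alignments["A"], small_complex.alignments["B"]
    )
    with pytest.raises(ValueError):
        cv.permutation_pvalues(paired, n_perm=0)


# -- BH q-values -----------------------------------------------------------

def bh_reference(p):
    """Independent step-up implementation used as oracle."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@pytest.mark.parametrize(
    "p, expected",
    [
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.03], [0.03]),
    ],
)
def test_bh_examples(p, expected):
    np.testing.assert_allclose(cv.bh_qvalues(p), expected, atol=1e-12)


def test_bh_matches_independent_step_up():
    rng = np.random.default_rng(12)
    for _ in range(200):
        p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 40))
        np.testing.assert_allclose(cv.bh_qvalues(p), bh_reference(p), atol=1e-12)


def test_bh_empty_and_invalid():
    assert cv.bh_qvalues([]).size == 0
    with pytest.raises(ValueError):
        cv.bh_qvalues([0.0, 0.5])
    with pytest.raises(ValueError):
        cv.bh_qvalues([1.5])


# -- summaries and ranking -------------------------------------------------

def _score(mi, p=0.5, q=0.5, col_a=1, col_b=1, n_eff=10):
    return cv.ResiduePairScore(col_a, col_b, mi, n_eff, p, q)


def test_summarize_pair_counts():
    scores = [
        _score(1.0, q=0.01), _score(0.5, q=0.2),
        _score(0.2, q=0.6), _score(0.0, q=1.0),
    ]
    s = cv.summarize_pair(scores, q_threshold=0.05, protein_a="A", protein_b="B")
    assert s.frac_significant == 0.25
    assert s.frac_nonzero_mi == 0.75


def test_summary_missing_pairs_in_denominator():
    scores = [_score(1.0, q=0.01)]
    s = cv.summarize_pair(scores, n_pairs_tested=4)
    assert s.frac_significant == 0.25 and s.frac_nonzero_mi == 0.25


def test_all_zero_mi_summary():
    scores = [_score(0.0, p=1.0, q=1.0) for _ in range(3)]
    s = cv.summarize_pair(scores)
    assert s.frac_nonzero_mi == 0.0 and s.frac_significant == 0.0


def test_frac_significant_bounded_by_nonzero(small_complex):
    paired = cv.pair_by_species(
        small_complex.alignments["A"], small_complex.alignments["B"]
    )
    scores = cv.score_pair(paired, n_perm=99, seed=2)
    s = cv.summarize_pair(scores, n_pairs_tested=36, protein_a="A", protein_b="B")
    assert 0 <= s.frac_significant <= s.frac_nonzero_mi <= 1


def test_rank_top_pairs_order_and_ties():
    s1 = ("A", "B", _score(2.0, p=0.1))
    s2 = ("A", "B", _score(1.0, p=0.01, col_a=3))
    s3 = ("A", "C", _score(1.0, p=0.005, col_a=2))
    top = cv.rank_top_pairs([s1, s2, s3], k=20)
    assert top == [s1, s3, s2]  # equal MI: smaller p first
    assert len(cv.rank_top_pairs([s1, s2, s3], k=2)) == 2


def test_apc_leaves_shape_and_reduces_background(small_complex):
    paired = cv.pair_by_species(
        small_complex.alignments["A"], small_complex.alignments["B"]
    )
    grid = cv.mi_grid(paired)
    corrected = cv.apc_correct(grid.mi)
    assert corrected.shape == grid.mi.shape
    assert np.nanmean(corrected) == pytest.approx(0.0, abs=0.2)
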