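import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parentsim import (
    Genotype,
    agresti_coull,
    build_nonconformity_table,
    count_nonconformities,
    simulate_population,
    table_from_counts,
)
from parentsim import reference as ref
from parentsim.exclusion import (
    MismatchRecord,
    duo_excluded_array,
    duo_locus_excluded,
    mismatch_counts_array,
    round_half_up,
    trio_excluded_array,
    trio_locus_excluded,
)
from parentsim.pedigree import ScenarioPairing, scenario_pairing

ALLELES4 = "abcd"
GENOTYPES4 = [Genotype(x, y) for x, y in itertools.combinations_with_replacement(ALLELES4, 2)]


def test_duo_rule_basic_cases():
    assert not duo_locus_excluded(Genotype("a", "b"), Genotype("a", "c"))
    assert duo_locus_excluded(Genotype("a", "b"), Genotype("c", "d"))
    assert not duo_locus_excluded(Genotype("a", "a"), Genotype("a", "a"))


@given(
    st.tuples(*[st.sampled_from(ALLELES4)] * 4)
)
@settings(derandomize=True, max_examples=200)
def test_duo_rule_is_symmetric(alleles):
    g1, g2 = Genotype(alleles[0], alleles[1]), Genotype(alleles[2], alleles[3])
    assert duo_locus_excluded(g1, g2) == duo_locus_excluded(g2, g1)


def test_trio_rule_basic_cases():
    # obligate {b}: father carries b
    assert not trio_locus_excluded(Genotype("b", "c"), Genotype("a", "a"), Genotype("a", "b"))
    # obligate {a, b}: father carries neither
    assert trio_locus_excluded(Genotype("c", "d"), Genotype("a", "b"), Genotype("a", "b"))
    # incompatible mother is a pipeline bug, not an exclusion
    with pytest.raises(ValueError):
        trio_locus_excluded(Genotype("a", "a"), Genotype("c", "d"), Genotype("a", "b"))


def test_trio_exclusion_implies_duo_exclusion_exhaustively():
    """Obligate paternal alleles are a subset of the child's alleles, so a
    duo exclusion always forces a trio exclusion; checked over every
    genotype triple at a 4-allele locus, scalar and vectorized."""
    compat_triples = []
    for father, mother, child in itertools.product(GENOTYPES4, repeat=3):
        if not (child.alleles & mother.alleles):
            continue
        if child.is_homozygous and child.allele_a not in mother.alleles:
            continue
        duo = duo_locus_excluded(father, child)
        trio = trio_locus_excluded(father, mother, child)
        assert trio or not duo, (father, mother, child)
        compat_triples.append((father, mother, child, duo, trio))
    # same decisions from the vectorized kernels
    to_idx = {a: i for i, a in enumerate(ALLELES4)}
    arr = lambda genos: np.array(
        [[[to_idx[g.allele_a], to_idx[g.allele_b]]] for g in genos], dtype=np.int16
    )
    fathers = arr([t[0] for t in compat_triples])
    mothers = arr([t[1] for t in compat_triples])
    children = arr([t[2] for t in compat_triples])
    np.testing.assert_array_equal(
        duo_excluded_array(fathers, children)[:, 0], [t[3] for t in compat_triples]
    )
    np.testing.assert_array_equal(
        trio_excluded_array(fathers, mothers, children)[:, 0], [t[4] for t in compat_triples]
    )


def test_count_nonconformities_on_single_locus_panel(triallelic_panel):
    pop = simulate_population(triallelic_panel, 50, seed=3)
    for family in pop:
        duo = count_nonconformities(scenario_pairing("parent", "duo"), family)
        trio = count_nonconformities(scenario_pairing("parent", "trio"), family)
        assert duo.k == 0 and trio.k == 0
    with pytest.raises(KeyError):
        count_nonconformities(
            ScenarioPairing("random_man", "NOPE", None, "B"), pop[0]
        )


def test_count_nonconformities_matches_vectorized_kernel(panel):
    pop = simulate_population(panel, 100, seed=8)
    for relationship in ("sibling", "uncle", "random_man"):
        for mode in ("duo", "trio"):
            pairing = scenario_pairing(relationship, mode)
            vec = mismatch_counts_array(pairing, pop.role_arrays)
            scalar = [count_nonconformities(pairing, fam).k for fam in pop]
            np.testing.assert_array_equal(vec, scalar)


@pytest.mark.parametrize(
    "x, n, center, half_width",
    [
        (1902, 10_000, 19.03, 0.77),
        (0, 10_000, 0.02, 0.03),
        (10_000, 10_000, 99.98, 0.03),
        (54, 10_000, 0.56, 0.15),
        (279, 10_000, 2.81, 0.32),
    ],
)
def test_agresti_coull_matches_published_cells(x, n, center, half_width):
    est = agresti_coull(x, n, alpha=0.05)
    assert est.center_rounded == center
    assert est.half_width_rounded == half_width


def test_agresti_coull_zero_count_center_is_positive():
    est = agresti_coull(0, 10_000)
    assert est.center > 0


@given(st.integers(min_value=0, max_value=500), st.integers(min_value=1, max_value=500))
@settings(derandomize=True, max_examples=200)
def test_agresti_coull_center_symmetry(x, extra):
    n = x + extra
    a, b = agresti_coull(x, n), agresti_coull(n - x, n)
    assert a.center + b.center == pytest.approx(100.0, abs=1e-9)
    assert a.half_width == pytest.approx(b.half_width, abs=1e-12)


@pytest.mark.parametrize("x, n, alpha", [(-1, 10, 0.05), (11, 10, 0.05), (5, 10, 0.0), (5, 10, 1.0), (0, 0, 0.05)])
def test_agresti_coull_rejects_bad_parameters(x, n, alpha):
    with pytest.raises(ValueError):
        agresti_coull(x, n, alpha)


def test_round_half_up_ties():
    assert round_half_up(2.705) == 2.71
    assert round_half_up(2.7049999) == 2.70
    assert round_half_up(0.025) == 0.03


def test_build_table_reproduces_sibling_cumulatives_and_rates():
    counts = ref.DUO_NONCONFORMITY_COUNTS["sibling"]
    records = [
        MismatchRecord(i, "sibling", "duo", k)
        for i, k in enumerate(np.repeat(np.arange(16), counts))
    ]
    table = build_nonconformity_table(records, n_loci=15, alpha=0.05)
    assert table.cumulative_by_k[:3] == (1902, 5170, 7960)
    assert table.rate_by_k[1].center_rounded == 51.70
    assert table.rate_by_k[1].half_width_rounded == 0.98
    assert table.n_pairs == 10_000

    trio = table_from_counts("sibling", "trio", ref.TRIO_NONCONFORMITY_COUNTS["sibling"])
    assert trio.rate_by_k[1].center_rounded == 4.28
    assert trio.rate_by_k[1].half_width_rounded == 0.40


def test_build_table_degenerate_and_error_cases():
    records = [MismatchRecord(i, "parent", "duo", 0) for i in range(100)]
    table = build_nonconformity_table(records, n_loci=15)
    assert table.cumulative_by_k == (100,) * 16
    assert len({r.center for r in table.rate_by_k}) == 1
    with pytest.raises(ValueError):
        build_nonconformity_table([], n_loci=15)
    mixed = records + [MismatchRecord(0, "sibling", "duo", 1)]
    with pytest.raises(ValueError):
        build_nonconformity_table(mixed, n_loci=15)
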