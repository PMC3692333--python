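import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parentsim import (
    Genotype,
    combine_lr,
    duo_pi,
    probability_of_paternity,
    summarize_log_lr,
    trio_pi,
)
from parentsim.paternity import LocusPI, PairLR, duo_pi_array, log_lr_array, trio_pi_array

from conftest import make_locus


# ---------------------------------------------------------------------------
# enumeration oracle: walk every ordered (maternal, paternal) transmission

def oracle_child_prob(child: Genotype, maternal: dict, paternal: dict) -> float:
    target = sorted((child.allele_a, child.allele_b))
    total = 0.0
    for m, pm in maternal.items():
        for f, pf in paternal.items():
            if sorted((m, f)) == target:
                total += pm * pf
    return total


def transmission(g: Genotype) -> dict:
    return {g.allele_a: 1.0} if g.is_homozygous else {g.allele_a: 0.5, g.allele_b: 0.5}


def hw_genotypes(locus):
    pop = dict(zip(locus.alleles, locus.frequencies))
    for a, b in itertools.combinations_with_replacement(locus.alleles, 2):
        prob = pop[a] ** 2 if a == b else 2 * pop[a] * pop[b]
        yield Genotype(a, b), prob


def oracle_trio_pi(father, mother, child, locus):
    pop = dict(zip(locus.alleles, locus.frequencies))
    num = oracle_child_prob(child, transmission(mother), transmission(father))
    den = oracle_child_prob(child, transmission(mother), pop)
    return None if den == 0 else num / den


def oracle_duo_pi(father, child, locus):
    """Marginalize the trio numerator/denominator over HW mother genotypes."""
    pop = dict(zip(locus.alleles, locus.frequencies))
    num = den = 0.0
    for mother, w in hw_genotypes(locus):
        num += w * oracle_child_prob(child, transmission(mother), transmission(father))
        den += w * oracle_child_prob(child, transmission(mother), pop)
    return num / den


# ---------------------------------------------------------------------------

LOCUS2 = make_locus("P2", ["a", "b"], [0.3, 0.7])
LOCUS3 = make_locus("P3", ["a", "b", "c"], [0.5, 0.3, 0.2])
EQUAL4 = make_locus("E4", ["a", "b", "c", "d"], [0.25, 0.25, 0.25, 0.25])


def test_duo_pi_closed_forms():
    locus = make_locus("L", ["a", "b", "c", "d"], [0.5, 0.25, 0.15, 0.1])
    # child aa, father aa -> 1 / p_a
    assert duo_pi(Genotype("a", "a"), Genotype("a", "a"), locus).value == pytest.approx(2.0)
    # child ab, father ab -> (p_a + p_b) / (4 p_a p_b); equal at 0.25 -> 2
    assert duo_pi(Genotype("a", "b"), Genotype("a", "b"), EQUAL4).value == pytest.approx(2.0)
    assert duo_pi(Genotype("a", "b"), Genotype("a", "b"), locus).value == pytest.approx(
        (0.5 + 0.25) / (4 * 0.5 * 0.25)
    )
    # no shared allele -> 0
    assert duo_pi(Genotype("c", "d"), Genotype("a", "b"), locus).value == 0.0
    with pytest.raises(KeyError):
        duo_pi(Genotype("z", "a"), Genotype("a", "a"), locus)


def test_trio_pi_closed_forms():
    locus = LOCUS3
    # child ab, mother aa: father must transmit b -> 1 / p_b
    assert trio_pi(
        Genotype("b", "b"), Genotype("a", "a"), Genotype("a", "b"), locus
    ).value == pytest.approx(1 / 0.3)
    # excluded
    assert trio_pi(
        Genotype("c", "c"), Genotype("a", "b"), Genotype("a", "b"), locus
    ).value == 0.0
    with pytest.raises(ValueError):
        trio_pi(Genotype("a", "a"), Genotype("c", "c"), Genotype("a", "b"), locus)


@pytest.mark.parametrize("locus", [LOCUS2, LOCUS3], ids=["2-allele", "3-allele"])
def test_pi_matches_enumeration_oracle_over_all_configurations(locus):
    genotypes = [
        Genotype(a, b) for a, b in itertools.combinations_with_replacement(locus.alleles, 2)
    ]
    for father, child in itertools.product(genotypes, repeat=2):
        assert duo_pi(father, child, locus).value == pytest.approx(
            oracle_duo_pi(father, child, locus), abs=1e-12
        )
        for mother in genotypes:
            expected = oracle_trio_pi(father, mother, child, locus)
            if expected is None:
                with pytest.raises(ValueError):
                    trio_pi(father, mother, child, locus)
            else:
                assert trio_pi(father, mother, child, locus).value == pytest.approx(
                    expected, abs=1e-12
                )


def test_vectorized_pi_agrees_with_scalar(panel):
    from parentsim import simulate_population
    from parentsim.pedigree import scenario_pairing

    pop = simulate_population(panel, 40, seed=17)
    fm = panel.frequency_matrix()
    arrays = pop.role_arrays
    for relationship in ("parent", "sibling", "cousin"):
        duo = scenario_pairing(relationship, "duo")
        trio = scenario_pairing(relationship, "trio")
        vec_duo = duo_pi_array(arrays[duo.alleged_father_role], arrays[duo.child_role], fm)
        vec_trio = trio_pi_array(
            arrays[trio.alleged_father_role],
            arrays[trio.mother_role],
            arrays[trio.child_role],
            fm,
        )
        for i, family in enumerate(pop):
            for locus_i, locus in enumerate(panel):
                father = family[duo.alleged_father_role].genotype_at(locus_i)
                child = family[duo.child_role].genotype_at(locus_i)
                mother = family[trio.mother_role].genotype_at(locus_i)
                assert vec_duo[i, locus_i] == pytest.approx(
                    duo_pi(father, child, locus).value, rel=1e-12
                )
                assert vec_trio[i, locus_i] == pytest.approx(
                    trio_pi(father, mother, child, locus).value, rel=1e-12
                )


def test_combine_lr_product_and_exclusion_rules():
    ones = [LocusPI(f"L{i}", 1.0) for i in range(15)]
    pair = combine_lr(ones)
    assert pair.lr == pytest.approx(1.0) and pair.log_lr == pytest.approx(0.0)
    tens = [LocusPI(f"L{i}", 10.0) for i in range(15)]
    assert combine_lr(tens).log_lr == pytest.approx(15.0)
    with_zero = ones[:-1] + [LocusPI("L14", 0.0)]
    excluded = combine_lr(with_zero)
    assert excluded.excluded and excluded.lr == 0.0
    assert excluded.log_lr is None and excluded.probability_of_paternity is None


@pytest.mark.parametrize(
    "log_lr, expected",
    [(2.8206, 99.8491), (3.2468, 99.9434), (0.7880, 85.9897)],
)
def test_probability_of_paternity_reproduces_published_pairs(log_lr, expected):
    assert probability_of_paternity(10**log_lr) == pytest.approx(expected, abs=1e-3)


def test_probability_of_paternity_edges_and_errors():
    assert probability_of_paternity(1.0) == pytest.approx(50.0)
    assert probability_of_paternity(3.0, prior=0.25) == pytest.approx(50.0)
    with pytest.raises(ValueError):
        probability_of_paternity(0.0)
    with pytest.raises(ValueError):
        probability_of_paternity(1.0, prior=1.0)


@given(st.floats(min_value=-6, max_value=6, allow_nan=False))
@settings(derandomize=True, max_examples=200)
def test_probability_complement_identity(log_lr):
    lr = 10.0**log_lr
    w, w_inv = probability_of_paternity(lr), probability_of_paternity(1 / lr)
    assert w + w_inv == pytest.approx(100.0, abs=1e-9)
    assert probability_of_paternity(lr * 2) > w  # strictly monotone


def test_summarize_log_lr_two_value_case():
    pairs = [
        PairLR("random_man", "duo", 0, 10**2.8206, 2.8206, 99.8491),
        PairLR("random_man", "duo", 1, 10**3.2468, 3.2468, 99.9434),
        PairLR("random_man", "duo", 2, 0.0, None, None),  # excluded, ignored
    ]
    s = summarize_log_lr(pairs, alpha=0.05)
    assert s.n_nonexcluded == 2
    assert s.mean_log_lr == pytest.approx(3.0337)
    # t with 1 df: 12.7062 * sd / sqrt(2)
    sd = np.std([2.8206, 3.2468], ddof=1)
    assert s.ci_half_width == pytest.approx(12.7062 * sd / math.sqrt(2), abs=1e-3)
    assert round(s.ci_half_width, 2) == 2.71
    assert s.mean_probability == pytest.approx(99.9076, abs=1e-3)


def test_summarize_log_lr_degenerate_sizes():
    one = summarize_log_lr([PairLR("cousin", "trio", 0, 10**7.6185, 7.6185, None)])
    assert one.n_nonexcluded == 1
    assert one.min_log_lr == one.max_log_lr == one.mean_log_lr == pytest.approx(7.6185)
    assert one.ci_half_width is None
    empty = summarize_log_lr([], relationship="random_man", mode="trio")
    assert empty.n_nonexcluded == 0 and empty.mean_log_lr is None


def test_log_lr_array_flags_excluded_pairs():
    pi = np.array([[2.0, 1.0, 5.0], [2.0, 0.0, 5.0]])
    out = log_lr_array(pi)
    assert out[0] == pytest.approx(1.0)
    assert np.isnan(out[1])
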