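"""Three-generation family simulation for parentage-testing studies.

Families are simulated from a :class:`~parentsim.frequencies.FrequencySet`:
founders are drawn under Hardy-Weinberg equilibrium and every child receives
one uniformly chosen allele from each parent, independently across loci
(Mendelian transmission, no mutation).

The pedigree realizes the seven alleged-father relationships evaluated by
the study. Role codes:

======  =================================================================
role    position in the pedigree
======  =================================================================
I, J    paternal grandfather / grandmother (founders)
E       true father, child of I x J
D, K    father's sister (aunt) and brother (uncle), children of I x J
F       mother of the tested child (founder)
B       tested child, child of E x F
C       full sibling of B, child of E x F
N       aunt D's partner (founder)
R       cousin of B: son of the father's sister, child of N x D
S       second partner of E (founder)
W       half brother of the tested child, child of E x S
J2      mother in the half-sibling scenario (founder)
M       tested child of the half-sibling scenario, child of E x J2
X       random unrelated man (founder)
======  =================================================================

Each relationship pairs an alleged father with a child (duo) and optionally
the child's true mother (trio): the true father E, sibling C, grandfather I,
uncle K, cousin R and random man X are each tested against child B (mother
F); the half brother W is tested against child M (mother J2), so that the
alleged father and child share exactly one parent (E).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np

from .frequencies import FrequencySet

#: Founder roles, in the order their genotypes are drawn.
FOUNDER_ROLES: tuple[str, ...] = ("I", "J", "F", "N", "S", "J2", "X")

#: child role -> (father role, mother role), in generation order.
PARENTAGE: dict[str, tuple[str, str]] = {
    "E": ("I", "J"),
    "D": ("I", "J"),
    "K": ("I", "J"),
    "B": ("E", "F"),
    "C": ("E", "F"),
    "R": ("N", "D"),
    "M": ("E", "J2"),
    "W": ("E", "S"),
}

_GEN1 = ("E", "D", "K")
_GEN2 = ("B", "C", "R", "M", "W")

ALL_ROLES: tuple[str, ...] = FOUNDER_ROLES + _GEN1 + _GEN2

#: Relationship of the alleged father to the tested child, in report order.
RELATIONSHIPS: tuple[str, ...] = (
    "parent",
    "sibling",
    "grandparent",
    "uncle",
    "half_sibling",
    "cousin",
    "random_man",
)


@dataclass(frozen=True)
class Genotype:
    """Unordered pair of allele labels at one locus."""

    allele_a: str
    allele_b: str

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.allele_a, self.allele_b))

    @property
    def is_homozygous(self) -> bool:
        return self.allele_a == self.allele_b


class Individual:
    """One pedigree member: a role code and a genotype at every panel locus.

    Genotypes are stored as allele indices into the panel's loci; labels are
    materialized on access.
    """

    __slots__ = ("role", "allele_indices", "panel")

    def __init__(self, role: str, allele_indices: np.ndarray, panel: FrequencySet):
        allele_indices = np.asarray(allele_indices)
        if allele_indices.shape != (panel.n_loci, 2):
            raise ValueError(
                f"genotype array for {role!r} has shape {allele_indices.shape}, "
                f"expected ({panel.n_loci}, 2)"
            )
        self.role = role
        self.allele_indices = allele_indices
        self.panel = panel

    def genotype_at(self, locus_index: int) -> Genotype:
        locus = self.panel[locus_index]
        a, b = self.allele_indices[locus_index]
        return Genotype(locus.alleles[int(a)], locus.alleles[int(b)])

    @property
    def genotypes(self) -> list[Genotype]:
        return [self.genotype_at(i) for i in range(self.panel.n_loci)]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Individual(role={self.role!r}, loci={self.panel.n_loci})"


@dataclass(frozen=True)
class Family:
    """All members of one simulated family, keyed by role code."""

    family_id: int
    members: Mapping[str, Individual]

    def __getitem__(self, role: str) -> Individual:
        return self.members[role]


@dataclass(frozen=True)
class ScenarioPairing:
    """One alleged-father evaluation: who is tested against whom.

    ``mother_role`` is None for duo (motherless) evaluation and names the
    child's true mother for trio evaluation.
    """

    relationship: str
    alleged_father_role: str
    mother_role: str | None
    child_role: str

    @property
    def mode(self) -> str:
        return "duo" if self.mother_role is None else "trio"


#: relationship -> (alleged father, true mother, child)
_SCENARIO_ROLES: dict[str, tuple[str, str, str]] = {
    "parent": ("E", "F", "B"),
    "sibling": ("C", "F", "B"),
    "grandparent": ("I", "F", "B"),
    "uncle": ("K", "F", "B"),
    "half_sibling": ("W", "J2", "M"),
    "cousin": ("R", "F", "B"),
    "random_man": ("X", "F", "B"),
}


def scenario_pairing(relationship: str, mode: str) -> ScenarioPairing:
    """The pairing evaluated for a relationship in duo or trio mode."""
    father, mother, child = _SCENARIO_ROLES[relationship]
    if mode == "duo":
        return ScenarioPairing(relationship, father, None, child)
    if mode == "trio":
        return ScenarioPairing(relationship, father, mother, child)
    raise ValueError(f"mode must be 'duo' or 'trio', got {mode!r}")


def all_scenario_pairings() -> list[ScenarioPairing]:
    """All 7 relationships x 2 modes, in report order."""
    return [scenario_pairing(rel, mode) for rel in RELATIONSHIPS for mode in ("duo", "trio")]


def _cumulative_matrix(freqs: FrequencySet) -> np.ndarray:
    """(L, max_alleles) right-padded cumulative frequencies for inverse-CDF draws."""
    width = max(loc.n_alleles for loc in freqs)
    cum = np.full((freqs.n_loci, width), np.inf)
    for i, loc in enumerate(freqs):
        # the final boundary is +inf so rounding in the cumsum can never push
        # a uniform draw past the last allele
        cum[i, : loc.n_alleles - 1] = np.cumsum(loc.frequencies)[:-1]
    return cum


def draw_founder(freqs: FrequencySet, rng: np.random.Generator, role: str = "founder") -> Individual:
    """Draw an individual under Hardy-Weinberg equilibrium.

    Both alleles at each locus are independent draws from the locus's
    allele-frequency distribution.
    """
    cum = _cumulative_matrix(freqs)
    u = rng.random((freqs.n_loci, 2))
    idx = np.sum(u[:, :, None] >= cum[:, None, :], axis=-1)
    return Individual(role, idx.astype(np.int16), freqs)


def mate(
    parent1: Individual,
    parent2: Individual,
    rng: np.random.Generator,
    role: str = "child",
) -> Individual:
    """Produce a child by Mendelian transmission.

    At each locus the child receives one uniformly chosen allele from each
    parent, independently across loci. Column 0 of the child's allele array
    holds the allele from ``parent1``, column 1 the allele from ``parent2``.
    """
    if parent1.panel is not parent2.panel and parent1.panel != parent2.panel:
        raise ValueError("parents are typed on different panels")
    L = parent1.panel.n_loci
    picks = rng.integers(0, 2, size=(L, 2))
    rows = np.arange(L)
    child = np.column_stack(
        [
            parent1.allele_indices[rows, picks[:, 0]],
            parent2.allele_indices[rows, picks[:, 1]],
        ]
    )
    return Individual(role, child.astype(np.int16), parent1.panel)


def _simulate_family_arrays(
    cum: np.ndarray, L: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Draw one family's genotypes as role -> (L, 2) allele-index arrays.

    RNG consumption order (fixed; part of the reproducibility contract):
    one uniform block for all founders, then one transmission-pick block per
    child generation.
    """
    u = rng.random((len(FOUNDER_ROLES), L, 2))
    founder_idx = np.sum(u[:, :, :, None] >= cum[None, :, None, :], axis=-1).astype(np.int16)
    g: dict[str, np.ndarray] = {
        role: founder_idx[i] for i, role in enumerate(FOUNDER_ROLES)
    }
    rows = np.arange(L)
    for generation in (_GEN1, _GEN2):
        picks = rng.integers(0, 2, size=(len(generation), L, 2))
        for j, child in enumerate(generation):
            father, mother = PARENTAGE[child]
            g[child] = np.column_stack(
                [
                    g[father][rows, picks[j, :, 0]],
                    g[mother][rows, picks[j, :, 1]],
                ]
            ).astype(np.int16)
    return g


def simulate_family(
    freqs: FrequencySet, family_id: int, rng: np.random.Generator
) -> Family:
    """Simulate one three-generation family (all roles in ``ALL_ROLES``)."""
    arrays = _simulate_family_arrays(_cumulative_matrix(freqs), freqs.n_loci, rng)
    members = {role: Individual(role, arr, freqs) for role, arr in arrays.items()}
    return Family(family_id, members)


class Population:
    """A sequence of simulated families with array-backed storage.

    Indexing yields :class:`Family` objects; the pipeline consumes the
    stacked per-role arrays directly via :attr:`role_arrays`.
    """

    def __init__(self, freqs: FrequencySet, role_arrays: dict[str, np.ndarray]):
        self.freqs = freqs
        self.role_arrays = role_arrays
        self.n_families = next(iter(role_arrays.values())).shape[0]

    def __len__(self) -> int:
        return self.n_families

    def __getitem__(self, i: int) -> Family:
        if not 0 <= i < self.n_families:
            raise IndexError(i)
        members = {
            role: Individual(role, arr[i], self.freqs)
            for role, arr in self.role_arrays.items()
        }
        return Family(i, members)

    def __iter__(self) -> Iterator[Family]:
        for i in range(self.n_families):
            yield self[i]

    def genotypes_frame(self):
        """Long-format genotype dump: family_id, role, locus, allele_a, allele_b."""
        import pandas as pd

        rows = []
        for role, arr in self.role_arrays.items():
            for locus_i, locus in enumerate(self.freqs):
                a = arr[:, locus_i, 0]
                b = arr[:, locus_i, 1]
                rows.append(
                    pd.DataFrame(
                        {
                            "family_id": np.arange(self.n_families),
                            "role": role,
                            "locus": locus.locus_name,
                            "allele_a": np.asarray(locus.alleles, dtype=object)[a],
                            "allele_b": np.asarray(locus.alleles, dtype=object)[b],
                        }
                    )
                )
        return (
            pd.concat(rows, ignore_index=True)
            .sort_values(["family_id", "role", "locus"], kind="stable")
            .reset_index(drop=True)
        )


def simulate_population(
    freqs: FrequencySet, n_families: int, seed: int | np.random.SeedSequence
) -> Population:
    """Simulate ``n_families`` independent families.

    A master :class:`numpy.random.SeedSequence` spawns one child stream per
    family, so family *i* has the same genotypes regardless of how many
    families are simulated after it.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_seeds = master.spawn(n_families)
    L = freqs.n_loci
    cum = _cumulative_matrix(freqs)
    role_arrays = {role: np.empty((n_families, L, 2), dtype=np.int16) for role in ALL_ROLES}
    for i, ss in enumerate(child_seeds):
        rng = np.random.Generator(np.random.PCG64(ss))
        arrays = _simulate_family_arrays(cum, L, rng)
        for role in ALL_ROLES:
            role_arrays[role][i] = arrays[role]
    return Population(freqs, role_arrays)


def audit_mendelian(family: Family) -> None:
    """Raise AssertionError unless every non-founder is Mendelian-consistent.

    At each locus the child's genotype must admit a partition into one
    allele carried by the recorded father and one carried by the recorded
    mother (no mutation is ever allowed).
    """
    for child, (father, mother) in PARENTAGE.items():
        c = family[child].allele_indices
        f = family[father].allele_indices
        m = family[mother].allele_indices
        for locus in range(c.shape[0]):
            c0, c1 = c[locus]
            ok = (c0 in f[locus] and c1 in m[locus]) or (c1 in f[locus] and c0 in m[locus])
            assert ok, (
                f"family {family.family_id}: {child} locus {locus} genotype {c[locus]} "
                f"incompatible with parents {father}={f[locus]}, {mother}={m[locus]}"
            )
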