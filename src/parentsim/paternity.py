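"""Paternity indices, combined likelihood ratios and their summaries.

The per-locus paternity index (PI) is the likelihood ratio

    PI = P(child genotype | tested man is the father)
         ---------------------------------------------
         P(child genotype | a random man is the father)

computed by the standard kinship algebra: the known parents transmit a
uniformly chosen allele, a random man transmits an allele by population
frequency, and in a duo (motherless) case the untyped mother also
contributes an allele by population frequency. Both conditionals share the
maternal factor, so duo and trio cases reduce to the same two-transmission
form with different "mother" distributions.

The combined LR is the product over loci; excluded loci have PI = 0, which
annihilates the product, so pairs with any non-matching locus carry no
log LR and are summarized only through the exclusion tables. The posterior
probability of paternity at prior pi is W = LR pi / (LR pi + 1 - pi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .frequencies import LocusFrequencies
from .pedigree import Genotype


@dataclass(frozen=True)
class LocusPI:
    """Paternity index at one locus; 0 exactly when the locus is excluded."""

    locus_name: str
    value: float


@dataclass(frozen=True)
class PairLR:
    """Combined likelihood ratio for one evaluated pair.

    ``log_lr`` (base 10) and ``probability_of_paternity`` (percent) are
    None for excluded pairs (lr == 0).
    """

    relationship: str
    mode: str
    family_id: int
    lr: float
    log_lr: float | None
    probability_of_paternity: float | None

    @property
    def excluded(self) -> bool:
        return self.lr == 0.0


def _child_probability(child: Genotype, maternal: dict[str, float], paternal: dict[str, float]) -> float:
    """P(child) when the maternal and paternal alleles are drawn from the
    given transmission distributions (mappings allele label -> probability)."""
    a, b = child.allele_a, child.allele_b
    if a == b:
        return maternal.get(a, 0.0) * paternal.get(a, 0.0)
    return maternal.get(a, 0.0) * paternal.get(b, 0.0) + maternal.get(b, 0.0) * paternal.get(a, 0.0)


def _transmission(genotype: Genotype) -> dict[str, float]:
    if genotype.is_homozygous:
        return {genotype.allele_a: 1.0}
    return {genotype.allele_a: 0.5, genotype.allele_b: 0.5}


def _population(locus: LocusFrequencies, genotype: Genotype) -> dict[str, float]:
    for label in genotype.alleles:
        locus.index_of(label)  # raises KeyError for foreign alleles
    return dict(zip(locus.alleles, locus.frequencies.tolist()))


def duo_pi(alleged_father: Genotype, child: Genotype, locus: LocusFrequencies) -> LocusPI:
    """Motherless paternity index.

    The numerator lets the tested man transmit uniformly and the untyped
    mother contribute by population frequency; the denominator is the
    Hardy-Weinberg probability of the child's genotype. Closed forms:
    child aa / father with a -> T(a)/p_a; child ab -> shared-allele
    transmission over 2 p_a p_b. Zero iff father and child share no allele.
    """
    pop = _population(locus, child)
    _population(locus, alleged_father)
    father_t = _transmission(alleged_father)
    num = _child_probability(child, pop, father_t)
    den = _child_probability(child, pop, pop)
    return LocusPI(locus.locus_name, num / den)


def trio_pi(
    alleged_father: Genotype, mother: Genotype, child: Genotype, locus: LocusFrequencies
) -> LocusPI:
    """Trio paternity index with the mother's genotype known.

    Both hypotheses condition on the mother transmitting uniformly; they
    differ only in the paternal transmission (tested man uniform vs random
    man by population frequency). Raises if mother and child are
    Mendelian-incompatible (impossible without mutation).
    """
    pop = _population(locus, child)
    _population(locus, alleged_father)
    _population(locus, mother)
    mother_t = _transmission(mother)
    den = _child_probability(child, mother_t, pop)
    if den == 0.0:
        raise ValueError(
            f"mother {mother} incompatible with child {child} at locus {locus.locus_name}"
        )
    num = _child_probability(child, mother_t, _transmission(alleged_father))
    return LocusPI(locus.locus_name, num / den)


def probability_of_paternity(lr: float, prior: float = 0.5) -> float:
    """Posterior probability of paternity, in percent.

    W = 100 * lr * prior / (lr * prior + 1 - prior); the default prior 0.5
    gives the conventional W = 100 * lr / (lr + 1).
    """
    if lr <= 0:
        raise ValueError("probability of paternity requires lr > 0")
    if not 0 < prior < 1:
        raise ValueError("prior must be in (0, 1)")
    return 100.0 * lr * prior / (lr * prior + 1.0 - prior)


def combine_lr(
    per_locus: list[LocusPI],
    relationship: str = "",
    mode: str = "",
    family_id: int = -1,
    prior: float = 0.5,
) -> PairLR:
    """Multiply per-locus PIs into a combined LR.

    If any locus PI is zero the pair is excluded: lr = 0 and no log LR or
    posterior probability is defined.
    """
    values = [p.value for p in per_locus]
    if any(v == 0.0 for v in values):
        return PairLR(relationship, mode, family_id, 0.0, None, None)
    log_lr = float(np.sum(np.log10(values)))
    return PairLR(
        relationship,
        mode,
        family_id,
        lr=10.0**log_lr,
        log_lr=log_lr,
        probability_of_paternity=probability_of_paternity(10.0**log_lr, prior),
    )


# ---------------------------------------------------------------------------
# vectorized PI over stacked genotype arrays (n, L, 2) of allele indices


def _carrier_halves(geno: np.ndarray, allele: np.ndarray) -> np.ndarray:
    """Transmission probability of ``allele`` for each genotype: 0, .5 or 1."""
    return 0.5 * (geno == allele[..., None]).sum(axis=-1)


def duo_pi_array(father: np.ndarray, child: np.ndarray, freq_matrix: np.ndarray) -> np.ndarray:
    """(n, L) duo paternity indices; 0 where the locus is excluded."""
    L = child.shape[-2]
    rows = np.arange(L)[None, :, None]
    p = freq_matrix[rows, child]  # (n, L, 2) population freqs of child alleles
    c0, c1 = child[..., 0], child[..., 1]
    t0 = _carrier_halves(father, c0)
    t1 = _carrier_halves(father, c1)
    het = c0 != c1
    num = np.where(het, p[..., 1] * t0 + p[..., 0] * t1, p[..., 0] * t0)
    den = np.where(het, 2 * p[..., 0] * p[..., 1], p[..., 0] ** 2)
    return num / den


def trio_pi_array(
    father: np.ndarray, mother: np.ndarray, child: np.ndarray, freq_matrix: np.ndarray
) -> np.ndarray:
    """(n, L) trio paternity indices; 0 where the locus is excluded."""
    L = child.shape[-2]
    rows = np.arange(L)[None, :, None]
    p = freq_matrix[rows, child]
    c0, c1 = child[..., 0], child[..., 1]
    m0, m1 = _carrier_halves(mother, c0), _carrier_halves(mother, c1)
    f0, f1 = _carrier_halves(father, c0), _carrier_halves(father, c1)
    het = c0 != c1
    num = np.where(het, m0 * f1 + m1 * f0, m0 * f0)
    den = np.where(het, m0 * p[..., 1] + m1 * p[..., 0], m0 * p[..., 0])
    if np.any(den == 0.0):
        raise ValueError("mother-child Mendelian incompatibility in trio PI")
    return num / den


def log_lr_array(pi: np.ndarray) -> np.ndarray:
    """Per-pair combined log10 LR; NaN for pairs with any excluded locus."""
    excluded = (pi == 0.0).any(axis=1)
    out = np.full(pi.shape[0], np.nan)
    if (~excluded).any():
        out[~excluded] = np.log10(pi[~excluded]).sum(axis=1)
    return out


# ---------------------------------------------------------------------------
# Log LR summaries (the Table 2 / Table 4 shape)


@dataclass(frozen=True)
class LRSummary:
    """Distribution of log10 LR over the non-excluded pairs of one scenario.

    The interval half-width is a t-based confidence half-width of the mean
    at the given alpha (undefined for fewer than two pairs); each log LR
    statistic carries its probability-of-paternity conversion in percent.
    """

    relationship: str
    mode: str
    n_nonexcluded: int
    alpha: float
    min_log_lr: float | None
    max_log_lr: float | None
    mean_log_lr: float | None
    ci_half_width: float | None
    min_probability: float | None
    max_probability: float | None
    mean_probability: float | None


def summarize_log_lr(
    pairs, relationship: str = "", mode: str = "", alpha: float = 0.05, prior: float = 0.5
) -> LRSummary:
    """Summarize log LRs of non-excluded pairs.

    ``pairs`` is a collection of PairLR (excluded ones are dropped) or of
    raw log10 LR values (NaN meaning excluded). With no surviving pair all
    statistics are None; with one, the half-width alone is None.
    """
    values = []
    for p in pairs:
        if isinstance(p, PairLR):
            if relationship == "":
                relationship, mode = p.relationship, p.mode
            if not p.excluded:
                values.append(p.log_lr)
        elif not math.isnan(p):
            values.append(float(p))
    n = len(values)
    if n == 0:
        return LRSummary(relationship, mode, 0, alpha, None, None, None, None, None, None, None)
    arr = np.array(values)
    mean = float(arr.mean())
    half = None
    if n > 1:
        sd = float(arr.std(ddof=1))
        half = float(stats.t.ppf(1 - alpha / 2, n - 1) * sd / math.sqrt(n))
    w = lambda loglr: probability_of_paternity(10.0**loglr, prior)
    return LRSummary(
        relationship=relationship,
        mode=mode,
        n_nonexcluded=n,
        alpha=alpha,
        min_log_lr=float(arr.min()),
        max_log_lr=float(arr.max()),
        mean_log_lr=mean,
        ci_half_width=half,
        min_probability=w(float(arr.min())),
        max_probability=w(float(arr.max())),
        mean_probability=w(mean),
    )
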