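"""STR allele-frequency panels.

A :class:`FrequencySet` describes the population model of a multiplex STR
panel: for each locus, the allele labels and their population frequencies.
Founder individuals are drawn from it under Hardy-Weinberg equilibrium and
it supplies the random-man denominators of every paternity index.

Real panels (e.g. the 15 autosomal Identifiler loci) are read from a simple
CSV; :func:`generate_synthetic_frequencies` produces forensic-grade
synthetic stand-ins with comparable allele counts and heterozygosity.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Frequencies at a locus must sum to 1 within this tolerance after parsing.
SUM_TOL_STRICT = 1e-3
#: Deviations below this are renormalized silently; above, with a warning.
SUM_TOL_CLEAN = 1e-6

#: Smallest allele frequency the synthetic generator will emit. A hard floor
#: keeps every paternity-index denominator finite.
MIN_FREQUENCY = 1e-4


@dataclass(frozen=True)
class LocusFrequencies:
    """Allele labels and frequencies at one STR locus.

    Allele labels are opaque tokens ("9", "9.3", "12"); no computation ever
    interprets them numerically.
    """

    locus_name: str
    alleles: tuple[str, ...]
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", freqs)
        if len(self.alleles) < 2:
            raise ValueError(f"locus {self.locus_name!r}: need at least 2 alleles")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"locus {self.locus_name!r}: duplicate allele labels")
        if freqs.shape != (len(self.alleles),):
            raise ValueError(f"locus {self.locus_name!r}: allele/frequency length mismatch")
        if not np.all(freqs > 0):
            raise ValueError(f"locus {self.locus_name!r}: frequencies must be positive")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError(f"locus {self.locus_name!r}: frequencies sum to {freqs.sum()!r}, not 1")

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    def index_of(self, label: str) -> int:
        try:
            return self.alleles.index(label)
        except ValueError:
            raise KeyError(f"allele {label!r} not in locus {self.locus_name!r}") from None

    def heterozygosity(self) -> float:
        """Expected heterozygosity 1 - sum(p_i^2) under Hardy-Weinberg."""
        return float(1.0 - np.sum(self.frequencies**2))


@dataclass(frozen=True)
class FrequencySet:
    """An ordered panel of loci with their allele frequencies."""

    loci: tuple[LocusFrequencies, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "loci", tuple(self.loci))
        if len(self.loci) < 1:
            raise ValueError("a FrequencySet needs at least one locus")
        names = [loc.locus_name for loc in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names in FrequencySet")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list[str]:
        return [loc.locus_name for loc in self.loci]

    def __iter__(self):
        return iter(self.loci)

    def __getitem__(self, i: int) -> LocusFrequencies:
        return self.loci[i]

    def frequency_matrix(self) -> np.ndarray:
        """(L, max_alleles) matrix of frequencies, zero-padded on the right."""
        width = max(loc.n_alleles for loc in self.loci)
        mat = np.zeros((self.n_loci, width))
        for i, loc in enumerate(self.loci):
            mat[i, : loc.n_alleles] = loc.frequencies
        return mat

    def mean_heterozygosity(self) -> float:
        return float(np.mean([loc.heterozygosity() for loc in self.loci]))


def generate_synthetic_frequencies(
    n_loci: int = 15,
    allele_count_range: tuple[int, int] = (8, 15),
    concentration: float = 1.0,
    seed: int | np.random.SeedSequence | None = None,
) -> FrequencySet:
    """Generate a synthetic STR frequency panel.

    Per locus, the allele count is drawn uniformly from
    ``allele_count_range`` (inclusive) and frequencies from a symmetric
    Dirichlet with the given concentration, floored at ``MIN_FREQUENCY``
    and renormalized. With the defaults (8-15 alleles, concentration 1)
    the panel has the multi-allelic, high-heterozygosity character of
    forensic identification kits.

    Identical seeds give bit-identical panels.
    """
    lo, hi = allele_count_range
    if not (2 <= lo <= hi <= 30):
        raise ValueError(f"allele_count_range must lie within [2, 30], got {allele_count_range}")
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if not concentration > 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    loci = []
    for i in range(n_loci):
        k = int(rng.integers(lo, hi + 1))
        freqs = rng.dirichlet(np.full(k, concentration))
        freqs = np.maximum(freqs, MIN_FREQUENCY)
        freqs = freqs / freqs.sum()
        labels = tuple(str(a) for a in range(6, 6 + k))  # conventional repeat-count style
        loci.append(LocusFrequencies(f"L{i + 1:02d}", labels, freqs))
    return FrequencySet(tuple(loci))


class FrequencyFormatError(ValueError):
    """Raised for malformed frequency CSV files."""


def read_frequency_csv(path) -> FrequencySet:
    """Read a `locus,allele,frequency` CSV into a FrequencySet.

    Loci keep file order. Frequencies at each locus must sum to 1 within
    1e-3; deviations beyond 1e-6 are renormalized with a logged warning.
    """
    per_locus: dict[str, list[tuple[str, float]]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        expected = {"locus", "allele", "frequency"}
        if reader.fieldnames is None or not expected.issubset(reader.fieldnames):
            raise FrequencyFormatError(f"{path}: header must contain {sorted(expected)}")
        for row in reader:
            locus, allele = row["locus"].strip(), row["allele"].strip()
            freq = float(row["frequency"])
            entries = per_locus.setdefault(locus, [])
            if any(a == allele for a, _ in entries):
                raise FrequencyFormatError(f"{path}: duplicate allele {allele!r} at locus {locus!r}")
            entries.append((allele, freq))
    loci = []
    for locus, entries in per_locus.items():
        labels = tuple(a for a, _ in entries)
        freqs = np.array([f for _, f in entries])
        total = freqs.sum()
        if abs(total - 1.0) > SUM_TOL_STRICT:
            raise FrequencyFormatError(
                f"{path}: locus {locus!r} frequencies sum to {total:.6f}, outside tolerance"
            )
        if abs(total - 1.0) > SUM_TOL_CLEAN:
            logger.warning("locus %r frequencies sum to %.6f; renormalizing", locus, total)
        loci.append(LocusFrequencies(locus, labels, freqs / total))
    return FrequencySet(tuple(loci))


def write_frequency_csv(freqs: FrequencySet, path) -> None:
    """Write a FrequencySet as a `locus,allele,frequency` CSV."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["locus", "allele", "frequency"])
        for locus in freqs:
            for allele, freq in zip(locus.alleles, locus.frequencies):
                writer.writerow([locus.locus_name, allele, repr(float(freq))])
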