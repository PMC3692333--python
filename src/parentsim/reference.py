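"""Published reference tabulations for desk-scale verification.

These are the reported results of a large in-silico parentage study on a
15-locus Identifiler panel: 10 000 simulated three-generation families
typed with allele frequencies of a Taiwanese Han population, evaluating
each close relative (and a random man) as the alleged father in duo and
trio testing.

Only the raw non-conformity histograms (row I) and the Log LR rows are
recorded here; the cumulative counts and the Agresti-Coull rate rows are
*recomputed* from them by this package, which is exactly what makes these
tables useful as an arithmetic cross-check. The underlying Taiwanese Han
allele-frequency table is external and is not bundled, so the histograms
themselves cannot be regenerated here — only checked for internal
consistency.

Counts are indexed by number of non-matching loci k = 0..15.
"""

from __future__ import annotations

from dataclasses import dataclass

N_FAMILIES = 10_000
N_LOCI = 15

#: Duo (motherless) non-conformity histograms, relationship -> counts at k=0..15.
DUO_NONCONFORMITY_COUNTS: dict[str, tuple[int, ...]] = {
    "parent": (10000, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "sibling": (1902, 3268, 2790, 1400, 493, 121, 20, 6, 0, 0, 0, 0, 0, 0, 0, 0),
    "grandparent": (279, 1137, 2063, 2582, 1987, 1185, 546, 164, 43, 10, 3, 1, 0, 0, 0, 0),
    "uncle": (276, 1162, 2127, 2545, 2015, 1142, 514, 170, 43, 6, 0, 0, 0, 0, 0, 0),
    "half_sibling": (256, 1148, 2110, 2567, 1980, 1205, 498, 180, 46, 8, 2, 0, 0, 0, 0, 0),
    "cousin": (49, 209, 726, 1456, 2067, 2206, 1762, 909, 410, 154, 43, 8, 1, 0, 0, 0),
    "random_man": (2, 32, 133, 432, 991, 1694, 2113, 1948, 1447, 762, 321, 97, 23, 3, 2, 0),
}

#: Trio non-conformity histograms, relationship -> counts at k=0..15.
TRIO_NONCONFORMITY_COUNTS: dict[str, tuple[int, ...]] = {
    "parent": (10000, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "uncle": (54, 301, 935, 1763, 2210, 2039, 1502, 752, 303, 106, 26, 9, 0, 0, 0, 0),
    "sibling": (49, 377, 1063, 1879, 2244, 2016, 1326, 655, 271, 91, 25, 4, 0, 0, 0, 0),
    "half_sibling": (44, 306, 915, 1693, 2302, 2071, 1518, 734, 291, 101, 23, 2, 0, 0, 0, 0),
    "grandparent": (36, 315, 939, 1668, 2170, 2114, 1489, 808, 337, 89, 30, 5, 0, 0, 0, 0),
    "cousin": (1, 20, 97, 318, 836, 1457, 1944, 1985, 1649, 1020, 471, 147, 45, 10, 0, 0),
    "random_man": (0, 1, 3, 14, 82, 245, 655, 1251, 1913, 2091, 1818, 1160, 548, 177, 39, 3),
}

#: Reported cumulative non-exclusion counts (row II), relationship -> k=0..15.
DUO_CUMULATIVE_COUNTS: dict[str, tuple[int, ...]] = {
    "parent": (10000,) * 16,
    "sibling": (1902, 5170, 7960, 9360, 9853, 9974, 9994) + (10000,) * 9,
    "grandparent": (279, 1416, 3479, 6061, 8048, 9233, 9779, 9943, 9986, 9996, 9999) + (10000,) * 5,
    "uncle": (276, 1438, 3565, 6110, 8125, 9267, 9781, 9951, 9994) + (10000,) * 7,
    "half_sibling": (256, 1404, 3514, 6081, 8061, 9266, 9764, 9944, 9990, 9998) + (10000,) * 6,
    "cousin": (49, 258, 984, 2440, 4507, 6713, 8475, 9384, 9794, 9948, 9991, 9999) + (10000,) * 4,
    "random_man": (2, 34, 167, 599, 1590, 3284, 5397, 7345, 8792, 9554, 9875, 9972, 9995, 9998, 10000, 10000),
}

TRIO_CUMULATIVE_COUNTS: dict[str, tuple[int, ...]] = {
    "parent": (10000,) * 16,
    "uncle": (54, 355, 1290, 3053, 5263, 7302, 8804, 9556, 9859, 9965, 9991) + (10000,) * 5,
    "sibling": (49, 426, 1489, 3368, 5612, 7628, 8954, 9609, 9880, 9971, 9996) + (10000,) * 5,
    "half_sibling": (44, 350, 1265, 2958, 5260, 7331, 8849, 9583, 9874, 9975, 9998) + (10000,) * 5,
    "grandparent": (36, 351, 1290, 2958, 5128, 7242, 8731, 9539, 9876, 9965, 9995) + (10000,) * 5,
    "cousin": (1, 21, 118, 436, 1272, 2729, 4673, 6658, 8307, 9327, 9798, 9945, 9990) + (10000,) * 3,
    "random_man": (0, 1, 4, 18, 100, 345, 1000, 2251, 4164, 6255, 8073, 9233, 9781, 9958, 9997, 10000),
}

#: Reported accumulative non-exclusion rate cells "center ± half-width" (%),
#: relationship -> (center, half_width) at k=0..15, as printed to 2 decimals.
DUO_RATE_CELLS: dict[str, tuple[tuple[float, float], ...]] = {
    "parent": ((99.98, 0.03),) * 16,
    "sibling": ((19.03, 0.77), (51.70, 0.98), (79.59, 0.79), (93.58, 0.48), (98.51, 0.24),
                (99.72, 0.10), (99.92, 0.06)) + ((99.98, 0.03),) * 9,
    "grandparent": ((2.81, 0.32), (14.17, 0.68), (34.80, 0.93), (60.61, 0.96), (80.47, 0.78),
                    (92.31, 0.52), (97.77, 0.29), (99.41, 0.15), (99.84, 0.08), (99.94, 0.05),
                    (99.97, 0.03)) + ((99.98, 0.03),) * 5,
    "uncle": ((2.78, 0.32), (14.39, 0.69), (35.66, 0.94), (61.10, 0.96), (81.24, 0.77),
              (92.65, 0.51), (97.79, 0.29), (99.49, 0.14), (99.92, 0.06)) + ((99.98, 0.03),) * 7,
    "half_sibling": ((2.58, 0.31), (14.05, 0.68), (35.15, 0.94), (60.81, 0.96), (80.60, 0.78),
                     (92.64, 0.51), (97.62, 0.30), (99.42, 0.15), (99.88, 0.07), (99.96, 0.04)) + ((99.98, 0.03),) * 6,
    "cousin": ((0.51, 0.14), (2.60, 0.31), (9.86, 0.58), (24.41, 0.84), (45.07, 0.98),
               (67.12, 0.92), (84.74, 0.70), (93.82, 0.47), (97.92, 0.28), (99.46, 0.14),
               (99.89, 0.06), (99.97, 0.03)) + ((99.98, 0.03),) * 4,
    "random_man": ((0.04, 0.04), (0.36, 0.12), (1.69, 0.25), (6.01, 0.47), (15.91, 0.72),
                   (32.85, 0.92), (53.97, 0.98), (73.44, 0.87), (87.90, 0.64), (95.52, 0.41),
                   (98.73, 0.22), (99.70, 0.11), (99.93, 0.05), (99.96, 0.04), (99.98, 0.03), (99.98, 0.03)),
}

TRIO_RATE_CELLS: dict[str, tuple[tuple[float, float], ...]] = {
    "parent": ((99.98, 0.03),) * 16,
    "uncle": ((0.56, 0.15), (3.57, 0.36), (12.91, 0.66), (30.54, 0.90), (52.63, 0.98),
              (73.01, 0.87), (88.02, 0.64), (95.54, 0.40), (98.57, 0.23), (99.63, 0.12),
              (99.89, 0.06)) + ((99.98, 0.03),) * 5,
    "sibling": ((0.51, 0.14), (4.28, 0.40), (14.90, 0.70), (33.69, 0.93), (56.12, 0.97),
                (76.27, 0.83), (89.52, 0.60), (96.07, 0.38), (98.78, 0.22), (99.69, 0.11),
                (99.94, 0.05)) + ((99.98, 0.03),) * 5,
    "half_sibling": ((0.46, 0.13), (3.52, 0.36), (12.66, 0.65), (29.59, 0.89), (52.60, 0.98),
                     (73.30, 0.87), (88.47, 0.63), (95.81, 0.39), (98.72, 0.22), (99.73, 0.10),
                     (99.96, 0.04)) + ((99.98, 0.03),) * 5,
    "grandparent": ((0.38, 0.12), (3.53, 0.36), (12.91, 0.66), (29.59, 0.89), (51.28, 0.98),
                    (72.41, 0.88), (87.30, 0.65), (95.37, 0.41), (98.74, 0.22), (99.63, 0.12),
                    (99.93, 0.05)) + ((99.98, 0.03),) * 5,
    "cousin": ((0.03, 0.03), (0.23, 0.09), (1.20, 0.21), (4.38, 0.40), (12.73, 0.65),
               (27.30, 0.87), (46.73, 0.98), (66.57, 0.92), (83.06, 0.74), (93.25, 0.49),
               (97.96, 0.28), (99.43, 0.15), (99.88, 0.07)) + ((99.98, 0.03),) * 3,
    "random_man": ((0.02, 0.03), (0.03, 0.03), (0.06, 0.05), (0.20, 0.09), (1.02, 0.20),
                   (3.47, 0.36), (10.02, 0.59), (22.52, 0.82), (41.64, 0.97), (62.54, 0.95),
                   (80.72, 0.77), (92.31, 0.52), (97.79, 0.29), (99.56, 0.13), (99.95, 0.04), (99.98, 0.03)),
}

CUMULATIVE_COUNTS = {"duo": DUO_CUMULATIVE_COUNTS, "trio": TRIO_CUMULATIVE_COUNTS}
RATE_CELLS = {"duo": DUO_RATE_CELLS, "trio": TRIO_RATE_CELLS}


@dataclass(frozen=True)
class ReferenceLRRow:
    """One reported Log LR summary row (with probability-of-paternity %)."""

    relationship: str
    n_nonexcluded: int
    min_log_lr: float | None
    min_probability: float | None
    max_log_lr: float | None
    max_probability: float | None
    mean_log_lr: float | None
    ci_half_width: float | None
    mean_probability: float | None


DUO_LOG_LR_ROWS: tuple[ReferenceLRRow, ...] = (
    ReferenceLRRow("parent", 10000, 1.4845, 96.8268, 11.4087, 100.0000, 5.0207, 0.0247, 99.9990),
    ReferenceLRRow("sibling", 1902, 1.2337, 94.4836, 10.4002, 100.0000, 5.6010, 0.0577, 99.9997),
    ReferenceLRRow("grandparent", 279, 1.5582, 97.3088, 7.9826, 100.0000, 4.0263, 0.1346, 99.9906),
    ReferenceLRRow("uncle", 276, 1.6478, 97.7994, 8.5425, 100.0000, 4.2644, 0.1412, 99.9946),
    ReferenceLRRow("half_sibling", 256, 1.0975, 92.6019, 6.8732, 100.0000, 4.2150, 0.1343, 99.9939),
    ReferenceLRRow("cousin", 49, 0.7880, 85.9897, 6.1611, 99.9999, 3.4479, 0.3127, 99.9644),
    ReferenceLRRow("random_man", 2, 2.8206, 99.8491, 3.2468, 99.9434, 3.0337, 2.7075, 99.9076),
)

TRIO_LOG_LR_ROWS: tuple[ReferenceLRRow, ...] = (
    ReferenceLRRow("parent", 10000, 4.0061, 99.9901, 16.0957, 100.0000, 7.4741, 0.0266, 100.0000),
    ReferenceLRRow("uncle", 54, 4.1748, 99.9933, 9.3911, 100.0000, 6.7822, 0.2991, 100.0000),
    ReferenceLRRow("sibling", 49, 4.9335, 99.9988, 9.9194, 100.0000, 6.9927, 0.3519, 100.0000),
    ReferenceLRRow("half_sibling", 44, 4.9754, 99.9989, 10.4723, 100.0000, 7.1267, 0.4025, 100.0000),
    ReferenceLRRow("grandparent", 36, 5.0455, 99.9991, 8.6544, 100.0000, 6.7147, 0.3326, 100.0000),
    ReferenceLRRow("cousin", 1, 7.6185, 100.0000, 7.6185, 100.0000, None, None, None),
    ReferenceLRRow("random_man", 0, None, None, None, None, None, None, None),
)


def nonconformity_counts(mode: str) -> dict[str, tuple[int, ...]]:
    if mode == "duo":
        return dict(DUO_NONCONFORMITY_COUNTS)
    if mode == "trio":
        return dict(TRIO_NONCONFORMITY_COUNTS)
    raise ValueError(f"mode must be 'duo' or 'trio', got {mode!r}")


def log_lr_rows(mode: str) -> tuple[ReferenceLRRow, ...]:
    return DUO_LOG_LR_ROWS if mode == "duo" else TRIO_LOG_LR_ROWS
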