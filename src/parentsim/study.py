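"""Full-study orchestration: model and results objects.

:class:`ParentageSimulation` holds the population model (a frequency panel)
and the study design (number of families, alpha, prior, relationships);
``fit(seed)`` simulates the families, evaluates every alleged-father
scenario in duo and trio mode, and returns a
:class:`ParentageSimulationResults` carrying the non-conformity tables,
the per-pair likelihood ratios, the Log LR summaries, a ``summary()``
rendering and CSV writers.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exclusion import NonConformityTable, table_from_counts
from .frequencies import FrequencySet, generate_synthetic_frequencies, read_frequency_csv
from .paternity import (
    LRSummary,
    duo_pi_array,
    log_lr_array,
    probability_of_paternity,
    summarize_log_lr,
    trio_pi_array,
)
from .pedigree import RELATIONSHIPS, Population, scenario_pairing, simulate_population

logger = logging.getLogger(__name__)

MODES = ("duo", "trio")


@dataclass
class StudyConfig:
    """Configuration of one study run.

    ``freq_file`` selects a real allele-frequency CSV; when None a synthetic
    panel is generated from ``n_loci`` / ``allele_count_range`` /
    ``concentration`` using ``seed``.
    """

    n_families: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    prior: float = 0.5
    freq_file: str | None = None
    n_loci: int = 15
    allele_count_range: tuple[int, int] = (8, 15)
    concentration: float = 1.0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.prior < 1:
            raise ValueError("prior must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "allele_count_range" in raw:
            raw["allele_count_range"] = tuple(raw["allele_count_range"])
        return cls(**raw)


class ParentageSimulation:
    """Monte Carlo model of false inclusion in duo/trio paternity testing.

    Parameters
    ----------
    freqs
        The population's STR allele-frequency panel.
    n_families
        Number of independent three-generation families to simulate.
    alpha
        Significance level of the Agresti-Coull and t-based intervals.
    prior
        Prior probability of paternity for posterior conversions.
    relationships
        Alleged-father relationships to evaluate (default: all seven).
    """

    def __init__(
        self,
        freqs: FrequencySet,
        n_families: int = 10_000,
        alpha: float = 0.05,
        prior: float = 0.5,
        relationships: tuple[str, ...] = RELATIONSHIPS,
    ):
        if n_families < 1:
            raise ValueError("n_families must be >= 1")
        unknown = set(relationships) - set(RELATIONSHIPS)
        if unknown:
            raise ValueError(f"unknown relationships: {sorted(unknown)}")
        self.freqs = freqs
        self.n_families = n_families
        self.alpha = alpha
        self.prior = prior
        self.relationships = tuple(relationships)

    @classmethod
    def from_frequency_csv(cls, path, **kwargs) -> "ParentageSimulation":
        return cls(read_frequency_csv(path), **kwargs)

    @classmethod
    def from_config(cls, config: StudyConfig) -> "ParentageSimulation":
        if config.freq_file:
            freqs = read_frequency_csv(config.freq_file)
        else:
            freqs = generate_synthetic_frequencies(
                n_loci=config.n_loci,
                allele_count_range=config.allele_count_range,
                concentration=config.concentration,
                seed=np.random.SeedSequence(config.seed).spawn(1)[0],
            )
        return cls(
            freqs,
            n_families=config.n_families,
            alpha=config.alpha,
            prior=config.prior,
        )

    def fit(self, seed: int = 0) -> "ParentageSimulationResults":
        """Simulate the population and evaluate every scenario.

        Deterministic given (model, seed): the seed drives family
        simulation only; all downstream statistics are exact functions of
        the genotypes.
        """
        t0 = time.perf_counter()
        master = np.random.SeedSequence(seed)
        population = simulate_population(self.freqs, self.n_families, master.spawn(1)[0])
        t_sim = time.perf_counter() - t0
        logger.info(
            "simulated %d families x %d loci in %.1f s (mean heterozygosity %.3f)",
            self.n_families, self.freqs.n_loci, t_sim, self.freqs.mean_heterozygosity(),
        )

        freq_matrix = self.freqs.frequency_matrix()
        arrays = population.role_arrays
        mismatch_counts: dict[tuple[str, str], np.ndarray] = {}
        log_lrs: dict[tuple[str, str], np.ndarray] = {}
        tables: dict[tuple[str, str], NonConformityTable] = {}
        lr_summaries: dict[tuple[str, str], LRSummary] = {}
        timings: dict[str, float] = {"simulate": t_sim}
        for relationship in self.relationships:
            t1 = time.perf_counter()
            for mode in MODES:
                pairing = scenario_pairing(relationship, mode)
                father = arrays[pairing.alleged_father_role]
                child = arrays[pairing.child_role]
                if mode == "duo":
                    pi = duo_pi_array(father, child, freq_matrix)
                else:
                    pi = trio_pi_array(
                        father, arrays[pairing.mother_role], child, freq_matrix
                    )
                k = (pi == 0.0).sum(axis=1)
                mismatch_counts[(relationship, mode)] = k
                log_lrs[(relationship, mode)] = log_lr_array(pi)
                tables[(relationship, mode)] = table_from_counts(
                    relationship, mode, np.bincount(k, minlength=self.freqs.n_loci + 1),
                    self.alpha,
                )
                lr_summaries[(relationship, mode)] = summarize_log_lr(
                    log_lrs[(relationship, mode)],
                    relationship=relationship,
                    mode=mode,
                    alpha=self.alpha,
                    prior=self.prior,
                )
            timings[relationship] = time.perf_counter() - t1
            logger.info("evaluated %s in %.2f s", relationship, timings[relationship])
        return ParentageSimulationResults(
            model=self,
            seed=seed,
            population=population,
            mismatch_counts=mismatch_counts,
            log_lrs=log_lrs,
            tables=tables,
            lr_summaries=lr_summaries,
            timings=timings,
        )


def _fmt(value: float | None, digits: int = 4) -> str:
    return "-" if value is None else f"{value:.{digits}f}"


@dataclass
class ParentageSimulationResults:
    """Fitted study: exclusion tables, LR summaries and renderings."""

    model: ParentageSimulation
    seed: int
    population: Population
    mismatch_counts: dict[tuple[str, str], np.ndarray]
    log_lrs: dict[tuple[str, str], np.ndarray]
    tables: dict[tuple[str, str], NonConformityTable]
    lr_summaries: dict[tuple[str, str], LRSummary]
    timings: dict[str, float] = field(default_factory=dict)

    # -- accessors ---------------------------------------------------------

    def nonconformity_table(self, relationship: str, mode: str) -> NonConformityTable:
        return self.tables[(relationship, mode)]

    def lr_summary(self, relationship: str, mode: str) -> LRSummary:
        return self.lr_summaries[(relationship, mode)]

    def k0_rate(self, relationship: str, mode: str):
        """Accumulative non-exclusion rate at zero mismatches (the headline risk)."""
        return self.tables[(relationship, mode)].rate_by_k[0]

    @property
    def provenance(self) -> dict:
        model = self.model
        return {
            "seed": self.seed,
            "n_families": model.n_families,
            "alpha": model.alpha,
            "prior": model.prior,
            "relationships": list(model.relationships),
            "n_loci": model.freqs.n_loci,
            "locus_names": model.freqs.locus_names,
            "mean_heterozygosity": model.freqs.mean_heterozygosity(),
        }

    # -- rendering ---------------------------------------------------------

    def nonconformity_frame(self, mode: str) -> pd.DataFrame:
        """Machine-readable table: one row per relationship x table-row."""
        L = self.model.freqs.n_loci
        rows = []
        for relationship in self.model.relationships:
            table = self.tables[(relationship, mode)]
            for row_name, values in (
                ("count", table.counts_by_k),
                ("cumulative", table.cumulative_by_k),
                ("rate_center", [r.center_rounded for r in table.rate_by_k]),
                ("rate_halfwidth", [r.half_width_rounded for r in table.rate_by_k]),
            ):
                rows.append(
                    {"relationship": relationship, "mode": mode, "row": row_name}
                    | {f"k{i}": values[i] for i in range(L + 1)}
                )
        return pd.DataFrame(rows)

    def nonconformity_frame_pretty(self, mode: str) -> pd.DataFrame:
        """Human-readable variant with '19.03 ± 0.77'-style rate cells."""
        L = self.model.freqs.n_loci
        rows = []
        for relationship in self.model.relationships:
            table = self.tables[(relationship, mode)]
            for row_name, values in (
                ("I", [str(c) for c in table.counts_by_k]),
                ("II", [str(c) for c in table.cumulative_by_k]),
                ("III", [str(r) for r in table.rate_by_k]),
            ):
                rows.append(
                    {"relationship": relationship, "row": row_name}
                    | {f"k{i}": values[i] for i in range(L + 1)}
                )
        return pd.DataFrame(rows)

    def lr_summary_frame(self) -> pd.DataFrame:
        """Log LR summary rows for both modes (the Table 2/4 shape)."""
        rows = []
        for mode in MODES:
            for relationship in self.model.relationships:
                s = self.lr_summaries[(relationship, mode)]
                rows.append(
                    {
                        "relationship": relationship,
                        "mode": mode,
                        "n_nonexcluded": s.n_nonexcluded,
                        "min_log_lr": s.min_log_lr,
                        "min_probability_pct": s.min_probability,
                        "max_log_lr": s.max_log_lr,
                        "max_probability_pct": s.max_probability,
                        "mean_log_lr": s.mean_log_lr,
                        "ci_half_width": s.ci_half_width,
                        "mean_probability_pct": s.mean_probability,
                    }
                )
        return pd.DataFrame(rows)

    def pair_records_frame(self) -> pd.DataFrame:
        """Per-pair records: mismatch count and log LR for every evaluation."""
        frames = []
        for (relationship, mode), k in self.mismatch_counts.items():
            log_lr = self.log_lrs[(relationship, mode)]
            excluded = np.isnan(log_lr)
            prob = np.full_like(log_lr, np.nan)
            prob[~excluded] = [
                probability_of_paternity(10.0**v, self.model.prior)
                for v in log_lr[~excluded]
            ]
            frames.append(
                pd.DataFrame(
                    {
                        "relationship": relationship,
                        "mode": mode,
                        "family_id": np.arange(len(k)),
                        "k": k,
                        "log_lr": log_lr,
                        "probability_pct": prob,
                        "excluded": excluded,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        """Plain-text overview of the fitted study."""
        model = self.model
        lines = [
            "Parentage false-inclusion simulation",
            "=" * 68,
            f"families: {model.n_families}    loci: {model.freqs.n_loci}    "
            f"seed: {self.seed}    alpha: {model.alpha}    prior: {model.prior}",
            f"panel mean heterozygosity: {model.freqs.mean_heterozygosity():.3f}",
            "",
            "Non-exclusion rate at zero mismatching loci (% ± half-width)",
            f"{'relationship':<14}{'duo':>18}{'trio':>18}",
            "-" * 50,
        ]
        for relationship in model.relationships:
            duo = self.k0_rate(relationship, "duo")
            trio = self.k0_rate(relationship, "trio")
            lines.append(f"{relationship:<14}{str(duo):>18}{str(trio):>18}")
        lines += [
            "",
            "Log10 LR over non-excluded pairs (mean ± CI half-width; W = posterior %)",
            f"{'relationship':<14}{'mode':<6}{'n':>6}{'min':>9}{'max':>9}"
            f"{'mean':>9}{'±':>9}{'W(mean)':>10}",
            "-" * 72,
        ]
        for mode in MODES:
            for relationship in model.relationships:
                s = self.lr_summaries[(relationship, mode)]
                lines.append(
                    f"{relationship:<14}{mode:<6}{s.n_nonexcluded:>6}"
                    f"{_fmt(s.min_log_lr):>9}{_fmt(s.max_log_lr):>9}"
                    f"{_fmt(s.mean_log_lr):>9}{_fmt(s.ci_half_width):>9}"
                    f"{_fmt(s.mean_probability):>10}"
                )
        return "\n".join(lines)

    def to_csv(self, out_dir) -> dict[str, Path]:
        """Write all report artifacts; returns name -> path."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for mode in MODES:
            p = out / f"nonconformity_{mode}.csv"
            self.nonconformity_frame(mode).to_csv(p, index=False)
            paths[f"nonconformity_{mode}"] = p
            p = out / f"nonconformity_{mode}_pretty.csv"
            self.nonconformity_frame_pretty(mode).to_csv(p, index=False)
            paths[f"nonconformity_{mode}_pretty"] = p
        p = out / "lr_summary.csv"
        self.lr_summary_frame().to_csv(p, index=False)
        paths["lr_summary"] = p
        p = out / "pair_records.csv"
        self.pair_records_frame().to_csv(p, index=False)
        paths["pair_records"] = p
        p = out / "report.jsonl"
        with open(p, "w", encoding="utf-8") as fh:
            for (relationship, mode), table in self.tables.items():
                fh.write(
                    json.dumps(
                        {
                            "record": "nonconformity",
                            "relationship": relationship,
                            "mode": mode,
                            "counts": list(table.counts_by_k),
                            "cumulative": list(table.cumulative_by_k),
                            "rate_center": [r.center for r in table.rate_by_k],
                            "rate_half_width": [r.half_width for r in table.rate_by_k],
                        }
                    )
                    + "\n"
                )
            for (relationship, mode), s in self.lr_summaries.items():
                fh.write(json.dumps({"record": "log_lr"} | asdict(s)) + "\n")
        paths["report_jsonl"] = p
        p = out / "provenance.json"
        with open(p, "w", encoding="utf-8") as fh:
            json.dump(self.provenance | {"timings_s": self.timings}, fh, indent=2)
        paths["provenance"] = p
        p = out / "summary.txt"
        p.write_text(self.summary() + "\n", encoding="utf-8")
        paths["summary"] = p
        return paths


def run_study(config: StudyConfig) -> ParentageSimulationResults:
    """Run the full study described by a config; write outputs if requested."""
    model = ParentageSimulation.from_config(config)
    results = model.fit(seed=config.seed)
    if config.out_dir:
        paths = results.to_csv(config.out_dir)
        logger.info("wrote %d report files to %s", len(paths), config.out_dir)
    return results


def render_tables(results: ParentageSimulationResults, out_dir) -> dict[str, Path]:
    """Write the four report tables (and companions); idempotent."""
    return results.to_csv(out_dir)
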