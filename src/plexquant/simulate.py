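"""Synthetic multiplexed-proteomics experiment generator with ground truth.

Emulates the statistical structure of a 4-channel isobaric reporter-ion
experiment run as two replicate pools: log-normal protein abundances, several
peptides per protein with per-peptide ionization efficiencies (log-normal,
constant across channels and pools, so ratios cancel them), a fraction of
peptide sequences shared between two parent proteins (their reporter signal is
the *sum* of the parents' contributions — the reason rollup is restricted to
unique peptides), multiplicative log-normal reporter noise, a spiked subset of
proteins with true fold changes applied to one channel group, and a term
annotation map whose planted terms are over-represented among the proteins
spiked in one group.

Everything is driven by a single integer seed: identical config implies
byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import AnnotationMap
from .errors import ConfigError, DataError
from .ingest import DEFAULT_CHANNEL_MAP, PSMTable

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_CHANNEL_GROUPS: tuple[tuple[str, str], ...] = tuple(DEFAULT_CHANNEL_MAP.items())


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    Defaults follow the benchmark design used throughout the test suite:
    200 proteins, 3-6 unique peptides each, 10% shared peptide sequences,
    two replicate pools over the four breed/stage channel groups, 20% of
    proteins spiked at fold changes {0.5, 0.67, 1.5, 2.0}, and 5% reporter
    noise (coefficient of variation, log-normal).
    """

    n_proteins: int = 200
    peptides_per_protein: tuple[int, int] = (3, 6)
    frac_shared_peptides: float = 0.10
    n_replicate_pools: int = 2
    channel_groups: tuple[tuple[str, str], ...] = DEFAULT_CHANNEL_GROUPS
    frac_spiked: float = 0.20
    spike_fc_values: tuple[float, ...] | None = (0.5, 0.67, 1.5, 2.0)
    spike_fc_range_up: tuple[float, float] = (1.5, 2.0)
    spike_fc_range_down: tuple[float, float] = (0.5, 0.70)
    cv_reporter: float = 0.05
    abundance_log_mean: float = 13.8  # natural-log scale, median intensity ~1e6
    abundance_log_sd: float = 1.0
    n_terms: int = 30
    frac_terms_enriched: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ConfigError("n_proteins must be positive")
        if self.n_replicate_pools <= 0:
            raise ConfigError("n_replicate_pools must be positive")
        if self.n_terms <= 0:
            raise ConfigError("n_terms must be positive")
        lo, hi = self.peptides_per_protein
        if lo < 1 or hi < lo:
            raise ConfigError(f"bad peptides_per_protein range {self.peptides_per_protein}")
        for name in ("frac_shared_peptides", "frac_spiked", "frac_terms_enriched"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.cv_reporter < 0:
            raise ConfigError("cv_reporter must be non-negative")
        if len(self.channel_groups) != 4:
            raise ConfigError("exactly 4 channel groups are required")
        tags = [t for _, t in self.channel_groups]
        labels = [g for g, _ in self.channel_groups]
        if len(set(tags)) != 4 or len(set(labels)) != 4:
            raise ConfigError("channel group labels and tags must be distinct")
        if self.spike_fc_range_up[0] < 1.3:
            raise ConfigError("spike_fc_range_up lower bound must be >= 1.3")
        if self.spike_fc_range_down[1] > 0.70:
            raise ConfigError("spike_fc_range_down upper bound must be <= 0.70")
        if self.spike_fc_values is not None:
            for v in self.spike_fc_values:
                if not (v <= 0.70 or v >= 1.3):
                    raise ConfigError(
                        f"spike fold changes must lie outside (0.70, 1.3), got {v}"
                    )
        if self.abundance_log_sd < 0:
            raise ConfigError("abundance_log_sd must be non-negative")

    @property
    def group_labels(self) -> list[str]:
        return [g for g, _ in self.channel_groups]

    @property
    def channel_map(self) -> dict[str, str]:
        return dict(self.channel_groups)


@dataclass
class GroundTruth:
    """Per-protein and per-term truth of one simulated experiment."""

    baseline: pd.Series  # protein -> base abundance
    multipliers: pd.DataFrame  # protein x group -> abundance multiplier
    spiked: pd.Series  # protein -> bool
    spike_group: pd.Series  # protein -> group label ('' for nulls)
    enriched_terms: dict[str, str]  # term_id -> group the planting targets
    peptide_map: dict[str, tuple[str, ...]]  # sequence -> parent proteins
    shared_peptides: set[str]

    @property
    def proteins(self) -> list[str]:
        return list(self.multipliers.index)

    def true_fc(self, case_group: str, control_group: str) -> pd.Series:
        """True fold change of every protein in case vs control (1.0 for nulls)."""
        return self.multipliers[case_group] / self.multipliers[control_group]

    def to_dir(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        prot = self.multipliers.copy()
        prot.columns = [f"mult_{g}" for g in prot.columns]
        prot.insert(0, "baseline", self.baseline)
        prot.insert(0, "spike_group", self.spike_group)
        prot.insert(0, "spiked", self.spiked)
        prot.rename_axis("protein_id").reset_index().to_csv(
            out_dir / "truth_proteins.tsv", sep="\t", index=False, float_format="%.10g"
        )
        pd.DataFrame(
            [{"term_id": t, "target_group": g} for t, g in sorted(self.enriched_terms.items())],
            columns=["term_id", "target_group"],
        ).to_csv(out_dir / "truth_enriched_terms.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "peptide_sequence": s,
                    "protein_ids": ";".join(ps),
                    "shared": s in self.shared_peptides,
                }
                for s, ps in sorted(self.peptide_map.items())
            ],
            columns=["peptide_sequence", "protein_ids", "shared"],
        ).to_csv(out_dir / "truth_peptides.tsv", sep="\t", index=False)


def _random_peptide(rng: np.random.Generator, existing: set[str]) -> str:
    while True:
        length = int(rng.integers(8, 16))
        seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), length))
        if seq not in existing:
            existing.add(seq)
            return seq


def generate_experiment(
    config: SimulationConfig,
) -> tuple[list[PSMTable], AnnotationMap, GroundTruth]:
    """Simulate PSM tables (one per replicate pool), an annotation map, and truth.

    Expected reporter intensity of peptide ``q`` in channel group ``g``:
    ``sum over parent proteins i of baseline_i * multiplier_{i,g}``, times the
    peptide's ionization factor, times log-normal noise with coefficient of
    variation ``cv_reporter`` (drawn independently per peptide, pool and
    channel; exactly 1 when ``cv_reporter`` is 0).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    groups = cfg.group_labels
    proteins = [f"P{i:04d}" for i in range(1, cfg.n_proteins + 1)]

    baseline = pd.Series(
        np.exp(rng.normal(cfg.abundance_log_mean, cfg.abundance_log_sd, cfg.n_proteins)),
        index=proteins,
        name="baseline",
    )

    # Spiked proteins: a fold change applied to one channel group's multiplier.
    n_spiked = int(round(cfg.frac_spiked * cfg.n_proteins))
    spiked_ids = sorted(rng.choice(proteins, size=n_spiked, replace=False))
    mult = pd.DataFrame(1.0, index=proteins, columns=groups)
    spike_group = pd.Series("", index=proteins, dtype=object)
    for pid in spiked_ids:
        g = groups[int(rng.integers(0, len(groups)))]
        if cfg.spike_fc_values is not None:
            fc = float(cfg.spike_fc_values[int(rng.integers(0, len(cfg.spike_fc_values)))])
        elif rng.random() < 0.5:
            fc = float(rng.uniform(*cfg.spike_fc_range_up))
        else:
            fc = float(rng.uniform(*cfg.spike_fc_range_down))
        mult.loc[pid, g] = fc
        spike_group[pid] = g
    spiked = pd.Series(mult.index.isin(spiked_ids), index=proteins, name="spiked")

    # Peptides: a fixed number of unique peptides per protein, plus shared
    # sequences carried by two parents.  frac_shared_peptides is the fraction
    # of all peptide sequences that are shared.
    existing: set[str] = set()
    peptide_map: dict[str, tuple[str, ...]] = {}
    lo, hi = cfg.peptides_per_protein
    for pid in proteins:
        for _ in range(int(rng.integers(lo, hi + 1))):
            peptide_map[_random_peptide(rng, existing)] = (pid,)
    n_unique = len(peptide_map)
    shared_peptides: set[str] = set()
    if cfg.frac_shared_peptides > 0 and cfg.n_proteins >= 2:
        n_shared = int(round(cfg.frac_shared_peptides * n_unique / (1 - cfg.frac_shared_peptides)))
        for _ in range(n_shared):
            pair = rng.choice(proteins, size=2, replace=False)
            seq = _random_peptide(rng, existing)
            peptide_map[seq] = (str(pair[0]), str(pair[1]))
            shared_peptides.add(seq)
    sequences = sorted(peptide_map)
    ion_factor = {s: float(np.exp(rng.normal(0.0, 0.5))) for s in sequences}

    sigma = math.sqrt(math.log1p(cfg.cv_reporter**2)) if cfg.cv_reporter > 0 else 0.0
    tables: list[PSMTable] = []
    for pool_idx in range(1, cfg.n_replicate_pools + 1):
        pool_id = f"pool{pool_idx}"
        rows: dict[str, list] = {c: [] for c in ("spectrum_id", "peptide_sequence", "protein_ids", "ion_score", "qvalue")}
        intensities: dict[str, list[float]] = {g: [] for g in groups}
        for scan, seq in enumerate(sequences, start=1):
            parents = peptide_map[seq]
            rows["spectrum_id"].append(f"{pool_id}_scan{scan:06d}")
            rows["peptide_sequence"].append(seq)
            rows["protein_ids"].append(parents)
            rows["ion_score"].append(float(rng.uniform(25.0, 110.0)))
            rows["qvalue"].append(float(rng.uniform(0.0, 0.009)))
            for g in groups:
                expected = sum(baseline[p] * mult.loc[p, g] for p in parents) * ion_factor[seq]
                if sigma > 0:
                    expected *= float(np.exp(rng.normal(0.0, sigma)))
                intensities[g].append(expected)
        df = pd.DataFrame(rows)
        for g, tag in cfg.channel_groups:
            df[f"intensity_{tag}"] = intensities[g]
        tables.append(PSMTable(df=df, pool_id=pool_id, channel_map=cfg.channel_map))

    annotation, enriched_target = _generate_annotation(
        cfg, rng, proteins, spiked_ids, spike_group
    )
    truth = GroundTruth(
        baseline=baseline,
        multipliers=mult,
        spiked=spiked,
        spike_group=spike_group,
        enriched_terms=enriched_target,
        peptide_map=peptide_map,
        shared_peptides=shared_peptides,
    )
    return tables, annotation, truth


def _generate_annotation(cfg, rng, proteins, spiked_ids, spike_group):
    """Build the annotation map; planted (enriched) terms draw ~80% of their
    members from proteins spiked in one target group."""
    n_enriched = int(round(cfg.frac_terms_enriched * cfg.n_terms))
    groups = cfg.group_labels
    terms: dict[str, tuple[str, str]] = {}
    p2t: dict[str, set[str]] = {p: set() for p in proteins}
    enriched_target: dict[str, str] = {}

    spiked_by_group = {
        g: [p for p in spiked_ids if spike_group[p] == g] for g in groups
    }
    background_ns = ["BP", "MF", "CC", "PATHWAY"]
    for j in range(cfg.n_terms):
        if j < n_enriched:
            term_id = f"GO:{7000000 + j:07d}"
            terms[term_id] = ("BP", f"planted process {j}")
            g = groups[j % len(groups)]
            enriched_target[term_id] = g
            k = int(rng.integers(8, 14))
            pool = spiked_by_group[g]
            n_from_spiked = min(len(pool), int(round(0.8 * k)))
            members = list(rng.choice(pool, size=n_from_spiked, replace=False)) if n_from_spiked else []
            others = [p for p in proteins if p not in members]
            n_fill = min(len(others), k - len(members))
            members += list(rng.choice(others, size=n_fill, replace=False))
        else:
            ns = background_ns[j % len(background_ns)]
            term_id = f"map{10000 + j:05d}" if ns == "PATHWAY" else f"GO:{1000000 + j:07d}"
            terms[term_id] = (ns, f"background {ns.lower()} term {j}")
            k = int(rng.integers(5, 21))
            members = list(rng.choice(proteins, size=min(k, len(proteins)), replace=False))
        for p in members:
            p2t[str(p)].add(term_id)

    # Every protein carries at least one annotation.
    background_terms = [t for t in terms if t not in enriched_target]
    for p in proteins:
        if not p2t[p] and background_terms:
            p2t[p].add(background_terms[int(rng.integers(0, len(background_terms)))])

    ann = AnnotationMap(
        protein_to_terms={p: frozenset(ts) for p, ts in p2t.items()},
        terms=terms,
    )
    return ann, enriched_target


def generate_densitometry(
    truth: GroundTruth,
    proteins: list[str],
    noise_cv: float = 0.05,
    seed: int = 0,
    n_lanes: int = 3,
) -> pd.DataFrame:
    """Synthetic western-blot band/actin intensities tracking the true fold changes.

    Per lane the band intensity is ``band_base * multiplier_group * noise``
    and actin is ``actin_base * noise``; when ``noise_cv > 0`` a shared
    per-lane loading factor multiplies both (it cancels under actin
    normalization).  With ``noise_cv = 0`` the actin-normalized group ratios
    equal the true fold changes exactly.
    """
    unknown = [p for p in proteins if p not in truth.multipliers.index]
    if unknown:
        raise DataError(f"unknown protein(s): {', '.join(unknown)}")
    if noise_cv < 0:
        raise ConfigError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(noise_cv**2)) if noise_cv > 0 else 0.0
    actin_base, band_base = 1000.0, 600.0
    rows = []
    for protein in proteins:
        for group in truth.multipliers.columns:
            m = truth.multipliers.loc[protein, group]
            for lane in range(1, n_lanes + 1):
                if sigma > 0:
                    load = float(np.exp(rng.normal(0.0, 0.2)))
                    band = band_base * m * load * float(np.exp(rng.normal(0.0, sigma)))
                    actin = actin_base * load * float(np.exp(rng.normal(0.0, sigma)))
                else:
                    band = band_base * m
                    actin = actin_base
                rows.append(
                    {
                        "protein": protein,
                        "group": group,
                        "lane": lane,
                        "band_intensity": band,
                        "actin_intensity": actin,
                    }
                )
    return pd.DataFrame(rows)


def fixture_fetal_counts() -> pd.DataFrame:
    """Per-sow viable-fetus counts reproducing the study's printed group
    summaries: MSD49 16.3 +/- 0.47, MSD72 14.3 +/- 0.47, DUD49 11 +/- 0.82,
    DUD72 8.67 +/- 0.47 (population SD, n = 3 sows per group)."""
    design = {
        "MSD49": [16, 16, 17],
        "MSD72": [14, 14, 15],
        "DUD49": [10, 11, 12],
        "DUD72": [8, 9, 9],
    }
    rows = [
        {"group": g, "sow_id": f"{g}_sow{i}", "viable_fetuses": c}
        for g, counts in design.items()
        for i, c in enumerate(counts, start=1)
    ]
    return pd.DataFrame(rows, columns=["group", "sow_id", "viable_fetuses"])
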