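"""Synthetic multi-platform two-class expression data.

Generates datasets with overlapping but unequal gene universes, a planted
gene set overexpressed in the favorable-outcome (FO) class on every
platform, per-platform additive offsets, lymph-node-contaminated FO
samples, class-dependent exponential survival times, and a dense cell-type
enrichment-score fixture. Everything is reproducible from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from rrhosig.dataset import FO, PO, ExpressionDataset

# per-platform additive location shift; downstream ranking must be
# invariant to it (tested)
PLATFORM_OFFSET = 2.0

# rng stream salts so study-level and table-level draws never collide
# with per-platform streams seeded as (seed, platform_index)
_STUDY_SALT = 10_007
_ENRICHMENT_SALT = 20_011


@dataclass
class SimulationConfig:
    """Knobs for the multi-platform study generator."""

    n_platforms: int = 3
    genes_per_platform: int = 5000
    shared_gene_fraction: float = 0.7
    n_signature_genes: int = 200
    effect_size: float = 2.0  # standardized mean difference, units of noise SD
    noise_sd: float = 1.0
    n_fo: int = 10
    n_po: int = 10
    n_contaminated_fo: int = 0
    contamination_boost: float = 6.0
    n_lymph_classifiers: int = 6
    survival_scale_fo: float = 60.0  # mean survival, months
    survival_scale_po: float = 12.0
    censor_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_platforms": self.n_platforms,
            "genes_per_platform": self.genes_per_platform,
            "n_signature_genes": self.n_signature_genes,
            "n_fo": self.n_fo,
            "n_po": self.n_po,
            "n_contaminated_fo": self.n_contaminated_fo,
            "n_lymph_classifiers": self.n_lymph_classifiers,
        }
        for name, v in counts.items():
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        for name in ("shared_gene_fraction", "censor_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be positive, got {self.noise_sd!r}")
        if self.n_contaminated_fo > self.n_fo:
            raise ValueError("n_contaminated_fo exceeds n_fo")
        n_shared = self.n_shared_genes
        if self.n_signature_genes + self.n_lymph_classifiers > n_shared:
            raise ValueError(
                f"signature ({self.n_signature_genes}) + lymph classifiers "
                f"({self.n_lymph_classifiers}) exceed the shared universe ({n_shared})"
            )

    @property
    def n_shared_genes(self) -> int:
        return int(round(self.shared_gene_fraction * self.genes_per_platform))


@dataclass
class StudyTruth:
    """Planted ground truth returned alongside the simulated datasets."""

    signature_genes: list[str]
    lymph_genes: list[str]
    contaminated_samples: dict[str, list[str]]  # platform id -> sample ids

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "StudyTruth":
        return cls(**json.loads(Path(path).read_text()))


def _gene_universes(config: SimulationConfig) -> tuple[list[str], list[list[str]]]:
    """Shared core + per-platform private genes.

    The core is common to all platforms, so pairwise and joint
    intersections coincide with it by construction.
    """
    n_shared = config.n_shared_genes
    n_private = config.genes_per_platform - n_shared
    shared = [f"GS{i:05d}" for i in range(n_shared)]
    universes = []
    for p in range(config.n_platforms):
        private = [f"GP{p}_{i:05d}" for i in range(n_private)]
        universes.append(shared + private)
    return shared, universes


def generate_dataset(
    config: SimulationConfig,
    platform_index: int,
    signature_genes,
    lymph_genes,
) -> ExpressionDataset:
    """Simulate one platform's probe × sample matrix.

    Baseline values are i.i.d. Gaussian(0, ``noise_sd``) plus an additive
    per-platform offset. Signature genes get ``effect_size × noise_sd``
    added in FO samples only; the first ``n_contaminated_fo`` FO samples
    get ``contamination_boost`` added on every lymph classifier gene.
    Survival times are exponential with the class-specific scale, then a
    random ``censor_fraction`` of samples is right-censored uniformly.
    """
    if not 0 <= platform_index < config.n_platforms:
        raise ValueError(f"platform_index {platform_index} out of range")
    if config.noise_sd <= 0:
        raise ValueError("noise_sd must be positive")

    _, universes = _gene_universes(config)
    genes = universes[platform_index]
    gene_set = set(genes)
    for g in list(signature_genes) + list(lymph_genes):
        if g not in gene_set:
            raise ValueError(f"gene {g!r} absent from platform {platform_index} universe")

    rng = np.random.default_rng((config.seed, platform_index))
    n_samples = config.n_fo + config.n_po
    values = rng.normal(0.0, config.noise_sd, size=(len(genes), n_samples))
    values += PLATFORM_OFFSET * platform_index

    pid = f"P{platform_index}"
    fo_ids = [f"{pid}_FO{i:02d}" for i in range(config.n_fo)]
    po_ids = [f"{pid}_PO{i:02d}" for i in range(config.n_po)]
    columns = fo_ids + po_ids
    classes = pd.Series([FO] * config.n_fo + [PO] * config.n_po, index=columns)

    gene_pos = {g: i for i, g in enumerate(genes)}
    sig_rows = [gene_pos[g] for g in signature_genes]
    if sig_rows and config.n_fo:
        values[np.ix_(sig_rows, range(config.n_fo))] += config.effect_size * config.noise_sd

    # lymph classifiers are background in pure tumor tissue: constant at the
    # platform baseline, elevated only by contamination — this makes the
    # downstream contamination filter's truth recovery deterministic
    lymph_rows = [gene_pos[g] for g in lymph_genes]
    if lymph_rows:
        values[lymph_rows, :] = PLATFORM_OFFSET * platform_index
    if lymph_rows and config.n_contaminated_fo:
        values[np.ix_(lymph_rows, range(config.n_contaminated_fo))] += config.contamination_boost

    scales = np.where(classes.values == FO, config.survival_scale_fo, config.survival_scale_po)
    times = rng.exponential(scales)
    events = np.ones(n_samples, dtype=int)
    censored = rng.random(n_samples) < config.censor_fraction
    times[censored] *= rng.random(int(censored.sum()))  # uniform censor time in (0, T)
    events[censored] = 0
    survival = pd.DataFrame({"time": times, "event": events}, index=columns)

    probe_ids = [f"{pid}_pr{i:05d}" for i in range(len(genes))]
    return ExpressionDataset(
        values=pd.DataFrame(values, index=probe_ids, columns=columns),
        probe_to_gene=pd.Series(genes, index=probe_ids),
        sample_classes=classes,
        survival=survival,
        platform_id=pid,
    )


def generate_study(config: SimulationConfig) -> tuple[list[ExpressionDataset], StudyTruth]:
    """Simulate all platforms plus the planted-truth record.

    Signature and lymph classifier genes are drawn (disjointly) from the
    gene core shared by every platform.
    """
    shared, _ = _gene_universes(config)
    if config.n_signature_genes + config.n_lymph_classifiers > len(shared):
        raise ValueError("requested signature larger than the joint gene intersection")

    rng = np.random.default_rng((config.seed, _STUDY_SALT))
    picked = rng.choice(
        len(shared),
        size=config.n_signature_genes + config.n_lymph_classifiers,
        replace=False,
    )
    signature_genes = sorted(shared[i] for i in picked[: config.n_signature_genes])
    lymph_genes = sorted(shared[i] for i in picked[config.n_signature_genes :])

    datasets = [
        generate_dataset(config, p, signature_genes, lymph_genes)
        for p in range(config.n_platforms)
    ]
    contaminated = {
        ds.platform_id: list(ds.class_samples(FO)[: config.n_contaminated_fo])
        for ds in datasets
    }
    truth = StudyTruth(
        signature_genes=signature_genes,
        lymph_genes=lymph_genes,
        contaminated_samples=contaminated,
    )
    return datasets, truth


def generate_enrichment_table(
    cell_types,
    probes,
    planted_assignments: dict,
    high_score: float = 700.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Dense probe × cell-type enrichment-score fixture.

    Planted (probe, cell type) cells score strictly above ``high_score``;
    every other cell scores strictly below it.
    """
    cell_types = list(cell_types)
    probes = list(probes)
    if not cell_types:
        raise ValueError("cell_types must be non-empty")
    probe_set = set(probes)
    ct_set = set(cell_types)
    for probe, ct in planted_assignments.items():
        if probe not in probe_set:
            raise ValueError(f"planted probe {probe!r} not in probe set")
        if ct not in ct_set:
            raise ValueError(f"planted cell type {ct!r} not in cell_types")

    rng = np.random.default_rng((seed, _ENRICHMENT_SALT))
    scores = rng.uniform(0.0, 0.9 * high_score, size=(len(probes), len(cell_types)))
    table = pd.DataFrame(scores, index=probes, columns=cell_types)
    for probe, ct in planted_assignments.items():
        table.loc[probe, ct] = high_score * (1.1 + 0.4 * rng.random())
    return table
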