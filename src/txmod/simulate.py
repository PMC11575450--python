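"""Synthetic sorted-cell references and condition-perturbed bulk mixtures.

Emulates the structure of a paired blood/bronchoalveolar-lavage (BAL)
transcriptomic cohort: sorted "mini-population" reference profiles for the major
immune cell types, bulk samples built as cell-type mixtures with
compartment-specific proportions (blood lymphocyte/monocyte-dominant, BAL
alveolar-macrophage-dominant), an HIV-like condition that halves the CD4
fraction and expands effector-memory CD8 T cells, and cytokine-inducible gene
programs switched on in affected compartments. Counts are negative-binomial
with a shared dispersion; every sample carries a known ground truth so each
downstream stage is testable without external data.

All randomness flows from one integer seed, split into named substreams, so any
output is bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io import CountMatrix, validate_sample_table

# substream keys (SeedSequence spawn keys) per operation
_STREAM_UNIVERSE = 0
_STREAM_REFERENCES = 1
_STREAM_BULK = 2
_STREAM_MEMORY = 3


@dataclass
class CellTypeSpec:
    name: str
    n_marker_genes: int = 20
    marker_log2_elevation: float = 6.0


@dataclass
class InducedProgram:
    """A cytokine-inducible gene program switched on by the condition."""

    name: str = "ifn_response"
    gene_set_size: int = 30
    log2fc: float = 1.5
    affected_compartments: tuple[str, ...] = ("blood",)


def _default_cell_types() -> list[CellTypeSpec]:
    return [CellTypeSpec(n) for n in
            ("CD4", "CD8_CM", "CD8_EM", "MAIT", "NK", "B", "monocyte", "macrophage")]


def _default_proportions() -> dict[str, dict[str, float]]:
    # blood: lymphocyte/monocyte dominant; BAL: alveolar-macrophage dominant
    return {
        "blood": {
            "CD4": 0.30, "CD8_CM": 0.12, "CD8_EM": 0.08, "MAIT": 0.05,
            "NK": 0.10, "B": 0.10, "monocyte": 0.23, "macrophage": 0.02,
        },
        "BAL": {
            "CD4": 0.10, "CD8_CM": 0.04, "CD8_EM": 0.06, "MAIT": 0.04,
            "NK": 0.04, "B": 0.02, "monocyte": 0.10, "macrophage": 0.60,
        },
    }


def _default_shifts() -> dict[str, float]:
    # condition effect: CD4 depletion, effector-memory CD8 expansion
    return {"CD4": 0.5, "CD8_EM": 1.8}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate a 2x2 design (blood/BAL x condition, 10 bulk samples per
    cell), negative-binomial counts with dispersion 0.2, library sizes
    log-uniform in [5e5, 2e6] (above the 500,000-read QC floor), and modest
    Dirichlet jitter of per-sample mixing fractions around the compartment
    means (concentration 200 x mean vector).
    """

    n_genes: int = 2000
    cell_types: list[CellTypeSpec] = field(default_factory=_default_cell_types)
    compartment_proportions: dict[str, dict[str, float]] = field(
        default_factory=_default_proportions
    )
    proportion_shifts: dict[str, float] = field(default_factory=_default_shifts)
    induced_programs: list[InducedProgram] = field(
        default_factory=lambda: [InducedProgram()]
    )
    nb_dispersion: float = 0.2
    library_size_range: tuple[int, int] = (500_000, 2_000_000)
    n_samples_per_group: int = 10
    dirichlet_concentration: float = 200.0
    memory_program_size: int = 30
    memory_fold: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        names = [ct.name for ct in self.cell_types]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate cell-type names")
        if self.n_genes <= 0 or self.nb_dispersion <= 0:
            raise ConfigError("n_genes and nb_dispersion must be positive")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ConfigError("library_size_range must be positive and ordered")
        budget = sum(ct.n_marker_genes for ct in self.cell_types)
        budget += sum(p.gene_set_size for p in self.induced_programs)
        budget += 2 * self.memory_program_size
        if budget > self.n_genes:
            raise ConfigError(
                f"marker/program budget ({budget}) exceeds n_genes ({self.n_genes})"
            )
        for comp, props in self.compartment_proportions.items():
            if set(props) != set(names):
                raise ConfigError(f"proportions for {comp!r} do not cover cell types")
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ConfigError(f"proportions for {comp!r} do not sum to 1")


@dataclass
class SimulationTruth:
    """Ground truth of a simulated dataset (the acceptance oracle)."""

    fractions: pd.DataFrame  # samples x cell types, rows sum to 1
    marker_map: dict[str, str]  # gene -> cognate cell type
    programs: dict[str, dict]  # program name -> {genes, log2fc, compartments}
    seed: int

    def __post_init__(self) -> None:
        sums = self.fractions.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ConfigError("truth fractions rows must sum to 1")


@dataclass
class GeneUniverse:
    """Deterministic gene-level layout shared by references and mixtures."""

    genes: list[str]
    base_weights: np.ndarray  # lognormal relative abundance, length n_genes
    markers: dict[str, np.ndarray]  # cell type -> marker gene indices
    program_indices: dict[str, np.ndarray]  # induced program name -> indices
    memory_indices: dict[str, np.ndarray]  # {"CD8_CM": ..., "CD8_EM": ...}


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def build_universe(config: GeneratorConfig) -> GeneUniverse:
    """Lay out marker blocks, induced programs and memory programs over the genes."""
    rng = _rng(config.seed, _STREAM_UNIVERSE)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    cursor = 0
    markers: dict[str, np.ndarray] = {}
    for ct in config.cell_types:
        markers[ct.name] = np.arange(cursor, cursor + ct.n_marker_genes)
        cursor += ct.n_marker_genes
    programs: dict[str, np.ndarray] = {}
    for prog in config.induced_programs:
        programs[prog.name] = np.arange(cursor, cursor + prog.gene_set_size)
        cursor += prog.gene_set_size
    memory: dict[str, np.ndarray] = {}
    for sub in ("CD8_CM", "CD8_EM"):
        memory[sub] = np.arange(cursor, cursor + config.memory_program_size)
        cursor += config.memory_program_size
    # Equalize each marker/program block's total base weight so that every
    # cell type's profile normalizer is identical: cell types then differ
    # only on their markers, not through compositional shifts of the
    # background genes (which would blur the simulation truth).
    block_mean = float(np.exp(0.5))  # lognormal(0, 1) mean
    for block in (*markers.values(), *memory.values()):
        base[block] *= block_mean * block.size / base[block].sum()
    return GeneUniverse(genes, base, markers, programs, memory)


def reference_profile(config: GeneratorConfig, universe: GeneUniverse,
                      cell_type: str) -> np.ndarray:
    """Relative expression profile (sums to 1) of one sorted cell type."""
    spec = {ct.name: ct for ct in config.cell_types}[cell_type]
    rel = universe.base_weights.copy()
    rel[universe.markers[cell_type]] *= 2.0 ** spec.marker_log2_elevation
    return rel / rel.sum()


def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-8:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _library_sizes(rng: np.random.Generator, n: int,
                   size_range: tuple[int, int]) -> np.ndarray:
    lo, hi = size_range
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)).astype(np.int64)


def simulate_reference_profiles(
    config: GeneratorConfig, replicates_per_type: int = 5
) -> tuple[CountMatrix, pd.DataFrame, SimulationTruth]:
    """Sorted-cell reference transcriptomes, ``replicates_per_type`` per type."""
    if replicates_per_type < 1:
        raise ConfigError("replicates_per_type must be >= 1")
    universe = build_universe(config)
    rng = _rng(config.seed, _STREAM_REFERENCES)
    names = [ct.name for ct in config.cell_types]
    columns, ids, meta_rows = [], [], []
    for ct in names:
        rel = reference_profile(config, universe, ct)
        libs = _library_sizes(rng, replicates_per_type, config.library_size_range)
        for r, lib in enumerate(libs):
            columns.append(_nb_counts(rng, rel * lib, config.nb_dispersion))
            sid = f"{ct}_ref{r:02d}"
            ids.append(sid)
            meta_rows.append(
                {"sample_id": sid, "compartment": "BAL", "condition": "HIVpos",
                 "cell_type": ct}
            )
    counts = CountMatrix(universe.genes, ids, np.column_stack(columns))
    meta = validate_sample_table(pd.DataFrame(meta_rows))
    fractions = pd.DataFrame(0.0, index=ids, columns=names)
    for sid, row in zip(ids, meta_rows):
        fractions.loc[sid, row["cell_type"]] = 1.0
    truth = SimulationTruth(
        fractions=fractions,
        marker_map={universe.genes[i]: ct for ct in names
                    for i in universe.markers[ct]},
        programs={},
        seed=config.seed,
    )
    return counts, meta, truth


def shifted_proportions(config: GeneratorConfig, compartment: str,
                        condition: str) -> dict[str, float]:
    """Compartment mixing proportions with condition shifts applied, renormalized."""
    props = dict(config.compartment_proportions[compartment])
    if condition == "HIVpos":
        for ct, factor in config.proportion_shifts.items():
            if ct in props:
                props[ct] *= factor
        total = sum(props.values())
        props = {ct: v / total for ct, v in props.items()}
    return props


def expected_mixture(config: GeneratorConfig, universe: GeneUniverse,
                     fractions: dict[str, float] | pd.Series,
                     compartment: str, condition: str) -> np.ndarray:
    """Analytic relative expression of a bulk sample (sums to 1).

    Mixture of reference profiles weighted by the true fractions, with induced
    programs applied multiplicatively for affected compartment/condition and
    the profile renormalized (a fixed sequencing depth is compositional).
    """
    mix = np.zeros(config.n_genes)
    for ct in (ct.name for ct in config.cell_types):
        mix += float(fractions[ct]) * reference_profile(config, universe, ct)
    if condition == "HIVpos":
        for prog in config.induced_programs:
            if compartment in prog.affected_compartments:
                mix[universe.program_indices[prog.name]] *= 2.0 ** prog.log2fc
    return mix / mix.sum()


def simulate_bulk_cohort(
    config: GeneratorConfig,
) -> tuple[CountMatrix, pd.DataFrame, SimulationTruth]:
    """Bulk mixtures for each compartment x condition cell of the design."""
    universe = build_universe(config)
    rng = _rng(config.seed, _STREAM_BULK)
    names = [ct.name for ct in config.cell_types]
    columns, ids, meta_rows, frac_rows = [], [], [], []
    for compartment in ("blood", "BAL"):
        for condition in ("HIVneg", "HIVpos"):
            props = shifted_proportions(config, compartment, condition)
            mean_vec = np.array([props[ct] for ct in names])
            alpha = config.dirichlet_concentration * mean_vec
            libs = _library_sizes(rng, config.n_samples_per_group,
                                  config.library_size_range)
            for i, lib in enumerate(libs):
                frac = rng.dirichlet(alpha)
                mix = expected_mixture(config, universe,
                                       dict(zip(names, frac)),
                                       compartment, condition)
                columns.append(_nb_counts(rng, mix * lib, config.nb_dispersion))
                sid = f"{compartment}_{condition}_s{i:02d}"
                ids.append(sid)
                meta_rows.append(
                    {"sample_id": sid, "compartment": compartment,
                     "condition": condition, "cell_type": "bulk"}
                )
                frac_rows.append(frac)
    counts = CountMatrix(universe.genes, ids, np.column_stack(columns))
    meta = validate_sample_table(pd.DataFrame(meta_rows))
    programs = {
        prog.name: {
            "genes": [universe.genes[i] for i in universe.program_indices[prog.name]],
            "log2fc": prog.log2fc,
            "compartments": list(prog.affected_compartments),
        }
        for prog in config.induced_programs
    }
    truth = SimulationTruth(
        fractions=pd.DataFrame(frac_rows, index=ids, columns=names),
        marker_map={universe.genes[i]: ct for ct in names
                    for i in universe.markers[ct]},
        programs=programs,
        seed=config.seed,
    )
    return counts, meta, truth


def simulate_memory_subsets(
    config: GeneratorConfig, n_cm: int = 12, n_em: int = 12,
    fold: float | None = None,
) -> tuple[CountMatrix, pd.DataFrame, SimulationTruth]:
    """Central-memory (CM) and effector-memory (EM) CD8 profile replicates.

    The two subsets differ on two disjoint gene programs, each elevated
    ``fold``-fold (default ``config.memory_fold`` = 12, above the 10-fold
    derivation rule so the rule is exercised with margin).
    """
    if n_cm < 2 or n_em < 2:
        raise ConfigError("need >= 2 replicates per memory subset for a t-test")
    if not any(ct.name.startswith("CD8") for ct in config.cell_types):
        raise ConfigError("config must include a CD8 cell type")
    if fold is None:
        fold = config.memory_fold
    universe = build_universe(config)
    rng = _rng(config.seed, _STREAM_MEMORY)
    columns, ids, meta_rows, frac_rows = [], [], [], []
    for subset, n in (("CD8_CM", n_cm), ("CD8_EM", n_em)):
        rel = universe.base_weights.copy()
        rel[universe.memory_indices[subset]] *= fold
        rel = rel / rel.sum()
        libs = _library_sizes(rng, n, config.library_size_range)
        for r, lib in enumerate(libs):
            columns.append(_nb_counts(rng, rel * lib, config.nb_dispersion))
            sid = f"{subset}_mem{r:02d}"
            ids.append(sid)
            meta_rows.append(
                {"sample_id": sid, "compartment": "blood", "condition": "HIVneg",
                 "cell_type": subset}
            )
            frac_rows.append({"CD8_CM": 1.0 if subset == "CD8_CM" else 0.0,
                              "CD8_EM": 1.0 if subset == "CD8_EM" else 0.0})
    counts = CountMatrix(universe.genes, ids, np.column_stack(columns))
    meta = validate_sample_table(pd.DataFrame(meta_rows))
    programs = {
        sub: {
            "genes": [universe.genes[i] for i in universe.memory_indices[sub]],
            "log2fc": float(np.log2(fold)) if fold > 0 else 0.0,
            "compartments": [],
        }
        for sub in ("CD8_CM", "CD8_EM")
    }
    truth = SimulationTruth(
        fractions=pd.DataFrame(frac_rows, index=ids),
        marker_map={},
        programs=programs,
        seed=config.seed,
    )
    return counts, meta, truth
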