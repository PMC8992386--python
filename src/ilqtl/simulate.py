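"""Forward simulation of backcross/selfing introgression-line libraries.

The simulator produces BCbFs lines with known truth — exact donor/recurrent
breakpoints, donor genome proportion, marker calls and phenotypes — so every
downstream stage (segment calling, Dunnett screening, the binomial scan) can
be validated against a ground truth the field never has for real libraries.

Model:

* Physical -> genetic map is linear at a single density (default 4 cM/Mb, a
  rice-like genome-wide average), so crossover positions uniform on the
  genetic map are uniform in bp.
* Meiosis follows the Haldane (no-interference) model: the crossover count
  per chromosome is Poisson with mean equal to the map length in Morgans,
  the gamete alternating between the two parental haplotypes, starting from
  either with probability 1/2.
* Breeding: F1 = donor x recurrent, then b backcrosses to the (fully inbred)
  recurrent parent, then s generations of selfing. Expected donor genome
  fraction after b backcrosses is 2^-(b+1); selfing leaves it unchanged.
* Phenotype: value = baseline + sum over QTLs of effect x (donor dosage / 2)
  + environment effect + N(0, residual SD); dosage in {0, 1, 2}, so a
  homozygous-donor QTL contributes the full additive effect.
* Optional truncation selection on the simulated phenotype (|value -
  baseline| > threshold x residual SD) emulates advancing only plants with a
  visible agronomic difference from the recurrent parent.

Without selection, each output line descends through its own single-plant
lineage, so lines are independent Monte-Carlo draws; with selection enabled a
population of configurable size is maintained per generation and parents of
the next generation are drawn from the selected fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import CONTROL_ID, GenomeSpec, GenotypeMatrix, MarkerMap, PhenotypeTable

MB = 1_000_000

RECURRENT, DONOR = 0, 1

# a haplotype is a list of (end_bp, origin) pairs covering (0, L]; origins of
# consecutive entries differ after normalization
Haplotype = list[tuple[float, int]]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class QTLEffect:
    chromosome: str
    position_bp: int
    trait: str
    additive: float  # trait units per homozygous donor substitution
    dominance: float = 0.0


@dataclass
class SimConfig:
    genome: GenomeSpec
    marker_spacing_bp: int = 2_500_000
    marker_positions: dict[str, list[int]] | None = None
    map_density_cm_per_mb: float = 4.0
    n_backcrosses: int = 2
    n_selfs: int = 2
    n_lines: int = 100
    population_size: int = 200
    selection_threshold_sd: float | None = None  # None disables selection
    qtls: list[QTLEffect] = field(default_factory=list)
    trait: str = "GL"
    baseline: float = 7.0
    environment_effects: dict[str, float] = field(default_factory=lambda: {"E1": 0.0, "E2": 0.15})
    residual_sd: float = 0.2
    n_replicates: int = 3
    n_control_replicates: int = 10
    genotyping_error_rate: float = 0.0
    donor: str = "sim_donor"
    seed: int = 0

    def __post_init__(self):
        if self.n_backcrosses < 1:
            raise ValueError("need at least one backcross")
        if min(self.n_lines, self.population_size, self.n_replicates) <= 0:
            raise ValueError("population sizes and replicate counts must be positive")
        for q in self.qtls:
            if q.chromosome not in self.genome:
                raise ValueError(f"QTL chromosome {q.chromosome!r} not in genome")
            if not 1 <= q.position_bp <= self.genome.lengths[q.chromosome]:
                raise ValueError(f"QTL position {q.position_bp} outside {q.chromosome}")


def default_test_genome() -> GenomeSpec:
    """Small three-chromosome genome used for fast method validation."""
    return GenomeSpec({"chr1": 30 * MB, "chr2": 25 * MB, "chr3": 20 * MB})


def rice_genome() -> GenomeSpec:
    """Approximate 12-chromosome rice genome (IRGSP-scale lengths, Mb rounded)."""
    lengths_mb = [43, 36, 36, 35, 30, 31, 30, 28, 23, 23, 29, 27]
    return GenomeSpec({f"chr{i + 1}": l * MB for i, l in enumerate(lengths_mb)})


def build_marker_map(config: SimConfig) -> MarkerMap:
    """Evenly spaced markers (or explicit positions) over the genome."""
    rows = []
    i = 0
    for chrom in config.genome.chromosomes:
        if config.marker_positions is not None:
            positions = config.marker_positions[chrom]
        else:
            L = config.genome.lengths[chrom]
            positions = list(range(config.marker_spacing_bp, L + 1, config.marker_spacing_bp))
        for p in positions:
            i += 1
            rows.append((f"RM{i:04d}", chrom, int(p)))
    table = pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp"])
    poly = {config.donor: np.ones(len(table), dtype=bool)}
    return MarkerMap(table, config.genome, poly)


# ---------------------------------------------------------------------------
# genetics
# ---------------------------------------------------------------------------

def build_genetic_map(genome: GenomeSpec, density_cm_per_mb: float) -> dict[str, float]:
    """Genetic length per chromosome in Morgans under the linear map."""
    if density_cm_per_mb <= 0:
        raise ValueError("map density must be positive")
    return {c: genome.lengths[c] / MB * density_cm_per_mb / 100.0 for c in genome.chromosomes}


def genetic_position(position_bp: float, density_cm_per_mb: float) -> float:
    """Genetic position (cM) of a physical position under the linear map."""
    return position_bp / MB * density_cm_per_mb


def _normalize(hap: Haplotype) -> Haplotype:
    out: Haplotype = []
    for end, origin in hap:
        if out and out[-1][1] == origin:
            out[-1] = (end, origin)
        else:
            out.append((end, origin))
    return out


def _state_at(hap: Haplotype, pos: float) -> int:
    for end, origin in hap:
        if pos <= end:
            return origin
    return hap[-1][1]


def _slice(hap: Haplotype, start: float, end: float) -> Haplotype:
    """Sub-haplotype covering (start, end]."""
    out: Haplotype = []
    prev = 0.0
    for seg_end, origin in hap:
        lo, hi = max(prev, start), min(seg_end, end)
        if hi > lo:
            out.append((hi, origin))
        prev = seg_end
        if prev >= end:
            break
    return out


def simulate_meiosis(
    hap_a: Haplotype, hap_b: Haplotype, length_bp: float, morgans: float, rng: np.random.Generator
) -> Haplotype:
    """One gamete from a diplotype under the Haldane model."""
    n_cx = rng.poisson(morgans)
    active = int(rng.integers(2))
    if n_cx == 0:
        return list(hap_a if active == 0 else hap_b)
    cuts = np.sort(rng.uniform(0.0, length_bp, size=n_cx))
    haps = (hap_a, hap_b)
    gamete: Haplotype = []
    prev = 0.0
    for cut in list(cuts) + [length_bp]:
        gamete.extend(_slice(haps[active], prev, float(cut)))
        active = 1 - active
        prev = float(cut)
    return _normalize(gamete)


@dataclass
class Plant:
    """A diplotype: two haplotypes per chromosome."""

    haplotypes: dict[str, tuple[Haplotype, Haplotype]]

    def donor_fraction(self, genome: GenomeSpec) -> float:
        total = 0.0
        for chrom, (h1, h2) in self.haplotypes.items():
            for hap in (h1, h2):
                prev = 0.0
                for end, origin in hap:
                    if origin == DONOR:
                        total += end - prev
                    prev = end
        return total / (2.0 * genome.total_size)

    def dosage_at(self, chrom: str, pos: float) -> int:
        h1, h2 = self.haplotypes[chrom]
        return _state_at(h1, pos) + _state_at(h2, pos)


def _f1(genome: GenomeSpec) -> Plant:
    return Plant(
        {
            c: ([(float(genome.lengths[c]), DONOR)], [(float(genome.lengths[c]), RECURRENT)])
            for c in genome.chromosomes
        }
    )


def _gamete(plant: Plant, genome: GenomeSpec, morgans: dict[str, float], rng) -> dict[str, Haplotype]:
    return {
        c: simulate_meiosis(*plant.haplotypes[c], float(genome.lengths[c]), morgans[c], rng)
        for c in genome.chromosomes
    }


def _recurrent_gamete(genome: GenomeSpec) -> dict[str, Haplotype]:
    return {c: [(float(genome.lengths[c]), RECURRENT)] for c in genome.chromosomes}


def backcross(plant: Plant, genome: GenomeSpec, morgans, rng) -> Plant:
    g = _gamete(plant, genome, morgans, rng)
    r = _recurrent_gamete(genome)
    return Plant({c: (g[c], r[c]) for c in genome.chromosomes})


def self_plant(plant: Plant, genome: GenomeSpec, morgans, rng) -> Plant:
    g1 = _gamete(plant, genome, morgans, rng)
    g2 = _gamete(plant, genome, morgans, rng)
    return Plant({c: (g1[c], g2[c]) for c in genome.chromosomes})


# ---------------------------------------------------------------------------
# phenotype and genotyping
# ---------------------------------------------------------------------------

def genetic_value(plant: Plant, qtls: list[QTLEffect], trait: str) -> float:
    v = 0.0
    for q in qtls:
        if q.trait != trait:
            continue
        d = plant.dosage_at(q.chromosome, float(q.position_bp))
        v += q.additive * d / 2.0
        if d == 1:
            v += q.dominance
    return v


def apply_phenotype_model(
    plant: Plant | None, config: SimConfig, environment: str, rng: np.random.Generator
) -> np.ndarray:
    """Replicate phenotype values for one plant (None = recurrent parent)."""
    g = 0.0 if plant is None else genetic_value(plant, config.qtls, config.trait)
    env = config.environment_effects.get(environment, 0.0)
    n = config.n_control_replicates if plant is None else config.n_replicates
    return config.baseline + g + env + rng.normal(0.0, config.residual_sd, size=n)


def genotype_at_markers(
    plant: Plant, marker_map: MarkerMap, rng: np.random.Generator, error_rate: float = 0.0
) -> list[str]:
    """Marker calls (D/R/H) with optional independent symmetric miscalls.

    With probability ``error_rate`` a call is replaced by one of the other
    two states, chosen uniformly.
    """
    calls = []
    for row in marker_map.table.itertuples(index=False):
        d = plant.dosage_at(row.chromosome, float(row.position_bp))
        calls.append("R" if d == 0 else "D" if d == 2 else "H")
    if error_rate > 0:
        states = ("R", "D", "H")
        flip = rng.random(len(calls)) < error_rate
        for i in np.flatnonzero(flip):
            others = [s for s in states if s != calls[i]]
            calls[i] = others[int(rng.integers(2))]
    return calls


# ---------------------------------------------------------------------------
# breeding scheme
# ---------------------------------------------------------------------------

@dataclass
class SimulatedIL:
    il_id: str
    plant: Plant
    true_donor_proportion: float
    calls: list[str]
    generation: tuple[int, int]


class GenerationEmptied(RuntimeError):
    pass


def _phenotype_once(plant: Plant, config: SimConfig, rng) -> float:
    return (
        config.baseline
        + genetic_value(plant, config.qtls, config.trait)
        + rng.normal(0.0, config.residual_sd)
    )


def _selected(plants: list[Plant], config: SimConfig, rng, generation: str) -> list[Plant]:
    if config.selection_threshold_sd is None:
        return plants
    cut = config.selection_threshold_sd * config.residual_sd
    keep = [p for p in plants if abs(_phenotype_once(p, config, rng) - config.baseline) > cut]
    if not keep:
        raise GenerationEmptied(f"selection emptied generation {generation}")
    return keep


def run_breeding_scheme(config: SimConfig, marker_map: MarkerMap | None = None) -> list[SimulatedIL]:
    """Simulate the full BCbFs scheme and return the final library."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    genome = config.genome
    morgans = build_genetic_map(genome, config.map_density_cm_per_mb)
    if marker_map is None:
        marker_map = build_marker_map(config)
    finals: list[Plant] = []
    if config.selection_threshold_sd is None:
        # independent single-plant lineages
        for _ in range(config.n_lines):
            plant = _f1(genome)
            for _b in range(config.n_backcrosses):
                plant = backcross(plant, genome, morgans, rng)
            for _s in range(config.n_selfs):
                plant = self_plant(plant, genome, morgans, rng)
            finals.append(plant)
    else:
        population = [_f1(genome)]
        for b in range(config.n_backcrosses):
            parents = _selected(population, config, rng, f"BC{b}") if b > 0 else population
            population = [
                backcross(parents[int(rng.integers(len(parents)))], genome, morgans, rng)
                for _ in range(config.population_size)
            ]
        for s in range(config.n_selfs):
            parents = _selected(population, config, rng, f"F{s + 1}")
            population = [
                self_plant(parents[int(rng.integers(len(parents)))], genome, morgans, rng)
                for _ in range(config.population_size)
            ]
        population = _selected(population, config, rng, "final")
        idx = rng.choice(len(population), size=min(config.n_lines, len(population)), replace=False)
        finals = [population[i] for i in idx]

    ils = []
    for i, plant in enumerate(finals, start=1):
        ils.append(
            SimulatedIL(
                il_id=f"IL{i:04d}",
                plant=plant,
                true_donor_proportion=plant.donor_fraction(genome),
                calls=genotype_at_markers(plant, marker_map, rng, config.genotyping_error_rate),
                generation=(config.n_backcrosses, config.n_selfs),
            )
        )
    return ils


# ---------------------------------------------------------------------------
# assembling pipeline inputs
# ---------------------------------------------------------------------------

def library_tables(
    ils: list[SimulatedIL], config: SimConfig, marker_map: MarkerMap
) -> tuple[GenotypeMatrix, PhenotypeTable, pd.DataFrame]:
    """Pack a simulated library into the pipeline's input objects.

    Returns (genotypes, phenotypes, truth table). Phenotypes cover every
    configured environment with independent replicate noise, plus control
    (recurrent parent) replicates per stratum.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    calls = pd.DataFrame(
        [il.calls for il in ils], index=[il.il_id for il in ils], columns=marker_map.marker_ids
    )
    genotypes = GenotypeMatrix(
        calls,
        {il.il_id: config.donor for il in ils},
        {il.il_id: il.generation for il in ils},
    )
    rows = []
    for env in config.environment_effects:
        for il in ils:
            for r, v in enumerate(apply_phenotype_model(il.plant, config, env, rng), start=1):
                rows.append((il.il_id, config.trait, env, r, v))
        for r, v in enumerate(apply_phenotype_model(None, config, env, rng), start=1):
            rows.append((CONTROL_ID, config.trait, env, r, v))
    phen = PhenotypeTable(pd.DataFrame(rows, columns=["il_id", "trait", "environment", "replicate", "value"]))
    truth = pd.DataFrame(
        {
            "il_id": [il.il_id for il in ils],
            "true_donor_proportion": [il.true_donor_proportion for il in ils],
        }
    )
    return genotypes, phen, truth


def true_segments_table(ils: list[SimulatedIL]) -> pd.DataFrame:
    """True donor intervals (per haplotype) of every simulated IL."""
    rows = []
    for il in ils:
        for chrom, haps in il.plant.haplotypes.items():
            for h, hap in enumerate(haps):
                prev = 0.0
                for end, origin in hap:
                    if origin == DONOR:
                        rows.append((il.il_id, chrom, h, prev, end))
                    prev = end
    return pd.DataFrame(rows, columns=["il_id", "chromosome", "haplotype", "start", "end"])
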