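"""Synthetic phased panels with the statistical structure the pipeline assumes.

Four generators cover the pipeline's assumptions:

``star``
    A selective-sweep genealogy: all lineages descend independently from a
    single founder, so each chromosome carries K ~ Poisson(mu*L*T) private
    derived mutations at distinct sites (infinite sites — no site is ever
    reused).  This is the model under which the clock estimator is unbiased.
``tree``
    A random genealogy in which every ancestor haplotype remains sampled:
    chromosomes are created sequentially, each copying a uniformly chosen
    existing chromosome and adding Poisson-distributed private mutations.
    Because all internal haplotypes are observed, the haplotype network's
    greedy minimum-distance linking provably recovers the true tree, which
    makes this generator a sharp oracle for network construction.
``recombinant``
    Copies of two parent haplotypes plus single-crossover products at a
    known breakpoint — the oracle for crossover inference and for the
    recurrent-site signature of recombination.
``classified``
    Chromosomes instantiated exactly from a label -> per-population count
    table over named haplotype definitions, with optional MISSING injection
    to create ambiguity classes — the round-trip oracle for classification.

Determinism: every generator is a pure function of the seed, and each
chromosome consumes its own RNG substream (spawned from the seed), so
adding chromosomes never perturbs the ones already generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .classify import HaplotypeDefinitionTable
from .types import MISSING, HapclockError, PhasedPanel, SiteAnnotation

#: Infinite-sites guard: reject configurations where the expected number of
#: mutations per chromosome exceeds this fraction of the region length.
MAX_MUTATION_DENSITY = 0.1


@dataclass
class SimConfig:
    """Configuration for the synthetic-panel generators.

    Fields are interpreted per model; see the generator docstrings.
    Defaults mirror the dated sweep's regime: region length 127,419 nt,
    rate 8.145e-10 per site per year, and a TMRCA of 8,000 years puts the
    expected per-chromosome mutation count near 0.8 — the observed mean
    difference scale (822 differences over 1,013 chromosomes).
    """

    model: str = "star"
    n_chrom: int = 200
    region_length: int = 127_419
    mutation_rate: float = 8.145398347818467e-10
    tmrca: float = 8_000.0
    seed: int | None = None
    population: str = "SIM"
    # recombinant model
    parent_a: str | None = None
    parent_b: str | None = None
    sites: Sequence[SiteAnnotation] | None = None
    crossover_position: int | None = None
    n_parent_a: int = 0
    n_parent_b: int = 0
    n_recombinant: int = 0
    # classified model
    frequency_table: Mapping[str, Mapping[str, int]] | None = None
    definitions: HaplotypeDefinitionTable | None = None
    missing_sites: Mapping[str, Sequence[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.region_length <= 0 or self.mutation_rate < 0 or self.tmrca < 0:
            raise HapclockError("rates, lengths and times must be non-negative")


def _check_density(config: SimConfig) -> float:
    lam = config.mutation_rate * config.region_length * config.tmrca
    if lam > MAX_MUTATION_DENSITY * config.region_length:
        raise HapclockError(
            "expected mutations per chromosome exceed the infinite-sites regime"
        )
    return lam


def _draw_new_positions(
    rng: np.random.Generator, k: int, region_length: int, used: set[int]
) -> list[int]:
    """k distinct 1-based positions not in ``used`` (infinite sites by rejection)."""
    if k > region_length - len(used):
        raise HapclockError("region too short for requested mutation count")
    out: list[int] = []
    while len(out) < k:
        pos = int(rng.integers(1, region_length + 1))
        if pos not in used:
            used.add(pos)
            out.append(pos)
    return out


def _panel_from_mutations(
    per_chrom_sites: list[set[int]], config: SimConfig
) -> PhasedPanel:
    positions = sorted(set().union(*per_chrom_sites)) if per_chrom_sites else []
    col = {p: j for j, p in enumerate(positions)}
    alleles = np.zeros((len(per_chrom_sites), len(positions)), dtype=np.int8)
    for i, sites in enumerate(per_chrom_sites):
        for p in sites:
            alleles[i, col[p]] = 1
    annotation = [
        SiteAnnotation(
            site_id=f"s{p}", position=p, ancestral_allele="A", derived_allele="G"
        )
        for p in positions
    ]
    n = len(per_chrom_sites)
    return PhasedPanel(
        sites=annotation,
        chrom_ids=[(f"sim{i // 2}", i % 2) for i in range(n)],
        populations=[config.population] * n,
        alleles=alleles,
    )


def simulate_star(config: SimConfig) -> tuple[PhasedPanel, dict]:
    """Sweep-like star genealogy: private Poisson mutations per lineage.

    Every chromosome descends directly from an all-ancestral founder and
    accumulates K ~ Poisson(mu*L*T) derived mutations at distinct sites.
    The truth record stores T and the per-chromosome K.
    """
    if config.model != "star":
        raise HapclockError("config.model must be 'star'")
    lam = _check_density(config)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_chrom)
    used: set[int] = set()
    per_chrom: list[set[int]] = []
    ks: list[int] = []
    for i in range(config.n_chrom):
        rng = np.random.default_rng(streams[i])
        k = int(rng.poisson(lam))
        per_chrom.append(set(_draw_new_positions(rng, k, config.region_length, used)))
        ks.append(k)
    panel = _panel_from_mutations(per_chrom, config)
    truth = {"model": "star", "tmrca": config.tmrca, "k_per_chrom": ks}
    return panel, truth


def simulate_tree_panel(config: SimConfig) -> tuple[PhasedPanel, dict]:
    """Random genealogy with persisting ancestral haplotypes.

    Chromosome 0 is the all-ancestral founder.  Each subsequent chromosome
    copies a uniformly chosen existing chromosome and adds
    K ~ Poisson(mu*L*T) private mutations (T is the per-branch duration).
    The truth record stores the parent of each chromosome, the branch on
    which each site arose, and each site's carrier set.
    """
    if config.model != "tree":
        raise HapclockError("config.model must be 'tree'")
    lam = _check_density(config)
    if config.n_chrom < 1:
        raise HapclockError("need at least one chromosome")
    streams = np.random.SeedSequence(config.seed).spawn(config.n_chrom)
    used: set[int] = set()
    per_chrom: list[set[int]] = [set()]
    parents: list[int | None] = [None]
    origin: dict[int, int] = {}
    for i in range(1, config.n_chrom):
        rng = np.random.default_rng(streams[i])
        parent = int(rng.integers(i))
        k = int(rng.poisson(lam))
        new = _draw_new_positions(rng, k, config.region_length, used)
        per_chrom.append(per_chrom[parent] | set(new))
        parents.append(parent)
        for p in new:
            origin[p] = i
    carriers: dict[int, frozenset[int]] = {}
    for p, owner in origin.items():
        carriers[p] = frozenset(
            i for i in range(config.n_chrom) if p in per_chrom[i]
        )
    panel = _panel_from_mutations(per_chrom, config)
    truth = {
        "model": "tree",
        "parents": parents,
        "site_origin": origin,
        "carrier_sets": carriers,
    }
    return panel, truth


def simulate_recombinant_panel(config: SimConfig) -> tuple[PhasedPanel, dict]:
    """Two parent haplotypes plus single-crossover recombinants.

    The recombinant takes ``parent_a`` at positions <= ``crossover_position``
    and ``parent_b`` beyond it.  The truth record stores the parents and the
    breakpoint.
    """
    if config.model != "recombinant":
        raise HapclockError("config.model must be 'recombinant'")
    if config.parent_a is None or config.parent_b is None or config.sites is None:
        raise HapclockError("recombinant model needs parent_a, parent_b and sites")
    sites = list(config.sites)
    for h in (config.parent_a, config.parent_b):
        if len(h) != len(sites):
            raise HapclockError("parent haplotype length does not match sites")
    pos = [s.position for s in sites]
    if config.crossover_position is None or not (
        pos[0] <= config.crossover_position < pos[-1]
    ):
        raise HapclockError(
            f"crossover position {config.crossover_position} outside region "
            f"[{pos[0]}, {pos[-1]})"
        )
    recomb = "".join(
        a if p <= config.crossover_position else b
        for a, b, p in zip(config.parent_a, config.parent_b, pos)
    )
    rows = (
        [config.parent_a] * config.n_parent_a
        + [config.parent_b] * config.n_parent_b
        + [recomb] * config.n_recombinant
    )
    if not rows:
        raise HapclockError("no chromosomes requested")
    alleles = np.array([[int(c) for c in r] for r in rows], dtype=np.int8)
    panel = PhasedPanel(
        sites=sites,
        chrom_ids=[(f"sim{i // 2}", i % 2) for i in range(len(rows))],
        populations=[config.population] * len(rows),
        alleles=alleles,
    )
    truth = {
        "model": "recombinant",
        "parents": (config.parent_a, config.parent_b),
        "crossover_position": config.crossover_position,
        "recombinant": recomb,
    }
    return panel, truth


def simulate_classified_panel(config: SimConfig) -> PhasedPanel:
    """Chromosomes instantiated exactly from a label -> population count table.

    ``config.frequency_table`` maps haplotype name -> {population: count};
    every label must exist in ``config.definitions``.  ``missing_sites``
    maps a site label to the haplotype names whose chromosomes get a
    MISSING call there (to create ambiguity classes on purpose).
    """
    if config.model != "classified":
        raise HapclockError("config.model must be 'classified'")
    defs = config.definitions
    table = config.frequency_table
    if defs is None or not table:
        raise HapclockError("classified model needs definitions and a frequency table")
    if config.sites is not None:
        sites = list(config.sites)
        labels = [s.label for s in sites]
        if labels != list(defs.site_universe):
            raise HapclockError("site annotation does not match definition universe")
    else:
        sites = [
            SiteAnnotation(
                site_id=lab, position=j + 1, ancestral_allele="A", derived_allele="G",
                nickname=lab,
            )
            for j, lab in enumerate(defs.site_universe)
        ]
    col = {lab: j for j, lab in enumerate(defs.site_universe)}

    rows: list[np.ndarray] = []
    pops: list[str] = []
    for label in table:
        if label not in defs.entries:
            raise HapclockError(f"frequency table label {label!r} not in definitions")
        pattern = defs.pattern(label).copy()
        for site_label, affected in config.missing_sites.items():
            if label in affected:
                pattern = pattern.copy()
                pattern[col[site_label]] = MISSING
        for pop in sorted(table[label]):
            count = table[label][pop]
            if count < 0:
                raise HapclockError("frequency-table counts must be non-negative")
            for _ in range(count):
                rows.append(pattern)
                pops.append(pop)
    if not rows:
        raise HapclockError("frequency table instantiates no chromosomes")
    alleles = np.vstack(rows)
    return PhasedPanel(
        sites=sites,
        chrom_ids=[(f"sim{i // 2}", i % 2) for i in range(len(rows))],
        populations=pops,
        alleles=alleles,
    )


def simulate(config: SimConfig):
    """Dispatch on ``config.model``."""
    if config.model == "star":
        return simulate_star(config)
    if config.model == "tree":
        return simulate_tree_panel(config)
    if config.model == "recombinant":
        return simulate_recombinant_panel(config)
    if config.model == "classified":
        return simulate_classified_panel(config)
    raise HapclockError(f"unknown model {config.model!r}")
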