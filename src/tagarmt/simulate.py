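"""Stage-structured synthetic mtDNA series for pipeline testing.

The generator emulates the structure the analyses assume: a pool of
haplogroup-rooted founder haplotypes split into West/East Eurasian
macro-clusters, skewed haplotype frequency spectra drawn from a symmetric
Dirichlet (small concentration -> singleton-rich spectra), private
substitutions placed uniformly over unoccupied HVRI positions
(infinite-sites within the window), and serial bottleneck resampling of
founder frequencies between chronological stages (drift).

By default new mutations never touch positions used by any motif in the
bundled haplogroup table, so the haplogroup caller recovers every founder
label exactly by construction; set ``allow_motif_positions`` to relax this.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .haplogroups import MotifTable, default_motif_table
from .io import (
    HVR1_END,
    HVR1_START,
    CodingCall,
    HVRIHaplotype,
    SampleRecord,
    SeriesTable,
    VariantCall,
)

STAGE_CODES = ("P", "S", "T")  # Early, Middle, Late
_BASES = "ACGT"


@dataclass(frozen=True)
class Founder:
    """A haplogroup-rooted founder haplotype with its diagnostic calls."""

    label: str
    macro: str
    hvr1: frozenset[VariantCall]
    coding: frozenset[CodingCall]


def pool_from_motif_table(table: MotifTable | None = None) -> list[Founder]:
    """One founder per rule: the rule's motif on its coding background."""
    table = table or default_motif_table()
    return [
        Founder(r.label, r.macro, r.hvr1, r.coding) for r in table.rules
    ]


@dataclass
class SimulationConfig:
    """Study-condition defaults mirror the real series: stage sizes 46/24/9,
    East-Eurasian fractions 0.348/0.458/0.111, a singleton-rich spectrum."""

    seed: int = 0
    n_per_stage: tuple[int, ...] = (46, 24, 9)
    east_fraction: tuple[float, ...] = (0.348, 0.458, 0.111)
    pool: list[Founder] | None = None
    spectrum_concentration: float = 0.5
    mutation_rate: float = 0.3
    bottleneck: int | None = 25
    allow_motif_positions: bool = False

    def __post_init__(self) -> None:
        if len(self.n_per_stage) != len(self.east_fraction):
            raise ValueError("n_per_stage and east_fraction lengths differ")
        if len(self.n_per_stage) > len(STAGE_CODES):
            raise ValueError(f"at most {len(STAGE_CODES)} stages supported")
        if any(n < 1 for n in self.n_per_stage):
            raise ValueError("stage sizes must be >= 1")
        if any(not 0 <= f <= 1 for f in self.east_fraction):
            raise ValueError("east fractions must lie in [0, 1]")
        if self.spectrum_concentration <= 0:
            raise ValueError("spectrum_concentration must be positive")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be >= 0")
        if self.bottleneck is not None and self.bottleneck < 1:
            raise ValueError("bottleneck must be >= 1")


def _forbidden_positions(pool: Sequence[Founder]) -> frozenset[int]:
    table = default_motif_table()
    pos = {v.position for r in table.rules for v in r.hvr1}
    pos |= {v.position for f in pool for v in f.hvr1}
    return frozenset(pos)


def _mutate(
    founder: Founder,
    free_positions: np.ndarray,
    rate: float,
    rng: np.random.Generator,
) -> HVRIHaplotype:
    variants = set(founder.hvr1)
    occupied = {v.position for v in variants}
    candidates = free_positions[~np.isin(free_positions, list(occupied))]
    m = min(rng.poisson(rate), len(candidates))
    if m:
        for p in rng.choice(candidates, size=m, replace=False):
            variants.add(VariantCall(int(p), _BASES[rng.integers(4)]))
    return HVRIHaplotype(frozenset(variants))


def _drift(freqs: np.ndarray, bottleneck: int, rng: np.random.Generator) -> np.ndarray:
    counts = rng.multinomial(bottleneck, freqs)
    return counts / counts.sum()


def simulate_series(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> list[SeriesTable]:
    """One SeriesTable per stage; records carry their true founder label."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    pool = cfg.pool if cfg.pool is not None else pool_from_motif_table()
    if not pool:
        raise ValueError("empty founder pool")
    east = [f for f in pool if f.macro == "East"]
    west = [f for f in pool if f.macro == "West"]
    if cfg.allow_motif_positions:
        forbidden: frozenset[int] = frozenset()
    else:
        forbidden = _forbidden_positions(pool)
    free = np.array(
        [p for p in range(HVR1_START, HVR1_END + 1) if p not in forbidden]
    )

    # per-macro founder frequencies, drifting between stages
    freqs = {
        macro: rng.dirichlet([cfg.spectrum_concentration] * len(group))
        if group
        else np.array([])
        for macro, group in (("East", east), ("West", west))
    }

    tables = []
    for s, (n, f_east) in enumerate(zip(cfg.n_per_stage, cfg.east_fraction)):
        if s > 0 and cfg.bottleneck is not None:
            for macro in freqs:
                if len(freqs[macro]):
                    freqs[macro] = _drift(freqs[macro], cfg.bottleneck, rng)
        if east and west:
            n_east = int(rng.binomial(n, f_east))
        else:
            n_east = n if east else 0
        records = []
        for i in range(n):
            macro, group = (
                ("East", east) if i < n_east else ("West", west)
            )
            founder = group[rng.choice(len(group), p=freqs[macro])]
            records.append(
                SampleRecord(
                    sample_id=f"{STAGE_CODES[s]}{i + 1:03d}",
                    stage_code=STAGE_CODES[s],
                    hvr1=_mutate(founder, free, cfg.mutation_rate, rng),
                    coding=founder.coding,
                    haplogroup_label=founder.label,
                )
            )
        tables.append(SeriesTable(records, name=f"sim_stage{s + 1}"))
    return tables


def simulate_two_population_fst(
    cfg: SimulationConfig,
    overlap: float,
    n_per_pop: tuple[int, int] = (30, 30),
    pool_size: int = 6,
    rng: np.random.Generator | None = None,
) -> tuple[SeriesTable, SeriesTable]:
    """Two populations drawn from founder pools with controlled overlap.

    ``overlap`` is the fraction of each population's ``pool_size`` founders
    shared with the other; expected F_ST increases as overlap decreases.
    """
    if not 0 <= overlap <= 1:
        raise ValueError("overlap must lie in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    pool = cfg.pool if cfg.pool is not None else pool_from_motif_table()
    n_shared = round(overlap * pool_size)
    needed = 2 * pool_size - n_shared
    if len(pool) < needed:
        raise ValueError(
            f"pool of {len(pool)} founders too small for pool_size="
            f"{pool_size}, overlap={overlap} (needs {needed})"
        )
    pool_a = pool[:pool_size]
    pool_b = pool[:n_shared] + pool[pool_size : 2 * pool_size - n_shared]
    if cfg.allow_motif_positions:
        forbidden: frozenset[int] = frozenset()
    else:
        forbidden = _forbidden_positions(pool)
    free = np.array(
        [p for p in range(HVR1_START, HVR1_END + 1) if p not in forbidden]
    )

    tables = []
    for name, group, n in (
        ("popA", pool_a, n_per_pop[0]),
        ("popB", pool_b, n_per_pop[1]),
    ):
        fr = rng.dirichlet([cfg.spectrum_concentration] * len(group))
        records = []
        for i in range(n):
            founder = group[rng.choice(len(group), p=fr)]
            records.append(
                SampleRecord(
                    sample_id=f"{name}-{i + 1:03d}",
                    stage_code="P",
                    hvr1=_mutate(founder, free, cfg.mutation_rate, rng),
                    coding=founder.coding,
                    haplogroup_label=founder.label,
                )
            )
        tables.append(SeriesTable(records, name=name))
    return tables[0], tables[1]


def empirical_miss_rate(
    p: float, n: int, n_replicates: int = 10_000, rng: np.random.Generator | None = None
) -> float:
    """Monte-Carlo fraction of Binomial(n, p) samples with zero carriers."""
    rng = rng if rng is not None else np.random.default_rng()
    return float(np.mean(rng.binomial(n, p, size=n_replicates) == 0))
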