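"""Per-generation scheduler, full simulation runs, and the factorial driver.

A run couples two reproductively isolated species in a three-patch
landscape.  Each generation proceeds through fixed stages:

1. every patch's resource quality advances at its configured rate;
2. random mating within each species × patch produces the offspring cohort
   (recombination then mutation; mid-parent trait recorded per offspring);
3. all parents are killed (non-overlapping generations);
4. offspring are culled by Gaussian relative fitness against their patch's
   resource quality — the stage through which competition acts;
5. after the canalization phase (default 20 generations), every survivor
   may disperse; dispersers that miss all patches die;
6. a carrying capacity K is enforced per patch on the joint census of both
   species by uniform random removal;
7. a census / quantitative-genetics row is appended to the run record.

Runs stop at the configured horizon (default 750 generations) or at the
first regional extinction of a founded species.  All randomness flows from
a single seed, so runs replay bit-identically.

Populations are held as stacked per-species arrays (one row per
individual) so each stage is a handful of vectorized operations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from netcomm.network_genome import (
    DEFAULT_ENV_MAX,
    build_topology_batch,
    phenotype_batch,
)
from netcomm.reproduction import mutate_batch, recombine_batch
from netcomm.selection_demography import (
    DEFAULT_RATES,
    relative_fitness,
    update_resource,
)
from netcomm.landscape_dispersal import (
    DEFAULT_EDGE_GAP,
    DEFAULT_RADIUS,
    Landscape,
    build_landscape,
    disperse_batch,
)
from netcomm.metrics_analysis import midparent_heritability

__all__ = [
    "SpeciesParams",
    "SimConfig",
    "SpeciesPop",
    "WorldState",
    "RunRecord",
    "initialize_run",
    "step_generation",
    "run_simulation",
    "run_experiment",
    "run_metapopulation_arm",
    "DEFAULT_METAPOP_LANDSCAPES",
    "enumerate_design",
    "run_seed",
]


@dataclass
class SpeciesParams:
    """Genetic architecture and dispersal of one species.

    Defaults are the focal-species settings of the factorial design:
    a 16-gene scale-free network, mutation rate 1e−4 per chromosomal
    element, recombination rate 0.05, founded with 100 individuals.
    """

    name: str = "focal"
    n: int = 16
    topology: str = "scale_free"
    mu: float = 1e-4
    rec: float = 0.05
    d: float = 0.05
    start_patch: int = 0
    n0: int = 100

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("network size must be >= 2")
        if self.topology not in ("random", "scale_free"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mutation rate must be in [0, 1]")
        if not 0.0 <= self.rec <= 1.0:
            raise ValueError("recombination rate must be in [0, 1]")
        if not 0.0 <= self.d <= 1.0:
            raise ValueError("dispersal probability must be in [0, 1]")
        if self.n0 < 0:
            raise ValueError("founding census cannot be negative")


@dataclass
class SimConfig:
    """Global constants of a simulation run."""

    generations: int = 750
    canalization_gens: int = 20
    omega: float = 2.0
    lambda_: float = 1.5
    K: int = 200
    env_max: float = DEFAULT_ENV_MAX
    env_init: float = 70.0
    patch_radius: float = DEFAULT_RADIUS
    edge_gap: float = DEFAULT_EDGE_GAP
    rates: tuple[float, float, float] = DEFAULT_RATES
    drift: str = "increase"

    def __post_init__(self) -> None:
        self.rates = tuple(self.rates)
        if self.generations <= 0 or self.K <= 0 or self.lambda_ <= 0:
            raise ValueError("generations, K and lambda_ must be positive")
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if not 0 <= self.canalization_gens < self.generations:
            raise ValueError("canalization_gens must be in [0, generations)")
        if len(self.rates) != 3:
            raise ValueError("exactly three patch rates required")


@dataclass
class SpeciesPop:
    """Stacked genomes of all living members of one species (row = individual)."""

    heads: np.ndarray  # (M, n) int32
    funcs: np.ndarray  # (M, n) int8
    roots: np.ndarray  # (M,) int8
    patch: np.ndarray  # (M,) int64 patch id
    phen: np.ndarray  # (M,) float
    midparent: np.ndarray  # (M,) float; NaN for founders

    @property
    def size(self) -> int:
        return int(self.patch.shape[0])

    def subset(self, idx) -> "SpeciesPop":
        return SpeciesPop(
            self.heads[idx],
            self.funcs[idx],
            self.roots[idx],
            self.patch[idx],
            self.phen[idx],
            self.midparent[idx],
        )

    @classmethod
    def empty(cls, n: int) -> "SpeciesPop":
        return cls(
            np.empty((0, n), dtype=np.int32),
            np.empty((0, n), dtype=np.int8),
            np.empty(0, dtype=np.int8),
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=float),
            np.empty(0, dtype=float),
        )


@dataclass
class WorldState:
    landscape: Landscape
    species: list[SpeciesParams]
    pops: list[SpeciesPop]
    generation: int = 0
    rows: list[dict] = field(default_factory=list)


@dataclass
class RunRecord:
    """Full per-generation trace of one run plus its terminal summary.

    ``table`` has one row per recorded generation with the per-patch
    resource qualities, per species × patch censuses and mean phenotypes,
    and per-species regional phenotype statistics (mean, phenotypic
    variance, mid-parent heritability, additive variance) and migrant
    counts.  ``extinction_gen`` maps species name to the generation its
    regional census first hit zero (None if it never did).
    """

    table: pd.DataFrame
    species: list[str]
    extinction_gen: dict[str, int | None]
    coexistence: bool
    generations_run: int
    config: SimConfig
    params: list[SpeciesParams]
    seed: int

    def regional_census(self, species: str) -> pd.Series:
        cols = [f"census_{species}_p{p}" for p in range(3)]
        return self.table[cols].sum(axis=1)

    def total_regional_census(self) -> pd.Series:
        out = None
        for s in self.species:
            c = self.regional_census(s)
            out = c if out is None else out + c
        return out


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def initialize_run(
    config: SimConfig,
    focal: SpeciesParams,
    competitor: SpeciesParams,
    rng: np.random.Generator,
) -> WorldState:
    """Found each species in its own patch with independently random genomes.

    The two species must start in different patches; the third patch begins
    empty.  All patches share the initial resource quality ``env_init``.
    A species with ``n0 == 0`` is simply absent (the single-species
    metapopulation arm uses this).
    """
    if focal.n0 > 0 and competitor.n0 > 0 and focal.start_patch == competitor.start_patch:
        raise ValueError("the two species must start in different patches")
    landscape = build_landscape(
        radius=config.patch_radius,
        edge_gap=config.edge_gap,
        rates=config.rates,
        env_max=config.env_max,
        K=config.K,
        env_init=config.env_init,
    )
    pops = []
    for sp in (focal, competitor):
        if sp.n0 == 0:
            pops.append(SpeciesPop.empty(sp.n))
            continue
        heads, funcs, roots = build_topology_batch(sp.n0, sp.n, sp.topology, rng)
        phen = phenotype_batch(heads, funcs, roots, config.env_max)
        pops.append(
            SpeciesPop(
                heads=heads,
                funcs=funcs,
                roots=roots,
                patch=np.full(sp.n0, sp.start_patch, dtype=np.int64),
                phen=phen,
                midparent=np.full(sp.n0, np.nan),
            )
        )
    world = WorldState(
        landscape=landscape, species=[focal, competitor], pops=pops, generation=0
    )
    world.rows.append(_census_row(world, migrants=[0] * len(pops)))
    return world


def _census_row(world: WorldState, migrants: Sequence[int]) -> dict:
    row: dict = {"generation": world.generation}
    for p in world.landscape.patches:
        row[f"resource_q_p{p.id}"] = p.resource_quality
    for sp, pop, mig in zip(world.species, world.pops, migrants):
        name = sp.name
        for p in range(3):
            mask = pop.patch == p
            row[f"census_{name}_p{p}"] = int(mask.sum())
            row[f"mean_phen_{name}_p{p}"] = (
                float(pop.phen[mask].mean()) if mask.any() else np.nan
            )
        row[f"migrants_{name}"] = int(mig)
        if pop.size:
            row[f"mean_phen_{name}"] = float(pop.phen.mean())
            row[f"phen_var_{name}"] = float(pop.phen.var(ddof=1)) if pop.size > 1 else 0.0
        else:
            row[f"mean_phen_{name}"] = np.nan
            row[f"phen_var_{name}"] = np.nan
        paired = np.isfinite(pop.midparent)
        h2 = midparent_heritability(pop.phen[paired], pop.midparent[paired])
        row[f"h2_{name}"] = h2
        pv = row[f"phen_var_{name}"]
        row[f"add_var_{name}"] = h2 * pv if np.isfinite(h2) and np.isfinite(pv) else np.nan
    return row


# ---------------------------------------------------------------------------
# one generation
# ---------------------------------------------------------------------------

def _reproduce_species(
    pop: SpeciesPop,
    sp: SpeciesParams,
    config: SimConfig,
    rng: np.random.Generator,
) -> SpeciesPop:
    """Offspring cohort for one species across all patches (stage 2)."""
    a_parts: list[np.ndarray] = []
    b_parts: list[np.ndarray] = []
    for p in range(3):
        members = np.flatnonzero(pop.patch == p)
        m = members.size
        if m < 2:
            continue
        mates = rng.integers(0, m - 1, size=m)
        mates = mates + (mates >= np.arange(m))
        counts = rng.poisson(config.lambda_, size=m)
        a_parts.append(np.repeat(members, counts))
        b_parts.append(np.repeat(members[mates], counts))
    if not a_parts:
        return SpeciesPop.empty(sp.n)
    a_idx = np.concatenate(a_parts)
    b_idx = np.concatenate(b_parts)
    heads, funcs, roots = recombine_batch(
        pop.heads[a_idx], pop.funcs[a_idx], pop.roots[a_idx],
        pop.heads[b_idx], pop.funcs[b_idx], pop.roots[b_idx],
        sp.rec, rng,
    )
    heads, funcs = mutate_batch(heads, funcs, sp.mu, rng)
    phen = phenotype_batch(heads, funcs, roots, config.env_max)
    midparent = 0.5 * (pop.phen[a_idx] + pop.phen[b_idx])
    return SpeciesPop(
        heads=heads,
        funcs=funcs,
        roots=roots,
        patch=pop.patch[a_idx].copy(),
        phen=phen,
        midparent=midparent,
    )


def step_generation(
    world: WorldState, config: SimConfig, rng: np.random.Generator
) -> WorldState:
    """Advance the world by one generation through all scheduler stages."""
    world.generation += 1
    landscape = world.landscape

    # stage 1: resource dynamics
    for i, patch in enumerate(landscape.patches):
        landscape.patches[i] = update_resource(
            patch, env_max=config.env_max, drift=config.drift, rng=rng
        )
    qualities = np.array([p.resource_quality for p in landscape.patches])

    # stages 2-3: reproduction, then parents are killed
    world.pops = [
        _reproduce_species(pop, sp, config, rng)
        for pop, sp in zip(world.pops, world.species)
    ]

    # stage 4: viability selection against the local optimum
    for s, pop in enumerate(world.pops):
        if pop.size == 0:
            continue
        rf = relative_fitness(qualities[pop.patch] - pop.phen, config.omega)
        survive = rng.random(pop.size) < rf
        world.pops[s] = pop.subset(survive)

    # stage 5: dispersal (post-canalization only)
    migrants = [0] * len(world.pops)
    if world.generation > config.canalization_gens:
        for s, (pop, sp) in enumerate(zip(world.pops, world.species)):
            if pop.size == 0 or sp.d == 0.0:
                continue
            dest = pop.patch.copy()
            for p in range(3):
                members = np.flatnonzero(pop.patch == p)
                if members.size == 0:
                    continue
                dest[members] = disperse_batch(
                    members.size, landscape.patches[p], sp.d, landscape, rng
                )
            alive = dest >= 0
            migrants[s] = int((alive & (dest != pop.patch)).sum())
            pop = pop.subset(alive)
            pop.patch = dest[alive]
            world.pops[s] = pop

    # stage 6: carrying capacity on the joint census per patch
    keep_masks = [np.ones(pop.size, dtype=bool) for pop in world.pops]
    for p in range(3):
        counts = [int((pop.patch == p).sum()) for pop in world.pops]
        total = sum(counts)
        if total <= config.K:
            continue
        keep = np.zeros(total, dtype=bool)
        keep[rng.choice(total, size=config.K, replace=False)] = True
        offset = 0
        for s, pop in enumerate(world.pops):
            members = np.flatnonzero(pop.patch == p)
            keep_masks[s][members] = keep[offset : offset + counts[s]]
            offset += counts[s]
    world.pops = [pop.subset(mask) for pop, mask in zip(world.pops, keep_masks)]

    # stage 7: census row
    world.rows.append(_census_row(world, migrants))
    return world


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

def run_simulation(
    config: SimConfig,
    focal: SpeciesParams,
    competitor: SpeciesParams,
    seed: int,
) -> RunRecord:
    """One complete run: deterministic given ``seed``.

    Terminates at ``config.generations`` or at the first generation in
    which a founded species has zero individuals region-wide.
    """
    rng = np.random.default_rng(seed)
    world = initialize_run(config, focal, competitor, rng)
    founded = [sp.n0 > 0 for sp in world.species]
    extinction: dict[str, int | None] = {sp.name: None for sp in world.species}
    for _ in range(config.generations):
        step_generation(world, config, rng)
        stop = False
        for f, sp, pop in zip(founded, world.species, world.pops):
            if f and pop.size == 0 and extinction[sp.name] is None:
                extinction[sp.name] = world.generation
                stop = True
        if stop:
            break
    table = pd.DataFrame(world.rows)
    alive = [f and world.pops[i].size > 0 for i, f in enumerate(founded)]
    coexist = (
        world.generation == config.generations
        and sum(founded) == 2
        and all(a for a, f in zip(alive, founded) if f)
    )
    return RunRecord(
        table=table,
        species=[sp.name for sp in world.species],
        extinction_gen=extinction,
        coexistence=bool(coexist),
        generations_run=world.generation,
        config=config,
        params=list(world.species),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# factorial experiment driver
# ---------------------------------------------------------------------------

#: factor names understood by the experiment driver
_COMPETITOR_FACTORS = {"competitor_n": "n", "competitor_topology": "topology",
                       "competitor_mu": "mu", "competitor_rec": "rec",
                       "competitor_d": "d"}
_FOCAL_FACTORS = {"focal_d": "d", "focal_n": "n", "focal_mu": "mu",
                  "focal_rec": "rec", "focal_topology": "topology"}

#: the seven landscape rate arrangements used for the metapopulation arm:
#: the three homogeneous landscapes, three two-rate landscapes (one per
#: rate pair), and the single all-different landscape
DEFAULT_METAPOP_LANDSCAPES: tuple[tuple[float, float, float], ...] = (
    (1e-3, 1e-3, 1e-3),
    (2.5e-4, 2.5e-4, 2.5e-4),
    (1e-4, 1e-4, 1e-4),
    (1e-3, 1e-3, 2.5e-4),
    (2.5e-4, 2.5e-4, 1e-4),
    (1e-3, 1e-4, 1e-4),
    (1e-3, 2.5e-4, 1e-4),
)


def enumerate_design(design: dict[str, Sequence]) -> list[dict]:
    """Expand a factor-grid dict into the list of cells (cartesian product)."""
    keys = list(design)
    cells = []
    for combo in itertools.product(*(design[k] for k in keys)):
        cells.append(dict(zip(keys, combo)))
    return cells


def run_seed(master_seed: int, cell_index: int, replicate: int) -> int:
    """Stable per-run seed derived from the master seed and design position."""
    ss = np.random.SeedSequence(entropy=[master_seed, cell_index, replicate])
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def _apply_cell(
    cell: dict,
    config: SimConfig,
    focal: SpeciesParams,
    competitor: SpeciesParams,
) -> tuple[SimConfig, SpeciesParams, SpeciesParams]:
    comp_over = {attr: cell[k] for k, attr in _COMPETITOR_FACTORS.items() if k in cell}
    focal_over = {attr: cell[k] for k, attr in _FOCAL_FACTORS.items() if k in cell}
    cfg_over = {}
    if "rates" in cell:
        cfg_over["rates"] = tuple(cell["rates"])
    return (
        replace(config, **cfg_over) if cfg_over else config,
        replace(focal, **focal_over) if focal_over else focal,
        replace(competitor, **comp_over) if comp_over else competitor,
    )


def run_experiment(
    design: dict[str, Sequence],
    replicates: int,
    master_seed: int,
    config: SimConfig | None = None,
    focal: SpeciesParams | None = None,
    competitor: SpeciesParams | None = None,
    keep_records: bool = False,
) -> tuple[pd.DataFrame, list[RunRecord]]:
    """Run a full-factorial design and summarize each run in one table row.

    ``design`` maps factor names (``competitor_n``, ``competitor_topology``,
    ``competitor_mu``, ``competitor_rec``, ``competitor_d``, ``focal_d``,
    ``rates``) to the grid of values; every combination is run
    ``replicates`` times with reproducible per-run seeds.  The summary holds
    the factor values, landscape heterogeneity, coexistence flag,
    persistence time, maximum observed regional census, and the
    census-weighted trait–environment mismatch.
    """
    from netcomm.metrics_analysis import mismatch, persistence_time

    config = config or SimConfig()
    focal = focal or SpeciesParams(name="focal", start_patch=0)
    competitor = competitor or SpeciesParams(name="competitor", start_patch=1)
    cells = enumerate_design(design)
    rows = []
    records: list[RunRecord] = []
    for ci, cell in enumerate(cells):
        cfg, foc, comp = _apply_cell(cell, config, focal, competitor)
        for rep in range(replicates):
            seed = run_seed(master_seed, ci, rep)
            rec = run_simulation(cfg, foc, comp, seed)
            row = {k: (tuple(v) if isinstance(v, (list, tuple)) else v)
                   for k, v in cell.items()}
            row.update(
                cell_index=ci,
                replicate=rep,
                seed=seed,
                landscape=_landscape_label(cfg.rates),
                heterogeneity=len(set(cfg.rates)),
                coexistence=rec.coexistence,
                persistence=persistence_time(rec),
                generations_run=rec.generations_run,
                max_regional_census=int(rec.total_regional_census().max()),
                mismatch=mismatch(rec),
            )
            rows.append(row)
            if keep_records:
                records.append(rec)
    return pd.DataFrame(rows), records


def _landscape_label(rates: Sequence[float]) -> str:
    return "|".join(format(r, ".2e") for r in sorted(rates, reverse=True))


def run_metapopulation_arm(
    landscapes: Sequence[tuple[float, float, float]] = DEFAULT_METAPOP_LANDSCAPES,
    replicates: int = 3,
    master_seed: int = 0,
    config: SimConfig | None = None,
    focal: SpeciesParams | None = None,
    keep_records: bool = False,
) -> tuple[pd.DataFrame, list[RunRecord]]:
    """Single-species control runs across landscape arrangements.

    The focal species (default architecture) runs alone — the competitor is
    founded with zero individuals — over each landscape, ``replicates``
    times.  The summary matches :func:`run_experiment` so the two arms can
    be contrasted by landscape label.
    """
    config = config or SimConfig()
    focal = focal or SpeciesParams(name="focal", start_patch=0)
    absent = SpeciesParams(name="competitor", start_patch=1, n0=0)
    design = {"rates": [tuple(r) for r in landscapes]}
    return run_experiment(
        design,
        replicates=replicates,
        master_seed=master_seed,
        config=config,
        focal=focal,
        competitor=absent,
        keep_records=keep_records,
    )
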