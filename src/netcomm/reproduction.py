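"""Mating, recombination and mutation within a species and patch.

Individuals are hermaphrodites that mate at random with a distinct
conspecific in the same patch.  Each resident seeds one mating (partners may
be drawn more than once), and the number of offspring per mating is
Poisson(λ), λ = 1.5 by default, so per-capita growth before selection is λ.
Offspring chromosomes are chimeras of the two parental chromosomes built by
a Markov switching rule along the gene blocks: copying starts from a
randomly chosen parent and switches to the other parent wherever a uniform
draw falls below the recombination rate.  The heritable root-gene state is
inherited from the parent contributing the first chromosome segment.

Mutation then tests every mutable chromosomal element — the head entry and
the function bit of each non-basal gene, 2(n−1) elements in all — against
the per-element mutation rate.  All mutations are non-synonymous: a hit
function bit flips, and a hit head entry is resampled uniformly among the
*other* earlier genes, which both changes the topology and preserves the
single-input acyclic structure.  (Gene 1 has a single legal head, gene 0,
so a hit there has no alternative target and leaves the head in place.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from netcomm.network_genome import Genome

__all__ = [
    "draw_offspring_count",
    "recombine",
    "recombine_batch",
    "mutate",
    "mutate_batch",
    "reproduce_patch",
    "MatingRecord",
]


@dataclass
class MatingRecord:
    """Bookkeeping for one mating: parents, their mid-parent trait, brood size."""

    parent_a: int
    parent_b: int
    midparent_phenotype: float
    offspring_count: int


def draw_offspring_count(lambda_: float, rng: np.random.Generator) -> int:
    """Number of offspring from one mating: a Poisson(λ) draw."""
    if lambda_ <= 0:
        raise ValueError("offspring rate lambda_ must be positive")
    return int(rng.poisson(lambda_))


def recombine_batch(
    heads_a: np.ndarray,
    funcs_a: np.ndarray,
    roots_a: np.ndarray,
    heads_b: np.ndarray,
    funcs_b: np.ndarray,
    roots_b: np.ndarray,
    r: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Recombine stacked parental chromosome pairs (row-wise).

    Element *j* of each offspring chromosome is the (head, function) block of
    gene *j* taken from one parent; the source parent starts at random and
    switches between elements independently with probability ``r``.  The
    root state comes from the starting parent.
    """
    if heads_a.shape != heads_b.shape:
        raise ValueError("parental chromosomes have different lengths")
    if not 0.0 <= r <= 1.0:
        raise ValueError("recombination rate must be in [0, 1]")
    m, n = heads_a.shape
    start = rng.integers(0, 2, size=m).astype(np.int8)
    switches = rng.random((m, n - 1)) < r
    source = np.empty((m, n), dtype=np.int8)
    source[:, 0] = start
    source[:, 1:] = (start[:, None] + np.cumsum(switches, axis=1)) % 2
    use_b = source.astype(bool)
    heads = np.where(use_b, heads_b, heads_a)
    funcs = np.where(use_b, funcs_b, funcs_a)
    roots = np.where(start.astype(bool), roots_b, roots_a).astype(np.int8)
    return heads, funcs, roots


def recombine(
    parent_a: Genome, parent_b: Genome, r: float, rng: np.random.Generator
) -> Genome:
    """Build one offspring chromosome from two parental genomes."""
    if parent_a.n_genes != parent_b.n_genes:
        raise ValueError("parental chromosomes have different lengths")
    heads, funcs, roots = recombine_batch(
        parent_a.heads[None, :],
        parent_a.functions[None, :],
        np.array([parent_a.root_state], dtype=np.int8),
        parent_b.heads[None, :],
        parent_b.functions[None, :],
        np.array([parent_b.root_state], dtype=np.int8),
        r,
        rng,
    )
    return Genome(heads[0], funcs[0], int(roots[0]))


def mutate_batch(
    heads: np.ndarray,
    funcs: np.ndarray,
    mu: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Mutate stacked chromosomes in place-safe copies; returns new arrays.

    Each of the 2(n−1) mutable elements per chromosome is hit independently
    with probability ``mu``.  Function hits flip the bit; head hits resample
    the head uniformly among earlier genes other than the current head, so
    the ``heads[i] < i`` tree invariant is preserved and every realized head
    mutation changes the topology.
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mutation rate must be in [0, 1]")
    m, n = heads.shape
    heads = heads.copy()
    funcs = funcs.copy()
    if mu == 0.0 or n < 2:
        return heads, funcs
    func_hits = rng.random((m, n - 1)) < mu
    head_hits = rng.random((m, n - 1)) < mu
    funcs[:, 1:] ^= func_hits.astype(np.int8)
    # head resampling: gene index g >= 2 has g-1 alternatives to its current head
    hit_rows, hit_cols = np.nonzero(head_hits)
    genes = hit_cols + 1
    ok = genes >= 2
    hit_rows, genes = hit_rows[ok], genes[ok]
    if genes.size:
        cur = heads[hit_rows, genes]
        draw = (rng.random(genes.size) * (genes - 1)).astype(np.int64)
        new = draw + (draw >= cur)
        heads[hit_rows, genes] = new
    return heads, funcs


def mutate(genome: Genome, mu: float, rng: np.random.Generator) -> Genome:
    """Return a mutated copy of one genome (root state is not mutable)."""
    heads, funcs = mutate_batch(
        genome.heads[None, :], genome.functions[None, :], mu, rng
    )
    return Genome(heads[0], funcs[0], genome.root_state)


def reproduce_patch(
    residents: list[Genome],
    phenotypes: np.ndarray,
    lambda_: float,
    r: float,
    mu: float,
    rng: np.random.Generator,
) -> tuple[list[Genome], np.ndarray, list[MatingRecord]]:
    """Random mating among conspecific residents of one patch.

    Every resident seeds one mating with a uniformly drawn distinct partner
    and produces a Poisson(λ) brood via recombination then mutation.  Returns
    the offspring genomes, their mid-parent phenotypes and the mating log.
    A lone resident produces nothing.
    """
    if lambda_ <= 0:
        raise ValueError("offspring rate lambda_ must be positive")
    m = len(residents)
    if m < 2:
        return [], np.empty(0), []
    mates = rng.integers(0, m - 1, size=m)
    mates = mates + (mates >= np.arange(m))
    counts = rng.poisson(lambda_, size=m)
    offspring: list[Genome] = []
    midparents: list[float] = []
    records: list[MatingRecord] = []
    for a in range(m):
        b = int(mates[a])
        mid = 0.5 * (float(phenotypes[a]) + float(phenotypes[b]))
        k = int(counts[a])
        records.append(MatingRecord(a, b, mid, k))
        for _ in range(k):
            child = mutate(recombine(residents[a], residents[b], r, rng), mu, rng)
            offspring.append(child)
            midparents.append(mid)
    return offspring, np.asarray(midparents), records
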