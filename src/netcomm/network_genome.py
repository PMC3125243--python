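"""Boolean gene-network genomes and the phenotypes they encode.

A genome is a single chromosome describing a directed Boolean network of
``n`` genes in which every gene except the basal-most (index 0) receives
exactly one regulatory input ("head").  Construction always attaches a new
gene to a previously added gene, so the head of gene ``i`` satisfies
``heads[i] < i`` and the network is a rooted tree: acyclic, with a unique,
dynamics-free state assignment obtained in one pass from the root downward.

Gene states are binary.  The basal gene carries a heritable ``root_state``
bit; every other gene is on exactly when the state of its head matches its
function bit (1 = activator, 0 = repressor) — the XNOR rule:

    ====================  ==========  ===========
    head state            activator   repressor
    ====================  ==========  ===========
    on  (1)               on          off
    off (0)               off         on
    ====================  ==========  ===========

The quantitative trait is the number of *terminal* genes (out-degree 0) in
the on state, rescaled to the environmental range: ``(env_max / T) * S``
for ``T`` terminals of which ``S`` are on.  Smaller networks therefore
express the trait at coarser resolution than larger ones.

Batch variants (``*_batch``) operate on stacked arrays — one row per
genome — and are the kernels the simulation engine uses; the scalar
functions are thin wrappers around them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Genome",
    "build_topology",
    "build_topology_batch",
    "evaluate_states",
    "evaluate_states_batch",
    "phenotype",
    "phenotype_batch",
    "out_degree_distribution",
    "out_degree_batch",
    "genome_to_text",
    "genome_from_text",
    "genome_to_dot",
]

DEFAULT_ENV_MAX = 140.0

#: sentinel head index for the basal gene, which has no regulator
NO_HEAD = -1


class InvalidGenomeError(ValueError):
    """Raised when a chromosome violates the single-input tree structure."""


@dataclass
class Genome:
    """A single-chromosome encoding of a single-input Boolean gene network.

    Parameters
    ----------
    heads
        Integer array of length ``n_genes``; ``heads[i]`` is the index of
        gene *i*'s unique upstream regulator.  ``heads[0]`` is ``-1`` (the
        basal gene has no input).  The tree invariant ``0 <= heads[i] < i``
        holds for every other gene.
    functions
        Bit array of length ``n_genes``; ``functions[i]`` is 1 if the edge
        into gene *i* is activating, 0 if repressing.  Entry 0 is unused.
    root_state
        Heritable on/off bit of the basal gene.
    """

    heads: np.ndarray
    functions: np.ndarray
    root_state: int

    def __post_init__(self) -> None:
        self.heads = np.asarray(self.heads, dtype=np.int32)
        self.functions = np.asarray(self.functions, dtype=np.int8)
        self.validate()

    @property
    def n_genes(self) -> int:
        return int(self.heads.shape[0])

    def validate(self) -> None:
        """Check every structural invariant; raise :class:`InvalidGenomeError`."""
        n = self.heads.shape[0]
        if n < 1:
            raise InvalidGenomeError("a genome needs at least one gene")
        if self.functions.shape[0] != n:
            raise InvalidGenomeError("heads and functions lengths differ")
        if self.heads[0] != NO_HEAD:
            raise InvalidGenomeError("the basal gene must have no head")
        if n > 1:
            idx = np.arange(1, n)
            h = self.heads[1:]
            if np.any((h < 0) | (h >= idx)):
                raise InvalidGenomeError(
                    "each non-basal gene's head must be an earlier gene "
                    "(acyclic, no self-regulation)"
                )
        if not np.all((self.functions == 0) | (self.functions == 1)):
            raise InvalidGenomeError("function bits must be 0 or 1")
        if self.root_state not in (0, 1):
            raise InvalidGenomeError("root_state must be 0 or 1")

    def copy(self) -> "Genome":
        return Genome(self.heads.copy(), self.functions.copy(), self.root_state)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return (
            self.root_state == other.root_state
            and np.array_equal(self.heads, other.heads)
            and np.array_equal(self.functions, other.functions)
        )


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_topology_batch(
    m: int, n: int, kind: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build ``m`` independent random genomes of ``n`` genes as stacked arrays.

    Returns ``(heads, functions, root_states)`` with shapes ``(m, n)``,
    ``(m, n)`` and ``(m,)``.  For ``kind='random'`` each new gene attaches
    uniformly to a previously added gene.  For ``kind='scale_free'`` a
    lottery rule is used: the attachment probability of an existing gene is
    proportional to its current out-degree plus one (the +1 lets genes with
    no downstream edge yet win their first one), producing the heavy-tailed
    out-degree distributions characteristic of preferential attachment.
    """
    if n < 2:
        raise ValueError(f"network size must be >= 2, got {n}")
    if kind not in ("random", "scale_free"):
        raise ValueError(f"unknown topology kind {kind!r}")
    heads = np.full((m, n), NO_HEAD, dtype=np.int32)
    heads[:, 1] = 0
    if kind == "random":
        for i in range(2, n):
            heads[:, i] = rng.integers(0, i, size=m)
    else:
        # lottery weights: out-degree + 1 over genes 0..i-1, updated per gene
        weights = np.zeros((m, n), dtype=np.float64)
        weights[:, 0] = 1.0
        weights[:, 1] = 1.0
        weights[np.arange(m), heads[:, 1]] += 1.0
        for i in range(2, n):
            w = weights[:, :i]
            cum = np.cumsum(w, axis=1)
            u = rng.random(m) * cum[:, -1]
            choice = (cum > u[:, None]).argmax(axis=1)
            heads[:, i] = choice
            weights[np.arange(m), choice] += 1.0
            weights[:, i] = 1.0
    functions = rng.integers(0, 2, size=(m, n)).astype(np.int8)
    functions[:, 0] = 0  # unused slot
    root_states = rng.integers(0, 2, size=m).astype(np.int8)
    return heads, functions, root_states


def build_topology(n: int, kind: str, rng: np.random.Generator) -> Genome:
    """Construct one random genome of ``n`` genes with the given topology kind."""
    heads, functions, roots = build_topology_batch(1, n, kind, rng)
    return Genome(heads[0], functions[0], int(roots[0]))


# ---------------------------------------------------------------------------
# state evaluation and phenotype
# ---------------------------------------------------------------------------

def evaluate_states_batch(
    heads: np.ndarray, functions: np.ndarray, root_states: np.ndarray
) -> np.ndarray:
    """Gene states for stacked genomes, one topological pass from the root.

    ``states[g, i] = 1`` iff the state of gene *i*'s head equals its function
    bit (XNOR).  Because ``heads[:, i] < i``, a single left-to-right sweep
    resolves every gene.
    """
    m, n = heads.shape
    states = np.zeros((m, n), dtype=np.int8)
    states[:, 0] = root_states
    rows = np.arange(m)
    for i in range(1, n):
        states[:, i] = states[rows, heads[:, i]] == functions[:, i]
    return states


def evaluate_states(genome: Genome) -> np.ndarray:
    """State vector (length ``n_genes``) of a single genome."""
    return evaluate_states_batch(
        genome.heads[None, :],
        genome.functions[None, :],
        np.array([genome.root_state], dtype=np.int8),
    )[0]


def out_degree_batch(heads: np.ndarray) -> np.ndarray:
    """Per-gene out-degree for stacked genomes; each row sums to ``n - 1``."""
    m, n = heads.shape
    if n <= 1:
        return np.zeros((m, n), dtype=np.int32)
    rows = np.repeat(np.arange(m, dtype=np.int64), n - 1)
    flat = rows * n + heads[:, 1:].ravel()
    deg = np.bincount(flat, minlength=m * n).reshape(m, n)
    return deg.astype(np.int32)


def out_degree_distribution(genome: Genome) -> np.ndarray:
    """Out-degree of every gene in a single genome."""
    return out_degree_batch(genome.heads[None, :])[0]


def phenotype_batch(
    heads: np.ndarray,
    functions: np.ndarray,
    root_states: np.ndarray,
    env_max: float = DEFAULT_ENV_MAX,
) -> np.ndarray:
    """Trait values for stacked genomes: ``(env_max / T) * S``.

    ``T`` is the number of terminal genes (out-degree 0) and ``S`` the number
    of those in the on state.  A rooted tree always has at least one leaf,
    so ``T >= 1``.
    """
    if env_max <= 0:
        raise ValueError("env_max must be positive")
    states = evaluate_states_batch(heads, functions, root_states)
    terminal = out_degree_batch(heads) == 0
    t = terminal.sum(axis=1)
    s = (states.astype(bool) & terminal).sum(axis=1)
    return env_max * s / t


def phenotype(genome: Genome, env_max: float = DEFAULT_ENV_MAX) -> float:
    """Quantitative trait value of a single genome on the ``[0, env_max]`` scale."""
    return float(
        phenotype_batch(
            genome.heads[None, :],
            genome.functions[None, :],
            np.array([genome.root_state], dtype=np.int8),
            env_max,
        )[0]
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def genome_to_text(genome: Genome) -> str:
    """Serialize to the plain-text chromosome layout.

    Header line ``n_genes root_state``; one block line per gene with the
    head index (``-`` for the basal gene) and the function bit.
    """
    lines = [f"{genome.n_genes} {genome.root_state}"]
    for i in range(genome.n_genes):
        head = "-" if i == 0 else str(int(genome.heads[i]))
        func = "-" if i == 0 else str(int(genome.functions[i]))
        lines.append(f"{i} {head} {func}")
    return "\n".join(lines) + "\n"


def genome_from_text(text: str) -> Genome:
    """Parse the plain-text chromosome layout back into a :class:`Genome`."""
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    try:
        n, root = (int(tok) for tok in lines[0].split())
    except (ValueError, IndexError) as exc:
        raise InvalidGenomeError(f"bad chromosome header: {lines[0]!r}") from exc
    if len(lines) != n + 1:
        raise InvalidGenomeError(f"expected {n} gene blocks, got {len(lines) - 1}")
    heads = np.full(n, NO_HEAD, dtype=np.int32)
    functions = np.zeros(n, dtype=np.int8)
    for ln in lines[1:]:
        toks = ln.split()
        i = int(toks[0])
        if i != 0:
            heads[i] = int(toks[1])
            functions[i] = int(toks[2])
    return Genome(heads, functions, root)


def genome_to_dot(genome: Genome, states: np.ndarray | None = None) -> str:
    """Export the network as Graphviz DOT; filled nodes are up-regulated."""
    if states is None:
        states = evaluate_states(genome)
    lines = ["digraph genome {"]
    for i in range(genome.n_genes):
        fill = "black" if states[i] else "white"
        font = "white" if states[i] else "black"
        lines.append(
            f'  g{i} [style=filled, fillcolor={fill}, fontcolor={font}];'
        )
    for i in range(1, genome.n_genes):
        style = "solid" if genome.functions[i] else "dashed"
        lines.append(f"  g{genome.heads[i]} -> g{i} [style={style}];")
    lines.append("}")
    return "\n".join(lines) + "\n"
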