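"""Gaussian stabilizing selection, the three-stage death process, and
per-patch resource-quality dynamics.

Fitness is relative to the local environment: an individual whose trait sits
a distance Δ from the patch's resource quality survives the viability stage
with probability ``RF = exp(−Δ² / (2ω²))``, the standard Gaussian
stabilizing-selection kernel with breadth ω (default 2).  Competition acts
through this stage: whichever species tracks the local optimum better loses
fewer offspring.

Death happens in three stages each generation: all parents are killed
(non-overlapping generations), offspring are culled by relative fitness,
and finally a carrying capacity K (default 200 per patch) is enforced by
killing uniformly random individuals — regardless of species or fitness —
until the joint patch census is at most K.

Each patch's resource quality drifts at a configured per-generation rate
(default set {1e−3, 2.5e−4, 1e−4} units/generation), reflecting off the
ends of the trait range.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from netcomm.network_genome import DEFAULT_ENV_MAX

__all__ = [
    "Patch",
    "relative_fitness",
    "viability_cull",
    "capacity_cull",
    "kill_parents",
    "update_resource",
    "DEFAULT_RATES",
]

#: per-generation rates of resource-quality change used in the experiments
DEFAULT_RATES = (1e-3, 2.5e-4, 1e-4)


@dataclass
class Patch:
    """A circular habitat patch.

    ``resource_quality`` is the evolving trait optimum on the environmental
    scale ``[0, env_max]``; ``rate`` is its per-generation change, applied
    by :func:`update_resource` in the configured ``drift`` mode.
    """

    id: int
    center: tuple[float, float]
    radius: float
    K: int
    resource_quality: float
    rate: float

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("carrying capacity K must be positive")
        if self.radius <= 0:
            raise ValueError("patch radius must be positive")


def relative_fitness(delta, omega: float = 2.0):
    """Survival probability for trait–environment distance ``delta``.

    ``RF = exp(−Δ² / (2ω²))``; equals 1 at a perfect match and decays
    monotonically with the mismatch.  Accepts scalars or arrays.
    """
    if omega <= 0:
        raise ValueError("selection breadth omega must be positive")
    delta = np.abs(delta)
    return np.exp(-(delta**2) / (2.0 * omega**2))


def viability_cull(
    phenotypes: np.ndarray,
    resource_quality: float,
    omega: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean survival mask: each individual survives w.p. its relative fitness."""
    phenotypes = np.asarray(phenotypes, dtype=float)
    if phenotypes.size == 0:
        return np.zeros(0, dtype=bool)
    rf = relative_fitness(resource_quality - phenotypes, omega)
    return rng.random(phenotypes.size) < rf


def capacity_cull(census: int, K: int, rng: np.random.Generator) -> np.ndarray:
    """Indices of survivors after the carrying-capacity stage in one patch.

    If the joint (both-species) census exceeds ``K``, uniformly random
    individuals are removed — without regard to species or fitness — until
    exactly ``K`` remain; otherwise everyone survives.  Returns sorted
    indices into the patch's resident list.
    """
    if K <= 0:
        raise ValueError("carrying capacity K must be positive")
    if census <= K:
        return np.arange(census)
    keep = rng.choice(census, size=K, replace=False)
    keep.sort()
    return keep


def kill_parents(parents, offspring):
    """Non-overlapping generations: the next cohort is the offspring alone."""
    return offspring


def update_resource(
    patch: Patch,
    env_max: float = DEFAULT_ENV_MAX,
    drift: str = "increase",
    rng: np.random.Generator | None = None,
) -> Patch:
    """Advance a patch's resource quality by one generation.

    ``drift`` selects the direction of change: ``'increase'`` (default) and
    ``'decrease'`` move deterministically at ``patch.rate`` per generation;
    ``'random_walk'`` takes a ±rate step.  Values reflect off the
    ``[0, env_max]`` boundaries.
    """
    if drift == "increase":
        step = patch.rate
    elif drift == "decrease":
        step = -patch.rate
    elif drift == "random_walk":
        if rng is None:
            raise ValueError("random_walk drift needs an rng")
        step = patch.rate if rng.random() < 0.5 else -patch.rate
    else:
        raise ValueError(f"unknown drift mode {drift!r}")
    q = patch.resource_quality + step
    if q > env_max:
        q = 2.0 * env_max - q
    elif q < 0.0:
        q = -q
    return replace(patch, resource_quality=q)
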