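"""Three-patch landscape geometry and the passive dispersal kernel.

The landscape is three equal circular patches whose centers sit at the
vertices of an equilateral triangle, spaced ``edge_gap`` units edge to edge
(default 50).  Dispersers are passive — seeds or resting-stage eggs rather
than habitat selectors: with probability ``d`` an individual departs from a
uniform-random point inside its source patch, travels a uniform distance in
[0, 100] units at a uniform angle, and survives only if it lands inside
some patch (possibly its own).  Landing in the matrix between patches is
immediately lethal.  With the default patch radius of 10, center spacing is
70 units, so inter-patch moves are possible but most long-range moves die —
successful colonization is rare and costly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from netcomm.network_genome import DEFAULT_ENV_MAX
from netcomm.selection_demography import Patch, DEFAULT_RATES

__all__ = [
    "Landscape",
    "build_landscape",
    "locate_patch",
    "attempt_dispersal",
    "disperse_batch",
    "MAX_DISPERSAL_DISTANCE",
    "DEFAULT_RADIUS",
    "DEFAULT_EDGE_GAP",
]

MAX_DISPERSAL_DISTANCE = 100.0
DEFAULT_RADIUS = 10.0
DEFAULT_EDGE_GAP = 50.0

#: outcome codes for a dispersal attempt
STAYED, MOVED, DIED = "stayed", "moved", "died"


@dataclass
class Landscape:
    """Exactly three pairwise-equidistant, non-overlapping circular patches."""

    patches: list[Patch]
    edge_gap: float
    env_max: float = DEFAULT_ENV_MAX

    def __post_init__(self) -> None:
        if len(self.patches) != 3:
            raise ValueError("a landscape has exactly three patches")

    @property
    def centers(self) -> np.ndarray:
        return np.array([p.center for p in self.patches])

    @property
    def heterogeneity(self) -> int:
        """Number of unique per-patch rates of resource-quality change (1–3)."""
        return len({p.rate for p in self.patches})


def build_landscape(
    radius: float = DEFAULT_RADIUS,
    edge_gap: float = DEFAULT_EDGE_GAP,
    rates: tuple[float, float, float] = DEFAULT_RATES,
    env_max: float = DEFAULT_ENV_MAX,
    K: int = 200,
    env_init: float = 70.0,
) -> Landscape:
    """Place three patches at the vertices of an equilateral triangle.

    Side length is ``edge_gap + 2*radius`` so patch edges sit ``edge_gap``
    apart.  ``rates`` assigns each patch its per-generation resource drift;
    the count of unique values is the landscape heterogeneity.
    """
    if radius <= 0:
        raise ValueError("patch radius must be positive")
    if edge_gap < 0:
        raise ValueError("edge gap cannot be negative")
    rates = tuple(rates)
    if len(rates) != 3:
        raise ValueError(f"need exactly 3 patch rates, got {len(rates)}")
    side = edge_gap + 2.0 * radius
    centers = [
        (0.0, 0.0),
        (side, 0.0),
        (side / 2.0, side * np.sqrt(3.0) / 2.0),
    ]
    patches = [
        Patch(
            id=i,
            center=centers[i],
            radius=radius,
            K=K,
            resource_quality=env_init,
            rate=rates[i],
        )
        for i in range(3)
    ]
    return Landscape(patches=patches, edge_gap=edge_gap, env_max=env_max)


def locate_patch(point: tuple[float, float], landscape: Landscape) -> Patch | None:
    """The patch whose closed disc contains ``point``, or None (the matrix).

    Patches do not overlap, so at most one patch qualifies.
    """
    x, y = point
    for p in landscape.patches:
        cx, cy = p.center
        if (x - cx) ** 2 + (y - cy) ** 2 <= p.radius**2:
            return p
    return None


def disperse_batch(
    m: int,
    source: Patch,
    d: float,
    landscape: Landscape,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized dispersal outcomes for ``m`` individuals in one patch.

    Returns an int array of length ``m``: the destination patch id for each
    survivor (equal to ``source.id`` for those that stayed or landed back
    home) and ``-1`` for those that dispersed into the matrix and died.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError("dispersal probability must be in [0, 1]")
    dest = np.full(m, source.id, dtype=np.int64)
    if m == 0 or d == 0.0:
        return dest
    moving = rng.random(m) < d
    k = int(moving.sum())
    if k == 0:
        return dest
    # uniform origin inside the source disc
    r0 = source.radius * np.sqrt(rng.random(k))
    a0 = rng.random(k) * 2.0 * np.pi
    ox = source.center[0] + r0 * np.cos(a0)
    oy = source.center[1] + r0 * np.sin(a0)
    # uniform flight angle and distance
    angle = rng.random(k) * 2.0 * np.pi
    dist = rng.random(k) * MAX_DISPERSAL_DISTANCE
    ex = ox + dist * np.cos(angle)
    ey = oy + dist * np.sin(angle)
    landed = np.full(k, -1, dtype=np.int64)
    for p in landscape.patches:
        cx, cy = p.center
        inside = (ex - cx) ** 2 + (ey - cy) ** 2 <= p.radius**2
        landed[inside] = p.id
    dest[moving] = landed
    return dest


def attempt_dispersal(
    source: Patch,
    d: float,
    landscape: Landscape,
    rng: np.random.Generator,
) -> tuple[str, Patch | None]:
    """One individual's dispersal attempt.

    Returns ``("stayed", source)``, ``("moved", destination)`` (destination
    may be the source patch if the flight loops back inside it), or
    ``("died", None)`` for a landing in the inter-patch matrix.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError("dispersal probability must be in [0, 1]")
    if rng.random() >= d:
        return STAYED, source
    r0 = source.radius * np.sqrt(rng.random())
    a0 = rng.random() * 2.0 * np.pi
    origin = (
        source.center[0] + r0 * np.cos(a0),
        source.center[1] + r0 * np.sin(a0),
    )
    angle = rng.random() * 2.0 * np.pi
    dist = rng.random() * MAX_DISPERSAL_DISTANCE
    endpoint = (
        origin[0] + dist * np.cos(angle),
        origin[1] + dist * np.sin(angle),
    )
    target = locate_patch(endpoint, landscape)
    if target is None:
        return DIED, None
    return MOVED, target
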