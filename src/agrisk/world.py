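"""Spatial world model and distance-kernel disease transmission.

The simulated production system is one player-controlled facility surrounded
by computer-controlled neighbors on a 2-D arena.  Disease spreads between
facilities with a probability that decays with the square of Euclidean
distance and is attenuated by the *target* facility's biosecurity level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Sequence

import numpy as np

__all__ = [
    "PLAYER_ID",
    "MONTHS_PER_ROUND",
    "BiosecurityLevel",
    "Facility",
    "TransmissionParams",
    "LayoutParams",
    "WorldState",
    "init_world",
    "transmission_probability",
    "combine_sources",
    "step_month",
    "infection_frequency",
]

#: Reserved facility index of the participant's facility.
PLAYER_ID = 0

#: A round ("decision year") consists of six decision months.
MONTHS_PER_ROUND = 6


class BiosecurityLevel(IntEnum):
    """Ordinal biosecurity protection level of a facility."""

    NONE = 0
    LOW = 1
    MEDIUM = 2
    HIGH = 3


@dataclass(frozen=True)
class TransmissionParams:
    """Parameters of the distance-decay transmission kernel.

    Parameters
    ----------
    p_inf:
        Baseline per-month transmission probability at unit distance.
    per_level_factor:
        Fraction of the raw probability *retained* per biosecurity level of
        the target.  The default 0.75 means each successive level reduces
        the probability of infection by 25%.
    min_distance:
        Distance floor; closer pairs are treated as being at this distance
        so the raw probability never exceeds ``p_inf``.
    adjustment:
        ``"multiplicative"``: retained fraction ``per_level_factor ** level``
        (compounding 25% reductions).  ``"linear"``: retained fraction
        ``1 - (1 - per_level_factor) * level``, floored at 0 (a flat 25
        percentage-point-of-the-raw-value cut per level).
    """

    p_inf: float = 0.15
    per_level_factor: float = 0.75
    min_distance: float = 1.0
    adjustment: str = "multiplicative"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_inf <= 1.0:
            raise ValueError(f"p_inf must be in [0, 1], got {self.p_inf}")
        if not 0.0 <= self.per_level_factor <= 1.0:
            raise ValueError(
                f"per_level_factor must be in [0, 1], got {self.per_level_factor}"
            )
        if self.min_distance <= 0:
            raise ValueError("min_distance must be positive")
        if self.adjustment not in ("multiplicative", "linear"):
            raise ValueError(f"unknown adjustment {self.adjustment!r}")

    def level_retention(self, level) -> np.ndarray | float:
        """Fraction of the raw probability retained at a biosecurity level."""
        level = np.asarray(level)
        if self.adjustment == "multiplicative":
            out = self.per_level_factor ** level
        else:
            out = np.maximum(1.0 - (1.0 - self.per_level_factor) * level, 0.0)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class LayoutParams:
    """Arena geometry: a square of side ``arena_side`` with the player at its
    center and computer facilities placed uniformly at random."""

    arena_side: float = 10.0

    def __post_init__(self) -> None:
        if self.arena_side <= 0:
            raise ValueError("arena_side must be positive")


@dataclass(frozen=True)
class Facility:
    """Read-only view of one facility's state."""

    id: int
    position: tuple[float, float]
    biosecurity: BiosecurityLevel
    infected: bool

    @property
    def is_player(self) -> bool:
        return self.id == PLAYER_ID


@dataclass
class WorldState:
    """Positions, biosecurity levels, and infection flags of all facilities.

    Index 0 is the player; indices ``1..n`` are the computer-controlled
    neighbors.  Positions are fixed within a round, and the infected set is
    monotone non-decreasing (there is no recovery).
    """

    positions: np.ndarray  # (n_total, 2) float
    levels: np.ndarray  # (n_total,) int in 0..3
    infected: np.ndarray  # (n_total,) bool
    month: int = 1
    distances: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.levels = np.asarray(self.levels, dtype=np.int64)
        self.infected = np.asarray(self.infected, dtype=bool)
        n = self.positions.shape[0]
        if self.levels.shape != (n,) or self.infected.shape != (n,):
            raise ValueError("positions, levels and infected sizes disagree")
        if np.any(self.levels < 0) or np.any(self.levels > 3):
            raise ValueError("biosecurity levels must be in 0..3")
        if self.distances is None:
            diff = self.positions[:, None, :] - self.positions[None, :, :]
            self.distances = np.sqrt((diff ** 2).sum(axis=-1))

    @property
    def n_total(self) -> int:
        return self.positions.shape[0]

    @property
    def n_computer(self) -> int:
        return self.n_total - 1

    @property
    def player_infected(self) -> bool:
        return bool(self.infected[PLAYER_ID])

    @property
    def player_level(self) -> int:
        return int(self.levels[PLAYER_ID])

    @property
    def facilities(self) -> list[Facility]:
        return [
            Facility(
                id=i,
                position=(float(self.positions[i, 0]), float(self.positions[i, 1])),
                biosecurity=BiosecurityLevel(int(self.levels[i])),
                infected=bool(self.infected[i]),
            )
            for i in range(self.n_total)
        ]

    def copy(self) -> "WorldState":
        # Hot path: bypass __post_init__ revalidation; positions/distances
        # are fixed within a round and shared, mutable arrays are copied.
        new = object.__new__(WorldState)
        new.positions = self.positions
        new.levels = self.levels.copy()
        new.infected = self.infected.copy()
        new.month = self.month
        new.distances = self.distances
        return new


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def init_world(
    n_facilities: int,
    rng_seed,
    layout_params: LayoutParams | None = None,
) -> WorldState:
    """Create a fresh round world.

    ``n_facilities`` computer neighbors are placed uniformly at random in a
    square arena, each with a biosecurity level drawn uniformly from
    {0, 1, 2, 3}; the player sits at the arena center at level 0.  Exactly
    one randomly chosen computer facility starts the round infected.
    """
    if n_facilities < 1:
        raise ValueError(f"need at least one computer facility, got {n_facilities}")
    layout = layout_params or LayoutParams()
    rng = _as_rng(rng_seed)
    side = layout.arena_side
    positions = np.empty((n_facilities + 1, 2), dtype=float)
    positions[PLAYER_ID] = (side / 2.0, side / 2.0)
    positions[1:] = rng.uniform(0.0, side, size=(n_facilities, 2))
    levels = np.zeros(n_facilities + 1, dtype=np.int64)
    levels[1:] = rng.integers(0, 4, size=n_facilities)
    infected = np.zeros(n_facilities + 1, dtype=bool)
    seed_idx = 1 + int(rng.integers(0, n_facilities))
    infected[seed_idx] = True
    return WorldState(positions=positions, levels=levels, infected=infected, month=1)


def transmission_probability(
    distance: float, target_level: int, params: TransmissionParams
) -> float:
    """Per-month probability that one infected source infects a clean target.

    The raw probability ``p_inf / D**2`` (with D floored at ``min_distance``
    and the result clamped to [0, 1]) is attenuated by the target facility's
    biosecurity level.
    """
    if distance < 0:
        raise ValueError(f"distance must be non-negative, got {distance}")
    if distance == 0:
        raise ValueError("distance must be positive (distinct facilities)")
    if not 0 <= int(target_level) <= 3:
        raise ValueError(f"target_level must be in 0..3, got {target_level}")
    d = max(float(distance), params.min_distance)
    raw = min(params.p_inf / d ** 2, 1.0)
    return float(raw * params.level_retention(int(target_level)))


def _pair_probabilities(
    distances: np.ndarray, target_levels: np.ndarray, params: TransmissionParams
) -> np.ndarray:
    """Vectorized transmission_probability: distances (..., k) x levels (k,)."""
    d = np.maximum(distances, params.min_distance)
    raw = np.minimum(params.p_inf / d ** 2, 1.0)
    return raw * params.level_retention(target_levels)


def combine_sources(per_source_probabilities: Sequence[float]) -> float:
    """Probability of at least one successful transmission among independent
    sources: ``1 - prod(1 - p_i)``; an empty list gives 0."""
    p = np.asarray(list(per_source_probabilities), dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1)):
        raise ValueError("source probabilities must lie in [0, 1]")
    if p.size == 0:
        return 0.0
    return float(1.0 - np.prod(1.0 - p))


def step_month(
    world: WorldState, params: TransmissionParams, rng
) -> WorldState:
    """Advance the world by one month of disease spread.

    Every currently uninfected facility independently becomes infected with
    the combined probability over all currently infected facilities (new
    infections do not transmit until the following month).
    """
    if world.month > MONTHS_PER_ROUND:
        raise RuntimeError("cannot step a finished round (month > 6)")
    rng = _as_rng(rng)
    new_world = world.copy()
    inf = world.infected
    if inf.any() and not inf.all():
        sus_idx = np.flatnonzero(~inf)
        d = world.distances[np.ix_(inf, ~inf)]
        pair_p = _pair_probabilities(d, world.levels[sus_idx], params)
        p_any = 1.0 - np.prod(1.0 - pair_p, axis=0)
        hits = rng.random(p_any.size) < p_any
        new_world.infected[sus_idx[hits]] = True
    new_world.month = world.month + 1
    return new_world


def infection_frequency(
    distance: float,
    target_level: int,
    params: TransmissionParams,
    n_replicates: int,
    rng_seed,
) -> float:
    """Monte-Carlo estimate of the one-month infection probability.

    Builds a minimal two-facility world (one infected source at ``distance``
    from an unprotected-or-protected target) and runs ``step_month`` on
    ``n_replicates`` independent replicates, returning the infected fraction.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = _as_rng(rng_seed)
    template = WorldState(
        positions=np.array([[0.0, 0.0], [float(distance), 0.0]]),
        levels=np.array([target_level, 0]),
        infected=np.array([False, True]),
        month=1,
    )
    hits = 0
    for _ in range(n_replicates):
        stepped = step_month(template, params, rng)
        hits += int(stepped.infected[PLAYER_ID])
    return hits / n_replicates
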