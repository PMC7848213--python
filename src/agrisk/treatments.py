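"""Information treatments: per-round visibility regimes and the schedule
generator.

A treatment controls whether the neighbors' disease status and biosecurity
configuration are shown, cloaked, or purchasable ("revealable") at one of
two price points.  One quarter of the rounds in a default session are fully
visible; the remaining 75% inject uncertainty, covering every combination
of the two visibility dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "Visibility",
    "TreatmentSpec",
    "FULL_VISIBILITY",
    "REVEAL_PRICES",
    "generate_treatment_schedule",
]

REVEAL_PRICES = (1_000.0, 2_000.0)


class Visibility(str, Enum):
    VISIBLE = "visible"
    HIDDEN = "hidden"
    REVEALABLE = "revealable"


@dataclass(frozen=True)
class TreatmentSpec:
    """Visibility regime of one round; prices present iff revealable."""

    disease_visibility: Visibility
    biosecurity_visibility: Visibility
    reveal_price_disease: float | None = None
    reveal_price_biosecurity: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "disease_visibility", Visibility(self.disease_visibility)
        )
        object.__setattr__(
            self, "biosecurity_visibility", Visibility(self.biosecurity_visibility)
        )
        for vis, price, name in (
            (self.disease_visibility, self.reveal_price_disease, "disease"),
            (self.biosecurity_visibility, self.reveal_price_biosecurity, "biosecurity"),
        ):
            if (vis is Visibility.REVEALABLE) != (price is not None):
                raise ValueError(
                    f"reveal price for {name} must be present iff its "
                    f"visibility is revealable"
                )
            if price is not None and price <= 0:
                raise ValueError("reveal prices must be positive")

    @property
    def fully_visible(self) -> bool:
        return (
            self.disease_visibility is Visibility.VISIBLE
            and self.biosecurity_visibility is Visibility.VISIBLE
        )


FULL_VISIBILITY = TreatmentSpec(Visibility.VISIBLE, Visibility.VISIBLE)

# The eight visibility combinations that inject uncertainty (everything
# except visible/visible).
_UNCERTAIN_COMBOS = [
    (d, b)
    for d in Visibility
    for b in Visibility
    if not (d is Visibility.VISIBLE and b is Visibility.VISIBLE)
]


def generate_treatment_schedule(
    n_rounds: int = 32,
    rng_seed=0,
    reveal_prices: tuple[float, float] = REVEAL_PRICES,
) -> list[TreatmentSpec]:
    """Build a shuffled per-round treatment schedule.

    Exactly ``n_rounds / 4`` rounds are fully visible; the rest cycle
    round-robin over the eight uncertainty combinations, with revealable
    dimensions alternating between the two price points so both prices
    occur for disease reveals and for biosecurity reveals.

    ``n_rounds`` must be divisible by 4 and large enough (>= 24) that every
    uncertainty combination appears at least twice (price coverage).
    """
    if n_rounds % 4 != 0:
        raise ValueError(f"n_rounds must be divisible by 4, got {n_rounds}")
    n_uncertain = 3 * n_rounds // 4
    if n_uncertain < 2 * len(_UNCERTAIN_COMBOS):
        raise ValueError(
            f"n_rounds={n_rounds} cannot cover every uncertainty combination "
            f"at both reveal prices; need at least 24 rounds"
        )
    n_full = n_rounds // 4
    schedule: list[TreatmentSpec] = [FULL_VISIBILITY] * n_full

    # Round-robin instance counts per combo, then alternate prices within
    # each combo's instances.
    base, extra = divmod(n_uncertain, len(_UNCERTAIN_COMBOS))
    for ci, (dis, bio) in enumerate(_UNCERTAIN_COMBOS):
        count = base + (1 if ci < extra else 0)
        for i in range(count):
            price = reveal_prices[i % 2]
            schedule.append(
                TreatmentSpec(
                    disease_visibility=dis,
                    biosecurity_visibility=bio,
                    reveal_price_disease=(
                        price if dis is Visibility.REVEALABLE else None
                    ),
                    reveal_price_biosecurity=(
                        price if bio is Visibility.REVEALABLE else None
                    ),
                )
            )

    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    order = rng.permutation(len(schedule))
    return [schedule[i] for i in order]
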