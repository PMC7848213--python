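"""Game economy: costs, penalties, endowment, and USD conversion."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["EconomyParams", "convert_to_usd", "EXPO_CONVERSION", "MTURK_CONVERSION"]

#: Simulation dollars per 1 USD for in-person (trade-show) participants.
EXPO_CONVERSION = 12_000.0
#: Simulation dollars per 1 USD for online participants.
MTURK_CONVERSION = 23_500.0


@dataclass(frozen=True)
class EconomyParams:
    """Monetary parameters of the game, in simulation dollars.

    ``round_endowment`` is the per-round operating income; the sources only
    report net session profits, so its level is a free configuration knob
    and session-profit magnitudes are not comparable across settings.
    """

    upgrade_cost: float = 1_000.0
    infection_penalty: float = 25_000.0
    reveal_count: int = 10
    round_endowment: float = 10_000.0
    usd_conversion: float = MTURK_CONVERSION

    def __post_init__(self) -> None:
        for name in ("upgrade_cost", "infection_penalty", "round_endowment"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.reveal_count < 1:
            raise ValueError("reveal_count must be >= 1")
        if self.usd_conversion <= 0:
            raise ValueError("usd_conversion must be positive")


def convert_to_usd(sim_dollars: float, usd_conversion: float) -> float:
    """Convert simulation dollars to USD at ``usd_conversion`` sim-$ per $1."""
    if usd_conversion <= 0:
        raise ValueError("usd_conversion must be positive")
    return sim_dollars / usd_conversion
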