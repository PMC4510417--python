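"""The 14 muscle-combination analysis schemes.

Eight muscles are recorded per leg: five thigh muscles — vastus lateralis
(VL), rectus femoris (RF), semitendinosus (SE), biceps femoris (BF), tensor
fasciae latae (TF) — and three lower-leg muscles — tibialis anterior (TA),
soleus (SO), lateral gastrocnemius (LG).  Four data-organization strategies
give 14 schemes in total:

1. all 8 muscles of one leg over the entire gait cycle (2 schemes);
2. all 8 muscles of one leg over one gait phase (4 schemes);
3. the 3 lower-leg muscles of one leg over one gait phase (4 schemes);
4. the 5 thigh muscles of one leg over one gait phase (4 schemes).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SchemeSpec", "enumerate_schemes", "MUSCLES", "MUSCLE_SETS", "default_muscle_map"]

#: per-leg muscle roster, thigh first then lower leg
MUSCLES = ["VL", "RF", "SE", "BF", "TF", "TA", "SO", "LG"]

MUSCLE_SETS = {
    "all8": MUSCLES,
    "lower3": ["TA", "SO", "LG"],
    "thigh5": ["VL", "RF", "SE", "BF", "TF"],
}

_STRATEGY_SET = {1: "all8", 2: "all8", 3: "lower3", 4: "thigh5"}

_SIDE_PREFIX = {"left": "L", "right": "R"}


@dataclass(frozen=True)
class SchemeSpec:
    """One (muscle subset, side, segment) analysis configuration."""

    id: int
    strategy: int
    side: str           # left | right
    segment: str        # full | stance | swing
    muscle_set: str     # all8 | lower3 | thigh5
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.strategy == 1:
            if self.segment != "full" or self.muscle_set != "all8":
                raise ValueError("strategy 1 uses the full cycle on all 8 muscles")
        else:
            if self.segment not in ("stance", "swing"):
                raise ValueError("strategies 2-4 analyse one gait phase")
            if self.muscle_set != _STRATEGY_SET[self.strategy]:
                raise ValueError(
                    f"strategy {self.strategy} uses muscle set {_STRATEGY_SET[self.strategy]}"
                )

    @property
    def n_channels(self) -> int:
        return len(self.channels)


def default_muscle_map() -> dict[str, list[str]]:
    """Channel labels per side: ``L_VL .. L_LG, R_VL .. R_LG``."""
    return {side: [f"{p}_{m}" for m in MUSCLES] for side, p in _SIDE_PREFIX.items()}


def _resolve(muscle_map: dict[str, list[str]], side: str, muscle_set: str) -> tuple[str, ...]:
    leg = muscle_map[side]
    if len(leg) != len(MUSCLES):
        raise ValueError(f"muscle map for {side} must list the 8 muscles {MUSCLES}")
    by_muscle = dict(zip(MUSCLES, leg))
    try:
        return tuple(by_muscle[m] for m in MUSCLE_SETS[muscle_set])
    except KeyError as exc:  # pragma: no cover - guarded by length check
        raise ValueError(f"missing muscle label: {exc}") from None


def enumerate_schemes(muscle_map: dict[str, list[str]] | None = None) -> list[SchemeSpec]:
    """All 14 schemes in deterministic (strategy, side, segment) order.

    The channel-count sequence over the returned list is
    (8, 8, 8, 8, 8, 8, 3, 3, 3, 3, 5, 5, 5, 5).
    """
    muscle_map = muscle_map if muscle_map is not None else default_muscle_map()
    for side in ("left", "right"):
        if side not in muscle_map:
            raise ValueError(f"muscle map missing side {side!r}")
    schemes: list[SchemeSpec] = []
    next_id = 1
    for side in ("left", "right"):
        schemes.append(
            SchemeSpec(
                id=next_id, strategy=1, side=side, segment="full",
                muscle_set="all8", channels=_resolve(muscle_map, side, "all8"),
            )
        )
        next_id += 1
    for strategy in (2, 3, 4):
        mset = _STRATEGY_SET[strategy]
        for side in ("left", "right"):
            for segment in ("stance", "swing"):
                schemes.append(
                    SchemeSpec(
                        id=next_id, strategy=strategy, side=side, segment=segment,
                        muscle_set=mset, channels=_resolve(muscle_map, side, mset),
                    )
                )
                next_id += 1
    return schemes
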