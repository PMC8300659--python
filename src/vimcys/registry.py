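"""Registry of crosslinking and oxidizing agents.

Spacer-arm lengths are the manufacturer-quoted maximal S-to-S (or N-to-N)
distances bridged by each reagent, in Angstrom.  The registry is shared by
the densitometry analyses (spacer-length selectivity) and the structural
feasibility classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable

CHEMISTRIES = ("thiol", "amine", "oxidant")


@dataclass(frozen=True)
class Crosslinker:
    """A bifunctional (or trifunctional) crosslinking agent.

    Parameters
    ----------
    name
        Registry key, e.g. ``"DBB"``.
    chemistry
        Reactive chemistry: ``"thiol"`` (maleimide/bromo, targets Cys SG),
        ``"amine"`` (NHS ester, targets Lys NZ), or ``"oxidant"``
        (disulfide-inducing; no spacer arm).
    spacer_arm
        Spacer-arm length in A; ``None`` for oxidants, which form a direct
        S-S bond.
    arms
        Number of reactive arms (TMEA is trifunctional).
    reversible
        True for disulfide-forming agents (reducible crosslink).
    """

    name: str
    chemistry: str
    spacer_arm: float | None = None
    arms: int = 2
    reversible: bool = False

    def __post_init__(self) -> None:
        if self.chemistry not in CHEMISTRIES:
            raise ValueError(
                f"unknown chemistry {self.chemistry!r} for {self.name!r}; "
                f"expected one of {CHEMISTRIES}"
            )
        if self.chemistry != "oxidant":
            if self.spacer_arm is None or self.spacer_arm <= 0:
                raise ValueError(
                    f"chemical crosslinker {self.name!r} needs spacer_arm > 0"
                )


#: Default registry: thiol crosslinkers of increasing spacer length, the
#: amine-reactive control DST, and the disulfide-inducing oxidants.
DEFAULT_REGISTRY: tuple[Crosslinker, ...] = (
    Crosslinker("DBB", "thiol", spacer_arm=4.88),
    Crosslinker("TMEA", "thiol", spacer_arm=10.3, arms=3),
    Crosslinker("BMH", "thiol", spacer_arm=13.0),
    Crosslinker("DST", "amine", spacer_arm=6.4),
    Crosslinker("diamide", "oxidant", reversible=True),
    Crosslinker("H2O2", "oxidant", reversible=True),
)


def validate_registry(registry: Iterable[Crosslinker]) -> list[Crosslinker]:
    """Return the registry as a list, rejecting duplicate names."""
    entries = list(registry)
    names = [x.name for x in entries]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate crosslinker entries: {dupes}")
    return entries


def registry_to_json(registry: Iterable[Crosslinker], path: str | Path) -> None:
    entries = validate_registry(registry)
    Path(path).write_text(json.dumps([asdict(x) for x in entries], indent=1))


def registry_from_json(path: str | Path) -> list[Crosslinker]:
    raw = json.loads(Path(path).read_text())
    return validate_registry(Crosslinker(**entry) for entry in raw)


def get(registry: Iterable[Crosslinker], name: str) -> Crosslinker:
    for x in registry:
        if x.name == name:
            return x
    raise KeyError(name)
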