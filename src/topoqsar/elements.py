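"""Element data backing the Kier–Hall valence-degree and mass-weighted descriptors.

Each entry carries the atomic number Z, the valence-electron count Zv, the
principal quantum number L of the valence shell, and the relative atomic
mass.  These are the only element properties any descriptor in this package
consumes.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ElementInfo:
    symbol: str
    Z: int
    Zv: int
    L: int
    mass: float

    def __post_init__(self) -> None:
        if not (0 < self.Zv <= self.Z):
            raise ValueError(f"{self.symbol}: require 0 < Zv <= Z")
        if self.L < 1 or self.mass <= 0:
            raise ValueError(f"{self.symbol}: invalid L or mass")


ELEMENTS: dict[str, ElementInfo] = {
    e.symbol: e
    for e in [
        ElementInfo("H", 1, 1, 1, 1.008),
        ElementInfo("B", 5, 3, 2, 10.81),
        ElementInfo("C", 6, 4, 2, 12.011),
        ElementInfo("N", 7, 5, 2, 14.007),
        ElementInfo("O", 8, 6, 2, 15.999),
        ElementInfo("F", 9, 7, 2, 18.998),
        ElementInfo("Si", 14, 4, 3, 28.085),
        ElementInfo("P", 15, 5, 3, 30.974),
        ElementInfo("S", 16, 6, 3, 32.06),
        ElementInfo("Cl", 17, 7, 3, 35.45),
        ElementInfo("Br", 35, 7, 4, 79.904),
        ElementInfo("I", 53, 7, 5, 126.904),
    ]
}

#: mass of carbon, the Burden-matrix diagonal normaliser
CARBON_MASS = ELEMENTS["C"].mass


def valence_degree(symbol: str, h_count: int) -> float:
    """Kier–Hall valence degree delta_v for a neutral atom.

    Second-period atoms use ``Zv - h``; heavier atoms use the
    core-electron-corrected form ``(Zv - h) / (Z - Zv - 1)``.
    """
    try:
        e = ELEMENTS[symbol]
    except KeyError:
        raise ValueError(f"element {symbol!r} not supported for valence degree") from None
    if e.L <= 2:
        return float(e.Zv - h_count)
    return (e.Zv - h_count) / (e.Z - e.Zv - 1)
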