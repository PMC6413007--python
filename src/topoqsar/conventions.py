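"""Convention toggles for descriptor definitions that the literature leaves open.

Two families of descriptors in this package have more than one defensible
definition in the printed sources:

* the combined connectivity indices ``C`` (quotient) and ``D`` (difference)
  of the simple and valence chi of the same order/kind -- the orientation of
  the quotient and of the difference is not written out anywhere;
* the Burden connectivity matrix behind the BELm eigenvalue descriptors --
  Burden's original off-diagonal recipe versus a plain variant without the
  terminal-bond increment.

Screening counts are sensitive to these choices, so they are first-class,
recorded configuration rather than hidden constants.  ``Conventions`` also
carries the R-group marker semantics used by the library builder.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

#: C = chi / chi_v ("simple_over_valence") or chi_v / chi ("valence_over_simple")
C_ORIENTATIONS = ("simple_over_valence", "valence_over_simple")
#: D = chi - chi_v ("simple_minus_valence") or chi_v - chi ("valence_minus_simple")
D_ORIENTATIONS = ("simple_minus_valence", "valence_minus_simple")
#: Burden off-diagonal recipe
BURDEN_VARIANTS = ("original", "plain")


@dataclass(frozen=True)
class Conventions:
    """Bundle of convention switches, recorded in every output's metadata."""

    cd_quotient: str = "simple_over_valence"
    cd_difference: str = "simple_minus_valence"
    burden: str = "original"
    #: True: the [R] marker is itself the attachment atom (kept as carbon or a
    #: configured element).  False: the marker is a placeholder removed on
    #: attachment, bonding its scaffold and fragment neighbours directly.
    marker_is_atom: bool = True

    def __post_init__(self) -> None:
        if self.cd_quotient not in C_ORIENTATIONS:
            raise ValueError(f"cd_quotient must be one of {C_ORIENTATIONS}")
        if self.cd_difference not in D_ORIENTATIONS:
            raise ValueError(f"cd_difference must be one of {D_ORIENTATIONS}")
        if self.burden not in BURDEN_VARIANTS:
            raise ValueError(f"burden must be one of {BURDEN_VARIANTS}")

    def with_(self, **kwargs) -> "Conventions":
        return replace(self, **kwargs)

    def describe(self) -> dict[str, str]:
        return {
            "cd_quotient": self.cd_quotient,
            "cd_difference": self.cd_difference,
            "burden": self.burden,
            "marker_is_atom": str(self.marker_is_atom),
        }


DEFAULT = Conventions()


def cd_grid() -> list[Conventions]:
    """All four C/D orientation combinations (Burden/marker at defaults)."""
    return [
        Conventions(cd_quotient=c, cd_difference=d)
        for c, d in product(C_ORIENTATIONS, D_ORIENTATIONS)
    ]
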