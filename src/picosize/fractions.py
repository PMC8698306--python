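"""Size-fraction windows defined by successive filter pore sizes.

A serial-filtration design with pore sizes 2.0, 1.2, 0.6 and 0.2 μm
partitions the picophytoplankton size range into three windows:
0.2–0.6, 0.6–1.2 and 1.2–2.0 μm.  Each window is represented by a
:class:`SizeFraction`; the midpoint (Range_min + Range_max)/2 is the
representative diameter used by the size-spectrum estimator.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SizeFraction:
    """A diameter window [lower, upper) in μm bounded by two pore sizes."""

    lower: float
    upper: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.lower < self.upper:
            raise ValueError(
                f"invalid size fraction bounds: ({self.lower}, {self.upper})"
            )
        if not self.label:
            object.__setattr__(self, "label", f"{self.lower:g}-{self.upper:g}")

    @property
    def midpoint(self) -> float:
        """Representative diameter, (Range_min + Range_max) / 2, in μm."""
        return 0.5 * (self.lower + self.upper)

    def contains(self, diameter: float) -> bool:
        return self.lower <= diameter < self.upper


#: The study's three analysed fractions; half-open below the top fraction.
DEFAULT_FRACTIONS: tuple[SizeFraction, ...] = (
    SizeFraction(0.2, 0.6),
    SizeFraction(0.6, 1.2),
    SizeFraction(1.2, 2.0),
)

#: Pore size of the pre-filter that discards cells above the pico range (μm).
PREFILTER_PORE_UM = 2.0


def fraction_labels(fractions=DEFAULT_FRACTIONS) -> list[str]:
    return [f.label for f in fractions]


def parse_fractions(bounds: list[float]) -> tuple[SizeFraction, ...]:
    """Build consecutive fractions from an increasing list of pore sizes.

    ``[0.2, 0.6, 1.2, 2.0]`` yields the three default windows.
    """
    if len(bounds) < 2:
        raise ValueError("need at least two pore sizes to form a fraction")
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError("pore sizes must be strictly increasing")
    return tuple(SizeFraction(lo, hi) for lo, hi in zip(bounds, bounds[1:]))
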