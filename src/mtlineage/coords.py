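"""Circular rCRS coordinate arithmetic.

Human mtDNA positions are reported as 1-based coordinates on the revised
Cambridge Reference Sequence (rCRS, 16,569 bp). The molecule is circular, so
analysis windows may span the origin: the control region runs from np 16024
through the origin to np 576.
"""

from __future__ import annotations

from dataclasses import dataclass

MT_LENGTH = 16569


@dataclass(frozen=True)
class CoordinateWindow:
    """A closed interval of 1-based rCRS positions, possibly origin-spanning.

    ``start > end`` is only legal when ``circular`` is true, in which case the
    window covers ``start..MT_LENGTH`` followed by ``1..end``.
    """

    start: int
    end: int
    circular: bool = False

    def __post_init__(self) -> None:
        for p in (self.start, self.end):
            if not 1 <= p <= MT_LENGTH:
                raise ValueError(f"position {p} outside 1..{MT_LENGTH}")
        if self.start > self.end and not self.circular:
            raise ValueError(
                f"window {self.start}..{self.end} spans the origin; "
                "set circular=True"
            )

    def contains(self, position: int) -> bool:
        if not 1 <= position <= MT_LENGTH:
            return False
        if self.start <= self.end:
            return self.start <= position <= self.end
        return position >= self.start or position <= self.end

    def __contains__(self, position: int) -> bool:
        return self.contains(position)

    def __len__(self) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        return (MT_LENGTH - self.start + 1) + self.end

    def positions(self) -> list[int]:
        """All positions in window order (5' to 3' across the origin)."""
        if self.start <= self.end:
            return list(range(self.start, self.end + 1))
        return list(range(self.start, MT_LENGTH + 1)) + list(
            range(1, self.end + 1)
        )

    def contains_window(self, other: "CoordinateWindow") -> bool:
        """True if every position of *other* lies inside this window."""
        if not (self.contains(other.start) and self.contains(other.end)):
            return False
        # Both endpoints inside; the nested window must not wrap around a
        # region this window excludes. Compare offsets from self.start.
        off_s = (other.start - self.start) % MT_LENGTH
        off_e = (other.end - self.start) % MT_LENGTH
        return off_s <= off_e and off_e < len(self)


#: Hypervariable segment 1 of the control region.
HVS1 = CoordinateWindow(16024, 16365)
#: The entire control region (spans the origin; ~1,122 bp).
CONTROL_REGION = CoordinateWindow(16024, 576, circular=True)
#: The 546-bp window used for cross-dataset Eurasian comparisons.
EURASIAN_546 = CoordinateWindow(16024, 16569)

WINDOWS = {
    "hvs1": HVS1,
    "cr": CONTROL_REGION,
    "eurasian546": EURASIAN_546,
}


@dataclass(frozen=True)
class ReferenceSequence:
    """A circular mtDNA reference of canonical length."""

    name: str
    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) != MT_LENGTH:
            raise ValueError(
                f"reference length {len(self.bases)} != {MT_LENGTH}"
            )
        if set(self.bases) - set("ACGTN"):
            raise ValueError("reference alphabet must be A/C/G/T/N")

    def base_at(self, position: int) -> str:
        if not 1 <= position <= MT_LENGTH:
            raise ValueError(f"position {position} outside 1..{MT_LENGTH}")
        return self.bases[position - 1]

    def window_sequence(self, window: CoordinateWindow) -> str:
        return "".join(self.bases[p - 1] for p in window.positions())
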