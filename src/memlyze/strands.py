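"""The five-strand topology of the 42-residue amyloid-β peptide.

The peptide splits into an N-terminal polar region (residues 1-16) carrying a
β-hairpin (β1 = 2-5, β2 = 11-14) and a C-terminal apolar region (17-42) with
three antiparallel strands (β3 = 17-22, β4 = 31-36, β5 = 39-41). Turn/loop
ranges fill the gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["StrandMap", "DEFAULT_STRAND_MAP", "AB42_SEQUENCE"]

# one-letter amino-acid sequence of the 42-residue amyloid-β peptide
AB42_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"

THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class StrandMap:
    """Named residue ranges (1-based, inclusive) of strands and linkers."""

    strands: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "b1": (2, 5),
            "b2": (11, 14),
            "b3": (17, 22),
            "b4": (31, 36),
            "b5": (39, 41),
        }
    )
    turns: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "turn1": (6, 10),       # hairpin turn between b1 and b2
            "coil12": (15, 16),     # linker between the two regions
            "loop2": (23, 30),      # long loop between b3 and b4
            "turn3": (37, 38),      # tight turn between b4 and b5
        }
    )
    n_residues: int = 42
    polar_region: tuple[int, int] = (1, 16)
    apolar_region: tuple[int, int] = (17, 42)

    def __post_init__(self) -> None:
        ranges = sorted(self.strands.values())
        prev_hi = 0
        for lo, hi in ranges:
            if lo <= prev_hi:
                raise ValueError("strand ranges must be disjoint and ascending")
            if not (1 <= lo <= hi <= self.n_residues):
                raise ValueError(f"strand range ({lo}, {hi}) outside 1-{self.n_residues}")
            prev_hi = hi
        p_lo, p_hi = self.polar_region
        a_lo, a_hi = self.apolar_region
        for name in ("b1", "b2"):
            lo, hi = self.strands[name]
            if not (p_lo <= lo and hi <= p_hi):
                raise ValueError(f"{name} must lie in the polar region")
        for name in ("b3", "b4", "b5"):
            lo, hi = self.strands[name]
            if not (a_lo <= lo and hi <= a_hi):
                raise ValueError(f"{name} must lie in the apolar region")

    def strand_of(self, residue_index: int) -> str | None:
        """Name of the strand containing a residue, or None."""
        for name, (lo, hi) in self.strands.items():
            if lo <= residue_index <= hi:
                return name
        return None

    def residues(self, name: str) -> range:
        lo, hi = self.strands[name] if name in self.strands else self.turns[name]
        return range(lo, hi + 1)


DEFAULT_STRAND_MAP = StrandMap()
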