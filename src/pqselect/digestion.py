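"""In-silico tryptic digestion.

Trypsin cleaves C-terminal to lysine (K) and arginine (R).  By default the
common proline exception is applied: a K/R immediately followed by proline is
not cleaved.  Peptides are reported with 0-based half-open residue
coordinates into the parent sequence, and peptides with up to
``max_missed_cleavages`` internal cleavable sites can be emitted alongside
the fully cleaved products.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_io import validate_peptide


@dataclass(frozen=True)
class DigestSettings:
    """Digestion parameters: missed-cleavage allowance and the proline rule."""

    max_missed_cleavages: int = 0
    proline_rule: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.max_missed_cleavages <= 5:
            raise ValueError("max_missed_cleavages must be in [0, 5]")


@dataclass(frozen=True)
class DigestedPeptide:
    sequence: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    missed_cleavages: int


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """0-based cut positions strictly inside the sequence.

    A cut position p means the bond between residues p-1 and p is cleaved,
    i.e. residue p-1 is K/R (and residue p is not P when the proline rule is
    on).
    """
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR":
            if proline_rule and sequence[i + 1] == "P":
                continue
            sites.append(i + 1)
    return sites


def digest_tryptic(sequence: str,
                   settings: DigestSettings = DigestSettings()) -> list[DigestedPeptide]:
    """Digest a protein sequence, returning peptides with coordinates.

    The 0-missed-cleavage products tile the sequence exactly; products with
    1..max_missed_cleavages internal sites are appended.  Output is ordered
    by start coordinate, then end coordinate.
    """
    validate_peptide(sequence)
    cuts = [0] + cleavage_sites(sequence, settings.proline_rule) + [len(sequence)]
    peptides = []
    for i in range(len(cuts) - 1):
        for span in range(1, settings.max_missed_cleavages + 2):
            j = i + span
            if j >= len(cuts):
                break
            start, end = cuts[i], cuts[j]
            peptides.append(DigestedPeptide(sequence[start:end], start, end,
                                            missed_cleavages=span - 1))
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def count_missed_cleavages(peptide: str,
                           settings: DigestSettings = DigestSettings()) -> int:
    """Number of internal (non-C-terminal) cleavable K/R sites in a peptide."""
    validate_peptide(peptide)
    internal = cleavage_sites(peptide, settings.proline_rule)
    # a site at len(peptide) can't occur (sites are strictly internal), so
    # every site counts as a missed cleavage
    return len(internal)
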