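"""Cleavage-rule-free uniqueness checking of peptides against proteomes.

A candidate reporter peptide fused to a protein must not occur anywhere in
the background proteome it will be measured in — as a plain substring of any
protein sequence, irrespective of tryptic context.  The index here answers
exactly that question and can optionally collapse isoleucine/leucine (which
are isobaric and indistinguishable by fragment mass).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core_io import ProteinRecord, validate_peptide

# separator that can never appear in a canonical sequence or query, so a
# match can never span two concatenated records
_SEPARATOR = "#"

_IL_TABLE = str.maketrans({"I": "L"})


@dataclass
class ProteomeIndex:
    """Substring index over one proteome (concatenation with separators)."""

    label: str
    equate_il: bool
    accessions: list[str]
    _text: str = field(repr=False)
    _starts: list[int] = field(repr=False)  # start offset of each record in _text


def _fold(sequence: str, equate_il: bool) -> str:
    return sequence.translate(_IL_TABLE) if equate_il else sequence


def build_proteome_index(records: Sequence[ProteinRecord],
                         equate_il: bool = False,
                         label: str = "proteome") -> ProteomeIndex:
    """Build a substring index over protein records.

    With ``equate_il`` on, I and L are collapsed to a single symbol on both
    the indexed sequences and (later) the queries.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot index an empty proteome")
    accessions, parts, starts = [], [], []
    offset = 0
    for rec in records:
        accessions.append(rec.accession)
        folded = _fold(rec.sequence, equate_il)
        starts.append(offset)
        parts.append(folded)
        offset += len(folded) + 1  # +1 for the separator
    return ProteomeIndex(label=label, equate_il=equate_il,
                         accessions=accessions,
                         _text=_SEPARATOR.join(parts), _starts=starts)


@dataclass(frozen=True)
class ProteotypicVerdict:
    peptide_sequence: str
    proteome_label: str
    proteotypic: bool
    n_hits: int
    hits: tuple[tuple[str, int], ...]  # (accession, 0-based offset), capped


def is_proteotypic(peptide: str, index: ProteomeIndex,
                   max_hits: int = 100) -> ProteotypicVerdict:
    """Scan the index for the peptide; proteotypic means zero occurrences.

    Hit offsets are 0-based into the matched protein's sequence.  Reporting
    is capped at ``max_hits`` hits (the total count keeps counting), which
    bounds output for pathological low-complexity queries.
    """
    validate_peptide(peptide)
    query = _fold(peptide, index.equate_il)
    hits: list[tuple[str, int]] = []
    n_hits = 0
    pos = index._text.find(query)
    while pos != -1:
        record_i = bisect.bisect_right(index._starts, pos) - 1
        n_hits += 1
        if len(hits) < max_hits:
            hits.append((index.accessions[record_i],
                         pos - index._starts[record_i]))
        pos = index._text.find(query, pos + 1)
    return ProteotypicVerdict(
        peptide_sequence=peptide, proteome_label=index.label,
        proteotypic=n_hits == 0, n_hits=n_hits, hits=tuple(hits))


def naive_scan(peptide: str, records: Iterable[ProteinRecord],
               equate_il: bool = False) -> list[tuple[str, int]]:
    """Reference scan of every record independently (oracle for the index)."""
    query = _fold(peptide, equate_il)
    hits = []
    for rec in records:
        text = _fold(rec.sequence, equate_il)
        pos = text.find(query)
        while pos != -1:
            hits.append((rec.accession, pos))
            pos = text.find(query, pos + 1)
    return hits


def batch_report(peptides: Sequence[str],
                 indexes: Sequence[ProteomeIndex],
                 max_hits: int = 100) -> list[ProteotypicVerdict]:
    """Per-peptide × per-proteome verdicts, in input order.

    A peptide is globally proteotypic iff its verdict is proteotypic in
    every index (see :func:`globally_proteotypic`).
    """
    return [is_proteotypic(pep, index, max_hits)
            for pep in peptides for index in indexes]


def globally_proteotypic(peptide: str,
                         verdicts: Iterable[ProteotypicVerdict]) -> bool:
    relevant = [v for v in verdicts if v.peptide_sequence == peptide]
    return bool(relevant) and all(v.proteotypic for v in relevant)


def write_uniqueness_report(verdicts: Iterable[ProteotypicVerdict],
                            path, first_hits: int = 5) -> None:
    """Uniqueness TSV: peptide, proteome, n_hits, first hits as acc:offset."""
    import csv

    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["peptide_sequence", "proteome", "proteotypic",
                         "n_hits", "hits"])
        for v in verdicts:
            shown = ";".join(f"{acc}:{off}" for acc, off in v.hits[:first_hits])
            writer.writerow([v.peptide_sequence, v.proteome_label,
                             int(v.proteotypic), v.n_hits, shown])
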