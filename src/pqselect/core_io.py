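"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats
-------
* FASTA protein databases (parsed with Bio.SeqIO; sequences uppercased,
  records with non-canonical residues rejected and counted).
* PSM tables: tab-separated, one row per annotated fragment ion with columns
  ``experiment_id, spectrum_id, peptide_sequence, protein_accessions,
  fragment, intensity``.  ``protein_accessions`` is semicolon-joined; the
  fragment token grammar is ``<series><index>^<charge>`` (e.g. ``y7^1``).
  A PSM with no matched fragments is a single row with empty fragment and
  intensity fields.
* Selection reports (TSV), transition lists (CSV) and calibration tables
  (TSV), all with deterministic row and column order so that
  ``read(write(x)) == x`` bit-exactly.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

from .errors import FormatError

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

_FRAGMENT_RE = re.compile(r"^([by])(\d+)\^([12])$")


def validate_peptide(sequence: str) -> str:
    """Return the sequence if it is a non-empty canonical peptide, else raise."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    bad = set(sequence) - CANONICAL_RESIDUES
    if bad:
        raise ValueError(
            f"non-canonical residue(s) {sorted(bad)} in peptide {sequence!r}"
        )
    return sequence


@dataclass(frozen=True)
class ProteinRecord:
    """One protein database entry."""

    accession: str
    description: str
    sequence: str


@dataclass(frozen=True)
class FragmentAnnotation:
    """One matched b/y fragment ion of a PSM."""

    series: str  # 'b' or 'y'
    index: int
    charge: int
    intensity: float

    def __post_init__(self) -> None:
        if self.series not in ("b", "y"):
            raise ValueError(f"fragment series must be b or y, got {self.series!r}")
        if self.index < 1:
            raise ValueError("fragment index must be >= 1")
        if self.charge not in (1, 2):
            raise ValueError("fragment charge must be 1 or 2")
        if self.intensity < 0:
            raise ValueError("fragment intensity must be non-negative")

    @property
    def token(self) -> str:
        return f"{self.series}{self.index}^{self.charge}"


@dataclass(frozen=True)
class PSM:
    """One peptide-spectrum match with its annotated fragment ions."""

    spectrum_id: str
    peptide_sequence: str
    protein_accessions: tuple[str, ...]
    experiment_id: str
    annotations: tuple[FragmentAnnotation, ...] = ()

    def __post_init__(self) -> None:
        validate_peptide(self.peptide_sequence)
        for ann in self.annotations:
            if ann.index >= len(self.peptide_sequence):
                raise ValueError(
                    f"fragment index {ann.index} not below peptide length "
                    f"{len(self.peptide_sequence)} ({self.peptide_sequence})"
                )


@dataclass(frozen=True)
class TransitionRow:
    """One SRM transition (precursor/product m/z pair)."""

    peptide_sequence: str
    precursor_mz: float
    precursor_charge: int
    fragment_series: str
    fragment_index: int
    fragment_charge: int
    product_mz: float
    label: str  # 'light' or 'heavy'

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0 or self.product_mz <= 0:
            raise ValueError("m/z values must be positive")
        if self.label not in ("light", "heavy"):
            raise ValueError(f"label must be light or heavy, got {self.label!r}")


@dataclass
class FastaResult:
    """Parsed FASTA file: accepted records plus the rejected accessions."""

    records: list[ProteinRecord] = field(default_factory=list)
    rejected: list[str] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def read_fasta(path: str | Path) -> FastaResult:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased and whitespace-stripped.  Records whose sequence
    is empty or contains residues outside the canonical 20-letter alphabet
    are rejected and reported in ``FastaResult.rejected``.  A duplicate
    accession raises :class:`FormatError`.
    """
    result = FastaResult()
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id
        if accession in seen:
            raise FormatError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        sequence = str(rec.seq).upper().replace(" ", "")
        if not sequence or set(sequence) - CANONICAL_RESIDUES:
            result.rejected.append(accession)
            continue
        description = rec.description[len(rec.id):].strip()
        result.records.append(ProteinRecord(accession, description, sequence))
    return result


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as handle:
        for rec in records:
            header = f">{rec.accession}"
            if rec.description:
                header += f" {rec.description}"
            handle.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i:i + width] + "\n")


def parse_fragment_token(token: str) -> tuple[str, int, int]:
    """Parse ``y7^1`` into ``('y', 7, 1)``; anything else is a FormatError."""
    match = _FRAGMENT_RE.match(token)
    if match is None:
        raise FormatError(f"malformed fragment token {token!r}")
    return match.group(1), int(match.group(2)), int(match.group(3))


_PSM_COLUMNS = ["experiment_id", "spectrum_id", "peptide_sequence",
                "protein_accessions", "fragment", "intensity"]


def read_psm_table(path: str | Path) -> list[PSM]:
    """Read the flat PSM TSV into grouped :class:`PSM` objects.

    Rows are grouped by ``(experiment_id, spectrum_id)``.  The returned list
    is ordered by first appearance of each spectrum, but parsing is
    order-insensitive: shuffling rows yields the same set of PSMs.
    """
    groups: dict[tuple[str, str], dict] = {}
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"empty PSM table {path}") from None
        if header != _PSM_COLUMNS:
            raise FormatError(
                f"unexpected PSM table header {header!r}; expected {_PSM_COLUMNS!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f for f in row):
                continue
            if len(row) != len(_PSM_COLUMNS):
                raise FormatError(f"{path}:{lineno}: expected "
                                  f"{len(_PSM_COLUMNS)} fields, got {len(row)}")
            exp_id, spec_id, peptide, accessions, fragment, intensity = row
            key = (exp_id, spec_id)
            info = groups.setdefault(key, {
                "peptide": peptide,
                "accessions": tuple(a for a in accessions.split(";") if a),
                "annotations": [],
            })
            if info["peptide"] != peptide:
                raise FormatError(
                    f"{path}:{lineno}: spectrum {spec_id!r} maps to conflicting "
                    f"peptides {info['peptide']!r} and {peptide!r}")
            if fragment == "" and intensity == "":
                continue  # annotation-free PSM row
            series, index, charge = parse_fragment_token(fragment)
            try:
                value = float(intensity)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric intensity {intensity!r}"
                ) from None
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative intensity {value}")
            info["annotations"].append(
                FragmentAnnotation(series, index, charge, value))
    psms = []
    for (exp_id, spec_id), info in groups.items():
        psms.append(PSM(
            spectrum_id=spec_id,
            peptide_sequence=info["peptide"],
            protein_accessions=info["accessions"],
            experiment_id=exp_id,
            annotations=tuple(info["annotations"]),
        ))
    return psms


def write_psm_table(psms: Iterable[PSM], path: str | Path) -> None:
    """Write PSMs in the flat one-row-per-fragment TSV dialect."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_PSM_COLUMNS)
        for psm in psms:
            prefix = [psm.experiment_id, psm.spectrum_id, psm.peptide_sequence,
                      ";".join(psm.protein_accessions)]
            if not psm.annotations:
                writer.writerow(prefix + ["", ""])
                continue
            for ann in psm.annotations:
                writer.writerow(prefix + [ann.token, repr(ann.intensity)])


def _fmt(value: float) -> str:
    """repr-based float formatting: shortest string that round-trips exactly."""
    return repr(float(value))


def write_selection_report(table, path: str | Path) -> None:
    """Write a SelectionTable as TSV (Table-1 analogue).

    Rows are ordered by descending mean differential score with a
    lexicographic tie-break on the peptide sequence; columns are fixed so the
    report round-trips bit-exactly through :func:`read_selection_report`.
    """
    experiments = sorted({e for row in table.rows for e in row.scores})
    header = (["peptide_sequence", "mean_score"]
              + [f"score_{e}" for e in experiments]
              + ["avg_ion_coverage", "spectral_counts", "selection_sets"])
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for row in table.rows:
            counts = ";".join(f"{e}:{row.spectral_counts[e]}"
                              for e in sorted(row.spectral_counts))
            writer.writerow(
                [row.peptide_sequence, _fmt(row.mean_score)]
                + [(_fmt(row.scores[e]) if row.scores.get(e) is not None else "")
                   for e in experiments]
                + [_fmt(row.avg_ion_coverage), counts,
                   ";".join(str(s) for s in sorted(row.selection_sets))])


def read_selection_report(path: str | Path):
    """Read a selection report TSV back into a SelectionTable."""
    from .selection import SelectionRow, SelectionTable  # cycle guard

    rows = []
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader)
        exp_cols = [(i, name[len("score_"):]) for i, name in enumerate(header)
                    if name.startswith("score_")]
        for fields in reader:
            scores = {exp: (float(fields[i]) if fields[i] else None)
                      for i, exp in exp_cols}
            counts = {}
            if fields[-2]:
                for token in fields[-2].split(";"):
                    exp, _, num = token.rpartition(":")
                    counts[exp] = int(num)
            rows.append(SelectionRow(
                peptide_sequence=fields[0],
                mean_score=float(fields[1]),
                scores=scores,
                avg_ion_coverage=float(fields[-3]),
                spectral_counts=counts,
                selection_sets=frozenset(int(s) for s in fields[-1].split(";")
                                         if s),
            ))
    return SelectionTable(rows=rows)


_SERIES_ORDER = {"y": 0, "b": 1}
_LABEL_ORDER = {"light": 0, "heavy": 1}

_TRANSITION_COLUMNS = ["peptide_sequence", "precursor_mz", "precursor_charge",
                       "product_mz", "fragment_ion", "label"]


def transition_sort_key(row: TransitionRow):
    return (row.peptide_sequence, _SERIES_ORDER[row.fragment_series],
            row.fragment_index, row.fragment_charge, _LABEL_ORDER[row.label])


def write_transition_list(rows: Sequence[TransitionRow], path: str | Path) -> None:
    """Write transitions as CSV in the column layout common SRM software imports."""
    ordered = sorted(rows, key=transition_sort_key)
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(_TRANSITION_COLUMNS)
        for row in ordered:
            writer.writerow([row.peptide_sequence, _fmt(row.precursor_mz),
                             row.precursor_charge, _fmt(row.product_mz),
                             f"{row.fragment_series}{row.fragment_index}"
                             f"^{row.fragment_charge}",
                             row.label])


def read_transition_list(path: str | Path) -> list[TransitionRow]:
    rows = []
    with open(path, newline="") as handle:
        reader = csv.reader(handle)
        header = next(reader)
        if header != _TRANSITION_COLUMNS:
            raise FormatError(f"unexpected transition list header {header!r}")
        for fields in reader:
            series, index, charge = parse_fragment_token(fields[4])
            rows.append(TransitionRow(
                peptide_sequence=fields[0],
                precursor_mz=float(fields[1]),
                precursor_charge=int(fields[2]),
                fragment_series=series,
                fragment_index=index,
                fragment_charge=charge,
                product_mz=float(fields[3]),
                label=fields[5],
            ))
    return rows


_CALIBRATION_COLUMNS = ["level", "amount", "unit", "replicate", "response", "s2n"]


def read_calibration_table(path: str | Path):
    """Read a calibration TSV into a CalibrationSeries (srm module)."""
    from .srm import CalibrationSeries  # cycle guard

    per_level: dict[int, dict] = {}
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader)
        if header != _CALIBRATION_COLUMNS:
            raise FormatError(f"unexpected calibration header {header!r}")
        unit = None
        for fields in reader:
            level = int(fields[0])
            info = per_level.setdefault(level, {"amount": float(fields[1]),
                                                "responses": [], "s2n": []})
            unit = fields[2]
            info["responses"].append(float(fields[4]))
            info["s2n"].append(float(fields[5]))
    levels = sorted(per_level)
    return CalibrationSeries(
        amounts=[per_level[l]["amount"] for l in levels],
        responses=[per_level[l]["responses"] for l in levels],
        s2n=[per_level[l]["s2n"] for l in levels],
        unit=unit or "fmol",
    )


def write_calibration_table(series, path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_CALIBRATION_COLUMNS)
        for level, amount in enumerate(series.amounts):
            for rep, (resp, s2n) in enumerate(
                    zip(series.responses[level], series.s2n[level]), start=1):
                writer.writerow([level, _fmt(amount), series.unit, rep,
                                 _fmt(resp), _fmt(s2n)])
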