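"""Elimination filters and the three reporter-peptide selection strategies.

Candidate reporter peptides must behave well in LC-SRM, so peptides with any
of five liabilities are discarded:

1. methionine or cysteine (oxidation artefacts),
2. missed cleavages (variable tryptic release),
3. N-terminal glutamine (pyro-glutamate formation),
4. consecutive prolines (elution peak broadening),
5. length below 9 residues.

Surviving peptides are then picked by three complementary strategies:

* **Method 1** — differential score strictly above a high threshold
  (default 6) in every replicate.
* **Method 2** — restrict to peptides with at least 3 spectra per
  experiment, recompute the protein scales on the restricted set, and keep
  peptides scoring strictly above a lower threshold (default 2) in every
  replicate.
* **Method 3** — average fragment ion coverage of 30 or higher (inclusive)
  with identification in every replicate.

The union, re-checked against the filters, forms the final selection table.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable

from .core_io import validate_peptide
from .digestion import DigestSettings, count_missed_cleavages
from .scoring import (DifferentialScore, HuberSettings, PeptideMetrics,
                      apply_protein_floor, differential_scores,
                      experiments_identified, ion_coverage, spectral_counts)

FILTER_REASONS = ("contains_Met_or_Cys", "missed_cleavage", "starts_with_Gln",
                  "consecutive_prolines", "too_short")


@dataclass(frozen=True)
class FilterVerdict:
    peptide_sequence: str
    passed: bool
    reasons: frozenset[str]


@dataclass(frozen=True)
class SelectionThresholds:
    """The strategy thresholds; defaults match the published workflow."""

    method1_score: float = 6.0
    method2_score: float = 2.0
    method2_min_spectra: int = 3
    method3_coverage: float = 30.0
    required_replicates: int = 3
    min_length: int = 9

    def __post_init__(self) -> None:
        for name in ("method1_score", "method2_score", "method2_min_spectra",
                     "method3_coverage", "required_replicates", "min_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SelectionRow:
    peptide_sequence: str
    mean_score: float
    scores: dict = field(hash=False)
    avg_ion_coverage: float
    spectral_counts: dict = field(hash=False)
    selection_sets: frozenset[int]


@dataclass
class SelectionTable:
    rows: list[SelectionRow]

    def __len__(self) -> int:
        return len(self.rows)

    def peptides(self) -> list[str]:
        return [row.peptide_sequence for row in self.rows]


def elimination_filter(peptide: str,
                       settings: DigestSettings = DigestSettings(),
                       min_length: int = 9) -> FilterVerdict:
    """Evaluate all five elimination criteria (never short-circuited)."""
    validate_peptide(peptide)
    reasons = set()
    if "M" in peptide or "C" in peptide:
        reasons.add("contains_Met_or_Cys")
    if count_missed_cleavages(peptide, settings) > 0:
        reasons.add("missed_cleavage")
    if peptide.startswith("Q"):
        reasons.add("starts_with_Gln")
    if "PP" in peptide:
        reasons.add("consecutive_prolines")
    if len(peptide) < min_length:
        reasons.add("too_short")
    return FilterVerdict(peptide_sequence=peptide, passed=not reasons,
                         reasons=frozenset(reasons))


def _passes_in_all_replicates(score: DifferentialScore, threshold: float,
                              required_replicates: int) -> bool:
    defined = score.defined_scores
    if len(defined) < required_replicates:
        return False
    return all(s > threshold for s in defined.values())


def select_method1(scores: Iterable[DifferentialScore],
                   thresholds: SelectionThresholds = SelectionThresholds()
                   ) -> set[str]:
    """Peptides with score strictly above method1_score in every replicate."""
    return {s.peptide_sequence for s in scores
            if _passes_in_all_replicates(s, thresholds.method1_score,
                                         thresholds.required_replicates)}


def select_method2(metrics: Iterable[PeptideMetrics],
                   thresholds: SelectionThresholds = SelectionThresholds(),
                   settings: HuberSettings = HuberSettings(),
                   min_peptides_per_protein: int = 3) -> set[str]:
    """High-evidence variant: ≥3 spectra per experiment, recomputed scales.

    Metrics are restricted to peptides with at least ``method2_min_spectra``
    PSMs in an experiment; the peptides-per-protein floor is re-applied and
    protein scales recomputed on the restricted set before thresholding.
    """
    restricted = [m for m in metrics
                  if m.spectral_count >= thresholds.method2_min_spectra]
    restricted, _ = apply_protein_floor(restricted, min_peptides_per_protein)
    scores = differential_scores(restricted, settings)
    return {s.peptide_sequence for s in scores
            if _passes_in_all_replicates(s, thresholds.method2_score,
                                         thresholds.required_replicates)}


def select_method3(metrics: Iterable[PeptideMetrics],
                   thresholds: SelectionThresholds = SelectionThresholds()
                   ) -> set[str]:
    """Peptides identified in every replicate with ion coverage ≥ threshold."""
    metrics = list(metrics)
    coverage = ion_coverage(metrics)
    identified = experiments_identified(metrics)
    return {pep for pep, cov in coverage.items()
            if cov >= thresholds.method3_coverage
            and len(identified[pep]) >= thresholds.required_replicates}


def combine_selections(method_sets: dict[int, set[str]],
                       scores: Iterable[DifferentialScore],
                       metrics: Iterable[PeptideMetrics],
                       digest_settings: DigestSettings = DigestSettings(),
                       thresholds: SelectionThresholds = SelectionThresholds()
                       ) -> tuple[SelectionTable, list[FilterVerdict]]:
    """Union of the method outputs, filter-checked and deterministically
    ordered (descending mean score, lexicographic tie-break).

    Returns the table and an audit list of verdicts for peptides a method
    selected but the elimination filter rejected.
    """
    metrics = list(metrics)
    score_by_pep = {s.peptide_sequence: s for s in scores}
    coverage = ion_coverage(metrics)
    counts = spectral_counts(metrics)

    union = sorted(set().union(*method_sets.values()) if method_sets else set())
    rows, rejected = [], []
    for peptide in union:
        verdict = elimination_filter(peptide, digest_settings,
                                     thresholds.min_length)
        if not verdict.passed:
            rejected.append(verdict)
            continue
        score = score_by_pep.get(peptide)
        mean = score.mean_score if score is not None else None
        rows.append(SelectionRow(
            peptide_sequence=peptide,
            mean_score=float("nan") if mean is None else mean,
            scores=dict(score.scores) if score is not None else {},
            avg_ion_coverage=coverage.get(peptide, 0.0),
            spectral_counts=counts.get(peptide, {}),
            selection_sets=frozenset(m for m, sel in method_sets.items()
                                     if peptide in sel),
        ))
    rows.sort(key=lambda r: (-(r.mean_score if r.mean_score == r.mean_score
                               else float("-inf")), r.peptide_sequence))
    return SelectionTable(rows=rows), rejected


def run_selection(psms,
                  thresholds: SelectionThresholds = SelectionThresholds(),
                  huber_settings: HuberSettings = HuberSettings(),
                  digest_settings: DigestSettings = DigestSettings()
                  ) -> tuple[SelectionTable, list[FilterVerdict]]:
    """Full triage: metrics → filters → three methods → combined table."""
    from .scoring import build_peptide_metrics

    result = build_peptide_metrics(psms)
    candidates = {m.peptide_sequence for m in result.metrics}
    passed = {pep for pep in candidates
              if elimination_filter(pep, digest_settings,
                                    thresholds.min_length).passed}
    filtered_metrics = [m for m in result.metrics
                        if m.peptide_sequence in passed]
    scores = differential_scores(filtered_metrics, huber_settings)
    sets = {
        1: select_method1(scores, thresholds),
        2: select_method2(filtered_metrics, thresholds, huber_settings),
        3: select_method3(filtered_metrics, thresholds),
    }
    return combine_selections(sets, scores, filtered_metrics,
                              digest_settings, thresholds)


@dataclass(frozen=True)
class ReferenceCandidate:
    """One row of the bundled reference candidate list."""

    rank: int
    peptide: str
    abbreviation: str
    selection_set: int


def load_reference_candidates() -> list[ReferenceCandidate]:
    """The 15 reference reporter-peptide candidates shipped with the package."""
    rows = []
    with resources.files("pqselect.data").joinpath("table1.tsv").open() as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for record in reader:
            rows.append(ReferenceCandidate(
                rank=int(record["rank"]),
                peptide=record["peptide"],
                abbreviation=record["abbreviation"],
                selection_set=int(record["selection_set"]),
            ))
    return rows
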