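"""Peptide intensity metrics and robust differential scoring.

The pipeline summarises discovery (shotgun) identification data into
per-peptide, per-experiment metrics and then standardises each peptide's
average matched intensity against its parent protein's robust location and
scale:

    z_ij = (I_pep(i, j) - m_j) / s_j

where ``I_pep(i, j)`` is the average matched intensity of peptide *i* of
protein *j*, ``m_j`` is the Huber location (iteratively winsorized mean,
initialised at the median) and ``s_j`` is the consistency-scaled median
absolute deviation, held fixed during the iteration.  High scores flag
"flyer" peptides that ionize far above their protein's typical peptide and
are therefore attractive SRM reporters.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from statistics import fmean
from typing import Iterable, Sequence

import numpy as np

from .core_io import PSM


@dataclass(frozen=True)
class HuberSettings:
    """Parameters of the Huber location/scale estimator.

    ``k`` is the winsorization half-width in scale units (values beyond
    location ± k·scale are clamped before averaging).  ``tolerance`` is the
    convergence threshold for the location update, measured relative to the
    fixed scale, matching the estimator this mirrors (R MASS ``huber``).
    """

    k: float = 1.2
    tolerance: float = 1e-6
    max_iterations: int = 50
    mad_consistency_constant: float = 1.4826

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass(frozen=True)
class HuberResult:
    location: float
    scale: float
    degenerate: bool  # scale == 0: location is the plain median


def huber_estimate(values: Sequence[float],
                   settings: HuberSettings = HuberSettings()) -> HuberResult:
    """Robust location/scale via iterative winsorization with fixed MAD scale.

    scale = c * median(|x - median(x)|); location starts at the median and is
    iterated as the mean of the data clamped to location ± k*scale until the
    update moves by less than tolerance * scale.  When the MAD is zero the
    data are (half-)constant: the median is returned with a degenerate flag
    and no iteration is performed.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("huber_estimate requires at least 2 values")
    median = float(np.median(x))
    scale = settings.mad_consistency_constant * float(np.median(np.abs(x - median)))
    if scale == 0.0:
        return HuberResult(location=median, scale=0.0, degenerate=True)
    location = median
    half_width = settings.k * scale
    for _ in range(settings.max_iterations):
        updated = float(np.mean(np.clip(x, location - half_width,
                                        location + half_width)))
        if abs(updated - location) < settings.tolerance * scale:
            location = updated
            break
        location = updated
    return HuberResult(location=location, scale=scale, degenerate=False)


def matched_intensity_per_psm(psm: PSM) -> float:
    """Summed intensity of all annotated b/y fragment ions of one PSM."""
    return float(sum(ann.intensity for ann in psm.annotations))


@dataclass(frozen=True)
class PeptideMetrics:
    """Per-peptide, per-experiment summary of the identification evidence."""

    peptide_sequence: str
    protein_accession: str
    experiment_id: str
    avg_matched_intensity: float
    spectral_count: int
    avg_ion_coverage: float


@dataclass
class MetricsResult:
    """Metrics plus bookkeeping on what the upstream filters dropped."""

    metrics: list[PeptideMetrics]
    n_ambiguous_peptides: int = 0
    n_dropped_protein_floor: int = 0

    def __iter__(self):
        return iter(self.metrics)

    def __len__(self) -> int:
        return len(self.metrics)


def build_peptide_metrics(psms: Iterable[PSM],
                          min_peptides_per_protein: int = 3) -> MetricsResult:
    """Aggregate PSMs into per-(peptide, experiment) metrics.

    Two upstream rules are applied:

    * peptides mapping to more than one protein accession (in any PSM, or
      across PSMs) are dropped as ambiguous;
    * within each experiment, peptides of proteins identified with fewer
      than ``min_peptides_per_protein`` distinct retained peptides are
      dropped (the protein's robust scale would be meaningless).
    """
    psms = list(psms)
    by_peptide: dict[str, set[str]] = defaultdict(set)
    for psm in psms:
        by_peptide[psm.peptide_sequence].update(psm.protein_accessions)
    ambiguous = {pep for pep, accs in by_peptide.items() if len(accs) != 1}

    grouped: dict[tuple[str, str], list[PSM]] = defaultdict(list)
    for psm in psms:
        if psm.peptide_sequence in ambiguous:
            continue
        grouped[(psm.experiment_id, psm.peptide_sequence)].append(psm)

    metrics = []
    for (experiment_id, peptide), members in grouped.items():
        sums = [matched_intensity_per_psm(p) for p in members]
        coverages = [len(p.annotations) for p in members]
        metrics.append(PeptideMetrics(
            peptide_sequence=peptide,
            protein_accession=next(iter(by_peptide[peptide])),
            experiment_id=experiment_id,
            avg_matched_intensity=fmean(sums),
            spectral_count=len(members),
            avg_ion_coverage=fmean(coverages),
        ))

    kept, n_floor = apply_protein_floor(metrics, min_peptides_per_protein)
    return MetricsResult(metrics=kept,
                         n_ambiguous_peptides=len(ambiguous),
                         n_dropped_protein_floor=n_floor)


def apply_protein_floor(metrics: Iterable[PeptideMetrics],
                        min_peptides_per_protein: int = 3
                        ) -> tuple[list[PeptideMetrics], int]:
    """Drop metrics of proteins with too few distinct peptides per experiment."""
    peptides_per_protein: dict[tuple[str, str], set[str]] = defaultdict(set)
    metrics = list(metrics)
    for m in metrics:
        peptides_per_protein[(m.experiment_id, m.protein_accession)].add(
            m.peptide_sequence)
    kept, dropped = [], 0
    for m in metrics:
        key = (m.experiment_id, m.protein_accession)
        if len(peptides_per_protein[key]) >= min_peptides_per_protein:
            kept.append(m)
        else:
            dropped += 1
    return kept, dropped


@dataclass(frozen=True)
class ProteinScale:
    """Robust location/scale of one protein's peptide intensities in one
    experiment."""

    protein_accession: str
    experiment_id: str
    location: float
    scale: float
    n_peptides: int
    degenerate: bool


def protein_scales(metrics: Iterable[PeptideMetrics],
                   settings: HuberSettings = HuberSettings()
                   ) -> dict[tuple[str, str], ProteinScale]:
    """Huber location/scale per (protein, experiment), keyed accordingly."""
    groups: dict[tuple[str, str], list[float]] = defaultdict(list)
    for m in metrics:
        groups[(m.protein_accession, m.experiment_id)].append(
            m.avg_matched_intensity)
    scales = {}
    for key, values in groups.items():
        est = huber_estimate(values, settings)
        scales[key] = ProteinScale(
            protein_accession=key[0], experiment_id=key[1],
            location=est.location, scale=est.scale,
            n_peptides=len(values), degenerate=est.degenerate)
    return scales


@dataclass
class DifferentialScore:
    """Per-experiment standardized intensity scores of one peptide."""

    peptide_sequence: str
    protein_accession: str
    scores: dict[str, float | None] = field(default_factory=dict)
    degenerate_experiments: frozenset[str] = frozenset()

    @property
    def defined_scores(self) -> dict[str, float]:
        return {e: s for e, s in self.scores.items() if s is not None}

    @property
    def mean_score(self) -> float | None:
        defined = self.defined_scores
        if not defined:
            return None
        return fmean(defined.values())


def differential_scores(metrics: Iterable[PeptideMetrics],
                        settings: HuberSettings = HuberSettings()
                        ) -> list[DifferentialScore]:
    """Standardize each peptide against its protein, per experiment.

    Peptides of a protein whose scale is degenerate (MAD = 0) in an
    experiment get an undefined score there, recorded in
    ``degenerate_experiments``; the mean score averages the defined
    per-experiment scores only.
    """
    metrics = list(metrics)
    scales = protein_scales(metrics, settings)
    per_peptide: dict[str, DifferentialScore] = {}
    degenerate: dict[str, set[str]] = defaultdict(set)
    for m in metrics:
        entry = per_peptide.setdefault(m.peptide_sequence, DifferentialScore(
            peptide_sequence=m.peptide_sequence,
            protein_accession=m.protein_accession))
        ps = scales[(m.protein_accession, m.experiment_id)]
        if ps.degenerate:
            entry.scores[m.experiment_id] = None
            degenerate[m.peptide_sequence].add(m.experiment_id)
        else:
            entry.scores[m.experiment_id] = (
                (m.avg_matched_intensity - ps.location) / ps.scale)
    for peptide, exps in degenerate.items():
        per_peptide[peptide].degenerate_experiments = frozenset(exps)
    return list(per_peptide.values())


def ion_coverage(metrics: Iterable[PeptideMetrics]) -> dict[str, float]:
    """Average ion coverage per peptide across experiments.

    The annotated-ion count is averaged per PSM within each experiment first
    (``avg_ion_coverage`` of the metrics), then across the experiments in
    which the peptide was identified.
    """
    groups: dict[str, list[float]] = defaultdict(list)
    for m in metrics:
        groups[m.peptide_sequence].append(m.avg_ion_coverage)
    return {pep: fmean(values) for pep, values in groups.items()}


def ion_coverage_summed(metrics: Iterable[PeptideMetrics]) -> dict[str, float]:
    """Alternative coverage convention: total annotated ions summed across
    all spectra of an experiment, then averaged across experiments."""
    groups: dict[str, list[float]] = defaultdict(list)
    for m in metrics:
        groups[m.peptide_sequence].append(m.avg_ion_coverage * m.spectral_count)
    return {pep: fmean(values) for pep, values in groups.items()}


def experiments_identified(metrics: Iterable[PeptideMetrics]) -> dict[str, set[str]]:
    """Experiments in which each peptide has at least one PSM."""
    result: dict[str, set[str]] = defaultdict(set)
    for m in metrics:
        result[m.peptide_sequence].add(m.experiment_id)
    return dict(result)


def spectral_counts(metrics: Iterable[PeptideMetrics]) -> dict[str, dict[str, int]]:
    """Per-peptide spectral counts keyed by experiment."""
    result: dict[str, dict[str, int]] = defaultdict(dict)
    for m in metrics:
        result[m.peptide_sequence][m.experiment_id] = m.spectral_count
    return dict(result)
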