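"""Seedable generators with known ground truth for every pipeline stage.

Three generators are provided:

* :func:`simulate_discovery_dataset` — a shotgun discovery dataset: proteins
  with several identified peptides each, log-normally dispersed matched
  intensities, replicate experiments, per-spectrum fragment annotations, and
  planted "flyer" peptides whose standardized effect (in the robust-scale
  units the differential score uses) is known exactly;
* :func:`simulate_proteome` — random protein records with optional planted
  peptide occurrences at recorded positions, for uniqueness testing;
* :func:`simulate_calibration_series` — a dilution series with a planted
  limit of detection: above it the response is linear with multiplicative
  noise and S/N comfortably clears the detection rule, below it the
  response flattens and S/N collapses.

All generators are pure functions of (config, seed).  Per-protein random
sub-streams are derived from the global seed so adding proteins to a config
does not perturb the proteins already generated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import FragmentAnnotation, PSM, ProteinRecord
from .scoring import HuberSettings, huber_estimate
from .srm import CalibrationSeries, candidate_fragments

# body alphabet for simulated peptides: no K/R/P (cleavage rules), no M/C
# (filter 1), no Q (filter 3 at position 0 — kept out everywhere for
# simplicity), so generated peptides pass the elimination filters and carry
# no missed cleavages
_BODY_ALPHABET = "ADEFGHILNSTVWY"
_TERMINAL = "KR"


@dataclass(frozen=True)
class DiscoveryConfig:
    """Shape of the simulated discovery experiment.

    Intensities are log-normal per protein: protein log-locations are drawn
    from Normal(log_intensity_location, protein_spread) and peptide
    intensities from LogNormal(location_p, peptide_dispersion) per
    experiment.  ``flyers`` plants one high-responding peptide per entry in
    the given protein, displaced so that its realized differential score in
    each experiment equals the requested standardized effect exactly (the
    effect is defined in the same robust-scale units the score uses).
    """

    n_proteins: int = 50
    peptides_per_protein: int = 8
    n_experiments: int = 3
    log_intensity_location: float = 10.0
    protein_spread: float = 1.0
    peptide_dispersion: float = 0.5  # sigma on the log scale
    flyers: tuple[tuple[int, float], ...] = ()  # (protein index, effect)
    mean_spectra_per_peptide: float = 3.0
    flyer_spectra: int | None = None  # exact PSM count for flyers, if set
    mean_ions_per_psm: float = 15.0
    peptide_length_range: tuple[int, int] = (9, 14)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peptides_per_protein < 3:
            raise ValueError("peptides_per_protein must be >= 3 (the scoring "
                             "engine drops proteins with fewer peptides)")
        if self.n_proteins < 1 or self.n_experiments < 1:
            raise ValueError("counts must be >= 1")
        if self.mean_spectra_per_peptide < 1 or self.mean_ions_per_psm < 1:
            raise ValueError("per-peptide/per-PSM means must be >= 1")
        for protein, effect in self.flyers:
            if not 0 <= protein < self.n_proteins:
                raise ValueError(f"flyer protein index {protein} out of range")
            if not np.isfinite(effect):
                raise ValueError("flyer effect must be finite")


def _random_peptide(rng: np.random.Generator, length_range: tuple[int, int],
                    taken: set[str]) -> str:
    for _ in range(1000):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        body = "".join(rng.choice(list(_BODY_ALPHABET), size=length - 1))
        peptide = body + str(rng.choice(list(_TERMINAL)))
        if peptide not in taken:
            taken.add(peptide)
            return peptide
    raise RuntimeError("could not generate a unique peptide")


def _plant_flyer(baselines: np.ndarray, effect: float,
                 settings: HuberSettings) -> float:
    """Intensity whose differential score among the baselines equals
    ``effect`` (fixed point of I = m + effect * s with I included)."""
    est = huber_estimate(baselines, settings)
    value = est.location + effect * max(est.scale, 1e-12)
    for _ in range(300):
        est = huber_estimate(np.append(baselines, value), settings)
        target = est.location + effect * est.scale
        if abs(target - value) <= 1e-10 * max(1.0, abs(value)):
            break
        value = 0.5 * value + 0.5 * target  # damped for stability
    return max(value, 1e-9)


def simulate_discovery_dataset(config: DiscoveryConfig,
                               huber_settings: HuberSettings = HuberSettings()
                               ) -> tuple[list[PSM], pd.DataFrame]:
    """Generate PSMs and a truth table of per-peptide standardized effects.

    Returns ``(psms, truth)`` where truth has one row per peptide with
    columns ``protein``, ``peptide`` and ``effect`` (0 for baseline
    peptides).  Per-PSM matched intensities jitter multiplicatively around
    the peptide's planted average but are rescaled so the per-experiment
    average matched intensity is exact.
    """
    flyers_per_protein: dict[int, list[float]] = {}
    for protein, effect in config.flyers:
        flyers_per_protein.setdefault(protein, []).append(effect)
    for protein, effects in flyers_per_protein.items():
        if len(effects) > config.peptides_per_protein - 2:
            raise ValueError("too many flyers for one protein: at least two "
                             "baseline peptides are required")

    psms: list[PSM] = []
    truth_rows = []
    taken: set[str] = set()
    experiments = [f"exp{e + 1}" for e in range(config.n_experiments)]
    for p in range(config.n_proteins):
        rng_p = np.random.default_rng([config.seed, 7919, p])
        accession = f"SIM{p:04d}"
        peptides = [_random_peptide(rng_p, config.peptide_length_range, taken)
                    for _ in range(config.peptides_per_protein)]
        effects = flyers_per_protein.get(p, [])
        # flyer peptides occupy the first slots of the protein
        effect_of = {peptides[i]: eff for i, eff in enumerate(effects)}
        location_p = rng_p.normal(config.log_intensity_location,
                                  config.protein_spread)
        for pep in peptides:
            truth_rows.append({"protein": accession, "peptide": pep,
                               "effect": effect_of.get(pep, 0.0)})
        for e, experiment in enumerate(experiments):
            rng_pe = np.random.default_rng([config.seed, p, e])
            n_fly = len(effects)
            baselines = np.exp(rng_pe.normal(location_p,
                                             config.peptide_dispersion,
                                             config.peptides_per_protein - n_fly))
            intensities = {}
            for i, pep in enumerate(peptides[n_fly:]):
                intensities[pep] = float(baselines[i])
            for i, eff in enumerate(effects):
                intensities[peptides[i]] = _plant_flyer(baselines, eff,
                                                        huber_settings)
            for pep in peptides:
                if pep in effect_of and config.flyer_spectra is not None:
                    n_psm = config.flyer_spectra
                else:
                    n_psm = 1 + int(rng_pe.poisson(
                        config.mean_spectra_per_peptide - 1))
                weights = np.exp(rng_pe.normal(0.0, 0.1, n_psm))
                psm_sums = intensities[pep] * weights / weights.mean()
                cands = candidate_fragments(pep)
                for s_idx, psm_sum in enumerate(psm_sums):
                    n_ions = min(1 + int(rng_pe.poisson(
                        config.mean_ions_per_psm - 1)), len(cands))
                    chosen = rng_pe.choice(len(cands), size=n_ions,
                                           replace=False)
                    shares = rng_pe.dirichlet(np.ones(n_ions))
                    annotations = tuple(
                        FragmentAnnotation(series=cands[c][0],
                                           index=cands[c][1],
                                           charge=cands[c][2],
                                           intensity=float(psm_sum * w))
                        for c, w in zip(chosen, shares))
                    psms.append(PSM(
                        spectrum_id=f"{accession}.{pep}.{s_idx}",
                        peptide_sequence=pep,
                        protein_accessions=(accession,),
                        experiment_id=experiment,
                        annotations=annotations))
    truth = pd.DataFrame(truth_rows, columns=["protein", "peptide", "effect"])
    return psms, truth


@dataclass(frozen=True)
class PlantedPeptide:
    peptide: str
    protein_index: int
    offset: int


def simulate_proteome(n_proteins: int,
                      length_range: tuple[int, int] = (200, 400),
                      planted: Sequence[tuple[str, int, int]] = (),
                      seed: int = 0
                      ) -> tuple[list[ProteinRecord], list[PlantedPeptide]]:
    """Random proteome with optional planted peptide occurrences.

    ``planted`` entries are (peptide, protein_index, offset); an offset of
    -1 picks a random in-bounds position.  Residues are i.i.d. uniform over
    the canonical alphabet, so an accidental occurrence of a specific
    11-mer is astronomically unlikely (20^-11 per position).
    """
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    records, truth = [], []
    per_protein: dict[int, list[tuple[str, int]]] = {}
    for pep, idx, off in planted:
        if not 0 <= idx < n_proteins:
            raise ValueError(f"planted protein index {idx} out of range")
        per_protein.setdefault(idx, []).append((pep, off))
    for i in range(n_proteins):
        rng_i = np.random.default_rng([seed, 104729, i])
        length = int(rng_i.integers(length_range[0], length_range[1] + 1))
        residues = list(rng_i.choice(alphabet, size=length))
        for pep, off in per_protein.get(i, []):
            if len(pep) > length:
                raise ValueError(f"planted peptide {pep!r} longer than host "
                                 f"protein ({length} aa)")
            if off == -1:
                off = int(rng_i.integers(0, length - len(pep) + 1))
            if off + len(pep) > length:
                raise ValueError("planted offset out of bounds")
            residues[off:off + len(pep)] = list(pep)
            truth.append(PlantedPeptide(pep, i, off))
        records.append(ProteinRecord(accession=f"RND{i:04d}",
                                     description="simulated protein",
                                     sequence="".join(residues)))
    return records, truth


@dataclass(frozen=True)
class CalibrationConfig:
    """Shape of a simulated dilution series with a planted LOD.

    At and above the planted LOD the response is slope x amount with
    multiplicative Normal(0, noise_cv) noise and the S/N scales linearly
    from ``sn_at_lod`` at the LOD; below it the response is attenuated by
    ``attenuation`` per level and S/N sits at ``sn_below_lod``, under the
    detection threshold.
    """

    amounts: tuple[float, ...] = (0.1, 0.2, 0.4, 0.8, 1.6, 3.2, 6.4)  # fmol
    planted_lod: float = 0.2
    slope: float = 1e5  # response units per fmol
    noise_cv: float = 0.10
    sn_at_lod: float = 4.0
    sn_below_lod: float = 1.5
    attenuation: float = 0.5
    replicates: int = 3
    unit: str = "fmol"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_lod not in self.amounts:
            raise ValueError("planted_lod must be one of the dilution levels")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def simulate_calibration_series(config: CalibrationConfig
                                ) -> tuple[CalibrationSeries, float]:
    """Generate a calibration series; returns (series, planted LOD)."""
    rng = np.random.default_rng([config.seed, 15485863])
    responses, s2n = [], []
    for amount in config.amounts:
        level_resp, level_sn = [], []
        for _ in range(config.replicates):
            noise = 1.0 + rng.normal(0.0, config.noise_cv)
            if amount >= config.planted_lod:
                resp = config.slope * amount * noise
                sn = config.sn_at_lod * (amount / config.planted_lod) * noise
            else:
                # attenuation compounds for each level below the LOD
                steps = sum(1 for a in config.amounts
                            if config.planted_lod > a >= amount)
                resp = (config.slope * amount
                        * config.attenuation ** steps * noise)
                sn = config.sn_below_lod * noise
            level_resp.append(max(resp, 0.0))
            level_sn.append(max(sn, 0.0))
        responses.append(level_resp)
        s2n.append(level_sn)
    series = CalibrationSeries(amounts=list(config.amounts),
                               responses=responses, s2n=s2n,
                               unit=config.unit)
    return series, config.planted_lod
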