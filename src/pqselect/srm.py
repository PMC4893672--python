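"""SRM assay arithmetic.

Covers the downstream math of a targeted assay built on a reporter peptide:

* monoisotopic precursor and b/y fragment m/z, for light peptides and their
  stable-isotope labelled ("heavy") counterparts;
* transition-list construction (top-N fragment ions) and the evenness score
  used to judge how equally a peptide spreads signal over its transitions;
* stable-isotope-dilution quantification: peak area ratio (PAR) of light to
  heavy summed transition areas, converted to absolute amount via the known
  heavy spike-in;
* limit-of-detection estimation from a dilution series, by the S/N > 3 rule
  and by compensation for calibration-curve non-linearity.

Residue and water monoisotopic masses come from pyteomics; the default heavy
labels are fully labelled C-terminal Lys (+8.0142 Da, 13C6 15N2) and Arg
(+10.0083 Da, 13C6 15N4), the standard SILAC-style chemistry for tryptic
peptides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import fmean, stdev
from typing import Mapping, Sequence

import numpy as np
from pyteomics import mass as _pmass
from scipy import stats as _stats

from .core_io import TransitionRow, validate_peptide

PROTON_MASS = 1.00727646688  # Da

_WATER_MASS = _pmass.calculate_mass(formula="H2O")
_RESIDUE_MASSES = {aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"}


@dataclass(frozen=True)
class MassSettings:
    residue_masses: Mapping[str, float] = field(
        default_factory=lambda: dict(_RESIDUE_MASSES))
    water_mass: float = _WATER_MASS
    proton_mass: float = PROTON_MASS
    # mass shift of the labelled residue, applied to the C-terminal residue
    heavy_shifts: Mapping[str, float] = field(
        default_factory=lambda: {"K": 8.014199, "R": 10.008269})


def _residue_sum(sequence: str, masses: MassSettings) -> float:
    try:
        return sum(masses.residue_masses[aa] for aa in sequence)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None


def _heavy_shift(sequence: str, masses: MassSettings) -> float:
    """Label shift for a peptide labelled on its C-terminal residue."""
    return masses.heavy_shifts.get(sequence[-1], 0.0)


def peptide_mz(sequence: str, charge: int, label: str = "light",
               masses: MassSettings = MassSettings()) -> float:
    """Precursor m/z of a peptide at the given charge state."""
    validate_peptide(sequence)
    if charge < 1:
        raise ValueError("charge must be >= 1")
    total = _residue_sum(sequence, masses) + masses.water_mass
    if label == "heavy":
        total += _heavy_shift(sequence, masses)
    elif label != "light":
        raise ValueError(f"label must be light or heavy, got {label!r}")
    return (total + charge * masses.proton_mass) / charge


def fragment_mz(sequence: str, series: str, index: int, charge: int,
                label: str = "light",
                masses: MassSettings = MassSettings()) -> float:
    """m/z of a b- or y-series fragment ion.

    The heavy-label shift (on the C-terminal residue) applies only when the
    labelled residue lies inside the fragment, i.e. to y ions.
    """
    validate_peptide(sequence)
    if not 1 <= index < len(sequence):
        raise ValueError(f"fragment index {index} out of range for "
                         f"{len(sequence)}-mer")
    if charge not in (1, 2):
        raise ValueError("fragment charge must be 1 or 2")
    if series == "b":
        total = _residue_sum(sequence[:index], masses)
    elif series == "y":
        total = _residue_sum(sequence[-index:], masses) + masses.water_mass
        if label == "heavy":
            total += _heavy_shift(sequence, masses)
    else:
        raise ValueError(f"series must be b or y, got {series!r}")
    if label not in ("light", "heavy"):
        raise ValueError(f"label must be light or heavy, got {label!r}")
    return (total + charge * masses.proton_mass) / charge


def candidate_fragments(sequence: str) -> list[tuple[str, int, int]]:
    """All (series, index, charge) fragment candidates: y1.., b2.. at 1-2+.

    b1 ions are excluded (conventionally unobservable on triple quads).
    """
    n = len(sequence)
    cands = [("y", i, c) for i in range(1, n) for c in (1, 2)]
    cands += [("b", i, c) for i in range(2, n) for c in (1, 2)]
    return cands


def build_transitions(peptide: str, precursor_charge: int = 2,
                      observed_intensities: Mapping[tuple[str, int, int], float]
                      | None = None,
                      top_n: int = 8,
                      masses: MassSettings = MassSettings(),
                      mz_range: tuple[float, float] = (100.0, 1500.0)
                      ) -> list[TransitionRow]:
    """Build light+heavy transition rows for the top-N fragment ions.

    Candidates are all singly/doubly charged y and b ions (no b1) whose
    light product m/z lies within ``mz_range``.  With observed intensities
    the candidates are ranked by descending intensity (unobserved ions rank
    last); without, by the conventional prior: y before b, longer fragments
    first, lower charge first.  Each selected fragment is emitted as a light
    and a matching heavy transition.
    """
    validate_peptide(peptide)
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    cands = [(s, i, c) for (s, i, c) in candidate_fragments(peptide)
             if mz_range[0] <= fragment_mz(peptide, s, i, c, "light", masses)
             <= mz_range[1]]

    def default_key(cand):
        s, i, c = cand
        return (0 if s == "y" else 1, -i, c)

    if observed_intensities is not None:
        cands.sort(key=lambda cand: (-observed_intensities.get(cand, 0.0),
                                     default_key(cand)))
    else:
        cands.sort(key=default_key)
    rows = []
    for s, i, c in cands[:top_n]:
        for lab in ("light", "heavy"):
            rows.append(TransitionRow(
                peptide_sequence=peptide,
                precursor_mz=peptide_mz(peptide, precursor_charge, lab, masses),
                precursor_charge=precursor_charge,
                fragment_series=s, fragment_index=i, fragment_charge=c,
                product_mz=fragment_mz(peptide, s, i, c, lab, masses),
                label=lab))
    return rows


def evenness_score(areas: Sequence[float]) -> float:
    """Normalized Shannon entropy of the transition area distribution.

    1.0 means signal is spread perfectly evenly over the transitions; 0.0
    means a single transition carries everything.
    """
    a = np.asarray(areas, dtype=float)
    if a.size < 2:
        raise ValueError("evenness needs at least 2 areas")
    if np.any(a < 0):
        raise ValueError("areas must be non-negative")
    total = a.sum()
    if total == 0:
        raise ValueError("all-zero areas")
    p = a / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / math.log(a.size))


@dataclass(frozen=True)
class ParResult:
    par_mean: float
    per_replicate: tuple[float, ...]
    cv_percent: float  # 100 * sd / mean across replicates (0 for 1 replicate)


def _as_replicates(areas) -> list[list[float]]:
    first = areas[0]
    if isinstance(first, (int, float)):
        return [list(areas)]
    return [list(rep) for rep in areas]


def compute_par(light_areas, heavy_areas) -> ParResult:
    """Peak area ratio of summed light to summed heavy transition areas.

    Accepts a single replicate (flat list of per-transition areas) or a
    list of replicates; light and heavy must have matching shapes (same
    transition identities in the same order).
    """
    light = _as_replicates(light_areas)
    heavy = _as_replicates(heavy_areas)
    if len(light) != len(heavy) or any(len(l) != len(h)
                                       for l, h in zip(light, heavy)):
        raise ValueError("light and heavy transition areas must match")
    pars = []
    for l, h in zip(light, heavy):
        total_h = sum(h)
        if total_h <= 0:
            raise ValueError("zero heavy signal: PAR undefined")
        pars.append(sum(l) / total_h)
    mean = fmean(pars)
    cv = 100.0 * stdev(pars) / mean if len(pars) > 1 and mean != 0 else 0.0
    return ParResult(par_mean=mean, per_replicate=tuple(pars), cv_percent=cv)


def round_half_even(value: float, ndigits: int = 2) -> float:
    """Banker's rounding for display values."""
    from decimal import ROUND_HALF_EVEN, Decimal

    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum,
                                               rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class QuantResult:
    """Absolute quantification of the light peptide from PAR x heavy amount."""

    peptide: str | None
    par: float
    heavy_amount: float  # fmol on column
    light_amount: float  # fmol, = par * heavy_amount (full precision)
    light_amount_2dp: float
    cv_percent: float | None = None


def quantify_light(par: float, heavy_amount: float,
                   peptide: str | None = None,
                   cv_percent: float | None = None) -> QuantResult:
    """Convert a light/heavy peak area ratio into absolute light amount."""
    if par < 0:
        raise ValueError("PAR must be non-negative")
    if heavy_amount <= 0:
        raise ValueError("heavy spike-in amount must be positive")
    light = par * heavy_amount
    return QuantResult(peptide=peptide, par=par, heavy_amount=heavy_amount,
                       light_amount=light,
                       light_amount_2dp=round_half_even(light, 2),
                       cv_percent=cv_percent)


@dataclass
class CalibrationSeries:
    """A dilution series: spiked amounts with replicate responses and S/N."""

    amounts: list[float]          # strictly increasing, on-column
    responses: list[list[float]]  # per level, per replicate summed areas
    s2n: list[list[float]]        # per level, per replicate S/N
    unit: str = "fmol"

    def __post_init__(self) -> None:
        if len(self.amounts) < 3:
            raise ValueError("a calibration series needs at least 3 levels")
        if any(b <= a for a, b in zip(self.amounts, self.amounts[1:])):
            raise ValueError("amounts must be strictly increasing")
        if not (len(self.responses) == len(self.s2n) == len(self.amounts)):
            raise ValueError("responses/s2n must have one entry per level")
        if any(r < 0 for level in self.responses for r in level):
            raise ValueError("responses must be non-negative")

    def mean_responses(self) -> list[float]:
        return [fmean(level) for level in self.responses]

    def mean_s2n(self) -> list[float]:
        return [fmean(level) for level in self.s2n]


def estimate_lod_sn(series: CalibrationSeries,
                    sn_threshold: float = 3.0) -> float | None:
    """LOD by the S/N rule: lowest amount whose mean S/N strictly exceeds
    the threshold with every higher level also qualifying (no gaps).

    The no-gap condition stops a noise spike at a low amount from claiming
    detection below a level where the signal is actually lost.  Returns
    None when no level qualifies.
    """
    qualifies = [sn > sn_threshold for sn in series.mean_s2n()]
    lod = None
    for amount, ok in zip(reversed(series.amounts), reversed(qualifies)):
        if not ok:
            break
        lod = amount
    return lod


def estimate_lod_linearity(series: CalibrationSeries,
                           deviation_tolerance: float = 0.20) -> float | None:
    """LOD compensated for calibration-curve non-linearity.

    An ordinary least squares line is fitted to mean response vs amount over
    the top half of the levels (where the curve is trusted to be linear);
    walking down from the highest level, the LOD is the lowest amount whose
    mean response stays within ``deviation_tolerance`` (relative) of the
    fit.  Levels below the first violation — where the curve bends away —
    are excluded.
    """
    n = len(series.amounts)
    if n < 4:
        raise ValueError("linearity LOD needs at least 4 levels")
    means = series.mean_responses()
    n_top = n - n // 2  # ceil(n/2) levels from the top
    start = n - n_top
    fit = _stats.linregress(series.amounts[start:], means[start:])
    lod = None
    for amount, response in zip(reversed(series.amounts), reversed(means)):
        predicted = fit.slope * amount + fit.intercept
        if predicted <= 0:
            break
        if abs(response - predicted) / abs(predicted) > deviation_tolerance:
            break
        lod = amount
    return lod
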