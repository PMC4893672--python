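"""Optimal tryptic context search for a reporter peptide.

A reporter peptide fused into a host protein is only quantitative if trypsin
releases it efficiently, which depends on the residues flanking the
junction.  The workflow: take every tryptic peptide of the host proteome,
merge it before and after the reporter ("core") peptide, score the
probability of cleavage at the junction tryptic site with a pluggable
cleavage model, and rank the merged peptides by that probability.

The cleavage model is a plain callable contract
``model(merged_sequence, junction) -> probability in [0, 1]`` where
``junction`` is the 0-based position of the K/R whose C-terminal bond is
scored.  A transparent rule-based model is provided as the default
implementation of the contract; any predictor honouring the signature can
be plugged in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Literal, Sequence

from .core_io import validate_peptide
from .errors import ModelContractError

CleavageModel = Callable[[str, int], float]


@dataclass(frozen=True)
class MergedPeptide:
    """A flank/core merge with the junction site to be scored."""

    flank: str
    core: str
    side: str  # 'before' or 'after'
    merged_sequence: str
    junction: int  # 0-based index of the junction K/R in merged_sequence
    cleavage_probability: float | None = None


@dataclass
class MergedLibrary:
    """Merged peptides plus a count of flanks skipped for rule violations."""

    peptides: list[MergedPeptide]
    n_skipped_flanks: int = 0

    def __iter__(self):
        return iter(self.peptides)

    def __len__(self) -> int:
        return len(self.peptides)


def _merge_before(flank: str, core: str) -> MergedPeptide:
    # junction is the flank's C-terminal K/R
    return MergedPeptide(flank=flank, core=core, side="before",
                         merged_sequence=flank + core,
                         junction=len(flank) - 1)


def _merge_after(flank: str, core: str) -> MergedPeptide:
    # junction is the core's C-terminal K/R
    return MergedPeptide(flank=flank, core=core, side="after",
                         merged_sequence=core + flank,
                         junction=len(core) - 1)


def build_merged_library(core: str, flanks: Sequence[str],
                         side: Literal["before", "after", "both"] = "both"
                         ) -> MergedLibrary:
    """Merge each flank before and/or after the core peptide.

    A "before" flank must end in K/R (it must itself be a tryptic peptide
    whose C-terminus forms the junction): with ``side="before"`` a violating
    flank raises; with ``side="both"`` it is skipped for the before merge
    and counted.  An "after" merge requires the core to end in K/R.
    """
    validate_peptide(core)
    if side not in ("before", "after", "both"):
        raise ValueError(f"side must be before/after/both, got {side!r}")
    if side in ("after", "both") and core[-1] not in "KR":
        raise ValueError(
            f"core {core!r} does not end in K/R; no junction for 'after' merges")
    peptides: list[MergedPeptide] = []
    skipped = 0
    for flank in flanks:
        validate_peptide(flank)
        if side in ("before", "both"):
            if flank[-1] not in "KR":
                if side == "before":
                    raise ValueError(
                        f"'before' flank {flank!r} does not end in K/R")
                skipped += 1
            else:
                peptides.append(_merge_before(flank, core))
        if side in ("after", "both"):
            peptides.append(_merge_after(flank, core))
    return MergedLibrary(peptides=peptides, n_skipped_flanks=skipped)


def heuristic_cleavage_model(merged_sequence: str, junction: int) -> float:
    """Rule-based junction cleavage score (default CleavageModel).

    Rules (multiplicative, clamped to [0.001, 0.999]):

    * base probability 0.9 for a K/R junction;
    * x 0.01 if the residue after the junction is proline (cleavage
      essentially blocked);
    * x 0.6 for each acidic residue (D/E) directly before or after the
      junction (acidic neighbourhoods slow trypsin);
    * x 0.8 if the residue after the junction is K/R (competing adjacent
      sites produce ragged ends).
    """
    if not 0 <= junction < len(merged_sequence):
        raise ValueError(f"junction {junction} outside sequence")
    if merged_sequence[junction] not in "KR":
        raise ValueError(
            f"junction residue {merged_sequence[junction]!r} is not K or R")
    p = 0.9
    after = (merged_sequence[junction + 1]
             if junction + 1 < len(merged_sequence) else "")
    before = merged_sequence[junction - 1] if junction > 0 else ""
    if after == "P":
        p *= 0.01
    if before in "DE":
        p *= 0.6
    if after in "DE":
        p *= 0.6
    if after in "KR":
        p *= 0.8
    return min(max(p, 0.001), 0.999)


def constant_model(probability: float = 0.5) -> CleavageModel:
    """A model returning a fixed probability (useful to exercise tie-breaks)."""

    def model(merged_sequence: str, junction: int) -> float:
        return probability

    return model


def rank_contexts(library: Iterable[MergedPeptide],
                  model: CleavageModel = heuristic_cleavage_model
                  ) -> list[MergedPeptide]:
    """Score every merged peptide and sort by descending probability.

    Ties break lexicographically on the merged sequence.  A model returning
    a value outside [0, 1] is a contract violation and raises.
    """
    scored = []
    for mp in library:
        p = model(mp.merged_sequence, mp.junction)
        if not 0.0 <= p <= 1.0:
            raise ModelContractError(
                f"cleavage model {getattr(model, '__name__', model)!r} "
                f"returned {p} for {mp.merged_sequence!r} (outside [0, 1])")
        scored.append(MergedPeptide(
            flank=mp.flank, core=mp.core, side=mp.side,
            merged_sequence=mp.merged_sequence, junction=mp.junction,
            cleavage_probability=p))
    scored.sort(key=lambda m: (-m.cleavage_probability, m.merged_sequence))
    return scored


def write_ranked_contexts(ranked: Sequence[MergedPeptide], path,
                          model_name: str = "heuristic") -> None:
    """Ranked-context TSV: merged sequence, flank, side, junction, probability."""
    import csv

    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["merged_sequence", "flank", "side", "junction",
                         "cleavage_probability", "model"])
        for mp in ranked:
            writer.writerow([mp.merged_sequence, mp.flank, mp.side,
                             mp.junction, repr(mp.cleavage_probability),
                             model_name])


# Flanking contexts selected for the two lead reporter peptides by the
# original decision-tree cleavage predictor; shipped as the reference answer
# of that ranking, not as an expected output of the heuristic model.
REFERENCE_CONTEXTS: dict[str, tuple[str, str]] = {
    "EAVSEILETSR": ("LTLIFR", "FAYLYD"),   # PQS1
    "GLGASPGIGAGR": ("VAEAYR", "FLETEN"),  # PQS2
}
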