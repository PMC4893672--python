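# Methods

This note documents the models, conventions and numerical choices behind
`pqselect`, and what its synthetic data do and do not establish about real
measurements.

## Peptide metrics and the differential score

The matched intensity of a PSM is the sum of the intensities of its
annotated singly and doubly charged b and y fragment ions; a PSM with no
annotations contributes zero.  Per peptide and replicate experiment, the
average matched intensity is the mean over that peptide's PSMs, the
spectral count is the number of PSMs, and the ion coverage is the mean
annotated-ion count per PSM.

Two upstream rules precede all scoring.  Peptides mapping to more than one
protein accession are dropped as ambiguous: the score compares a peptide to
*its* protein, which is undefined otherwise.  Peptides of proteins with
fewer than three distinct retained peptides are dropped per experiment,
because a robust scale estimated from fewer than three values is
meaningless.  The floor is applied per experiment since the protein
statistics are estimated per experiment.

For each protein and experiment the location `m_j` and scale `s_j` of the
peptide intensities are estimated by Huber statistics: the scale is the
consistency-scaled median absolute deviation (constant 1.4826, held fixed
throughout), and the location starts at the median and is iterated as the
mean of the data winsorized to location ± k·scale with k = 1.2, until the
update moves less than `tolerance × scale` (default 1e-6, maximum 50
iterations).  These are the semantics of the R `MASS::huber` estimator,
which one test cross-checks directly through `Rscript`; the convergence
criterion is deliberately measured relative to the fixed scale, as that
implementation does.  When the MAD is zero (at least half the values
identical) the estimate is flagged degenerate: affected peptides get an
undefined score in that experiment rather than an infinite one, and are
excluded from selection with the reason recorded.  Protein statistics
include the peptide being scored — no leave-one-out correction is applied.

The differential score is `z_ij = (I_pep(i,j) − m_j) / s_j`, averaged
across the experiments where it is defined.  Because `I`, `m_j` and `s_j`
all scale linearly with the raw intensities, the score is exactly invariant
under global intensity rescaling (a calibration-free property the tests
verify).  Intensities are scored on the raw scale, not log-transformed.

Ion coverage is averaged per PSM within an experiment first, then across
experiments.  The alternative reading — summing annotated ions over all
spectra of an experiment — is available as `ion_coverage_summed`, but the
per-spectrum convention is the default: a selection threshold of 30 is only
attainable per spectrum, since an 11-residue peptide has at most
4·(n−1)−2 = 38 observable b/y ions over two charge states.

## Filters and selection strategies

The elimination filters remove peptides with methionine or cysteine
(oxidation variability), missed cleavages (variable tryptic release),
N-terminal glutamine (pyro-glutamate formation), consecutive prolines
(peak broadening), or length below 9 residues.  All five checks are always
evaluated so a rejected peptide reports every reason.

Method 1 keeps peptides with a defined score strictly above 6 in every
replicate.  Method 2 restricts to peptides with at least 3 spectra in an
experiment, re-applies the three-peptides-per-protein floor, recomputes the
protein scales on the restricted set, and keeps peptides scoring strictly
above 2 in every replicate; recomputation was chosen (over reusing
full-set scales) because the restricted set is the population actually
being compared.  The per-replicate reading of the method-2 threshold
mirrors method 1's phrasing; a mean-score variant is a one-line change in
`_passes_in_all_replicates` if ever needed.  Method 3 keeps peptides
identified in every replicate with mean ion coverage of 30 or higher
(inclusive, per its wording; the score thresholds are strict, per theirs).
The combined table is the filter-checked union, ordered by descending mean
score with a lexicographic tie-break.

The package ships a 15-peptide reference candidate list produced by these
rules on an archaeal (Pyrococcus furiosus) discovery dataset, split 7/3/5
over the three methods; reproducing that list from raw instrument data is
out of scope — the list is a fixture, not a computation.

## Digestion

Trypsin cleaves after K/R; the proline exception (no cleavage before P) is
on by default and exposed as a flag, since common search engines apply it
and all 15 reference candidates are consistent with it.  Peptides carry
0-based half-open coordinates; the zero-missed-cleavage products tile the
parent exactly, and missed-cleavage products up to a configurable maximum
(≤ 5) are appended.  N-terminal methionine clipping is not applied.  The
digester is validated against an independent quadratic-time reference and
against `pyteomics.parser.cleave` driven with an explicit `[KR](?!P)` rule
(pyteomics' builtin trypsin rule carries additional ExPASy exceptions that
are deliberately not used here).

## Proteome uniqueness

Candidates are searched as plain substrings of every protein in one or
more FASTA databases — no cleavage-rule or flanking-residue requirement,
since a fused reporter can sit in any context.  The index concatenates
sequences around a separator character outside the amino-acid alphabet, so
a query can never match across record boundaries; equivalence with a
per-record naive scan, including boundary-straddling queries, is tested on
a thousand random cases.  I/L equivalence (isobaric, indistinguishable by
fragment mass) is off by default but available, as it is the standard
caveat on MS uniqueness claims.  Matching ignores modifications.  Hit
reporting is capped (default 100) with the full count retained, bounding
output on low-complexity queries.

## Tryptic context ranking

To engineer efficient release of a reporter fused into a host protein,
every tryptic peptide of the host proteome is merged before and after the
core peptide, and the single junction tryptic site of each merged peptide
is scored by a cleavage model — a plain callable contract
`(merged_sequence, junction) → [0, 1]`.  Sites internal to the flank are
not scored.  "Before" and "after" libraries are ranked independently.  The
default model is a transparent heuristic: base 0.9; ×0.01 for proline
after the junction; ×0.6 per acidic residue adjacent to the junction;
×0.8 for K/R after the junction; clamped to [0.001, 0.999].  It is a
documented, reproducible stand-in honouring the contract — ranking
fidelity to any trained cleavage predictor is not claimed, and the shipped
reference contexts (LTLIFR-…-FAYLYD and VAEAYR-…-FLETEN for the two lead
reporters) are recorded as the answer of the original decision-tree
predictor, not as expected output of the heuristic.

## SRM arithmetic

Monoisotopic residue and water masses come from pyteomics; the proton mass
is 1.00727646688 Da.  Precursor m/z is `(Σ residues + water + z·proton)/z`;
b ions omit the water, y ions keep it.  Heavy labels default to fully
labelled C-terminal Lys (+8.014199 Da) and Arg (+10.008269 Da), so y ions
shift and b ions do not; the shift table is configurable.  Transition
candidates are all y (index ≥ 1) and b (index ≥ 2; b1 is conventionally
unobservable) ions at charges 1–2 within a configurable m/z window
(default 100–1500 Th), ranked by observed intensity when available and
otherwise by the conventional prior y-before-b, longer-first, lower charge
first; the top 8 are emitted for light and heavy.  Transition evenness is
the normalized Shannon entropy of the area distribution.

PAR is the ratio of summed light to summed heavy transition areas per
replicate; the replicate CV is 100·sd/mean (sample sd).  The light amount
is exactly PAR × heavy spike-in; display values are rounded half-to-even
at two decimals with full precision retained.

The S/N LOD is the lowest amount whose mean S/N strictly exceeds the
threshold (default 3) *and* that starts an unbroken qualifying run up to
the top of the series — the no-gap rule keeps a noise spike at a low
amount from claiming detection below a level where signal is lost.  The
linearity-compensated LOD fits ordinary least squares to mean response
versus amount over the top half of the levels and walks downward until a
level deviates more than 20% (relative, configurable) from the line;
levels below the bend are excluded.  This estimator is intended for
low-noise averaged series: with strong noise the extrapolated intercept
makes relative deviations at the lowest amounts unreliable, which is why
the recovery guarantee is stated (and tested) for the S/N method only.
S/N values are consumed as input; computing them from raw chromatograms is
out of scope.

## Synthetic data: what it emulates and what it does not

The discovery generator emulates the data structure the scoring assumes:
proteins with several identified peptides, three replicate experiments,
log-normal peptide intensities (dispersion σ = 0.5 on the log scale,
right-skewed as MS intensities are), Poisson spectral counts (mean 3,
minimum 1), and per-PSM fragment annotations whose intensities are split
by a symmetric Dirichlet over the candidate b/y ions and sum to the PSM's
matched intensity.  Defaults are 50 proteins × 8 peptides — the
well-covered stratum of a discovery run, which is the population the
protein-level robust statistics need.  Generated peptides avoid M, C, P, Q
and internal K/R so they pass the elimination filters and carry no missed
cleavages; peptide sequences are unique across proteins.  Per-protein
random substreams derived from the global seed keep existing proteins
byte-stable when a config adds more.

Flyers are planted at the fixed point where the peptide's realized
differential score (with the flyer included in the protein statistics)
equals the requested effect — i.e. the "true standardized effect" is
defined in the same robust-scale units the score uses, and the planted
score is exact to ~1e-9.  This makes recovery tests assess the selection
thresholds and bookkeeping, not estimator sampling noise: planting at a
scale estimated from baseline draws alone would make recovery of an
effect-8 flyer through a >6 threshold fail routinely at realistic peptide
counts, because the flyer itself inflates the re-estimated MAD.  Under the
null (no flyers) the score distribution has an inherent positive mean of
about +0.2 — the log-normal right tail is winsorized asymmetrically — far
below any selection threshold; the tests document this bias rather than
pretending the null is exactly centred.

Passing on these simulations shows the pipeline's bookkeeping, invariances
and thresholds are correct.  It does not show that real discovery data
satisfy the log-normal model, that real flyer effects are stable across
replicates, or that ion-coverage distributions match an instrument's —
conclusions about a real assay still require the wet-lab validation steps
this package deliberately leaves out.

The calibration generator plants an LOD on the standard two-fold dilution
grid (0.1–6.4 fmol): above it, response is linear with 10% multiplicative
noise and S/N grows linearly from 4 at the LOD; below it, response is
halved per level and S/N sits at 1.5.  With three replicates per level the
S/N rule recovers the planted LOD within one dilution step in ≥ 90% of
seeded runs (measured: 100%).

## Known limitations

- The PSM TSV dialect is this package's own; laboratory LIMS exports must
  be converted to it (no mzIdentML/vendor parsing).
- The heuristic cleavage model ranks junction contexts plausibly but is
  not a trained predictor.
- The linearity LOD is sensitive to noise at the lowest levels (see
  above).
- Collision-energy optimization, retention-time prediction and peak
  picking are out of scope; observed transition intensities, if used for
  ranking, must come from elsewhere.
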