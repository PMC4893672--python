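# pqselect

In-silico selection of proteotypic reporter peptides for targeted
proteomics (SRM/MRM), and the downstream stable-isotope-dilution assay
arithmetic that turns those peptides into quantitative protein tags.

## The problem

Selected reaction monitoring quantifies a protein through one or a few of
its tryptic peptides, monitored as *transitions* — predefined pairs of
precursor and fragment m/z on a triple-quadrupole instrument.  Building a
good assay means finding peptides that (i) ionize and fragment strongly,
(ii) behave reproducibly under tryptic digestion and chromatography, and
(iii) are *proteotypic*: absent from the background proteome so the signal
is unambiguous.  A peptide with all three properties can even be fused to
an arbitrary protein as a universal quantification tag, with an optimal
tryptic context engineered around it so trypsin releases it efficiently.

`pqselect` implements this discovery-to-assay workflow on ordinary
peptide-spectrum-match (PSM) tables:

1. **Scoring** (`pqselect.scoring`) — per peptide *i* of protein *j* and
   per replicate experiment, the average matched intensity
   `I_pep(i, j)` (mean over PSMs of the summed annotated b/y fragment
   intensities) is standardized against the protein's robust statistics:

       z_ij = (I_pep(i, j) − m_j) / s_j

   where `m_j` is the Huber location (iteratively winsorized mean, k = 1.2)
   and `s_j` the consistency-scaled MAD of the protein's peptide
   intensities.  Large `z` flags "flyer" peptides that ionize far above
   their protein's typical peptide.
2. **Filtering and selection** (`pqselect.selection`) — five elimination
   filters (Met/Cys, missed cleavages, N-terminal Gln, consecutive Pro,
   length < 9) and three selection strategies (score > 6 in all
   replicates; score > 2 with ≥ 3 spectra per replicate on recomputed
   protein scales; mean ion coverage ≥ 30), merged into a ranked selection
   table.  The package ships the 15-peptide reference candidate list these
   rules produced on an archaeal discovery dataset.
3. **Uniqueness** (`pqselect.proteotypicity`) — substring search of
   candidates against whole proteome FASTA files, irrespective of cleavage
   rules, with optional I/L equivalence.
4. **Tryptic context** (`pqselect.tryptic_context`) — merge host-proteome
   tryptic peptides before/after a reporter and rank junctions by predicted
   cleavage probability through a pluggable model interface.
5. **Assay math** (`pqselect.srm`) — precursor/fragment m/z, light+heavy
   transition lists, transition evenness, peak-area-ratio (PAR)
   quantification against a heavy spike-in, and limit-of-detection
   estimation by the S/N > 3 rule and by calibration-linearity
   compensation.
6. **Simulation** (`pqselect.simulate`) — seedable generators for
   discovery datasets (with flyers planted at exact standardized effects),
   decoy proteomes and calibration series, so every stage is testable with
   known ground truth.

## Worked example

Simulate a 12-protein discovery experiment with two planted flyers
(standardized effects 9 and 12), then run the full triage:

```sh
$ pqselect simulate --kind discovery --out psm.tsv --seed 7 \
      --n-proteins 12 --flyer 0:9 --flyer 1:12
$ pqselect select --psm psm.tsv --out report.tsv --verbose
selected 2 peptides (0 rejected by filters)
$ head -3 report.tsv
peptide_sequence  mean_score  score_exp1  score_exp2  score_exp3  avg_ion_coverage  spectral_counts       selection_sets
SLDSYITDSFK       11.99999…   11.99999…   11.99999…   11.99999…   12.38888…         exp1:2;exp2:2;exp3:6  1
TDFYEWGHR         8.99999…    8.99999…    8.99999…    8.99999…    16.33333…         exp1:4;exp2:4;exp3:2  1
```

Both planted flyers are recovered by selection method 1 with mean
differential scores equal to their planted effects (12 and 9); no baseline
peptide is selected.  Quantification against a heavy spike-in:

```sh
$ pqselect quantify --par 0.679 --heavy-fmol 15
peptide=-  PAR=0.679  heavy_fmol=15.0  light_fmol=10.18  light_fmol_full=10.185
```

A light/heavy peak area ratio of 0.679 with 15 fmol of heavy peptide on
column means 10.18 fmol of endogenous light peptide was measured.  A
transition list for the lead reporter peptide:

```sh
$ pqselect transitions --peptide EAVSEILETSR --out transitions.csv
$ head -3 transitions.csv
peptide_sequence,precursor_mz,precursor_charge,product_mz,fragment_ion,label
EAVSEILETSR,617.3196994169399,2,847.4519731770599,y7^1,light
EAVSEILETSR,622.3238339169399,2,857.46024217706,y7^1,heavy
```

The heavy precursor sits 5.0041 Th above the light at charge 2 (+10.0083 Da
fully labelled C-terminal Arg), and y ions shift with it while b ions do
not.

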