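# Methods

## Scoring matrix from ps-SCL responses

The estimator is `M[p, a] = log10(max(floor, median_e response(p, a, e)))`
over independent experiments *e*.  The median (even counts: mean of the two
central values) is robust to single-well outliers; the log10 turns the
multiplicative assay scale into the additive score scale.  The detection
`floor` (default 1.0 readout unit, an ELISA-style detection limit) keeps
the log defined; raising it can only raise entries (floor monotonicity).

The screen is run at two mixture concentrations (200 and 100 µg/ml).  The
default concentration policy uses the 200 µg/ml rows only, which keeps the
estimator a plain per-mixture median; `max-over-concentrations` and
`pool-as-experiments` are available when both doses carry signal.  No
blank subtraction is applied before the log by default; a `blank` argument
exists for assays where a no-peptide background should be removed first.

Properties relied on elsewhere: adding a constant to every matrix entry
adds 10× that constant to every decamer score and preserves rankings, so
the unknown global assay scale *B* (which shifts all entries by log10 B)
never affects percent-of-max ordering.

## Additive scanning

A decamer scores the sum of its ten matrix entries; candidates are decamers
whose score falls in a percent-of-maximum band, inclusive at both ends for
selection (80 belongs to an 80–100 selection).  For *binning* into
adjacent report bands, bands are half-open `[lo, hi)` except the top band,
which is closed — so a peptide at exactly 90% reports in 90–100.
Windows containing non-canonical residues (B, J, O, U, X, Z, `*`) are
skipped individually; the rest of the protein still contributes.
Coordinates are 1-based inclusive starts.  Ties at equal percent rank
lexicographically for deterministic output.  Negative entries are allowed
and percent-of-max may be negative; nothing is clamped.  The scan streams
record by record with vectorized window scoring, so memory scales with the
result set, not the database.

## Assay analytics

* SI = mean(condition cpm) / mean(control cpm), arithmetic means over
  replicates; stimulatory iff SI ≥ 2, threshold inclusive.  SI is invariant
  to any common positive rescaling of cpm.
* Net cytokine and specific cytotoxicity are control-subtracted values
  floored at 0 (reported quantities are non-negative).
* EC50 comes from a four-parameter logistic fit in log10-dose space,
  `y = bottom + (top − bottom) / (1 + 10^(hill·(logEC50 − logd)))`, by
  bounded least squares with a deterministic initialization (plateaus from
  the extreme dose means, hill 1, EC50 at the dose nearest the midpoint).
  Bottom is bounded at 0 because the readouts are non-negative.  A fit is
  flagged non-converged — never raised — when the optimiser fails, the
  plateaus invert, the data are flat, or the EC50 lands at the edge of
  [min dose/100, max dose·100].  On noise-free 4PL data all four parameters
  are recovered to ≤1e−4 relative error for hill in [0.5, 3].  At the
  five-dose study titration (20…0.002 µM) with EC50 0.018 µM only one dose
  sits below the EC50, so the hill/bottom/EC50 trade-off dominates the
  estimator variance: the Cramér–Rao bound at CV 5% with 5 replicates gives
  sd(log10 EC50) ≈ 0.058, i.e. roughly one in six fits falls outside ±20%
  even for an efficient estimator.  This is a property of the design, not
  of the optimiser (misfit parameter sets have lower residual error than
  the truth).
* "Recognized as well as the cognate antigen" is operationalized as
  SI(peptide) ≥ SI(cognate) at the shared single concentration.

## Peptide-set analysis

Peptide identity is the exact upper-cased amino-acid string; control-cohort
subtraction is exact match (an I/L-equivalence flag exists, off by
default).  Source rollups count unique protein accessions and organism
names over the deduplicated peptide set; records lacking annotations are
reported separately, never mixed in.  Phylum composition routes missing
lineages to an `unassigned` bucket; fractions sum to 1.  16S cross-matching
compares case-insensitively at species or genus rank; genus defaults to the
first whitespace token of the organism name and species to the first two,
with an explicit lineage mapping overriding both.  Genus is the default
rank because 16S resolution at species level is limited.

## TCR repertoire overlap

Clones are keyed by (CDR3 amino-acid sequence, V gene, J gene) at gene —
not allele — resolution, compared as literal strings when unresolved.
Non-productive rows are dropped, duplicate keys merged with templates
summed, and frequencies recomputed over retained templates, so fractions
always refer to the productive repertoire and sum to 1.  The headline
percentage is shared clones over the focal (first) repertoire's unique
clones; both directions and the Jaccard index are always reported, since
printed overlap percentages in the literature rarely state their
denominator.

## Synthetic-data generator

The generator defines the conditions under which the pipeline is tested:

* **Ground truth.** W[p, a] i.i.d. exponential (scale 1) then centred per
  position, so random decamers score ~0 while the best decamer scores
  `Σ_p max_a W[p, a]` (≈ 26 for scale 1).  Scale 0 is the degenerate
  all-equal case.  The mixture readout is `B·10^W` (B = 100 pg/ml), making
  the matrix estimator exact in the noiseless limit: M = W + log10 B.
* **Noise.** Multiplicative lognormal with log-mean 0 and log-sd
  `sqrt(ln(1 + CV²))` — median-preserving, so the median-based matrix
  estimator stays unbiased at any CV.  Default plate CV 20%, assay wells
  15%, titrations 5%.
* **Activation model.** Expected cpm is
  `baseline·(1 + gain·sigmoid((score − threshold)/width))` with gain 9
  (maximum expected SI 10, a strong clone), width 1 score unit, and the
  threshold at 85% of the truth's maximum score — a clone selective for
  the top of its score range.  Only additivity of the *score* is a
  modelled assumption of the analysis; the sigmoidal link from score to
  proliferation is an invented stand-in with every parameter explicit.
* **Proteomes.** Background residues i.i.d. uniform over the 20 canonical
  amino acids (configurable frequencies); planted decamers are written
  intact at recorded positions, spaced so plants never overwrite each
  other.  `planted_band_decamers` populates the upper score bands by
  substituting 1–6 positions of the argmax decamer with mid-ranked
  residues, since random background essentially never reaches 80% of max.
* **Repertoires.** Clone keys are random CDR3s (C…F, length 10–18) with
  random V/J gene labels; frequencies follow a power law (exponent 1) over
  a random rank permutation; the shared clone set is constructed, not
  sampled, so the overlap percentage is exact whenever
  `shared_fraction · n_a` is an integer.

What the generator does **not** emulate: HLA-binding structure (anchor
positions), residue composition bias of real proteomes, position
interactions that violate additivity, plate/batch effects, non-productive
TCR reads (present only when requested) and sequencing error.  Passing
tests therefore show the analysis is correct under its own assumptions and
calibrated noise — not that real screens meet those assumptions.

## Problem sizes and determinism

The end-to-end prediction-validation run uses 2,000 proteins of 480–540
residues (~10⁶ unique decamers), 3 plate experiments at CV 20%, 60 planted
candidates, up to 30 assayed per band with 5 wells at CV 15% — sizes at
which the full loop completes in seconds while the top-band statistic is
stable across seeds.  Every stochastic routine takes a single integer seed
and uses its own `numpy` Generator; there is no global random state, and
all file writers use fixed float formats so reruns are byte-identical.

## Known limitations

* The 4PL EC50 design limitation above: at titrations whose lowest dose
  barely undercuts the EC50, single-fit precision of ±20% cannot be
  guaranteed; adding a sub-EC50 dose or replicate titrations is the remedy.
* Percent-of-max compresses when a large constant offset (log10 B) is
  added to all entries; band edges are therefore meaningful relative to
  the matrix as built, and comparisons across matrices assume a shared
  readout scale.
* Set analyses treat a peptide list as ground truth; no spectral evidence
  or remapping is performed.
* Overlap statistics compare CDR3s at the amino-acid level by default and
  so conflate convergent nucleotide rearrangements; mapping the CDR3 field
  to a nucleotide column via `load_repertoire`'s column map switches the
  clone key to nucleotide resolution.
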