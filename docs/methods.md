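# Methods

This note documents the models, statistics and numerical choices behind
riboshift, what the synthetic-data generators do and do not emulate, and the
known limitations of each component.

## Heptamer scanning and dual-ORF gene models

The scanner matches the four *S. cerevisiae* +1 shift heptamers
(`CTTAGGC`, `CTTAGTT`, `GCGAGTT`, `GCGTGAC`; RNA input is normalised to the
DNA alphabet on read) and keeps only occurrences in phase with the anchoring
ORF's start codon.  Coordinates are 0-based half-open internally; GFF3 I/O
converts to/from 1-based closed.  `N` is accepted in input but never
matches.  When several heptamers occur in one ORF each yields its own
candidate model; no attempt is made to pick "the" site, and no distance
filter between the heptamer and the 0-frame stop is imposed — callers can
filter the site table.

A dual-ORF model closes the 0-frame ORF at the first in-frame stop at or
after the heptamer (for `GCG_U.GA_C` this is the TGA inside the heptamer
itself) and the +1 ORF at the first stop read from heptamer base 5 in steps
of three.  The stop set is TAA/TAG/TGA (standard nuclear code).  Frame
fusion deletes heptamer base 4, which joins the 0-frame portion through the
P-site codon in frame with the +1 ORF; the rule reproduces
`CTTAGGC → CTTGGC` and is applied uniformly to all four motifs because it
preserves the P-site codon and the +1-frame A-site codon in every case.
The trans-frame protein is the standard translation of the fused CDS up to
its stop, and equals (by construction, and verified property-wise) the
0-frame peptide through the P-site codon concatenated with the +1-frame
peptide; an internal stop in the fused frame is reported as a model
inconsistency.

## Ribosome-profiling efficiency

With P-site-assigned counts, the estimator is a density ratio:
`FS% = 100 · (rpf₁/codons₁)/(rpf₀/codons₀)`.  Region 0 runs from the start
codon to the heptamer P-site codon; region 1 covers the +1 ORF from the
first +1 codon clear of the 0-frame ORF to the +1 stop.  Choices that the
underlying description leaves open:

- **Trimming** — `trim_codons = 1` by default, removing one codon at each
  region end, because initiation and termination occupancy peaks are known
  artefacts; configurable, including 0.
- **Counting mode** — `region` (all counts in the region; the default,
  matching a densities-downstream-of-the-stop reading) versus `frame`
  (only positions in the region's own frame, the stricter "RPFs on each
  frame" reading).  The two agree exactly at perfect frame fidelity; both
  are exposed and neither is asserted to be the canonical published
  pipeline.
- **Region-0 end** — the P-site codon by default; `region0_end="stop"`
  extends it to the 0-frame stop for genes with long overlaps.
- `rpf₀ = 0` yields an *undefined* estimate (NaN, flagged), never 0 or ∞:
  no signal is not evidence of no frameshifting.

Aggregation across datasets reports median, quartiles (linear
interpolation — no convention was prescribed) and whiskers at the most
extreme values within 1.5×IQR.  P-site assignment from raw (position,
length) reads uses a 12-nt offset for 28–30-nt reads by default (community
convention, overridable); reads with unknown lengths or out-of-range
shifted positions are dropped and counted.

## Dual-luciferase efficiency

`FS% = 100 · mean(F/R)_test / mean(F/R)_control` (`mean_of_ratios`,
default, matching the per-well structure of an 8-replicate assay);
`ratio_of_means` pools summed firefly over summed Renilla per class.  The
reported SD is a first-order delta-method propagation of the two
class-level coefficients of variation at standard-error scale, so it
estimates the dispersion of the *estimate* and agrees with the bootstrap
option; it is not the raw replicate SD.  Scale invariance (multiplying all
readings by any c > 0) holds exactly for both methods.

## Conservation scan

The scan is an explicitly simplified stand-in for phylogeny-aware
synonymous-rate scans: no tree is inferred.  The null model is the
alignment-wide per-slot synonymous rate, where a slot is a (row, column)
pair whose amino acid matches the reference and neither codon is a gap —
only codons that *could* be synonymous variants are eligible.  For each
17-codon window (step 1 codon, centered, truncated edge windows skipped)
the observed synonymous count is tested against Binomial(n = eligible
slots, p = global rate) with a one-sided lower tail.  Because per-column
event probabilities are heterogeneous (codon degeneracy varies) and the
binomial is discrete, the test is conservative; the null simulation places
the p < 0.05 rate near 0.035 rather than 0.05.  Raw p-values are reported
by default (a dotted p < 0.05 threshold is the usual display); a
Benjamini–Hochberg option is available.  Ratios and p-values are comparable
*in kind*, not in value, to tree-based scans.

## Stem-loop detection and DMS scoring

The folding step answers "is there a stable hairpin here and where is its
base", not "what is ΔG".  A dynamic programme over states (outer pair,
internal loops used) finds the maximum-score single hairpin: +2 per
Watson–Crick pair, +1 per G·U, −2 per bulge/internal loop (≤2 of them, ≤3 nt
each), −3 to open, terminal loop ≥3 nt, windows ≤200 nt.  Scores are
ordinal stacking units, not free energies.  Ties prefer the longer helix,
then the 5′-most hairpin.  The DP is validated against exhaustive
enumeration of all legal hairpins on short windows.

One caveat discovered during design: reverse-complementing a window does
*not* in general preserve the optimal score, because a G·U pair maps to an
unpairable A·C.  The mirror symmetry holds exactly for hairpins containing
only Watson–Crick pairs, and that is the form the property test asserts.

The spacer from the hairpin base to the heptamer is reported in nucleotides
and, when divisible by three, codons (the native ABP140 geometry is
6 nt = 2 codons; extending it by inserted codons shifts the value
accordingly).  DMS agreement is the rank statistic P(unpaired A/C
reactivity > paired A/C reactivity), computed from the Mann–Whitney U with
ties at ½ — invariant to reactivity scale, which varies between probing
experiments.

## Synthetic data

The generators define the study conditions; defaults are fixed once:

- **Gene**: 0-frame ORF of 50 codons, +1 ORF of 30 sense codons, 0-frame
  stop 2 codons past the heptamer A-site codon (the sites of interest sit
  near their 0-frame stops; for the antizyme-type motif the stop is inside
  the heptamer).  Construction plants the heptamer and both stops
  explicitly and rejection-samples against accidental heptamer occurrences
  at any offset, so scanning a simulated gene finds exactly the planted
  site.
- **Profiles**: ribosomes branch at the heptamer with probability θ;
  per-codon Poisson counts with gamma(shape 5) rate multipliers (a
  realistic codon-level overdispersion; shape 0 disables it), expected
  total `depth` = 10⁵ by default, P-site on the codon's first nucleotide
  with probability `frame_fidelity` (default 0.9, 1.0 for estimator
  calibration) and ±1 nt spill otherwise.
- **Alignments**: each non-reference codon mutates to a random synonymous
  alternative with probability 0.1 (× `constraint_factor` inside a
  designated window) and to a non-synonymous single-nt neighbour with
  probability 0.03; no indels, so simulated alignments are gapless (gap
  handling is tested through the back-translation path).
- **Luciferase**: control F/R ratios lognormal around 0.5, test around
  0.5·θ, with unit-mean noise exp(σZ − σ²/2) (σ = 0.1), n = 8 wells/class.
- **DMS**: within the hairpin span, unpaired A/C ~ Exponential(mean
  `dms_snr`), paired A/C ~ Exponential(mean 1), G/T = NaN.  Under this
  model the population rank score is snr/(1+snr) — 2/3 at snr 2, 0.9 at
  snr 9 — and the tests assert that closed form.

What passing on synthetic data does **not** show: robustness to ligation
and amplification bias, UTR signal, multi-isoform genes, alignment error,
indel-rich orthologs, or reactivity normalisation artefacts — none of which
the generators emulate.

## Pipeline

Stages run in dependency order with plain-file intermediates
(`sites.tsv`, `models.gff3`, `ribo_fs.tsv`, `reporter.tsv`,
`conservation.tsv`, hairpin records, `summary.json`).  Quantification
stages can resume from a previous run's `sites.tsv` when the scan stage is
not requested.  Stage outputs carry no timestamps, so identically seeded
runs are byte-identical.  Input-hash caching was considered and dropped:
runs are seconds-scale and a cache adds staleness risk.  A stage failure
marks dependents skipped and the run not-ok; independent stages still
complete.

## Problem sizes used in validation

Estimator recovery uses 100 profiles per efficiency at depth 10⁵ over a
50/30-codon gene; scanner and hairpin oracles use 1,000 sequences of
50–2,000 nt and 500 windows of ≤12 nt; conservation calibration and power
use 200 alignments of 20 rows × 200 codons each; reporter recovery uses
200 simulated 8-replicate assays.  These sizes give Monte-Carlo standard
errors comfortably inside the asserted tolerances.
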