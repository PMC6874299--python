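# Methods

This note documents the models behind each pipeline stage, the synthetic
data they are validated against, the tunable parameters and their defaults,
and the design choices made where several readings were defensible.

## Count-noise statistics (`smfish`)

Per-cell transcript counts are summarized by the sample mean, unbiased
variance, Fano factor (variance/mean), adjusted Fisher–Pearson skewness,
and Poisson-normalized skewness (skewness × √mean, since a Poisson with
rate λ has skewness λ^(−1/2)). Both normalized statistics equal 1 in
expectation under the Poisson null, the noise floor for an unregulated
gene; geometric-burst transcription raises the Fano factor to 1 + burst
size.

The Poisson fit uses the MLE (the sample mean — the estimator is not
otherwise pinned down by the "best fit" convention) and a χ² goodness-of-fit
test: observed count frequencies vs Poisson expectations, with bins merged
inward from both tails until every expected frequency is ≥ 5 and one degree
of freedom subtracted for the estimated rate. Cells with zero counts are
retained: they are real cells, and dropping them would bias the mean
upward. All-zero vectors are flagged degenerate rather than scored.

Estimator bias matters below a few thousand cells; the validation suite
works at n ≥ 2,000 where the bias-corrected estimators keep the mean Fano
within [0.98, 1.02] and mean normalized skewness within [0.95, 1.05] over
200 replicate vectors.

## Bursty-count generator

Bursty counts are drawn from the Gamma–Poisson mixture, the stationary
negative-binomial law of geometric bursts: mean = burst_rate × burst_size,
Fano = 1 + burst_size. A full two-state telegraph (Gillespie) simulator is
kept in the test suite as an independent oracle; in the fast-switching
limit (k_off ≫ k_on) its stationary counts approach the same law. The
stationary law, not the dynamics, is what the count statistics probe, so
the cheaper generator is the default.

## Nuclear-localization traces (`imaging`)

Preprocessing per fluorescence frame: a 3×3 median filter (hot-pixel
removal) followed by subtraction of a 50×50 mean-filtered copy (local
background); negative values are allowed. A missing frame is replaced by
the mean of its two adjacent processed frames; a missing first/last frame
or two adjacent missing frames cannot be interpolated and raise.

The localization measure per cell and frame: the within-mask image is
filtered with a nucleus-shaped uniform disk of radius 3 px (a Gaussian
option exists); the maximal filter response inside the mask — ties broken
toward the smallest row-major coordinate, deterministically — defines the
hypothetical nucleus centre; the ratio is mean over disk∩mask divided by
mean over mask∖disk. The filter runs on the per-cell masked crop, not the
whole frame, so neighbouring cells cannot capture the maximum. Because the
measure is a ratio of means over the same frame it is exactly invariant to
global illumination scaling.

Traces are min-normalized per cell (minimum exactly 1, making the series a
signal-to-noise readout over the cell's own baseline) and z-scored per cell
for correlation analysis; constant series get NaN z-scores and are
excluded.

Two-round filtering follows the area/segmentation/appearance then
amplitude scheme: (1) area outside median ± 3 × mean absolute deviation
(across cells, per frame) on ≥ 10% of frames; (2) segmentation score < 8 on
≥ 10% of frames; (3) absent at the first frame; then (4) response amplitude
(max of the min-normalized trace) outside [1.1, 6]. All five thresholds are
arguments.

Same-cell vs cross-cell correlation: Pearson r between the two channels of
one cell over a frame window, against a null of A_i × B_j pairs (i ≠ j),
subsampled to at most 10,000 seeded pairs. The window boundaries
(immediate response vs longer-term dynamics) are caller-chosen parameters;
no canonical cutoff is built in.

### Movie renderer

Synthetic movies place disk-shaped cells (concentric nucleus) on a
non-overlapping grid; nuclear pixels carry baseline × trace value,
cytoplasm the baseline, plus a Gaussian point-spread blur and optional
pixel noise. The default blur σ = 0.5 px keeps the optical spread
sub-pixel relative to the 3-px nucleus filter, so the rendered ratio stays
within a few percent of the trace value; real optics are deliberately not
modelled — the renderer exists to give the scoring algorithm a known
answer, not to imitate a microscope. Onset-recovery tests use a normalized
ratio threshold of 1.5, an artifact convention.

## Flow cytometry (`cytometry`)

G1 gating thresholds the bimodal FSC-W width channel at the minimum of a
Gaussian KDE (Silverman bandwidth) between its two highest modes; the grid
is padded by three bandwidths so point-mass modes at the data extremes are
still detected. A unimodal distribution triggers a warning and no gating.

Scatter outliers: two sequential OLS fits (FSC-A~SSC-A, then SSC-A~FSC-A),
each removing events with |residual| > 2.5 residual SD (the cutoff is an
argument; no canonical value exists). A numerically perfect fit skips
removal — on exactly collinear data nothing is an outlier.

Background fluorescence of an unlabeled control is regressed on FSC-W,
SSC-W, and culture density (cells/µl from N/(R·T)·C) with an intercept;
corrected fluorescence = measured − predicted, negatives kept. Several
control samples at different densities identify the density coefficient;
a single sample leaves it collinear with the intercept, which the
minimum-norm least-squares solution tolerates and which is harmless when
correcting at the same density (density is treated per sample). Noise is
CV² = unbiased variance / mean², computed after gating, outlier removal,
and background correction; a non-positive corrected mean is flagged.

## UMI RNA-seq quantification (`rnaseq`)

Coordinates are 0-based half-open throughout. Reads collapse to molecules
by (chromosome, strand, 5′ position, UMI); the per-position unique-UMI
count is capped at 4^L. Gene windows are strand-aware intervals from
400 bp upstream of the 3′ end to 200 bp downstream, clipped at chromosome
bounds. A unique molecule inside one window counts 1; multimapped
molecules (grouped by UMI + locus set; collapse precedes splitting, so
PCR duplicates cannot vote twice) contribute u_g/Σu to each candidate gene
g, where u are the windows' unique-molecule counts, or 1/k when no unique
evidence exists. Assigned mass is conserved exactly. Reads reporting more
than two alignments only warn — the upstream aligner convention caps loci
at two.

Samples under 150,000 raw reads are discarded (low-coverage samples
artificially enrich for highly expressed genes); retained samples are
scaled to 10^6 total; an interior discarded timepoint takes the mean of
the nearest retained earlier and later samples, a boundary one the single
nearest retained sample (the interior rule does not define the boundary
case, so nearest-neighbour is used there).

Response AUC integrates log2((x(t)+p)/(x(0)+p)) by the trapezoid rule
(units log2·min; pseudocount p = 1 normalized read by default). The
dependency score is the mean over conditions of (WT AUC + ε)/(double-
deletion AUC + ε) with ε = 1 log2·min to tame near-zero denominators;
with ε → 0 it is scale-free. Peak log2 induction is provided as an
alternative summary. Target selection is the strict inequality
WT > 2 × double-deletion in a stated condition. Expression variability is
the across-sample variance of a gene's log2 expression per data set
(data sets under 20 samples are skipped), and flexibility is max/min
expression across a condition panel.

## Growth and competition (`growth`)

Time to exponential growth is the time of the maximal central-difference
slope of the OD curve, after a centered 3-point moving average (raw
differences via window 1); ties return the earliest time, and a maximal
slope below 0.01 OD/h flags "no growth". For a lag-shifted logistic the
expected answer is lag + ln(K/x₀ − 1)/r. An alternative threshold-crossing
readout (first OD above baseline + δ) covers the "growth first detected"
convention. Replicates are summarized by the median and SD over surviving
(growing) replicates plus the surviving fraction.

Competition fitness: generations per passage g = log2(dilution factor);
the mutant's division rate relative to WT is 1 + slope of
log2(mutant/WT odds) regressed on cumulative generations, reported as a
percentage. This log-odds-slope formulation is a reconstruction of the
standard competition-assay convention and is validated against synthetic
series with known fitness ratios only; on noise-free series it is exact,
and with frequency-measurement SD 0.01 it stays within ~3 percentage
points over 10 passages.

## Binding tracks and k-mer preference (`chec`)

The first nucleotide of every read increments the signal track at its
genomic position; tracks are scaled to a fixed total (10^7 for cleavage
data; the same operation with another constant builds 5′ mRNA tracks).
Read strand is ignored for track building by default (a stranded option
exists). Promoters are the ≤700 bp upstream of each TSS, truncated at the
nearest transcript body on either strand and clipped to chromosome bounds;
empty promoters are flagged.

Per-promoter binding is the track sum over the promoter, z-scored across
promoters with the sample (n−1) standard deviation; replicate tracks are
reduced by the per-promoter median before z-scoring, and two factors'
promoter vectors are compared by Pearson correlation.

k-mer preference: every 7-mer occurrence inside a promoter contributes the
track sum over [start − 10, start + k + 10), clipped at the promoter edges
(partial windows retained); occurrences are pooled across promoters, the
mean per k-mer taken, and z-scores computed over k-mers with ≥ 5
occurrences. Both strands are scanned — each position scores the forward
k-mer and, as a separate species, its reverse complement; `collapse_rc`
folds the two into one canonical species (the 4^7/2 = 8,192 convention).
Degenerate cases (uniform tracks) give all-equal means; those z-scores are
reported as 0 with a warning rather than left undefined, since zero
deviation from the mean is the faithful description. The TATA scanner
matches TATA[AT]A[AT] on both strands; N never matches.

The planted-motif generator draws read starts with probability ∝ 1 inside
promoters and ∝ enrichment within ±10 bp of each planted-k-mer occurrence,
and requires ≥ 5 occurrences so that the preference statistic is defined.

## Synthetic-data conditions

Generator defaults define the validation conditions: localization traces
use per-frame pulse probability 0.05, rectangular pulses of width 5
frames, amplitude fold 3, and trace noise SD 0.05–0.1 — free parameters,
since the underlying pulse statistics of stressed cells are not pinned
down by any published value; cytometry uses FSC-W modes at 50 and 100
(SD 8, ≥6 SD separation), a linear autofluorescence model, and log-normal
true signal; competition series default to dilution factor 8 (3
generations per passage). The generators emulate the statistical structure
the pipelines measure, not instrument physics: no real PSF or camera
noise spectra, no sequencer error profiles, no cytometer calibration.
Passing tests therefore demonstrate algorithmic correctness on data
satisfying the model assumptions, not robustness to every artifact of
real instruments.

Every generator routes all randomness through one seeded NumPy generator
per call and attaches a ground-truth record sufficient to compute each
downstream statistic's expected value analytically.

## Validation problem sizes

The test and acceptance runs use: 200 × 2,000-cell Poisson vectors and
10,000-cell bursty vectors for the noise floor; 500 null replicates for
goodness-of-fit calibration; 100 rendered single-cell movies (34×34 px,
100 frames) for onset recovery; 80-cell two-channel trace sets for
correlation separation; 100 random alignment tables for the UMI oracle;
a 5-gene toy annotation for quantification; 8-gene toy genomes with
50,000 reads over 20 seeds for planted-motif recovery; and 20,000–50,000
cytometry events. These sizes keep every check fast while leaving the
statistical tolerances comfortably met.

## Known limitations

- The cell-quality filter recomputes the cross-cell area band on whatever
  cohort it is given; idempotence holds for well-behaved cohorts but is
  not a mathematical guarantee under adversarial area distributions.
- The competition division-rate formula is a convention reconstruction
  (see above), not a validated reproduction of any published table.
- Multimapper splitting supports the two-locus convention; reads with more
  alignments are accepted with a warning but still split over their loci.
- The threshold fallback segmenter is for rendered synthetic movies only;
  real bright-field segmentation is out of scope and masks are consumed
  as inputs.
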