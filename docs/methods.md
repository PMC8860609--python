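# Methods

This note records the models, conventions, parameter choices and known
limitations behind `tcpscan`, in the order the pipeline runs.

## Coordinates and containers

All coordinates are 0-based, half-open, in transcript space: a transcript
is the 5'UTR followed by the CDS, the main start codon's `A` sits at
position `utr5_len`, and footprints are located by their 5' end.  RNA and
DNA alphabets are folded to one internal alphabet (U -> T) at ingestion.
A gene profile is the dense matrix `RC[length 15..100][position]` (86
rows); footprints outside the 15-100 nt band are dropped and counted.
Multi-mapped reads are split across candidate positions in proportion to
the unique-read density in a 100-nt window centred on each candidate
(clipped at transcript ends, divided by the covered width); an all-zero
density vector splits uniformly, the minimal-assumption completion of a
0/0 formula.  Profiles are normalized by per-gene mRNA level; genes with
zero (or missing) mRNA cannot be normalized and are excluded and listed.

## The generative scanning model

No forward model of SSU scanning exists in the literature at the level
this package needs, so `tcpscan.synthetic` defines one explicitly.  Per
gene, with loading intensity `depth * mrna_level`:

* **Survival.**  The probability of still scanning at UTR position p is
  `prod_{q<p} (1 - hazard(q))`, hazard = `dropoff_scale` x local folding
  strength (uniform when no folding backend is supplied, making the
  geometric closed form exact).  This encodes the detachment-by-structure
  hypothesis the folding analyses probe.
* **Dwell.**  Occupancy at a planted upstream AUG is multiplied by
  `pause_high` (default 6) or `pause_low` (1.5) according to its planted
  context class.  Planted high contexts carry the same A-rich flanks as
  every main start (`AAAAAA|AUG|TCT`), low contexts the C/G-rich
  opposite, so a context PSSM learned from main starts separates the
  classes by construction.
* **Terminal accumulation.**  Mass `loading * survival(L_utr) *
  start_dwell` is placed at the start codon, split over footprint lengths
  19/29/37 nt with weights 0.40/0.35/0.25 (the order of prominence the
  footprint histograms show).
* **Footprint geometry.**  A footprint of length L occupying position p
  has its 5' end at `p - (L - 15)//2` (clipped at 0): the protected
  region extends symmetrically as the complex grows.  The data place no
  constraint on this geometry; it is a fixed convention, and recovery
  tests that need shift-free placement use a point-mass length law at
  15 nt.
* **Noise.**  Counts are Poisson per (length, position) cell.  Negative
  binomial overdispersion was considered and left out: Poisson is the
  simplest law with a defensible variance check, and nothing downstream
  is variance-sensitive beyond that.

Lengths away from starts follow a discretized log-normal on 15-75 nt
(median ~30).  Default transcriptome: log-normal UTRs (median 60 nt,
sigma 0.45), CDSs (median 900 nt), GC 0.38, log-normal mRNA levels.
Every effect can be switched off independently; the truth record stores
planted offsets, classes, motif sites, mRNA levels and the per-position
expected occupancy.

## Feature engine

PSSM scores are natural-log sums of per-position probabilities; the log
base only rescales scores and can never reorder them, so all rank-based
results are base-independent.  The context PSSM covers positions -6..-1
and +4..+6 around an AUG, built from the main-start contexts of the
top-expressed genes (default top 5%, Laplace pseudocount 1; ties broken
by gene id).  Flank positions that run off the transcript contribute
log(1/4).  Windows with no AUG take sentinels: distance -1, score
`9*log(min PSSM entry) - 1` (below any attainable score; 0 would mean a
*perfect* score).  Folding features fold 31 consecutive 30-nt windows at
offsets 0..30 ("positions 1..31"); aggregates cover offsets 0..29,
14..29 and 19..29, reading the 1-based "15/20:30" ranges as inclusive.
Composition blocks use overlapping k-mers with denominators 30/29/28.
Motif scores are the maximum log-probability sum over all in-window
placements; HOMER motif files are re-normalized with zeros floored at
1e-4.  Three folding backends satisfy one contract (`mfe(seq) <= 0`):
the RNAfold executable when installed, a Nussinov pair-maximization
proxy (-1 kcal/mol per Watson-Crick/GU pair, minimum loop 3) as the
deterministic default, and constant/GC-proxy stubs for closed-form
tests.  Rank-based analyses only need an ordering of folding strength,
which the proxy preserves.

## Density regression

One model per footprint length, windows split 60/20/20 into
train/test/validation, 20 independent replicates.  Greedy forward
selection proposes the candidate whose OLS refit maximizes the train-set
Spearman correlation, and accepts it only if the refit model's *test-set*
correlation improves on the previous accepted step by more than 0.001;
the final model is scored on the validation set.  The stop rule is an
anti-overfitting device calibrated for very large window counts: at the
hundreds of thousands of windows the full analysis uses, the test-set
correlation noise of a useless feature falls below 0.001, so selection
on pure noise terminates after at most one feature (verified by
simulation at 100k windows).  A pure in-sample stop cannot do this -
every added OLS feature raises the in-sample correlation - which is why
the rule is applied out-of-sample; both metrics are configurable.
Targets and features enter the OLS fit untransformed; only evaluation is
rank-based.  Partial Spearman correlations rank-transform all variables,
project out the controls (plus intercept) by least squares, and
correlate the residuals, with a t-approximation p-value on n-k-2 degrees
of freedom; constant or rank-deficient control columns are dropped with
a log message, and a residual that is zero to numerical precision
(variable fully explained by controls) reports exactly 0.  The
folding-only predictor refuses to run on split indices differing from
the main run's: the comparison is only meaningful on identical
validation windows.

## TCP-IC

Signal matrices average per-gene RC over anchors, aligned on the anchor,
with each offset column divided by the number of anchors whose
transcript covers it — anchors near transcript ends would otherwise
drag edge columns down.  Discretization thresholds each row by its own
summary (mean, 2x mean, mean+sd, median) or by coordinate ascent on the
whole-matrix MIC (candidates: the row's unique values plus +inf,
ascending-length sweeps, strict-improvement acceptance so ties keep the
current threshold).  Masking is strictly greater-than, and a point is a
surviving **cell**, not a read.

MIC uses grids up to `B(n) = max(4, floor(n^0.6))` cells (the floor
keeps a 2x2 grid always admissible), mutual information in bits,
normalizer `log2(min(x, y))` — exactly 1 for a perfect 2x2 split.  For
n <= 40 the maximization is exact: all cut placements on one axis are
enumerated, and the other axis is optimized by an exact dynamic program
(the `-n*H(Y|X)` objective is additive over x-bins).  For larger n a
MINE-style approximation equipartitions the smaller axis and optimizes
the other by the same program, in both orientations.  An independent
brute-force enumerator over both axes' cut sets serves as the test
oracle; production and oracle agree exactly on hundreds of random small
point sets.

The permutation null shuffles the offset (column) order jointly across
rows — this preserves each column's footprint-length profile and is the
more conservative reading of "permute along the position axis"; an
independent per-row mode is available behind a flag.  Note what the
joint null does *not* destroy: a pattern with one surviving cell per
column (a bijection between length and position) scores high MIC under
any column order, so such patterns are never called significant against
this null; contiguous blocks and band structures are.  p is the fraction
of permutations with MIC strictly above the observed value; an
all-degenerate signal therefore reports p = 0 with an explicit
degenerate flag rather than silently.  Compared cohorts are equalized to
the smallest surviving point count by adding epsilon = 1e-5 to every row
threshold per iteration; the implementation computes the stopping step
in closed form (`ceil((S - t)/epsilon)` per cell) and the literal walk
is kept as its oracle.

Cohort constructors split scored populations at empirical quantiles with
stable (score, gene, position) ordering, so group sizes are within one
of `floor(q*N)` and the q = 0.5 split partitions everything with ties
going high.  Stop-codon distance is first-nucleotide-to-first-nucleotide
of the first in-frame stop (`AUGUAA` -> 3), scanning through the UTR
into the CDS; frames 1/2 shift the codon lattice by +1/+2 nt.
Downstream-folding groups average the 20 windows starting 1..20 nt
after the AUG's last nucleotide, exposing per-anchor means in the group
metadata so alternative offsets can be audited.

## Study conditions (desk scale)

The canonical experiments in `tcpscan.experiments` fix these sizes:

* **Pause cohorts:** 200 genes, UTR median 150 nt, depth 15
  reads/transcript-unit, mRNA sigma 0.6, pause 8x vs 1x, planting
  probability 0.5/0.5, start accumulation and drop-off OFF, context
  quantile q = 0.10 (cohorts of ~70 anchors), 2x-mean discretization.
  The start term is switched off deliberately: it produces accumulation
  shared by both cohorts that otherwise dominates both signal matrices,
  and the comparison should probe the planted pausing, not the shared
  background.  Longer-than-yeast UTRs keep the main start outside most
  anchor windows for the same reason.
* **Null calibration:** 20 x 31 signal matrices of i.i.d. Poisson(2)
  cells, 200 permutations.  Column exchangeability holds exactly here,
  so the permutation p-value is uniform by construction and the rejection
  rate at alpha = 0.05 must sit near 10/201; the test suite asserts it
  lands in [0.02, 0.09] over 200 matrices and the acceptance script
  reports the fraction it measures.
* **Regression recovery:** 5000 UTR windows over 60 genes, planted
  target `-z(utr5_len) + z(has_aug) + z(fe_mean_1_30) + N(0, 0.8)`,
  20 split replicates.

These are stand-ins for the organism-scale originals (~6600 genes,
~1.6M windows); passing recovery tests show the estimators detect what
the generator planted at these sizes, not that real signals are this
clean.

## Known limitations

* The generator omits sequencing artifacts (adapter/quality noise, rRNA
  contamination, nuclease-digestion length artifacts), 80S/LSU
  footprints, and any correlation structure between neighboring genes;
  real data are substantially noisier and more confounded.
* The synthetic main-start signal concentrates in three cells, so its
  MIC is far below what organism-scale start-codon signals produce;
  reproducing real-data MIC magnitudes is out of scope.
* The Nussinov proxy ranks folding strength but is not a thermodynamic
  energy; absolute kcal/mol values require the RNAfold backend.
* MIC-optimized discretization is coordinate ascent, exact only against
  exhaustive search on small matrices; on 86 x 101 matrices it is a
  local optimum by construction and considerably slower than the fixed
  rules.
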