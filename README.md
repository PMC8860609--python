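# tcpscan

Modeling the scanning of the small ribosomal subunit (SSU) along 5'UTRs
from TCP-seq-style footprint data.

During translation initiation in *S. cerevisiae*, the 40S subunit loads
near the mRNA cap and scans the 5'UTR toward the start codon.  TCP-seq
captures this directly: RNase-protected footprints of SSU-containing
complexes, mapped by 5' end and length (15-100 nt, with characteristic
19/29/37 nt lengths at start codons).  `tcpscan` implements, over
transcript-space footprint tables, the two quantitative approaches this
kind of data supports:

1. **Per-length density regression.**  For each footprint length, the
   mRNA-normalized read-count density in 30-nt sliding windows is
   predicted by greedy forward-selected linear regression over a
   transcript-feature set (5'UTR length, local folding energies over a
   31-window lookahead, AUG-context scores under a Kozak-like PSSM,
   k-mer composition, motif PSSM scores).  Selection proposes the
   candidate maximizing the train-set Spearman correlation and stops when
   the test-set correlation fails to improve by more than 0.001, over 20
   random 60/20/20 train/test/validation splits.  Feature attribution
   uses partial Spearman correlation (rank, residualize on controls,
   correlate residuals).

2. **TCP-IC.**  Around a cohort of anchors (start codons, upstream AUGs
   grouped by context score or uORF length, motif sites), per-gene
   profiles are averaged into an anchor-aligned signal matrix
   S[length, offset] (offsets -50..+50, coverage-normalized per column).
   Each row is thresholded (row mean, 2x mean, mean+sd, median, or
   MIC-optimized), and the surviving cells form a point set whose
   **maximal information coefficient** is computed:

       MIC = max over grids (x by y, x*y <= n^0.6) of
             I_max(x, y) / log2(min(x, y))

   with mutual information in bits.  Significance comes from a
   permutation null (column order shuffled, re-discretized, MIC
   recomputed; p = fraction of permutations scoring strictly higher),
   and compared cohorts are equalized to the same surviving point count
   by iterative threshold inflation (epsilon = 1e-5).  A MIC score X is
   analogous to a correlation of R^2 = X, i.e. R = sqrt(X).

Because the original sequencing data are not redistributable at desk
scale, the package ships a generative scanning model
(`tcpscan.synthetic`): survival-style drop-off, context-dependent dwell
at planted upstream AUGs, terminal accumulation at the start codon split
over the 19/29/37 nt modes, Poisson counts — every effect independently
switchable, with a truth record for recovery tests.

## Worked example

```
python analysis/01_simulate.py --seed 1        # synthetic transcriptome + footprints
python analysis/02_build_profiles.py           # normalized RC profiles
python analysis/05_tcpic_cohorts.py --n-perm 100
```

prints, for the planted-pause dataset (seed 1):

```
       label    mic  p_value  n_anchors  n_points  mode r_equivalent
  main_start 0.1277     0.82        150       159 2mean       0.3573
context_high 0.4294     0.00         62       159 2mean       0.6553
 context_low 0.1760     0.03         61       159 2mean       0.4195
  uorf_short 0.4537     0.00        123       159 2mean       0.6736
   uorf_long 0.3551     0.00        124       159 2mean       0.5959
```

High-context upstream AUGs — the ones planted with strong pausing —
produce a clearly structured signal (MIC 0.43, p < 0.01) while
low-context AUGs, which pause no more than background, sit near the
null (MIC 0.18); all cohorts are compared at an equalized 159 surviving
points.  The main-start row is a negative control in this design: the
generator's start-codon accumulation is switched off here, and the
permutation test duly reports no structure (p = 0.82).
`analysis/04_regression.py` fits the per-length density models on the
same data and reports median validation Spearman correlations around
0.5-0.6 at the 19/29/37 nt lengths, with AUG-context and composition
features most frequently selected.

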