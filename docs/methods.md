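# Methods

## The measurement model

Nascent-transcription coverage is represented as strand-specific single-base
signal: each read contributes one count at the polymerase active site, so a
track is a run-length encoded vector of non-negative per-base values with
0-based half-open coordinates (bedGraph semantics). Minus-strand signal is
stored non-negative in a separate track; plotting it below the axis is a
display convention only.

Sequencing depth alone cannot compare stages whose *absolute* transcription
differs, so normalization is anchored to nuclear run-on measurements. A
scintillation count rate (CPM) is linear in the amount of engaged
polymerase; serial dilutions of a standard chromatin preparation give an
ordinary-least-squares calibration line `cpm = m·dna_ng + b` (slope in CPM
per ng, fit by `scipy.stats.linregress`). For a sorted fraction, the ratio
observed/expected CPM estimates its relative transcriptional activity. A
mixed fraction with composition fractions over stages (LZ, P, D) satisfies

    observed_i / expected_i = frac_LZ,i · a_LZ + frac_P,i · a_P + frac_D,i · a_D

and the stage activities `a` are the unconstrained least-squares solution of
this system (exact when square and consistent). The activity vector is
identified only up to the calibration scale; all downstream uses depend on
activity *ratios*, which are scale-invariant. Rank deficiency of the
composition matrix raises an error naming the stages whose columns carry no
independent information; negative estimates trigger a warning, and an NNLS
mode is available when non-negativity is a hard prior.

Track normalization follows
`factor(stage) = (1/library_size) × (a_stage / a_reference)` with LZ as the
default reference. The exported DESeq2-style size factor is the reciprocal
convention, `library_size / (a_stage / a_reference)`, so that
`counts / size_factor = (counts / library_size) × activity ratio` — i.e.
dividing by library size and multiplying by relative activity. When size
factors feed the trajectory builder they are first rescaled to geometric
mean 1 (DESeq2's own convention) so normalized counts stay on the raw-count
scale and the pseudocount (default 1 normalized count) acts as intended;
between-stage ratios are unaffected.

## Windows, indices, filters

Per gene, windows follow the direction of transcription (on the minus
strand the TSS is the gene's end coordinate):

| window   | definition                    | default |
|----------|-------------------------------|---------|
| pause    | [TSS, TSS + 250)              | 250 bp  |
| body     | [TSS + 250, 3′ end)           | —       |
| post-PAS | [3′ end, 3′ end + 5000)       | 5 kb    |

Pausing index (PI) = pause density / body density; post-PAS retention index
(RI) = body density / post-PAS density. Densities are counts per bp using
the window length *after* clipping at chromosome ends (clipping is flagged).
Ratios with a zero denominator are reported as NaN, never 0 or infinity.
Genes enter the analysis only if longer than 500 bp and with their 3′ end at
least 5000 bp from every other gene's TSS on the same chromosome; genes no
longer than the pause window yield no summary at all. A minimum-count gate
on PI exists but defaults to 0 (off).

A TSS+250 pause window is the operative default; symmetric (TSS ± 250)
variants are reachable through the window parameters.

**Exact scale invariance of PI/RI.** Rescaling a track is carried as a lazy
scalar (`SignalTrack.scale`) applied on read-out, so stored values are never
mutated; PI and RI are computed from raw window sums in which that common
scalar cancels algebraically. Consequently pausing indices are *bit-for-bit*
identical under any positive rescaling — including the run-on-derived
normalization factors — rather than equal only to rounding error. This is
what makes PI comparisons across stages normalization-free.

## Metagene profiles

Scaled metagenes rescale each gene body to a fixed number of bins (default
40) with unscaled flanks (500 bp in 10 bins per side), reverse minus-strand
profiles, and report the per-bin **median over 1000 random gene subsamples**
drawn without replacement within each subsample, with a 5–95% envelope.
The subsample size is not dictated by the procedure's description, so the
default is 10% of usable genes (minimum 2) — an explicit guess, exposed as a
parameter. Genes whose flanks would leave the chromosome are dropped from
the profile. Peak-centered metaplots bin signal ±10 kb (default) around
interval centers and can sort the per-peak matrix by any external ranking
(e.g. another stage's signal).

## Trajectories and clustering

The trajectory of a gene is the log2 fold change of its size-factor
normalized window counts relative to LZ — 9 columns (3 stages × 3 windows),
with LZ columns identically zero. Clustering is seeded k-means
(`sklearn.cluster.KMeans`, `n_init=10`) on per-gene z-scored rows; genes
whose trajectory never exceeds a flatness threshold (default 0.1 in |log2
FC|) or has zero variance are left unassigned (−1), mimicking
tightness-based exclusion in consensus-clustering tools. The Bi-CoPaM-style
consensus algorithm itself is deliberately **not** re-implemented: the
scientific content here is the construction and interpretation of the
trajectory matrix, and the substitute is validated by planted-pattern
recovery (two archetypes at Gaussian noise σ = 0.25 recovered with mean
adjusted Rand index ≥ 0.9 over 50 seeds). The flatness threshold is only an
analogue — not an equivalent — of a consensus-tightness parameter. Rows are
processed in sorted gene-id order, so assignments are invariant to input row
order; cluster labels are renumbered by decreasing size for stability.

Concordance between nascent transcription and mRNA abundance is an OLS
slope and Pearson correlation on log2-transformed values with a pseudocount.

## Permutation statistics

Peak "center" is `floor((start+end)/2)` in 0-based coordinates. The overlap
statistic is the fraction of A peaks containing ≥ 1 B center. The null
re-places A's intervals uniformly among all non-overlapping configurations
on their own chromosome, preserving each interval's length and chromosome —
the behaviour of `bedtools shuffle -chrom -noOverlapping`. Placement uses
the exact spacings construction (draw one uniform offset per interval in the
chromosome's free space, sort, add cumulative lengths under a random
interval order) rather than rejection sampling: it is exactly uniform,
O(n log n), and never fails on feasible input; infeasible packings (total
interval length exceeding the chromosome) raise an error instead of
overlapping silently. Shuffled intervals may land on their original
positions, matching the cited flag semantics.

Empirical p-values use add-one smoothing by default:
`p = (#{null ⋄ observed} + 1) / (n_iter + 1)` with ⋄ ∈ {≥, ≤} by direction,
giving the floor `1/(n_iter+1)` (0.000999 at 1000 iterations — the printed
value that implies this convention); a raw-fraction mode is retained. Under
a true null the add-one p-value is conservative:
`P(p ≤ α) ≤ α + 1/(n_iter+1)`, verified by calibration simulation.

The co-occurrence test expands each accessible peak to a 5-kb window around
its center, builds per-peak boolean indicators for TRE and DSB-marker
centers, takes the proportion of peaks with both as the observed statistic,
and permutes the TRE column across peaks for the null (direction "less" for
segregation). When both labels are exchangeable the test is symmetric in
which column is shuffled. TSS-overlap comparisons between gene sets use a
±500 bp TSS window (a promoter-scale default; the width is configurable)
and delegate 2×2 testing to `scipy.stats` Fisher's exact and chi-squared
(with Yates correction). TRE-to-gene assignment maps each TRE center to the
nearest TSS within 50 kb, breaking ties toward the smaller coordinate and
then lexicographic gene id.

## The synthetic-data generator

The generator's defaults encode the study conditions the package targets:

- **Stages and activities:** LZ, P, D with planted relative activities
  (1.0, 2.7, 1.0) — the pachynema burst.
- **Window rates** (reads/bp, before the activity multiplier):
  LZ (0.20, 0.02, 0.004), P (0.20, 0.05, 0.012), D (0.12, 0.04, 0.010) —
  planted pausing indices 10, 4, 3 and retention indices ~4–5.
- **Annotation:** genes of 2–6 kb laid out with ≥ 6 kb intergenic gaps on
  equal-sized chromosomes, so every full-length gene passes the eligibility
  filters by construction; an optional fraction of deliberately short
  (400 bp) genes exercises the filters. Random strand per gene.
- **Signal:** independent Poisson counts per base on the gene's strand;
  intergenic background defaults to 0 (the background level is not dictated
  by the procedure being modelled, so it is off by default and exposed as a
  knob).
- **Run-on tables:** standards at 10-fold dilutions (500/50/5 ng, two
  replicates) exactly on a planted line (slope 20 CPM/ng, intercept 0) with
  optional Gaussian noise; samples with configurable composition rows
  (identity = three pure fractions by default; a Dirichlet helper produces
  17-sample mixed designs with a cycling dominant stage) and optional 5%
  multiplicative noise.
- **Peaks:** 400-bp accessible peaks at every TSS plus distal sites; 200-bp
  TREs at all TSS peaks and 30% of distal peaks; 150-bp DSB markers centered
  on accessible peaks, avoiding TRE-bearing peaks with probability
  `segregation` (default 0.9; 1 plants perfect exclusion, 0 independence).
- **Determinism:** one master seed; each operation draws from a named
  CRC32-keyed sub-stream, so outputs are byte-identical across runs and
  stable per operation.

What the generator does **not** emulate: read-level sequencing (FASTQ),
fragment lengths, sequence composition, mappability/GC bias, replicate
structure, contaminating cell types beyond the three stages (a fourth
component would be a config extension), or peak-calling noise. Passing tests
therefore demonstrate correctness of the *computations* under a clean
generative model, not robustness to alignment or calling artifacts in real
libraries.

## Problem sizes and numerical choices

Tests run the generator at 2 × 200–400 kb chromosomes with 12–24 genes,
where expected window counts (≥ 50) make planted ratios recoverable within
10%; calibration suites use 200 replicate tests at 1000 permutations each,
and clustering recovery uses 50 seeds. Least squares uses
`numpy.linalg.lstsq`; identifiability is checked via matrix rank before
solving. bedGraph parsing validates sortedness and non-overlap and reports
the offending line. Degenerate inputs are explicit errors (zero-length
windows, empty peak set A, empty null vector, k > number of genes) or
explicit missing values (NaN indices), never silent zeros.

## Known limitations

- The run-on solver assumes composition fractions sum to 1 over the three
  modelled stages; unmodelled contaminants bias activities toward the
  contaminant's activity share. The simulator can generate such tables, but
  the solver implements the three-component model as stated.
- The spacings shuffle is uniform over non-overlapping placements of the
  multiset of lengths; it does not condition on preserving gaps between
  specific interval pairs.
- The flatness threshold is a heuristic stand-in for consensus-clustering
  tightness and has no calibrated correspondence to it.
- Empirical p-values are bounded below by 1/(n_iter+1); claims below that
  resolution require more iterations, not extrapolation.
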