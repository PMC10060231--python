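# prophasetx

Analysis toolkit for **run-on-calibrated nascent transcription across meiotic
prophase I**. During the first meiotic prophase, spermatocytes hold RNA
polymerase II in a promoter-proximal paused state through
leptonema/zygonema (LZ) and release it into productive elongation in a
coordinated transcriptional burst at pachynema (P) that subsides in
diplonema (D). Because this burst changes *absolute* transcription levels
between stages, ordinary depth normalization of nascent-seq coverage
(ChRO-seq/PRO-seq-style tracks) erases the biology; this package implements
the bespoke computations needed to see it:

- **Run-on calibration and stage-activity deconvolution.** Serial-dilution
  standards define a line `cpm = m·x + b` (x = DNA input). For mixed sorted
  fractions with known stage composition, per-stage relative transcriptional
  activities solve, in least squares,

  ```
  observed CPM / expected CPM = (%LZ)·LZ + (%P)·P + (%D)·D
  ```

  Sequencing tracks are then rescaled by
  `(1 / library size) × (activity(stage) / activity(reference))`, with the
  matching DESeq2-style size factors exported.
- **Pausing and post-PAS retention indices.** Per gene, strand-aware windows:
  pause = [TSS, TSS+250), body = [TSS+250, 3′ end), post-PAS = 5 kb past the
  3′ end; pausing index = pause density / body density, retention index =
  body density / post-PAS density. Eligibility filters (length > 500 bp,
  3′ end ≥ 5 kb from any neighboring TSS), scaled metagene profiles (median
  of subsamples drawn without replacement), and peak-centered metaplots.
- **Fold-change trajectories and pattern clustering.** Per-gene log2 fold
  changes of size-factor-normalized window counts relative to LZ, clustered
  (seeded k-means on z-scored rows with a flatness filter) into groups such
  as burst-in-pachynema vs steady-then-declining.
- **Interval permutation statistics.** Chromosome- and size-preserving
  uniform shuffles (the `bedtools shuffle -chrom -noOverlapping` null),
  center-based overlap fractions, add-one-smoothed empirical p-values
  (floor `1/(n_iter+1)`), and a 5-kb expanded-window co-occurrence test that
  asks whether transcribed accessible peaks and DSB hotspots segregate.
- **A synthetic-data generator** that plants all of the above — stage
  activities (2.7× burst in P), pausing ratios, peak co-location or
  segregation, calibration standards — so every computation is testable
  end-to-end without external data.

## Worked example

```sh
prophasetx all --seed 1 --out-dir demo
```

simulates a dataset, calibrates it, and runs every stage. Key outputs:

`demo/norm/activities.csv` — deconvolved stage activities (the planted
2.7-fold pachynema burst is recovered exactly from the noiseless table):

```
stage,activity
LZ,1.0
P,2.7
D,1.0
```

`demo/pause/pause_summary.tsv` — per-gene windowed summaries; the median
pausing index relaxes across stages exactly as planted
(pause/body rate ratios 10, 4, 3):

```
stage   pausing_index  retention_index
LZ      9.52           4.58
P       3.87           4.09
D       2.84           4.10
```

`demo/overlap/overlap_results.json` — with TREs planted at accessible
peaks, the observed center-overlap fraction (0.81) exceeds all 1000 shuffle
replicates, so the enrichment p-value sits at the add-one floor
`1/1001 = 0.000999`; the TRE/DSB co-occurrence test reports depletion
(observed 0.11 vs null mean 0.19, p = 0.008, direction "less").

`demo/cluster/assignments.tsv` — trajectory cluster per gene (−1 means the
trajectory never left the LZ baseline by more than the flatness threshold).

Every subcommand writes a `manifest.json` with parameters, derived seeds,
and SHA-256 checksums of its outputs; the same master seed reproduces every
file byte-for-byte.

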