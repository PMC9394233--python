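# Methods

Statistical model and parameter choices behind `sctc_cnv`. Defaults quoted
here are the function defaults; every one can be overridden per call or via
`PipelineConfig`.

## 1. Binning and normalization

The genome is tiled into fixed-width bins (default 100 kb; the bundled hg19
grid has 30 970 autosomal + X/Y bins). A trailing partial bin is emitted
for each chromosome. Bins can be annotated with GC fraction (coverage-
weighted mean over overlapping track intervals), mappability, and a
blacklist; a bin is *usable* when it is unblacklisted and meets the
mappability floor.

Read counting (pysam) keeps primary, mapped, non-duplicate, non-
supplementary alignments; for proper pairs only read 1 is counted so a
fragment contributes once. A read is assigned to the bin containing its
leftmost aligned base.

Normalization divides counts by the median over usable non-empty bins and
takes log2, so the diploid baseline sits at 0 exactly. Optional GC
correction fits a lowess of log2 ratio on GC and subtracts it. Empty usable
bins become NaN and are carried as missing throughout the pipeline. The
per-sample noise scale `sigma_delta` is the Gaussian-consistent MAD of
successive-bin differences divided by √2, which is insensitive to true CN
steps.

## 2. Wave correction

WGA and library chemistry impose a sample-dependent "wave" along the
genome that is shared, up to scale, across samples. A calibration panel is
built from CN-flat normal profiles: members whose residual variance against
the panel mean exceeds `variance_threshold` are dropped in a single pass,
and the panel stores the autosomal mean wave field. `dewave` regresses a
target profile onto the panel field by least squares over common autosomal
bins and subtracts the fitted component. Sex chromosomes are excluded from
the fit (their baseline depends on sex) but are corrected with the fitted
coefficient. Panel members are handled leave-one-out so a sample never
corrects against itself.

## 3. Segmentation

Circular binary segmentation per chromosome: the maximal arc statistic
(vectorized over cumulative sums, all widths ≥ `min_width` = 10) is tested
by permutation (`n_permutations` = 1000, early-rejection stop) at
`alpha` = 0.01, recursing on significant splits.

The undo-splits pass merges adjacent segments in **standard-error units**:
a boundary is removed while

|Δmean| / √(1/n_left + 1/n_right) < `undo_sd` × σ̂,

with σ̂ the successive-difference MAD estimate above and `undo_sd` = 4.
Scaling the gate by the segment-length-dependent standard error, rather
than by the raw per-bin SD, keeps the criterion calibrated across segment
sizes: a fixed per-bin-SD gate is far too permissive for long segments at
single-cell noise levels (σ̂ ≈ 0.3–0.5) and erases genuine single-copy
events, while the SE-scaled gate removes only boundaries that are
statistically indistinguishable from noise. On synthetic single-copy
events this choice raises per-bin state recovery from ~0.83 to ~1.00
without inflating segment counts on flat profiles.

## 4. Copy-number calling

States are {loss −1, neutral 0, gain +1, amplification +2}, optionally
{double loss −2}. Each state has a fixed center
log2((c·cn + (1−c)·2)/2) for cellularity c (default 1), floored at
log2(0.05). Segment means are modelled as Gaussians around the centers
with σ_seg = σ̂/√n_bins, deflated by `rel_sd_long` = 2 for segments of
≥ `long_threshold` = 10 bins, and doubled for the open-ended amplification
state. An EM fit estimates only the state mixing proportions — shared
across the cohort when calling many cells together — and yields per-
segment posteriors, broadcast to bins. Chromosome Y is never called;
chromosome X is excluded unless `male_x` shifts its centers one copy down.

## 5. Condensation, distances, clustering

`condense_calls` collapses runs of genomically adjacent bins whose hard
calls are identical in every sample into regions; runs break at chromosome
boundaries, at any call change, and across gaps of bins not called in all
samples, so every region is a contiguous genomic interval. Distances
between cells are bin-weighted Hamming distances on hard calls (or mean
absolute posterior differences) over the condensed regions; average-
linkage hierarchical clustering gives a dendrogram exported as Newick.
`query_region` aggregates calls over an interval per sample:
amplification if any bin is amplified, else the majority call with ties
resolved upward.

## 6. Quality control

- **Multiplex band score**: count of positive bands out of 7 (pass at
  ≥ 5 by default; an alternative 8-band genomic mode).
- **Arm ratios / WGA uniformity**: per-arm read fractions divided by
  panel-mean fractions (leave-one-out for panel members). A sample fails
  when > 50 % of arms fall below ratio 0.1 or the top-3 arms hold > 50 %
  of reads — the signature of amplification collapsing onto a few arms.
- **Profile MAD**: plain median absolute deviation of log2 ratios,
  genome-wide or per chromosome.
- **Empty-bin gate**: flags samples whose empty-bin count exceeds an
  absolute fraction or `relative_multiple` = 3 × the cohort median.
- **Minimum depth**: binomial thinning of the count vector to a ladder of
  depths; at each depth the Spearman correlation between the thinned and
  full normalized profiles is averaged over iterations, and the smallest
  depth exceeding `threshold` = 0.9 is recommended.
- **Paired Wilcoxon signed-rank**: zero differences and incomplete pairs
  are dropped. For n ≤ 25 the test is exact: the sign-flip distribution of
  the signed-rank statistic is enumerated by dynamic programming over
  doubled midranks, so tied |differences| are handled exactly rather than
  pushed to an approximation — small-n ties otherwise produce a normal-
  approximation p that can differ from the exact value in the leading
  digit. For n > 25 a normal approximation with continuity correction and
  tie-corrected variance is used. Five complete pairs are required.

## 7. Synthetic data

`simulate_cells` draws per-bin counts from a negative binomial (size 10 by
default; Poisson when dispersion is None) with expectation proportional to
bin width × clone copy number ÷ 2, scaled to the requested read total.
All cells in a spec share one sinusoid wave field (sum of random-phase
components, max amplitude = `wave_amplitude`), applied multiplicatively
in log2 space, with a per-cell coupling coefficient. Additional knobs:
bin dropout, unusable bins, per-cell clone assignment with exported
per-bin copy-number truth. `simulate_failed_wga` reweights a cell's
expectation onto a Dirichlet-weighted subset of chromosome arms (residual
weight 10⁻⁴ elsewhere), mimicking amplification collapse.

Known simplifications: the wave is sinusoidal rather than GC-driven, bins
are i.i.d. given the mean (no alignment artefacts or mappability
gradients), and breakpoints fall exactly on bin boundaries. These are
deliberate — the generator exists to give sharp, checkable ground truth
for the estimators, not to imitate a sequencer.

## 8. Verification

Every module is tested against an independent oracle: an O(n²) exhaustive
search for the CBS arc statistic, full 2ⁿ sign-flip enumeration for the
exact Wilcoxon branch, a run-length oracle for region condensation,
base-level interval arithmetic for annotation, leave-one-out least squares
for dewaving, and hand-computed values for centers, ratios and MADs.
`scripts/acceptance.py` recomputes the headline numbers end-to-end:
breakpoint recovery within ±2 bins in ≥ 95 % of noisy replicates, ≥ 95 %
per-bin state recovery on a two-clone cohort at 2.5 M reads/cell, strict
segment-count reduction from dewaving on wave-biased flat normals, 100 %
sensitivity/specificity of the uniformity flag on 20 + 20 synthetic
samples, and monotone subsampling correlations reaching r = 1 at full
depth. Problem sizes were chosen so the whole suite runs in ~75 s on one
CPU while leaving comfortable statistical margins at the default
thresholds.
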