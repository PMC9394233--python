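# sctc-cnv

Copy-number profiling of single circulating tumour cells (CTCs) from
low-pass whole-genome sequencing. The package takes per-cell BAM/SAM files
(or precomputed count tables), bins reads on a fixed genomic grid, corrects
wave bias against a panel of diploid normals, segments each profile with
circular binary segmentation, calls integral copy-number states, condenses
calls into shared regions, and clusters cells — with a quality-control layer
designed for the failure modes of whole-genome-amplified single cells.

## What it does

- **`genome_bins`** — fixed-width bin grids (hg19 built in, or any
  chromosome-sizes file), blacklist/mappability/GC annotation, read counting
  from BAM/SAM via pysam, median normalization to log2 ratios with optional
  GC loess correction.
- **`wave_correction`** — builds a calibration panel from CN-flat normal
  samples and regresses each tumour profile onto the panel's shared wave
  field (leave-one-out least squares), removing GC/amplification wave bias
  before segmentation.
- **`segmentation`** — circular binary segmentation with permutation
  p-values and an undo-splits pass that merges breakpoints whose mean
  difference is small in standard-error units.
- **`calling`** — integral states {loss, neutral, gain, amplification}
  (optionally double-loss) from fixed admixture-aware log2 centers, with an
  EM fit of mixing proportions shared across a cohort and per-segment
  posteriors.
- **`clustering`** — condenses per-bin calls into maximal constant regions,
  computes weighted Hamming / posterior distances, average-linkage
  hierarchical clustering with Newick export, and region queries
  ("is chr8q gained in this cell?").
- **`qc`** — multiplex-band QC scores, chromosome-arm ratio uniformity
  flags for failed WGA, profile MAD, empty-bin outlier rejection, binomial
  read thinning, minimum-depth determination by subsampling, and an exact
  paired Wilcoxon signed-rank test.
- **`simulate`** — synthetic cohorts with exported ground truth: negative
  binomial (or Poisson) counts, clone copy-number profiles, shared sinusoid
  wave fields, failed-WGA arm collapse.
- **`pipeline` / CLI** — one-command orchestration from count tables to
  dendrogram, with per-sample quarantine instead of hard failure.

## Tests

```
python -m pytest -q tests/
```

The suite (178 tests, ~75 s on one CPU) checks every module against
brute-force or hand-computed oracles: an O(n²) exhaustive arc-statistic
oracle for CBS, a run-length oracle for region condensation, full 2ⁿ
sign-flip enumeration for the exact Wilcoxon test, base-level overlap
oracles for blacklist annotation, and end-to-end state recovery on
simulated cohorts. `tests/test_acceptance.py` holds the headline criteria.

## Quick start (CLI)

Simulate a demo cohort, normalize one cell, and segment it:

```
$ sctc-cnv simulate cells --seed 3 --out sim
8 cells written to sim

$ sctc-cnv normalize sim/cell0.counts.tsv --no-gc --out p.tsv
sigma_delta=0.2158 empty_bins=0

$ sctc-cnv segment p.tsv --nperm 200 --out p.segments.tsv
9 segments

$ head -3 p.segments.tsv
chrom	start_bp	end_bp	n_bins	mean_log2
chr1	0	10000000	100	-0.052298
chr1	10000000	24200000	142	0.562612

$ sctc-cnv qc score --bands 1,1,1,1,1,0,1
QC-6 PASS
```

`sctc-cnv run --config cfg.yaml --samples a.tsv --normals n1.tsv … --out out/`
executes every stage and writes profiles, segments, calls, condensed
regions, distances, a Newick dendrogram and a JSON manifest.

## Quick start (Python)

```python
import sctc_cnv as sc

grid = sc.make_toy_grid(n_chroms=2, bins_per_chrom=250)
clones = {
    "normal": sc.flat_clone(grid),
    "tumour": sc.clone_with_events(grid, [("chr1", 40, 120, 3),
                                          ("chr2", 0, 80, 1)]),
}
cells = {f"t{i}": ("tumour", 600_000) for i in range(3)}
cells.update({f"n{i}": ("normal", 600_000) for i in range(6)})
spec = sc.SimulationSpec(grid=grid, clones=clones, cells=cells,
                         wave_amplitude=0.2, wave_wavelength=60, seed=0)
profiles, truth = sc.simulate_cells(spec)

normals = [sc.normalize_profile(profiles[f"n{i}"]) for i in range(6)]
panel = sc.build_calibration_panel(normals, variance_threshold=10.0)

pairs = []
for i in range(3):
    prof = sc.dewave(sc.normalize_profile(profiles[f"t{i}"]), panel)
    seg = sc.segment_profile(prof, n_permutations=200, seed=0)
    print(f"t{i}: sigma_delta={prof.sigma_delta:.3f}  segments={seg.n_segments}")
    pairs.append((seg, prof))

called = sc.call_profiles(pairs)
regions = sc.condense_calls(called)
print(f"{regions.n_regions} condensed regions")
verdicts = sc.query_region(called, grid, "chr1:4000000-12000000")
print({s: v["call"] for s, v in verdicts.items()})
```

Output:

```
t0: sigma_delta=0.219  segments=5
t1: sigma_delta=0.224  segments=5
t2: sigma_delta=0.229  segments=5
9 condensed regions
{'t0': 1, 't1': 1, 't2': 1}
```

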