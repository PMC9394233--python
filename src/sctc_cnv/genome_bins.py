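"""Genome tiling, read counting and per-bin normalization.

The genome is tiled into fixed-width, non-overlapping, half-open bins (default
100 kb).  Reads from coordinate-sorted alignments are counted into bins by
their leftmost aligned base, low-quality and duplicate records are discarded,
and counts are converted to median-centred log2 ratios with optional
GC-content and mappability correction by locally weighted regression.

Zero-count usable bins are treated as *missing*, not as log2(0); their number
(the "empty bin" count) is a per-sample library-quality signal.  The
first-difference noise variance sigma_delta = var(diff(log2 ratios)) / 2 is
reported alongside, as the bin-size-selection noise metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genomes import HG19_CHROM_LENGTHS, add_chr, strip_chr

__all__ = [
    "BinGrid",
    "ReadCountProfile",
    "NormalizedProfile",
    "make_bin_grid",
    "make_hg19_grid",
    "annotate_bins",
    "count_reads",
    "normalize_profile",
]


@dataclass
class BinGrid:
    """The genome tiled into fixed-width bins.

    Bins are 0-based, half-open, contiguous within each chromosome; the last
    bin per chromosome is truncated to the chromosome end.  The global bin
    index (position in the arrays) is the stable key used by every profile.
    """

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    bin_size: int
    chrom: np.ndarray       # per-bin chromosome name (unicode array)
    start: np.ndarray       # per-bin start, int64
    end: np.ndarray         # per-bin end (exclusive), int64
    gc: np.ndarray          # per-bin GC fraction in [0, 1], NaN where unknown
    mappability: np.ndarray # per-bin mappability in [0, 1], NaN where unknown
    usable: np.ndarray      # per-bin usability flag, bool

    @property
    def n_bins(self) -> int:
        return len(self.start)

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous index range of one chromosome's bins."""
        idx = np.flatnonzero(self.chrom == chrom)
        if idx.size == 0:
            raise KeyError(f"chromosome {chrom!r} not in grid")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def resolve_chrom(self, name: str) -> str | None:
        """Map an external chromosome name onto the grid ('chr' prefix tolerated)."""
        for cand in (name, add_chr(name), strip_chr(name)):
            if cand in self.chrom_lengths:
                return cand
        return None


@dataclass
class ReadCountProfile:
    """Raw per-bin read counts for one sample."""

    sample_id: str
    grid: BinGrid
    raw_counts: np.ndarray          # int64, len == grid.n_bins
    total_mapped_reads: int
    unassigned_reads: int = 0
    filter_settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.raw_counts) != self.grid.n_bins:
            raise ValueError("count vector length does not match grid")
        if (self.raw_counts < 0).any():
            raise ValueError("negative read counts")


@dataclass
class NormalizedProfile:
    """Median-centred log2 ratios for one sample (NaN = missing bin)."""

    sample_id: str
    grid: BinGrid
    log2_ratio: np.ndarray          # float64, NaN where filtered or zero-count
    sigma_delta: float
    empty_bin_count: int
    gc_corrected: bool = False
    mappability_corrected: bool = False
    dewaved: bool = False
    usable_profile: bool = True

    @property
    def values(self) -> np.ndarray:
        """Non-missing log2 ratios in genome order."""
        return self.log2_ratio[~np.isnan(self.log2_ratio)]

    def copy_with(self, **kw) -> "NormalizedProfile":
        return replace(self, **kw)


def make_bin_grid(chrom_lengths: Mapping[str, int], bin_size: int = 100_000) -> BinGrid:
    """Tile chromosomes into fixed-width half-open bins.

    Every bin except possibly the last per chromosome has width ``bin_size``;
    the last is truncated at the chromosome end, so each chromosome yields
    ``ceil(length / bin_size)`` bins.
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(
                f"chromosome {chrom!r} has non-positive length {length}"
            )
    chroms, starts, ends = [], [], []
    for chrom, length in chrom_lengths.items():
        bin_starts = np.arange(0, length, bin_size, dtype=np.int64)
        bin_ends = np.minimum(bin_starts + bin_size, length)
        chroms.append(np.full(len(bin_starts), chrom, dtype=object))
        starts.append(bin_starts)
        ends.append(bin_ends)
    start = np.concatenate(starts)
    n = len(start)
    return BinGrid(
        chrom_names=list(chrom_lengths),
        chrom_lengths=dict(chrom_lengths),
        bin_size=bin_size,
        chrom=np.concatenate(chroms).astype(str),
        start=start,
        end=np.concatenate(ends),
        gc=np.full(n, np.nan),
        mappability=np.full(n, np.nan),
        usable=np.ones(n, dtype=bool),
    )


def make_hg19_grid(bin_size: int = 100_000) -> BinGrid:
    """Standard hg19 grid over chr1-22, X, Y (30 970 bins at 100 kb)."""
    return make_bin_grid(HG19_CHROM_LENGTHS, bin_size)


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(ivals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _bin_weighted_mean(
    grid: BinGrid, track: Iterable[tuple[str, int, int, float]]
) -> np.ndarray:
    """Length-weighted mean of a (chrom, start, end, value) track per bin."""
    acc = np.zeros(grid.n_bins)
    wsum = np.zeros(grid.n_bins)
    offsets = {c: grid.chrom_slice(c).start for c in grid.chrom_names}
    for chrom, s, e, val in track:
        resolved = grid.resolve_chrom(chrom)
        if resolved is None:
            continue
        if s >= e:
            raise ValueError(f"malformed track interval {chrom}:{s}-{e}")
        off = offsets[resolved]
        length = grid.chrom_lengths[resolved]
        e = min(e, length)
        first = s // grid.bin_size
        last = (e - 1) // grid.bin_size
        for b in range(first, last + 1):
            i = off + b
            ov = min(e, int(grid.end[i])) - max(s, int(grid.start[i]))
            if ov > 0:
                acc[i] += ov * val
                wsum[i] += ov
    out = np.full(grid.n_bins, np.nan)
    has = wsum > 0
    out[has] = acc[has] / wsum[has]
    return out


def annotate_bins(
    grid: BinGrid,
    blacklist: Sequence[tuple[str, int, int]] = (),
    gc_track: Iterable[tuple[str, int, int, float]] | None = None,
    mappability_track: Iterable[tuple[str, int, int, float]] | None = None,
    overlap_fraction_threshold: float = 0.5,
    min_mappability: float | None = None,
) -> BinGrid:
    """Annotate a grid with usability, GC and mappability.

    A bin becomes unusable when the merged blacklist covers at least
    ``overlap_fraction_threshold`` of it, or (when a mappability track and
    ``min_mappability`` are given) its mean mappability falls below the
    minimum.  Intervals on chromosomes absent from the grid are ignored with
    a warning.  Returns a new grid; the input is not modified.
    """
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in blacklist:
        if s >= e:
            raise ValueError(f"malformed blacklist interval {chrom}:{s}-{e}")
        resolved = grid.resolve_chrom(chrom)
        if resolved is None:
            warnings.warn(f"blacklist chromosome {chrom!r} not in grid; ignored")
            continue
        per_chrom.setdefault(resolved, []).append((int(s), int(e)))

    overlap = np.zeros(grid.n_bins)
    for chrom, ivals in per_chrom.items():
        off = grid.chrom_slice(chrom).start
        length = grid.chrom_lengths[chrom]
        for s, e in _merge_intervals(ivals):
            e = min(e, length)
            if s >= length:
                continue
            first = s // grid.bin_size
            last = (e - 1) // grid.bin_size
            for b in range(first, last + 1):
                i = off + b
                ov = min(e, int(grid.end[i])) - max(s, int(grid.start[i]))
                if ov > 0:
                    overlap[i] += ov

    widths = (grid.end - grid.start).astype(float)
    # unusable iff covered fraction >= threshold
    usable = overlap / widths < overlap_fraction_threshold

    gc = grid.gc.copy()
    mapp = grid.mappability.copy()
    if gc_track is not None:
        gc = _bin_weighted_mean(grid, gc_track)
    if mappability_track is not None:
        mapp = _bin_weighted_mean(grid, mappability_track)
    if min_mappability is not None:
        usable &= ~(mapp < min_mappability)

    return replace(grid, gc=gc, mappability=mapp, usable=usable)


def count_reads(
    alignments,
    grid: BinGrid,
    sample_id: str | None = None,
    min_mapq: int = 20,
    dedup: bool = True,
    paired_mode: str = "fragment",
) -> ReadCountProfile:
    """Count alignment records into bins by leftmost aligned position.

    ``alignments`` is a path to a SAM/BAM file or an open
    :class:`pysam.AlignmentFile`.  Secondary, supplementary and unmapped
    records are always excluded, duplicates when ``dedup`` is set, and records
    below ``min_mapq``.  In ``fragment`` mode a properly paired fragment is
    counted once, at its leftmost mate; in ``read`` mode every retained read
    counts.  Records on chromosomes absent from the grid are tallied as
    unassigned, not an error.
    """
    import pysam

    if paired_mode not in ("fragment", "read"):
        raise ValueError(f"unknown paired_mode {paired_mode!r}")

    own = False
    if not hasattr(alignments, "fetch"):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        own = True
    try:
        counts = np.zeros(grid.n_bins, dtype=np.int64)
        offsets = {c: grid.chrom_slice(c).start for c in grid.chrom_names}
        name_cache: dict[str, str | None] = {}
        retained = 0
        unassigned = 0
        for rec in alignments.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if dedup and rec.is_duplicate:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            if paired_mode == "fragment" and rec.is_paired and not rec.mate_is_unmapped:
                if rec.reference_id == rec.next_reference_id:
                    # count the leftmost mate only; ties go to read1
                    if rec.reference_start > rec.next_reference_start:
                        continue
                    if rec.reference_start == rec.next_reference_start and rec.is_read2:
                        continue
            refname = rec.reference_name
            if refname not in name_cache:
                name_cache[refname] = grid.resolve_chrom(refname)
            chrom = name_cache[refname]
            retained += 1
            if chrom is None:
                unassigned += 1
                continue
            pos = rec.reference_start
            if pos >= grid.chrom_lengths[chrom]:
                unassigned += 1
                continue
            counts[offsets[chrom] + pos // grid.bin_size] += 1
    finally:
        if own:
            alignments.close()

    if unassigned:
        warnings.warn(f"{unassigned} retained reads on chromosomes outside the grid")
    return ReadCountProfile(
        sample_id=sample_id or "sample",
        grid=grid,
        raw_counts=counts,
        total_mapped_reads=retained,
        unassigned_reads=unassigned,
        filter_settings={
            "min_mapq": min_mapq,
            "dedup": dedup,
            "paired_mode": paired_mode,
        },
    )


def sigma_delta(log2_ratio: np.ndarray) -> float:
    """First-difference noise variance: var(diff(non-missing log2)) / 2."""
    x = log2_ratio[~np.isnan(log2_ratio)]
    if len(x) < 3:
        return float("nan")
    return float(np.var(np.diff(x), ddof=1) / 2.0)


def _lowess_correct(values: np.ndarray, covariate: np.ndarray, frac: float) -> np.ndarray:
    """Divide values by a lowess fit against the covariate (NaN-safe)."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    out = values.copy()
    ok = ~np.isnan(values) & ~np.isnan(covariate)
    if ok.sum() < 10:
        warnings.warn("too few annotated bins for smooth correction; skipped")
        return out
    fitted = lowess(
        values[ok], covariate[ok], frac=frac, return_sorted=False
    )
    fitted = np.where(fitted > 0, fitted, np.nan)
    out[ok] = values[ok] / fitted
    return out


def normalize_profile(
    counts: ReadCountProfile,
    grid: BinGrid | None = None,
    do_gc: bool = False,
    do_mappability: bool = False,
    lowess_frac: float = 0.65,
    min_usable_bins: int = 100,
) -> NormalizedProfile:
    """Convert raw counts to median-centred log2 ratios.

    Usable zero-count bins become missing and are tallied as empty bins.
    With ``do_gc`` (``do_mappability``), counts are divided by a locally
    weighted regression fit against the bin's GC fraction (mappability)
    before scaling.  Ratios are scaled to median 1, log2-transformed and
    re-centred so the median log2 ratio is exactly 0.
    """
    grid = grid or counts.grid
    if do_gc and np.isnan(grid.gc).all():
        raise ValueError("GC correction requested but grid has no GC annotation")
    if do_mappability and np.isnan(grid.mappability).all():
        raise ValueError("mappability correction requested but grid lacks the track")

    vals = counts.raw_counts.astype(float)
    vals[~grid.usable] = np.nan
    empty = grid.usable & (counts.raw_counts == 0)
    vals[empty] = np.nan
    empty_bin_count = int(empty.sum())

    if do_gc:
        vals = _lowess_correct(vals, grid.gc, lowess_frac)
    if do_mappability:
        vals = _lowess_correct(vals, grid.mappability, lowess_frac)

    ok = ~np.isnan(vals)
    usable_profile = True
    if ok.sum() < min_usable_bins:
        warnings.warn(
            f"{counts.sample_id}: only {int(ok.sum())} non-missing usable bins "
            f"(< {min_usable_bins}); profile flagged unusable"
        )
        usable_profile = False

    log2r = np.full(grid.n_bins, np.nan)
    if ok.any():
        med = np.median(vals[ok])
        if med > 0:
            log2r[ok] = np.log2(vals[ok] / med)
            log2r[ok] -= np.median(log2r[ok])
        else:
            usable_profile = False

    return NormalizedProfile(
        sample_id=counts.sample_id,
        grid=grid,
        log2_ratio=log2r,
        sigma_delta=sigma_delta(log2r),
        empty_bin_count=empty_bin_count,
        gc_corrected=do_gc,
        mappability_corrected=do_mappability,
        usable_profile=usable_profile,
    )
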