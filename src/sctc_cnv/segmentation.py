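"""Circular binary segmentation of corrected log2-ratio profiles.

Per chromosome, the maximal circular two-sample statistic over all arcs
(i, j) of the bin sequence is found; the split is accepted when its
permutation p-value falls below ``alpha``, and the procedure recurses into
the resulting pieces.  Short segments are suppressed by a minimum segment
width, and marginal splits are merged back by the undo-splits rule:
adjacent segments whose mean difference is below ``undo_sd`` robust noise
units are collapsed.

Missing bins are skipped: the statistic runs on the compacted sequence of
non-missing values and breakpoints are mapped back to genome coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome_bins import NormalizedProfile

__all__ = ["Segment", "SegmentedProfile", "segment_profile", "undo_splits", "robust_sigma"]


@dataclass
class Segment:
    """One mean-constant run of non-missing bins on a chromosome."""

    chrom: str
    first_bin: int   # global bin index of first member (inclusive)
    last_bin: int    # global bin index of last member (inclusive)
    n_bins: int      # number of non-missing member bins
    mean_log2: float


@dataclass
class SegmentedProfile:
    """A profile partitioned into mean-constant segments."""

    sample_id: str
    grid: object
    segments: list[Segment]
    segment_id: np.ndarray   # per-bin segment index, -1 where missing
    settings: dict = field(default_factory=dict)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def means_per_bin(self) -> np.ndarray:
        """Per-bin segment mean (NaN where missing)."""
        out = np.full(len(self.segment_id), np.nan)
        for sid, seg in enumerate(self.segments):
            out[self.segment_id == sid] = seg.mean_log2
        return out


def robust_sigma(profile: NormalizedProfile) -> float:
    """Robust per-sample noise scale from successive bin differences.

    MAD of the first differences of non-missing log2 ratios, divided by
    sqrt(2) (a difference of two independent values) and scaled by 1.4826
    for Gaussian consistency.
    """
    x = profile.values
    if len(x) < 3:
        return 0.0
    d = np.diff(x)
    return float(np.median(np.abs(d - np.median(d))) / np.sqrt(2.0) * 1.4826)


def _max_arc_stat(x: np.ndarray, min_width: int, want_argmax: bool = True):
    """Maximal circular split statistic over valid arcs of ``x``.

    Arcs (i, j) must produce only pieces of length >= min_width (zero-length
    flanks allowed).  Returns (stat, i, j); ties broken by smallest (i, j).
    """
    n = len(x)
    S = np.concatenate(([0.0], np.cumsum(x)))
    mu = S[-1] / n
    best_t, best_i, best_j = -np.inf, -1, -1
    for k in range(min_width, n - min_width + 1):
        arc = S[k:] - S[:-k]
        i_idx = np.arange(n - k + 1)
        valid = ((i_idx == 0) | (i_idx >= min_width)) & (
            (i_idx + k == n) | (i_idx + k <= n - min_width)
        )
        if not valid.any():
            continue
        t = np.abs(arc - k * mu) / np.sqrt(k * (n - k) / n)
        t[~valid] = -np.inf
        pos = int(np.argmax(t))  # argmax returns the first (smallest i)
        tk = float(t[pos])
        if tk > best_t or (
            tk == best_t and (pos, pos + k) < (best_i, best_j)
        ):
            best_t, best_i, best_j = tk, pos, pos + k
    if not want_argmax:
        return best_t
    return best_t, best_i, best_j


def _perm_pvalue(
    x: np.ndarray,
    t_obs: float,
    min_width: int,
    n_permutations: int,
    alpha: float,
    rng: np.random.Generator,
) -> float:
    """Permutation p-value of the observed split statistic.

    Stops early once the exceedance count guarantees p > alpha (the split
    will be rejected regardless of the remaining permutations).
    """
    cutoff = alpha * (n_permutations + 1) - 1
    exceed = 0
    for b in range(n_permutations):
        xp = rng.permutation(x)
        if _max_arc_stat(xp, min_width, want_argmax=False) >= t_obs:
            exceed += 1
            if exceed > cutoff:
                return (exceed + 1) / (b + 2)
    return (exceed + 1) / (n_permutations + 1)


def _segment_recursive(
    x: np.ndarray,
    lo: int,
    hi: int,
    min_width: int,
    alpha: float,
    n_permutations: int,
    rng: np.random.Generator,
    breaks: list[int],
) -> None:
    n = hi - lo
    if n < 2 * min_width:
        return
    t_obs, i, j = _max_arc_stat(x[lo:hi], min_width)
    if not np.isfinite(t_obs):
        return
    p = _perm_pvalue(x[lo:hi], t_obs, min_width, n_permutations, alpha, rng)
    if p >= alpha:
        return
    cuts = sorted({c for c in (i, j) if 0 < c < n})
    if not cuts:
        return
    bounds = [lo] + [lo + c for c in cuts] + [hi]
    for a, b in zip(bounds[:-1], bounds[1:]):
        breaks.append(b)
        _segment_recursive(x, a, b, min_width, alpha, n_permutations, rng, breaks)


def segment_profile(
    profile: NormalizedProfile,
    alpha: float = 0.01,
    n_permutations: int = 1000,
    undo_sd: float = 4.0,
    min_width: int = 10,
    seed: int = 0,
) -> SegmentedProfile:
    """Segment a log2-ratio profile chromosome by chromosome.

    Splits are accepted at permutation p-value < ``alpha``; afterwards the
    undo-splits rule with multiplier ``undo_sd`` merges marginal neighbours.
    Chromosomes with fewer than ``min_width`` non-missing bins become a
    single segment with a warning.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    grid = profile.grid
    segments: list[Segment] = []
    seg_id = np.full(grid.n_bins, -1, dtype=np.int64)

    for chrom in grid.chrom_names:
        sl = grid.chrom_slice(chrom)
        idx = np.flatnonzero(~np.isnan(profile.log2_ratio[sl.start : sl.stop])) + sl.start
        if idx.size == 0:
            continue
        if idx.size < min_width:
            warnings.warn(
                f"{profile.sample_id}: chromosome {chrom} has {idx.size} "
                f"non-missing bins (< {min_width}); single segment"
            )
        x = profile.log2_ratio[idx]
        breaks: list[int] = []
        _segment_recursive(x, 0, len(x), min_width, alpha, n_permutations, rng, breaks)
        bounds = sorted(set(breaks) - {len(x)}) + [len(x)]
        start = 0
        for b in bounds:
            members = idx[start:b]
            sid = len(segments)
            segments.append(
                Segment(
                    chrom=chrom,
                    first_bin=int(members[0]),
                    last_bin=int(members[-1]),
                    n_bins=len(members),
                    mean_log2=float(np.mean(profile.log2_ratio[members])),
                )
            )
            seg_id[members] = sid
            start = b

    result = SegmentedProfile(
        sample_id=profile.sample_id,
        grid=grid,
        segments=segments,
        segment_id=seg_id,
        settings={
            "alpha": alpha,
            "n_permutations": n_permutations,
            "undo_sd": undo_sd,
            "min_width": min_width,
            "seed": seed,
        },
    )
    if undo_sd is not None and undo_sd > 0:
        result = undo_splits(result, profile, undo_sd)
    return result


def undo_splits(
    segmented: SegmentedProfile,
    profile: NormalizedProfile,
    undo_sd: float,
) -> SegmentedProfile:
    """Merge adjacent segments whose mean difference is below the noise gate.

    Within each chromosome, an adjacent pair is merged while

        |mean_a - mean_b|  <  undo_sd * sigma * sqrt(1/n_a + 1/n_b)

    where sigma is the robust per-sample noise scale — i.e. the mean
    difference is compared in standard-error units of the two segment
    means, so a marginal split between two long segments must clear a much
    lower absolute bar than one between short, noisy segments.  The pair
    with the smallest standardised difference is merged first; means are
    recomputed on merge and the pass repeats until stable.
    """
    sigma = robust_sigma(profile)
    # regroup per chromosome preserving order
    by_chrom: dict[str, list[Segment]] = {}
    for seg in segmented.segments:
        by_chrom.setdefault(seg.chrom, []).append(
            Segment(**seg.__dict__)
        )

    def seg_members(seg: Segment) -> np.ndarray:
        span = np.arange(seg.first_bin, seg.last_bin + 1)
        return span[~np.isnan(profile.log2_ratio[span])]

    for chrom, segs in by_chrom.items():
        changed = True
        while changed and len(segs) > 1:
            zdiffs = [
                abs(segs[i + 1].mean_log2 - segs[i].mean_log2)
                / np.sqrt(1.0 / segs[i].n_bins + 1.0 / segs[i + 1].n_bins)
                for i in range(len(segs) - 1)
            ]
            i = int(np.argmin(zdiffs))
            if zdiffs[i] < undo_sd * sigma:
                a, b = segs[i], segs[i + 1]
                members = np.concatenate([seg_members(a), seg_members(b)])
                segs[i] = Segment(
                    chrom=chrom,
                    first_bin=a.first_bin,
                    last_bin=b.last_bin,
                    n_bins=a.n_bins + b.n_bins,
                    mean_log2=float(np.mean(profile.log2_ratio[members])),
                )
                del segs[i + 1]
            else:
                changed = False

    segments: list[Segment] = []
    seg_id = np.full(segmented.grid.n_bins, -1, dtype=np.int64)
    for chrom in segmented.grid.chrom_names:
        for seg in by_chrom.get(chrom, []):
            sid = len(segments)
            segments.append(seg)
            seg_id[seg_members(seg)] = sid
    return SegmentedProfile(
        sample_id=segmented.sample_id,
        grid=segmented.grid,
        segments=segments,
        segment_id=seg_id,
        settings={**segmented.settings, "undo_sd": undo_sd},
    )
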