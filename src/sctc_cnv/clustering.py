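"""Condensed-segment clustering of called CN profiles.

Across a sample set, maximal runs of consecutive bins over which *every*
sample's hard call is constant are collapsed into single regions, weighted
by the number of member bins.  Samples are then compared by weighted call
concordance — soft (posterior products) by default, hard (Hamming on calls)
as an option — and clustered agglomeratively.  A region-level query
aggregates calls over a named locus (e.g. an amplified oncogene).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .calling import CalledProfile

__all__ = [
    "RegionMatrix",
    "condense_calls",
    "cluster_samples",
    "query_region",
    "linkage_to_newick",
]

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


@dataclass
class RegionMatrix:
    """Maximal constant-call regions across a sample set."""

    chrom: np.ndarray        # per region
    first_bin: np.ndarray    # global bin index, inclusive
    last_bin: np.ndarray
    weights: np.ndarray      # member-bin count per region
    calls: np.ndarray        # (n_regions, n_samples) int8
    posteriors: np.ndarray   # (n_regions, n_samples, n_states) bin-averaged
    sample_ids: list[str]
    states: tuple
    bin_index: list[np.ndarray] = field(default_factory=list)  # member bins per region

    @property
    def n_regions(self) -> int:
        return len(self.weights)

    def expand_to_bins(self) -> tuple[np.ndarray, np.ndarray]:
        """(bin indices, calls matrix) reconstructing the per-bin hard calls."""
        bins = np.concatenate(self.bin_index)
        calls = np.concatenate(
            [np.tile(self.calls[r], (len(self.bin_index[r]), 1)) for r in range(self.n_regions)]
        )
        return bins, calls


def condense_calls(profiles: list[CalledProfile]) -> RegionMatrix:
    """Collapse consecutive bins with identical calls in every sample.

    Runs break at chromosome boundaries and wherever any sample's hard call
    changes; only bins called in *all* samples participate.  Region
    posteriors are the means over member bins.
    """
    if not profiles:
        raise ValueError("no profiles")
    grid = profiles[0].grid
    states = profiles[0].states
    common = np.logical_and.reduce([p.called for p in profiles])
    if not common.any():
        raise ValueError("no bin is called in every sample")
    idx = np.flatnonzero(common)
    calls = np.column_stack([p.call[idx] for p in profiles])   # (n_common, n_samples)
    chroms = grid.chrom[idx]

    # start a new region where the chromosome or any sample's call changes,
    # or at a gap of not-jointly-called bins (regions stay contiguous)
    new = np.ones(len(idx), dtype=bool)
    if len(idx) > 1:
        same_chrom = chroms[1:] == chroms[:-1]
        same_calls = (calls[1:] == calls[:-1]).all(axis=1)
        adjacent = np.diff(idx) == 1
        new[1:] = ~(same_chrom & same_calls & adjacent)
    region_of = np.cumsum(new) - 1
    n_regions = region_of[-1] + 1

    first, last, weights, bin_lists = [], [], [], []
    reg_calls = np.empty((n_regions, len(profiles)), dtype=np.int8)
    reg_post = np.empty((n_regions, len(profiles), len(states)))
    reg_chrom = []
    for r in range(n_regions):
        members = idx[region_of == r]
        first.append(members[0])
        last.append(members[-1])
        weights.append(len(members))
        bin_lists.append(members)
        reg_chrom.append(grid.chrom[members[0]])
        for s, p in enumerate(profiles):
            reg_calls[r, s] = p.call[members[0]]
            reg_post[r, s] = np.nanmean(p.posteriors[members], axis=0)
    return RegionMatrix(
        chrom=np.array(reg_chrom),
        first_bin=np.array(first),
        last_bin=np.array(last),
        weights=np.array(weights, dtype=float),
        calls=reg_calls,
        posteriors=reg_post,
        sample_ids=[p.sample_id for p in profiles],
        states=states,
        bin_index=bin_lists,
    )


def _soft_distance(matrix: RegionMatrix, rows: np.ndarray) -> np.ndarray:
    """1 - weighted mean posterior concordance, pairwise."""
    w = matrix.weights[rows]
    P = matrix.posteriors[rows]                    # (R, S, K)
    n = len(matrix.sample_ids)
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            conc = (P[:, a, :] * P[:, b, :]).sum(axis=1)
            D[a, b] = D[b, a] = 1.0 - float((w * conc).sum() / w.sum())
    return D


def _hard_distance(matrix: RegionMatrix, rows: np.ndarray) -> np.ndarray:
    w = matrix.weights[rows]
    C = matrix.calls[rows]
    n = len(matrix.sample_ids)
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            mismatch = (C[:, a] != C[:, b]).astype(float)
            D[a, b] = D[b, a] = float((w * mismatch).sum() / w.sum())
    return D


def cluster_samples(
    matrix: RegionMatrix,
    linkage: str = "average",
    distance: str = "soft",
    exclude_sex: bool = True,
):
    """Agglomerative clustering of samples on weighted call concordance.

    Returns ``(distance_matrix, linkage_matrix, leaf_order)``.  The soft
    distance is 1 minus the region-weighted sum of per-state posterior
    products; the hard distance is the weighted Hamming distance on calls.
    Both are bounded in [0, 1].  Deterministic leaf order; with a single
    sample a degenerate result is returned with a warning.
    """
    rows = np.arange(matrix.n_regions)
    if exclude_sex:
        keep = ~np.isin(matrix.chrom, list(SEX_CHROMS))
        if keep.any():
            rows = rows[keep]
    if distance == "soft":
        D = _soft_distance(matrix, rows)
    elif distance == "hard":
        D = _hard_distance(matrix, rows)
    else:
        raise ValueError(f"unknown distance {distance!r}")

    n = len(matrix.sample_ids)
    if n < 2:
        warnings.warn("single sample: degenerate dendrogram")
        return D, np.empty((0, 4)), [0]
    Z = hierarchy.linkage(squareform(D, checks=False), method=linkage)
    order = hierarchy.leaves_list(Z).tolist()
    return D, Z, order


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height):
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    if tree.is_leaf():
        return f"{labels[tree.id]};"
    left = walk(tree.left, tree.dist)
    right = walk(tree.right, tree.dist)
    return f"({left},{right});"


def _parse_interval(interval) -> tuple[str, int, int]:
    if isinstance(interval, (tuple, list)):
        chrom, start, end = interval
        return str(chrom), int(start), int(end)
    chrom, _, rest = str(interval).partition(":")
    start, _, end = rest.partition("-")
    return chrom, int(start.replace(",", "")), int(end.replace(",", ""))


def query_region(
    profiles: list[CalledProfile],
    grid,
    interval,
    aggregation: str = "any_amp_then_majority",
) -> dict[str, dict]:
    """Aggregate calls over a genomic interval, per sample.

    Default rule: amplification if any overlapped bin is amplified,
    otherwise the majority call with ties resolved toward the higher state.
    Samples with no called bin in the interval get a ``no-resolution``
    verdict (``call`` is None).
    """
    if aggregation != "any_amp_then_majority":
        raise ValueError(f"unknown aggregation {aggregation!r}")
    chrom, start, end = _parse_interval(interval)
    resolved = grid.resolve_chrom(chrom)
    if resolved is None:
        raise ValueError(f"chromosome {chrom!r} not in grid")
    sl = grid.chrom_slice(resolved)
    sel = (
        (np.arange(grid.n_bins) >= sl.start)
        & (np.arange(grid.n_bins) < sl.stop)
        & (grid.start < end)
        & (grid.end > start)
    )
    if not sel.any():
        raise ValueError(f"interval {chrom}:{start}-{end} overlaps no bin")

    out = {}
    for p in profiles:
        bins = np.flatnonzero(sel & p.called)
        if bins.size == 0:
            out[p.sample_id] = {"call": None, "n_bins": 0, "verdict": "no-resolution"}
            continue
        calls = p.call[bins]
        if (calls == 2).any():
            agg = 2
        else:
            values, counts = np.unique(calls, return_counts=True)
            agg = int(values[counts == counts.max()].max())  # ties -> higher state
        out[p.sample_id] = {"call": agg, "n_bins": int(bins.size), "verdict": "ok"}
    return out
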