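"""Quality control for single-cell WGA products and sequencing libraries.

Covers the full QC layer of the pipeline: multiplex-PCR band scores and the
pass gate (score >= 5), the arm-level read-distribution ratio statistic with
leave-one-out panel normalization and the uniformity verdict that flags
collapsed WGA reactions, the MAD noise metric, empty-bin outlier rejection,
subsampling-based minimum-depth determination, and the paired Wilcoxon
signed-rank test used for method comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats as _stats

from .genome_bins import NormalizedProfile, ReadCountProfile, normalize_profile
from .genomes import DEFAULT_EXCLUDED_ARMS

__all__ = [
    "QCRecord",
    "ArmRatioProfile",
    "DepthRecommendation",
    "qc_score",
    "arm_ratios",
    "wga_uniformity_flag",
    "profile_mad",
    "empty_bin_flag",
    "binomial_thin",
    "determine_min_depth",
    "paired_wilcoxon",
]

#: Informative multiplex bands per QC method.  The modified multiplex yields
#: up to 7 bands on WGA product (the 8th amplicon spans a restriction site and
#: appears in undigested genomic DNA only); the 4-amplicon kit yields up to 4.
BAND_COUNTS = {"modified_vycap": 7, "ampli1": 4}
GENOMIC_BAND_COUNT = 8


@dataclass
class QCRecord:
    sample_id: str
    method: str
    band_present: tuple
    score: int
    pass_threshold: int
    passed: bool


@dataclass
class ArmRatioProfile:
    """Per-arm read fractions and panel-normalized distribution ratios."""

    sample_id: str
    arms: list[str]
    counts: np.ndarray
    fractions: np.ndarray           # over all arms; sums to 1
    retained_arms: list[str]
    ratios: dict                    # retained arm -> ratio (NaN if undefined)
    excluded_arms: frozenset
    metrics: dict = field(default_factory=dict)
    verdict: str | None = None


@dataclass
class DepthRecommendation:
    depths: tuple
    iterations: int
    correlations: dict              # depth -> list of Spearman r
    threshold: float
    recommended: float | None       # smallest depth with mean r >= threshold

    @property
    def mean_correlations(self) -> dict:
        return {d: float(np.mean(v)) for d, v in self.correlations.items() if v}


def qc_score(
    bands: Sequence[bool],
    method: str = "modified_vycap",
    pass_threshold: int = 5,
    sample_id: str = "sample",
    genomic: bool = False,
) -> QCRecord:
    """Score a multiplex-PCR QC by counting present bands.

    ``genomic`` permits the 8-band readout attainable on undigested genomic
    DNA with the modified multiplex; WGA products max out at 7 (4 for the
    four-amplicon kit).  Pass iff score >= ``pass_threshold``.
    """
    if method not in BAND_COUNTS:
        raise ValueError(f"unknown QC method {method!r}")
    expected = (
        GENOMIC_BAND_COUNT if (genomic and method == "modified_vycap")
        else BAND_COUNTS[method]
    )
    if len(bands) != expected:
        raise ValueError(
            f"{method} expects {expected} band flags, got {len(bands)}"
        )
    score = int(sum(bool(b) for b in bands))
    return QCRecord(
        sample_id=sample_id,
        method=method,
        band_present=tuple(bool(b) for b in bands),
        score=score,
        pass_threshold=pass_threshold,
        passed=score >= pass_threshold,
    )


def _fractions(counts: Mapping[str, float], arms: list[str]) -> np.ndarray:
    vec = np.array([float(counts.get(a, 0.0)) for a in arms])
    total = vec.sum()
    if total <= 0:
        raise ValueError("sample has no arm reads")
    return vec / total


def arm_ratios(
    sample: Mapping[str, float],
    panel: Sequence[Mapping[str, float]],
    excluded_arms: frozenset = DEFAULT_EXCLUDED_ARMS,
    leave_out_index: int | None = None,
    sample_id: str = "sample",
) -> ArmRatioProfile:
    """Arm-level distribution ratios of a sample against a reference panel.

    Per-arm read fractions (count / total, over *all* arms) are divided by
    the panel's mean fraction for that arm.  When the sample is itself a
    panel member, pass its ``leave_out_index`` so the panel mean excludes
    it.  Excluded arms are dropped from the ratios and downstream metrics;
    a zero panel mean on a retained arm yields a missing ratio with a
    warning.
    """
    if len(panel) < 2:
        raise ValueError("reference panel needs at least 2 members")
    arms = sorted(set(sample) | {a for m in panel for a in m})
    frac = _fractions(sample, arms)
    panel_fracs = np.vstack([_fractions(m, arms) for m in panel])
    if leave_out_index is not None:
        if not 0 <= leave_out_index < len(panel):
            raise IndexError("leave_out_index outside the panel")
        panel_fracs = np.delete(panel_fracs, leave_out_index, axis=0)
    panel_mean = panel_fracs.mean(axis=0)

    retained = [a for a in arms if a not in excluded_arms]
    ratios: dict[str, float] = {}
    for a in retained:
        i = arms.index(a)
        if panel_mean[i] <= 0:
            warnings.warn(f"panel mean fraction is 0 for arm {a}; ratio undefined")
            ratios[a] = float("nan")
        else:
            ratios[a] = float(frac[i] / panel_mean[i])
    return ArmRatioProfile(
        sample_id=sample_id,
        arms=arms,
        counts=np.array([float(sample.get(a, 0.0)) for a in arms]),
        fractions=frac,
        retained_arms=retained,
        ratios=ratios,
        excluded_arms=frozenset(excluded_arms),
    )


def wga_uniformity_flag(
    arms: ArmRatioProfile,
    low_cut: float = 0.1,
    low_fraction_max: float = 0.5,
    topk: int = 3,
    topk_share_max: float = 0.5,
) -> str:
    """Pass/fail verdict on read-distribution uniformity.

    A collapsed WGA reaction concentrates nearly all reads on a few
    chromosome arms while others receive almost none.  Fail iff the
    fraction of retained arms with distribution ratio < ``low_cut``
    exceeds ``low_fraction_max``, or the top-``topk`` retained arms hold
    more than ``topk_share_max`` of the retained reads (both strict
    inequalities, so exactly-at-threshold passes).
    """
    vals = np.array([arms.ratios[a] for a in arms.retained_arms])
    ok = ~np.isnan(vals)
    if not ok.any():
        raise ValueError("no defined distribution ratios")
    low_fraction = float((vals[ok] < low_cut).mean())

    idx = [arms.arms.index(a) for a in arms.retained_arms]
    retained_frac = arms.fractions[idx]
    total = retained_frac.sum()
    top_share = float(np.sort(retained_frac)[::-1][:topk].sum() / total) if total > 0 else 1.0

    verdict = (
        "fail"
        if (low_fraction > low_fraction_max or top_share > topk_share_max)
        else "pass"
    )
    arms.metrics.update(
        low_ratio_fraction=low_fraction, topk_read_share=top_share,
        low_cut=low_cut, topk=topk,
    )
    arms.verdict = verdict
    return verdict


def profile_mad(profile: NormalizedProfile, scope: str = "genome") -> float:
    """Median absolute deviation of log2 ratios, genome-wide or per chromosome.

    Plain MAD — median(|x - median(x)|) — with no Gaussian consistency
    constant, over non-missing bins in scope.
    """
    x = profile.log2_ratio
    if scope != "genome":
        resolved = profile.grid.resolve_chrom(scope)
        if resolved is None:
            raise ValueError(f"chromosome {scope!r} not in grid")
        sl = profile.grid.chrom_slice(resolved)
        x = x[sl]
    x = x[~np.isnan(x)]
    if len(x) < 10:
        raise ValueError(f"fewer than 10 non-missing bins in scope {scope!r}")
    return float(np.median(np.abs(x - np.median(x))))


def empty_bin_flag(
    profiles: Sequence[NormalizedProfile],
    max_empty_fraction: float | None = None,
    relative_multiple: float = 3.0,
) -> dict[str, bool]:
    """Flag samples with an outlying number of empty bins.

    Absolute mode (``max_empty_fraction`` given): flag when the empty-bin
    fraction exceeds the cutoff.  Relative mode (default): flag when it
    exceeds ``relative_multiple`` times the cohort median.  A single-sample
    cohort in relative mode is never flagged (no reference) and warns.
    """
    if not profiles:
        raise ValueError("no profiles")
    fracs = {}
    for p in profiles:
        usable = int(p.grid.usable.sum())
        fracs[p.sample_id] = p.empty_bin_count / usable if usable else 0.0
    if max_empty_fraction is not None:
        return {s: f > max_empty_fraction for s, f in fracs.items()}
    if len(profiles) < 2:
        warnings.warn("single-sample cohort: relative empty-bin flag has no reference")
        return {p.sample_id: False for p in profiles}
    med = float(np.median(list(fracs.values())))
    return {s: f > relative_multiple * med for s, f in fracs.items()}


def binomial_thin(
    counts: ReadCountProfile, probability: float, rng: np.random.Generator
) -> ReadCountProfile:
    """Thin each bin count binomially with the given retention probability."""
    if not 0 < probability <= 1:
        raise ValueError("retention probability must be in (0, 1]")
    if probability == 1.0:
        thinned = counts.raw_counts.copy()
    else:
        thinned = rng.binomial(counts.raw_counts, probability)
    return ReadCountProfile(
        sample_id=counts.sample_id,
        grid=counts.grid,
        raw_counts=thinned.astype(np.int64),
        total_mapped_reads=int(thinned.sum()),
        filter_settings={**counts.filter_settings, "thinned_p": probability},
    )


def determine_min_depth(
    counts: ReadCountProfile,
    depths: Sequence[float] = (0.5e6, 1e6, 2.5e6, 5e6),
    iterations: int = 10,
    seed: int = 0,
    threshold: float = 0.9,
    pipeline: Callable[[ReadCountProfile], NormalizedProfile] | None = None,
) -> DepthRecommendation:
    """Find the smallest sequencing depth that reproduces the full profile.

    Bin counts are binomially thinned to each target depth for ``iterations``
    replicates; each thinned profile is pushed through ``pipeline`` (default:
    normalization alone; supply a closure to add dewaving/segmentation) and
    its log2 ratios are Spearman-correlated with the full-depth profile over
    jointly non-missing bins.  The recommendation is the smallest depth whose
    mean correlation reaches ``threshold``, or None when all fall short.
    """
    pipeline = pipeline or normalize_profile
    total = counts.total_mapped_reads or int(counts.raw_counts.sum())
    if max(depths) > total:
        raise ValueError(
            f"largest depth ({max(depths):g}) exceeds total reads ({total})"
        )
    rng = np.random.default_rng(seed)
    full = pipeline(counts)
    full_ok = ~np.isnan(full.log2_ratio)

    corr: dict[float, list[float]] = {}
    for depth in sorted(depths):
        if depth > total:
            warnings.warn(f"depth {depth:g} exceeds total reads; skipped")
            continue
        corr[depth] = []
        p = depth / total
        for _ in range(iterations):
            sub = pipeline(binomial_thin(counts, p, rng))
            ok = full_ok & ~np.isnan(sub.log2_ratio)
            r = _stats.spearmanr(
                full.log2_ratio[ok], sub.log2_ratio[ok]
            ).statistic
            corr[depth].append(float(r))

    recommended = None
    for depth in sorted(corr):
        if corr[depth] and float(np.mean(corr[depth])) >= threshold:
            recommended = depth
            break
    return DepthRecommendation(
        depths=tuple(sorted(depths)),
        iterations=iterations,
        correlations=corr,
        threshold=threshold,
        recommended=recommended,
    )


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p for the signed-rank statistic.

    The null distribution of W+ over all 2^n sign assignments of the
    (mid)ranks is built by subset-sum dynamic programming.  Midranks of
    tied groups are half-integers, so ranks are doubled to keep the DP on
    an integer lattice; the sign-flip distribution is symmetric around
    n(n+1)/4 with or without ties.
    """
    doubled = np.rint(2.0 * ranks).astype(np.int64)
    max_w = int(doubled.sum())
    counts = np.zeros(max_w + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        counts[r:] = counts[r:] + counts[: max_w + 1 - r]
    w2 = int(np.rint(2.0 * w_plus))
    w_min = min(w2, max_w - w2)
    p = 2.0 * counts[: w_min + 1].sum() / 2.0 ** len(ranks)
    return float(min(p, 1.0))


def paired_wilcoxon(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Incomplete pairs (NaN on either side) and zero differences are dropped.
    For n <= 25 nonzero differences the exact sign-flip distribution of the
    signed-rank statistic is used (midranks, so tied |differences| are
    handled exactly); for larger n a normal approximation with continuity
    correction and tie-corrected variance.  At least 5 complete pairs are
    required; all-zero differences give p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 5:
        raise ValueError(f"only {int(ok.sum())} complete pairs (minimum 5)")
    d = x[ok] - y[ok]
    d = d[d != 0]
    if len(d) == 0:
        warnings.warn("all paired differences are zero")
        return 1.0
    n = len(d)
    absd = np.abs(d)
    # midranks with tolerance-grouping so ties are recognised despite float
    # rounding in the differences
    order = np.argsort(absd)
    sorted_abs = absd[order]
    group = np.zeros(n, dtype=int)
    for i in range(1, n):
        gap = sorted_abs[i] - sorted_abs[i - 1]
        same = gap <= max(1e-12, 1e-9 * sorted_abs[i])
        group[i] = group[i - 1] + (0 if same else 1)
    ranks = np.empty(n)
    pos = np.arange(1, n + 1, dtype=float)
    for g in range(group[-1] + 1):
        sel = group == g
        ranks[order[sel]] = pos[sel].mean()
    w_plus = float(ranks[d > 0].sum())
    tie_counts = np.bincount(group)

    if n <= 25:
        return _exact_signed_rank_p(w_plus, ranks)

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float(
        ((tie_counts ** 3 - tie_counts).sum()) / 48.0
    )
    if var <= 0:
        warnings.warn("degenerate variance in signed-rank approximation")
        return 1.0
    z = (abs(w_plus - mean) - 0.5) / np.sqrt(var)
    return float(min(2.0 * _stats.norm.sf(z), 1.0))
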