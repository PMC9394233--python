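"""Discrete copy-number calling from segment means.

Each segment mean is modelled as a Gaussian around the expected log2 ratio
of an integral copy-number state (loss = 1 copy, neutral = 2, gain = 3,
amplification = 4 and above), with the per-segment standard deviation
shrinking as sigma / sqrt(n_bins).  Long segments (>= ``long_threshold``
bins) are trusted further: their standard deviation is divided by
``rel_sd_long``.  State mixing proportions are fitted by EM with the state
centers held fixed; per-segment posteriors are broadcast to member bins.

Under cellularity c the expected center of a state with cn copies is
log2((c * cn + (1 - c) * 2) / 2): an admixture of tumour signal and diploid
background.  For a pure single tumour cell c = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome_bins import NormalizedProfile
from .genomes import SEX_CHROMOSOMES
from .segmentation import SegmentedProfile, robust_sigma

__all__ = [
    "CalledProfile",
    "expected_center",
    "call_profile",
    "call_profiles",
    "STATE_CODES",
    "STATE_LABELS",
]

# state code -> copies (autosomal baseline of 2)
STATE_CNS_4 = {-1: 1, 0: 2, 1: 3, 2: 4}
STATE_CNS_5 = {-2: 0, -1: 1, 0: 2, 1: 3, 2: 4}
STATE_LABELS = {-2: "double_loss", -1: "loss", 0: "neutral", 1: "gain", 2: "amplification"}
STATE_CODES = tuple(STATE_CNS_4)

#: Default EM starting proportions for (loss, neutral, gain, amplification).
EM_INIT_4 = (0.10, 0.70, 0.15, 0.05)
EM_INIT_5 = (0.02, 0.10, 0.68, 0.15, 0.05)
#: The amplification state absorbs arbitrarily high amplitudes through a
#: right-broadened standard deviation.
AMP_SD_FACTOR = 2.0
MIN_RATIO_FLOOR = np.log2(0.05)


@dataclass
class CalledProfile:
    """Per-bin discrete CN calls with per-state posteriors."""

    sample_id: str
    grid: object
    call: np.ndarray        # int8 per bin; only meaningful where `called`
    posteriors: np.ndarray  # (n_bins, n_states), rows sum to 1 where called
    called: np.ndarray      # bool per bin
    states: tuple           # state codes, ascending
    settings: dict = field(default_factory=dict)

    @property
    def state_index(self) -> dict:
        return {s: i for i, s in enumerate(self.states)}


def expected_center(cn: int, cellularity: float = 1.0) -> float:
    """Expected log2 ratio of an integral CN state under admixture.

    log2((cellularity * cn + (1 - cellularity) * 2) / 2), floored at
    log2(0.05) so a homozygous loss stays finite.
    """
    if cellularity <= 0 or cellularity > 1:
        raise ValueError(f"cellularity must be in (0, 1], got {cellularity}")
    if cn < 0:
        raise ValueError(f"copy number must be non-negative, got {cn}")
    mix = (cellularity * cn + (1 - cellularity) * 2) / 2.0
    if mix <= 2 ** MIN_RATIO_FLOOR:
        return float(MIN_RATIO_FLOOR)
    return float(np.log2(mix))


def _state_table(n_states: int, cellularity: float, cn_shift: int = 0):
    cns = STATE_CNS_5 if n_states == 5 else STATE_CNS_4
    codes = tuple(sorted(cns))
    centers = np.array(
        [expected_center(max(cns[c] + cn_shift, 0), cellularity) for c in codes]
    )
    sd_factor = np.array([AMP_SD_FACTOR if c == 2 else 1.0 for c in codes])
    return codes, centers, sd_factor


def _segment_observations(
    segmented: SegmentedProfile,
    profile: NormalizedProfile,
    rel_sd_long: float,
    long_threshold: int,
    male_x: bool,
):
    """Per-segment (mean, sd, weight, cn_shift, keep) rows for the EM."""
    sigma = robust_sigma(profile)
    rows = []
    for seg in segmented.segments:
        if seg.chrom in ("chrY", "Y"):
            rows.append(None)
            continue
        on_x = seg.chrom in ("chrX", "X")
        if on_x and not male_x:
            rows.append(None)
            continue
        sd = sigma / np.sqrt(seg.n_bins)
        if seg.n_bins >= long_threshold:
            sd = sd / rel_sd_long
        rows.append((seg.mean_log2, sd, seg.n_bins, -1 if on_x else 0))
    return sigma, rows


def _state_loglik(mean, sd, centers, sd_factor):
    sds = np.maximum(sd * sd_factor, 1e-12)
    return -0.5 * ((mean - centers) / sds) ** 2 - np.log(sds)


def _fit_mixing_proportions(obs, n_states, cellularity, max_iter=500, tol=1e-8):
    """EM over mixing proportions with fixed state centers.

    Returns (proportions, log-likelihood trace).  Observations are
    (mean, sd, weight, cn_shift) tuples.
    """
    init = EM_INIT_5 if n_states == 5 else EM_INIT_4
    pi = np.array(init)
    loglik_rows = []
    for mean, sd, w, shift in obs:
        _, centers, sdf = _state_table(n_states, cellularity, cn_shift=shift)
        loglik_rows.append(_state_loglik(mean, sd, centers, sdf))
    L = np.array(loglik_rows)                  # (n_obs, n_states)
    w = np.array([o[2] for o in obs], dtype=float)
    trace = []
    for _ in range(max_iter):
        log_joint = L + np.log(pi)
        m = log_joint.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_joint - m).sum(axis=1))
        trace.append(float((w * lse).sum()))
        gamma = np.exp(log_joint - lse[:, None])
        pi_new = (w[:, None] * gamma).sum(axis=0) / w.sum()
        pi_new = np.maximum(pi_new, 1e-12)
        pi_new /= pi_new.sum()
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            pi = pi_new
            break
        pi = pi_new
    return pi, trace


def call_profiles(
    pairs: list[tuple[SegmentedProfile, NormalizedProfile]],
    cellularity: float = 1.0,
    rel_sd_long: float = 2.0,
    long_threshold: int = 10,
    n_states: int = 4,
    male_x: bool = False,
) -> list[CalledProfile]:
    """Call CN states for a cohort, fitting one set of state priors by EM.

    Sex chromosomes are excluded by default; ``male_x`` includes chromosome
    X with its centers shifted one copy down (single-X baseline).  A
    degenerate noise scale (sigma = 0) collapses posteriors onto the
    nearest center with a log message.
    """
    if not pairs:
        raise ValueError("no profiles to call")
    per_sample = []
    all_obs = []
    for segmented, profile in pairs:
        if not segmented.segments:
            raise ValueError(f"{segmented.sample_id}: no segments to call")
        sigma, rows = _segment_observations(
            segmented, profile, rel_sd_long, long_threshold, male_x
        )
        per_sample.append((segmented, profile, sigma, rows))
        all_obs.extend(r for r in rows if r is not None)
    if not all_obs:
        raise ValueError("no callable segments (all on excluded chromosomes?)")

    degenerate = all(o[1] == 0 for o in all_obs)
    if degenerate:
        warnings.warn("noise scale is 0; posteriors collapse to nearest center")
        codes, _, _ = _state_table(n_states, cellularity)
        pi = np.full(len(codes), 1.0 / len(codes))
    else:
        usable = [o for o in all_obs if o[1] > 0] or all_obs
        pi, _ = _fit_mixing_proportions(usable, n_states, cellularity)

    out = []
    for segmented, profile, sigma, rows in per_sample:
        codes, _, _ = _state_table(n_states, cellularity)
        n_bins = segmented.grid.n_bins
        call = np.zeros(n_bins, dtype=np.int8)
        post = np.full((n_bins, len(codes)), np.nan)
        called = np.zeros(n_bins, dtype=bool)
        for sid, (seg, row) in enumerate(zip(segmented.segments, rows)):
            if row is None:
                continue
            mean, sd, _, shift = row
            _, centers, sdf = _state_table(n_states, cellularity, cn_shift=shift)
            if sd == 0:
                k = int(np.argmin(np.abs(mean - centers)))
                p = np.zeros(len(codes))
                p[k] = 1.0
            else:
                log_joint = _state_loglik(mean, sd, centers, sdf) + np.log(pi)
                log_joint -= log_joint.max()
                p = np.exp(log_joint)
                p /= p.sum()
            members = segmented.segment_id == sid
            call[members] = codes[int(np.argmax(p))]
            post[members] = p
            called[members] = True
        out.append(
            CalledProfile(
                sample_id=segmented.sample_id,
                grid=segmented.grid,
                call=call,
                posteriors=post,
                called=called,
                states=codes,
                settings={
                    "cellularity": cellularity,
                    "rel_sd_long": rel_sd_long,
                    "long_threshold": long_threshold,
                    "n_states": n_states,
                    "male_x": male_x,
                    "sigma": sigma,
                    "mixing_proportions": pi.tolist(),
                },
            )
        )
    return out


def call_profile(
    segmented: SegmentedProfile,
    profile: NormalizedProfile,
    **kwargs,
) -> CalledProfile:
    """Call one sample (EM priors fitted on this sample's segments alone)."""
    return call_profiles([(segmented, profile)], **kwargs)[0]
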