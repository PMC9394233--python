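"""QC scores, arm ratios, MAD, empty bins, subsampling and Wilcoxon."""

import itertools

import numpy as np
import pytest
from scipy import stats

from sctc_cnv.genome_bins import make_bin_grid
from sctc_cnv.qc import (
    arm_ratios,
    binomial_thin,
    determine_min_depth,
    empty_bin_flag,
    paired_wilcoxon,
    profile_mad,
    qc_score,
    wga_uniformity_flag,
)

from conftest import counts_from_array, profile_from_values


# --- multiplex band score --------------------------------------------------

def test_qc_score_exhaustive_popcount():
    for bits in itertools.product([0, 1], repeat=7):
        rec = qc_score(bits)
        assert rec.score == sum(bits)
        assert rec.passed == (sum(bits) >= 5)


def test_qc_score_band_count_contracts():
    assert qc_score([1] * 4, method="ampli1").score == 4
    assert qc_score([1] * 8, genomic=True).score == 8
    with pytest.raises(ValueError):
        qc_score([1] * 8)  # WGA product maxes at 7 bands
    with pytest.raises(ValueError):
        qc_score([1] * 7, method="ampli1")
    with pytest.raises(ValueError):
        qc_score([1] * 4, method="unknown")
    # genomic flag does not apply to the 4-amplicon kit
    assert qc_score([1] * 4, method="ampli1", genomic=True).score == 4


def test_qc_score_threshold_boundary():
    assert qc_score([1, 1, 1, 1, 1, 0, 0]).passed
    assert not qc_score([1, 1, 1, 1, 0, 0, 0]).passed


# --- arm ratios ------------------------------------------------------------

def test_arm_ratios_hand_oracle():
    sample = {"1p": 30, "1q": 50, "2p": 20}
    panel = [
        {"1p": 10, "1q": 10, "2p": 20},   # fractions 0.25, 0.25, 0.5
        {"1p": 30, "1q": 30, "2p": 40},   # fractions 0.3, 0.3, 0.4
    ]
    prof = arm_ratios(sample, panel, excluded_arms=frozenset())
    # sample fractions 0.3, 0.5, 0.2; panel means 0.275, 0.275, 0.45
    assert prof.ratios["1p"] == pytest.approx(0.3 / 0.275)
    assert prof.ratios["1q"] == pytest.approx(0.5 / 0.275)
    assert prof.ratios["2p"] == pytest.approx(0.2 / 0.45)
    assert prof.fractions.sum() == pytest.approx(1.0)


def test_arm_ratios_leave_one_out():
    member = {"a": 10, "b": 10}
    panel = [member, {"a": 30, "b": 10}, {"a": 30, "b": 10}]
    loo = arm_ratios(member, panel, excluded_arms=frozenset(), leave_out_index=0)
    # remaining panel fractions: (0.75, 0.25) twice -> mean 0.75
    assert loo.ratios["a"] == pytest.approx(0.5 / 0.75)
    full = arm_ratios(member, panel, excluded_arms=frozenset())
    assert full.ratios["a"] != loo.ratios["a"]
    with pytest.raises(IndexError):
        arm_ratios(member, panel, leave_out_index=5)


def test_arm_ratios_excluded_arms_dropped_from_ratios_not_fractions():
    sample = {"1p": 50, "13p": 50}
    panel = [{"1p": 60, "13p": 40}, {"1p": 50, "13p": 50}]
    prof = arm_ratios(sample, panel, excluded_arms=frozenset({"13p"}))
    assert "13p" not in prof.ratios
    assert prof.retained_arms == ["1p"]
    # fractions are still over all arms
    assert prof.fractions.sum() == pytest.approx(1.0)
    assert prof.ratios["1p"] == pytest.approx(0.5 / 0.55)


def test_arm_ratios_zero_panel_mean_warns_nan():
    sample = {"a": 10, "b": 10}
    panel = [{"a": 10, "b": 0}, {"a": 10, "b": 0}]
    with pytest.warns(UserWarning, match="ratio undefined"):
        prof = arm_ratios(sample, panel, excluded_arms=frozenset())
    assert np.isnan(prof.ratios["b"])


def test_arm_ratios_validation():
    with pytest.raises(ValueError):
        arm_ratios({"a": 1}, [{"a": 1}])  # panel too small
    with pytest.raises(ValueError):
        arm_ratios({"a": 0}, [{"a": 1}, {"a": 2}])  # no reads


# --- uniformity flag -------------------------------------------------------

def _uniform_arm_profile(n_arms=20):
    sample = {f"arm{i}": 100 for i in range(n_arms)}
    panel = [sample.copy(), sample.copy()]
    return arm_ratios(sample, panel, excluded_arms=frozenset())


def test_uniformity_passes_uniform_and_fails_collapsed():
    assert wga_uniformity_flag(_uniform_arm_profile()) == "pass"
    collapsed = {f"arm{i}": (1000 if i < 2 else 0.01) for i in range(20)}
    panel = [{f"arm{i}": 100 for i in range(20)}] * 2
    prof = arm_ratios(collapsed, panel, excluded_arms=frozenset())
    assert wga_uniformity_flag(prof) == "fail"
    assert prof.metrics["low_ratio_fraction"] > 0.5


def test_uniformity_thresholds_are_strict():
    """Exactly-at-threshold passes (strict inequalities)."""
    # 10 of 20 arms low -> low_fraction exactly 0.5 == default max -> pass
    sample = {f"arm{i}": (0.5 if i < 10 else 100) for i in range(20)}
    panel = [{f"arm{i}": 100 for i in range(20)}] * 2
    prof = arm_ratios(sample, panel, excluded_arms=frozenset())
    assert prof.metrics if prof.metrics else True
    verdict = wga_uniformity_flag(prof, low_cut=0.1, low_fraction_max=0.5,
                                  topk_share_max=1.0)
    assert prof.metrics["low_ratio_fraction"] == pytest.approx(0.5)
    assert verdict == "pass"


def test_uniformity_topk_gate():
    # 4 arms, top-3 share 0.75 exactly with equal arms -> pass at 0.75
    sample = {f"a{i}": 100 for i in range(4)}
    panel = [sample.copy()] * 2
    prof = arm_ratios(sample, panel, excluded_arms=frozenset())
    assert wga_uniformity_flag(prof, topk_share_max=0.75) == "pass"
    assert wga_uniformity_flag(prof, topk_share_max=0.74) == "fail"


# --- MAD -------------------------------------------------------------------

def test_profile_mad_hand_value():
    grid = make_bin_grid({"c1": 10 * 100_000}, 100_000)
    vals = [0.1, 0.2, 0.2, 0.3, 0.9, 0.2, 0.2, 0.2, 0.2, 0.2]
    prof = profile_from_values(grid, vals)
    # median 0.2; |x - 0.2| = [.1, 0, 0, .1, .7, 0, 0, 0, 0, 0] -> median 0
    assert profile_mad(prof) == pytest.approx(0.0)
    vals = [0.1, 0.2, 0.2, 0.3, 0.9] * 2
    prof = profile_from_values(grid, vals)
    # median 0.2; sorted devs [0,0,0,0,.1,.1,.1,.1,.7,.7] -> median 0.1
    assert profile_mad(prof) == pytest.approx(0.1)


def test_profile_mad_per_chromosome_scope():
    grid = make_bin_grid({"c1": 12 * 100_000, "c2": 12 * 100_000}, 100_000)
    rng = np.random.default_rng(0)
    x = np.concatenate([rng.normal(0, 0.1, 12), rng.normal(0, 0.5, 12)])
    prof = profile_from_values(grid, x)
    assert profile_mad(prof, scope="c2") > profile_mad(prof, scope="c1")
    with pytest.raises(ValueError):
        profile_mad(prof, scope="c9")


def test_profile_mad_needs_enough_bins():
    grid = make_bin_grid({"c1": 5 * 100_000}, 100_000)
    prof = profile_from_values(grid, np.zeros(5))
    with pytest.raises(ValueError, match="fewer than 10"):
        profile_mad(prof)


# --- empty-bin outliers ----------------------------------------------------

def _profile_with_empties(grid, n_empty, sid):
    vals = np.zeros(grid.n_bins)
    vals[:n_empty] = np.nan
    return profile_from_values(grid, vals, sid)


def test_empty_bin_flag_absolute_mode():
    grid = make_bin_grid({"c1": 100 * 100_000}, 100_000)
    profs = [_profile_with_empties(grid, n, f"s{n}") for n in (2, 5, 30)]
    flags = empty_bin_flag(profs, max_empty_fraction=0.1)
    assert flags == {"s2": False, "s5": False, "s30": True}


def test_empty_bin_flag_relative_mode():
    grid = make_bin_grid({"c1": 100 * 100_000}, 100_000)
    profs = [_profile_with_empties(grid, n, f"s{n}") for n in (4, 5, 6, 40)]
    flags = empty_bin_flag(profs, relative_multiple=3.0)
    # median fraction 0.055; 3x = 0.165; only s40 (0.4) exceeds
    assert flags == {"s4": False, "s5": False, "s6": False, "s40": True}


def test_empty_bin_flag_single_sample_warns():
    grid = make_bin_grid({"c1": 100 * 100_000}, 100_000)
    with pytest.warns(UserWarning, match="no reference"):
        flags = empty_bin_flag([_profile_with_empties(grid, 50, "s")])
    assert flags == {"s": False}


# --- subsampling -----------------------------------------------------------

def test_binomial_thin_identity_and_bounds():
    grid = make_bin_grid({"c1": 50 * 100_000}, 100_000)
    rng = np.random.default_rng(1)
    counts = counts_from_array(grid, rng.poisson(100, grid.n_bins))
    same = binomial_thin(counts, 1.0, rng)
    np.testing.assert_array_equal(same.raw_counts, counts.raw_counts)
    thin = binomial_thin(counts, 0.3, rng)
    assert (thin.raw_counts <= counts.raw_counts).all()
    assert thin.raw_counts.sum() == pytest.approx(0.3 * counts.raw_counts.sum(), rel=0.1)
    with pytest.raises(ValueError):
        binomial_thin(counts, 0.0, rng)


def test_determine_min_depth_monotone_and_reaches_one():
    grid = make_bin_grid({"c1": 400 * 100_000}, 100_000)
    rng = np.random.default_rng(2)
    base = rng.poisson(200, grid.n_bins).astype(np.int64)
    counts = counts_from_array(grid, base)
    total = counts.total_mapped_reads
    rec = determine_min_depth(
        counts,
        depths=(0.02 * total, 0.2 * total, total),
        iterations=4,
        seed=0,
        threshold=0.9,
    )
    means = [rec.mean_correlations[d] for d in sorted(rec.mean_correlations)]
    assert means == sorted(means)
    assert means[-1] == pytest.approx(1.0)
    assert rec.recommended is not None
    assert rec.mean_correlations[rec.recommended] >= 0.9


def test_determine_min_depth_depth_exceeding_total_rejected():
    grid = make_bin_grid({"c1": 200 * 100_000}, 100_000)
    counts = counts_from_array(grid, np.full(grid.n_bins, 10))
    with pytest.raises(ValueError, match="exceeds total"):
        determine_min_depth(counts, depths=(10 * counts.total_mapped_reads,))


# --- paired Wilcoxon -------------------------------------------------------

def enumeration_p(d):
    """Two-sided exact p by full 2^n enumeration of sign assignments."""
    d = np.asarray(d, dtype=float)
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mean_w = n * (n + 1) / 4.0
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, dtype=bool)].sum()
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / 2.0 ** n


@pytest.mark.parametrize("n", [5, 8, 10, 12])
def test_exact_branch_matches_full_enumeration(n):
    rng = np.random.default_rng(n)
    for _ in range(3):
        d = rng.normal(0.3, 1.0, n)
        while len(np.unique(np.abs(d))) < n or (d == 0).any():
            d = rng.normal(0.3, 1.0, n)
        x = rng.normal(0, 1, n)
        y = x - d
        assert paired_wilcoxon(x, y) == pytest.approx(enumeration_p(d))


def test_exact_branch_handles_ties_via_midrank_enumeration():
    rng = np.random.default_rng(13)
    for _ in range(4):
        # quantized differences force tied |d| groups
        d = np.round(rng.normal(0.2, 1.0, 10), 1)
        d = d[d != 0][:8]
        if len(d) < 6:
            continue
        x = rng.normal(0, 1, len(d))
        y = x - d
        assert paired_wilcoxon(x, y) == pytest.approx(enumeration_p(d))


def test_exact_branch_matches_scipy():
    rng = np.random.default_rng(77)
    for _ in range(5):
        x = rng.normal(0.2, 1.0, 15)
        y = rng.normal(0.0, 1.0, 15)
        expected = stats.wilcoxon(x, y, mode="exact").pvalue
        assert paired_wilcoxon(x, y) == pytest.approx(expected)


def test_nan_pairs_dropped():
    x = [1.0, 2.0, np.nan, 4.0, 5.0, 6.0, 7.0]
    y = [0.5, 2.5, 3.0, np.nan, 4.0, 5.5, 6.1]
    x2 = [1.0, 2.0, 5.0, 6.0, 7.0]
    y2 = [0.5, 2.5, 4.0, 5.5, 6.1]
    assert paired_wilcoxon(x, y) == paired_wilcoxon(x2, y2)


def test_zero_differences_dropped():
    x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
    y = [1.0, 2.5, 2.0, 3.0, 4.0, 5.0, 6.0]  # first pair ties exactly
    x2 = [2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
    y2 = [2.5, 2.0, 3.0, 4.0, 5.0, 6.0]
    # note: n drops below the zero-drop but both sides see identical data
    assert paired_wilcoxon(x, y) == pytest.approx(
        paired_wilcoxon(x2 + [9.0], y2 + [9.0])
    )


def test_all_zero_differences_p_one():
    x = [1.0, 2.0, 3.0, 4.0, 5.0]
    with pytest.warns(UserWarning, match="zero"):
        assert paired_wilcoxon(x, x) == 1.0


def test_minimum_pairs_enforced():
    with pytest.raises(ValueError, match="minimum 5"):
        paired_wilcoxon([1, 2, 3], [0, 1, 2])
    with pytest.raises(ValueError, match="equal length"):
        paired_wilcoxon([1, 2, 3], [1, 2])


def test_tie_corrected_approximation_matches_reference_formula():
    """Ties force the normal branch; check against a direct computation."""
    x = np.array([0.5, 0.7, 0.9, 1.1, 1.3, 1.5, 1.7, 1.9, 2.1, 2.3,
                  2.5, 2.7, 2.9, 3.1, 3.3, 3.5, 3.7, 3.9, 4.1, 4.3,
                  4.5, 4.7, 4.9, 5.1, 5.3, 5.5])
    rng = np.random.default_rng(8)
    d = rng.choice([-0.2, -0.1, 0.1, 0.1, 0.2, 0.3], size=len(x))
    y = x - d
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    n = len(d)
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (counts ** 3 - counts).sum() / 48.0
    z = (abs(w_plus - n * (n + 1) / 4.0) - 0.5) / np.sqrt(var)
    assert paired_wilcoxon(x, y) == pytest.approx(2 * stats.norm.sf(z))
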