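"""Calibration-panel construction and wave-bias removal.

Low-pass single-cell coverage carries a smooth, GC-correlated "wave" that is
shared across cells processed through the same pipeline.  A panel of
copy-number-neutral single cells (leukocytes) captures that shared bias:
each candidate normal is regressed (OLS, with intercept) on the remaining
panel members; members whose residual variance exceeds a threshold (default
0.05) are dropped in a single pass.  A sample profile is then dewaved by
regressing it on the retained members and subtracting the fitted component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome_bins import NormalizedProfile, sigma_delta
from .genomes import SEX_CHROMOSOMES

__all__ = ["CalibrationPanel", "build_calibration_panel", "dewave"]

#: Fewer retained members than this triggers a warning (panel still usable).
RECOMMENDED_MIN_MEMBERS = 6


@dataclass
class CalibrationPanel:
    """Normal single-cell profiles retained for wave correction."""

    members: list[NormalizedProfile]
    wave_variance: np.ndarray       # leave-one-out residual variance per member
    variance_threshold: float
    retained: np.ndarray            # bool per member
    autosomes_only: bool = True
    settings: dict = field(default_factory=dict)

    @property
    def retained_members(self) -> list[NormalizedProfile]:
        return [m for m, keep in zip(self.members, self.retained) if keep]

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())


def _scope_mask(profile: NormalizedProfile, autosomes_only: bool) -> np.ndarray:
    mask = ~np.isnan(profile.log2_ratio)
    if autosomes_only:
        mask &= ~np.isin(profile.grid.chrom, SEX_CHROMOSOMES)
    return mask


def _ols_fit(y: np.ndarray, X: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Least-squares fitted values of y on X plus intercept."""
    design = np.column_stack([np.ones(len(y)), X])
    if ridge > 0:
        A = design.T @ design + ridge * np.eye(design.shape[1])
        beta = np.linalg.solve(A, design.T @ y)
    else:
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return design @ beta


def _regress_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    try:
        fitted = _ols_fit(y, X)
        if not np.isfinite(fitted).all():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("singular panel design; falling back to ridge (1e-6)")
        fitted = _ols_fit(y, X, ridge=1e-6)
    return y - fitted


def build_calibration_panel(
    normals: list[NormalizedProfile],
    variance_threshold: float = 0.05,
    autosomes_only: bool = True,
    min_common_bins: int = 50,
) -> CalibrationPanel:
    """Build a wave-calibration panel from normal single-cell profiles.

    Each member's log2 ratios are regressed on all other members over the
    jointly non-missing usable bins; its wave variance is the residual
    variance.  Members above ``variance_threshold`` are excluded in one pass
    (no re-iteration on the retained subset).
    """
    if len(normals) < 2:
        raise ValueError("a calibration panel needs at least 2 normal profiles")
    grid = normals[0].grid
    for p in normals[1:]:
        if p.grid is not grid and p.grid.n_bins != grid.n_bins:
            raise ValueError("panel profiles must share one bin grid")

    masks = [_scope_mask(p, autosomes_only) for p in normals]
    common = np.logical_and.reduce(masks)
    if common.sum() < min_common_bins:
        raise ValueError(
            f"only {int(common.sum())} jointly non-missing bins "
            f"(minimum {min_common_bins})"
        )
    mat = np.column_stack([p.log2_ratio[common] for p in normals])

    n = len(normals)
    wave_var = np.empty(n)
    for i in range(n):
        others = np.delete(np.arange(n), i)
        resid = _regress_residuals(mat[:, i], mat[:, others])
        wave_var[i] = float(np.var(resid, ddof=1)) if len(resid) > 1 else 0.0

    retained = wave_var <= variance_threshold
    if retained.sum() == 0:
        raise ValueError(
            "no panel member passes the wave-variance threshold "
            f"{variance_threshold}"
        )
    if retained.sum() < RECOMMENDED_MIN_MEMBERS:
        warnings.warn(
            f"only {int(retained.sum())} panel members retained "
            f"(recommended minimum {RECOMMENDED_MIN_MEMBERS})"
        )
    return CalibrationPanel(
        members=list(normals),
        wave_variance=wave_var,
        variance_threshold=variance_threshold,
        retained=retained,
        autosomes_only=autosomes_only,
        settings={"min_common_bins": min_common_bins},
    )


def dewave(
    profile: NormalizedProfile,
    panel: CalibrationPanel,
    min_common_bins: int = 50,
) -> NormalizedProfile:
    """Remove the shared wave component from one profile.

    The profile is regressed (OLS with intercept) on the retained panel
    members over jointly non-missing bins; the fitted component is
    subtracted and the result re-centred to median 0.  Missing bins stay
    missing.  With too few common bins the profile is returned unchanged
    (dewaved flag left unset) with a warning.
    """
    members = panel.retained_members
    if not members:
        raise ValueError("panel has no retained members")
    y_mask = ~np.isnan(profile.log2_ratio)
    panel_mask = np.logical_and.reduce(
        [~np.isnan(m.log2_ratio) for m in members]
    )
    if panel.autosomes_only:
        panel_mask &= ~np.isin(profile.grid.chrom, SEX_CHROMOSOMES)
    common = y_mask & panel_mask
    if common.sum() < min_common_bins:
        warnings.warn(
            f"{profile.sample_id}: only {int(common.sum())} bins in common with "
            "the panel; profile returned un-dewaved"
        )
        return profile

    X = np.column_stack([m.log2_ratio[common] for m in members])
    resid = _regress_residuals(profile.log2_ratio[common], X)

    out = profile.log2_ratio.copy()
    out[common] = resid
    # bins outside the regression scope (e.g. sex chromosomes) keep their
    # original values, re-centred together with the corrected ones
    ok = ~np.isnan(out)
    out[ok] -= np.median(out[common])
    return profile.copy_with(
        log2_ratio=out,
        sigma_delta=sigma_delta(out),
        dewaved=True,
    )
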