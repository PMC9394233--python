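"""Synthetic single-cell low-pass sequencing data with exported ground truth.

Emulates the data regime of amplified single cells: integral-copy-number
clone structure, a smooth low-frequency "wave" bias shared by all cells of a
batch (plus a GC-linked component), a multiplicative linear GC bias,
negative-binomial overdispersion from whole-genome amplification, random bin
dropout, and — for failed amplification reactions — collapse of the read
mass onto a handful of chromosome arms.

Every generator is deterministic for a fixed spec + seed, and each simulated
cohort ships its truth tables (per-bin copy number, clone labels, bias
fields) so downstream stages can be scored against known state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genome_bins import BinGrid, ReadCountProfile, make_bin_grid
from .genomes import HG19_CENTROMERES, HG19_CHROM_LENGTHS, add_chr, strip_chr

__all__ = [
    "SimulationSpec",
    "make_toy_grid",
    "flat_clone",
    "clone_with_events",
    "arm_labels",
    "simulate_cells",
    "simulate_failed_wga",
    "simulate_arm_counts",
]


def make_toy_grid(
    n_chroms: int = 4,
    bins_per_chrom: int = 500,
    bin_size: int = 100_000,
    gc_seed: int = 1234,
) -> BinGrid:
    """Small grid for fast tests: ``n_chroms`` chromosomes of equal length.

    Bins carry a smooth synthetic GC track (random walk squashed into
    [0.3, 0.7]) so GC-bias simulation and correction can be exercised.
    """
    lengths = {f"chr{i + 1}": bins_per_chrom * bin_size for i in range(n_chroms)}
    grid = make_bin_grid(lengths, bin_size)
    rng = np.random.default_rng(gc_seed)
    walk = np.cumsum(rng.normal(0, 1, grid.n_bins))
    walk = (walk - walk.mean()) / (np.abs(walk).max() or 1.0)
    grid.gc = 0.5 + 0.2 * walk
    grid.mappability = np.ones(grid.n_bins)
    return grid


def flat_clone(grid: BinGrid, cn: int = 2) -> np.ndarray:
    """Copy-number-flat clone (leukocyte-like at the default cn = 2)."""
    return np.full(grid.n_bins, cn, dtype=np.int64)


def clone_with_events(
    grid: BinGrid, events: Sequence[tuple[str, int, int, int]], base_cn: int = 2
) -> np.ndarray:
    """Clone CN vector with events given as (chrom, first_bin, last_bin, cn).

    Bin offsets are chromosome-local, inclusive on both ends.
    """
    cn = np.full(grid.n_bins, base_cn, dtype=np.int64)
    for chrom, first, last, value in events:
        sl = grid.chrom_slice(chrom)
        if not (0 <= first <= last < sl.stop - sl.start):
            raise ValueError(f"event {chrom}:{first}-{last} outside chromosome")
        cn[sl.start + first : sl.start + last + 1] = value
    return cn


@dataclass
class SimulationSpec:
    """Full description of a synthetic cohort.

    ``clones`` maps clone name to an integral per-bin CN vector; ``cells``
    maps cell id to (clone name, total reads).  The wave field is drawn once
    per spec and shared by every cell (it models a batch-level artefact);
    its log2 amplitude and wavelength are in bins.
    """

    grid: BinGrid
    clones: dict[str, np.ndarray]
    cells: dict[str, tuple[str, int]]
    gc_bias: float = 0.0            # multiplicative linear slope vs (gc - 0.5)
    wave_amplitude: float = 0.0     # log2 units
    wave_wavelength: float = 150.0  # bins
    wave_components: int = 3
    wave_gc_coupling: float = 0.0   # log2 units per unit (gc - 0.5)
    dispersion: float | None = 10.0  # negative-binomial size; None = Poisson
    dropout_probability: float = 0.0
    failed_wga: dict | None = None  # {"n_active_arms": int, "concentration": float}
    seed: int = 0

    def __post_init__(self) -> None:
        for name, cn in self.clones.items():
            cn = np.asarray(cn)
            if cn.shape != (self.grid.n_bins,):
                raise ValueError(f"clone {name!r} CN length mismatch")
            if (cn < 0).any() or not np.issubdtype(cn.dtype, np.integer):
                raise ValueError(f"clone {name!r} CN must be non-negative integers")
            if not cn.any():
                raise ValueError(f"clone {name!r} is all-zero")
        for cell, (clone, reads) in self.cells.items():
            if clone not in self.clones:
                raise ValueError(f"cell {cell!r} references unknown clone {clone!r}")
            if reads <= 0:
                raise ValueError(f"cell {cell!r} has non-positive read total")


def _wave_field(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Batch-shared smooth bias in log2 units: sinusoids + GC coupling."""
    n = spec.grid.n_bins
    field_log2 = np.zeros(n)
    if spec.wave_amplitude > 0:
        t = np.arange(n, dtype=float)
        for k in range(spec.wave_components):
            lam = spec.wave_wavelength * (1.0 + 0.5 * k)
            phase = rng.uniform(0, 2 * np.pi)
            field_log2 += np.sin(2 * np.pi * t / lam + phase)
        field_log2 *= spec.wave_amplitude / spec.wave_components
    if spec.wave_gc_coupling != 0 and not np.isnan(spec.grid.gc).all():
        gc = np.nan_to_num(spec.grid.gc, nan=0.5)
        field_log2 += spec.wave_gc_coupling * (gc - 0.5)
    return field_log2


def _gc_factor(spec: SimulationSpec) -> np.ndarray:
    if spec.gc_bias == 0 or np.isnan(spec.grid.gc).all():
        return np.ones(spec.grid.n_bins)
    gc = np.nan_to_num(spec.grid.gc, nan=0.5)
    return np.clip(1.0 + spec.gc_bias * (gc - 0.5), 0.05, None)


def _draw_counts(
    expectation: np.ndarray, spec: SimulationSpec, rng: np.random.Generator
) -> np.ndarray:
    if spec.dispersion is None or not np.isfinite(spec.dispersion):
        counts = rng.poisson(expectation)
    else:
        r = spec.dispersion
        p = r / (r + np.maximum(expectation, 1e-12))
        counts = rng.negative_binomial(r, p)
    if spec.dropout_probability > 0:
        counts = np.where(
            rng.random(len(counts)) < spec.dropout_probability, 0, counts
        )
    return counts.astype(np.int64)


def _expected_profile(
    spec: SimulationSpec, cn: np.ndarray, total_reads: int,
    wave_log2: np.ndarray, arm_weight: np.ndarray | None = None,
) -> np.ndarray:
    rel = (cn / 2.0) * _gc_factor(spec) * np.exp2(wave_log2)
    rel[~spec.grid.usable] = 0.0
    if arm_weight is not None:
        rel = rel * arm_weight
    s = rel.sum()
    if s <= 0:
        raise ValueError("degenerate expectation (no usable signal)")
    return total_reads * rel / s


def simulate_cells(spec: SimulationSpec):
    """Simulate a cohort of single cells from a spec.

    Returns ``(profiles, truth)`` where ``profiles`` maps cell id to a
    :class:`ReadCountProfile` and ``truth`` holds per-cell CN vectors,
    clone labels, the shared wave field (log2) and per-cell expectations.
    """
    rng = np.random.default_rng(spec.seed)
    wave_log2 = _wave_field(spec, rng)
    profiles: dict[str, ReadCountProfile] = {}
    truth = {
        "wave_log2": wave_log2,
        "clone_of": {},
        "cn": {},
        "expectation": {},
    }
    for cell, (clone, reads) in spec.cells.items():
        cn = np.asarray(spec.clones[clone])
        exp = _expected_profile(spec, cn, reads, wave_log2)
        counts = _draw_counts(exp, spec, rng)
        profiles[cell] = ReadCountProfile(
            sample_id=cell,
            grid=spec.grid,
            raw_counts=counts,
            total_mapped_reads=int(counts.sum()),
            filter_settings={"simulated": True, "clone": clone},
        )
        truth["clone_of"][cell] = clone
        truth["cn"][cell] = cn
        truth["expectation"][cell] = exp
    return profiles, truth


def arm_labels(grid: BinGrid) -> np.ndarray:
    """Per-bin arm label.

    The hg19 centromere position is used when the chromosome has the hg19
    length for its name; any other chromosome splits at its midpoint (so
    synthetic toy genomes get two arms each, not a vacuous single arm).
    """
    labels = np.empty(grid.n_bins, dtype=object)
    for chrom in grid.chrom_names:
        sl = grid.chrom_slice(chrom)
        length = grid.chrom_lengths[chrom]
        if length == HG19_CHROM_LENGTHS.get(add_chr(chrom)):
            cen = HG19_CENTROMERES[add_chr(chrom)]
        else:
            cen = length // 2
        base = strip_chr(chrom)
        arms = np.where(grid.start[sl] < cen, f"{base}p", f"{base}q")
        labels[sl] = arms
    return labels.astype(str)


def simulate_failed_wga(spec: SimulationSpec):
    """Simulate cells whose amplification collapsed onto few chromosome arms.

    Arm weights come from a Dirichlet draw over ``n_active_arms`` randomly
    chosen arms (``concentration`` is the symmetric Dirichlet parameter);
    inactive arms receive a residual 1e-4 relative weight rather than an
    exact zero, mirroring the trace reads real failed reactions retain.
    With all arms active and a large concentration the draw degenerates to
    uniform weights, recovering the well-behaved generator.
    """
    if not spec.failed_wga:
        raise ValueError("spec.failed_wga is not configured")
    n_active = int(spec.failed_wga.get("n_active_arms", 3))
    conc = float(spec.failed_wga.get("concentration", 1.0))
    if n_active < 1:
        raise ValueError("n_active_arms must be >= 1")

    labels = arm_labels(spec.grid)
    unique_arms = list(dict.fromkeys(labels))
    if n_active > len(unique_arms):
        raise ValueError("more active arms requested than arms in the grid")

    rng = np.random.default_rng(spec.seed)
    wave_log2 = _wave_field(spec, rng)
    profiles: dict[str, ReadCountProfile] = {}
    truth = {"active_arms": {}, "clone_of": {}, "cn": {}, "label": "failed"}
    for cell, (clone, reads) in spec.cells.items():
        chosen = rng.choice(len(unique_arms), size=n_active, replace=False)
        weights = np.full(len(unique_arms), 1e-4)
        weights[chosen] = rng.dirichlet(np.full(n_active, conc))
        per_bin = np.array(
            [weights[unique_arms.index(a)] for a in labels]
        )
        cn = np.asarray(spec.clones[clone])
        exp = _expected_profile(spec, cn, reads, wave_log2, arm_weight=per_bin)
        counts = _draw_counts(exp, spec, rng)
        profiles[cell] = ReadCountProfile(
            sample_id=cell,
            grid=spec.grid,
            raw_counts=counts,
            total_mapped_reads=int(counts.sum()),
            filter_settings={"simulated": True, "failed_wga": True},
        )
        truth["active_arms"][cell] = [unique_arms[i] for i in chosen]
        truth["clone_of"][cell] = clone
        truth["cn"][cell] = cn
    return profiles, truth


def simulate_arm_counts(
    profiles: Mapping[str, ReadCountProfile],
    labels: np.ndarray | None = None,
) -> dict[str, dict[str, int]]:
    """Aggregate per-bin counts into per-arm totals (arm-QC input schema)."""
    out: dict[str, dict[str, int]] = {}
    for cell, prof in profiles.items():
        lab = labels if labels is not None else arm_labels(prof.grid)
        if len(lab) != prof.grid.n_bins:
            raise ValueError("arm labels do not match the grid")
        sums: dict[str, int] = {}
        for a in dict.fromkeys(lab):
            sums[a] = int(prof.raw_counts[lab == a].sum())
        out[cell] = sums
    return out
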