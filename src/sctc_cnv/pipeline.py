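"""End-to-end orchestration: count -> normalize -> panel -> dewave ->
segment -> call -> cluster -> QC report, under a single validated config.

Per-sample failures (normalization failure, empty-bin outliers) quarantine
the sample with a reason and the run continues; the run succeeds when at
least two samples reach clustering.  The effective configuration is written
verbatim into the results manifest for provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as _io
from .calling import call_profiles
from .clustering import cluster_samples, condense_calls, linkage_to_newick
from .genome_bins import ReadCountProfile, make_hg19_grid, normalize_profile
from .qc import empty_bin_flag
from .segmentation import segment_profile
from .wave_correction import build_calibration_panel, dewave

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("sctc_cnv")


@dataclass
class PipelineConfig:
    """Validated pipeline settings; unknown keys are rejected fail-fast."""

    genome: str = "hg19"
    chrom_sizes: str | None = None       # for genome == "custom"
    bin_size: int = 100_000
    blacklist: str | None = None
    min_mapq: int = 20
    dedup: bool = True
    paired_mode: str = "fragment"
    do_gc: bool = False
    do_mappability: bool = False
    lowess_frac: float = 0.65
    min_usable_bins: int = 100
    panel_variance_threshold: float = 0.05
    panel_autosomes_only: bool = True
    alpha: float = 0.01
    n_permutations: int = 1000
    undo_sd: float = 4.0
    min_width: int = 10
    seed: int = 0
    cellularity: float = 1.0
    rel_sd_long: float = 2.0
    long_threshold: int = 10
    n_states: int = 4
    male_x: bool = False
    linkage: str = "average"
    distance: str = "soft"
    exclude_sex: bool = True
    qc_pass_threshold: int = 5
    max_empty_fraction: float | None = None
    empty_relative_multiple: float = 3.0
    depth_threshold: float = 0.9
    depths: tuple = (0.5e6, 1e6, 2.5e6, 5e6)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["depths"] = list(d["depths"])
        return d


@dataclass
class PipelineResult:
    out_dir: Path
    clustered_samples: list[str]
    quarantined: dict[str, str]
    manifest: dict = field(default_factory=dict)

    @property
    def success(self) -> bool:
        return len(self.clustered_samples) >= 2


def _build_grid(config: PipelineConfig):
    if config.genome == "hg19":
        grid = make_hg19_grid(config.bin_size)
    elif config.genome == "custom":
        if not config.chrom_sizes:
            raise ValueError("genome 'custom' requires chrom_sizes")
        from .genome_bins import make_bin_grid

        grid = make_bin_grid(_io.read_chrom_sizes(config.chrom_sizes), config.bin_size)
    else:
        raise ValueError(f"unknown genome {config.genome!r}")
    if config.blacklist:
        from .genome_bins import annotate_bins

        grid = annotate_bins(grid, _io.read_bed(config.blacklist))
    return grid


def run_pipeline(
    config: PipelineConfig,
    samples: dict[str, ReadCountProfile],
    normals: dict[str, ReadCountProfile],
    out_dir,
) -> PipelineResult:
    """Run all stages on pre-counted samples and normals.

    ``samples``/``normals`` map sample id to a :class:`ReadCountProfile`
    on a shared grid (load them with :func:`sctc_cnv.io.read_count_table`
    or produce them with :func:`sctc_cnv.genome_bins.count_reads` /
    the synthetic generators).
    """
    out_dir = Path(out_dir)
    (out_dir / "profiles").mkdir(parents=True, exist_ok=True)
    quarantined: dict[str, str] = {}

    # --- normalize -------------------------------------------------------
    norm_kwargs = dict(
        do_gc=config.do_gc,
        do_mappability=config.do_mappability,
        lowess_frac=config.lowess_frac,
        min_usable_bins=config.min_usable_bins,
    )
    normalized = {}
    for sid, counts in samples.items():
        prof = normalize_profile(counts, **norm_kwargs)
        log.info("normalize %s: empty_bins=%d sigma_delta=%.4g usable=%s",
                 sid, prof.empty_bin_count, prof.sigma_delta, prof.usable_profile)
        _io.write_profile(prof, out_dir / "profiles" / f"{sid}.tsv", counts)
        if not prof.usable_profile:
            quarantined[sid] = "normalization failure (too few usable bins)"
            continue
        normalized[sid] = prof

    normal_profiles = []
    for sid, counts in normals.items():
        prof = normalize_profile(counts, **norm_kwargs)
        log.info("normalize normal %s: usable=%s", sid, prof.usable_profile)
        if prof.usable_profile:
            normal_profiles.append(prof)

    # --- empty-bin gate --------------------------------------------------
    if normalized:
        flags = empty_bin_flag(
            list(normalized.values()),
            max_empty_fraction=config.max_empty_fraction,
            relative_multiple=config.empty_relative_multiple,
        )
        for sid, flagged in flags.items():
            log.info("empty-bin gate %s: %s", sid, "FLAG" if flagged else "ok")
            if flagged:
                quarantined[sid] = "empty-bin outlier"
                normalized.pop(sid, None)

    # --- panel + dewave --------------------------------------------------
    panel = None
    if len(normal_profiles) >= 2:
        panel = build_calibration_panel(
            normal_profiles,
            variance_threshold=config.panel_variance_threshold,
            autosomes_only=config.panel_autosomes_only,
        )
        _io.save_panel(panel, out_dir / "panel")
        log.info("panel: %d/%d members retained", panel.n_retained, len(panel.members))
        normalized = {sid: dewave(p, panel) for sid, p in normalized.items()}
    else:
        log.warning("fewer than 2 normals; dewaving skipped")

    # --- segment + call --------------------------------------------------
    pairs = []
    for sid, prof in normalized.items():
        seg = segment_profile(
            prof,
            alpha=config.alpha,
            n_permutations=config.n_permutations,
            undo_sd=config.undo_sd,
            min_width=config.min_width,
            seed=config.seed,
        )
        log.info("segment %s: %d segments", sid, seg.n_segments)
        _io.write_segments(seg, out_dir / "profiles" / f"{sid}.segments.tsv")
        pairs.append((seg, prof))

    clustered: list[str] = []
    manifest: dict = {
        "config": config.to_dict(),
        "quarantined": quarantined,
    }
    if pairs:
        called = call_profiles(
            pairs,
            cellularity=config.cellularity,
            rel_sd_long=config.rel_sd_long,
            long_threshold=config.long_threshold,
            n_states=config.n_states,
            male_x=config.male_x,
        )
        for c in called:
            _io.write_calls(c, out_dir / "profiles" / f"{c.sample_id}.calls.tsv")

        if len(called) >= 2:
            matrix = condense_calls(called)
            D, Z, order = cluster_samples(
                matrix,
                linkage=config.linkage,
                distance=config.distance,
                exclude_sex=config.exclude_sex,
            )
            _io.write_regions(matrix, out_dir / "regions.tsv")
            _io.write_matrix(D, matrix.sample_ids, out_dir / "distances.tsv")
            (out_dir / "dendrogram.nwk").write_text(
                linkage_to_newick(Z, matrix.sample_ids) + "\n"
            )
            heat = [matrix.sample_ids[i] for i in order]
            manifest["leaf_order"] = heat
            clustered = list(matrix.sample_ids)
            log.info("clustered %d samples over %d regions",
                     len(clustered), matrix.n_regions)
        else:
            log.warning("fewer than 2 callable samples; clustering skipped")

    manifest["clustered_samples"] = clustered
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return PipelineResult(
        out_dir=out_dir,
        clustered_samples=clustered,
        quarantined=quarantined,
        manifest=manifest,
    )
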