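"""Plain-text readers and writers for the pipeline's stage artefacts.

Counts, profiles, segments, calls and regions travel as TSV with a JSON
sidecar for per-sample metadata, so any stage can be re-entered from its
predecessor's files.  Coordinates are 0-based half-open, as in BED.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_bins import BinGrid, NormalizedProfile, ReadCountProfile, make_bin_grid
from .wave_correction import CalibrationPanel

__all__ = [
    "read_chrom_sizes",
    "read_bed",
    "read_track",
    "read_count_table",
    "write_profile",
    "read_profile",
    "write_segments",
    "write_calls",
    "write_regions",
    "write_matrix",
    "save_panel",
    "load_panel",
]


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column (chrom, length) TSV -> ordered mapping."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "length"], usecols=[0, 1])
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def read_bed(path) -> list[tuple[str, int, int]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [
        (str(r[0]), int(r[1]), int(r[2])) for r in df.itertuples(index=False)
    ]


def read_track(path) -> list[tuple[str, int, int, float]]:
    """(chrom, start, end, value) TSV/bedGraph."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [
        (str(r[0]), int(r[1]), int(r[2]), float(r[3]))
        for r in df.itertuples(index=False)
    ]


def read_count_table(path, grid: BinGrid | None = None, sample_id: str | None = None) -> ReadCountProfile:
    """Per-bin count TSV with header (chrom, start, end, count).

    Without a grid, one is reconstructed from the table's bins (bin size
    inferred from the first bin's width).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"count table needs columns {sorted(required)}")
    if grid is None:
        bin_size = int(df["end"].iloc[0] - df["start"].iloc[0])
        lengths: dict[str, int] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            lengths[str(chrom)] = int(sub["end"].max())
        grid = make_bin_grid(lengths, bin_size)
    if len(df) != grid.n_bins:
        raise ValueError(
            f"table has {len(df)} bins but grid has {grid.n_bins}"
        )
    counts = df["count"].to_numpy(dtype=np.int64)
    return ReadCountProfile(
        sample_id=sample_id or Path(path).stem,
        grid=grid,
        raw_counts=counts,
        total_mapped_reads=int(counts.sum()),
    )


def _bin_frame(grid: BinGrid) -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": grid.chrom, "start": grid.start, "end": grid.end,
         "usable": grid.usable.astype(int)}
    )


def write_profile(
    profile: NormalizedProfile,
    path,
    counts: ReadCountProfile | None = None,
) -> None:
    """Per-sample TSV (chrom, start, end, usable, raw_count, log2_ratio)
    plus a JSON sidecar with the noise metrics and provenance flags."""
    path = Path(path)
    df = _bin_frame(profile.grid)
    df["raw_count"] = counts.raw_counts if counts is not None else -1
    df["log2_ratio"] = [
        "" if np.isnan(v) else f"{v:.6g}" for v in profile.log2_ratio
    ]
    df.to_csv(path, sep="\t", index=False)
    sidecar = {
        "sample_id": profile.sample_id,
        "total_mapped_reads": counts.total_mapped_reads if counts else None,
        "sigma_delta": None if np.isnan(profile.sigma_delta) else profile.sigma_delta,
        "empty_bin_count": profile.empty_bin_count,
        "gc_corrected": profile.gc_corrected,
        "mappability_corrected": profile.mappability_corrected,
        "dewaved": profile.dewaved,
        "usable_profile": profile.usable_profile,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1)
    )


def read_profile(path, grid: BinGrid | None = None) -> NormalizedProfile:
    from .genome_bins import sigma_delta as _sd

    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if grid is None:
        bin_size = int(df["end"].iloc[0] - df["start"].iloc[0])
        lengths = {
            str(c): int(sub["end"].max()) for c, sub in df.groupby("chrom", sort=False)
        }
        grid = make_bin_grid(lengths, bin_size)
        grid.usable = df["usable"].to_numpy(dtype=bool)
    log2 = pd.to_numeric(df["log2_ratio"], errors="coerce").to_numpy(dtype=float)
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return NormalizedProfile(
        sample_id=meta.get("sample_id", path.stem),
        grid=grid,
        log2_ratio=log2,
        sigma_delta=meta.get("sigma_delta") or _sd(log2),
        empty_bin_count=meta.get("empty_bin_count", 0),
        gc_corrected=meta.get("gc_corrected", False),
        mappability_corrected=meta.get("mappability_corrected", False),
        dewaved=meta.get("dewaved", False),
        usable_profile=meta.get("usable_profile", True),
    )


def write_segments(segmented, path) -> None:
    """BED-like TSV of segments with bin counts and means."""
    grid = segmented.grid
    rows = [
        {
            "chrom": s.chrom,
            "start_bp": int(grid.start[s.first_bin]),
            "end_bp": int(grid.end[s.last_bin]),
            "n_bins": s.n_bins,
            "mean_log2": round(s.mean_log2, 6),
        }
        for s in segmented.segments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    Path(str(path) + ".json").write_text(json.dumps(segmented.settings, indent=1))


def write_calls(called, path) -> None:
    grid = called.grid
    df = _bin_frame(grid)
    df["call"] = np.where(called.called, called.call, "")
    for i, s in enumerate(called.states):
        from .calling import STATE_LABELS
        df[f"p_{STATE_LABELS[s]}"] = [
            "" if np.isnan(v) else f"{v:.6g}" for v in called.posteriors[:, i]
        ]
    df.to_csv(path, sep="\t", index=False)


def write_regions(matrix, path) -> None:
    grid_cols = {
        "chrom": matrix.chrom,
        "first_bin": matrix.first_bin,
        "last_bin": matrix.last_bin,
        "n_bins": matrix.weights.astype(int),
    }
    df = pd.DataFrame(grid_cols)
    for s, sid in enumerate(matrix.sample_ids):
        df[sid] = matrix.calls[:, s]
    df.to_csv(path, sep="\t", index=False)


def write_matrix(D: np.ndarray, labels: list[str], path) -> None:
    pd.DataFrame(D, index=labels, columns=labels).to_csv(path, sep="\t")


def save_panel(panel: CalibrationPanel, directory) -> None:
    """Directory of member profile TSVs plus a manifest JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "variance_threshold": panel.variance_threshold,
        "autosomes_only": panel.autosomes_only,
        "members": [],
    }
    for m, var, keep in zip(panel.members, panel.wave_variance, panel.retained):
        fname = f"{m.sample_id}.tsv"
        write_profile(m, directory / fname)
        manifest["members"].append(
            {"sample_id": m.sample_id, "file": fname,
             "wave_variance": float(var), "retained": bool(keep)}
        )
    (directory / "panel.json").write_text(json.dumps(manifest, indent=1))


def load_panel(directory, grid: BinGrid | None = None) -> CalibrationPanel:
    directory = Path(directory)
    manifest = json.loads((directory / "panel.json").read_text())
    members, variances, retained = [], [], []
    for entry in manifest["members"]:
        members.append(read_profile(directory / entry["file"], grid=grid))
        variances.append(entry["wave_variance"])
        retained.append(entry["retained"])
    return CalibrationPanel(
        members=members,
        wave_variance=np.array(variances),
        variance_threshold=manifest["variance_threshold"],
        retained=np.array(retained, dtype=bool),
        autosomes_only=manifest.get("autosomes_only", True),
    )
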