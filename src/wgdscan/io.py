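"""Plain-text readers and writers for every container in the package.

Formats: BED-like TSV for bin grids (chrom, start, end, gc, blacklisted),
a bins × cells TSV matrix for counts, BED + JSON for called profiles, JSON
for ground truth and curation reports, CSV for fiber tables (see
:mod:`wgdscan.fibers`) and multi-channel TIFF for images.  Coordinates are
0-based half-open throughout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import InvalidArgumentError
from .cnv import CopyNumberProfile
from .genome import BinGrid, CellLibrary

__all__ = [
    "write_grid",
    "read_grid",
    "write_counts",
    "read_counts",
    "write_profile_bed",
    "write_profile_json",
    "write_ground_truth",
    "read_image_channels",
]


def write_grid(grid: BinGrid, path: str | Path) -> None:
    out = grid.bins.copy()
    out["blacklisted"] = out["blacklisted"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_grid(path: str | Path) -> BinGrid:
    bins = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    bins["blacklisted"] = bins["blacklisted"].astype(bool)
    return BinGrid(bins)


def write_counts(cells: list[CellLibrary], path: str | Path) -> None:
    """Bins × cells TSV matrix; first columns locate the bin, then one per cell."""
    if not cells:
        raise InvalidArgumentError("no cells to write")
    grid = cells[0].grid
    out = grid.bins[["chrom", "start", "end"]].copy()
    for cell in cells:
        out[cell.cell_id] = cell.counts
    out.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path, grid: BinGrid, conditions: dict[str, str] | None = None) -> list[CellLibrary]:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    cell_cols = [c for c in frame.columns if c not in ("chrom", "start", "end")]
    conditions = conditions or {}
    return [
        CellLibrary(
            cell_id=c,
            condition=conditions.get(c, ""),
            counts=frame[c].to_numpy(dtype=np.int64),
            grid=grid,
        )
        for c in cell_cols
    ]


def write_profile_bed(profile: CopyNumberProfile, path: str | Path) -> None:
    profile.segments[["chrom", "start", "end", "state"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def write_profile_json(profile: CopyNumberProfile, path: str | Path) -> None:
    payload = {
        "algorithm": profile.algorithm,
        "expected_ploidy": profile.expected_ploidy,
        "segments": profile.segments.to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=float))


def write_ground_truth(cells: list[CellLibrary], path: str | Path) -> None:
    payload = {
        cell.cell_id: {
            "condition": cell.condition,
            "true_copy_numbers": None
            if cell.true_copy_numbers is None
            else [int(x) for x in cell.true_copy_numbers],
        }
        for cell in cells
    }
    Path(path).write_text(json.dumps(payload))


def read_image_channels(path: str | Path) -> dict[str, np.ndarray]:
    """Read a multi-channel TIFF written by :meth:`ImageBundle.to_tiff`."""
    import tifffile

    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    names = meta.get("channels")
    if stack.ndim == 2:
        stack = stack[None]
    if not names:
        names = [f"channel{i}" for i in range(stack.shape[0])]
    return {name: stack[i] for i, name in enumerate(names)}
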