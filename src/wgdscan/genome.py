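"""Genomic bin grids, per-cell count libraries and karyotype ground truth.

All coordinates are 0-based half-open (BED convention).  A :class:`BinGrid`
is the genomic tiling every count vector and copy-number call lives on; a
:class:`CellLibrary` is one cell's binned read counts plus condition
metadata; a :class:`KaryotypeSpec` describes a ground-truth karyotype used
by the simulator and by downstream recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import InvalidArgumentError

__all__ = ["BinGrid", "CellLibrary", "KaryotypeSpec"]


@dataclass(frozen=True)
class BinGrid:
    """An ordered, non-overlapping tiling of a genome into bins.

    Parameters
    ----------
    bins : pandas.DataFrame
        Columns ``chrom`` (str), ``start`` (int, bp), ``end`` (int, bp),
        ``gc`` (float in [0, 1]) and ``blacklisted`` (bool).  Rows must be
        sorted by (chrom, start) with ``end > start`` and no overlap within
        a chromosome.
    """

    bins: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "gc", "blacklisted"}
        missing = required - set(self.bins.columns)
        if missing:
            raise InvalidArgumentError(f"bin table missing columns: {sorted(missing)}")
        b = self.bins
        if len(b) == 0:
            raise InvalidArgumentError("bin grid is empty")
        if (b["end"] <= b["start"]).any():
            raise InvalidArgumentError("every bin must satisfy end > start")
        if ((b["gc"] < 0) | (b["gc"] > 1)).any():
            raise InvalidArgumentError("gc fractions must lie in [0, 1]")
        for _, chrom_bins in b.groupby("chrom", sort=False):
            starts = chrom_bins["start"].to_numpy()
            ends = chrom_bins["end"].to_numpy()
            if not (np.diff(starts) > 0).all():
                raise InvalidArgumentError("bins must be sorted by start within a chromosome")
            if (starts[1:] < ends[:-1]).any():
                raise InvalidArgumentError("bins overlap within a chromosome")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def widths(self) -> np.ndarray:
        """Bin widths in bp (weights for all length-weighted statistics)."""
        return (self.bins["end"] - self.bins["start"]).to_numpy()

    @property
    def blacklisted(self) -> np.ndarray:
        return self.bins["blacklisted"].to_numpy(dtype=bool)

    @property
    def gc(self) -> np.ndarray:
        return self.bins["gc"].to_numpy(dtype=float)

    @property
    def chroms(self) -> np.ndarray:
        return self.bins["chrom"].to_numpy()

    def with_blacklist(self, flags: np.ndarray) -> "BinGrid":
        """Return a copy whose blacklist is the union of current flags and *flags*."""
        flags = np.asarray(flags, dtype=bool)
        if flags.shape != (self.n_bins,):
            raise InvalidArgumentError("blacklist flag vector length must equal n_bins")
        bins = self.bins.copy()
        bins["blacklisted"] = bins["blacklisted"].to_numpy(dtype=bool) | flags
        return BinGrid(bins)

    def same_grid(self, other: "BinGrid") -> bool:
        a = self.bins[["chrom", "start", "end"]].reset_index(drop=True)
        b = other.bins[["chrom", "start", "end"]].reset_index(drop=True)
        return a.equals(b)


@dataclass
class KaryotypeSpec:
    """Ground-truth karyotype: a baseline ploidy plus aberrant intervals.

    Aberrations are ``(chrom, start_bin, end_bin, copy_number)`` tuples with
    chromosome-local, half-open bin indices.  Bins not covered by an
    aberration carry the baseline ploidy.
    """

    baseline_ploidy: int
    aberrations: list[tuple[str, int, int, int]] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        if self.baseline_ploidy < 0:
            raise InvalidArgumentError("baseline ploidy must be >= 0")
        for chrom, s, e, cn in self.aberrations:
            if e <= s or s < 0:
                raise InvalidArgumentError(f"aberration on {chrom} has empty interval [{s}, {e})")
            if cn < 0 or int(cn) != cn:
                raise InvalidArgumentError("aberration copy numbers must be integers >= 0")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e, _ in self.aberrations:
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            for (_, e0), (s1, _) in zip(ivals, ivals[1:]):
                if s1 < e0:
                    raise InvalidArgumentError(f"aberrations overlap on {chrom}")

    def copy_numbers(self, grid: BinGrid) -> np.ndarray:
        """Per-bin integer copy number on *grid* (baseline outside aberrations)."""
        cn = np.full(grid.n_bins, self.baseline_ploidy, dtype=int)
        chroms = grid.chroms
        for chrom, s, e, state in self.aberrations:
            idx = np.flatnonzero(chroms == chrom)
            if len(idx) == 0 or e > len(idx):
                raise InvalidArgumentError(
                    f"aberration {chrom}:[{s},{e}) falls outside the grid"
                )
            cn[idx[s:e]] = state
        return cn


@dataclass
class CellLibrary:
    """One cell's binned read counts plus condition metadata."""

    cell_id: str
    condition: str
    counts: np.ndarray
    grid: BinGrid
    true_copy_numbers: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.grid.n_bins,):
            raise InvalidArgumentError("count vector length must equal the number of bins")
        if (self.counts < 0).any():
            raise InvalidArgumentError("counts must be non-negative")

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())
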