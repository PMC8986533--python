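"""Karyotype-level scores and genome-wide copy-number heatmaps.

Three population readouts summarize how abnormal a set of single-cell
profiles is relative to the expected ploidy:

* per-cell **aneuploidy score**: mean over bins of |state − ploidy|;
* per-cell **aneuploid genome fraction**: length-weighted fraction of bins
  whose state differs from the ploidy;
* population **heterogeneity score**: Simpson-type diversity per bin,
  1 − Σ_s f_s² with f_s the fraction of cells in state s, averaged
  (length-weighted) over the genome.  Zero when every cell agrees at every
  bin; bounded above by 1 − 1/n_states.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._errors import GridMismatchError, InvalidArgumentError
from .cnv import CopyNumberProfile

__all__ = [
    "aneuploidy_score",
    "heterogeneity_score",
    "state_matrix",
    "plot_genome_heatmap",
]


def aneuploidy_score(profile: CopyNumberProfile, ploidy: int) -> tuple[float, float]:
    """Mean |state − ploidy| and the aneuploid genome fraction for one cell.

    Both are length-weighted over non-blacklisted bins with defined states.
    """
    states = profile.states_or_raise()
    keep = (~profile.grid.blacklisted) & (states >= 0)
    if not keep.any():
        raise InvalidArgumentError("profile has no bins with defined states")
    widths = profile.grid.widths.astype(float)
    total = widths[keep].sum()
    score = float(np.sum(widths[keep] * np.abs(states[keep] - ploidy)) / total)
    fraction = float(widths[keep & (states != ploidy)].sum() / total)
    return score, fraction


def heterogeneity_score(profiles: list[CopyNumberProfile]) -> tuple[np.ndarray, float]:
    """Per-bin Simpson diversity across cells and its genome-wide mean.

    Requires at least two profiles on a shared grid; bins where any cell is
    undefined (blacklisted) are excluded from the genome-wide mean.
    """
    if len(profiles) < 2:
        raise InvalidArgumentError("heterogeneity is undefined for fewer than 2 cells")
    grid = profiles[0].grid
    for p in profiles[1:]:
        if not p.grid.same_grid(grid):
            raise GridMismatchError("all profiles must share one bin grid")
    matrix = np.stack([p.states_or_raise() for p in profiles])  # cells x bins
    n_cells, n_bins = matrix.shape
    per_bin = np.full(n_bins, np.nan)
    defined = (matrix >= 0).all(axis=0) & ~grid.blacklisted
    for b in np.flatnonzero(defined):
        _, counts = np.unique(matrix[:, b], return_counts=True)
        f = counts / n_cells
        per_bin[b] = 1.0 - float(np.sum(f**2))
    widths = grid.widths.astype(float)
    genome_wide = float(
        np.sum(widths[defined] * per_bin[defined]) / widths[defined].sum()
    )
    return per_bin, genome_wide


def state_matrix(profiles: list[CopyNumberProfile]) -> pd.DataFrame:
    """Cells × bins integer state matrix (−1 = undefined), row order preserved."""
    if not profiles:
        raise InvalidArgumentError("no profiles given")
    grid = profiles[0].grid
    for p in profiles[1:]:
        if not p.grid.same_grid(grid):
            raise GridMismatchError("all profiles must share one bin grid")
    cols = [f"{c}:{s}-{e}" for c, s, e in grid.bins[["chrom", "start", "end"]].itertuples(index=False)]
    return pd.DataFrame(
        np.stack([p.states_or_raise() for p in profiles]),
        index=[getattr(p, "cell_id", None) or f"cell{i}" for i, p in enumerate(profiles)],
        columns=cols,
    )


def plot_genome_heatmap(
    profiles: list[CopyNumberProfile],
    output_path: str | None = None,
    max_state: int | None = None,
):
    """Render a genome-wide copy-number heatmap, one row per cell.

    Bins run in genome order along x; colors map integer states through a
    discrete colormap with a legend; row order is exactly the input order
    (no clustering).  Returns (figure, state matrix DataFrame); the matrix
    is the bit-exact test surface behind the rendering.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    matrix = state_matrix(profiles)
    data = matrix.to_numpy()
    if max_state is None:
        max_state = max(int(data.max()), 1)
    base = plt.get_cmap("coolwarm", max_state + 1)
    cmap = ListedColormap(["#bbbbbb"] + [base(i) for i in range(max_state + 1)])
    norm = BoundaryNorm(np.arange(-1.5, max_state + 1.5), cmap.N)

    grid = profiles[0].grid
    fig, ax = plt.subplots(figsize=(10, max(2, 0.25 * len(profiles))))
    ax.imshow(data, aspect="auto", interpolation="nearest", cmap=cmap, norm=norm)
    chroms = grid.chroms
    edges = np.flatnonzero(chroms[1:] != chroms[:-1]) + 0.5
    for e in edges:
        ax.axvline(e, color="black", linewidth=0.5)
    ax.set_yticks(range(len(matrix.index)))
    ax.set_yticklabels(matrix.index, fontsize=6)
    ax.set_xlabel("genomic bin")
    cbar = fig.colorbar(
        plt.cm.ScalarMappable(cmap=cmap, norm=norm),
        ax=ax,
        ticks=np.arange(-1, max_state + 1),
    )
    cbar.set_label("copy-number state (-1 = undefined)")
    fig.tight_layout()
    if output_path is not None:
        fig.savefig(output_path, dpi=150)
        plt.close(fig)
    return fig, matrix
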