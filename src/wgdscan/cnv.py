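"""Single-cell copy-number calling from binned read counts.

The pipeline mirrors standard single-cell whole-genome CNV practice:
GC-correct the raw bin counts, blacklist artifact-prone bins from control
libraries, optionally normalize G2/M libraries to a matched G1 reference,
segment the signal, and anchor segment means to integer copy-number states
under a ground-ploidy constraint (e.g. the modal state of a tetraploid
G2/M library must land in [3.5, 4.5] × 2 DNA content terms — concretely,
bounds such as (3.5, 4.5) or (7.5, 8.5) on the modal state).

Two algorithmically independent callers are provided so that their
agreement (concordance) can be used as a per-library quality filter:

* ``segment_changepoint`` — recursive binary changepoint search per
  chromosome minimizing squared error with a BIC-style penalty;
* ``segment_hmm`` — Viterbi decode of a Gaussian HMM whose emission means
  are pinned proportional to candidate copy numbers, with a sticky
  transition prior and a single deterministic parameterization (no EM, no
  random restarts).

Rounding of segment means to states is half-away-from-zero so that state
boundaries are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import (
    DegenerateInputError,
    GridMismatchError,
    InvalidArgumentError,
    PloidyConstraintError,
)
from .genome import BinGrid, CellLibrary

__all__ = [
    "CopyNumberProfile",
    "gc_correct",
    "build_blacklist",
    "normalize_to_reference",
    "segment_changepoint",
    "segment_hmm",
    "assign_integer_states",
    "call_cell",
]


def _round_half_away(x: np.ndarray | float) -> np.ndarray | float:
    """Round half away from zero (0.5 -> 1), unlike banker's rounding."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass
class CopyNumberProfile:
    """Integer copy-number states and segments for one cell.

    ``states`` is per-bin; blacklisted bins carry -1 (undefined).  Before
    :func:`assign_integer_states` runs, ``states`` is None and only the
    segmentation (with per-segment signal means) is populated.  ``segments``
    has columns chrom, start, end, start_bin, end_bin (bin-index half-open),
    mean and state.
    """

    grid: BinGrid
    segments: pd.DataFrame
    algorithm: str
    states: np.ndarray | None = None
    expected_ploidy: int | None = None
    signal: np.ndarray | None = None

    def states_or_raise(self) -> np.ndarray:
        if self.states is None:
            raise InvalidArgumentError("profile has no assigned integer states yet")
        return self.states


# --------------------------------------------------------------------------- #
# per-bin corrections
# --------------------------------------------------------------------------- #

def gc_correct(counts: np.ndarray, grid: BinGrid) -> np.ndarray:
    """Divide out a quadratic GC-bias fit, preserving the genome-wide mean.

    The count-versus-GC relationship is fitted on non-blacklisted bins with
    a degree-2 polynomial; each bin is divided by its fitted factor and the
    result rescaled so the mean over non-blacklisted bins is unchanged.
    Blacklisted bins are corrected with the same curve but excluded from the
    fit and the rescaling.
    """
    counts = np.asarray(counts, dtype=float)
    keep = ~grid.blacklisted
    if keep.sum() < 20:
        raise InvalidArgumentError("GC correction needs at least 20 non-blacklisted bins")
    if not counts[keep].any():
        raise DegenerateInputError("all-zero counts: nothing to GC-correct")
    gc = grid.gc
    coeffs = np.polyfit(gc[keep], counts[keep], deg=2)
    fitted = np.polyval(coeffs, gc)
    # Guard against a fit dipping to zero in sparsely populated GC ranges.
    floor = 0.05 * float(np.mean(fitted[keep]))
    fitted = np.maximum(fitted, max(floor, 1e-12))
    corrected = counts / fitted
    scale = counts[keep].mean() / corrected[keep].mean()
    return corrected * scale


def build_blacklist(
    control_libraries: list[CellLibrary], grid: BinGrid, mad_factor: float = 3.0
) -> BinGrid:
    """Flag bins whose mean control coverage is a median ± MAD outlier.

    A bin is blacklisted when |coverage − median| > mad_factor × MAD, where
    both statistics are over all bins' mean coverage across the control
    libraries (extreme low *or* high coverage is flagged).
    """
    if not control_libraries:
        raise InvalidArgumentError("at least one control library is required")
    for lib in control_libraries:
        if not lib.grid.same_grid(grid):
            raise GridMismatchError(f"control library {lib.cell_id} is not on the given grid")
    coverage = np.mean([lib.counts for lib in control_libraries], axis=0)
    med = float(np.median(coverage))
    mad = float(np.median(np.abs(coverage - med)))
    flags = np.abs(coverage - med) > mad_factor * mad
    return grid.with_blacklist(flags)


def normalize_to_reference(
    corrected: np.ndarray, reference: np.ndarray, grid: BinGrid
) -> np.ndarray:
    """Per-bin ratio to a matched G1 reference, median-rescaled to 1.

    G2/M libraries are analysed against the mean corrected counts of
    matched G1 libraries of the same ploidy class, which cancels residual
    position-specific coverage structure shared between phases.
    """
    corrected = np.asarray(corrected, dtype=float)
    reference = np.asarray(reference, dtype=float)
    keep = ~grid.blacklisted
    bad = keep & (reference <= 0)
    if bad.any():
        b = int(np.flatnonzero(bad)[0])
        row = grid.bins.iloc[b]
        raise InvalidArgumentError(
            f"reference is non-positive at non-blacklisted bin {b} "
            f"({row['chrom']}:{row['start']}-{row['end']})"
        )
    ratio = np.zeros_like(corrected)
    ok = reference > 0
    ratio[ok] = corrected[ok] / reference[ok]
    med = float(np.median(ratio[keep]))
    if med <= 0:
        raise DegenerateInputError("median ratio is non-positive; cannot rescale")
    return ratio / med


# --------------------------------------------------------------------------- #
# segmentation
# --------------------------------------------------------------------------- #

def _robust_sigma(x: np.ndarray) -> float:
    """Noise scale from the MAD of first differences (level-shift robust)."""
    if len(x) < 2:
        return 0.0
    d = np.diff(x)
    return float(np.median(np.abs(d - np.median(d))) / 0.6745 / np.sqrt(2.0))


def _best_interval(prefix: np.ndarray, lo: int, hi: int) -> tuple[int, int, float]:
    """Best sub-interval [i, j) to split out of [lo, hi) by SSE gain.

    Testing an interval (two changepoints at once) rather than a single
    split is what lets an interior bump flanked by equal levels be found —
    the circular-binary-segmentation idea.  Single splits are the special
    cases i == lo or j == hi.  Exhaustive O(n²) scan.
    """
    n = hi - lo
    total_sum = prefix[hi] - prefix[lo]
    best_gain, best_i, best_j = -np.inf, lo, hi
    for i in range(lo, hi):
        j_hi = hi if i > lo else hi - 1  # (lo, hi) itself is not a split
        if j_hi <= i:
            continue
        js = np.arange(i + 1, j_hi + 1)
        n_in = js - i
        s_in = prefix[js] - prefix[i]
        n_out = n - n_in
        diff = s_in / n_in - (total_sum - s_in) / n_out
        gains = (n_in * n_out / n) * diff**2
        k = int(np.argmax(gains))
        if gains[k] > best_gain:
            best_gain, best_i, best_j = float(gains[k]), i, int(js[k])
    return best_i, best_j, best_gain


def _binary_segment(x: np.ndarray, threshold: float) -> list[int]:
    """Recursive interval segmentation; returns sorted interior changepoints."""
    prefix = np.concatenate([[0.0], np.cumsum(x)])
    changepoints: set[int] = set()
    stack = [(0, len(x))]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2:
            continue
        i, j, gain = _best_interval(prefix, lo, hi)
        if gain > threshold:
            if i > lo:
                changepoints.add(i)
                stack.append((lo, i))
            if j < hi:
                changepoints.add(j)
                stack.append((j, hi))
            stack.append((i, j))
    return sorted(changepoints)


def _segments_from_boundaries(
    grid: BinGrid, signal: np.ndarray, boundaries: list[tuple[int, int]]
) -> pd.DataFrame:
    rows = []
    chroms = grid.chroms
    starts = grid.bins["start"].to_numpy()
    ends = grid.bins["end"].to_numpy()
    for lo, hi in boundaries:
        rows.append(
            {
                "chrom": chroms[lo],
                "start": int(starts[lo]),
                "end": int(ends[hi - 1]),
                "start_bin": lo,
                "end_bin": hi,
                "mean": float(signal[lo:hi].mean()),
                "state": -1,
            }
        )
    return pd.DataFrame(rows)


def segment_changepoint(
    signal: np.ndarray, grid: BinGrid, penalty: float = 6.0
) -> CopyNumberProfile:
    """Piecewise-constant segmentation by penalized recursive binary splitting.

    Per chromosome, a split is accepted when its squared-error gain exceeds
    ``penalty × σ² × log n`` with σ estimated robustly from first
    differences — a BIC-style complexity charge.  Doubling the penalty can
    only prune the (nested) split tree, so segment counts are monotone
    non-increasing in the penalty.  Deterministic for fixed input.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape != (grid.n_bins,):
        raise GridMismatchError("signal length must equal the number of bins")
    if penalty < 0:
        raise InvalidArgumentError("penalty must be >= 0")
    sigma = _robust_sigma(signal[~grid.blacklisted])
    boundaries: list[tuple[int, int]] = []
    chroms = grid.chroms
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        lo0, hi0 = int(idx[0]), int(idx[-1]) + 1
        x = signal[lo0:hi0].copy()
        # Interpolate over blacklisted bins so they do not force breakpoints.
        bl = grid.blacklisted[lo0:hi0]
        if bl.any() and (~bl).any():
            x[bl] = np.interp(np.flatnonzero(bl), np.flatnonzero(~bl), x[~bl])
        n = len(x)
        threshold = penalty * sigma**2 * np.log(max(n, 2))
        cps = _binary_segment(x, threshold) if n >= 2 else []
        edges = [0] + cps + [n]
        for a, b in zip(edges, edges[1:]):
            boundaries.append((lo0 + a, lo0 + b))
    segments = _segments_from_boundaries(grid, signal, boundaries)
    return CopyNumberProfile(grid=grid, segments=segments, algorithm="changepoint", signal=signal)


def _estimate_per_copy_level(signal: np.ndarray, max_state: int, ploidy: int | None) -> float:
    med = float(np.median(signal))
    if med <= 0:
        raise DegenerateInputError("median signal is non-positive; cannot anchor HMM means")
    if ploidy is not None:
        return med / ploidy
    # Try each candidate modal state; keep the per-copy level whose state
    # lattice explains the signal best (smallest distance to nearest level).
    best_level, best_cost = med, np.inf
    for m in range(1, max_state + 1):
        level = med / m
        states = np.clip(_round_half_away(signal / level), 0, max_state)
        cost = float(np.mean((signal - states * level) ** 2)) + 1e-9 * m
        if cost < best_cost:
            best_cost, best_level = cost, level
    return best_level


def segment_hmm(
    signal: np.ndarray,
    grid: BinGrid,
    max_state: int = 10,
    ploidy: int | None = None,
    self_transition: float = 0.99,
) -> CopyNumberProfile:
    """Viterbi segmentation with copy-number-proportional emission means.

    States 0..max_state emit Gaussians with means pinned at state × d (d a
    robust per-copy level: median signal over the modal state, searched if
    ``ploidy`` is not given) and a shared noise scale estimated from first
    differences.  The sticky transition prior (self-transition probability
    ``self_transition``) discourages single-bin flickers.  State indices
    are mean-ordered by construction, so label permutation cannot occur.
    No EM is run: the parameterization is closed-form and deterministic.
    """
    from hmmlearn import hmm as _hmm

    signal = np.asarray(signal, dtype=float)
    if signal.shape != (grid.n_bins,):
        raise GridMismatchError("signal length must equal the number of bins")
    if ploidy is not None and max_state < ploidy + 2:
        raise InvalidArgumentError("max_state must be at least ploidy + 2")
    keep = ~grid.blacklisted
    level = _estimate_per_copy_level(signal[keep], max_state, ploidy)
    sigma = max(_robust_sigma(signal[keep]), 1e-6 * level)

    n_states = max_state + 1
    model = _hmm.GaussianHMM(n_components=n_states, covariance_type="spherical", init_params="")
    model.startprob_ = np.full(n_states, 1.0 / n_states)
    off = (1.0 - self_transition) / (n_states - 1)
    model.transmat_ = np.full((n_states, n_states), off)
    np.fill_diagonal(model.transmat_, self_transition)
    means = level * np.arange(n_states, dtype=float)
    means[0] = 0.05 * level  # state 0 emits near-zero, not exactly zero
    model.means_ = means.reshape(-1, 1)
    model.covars_ = np.full(n_states, sigma**2)

    x = signal.copy()
    if grid.blacklisted.any() and keep.any():
        x[~keep] = np.interp(np.flatnonzero(~keep), np.flatnonzero(keep), x[keep])

    chroms = grid.chroms
    boundaries: list[tuple[int, int]] = []
    path = np.empty(grid.n_bins, dtype=int)
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        lo0, hi0 = int(idx[0]), int(idx[-1]) + 1
        path[lo0:hi0] = model.predict(x[lo0:hi0].reshape(-1, 1))
        edges = [lo0] + [
            int(i) for i in range(lo0 + 1, hi0) if path[i] != path[i - 1]
        ] + [hi0]
        for a, b in zip(edges, edges[1:]):
            boundaries.append((a, b))
    segments = _segments_from_boundaries(grid, signal, boundaries)
    return CopyNumberProfile(grid=grid, segments=segments, algorithm="hmm", signal=signal)


# --------------------------------------------------------------------------- #
# integer state assignment under a ground-ploidy constraint
# --------------------------------------------------------------------------- #

def assign_integer_states(
    profile: CopyNumberProfile,
    ploidy_bounds: tuple[float, float],
    per_copy_depth: float | None = None,
) -> CopyNumberProfile:
    """Anchor segment means to integer states with the modal state in bounds.

    A global per-copy scale s is grid-searched so that the length-weighted
    modal integer state (the ground ploidy) lies within ``ploidy_bounds``;
    among feasible scales the one minimizing the length-weighted squared
    anchoring error Σ w (mean − state·s)² wins.  Segment states are
    round-half-away-from-zero of mean/s.  Raises
    :class:`PloidyConstraintError` when no scale satisfies the bounds.
    """
    lo, hi = ploidy_bounds
    if not lo < hi:
        raise InvalidArgumentError("ploidy_bounds must satisfy min < max")
    seg = profile.segments
    if seg.empty:
        raise InvalidArgumentError("profile has no segments")
    means = seg["mean"].to_numpy(dtype=float)
    weights = (seg["end_bin"] - seg["start_bin"]).to_numpy(dtype=float)

    if per_copy_depth is not None and per_copy_depth > 0:
        anchor = per_copy_depth * 0.5 * (lo + hi)
    else:
        order = np.argsort(means)
        cum = np.cumsum(weights[order])
        anchor = float(means[order][np.searchsorted(cum, cum[-1] / 2.0)])
    if anchor <= 0:
        raise DegenerateInputError("non-positive anchoring level; cannot assign states")

    # Candidate scales are screened by self-consistency of the ground state:
    # in a single cell every bin carries an integer copy number, so the
    # modal state's own mean must re-derive its integer value
    # (|mean_modal / s − modal| small).  Among scales within the tolerance
    # the one whose ground ploidy sits nearest the nominal bounds centre
    # wins (pure anchoring error can lock onto a shifted lattice when the
    # signal carries a smooth multiplicative bias — exactly the artifact
    # the wavy-pattern filter downstream must still be able to see).
    self_tol = 0.1
    center = 0.5 * (lo + hi)
    candidates: list[tuple[float, float, float, float, np.ndarray]] = []
    for p in np.arange(lo, hi + 1e-12, 0.005):
        s = anchor / p
        states = np.maximum(_round_half_away(means / s), 0.0)
        uniq, inv = np.unique(states, return_inverse=True)
        mode_weights = np.bincount(inv, weights=weights)
        modal = float(uniq[int(np.argmax(mode_weights))])  # ties -> lowest state
        if not (lo <= modal <= hi):
            continue
        on_modal = states == modal
        mean_modal = float(np.average(means[on_modal], weights=weights[on_modal]))
        self_dev = abs(mean_modal / s - modal)
        sse = float(np.sum(weights * (means - states * s) ** 2))
        candidates.append((p, self_dev, sse, s, states.astype(int)))
    if not candidates:
        raise PloidyConstraintError(
            f"no per-copy scale places the modal state inside {ploidy_bounds}"
        )
    within = [c for c in candidates if c[1] <= self_tol]
    if within:
        _, _, _, scale, states = min(
            within, key=lambda c: (abs(c[0] - center), round(c[1], 3), c[2])
        )
    else:
        _, _, _, scale, states = min(candidates, key=lambda c: (round(c[1], 3), c[2]))

    segments = seg.copy()
    segments["state"] = states
    per_bin = np.full(profile.grid.n_bins, -1, dtype=int)
    for row in segments.itertuples(index=False):
        per_bin[row.start_bin : row.end_bin] = row.state
    per_bin[profile.grid.blacklisted] = -1
    uniq, inv = np.unique(states, return_inverse=True)
    modal_state = int(uniq[int(np.argmax(np.bincount(inv, weights=weights)))])
    return CopyNumberProfile(
        grid=profile.grid,
        segments=segments,
        algorithm=profile.algorithm,
        states=per_bin,
        expected_ploidy=modal_state,
        signal=profile.signal,
    )


# --------------------------------------------------------------------------- #
# convenience pipeline
# --------------------------------------------------------------------------- #

def call_cell(
    library: CellLibrary,
    ploidy_bounds: tuple[float, float],
    reference: np.ndarray | None = None,
    penalty: float = 6.0,
    max_state: int | None = None,
) -> tuple[CopyNumberProfile, CopyNumberProfile]:
    """Run the full per-cell pipeline with both callers.

    GC-correct, optionally normalize to a G1 reference (the ratio signal is
    rescaled back to corrected-count units so downstream read-depth rules
    keep their meaning), segment with the changepoint and HMM callers, and
    anchor both to integer states under ``ploidy_bounds``.  Returns
    (changepoint profile, hmm profile).
    """
    corrected = gc_correct(library.counts, library.grid)
    signal = corrected
    if reference is not None:
        keep = ~library.grid.blacklisted
        ratio = normalize_to_reference(corrected, reference, library.grid)
        signal = ratio * corrected[keep].mean()
    hi_ploidy = ploidy_bounds[1]
    if max_state is None:
        max_state = int(np.ceil(hi_ploidy)) + 3
    central = int(round(0.5 * (ploidy_bounds[0] + ploidy_bounds[1])))
    prof_cp = segment_changepoint(signal, library.grid, penalty=penalty)
    prof_hmm = segment_hmm(signal, library.grid, max_state=max_state, ploidy=central)
    prof_cp = assign_integer_states(prof_cp, ploidy_bounds)
    prof_hmm = assign_integer_states(prof_hmm, ploidy_bounds)
    return prof_cp, prof_hmm
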