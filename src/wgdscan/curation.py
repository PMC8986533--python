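"""Library-level quality curation for single-cell copy-number profiles.

Three filters decide whether a library is kept:

1. **Concordance** — the two independent callers must agree on at least
   95% of the genome for diploid (2n) libraries, or 90% for polyploid
   (4n/8n) libraries, length-weighted over non-blacklisted bins.
2. **Read depth** — a library needs on average at least 10 reads per
   chromosome copy per bin (a bin called 2-somy needs 20 reads, 3-somy 30,
   etc.), i.e. roughly 60,000 total reads for a 2n G1 genome on ~3,000
   1-Mb bins, up to 240,000 for an 8n G2/M genome.
3. **Wavy pattern** — smooth coverage waves create spurious states one copy
   above or below the expected ploidy whose read-count means sit too close
   to the expected state's mean.  For every state covering more than 1% of
   the genome, a non-rounded copy number

       non_rounded = mean_state / (mean_expected / cn_expected)

   is computed; a deviation of more than 0.25 copies from the integer
   state (for 5-somy: a value below 4.75 or above 5.25) discards the
   library.

Boundary conventions are literal: exactly 10 reads per copy passes,
exactly 0.25 deviation passes, exactly 1% genome fraction does not trigger
the wavy evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._errors import DegenerateInputError, GridMismatchError, InvalidArgumentError
from .cnv import CopyNumberProfile
from .genome import CellLibrary

__all__ = [
    "StateStatistics",
    "CurationReport",
    "CurationThresholds",
    "concordance",
    "per_bin_read_threshold",
    "min_required_reads",
    "read_depth_filter",
    "non_rounded_copy_number",
    "wavy_pattern_filter",
    "state_statistics",
    "curate_library",
]


@dataclass(frozen=True)
class CurationThresholds:
    """All curation cut-offs in one place (defaults are the published rules)."""

    concordance_2n: float = 0.95
    concordance_poly: float = 0.90
    min_reads_per_copy: float = 10.0
    wavy_trigger_fraction: float = 0.01
    wavy_max_deviation: float = 0.25
    wavy_armed: bool = True


@dataclass
class StateStatistics:
    """Per-state means and genome fractions of a called profile.

    ``mean_by_state`` maps each observed copy-number state to the mean
    corrected count over its bins; ``fraction_by_state`` to its
    length-weighted genome fraction (non-blacklisted bins only; fractions
    sum to 1).  ``expected_state`` is the library's ground ploidy and
    ``mean_expected`` the mean corrected count of bins called at it.
    """

    mean_by_state: dict[int, float]
    fraction_by_state: dict[int, float]
    n_bins_by_state: dict[int, int]
    expected_state: int
    mean_expected: float


def state_statistics(profile: CopyNumberProfile) -> StateStatistics:
    """Compute :class:`StateStatistics` from a profile with assigned states.

    Means are over the profile's (GC-corrected) signal; fractions are
    bin-length-weighted over non-blacklisted bins.
    """
    states = profile.states_or_raise()
    if profile.signal is None:
        raise InvalidArgumentError("profile carries no signal to average per state")
    if profile.expected_ploidy is None:
        raise InvalidArgumentError("profile has no expected ploidy (run state assignment)")
    keep = (states >= 0) & ~profile.grid.blacklisted
    widths = profile.grid.widths.astype(float)
    total = widths[keep].sum()
    mean_by_state: dict[int, float] = {}
    fraction_by_state: dict[int, float] = {}
    n_bins_by_state: dict[int, int] = {}
    for s in np.unique(states[keep]):
        sel = keep & (states == s)
        mean_by_state[int(s)] = float(profile.signal[sel].mean())
        fraction_by_state[int(s)] = float(widths[sel].sum() / total)
        n_bins_by_state[int(s)] = int(sel.sum())
    expected = int(profile.expected_ploidy)
    if expected not in mean_by_state:
        raise DegenerateInputError(
            f"no bins called at the expected state {expected}; cannot anchor statistics"
        )
    return StateStatistics(
        mean_by_state=mean_by_state,
        fraction_by_state=fraction_by_state,
        n_bins_by_state=n_bins_by_state,
        expected_state=expected,
        mean_expected=mean_by_state[expected],
    )


def concordance(a: CopyNumberProfile, b: CopyNumberProfile) -> float:
    """Length-weighted fraction of the genome on which two callers agree.

    Computed over non-blacklisted bins with defined states in both
    profiles; symmetric in its arguments.
    """
    if not a.grid.same_grid(b.grid):
        raise GridMismatchError("concordance requires profiles on the same bin grid")
    sa = a.states_or_raise()
    sb = b.states_or_raise()
    keep = (~a.grid.blacklisted) & (sa >= 0) & (sb >= 0)
    widths = a.grid.widths.astype(float)
    total = widths[keep].sum()
    if total == 0:
        raise DegenerateInputError("no bins with defined states in both profiles")
    return float(widths[keep & (sa == sb)].sum() / total)


def per_bin_read_threshold(state: int, min_reads_per_copy: float = 10.0) -> float:
    """Minimum mean reads per bin for a bin called at ``state`` copies.

    10 reads per chromosome copy: 2-somy needs 20 reads, 3-somy 30, etc.
    """
    if state < 0:
        raise InvalidArgumentError("copy-number state must be >= 0")
    return min_reads_per_copy * state


def min_required_reads(ploidy: int, n_bins: int, min_reads_per_copy: float = 10.0) -> float:
    """Minimum total reads for a library: 10 × ploidy × n_bins.

    Roughly 60,000 for a diploid G1 genome and 240,000 for an octoploid
    G2/M genome on ~3,000 one-megabase bins.
    """
    if ploidy < 1 or n_bins < 1:
        raise InvalidArgumentError("ploidy and n_bins must be >= 1")
    return min_reads_per_copy * ploidy * n_bins


def read_depth_filter(
    library: CellLibrary,
    profile: CopyNumberProfile,
    min_reads_per_copy: float = 10.0,
) -> tuple[bool, float]:
    """Pass iff the mean of count/state over called bins is >= the minimum.

    Bins with state 0 (and blacklisted/undefined bins) are excluded from
    the mean; the boundary is inclusive (exactly 10 reads per copy passes).
    Returns (pass flag, observed mean reads per copy per bin).
    """
    if not library.grid.same_grid(profile.grid):
        raise GridMismatchError("profile is not on the library's grid")
    states = profile.states_or_raise()
    keep = (~library.grid.blacklisted) & (states > 0)
    if not keep.any():
        raise DegenerateInputError("no bins with positive copy-number state")
    observed = float(np.mean(library.counts[keep] / states[keep]))
    return observed >= min_reads_per_copy, observed


def non_rounded_copy_number(mean_state: float, mean_expected: float, cn_expected: int) -> float:
    """Continuous re-estimate of a called state's copy number.

    non_rounded = mean_state / (mean_expected / cn_expected); e.g. for a
    5-somy call in a 4n sample, Mean_5-somy / (Mean_4-somy / 4).
    """
    if cn_expected < 1:
        raise InvalidArgumentError("expected copy number must be >= 1")
    if not mean_expected > 0:
        raise InvalidArgumentError("mean of the expected state must be > 0")
    return mean_state / (mean_expected / cn_expected)


def wavy_pattern_filter(
    stats: StateStatistics,
    genome_fraction_trigger: float = 0.01,
    max_deviation: float = 0.25,
) -> tuple[list[tuple[int, float, float, bool]], bool]:
    """Evaluate non-rounded copy numbers for abundant non-expected states.

    Every state other than the expected one whose genome fraction strictly
    exceeds ``genome_fraction_trigger`` is evaluated; the library fails iff
    any evaluated state deviates by strictly more than ``max_deviation``
    copies from its integer value (for 5-somy with the default 0.25: below
    4.75 or above 5.25).  Returns ([(state, fraction, non_rounded, pass)],
    overall pass).
    """
    evaluations: list[tuple[int, float, float, bool]] = []
    overall = True
    for s, frac in sorted(stats.fraction_by_state.items()):
        if s == stats.expected_state or frac <= genome_fraction_trigger:
            continue
        nr = non_rounded_copy_number(
            stats.mean_by_state[s], stats.mean_expected, stats.expected_state
        )
        ok = abs(nr - s) <= max_deviation
        evaluations.append((s, frac, nr, ok))
        overall = overall and ok
    return evaluations, overall


@dataclass
class CurationReport:
    """Keep/discard decision for one library with every filter's evidence."""

    cell_id: str
    concordance: float
    concordance_threshold: float
    concordance_pass: bool
    read_depth_pass: bool
    mean_reads_per_copy: float
    wavy_evaluations: list[tuple[int, float, float, bool]] = field(default_factory=list)
    wavy_pass: bool = True
    wavy_armed: bool = True
    keep: bool = False
    reasons: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "concordance": self.concordance,
            "concordance_threshold": self.concordance_threshold,
            "concordance_pass": self.concordance_pass,
            "read_depth_pass": self.read_depth_pass,
            "mean_reads_per_copy": self.mean_reads_per_copy,
            "wavy_evaluations": [
                {"state": s, "genome_fraction": f, "non_rounded": nr, "pass": ok}
                for s, f, nr, ok in self.wavy_evaluations
            ],
            "wavy_pass": self.wavy_pass,
            "wavy_armed": self.wavy_armed,
            "keep": self.keep,
            "reasons": self.reasons,
        }

    @property
    def worst_deviation(self) -> float:
        if not self.wavy_evaluations:
            return 0.0
        return max(abs(nr - s) for s, _, nr, _ in self.wavy_evaluations)


def curate_library(
    library: CellLibrary,
    profile_a: CopyNumberProfile,
    profile_b: CopyNumberProfile,
    ploidy_class: int,
    thresholds: CurationThresholds = CurationThresholds(),
) -> CurationReport:
    """Apply concordance, read-depth and wavy-pattern filters to one library.

    ``ploidy_class`` (2, 4 or 8) selects the concordance threshold (0.95
    for 2n, 0.90 for polyploid classes).  All filters are pure predicates,
    so the keep/discard decision is independent of evaluation order; the
    report records each decision with its evidence.  The read-depth filter
    uses ``profile_a`` (the reported profile); the wavy-pattern filter is
    evaluated on both profiles and discards when either fails.
    """
    if ploidy_class not in (2, 4, 8):
        raise InvalidArgumentError("ploidy_class must be one of 2, 4, 8")
    conc_threshold = (
        thresholds.concordance_2n if ploidy_class == 2 else thresholds.concordance_poly
    )
    conc = concordance(profile_a, profile_b)
    conc_pass = conc >= conc_threshold

    depth_pass, observed_depth = read_depth_filter(
        library, profile_a, thresholds.min_reads_per_copy
    )

    wavy_evals: list[tuple[int, float, float, bool]] = []
    wavy_pass = True
    if thresholds.wavy_armed:
        # Both callers' profiles are evaluated: a smooth wave can slip one
        # caller onto a shifted state lattice where its non-rounded values
        # look clean, while the other caller still exposes the artifact.
        # Any single failing state on either profile discards the library.
        for profile in (profile_a, profile_b):
            stats = state_statistics(profile)
            evals, ok = wavy_pattern_filter(
                stats, thresholds.wavy_trigger_fraction, thresholds.wavy_max_deviation
            )
            wavy_evals.extend(evals)
            wavy_pass = wavy_pass and ok

    reasons = []
    if not conc_pass:
        reasons.append(
            f"concordance {conc:.3f} below threshold {conc_threshold:.2f}"
        )
    if not depth_pass:
        reasons.append(
            f"read-depth: {observed_depth:.1f} reads per copy per bin "
            f"below {thresholds.min_reads_per_copy:g}"
        )
    if not wavy_pass:
        worst = max(abs(nr - s) for s, _, nr, ok in wavy_evals if not ok)
        reasons.append(
            f"wavy-pattern: non-rounded deviation {worst:.2f} exceeds "
            f"{thresholds.wavy_max_deviation:g}"
        )

    return CurationReport(
        cell_id=library.cell_id,
        concordance=conc,
        concordance_threshold=conc_threshold,
        concordance_pass=conc_pass,
        read_depth_pass=depth_pass,
        mean_reads_per_copy=observed_depth,
        wavy_evaluations=wavy_evals,
        wavy_pass=wavy_pass,
        wavy_armed=thresholds.wavy_armed,
        keep=conc_pass and depth_pass and wavy_pass,
        reasons=reasons,
    )
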