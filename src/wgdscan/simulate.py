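"""Synthetic inputs with known ground truth for all three analysis tracks.

Three generators mirror the data the analyses consume:

* binned single-cell read counts for 2n/4n/8n karyotypes with aneuploid
  segments, GC bias, negative-binomial noise and a smooth multiplicative
  "wavy" artifact (the coverage aberration that produces spurious ±1
  copy-number calls);
* DNA-combing fiber tables with configurable fork speed, second-pulse
  stalling and exponential inter-origin spacing;
* 2D fluorescence fields of elliptical nuclei with Gaussian damage foci and
  an optional marker channel sharing a controlled fraction of spot centres.

Every generator is a pure function of its seed: identical seed and
configuration give bitwise-identical output, and the returned ground truth
is sufficient to compute the ideal answer of every downstream operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import InvalidArgumentError
from .fibers import CLDU, IDU, UNLABELED, FiberSegment, FiberSet, FiberTrack
from .genome import BinGrid, CellLibrary, KaryotypeSpec

__all__ = [
    "SimulationConfig",
    "ImageBundle",
    "make_toy_genome",
    "random_karyotype",
    "simulate_cell_counts",
    "simulate_population",
    "simulate_fibers",
    "simulate_focus_image",
]


# --------------------------------------------------------------------------- #
# single-cell counts
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class SimulationConfig:
    """Noise and bias model for simulated single-cell read counts.

    The expected count of bin *b* with true copy number CN(b) is

        depth_per_copy × CN(b) × f(gc_b) × (1 + A · sin(2π b / period))

    with ``f`` the quadratic GC-bias factor and A the wavy-artifact
    amplitude.  Counts are negative binomial with variance =
    ``nb_dispersion`` × mean (Poisson in the dispersion → 1 limit).

    Defaults model a clean library at 10 reads per bin per chromosome copy
    with mild overdispersion (1.3, typical of sparse single-cell whole-
    genome bins) and no GC or wave bias.
    """

    depth_per_copy: float = 10.0
    nb_dispersion: float = 1.3
    gc_coefficients: tuple[float, float, float] = (1.0, 0.0, 0.0)
    wave_amplitude: float = 0.0
    wave_period: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.depth_per_copy > 0:
            raise InvalidArgumentError("depth_per_copy must be > 0")
        if self.nb_dispersion < 1.0:
            raise InvalidArgumentError("nb_dispersion must be >= 1 (variance inflation)")
        if not (0.0 <= self.wave_amplitude < 1.0):
            raise InvalidArgumentError("wave_amplitude must lie in [0, 1)")
        if not self.wave_period > 0:
            raise InvalidArgumentError("wave_period must be > 0")


def make_toy_genome(n_chromosomes: int, bins_per_chromosome: int, bin_width: int) -> BinGrid:
    """A contiguous fixed-width tiling standing in for a 1-Mb binned genome.

    GC content follows a seed-free smooth sinusoid over the global bin index,
    confined to [0.3, 0.6]; no bins are blacklisted.
    """
    if n_chromosomes < 1 or bins_per_chromosome < 1 or bin_width < 1:
        raise InvalidArgumentError("all toy-genome arguments must be >= 1")
    n = n_chromosomes * bins_per_chromosome
    idx = np.arange(n)
    gc = 0.45 + 0.15 * np.sin(2.0 * np.pi * idx / 311.0)
    local = idx % bins_per_chromosome
    bins = pd.DataFrame(
        {
            "chrom": [f"chr{c + 1}" for c in idx // bins_per_chromosome],
            "start": local * bin_width,
            "end": (local + 1) * bin_width,
            "gc": gc,
            "blacklisted": False,
        }
    )
    return BinGrid(bins)


def _expected_counts(grid: BinGrid, copy_numbers: np.ndarray, config: SimulationConfig) -> np.ndarray:
    c0, c1, c2 = config.gc_coefficients
    gc = grid.gc
    gc_factor = c0 + c1 * gc + c2 * gc**2
    if (gc_factor <= 0).any():
        raise InvalidArgumentError("gc_coefficients produce non-positive bias factors")
    b = np.arange(grid.n_bins)
    wave = 1.0 + config.wave_amplitude * np.sin(2.0 * np.pi * b / config.wave_period)
    return config.depth_per_copy * copy_numbers * gc_factor * wave


def _draw_counts(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    counts = np.zeros_like(mean, dtype=np.int64)
    pos = mean > 0
    if dispersion <= 1.0 + 1e-9:
        counts[pos] = rng.poisson(mean[pos])
    else:
        # var = phi * mu  =>  NB(n = mu/(phi-1), p = 1/phi)
        n = mean[pos] / (dispersion - 1.0)
        counts[pos] = rng.negative_binomial(n, 1.0 / dispersion)
    return counts


def simulate_cell_counts(
    grid: BinGrid,
    karyotype: KaryotypeSpec,
    config: SimulationConfig,
    cell_id: str = "cell0",
    _rng: np.random.Generator | None = None,
) -> CellLibrary:
    """Simulate one cell's binned read counts; ground-truth CN is retained."""
    copy_numbers = karyotype.copy_numbers(grid)
    mean = _expected_counts(grid, copy_numbers, config)
    rng = _rng if _rng is not None else np.random.default_rng(config.seed)
    counts = _draw_counts(mean, config.nb_dispersion, rng)
    return CellLibrary(
        cell_id=cell_id,
        condition=karyotype.label,
        counts=counts,
        grid=grid,
        true_copy_numbers=copy_numbers,
    )


def simulate_population(
    grid: BinGrid,
    specs: list[tuple[KaryotypeSpec, int]],
    config: SimulationConfig,
) -> list[CellLibrary]:
    """Simulate a mixed population: ``n`` cells per karyotype spec.

    Per-cell seeds are derived deterministically from ``config.seed`` so the
    whole population is reproducible while cells stay independent.
    """
    if not specs:
        raise InvalidArgumentError("at least one (karyotype, count) spec is required")
    total = sum(n for _, n in specs)
    children = np.random.SeedSequence(config.seed).spawn(total)
    cells: list[CellLibrary] = []
    k = 0
    for spec, n in specs:
        if n < 0:
            raise InvalidArgumentError("cell counts must be >= 0")
        for i in range(n):
            rng = np.random.default_rng(children[k])
            cells.append(
                simulate_cell_counts(
                    grid, spec, config, cell_id=f"{spec.label or 'cell'}_{i}", _rng=rng
                )
            )
            k += 1
    return cells


def random_karyotype(
    grid: BinGrid,
    baseline_ploidy: int,
    n_aberrations: int,
    seed: int | np.random.Generator = 0,
    min_length: int = 5,
    max_length: int = 80,
    label: str = "",
) -> KaryotypeSpec:
    """Draw a karyotype with random non-overlapping ±1-copy aberrations.

    Aberration intervals (``min_length``–``max_length`` bins) are placed
    uniformly without overlap; each gains or loses one copy relative to
    baseline with equal probability — the over-/under-replicated segment
    pattern seen in G2/M cells after an unscheduled genome doubling.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = pd.unique(grid.chroms)
    sizes = {c: int((grid.chroms == c).sum()) for c in chroms}
    aberrations: list[tuple[str, int, int, int]] = []
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    attempts = 0
    while len(aberrations) < n_aberrations:
        if attempts > 200 * max(n_aberrations, 1):
            raise InvalidArgumentError("could not place the requested aberrations")
        attempts += 1
        chrom = str(rng.choice(chroms))
        length = int(rng.integers(min_length, max_length + 1))
        if length >= sizes[chrom]:
            continue
        start = int(rng.integers(0, sizes[chrom] - length))
        end = start + length
        if any(start < e and s < end for s, e in taken[chrom]):
            continue
        state = baseline_ploidy + int(rng.choice([-1, 1]))
        if state < 0:
            continue
        taken[chrom].append((start, end))
        aberrations.append((chrom, start, end, state))
    return KaryotypeSpec(baseline_ploidy, aberrations, label=label)


# --------------------------------------------------------------------------- #
# fibers
# --------------------------------------------------------------------------- #

def simulate_fibers(
    n_fibers: int,
    speed_mean: float = 1.5,
    speed_sd: float = 0.3,
    pulse_minutes: float = 30.0,
    stall_probability: float = 0.0,
    iod_mean: float = 200.0,
    stretch: float = 2.0,
    seed: int = 0,
    mean_extra_origins: float = 1.0,
) -> FiberSet:
    """Simulate combed fibers with CldU→IdU forks and exponential IODs.

    Per fork, one speed is drawn per pulse from Normal(speed_mean, speed_sd)
    truncated > 0; with probability ``stall_probability`` the second-pulse
    (IdU) speed is additionally multiplied by a stall factor uniform in
    [0, 0.5].  Each fiber carries 1 + Poisson(``mean_extra_origins``)
    origins spaced Exponential(``iod_mean``) kb apart; each origin
    contributes one fork.  Track lengths are stored in µm via ``stretch``
    (kb/µm).
    """
    if n_fibers < 0:
        raise InvalidArgumentError("n_fibers must be >= 0")
    if not speed_mean > 0 or not pulse_minutes > 0:
        raise InvalidArgumentError("speed_mean and pulse_minutes must be > 0")
    if not stretch > 0:
        raise InvalidArgumentError("stretch must be > 0")
    if not (0.0 <= stall_probability <= 1.0):
        raise InvalidArgumentError("stall_probability must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    tracks: list[FiberTrack] = []
    origins: dict[str, list[float]] = {}
    true_speeds: list[float] = []

    def draw_speed() -> float:
        while True:
            v = rng.normal(speed_mean, speed_sd)
            if v > 0:
                return v

    for i in range(n_fibers):
        fiber_id = f"fiber{i}"
        n_origins = 1 + int(rng.poisson(mean_extra_origins))
        spacings = rng.exponential(iod_mean, size=n_origins)
        positions = np.cumsum(spacings)
        origins[fiber_id] = [float(p) for p in positions]
        segments: list[FiberSegment] = []
        for j in range(n_origins):
            v1 = draw_speed()
            v2 = draw_speed()
            if rng.random() < stall_probability:
                v2 *= rng.uniform(0.0, 0.5)
            true_speeds.extend([v1, v2])
            cldu_um = v1 * pulse_minutes / stretch
            idu_um = v2 * pulse_minutes / stretch
            if segments:
                gap_kb = max(float(rng.exponential(iod_mean / 4.0)), 1.0)
                segments.append(FiberSegment(UNLABELED, gap_kb / stretch))
            segments.append(FiberSegment(CLDU, cldu_um))
            segments.append(FiberSegment(IDU, idu_um))
        tracks.append(FiberTrack(fiber_id, segments))

    return FiberSet(
        tracks=tracks,
        origins=origins,
        pulse_minutes=pulse_minutes,
        stretch_kb_per_um=stretch,
        ground_truth={
            "speed_mean": speed_mean,
            "speed_sd": speed_sd,
            "stall_probability": stall_probability,
            "iod_mean": iod_mean,
            "pulse_speeds": true_speeds,
        },
    )


# --------------------------------------------------------------------------- #
# images
# --------------------------------------------------------------------------- #

@dataclass
class ImageBundle:
    """Synthetic fluorescence field plus its complete ground truth.

    ``channels`` holds 2D float arrays keyed ``"dna"``, ``"damage"`` and
    optionally ``"marker"``; ``nuclei_labels`` is the ground-truth label
    image (0 = background); ``damage_foci``/``marker_foci`` list planted
    spot centres (row, col) per nucleus.
    """

    channels: dict[str, np.ndarray]
    nuclei_labels: np.ndarray
    nuclei: list[dict]
    damage_foci: list[np.ndarray]
    marker_foci: list[np.ndarray] = field(default_factory=list)
    shared_foci_per_nucleus: list[int] = field(default_factory=list)

    def to_tiff(self, path) -> None:
        import tifffile

        names = [k for k in ("dna", "damage", "marker") if k in self.channels]
        stack = np.stack([self.channels[k].astype(np.float32) for k in names])
        tifffile.imwrite(
            path,
            stack,
            photometric="minisblack",
            planarconfig="separate",
            metadata={"axes": "CYX", "channels": names},
        )


def _add_gaussian_spots(img: np.ndarray, centres: np.ndarray, sigma: float, amplitude: float) -> None:
    h, w = img.shape
    half = int(np.ceil(4 * sigma))
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    kernel = amplitude * np.exp(-(yy**2 + xx**2) / (2.0 * sigma**2))
    for r, c in centres:
        r, c = int(round(r)), int(round(c))
        r0, r1 = max(r - half, 0), min(r + half + 1, h)
        c0, c1 = max(c - half, 0), min(c + half + 1, w)
        img[r0:r1, c0:c1] += kernel[
            r0 - (r - half) : kernel.shape[0] - ((r + half + 1) - r1),
            c0 - (c - half) : kernel.shape[1] - ((c + half + 1) - c1),
        ]


def simulate_focus_image(
    shape: tuple[int, int] = (512, 512),
    n_nuclei: int = 10,
    foci_per_nucleus: float = 8.0,
    focus_sigma: float = 2.0,
    focus_intensity: float = 100.0,
    noise_sd: float = 10.0,
    overlap_fraction: float | None = None,
    seed: int = 0,
    nucleus_radius: float = 30.0,
    dna_intensity: float = 200.0,
    min_spot_separation: float = 0.0,
) -> ImageBundle:
    """Simulate a DNA channel, a damage (foci) channel and optionally a marker.

    Nuclei are non-overlapping ellipses kept clear of the field border; the
    damage channel plants Poisson(``foci_per_nucleus``) isotropic Gaussian
    spots per nucleus; a marker channel, requested by setting
    ``overlap_fraction``, shares exactly round(overlap_fraction × n_foci)
    spot centres with the damage channel per nucleus.  Raises if the
    requested nuclei cannot be packed (no silent truncation).

    ``min_spot_separation`` > 0 plants only mutually resolvable spots (for
    detector benchmarks: spots closer than a detector's suppression radius
    are indistinguishable from a single focus by construction); the
    default 0 places spots uniformly at random.
    """
    if overlap_fraction is not None and not (0.0 <= overlap_fraction <= 1.0):
        raise InvalidArgumentError("overlap_fraction must lie in [0, 1]")
    if foci_per_nucleus < 0 or noise_sd < 0:
        raise InvalidArgumentError("foci_per_nucleus and noise_sd must be >= 0")
    h, w = shape
    rng = np.random.default_rng(seed)
    margin = nucleus_radius * 1.3 + 2
    if 2 * margin >= min(h, w) and n_nuclei > 0:
        raise InvalidArgumentError("nuclei cannot fit in the field without touching borders")

    centres: list[tuple[float, float]] = []
    nuclei: list[dict] = []
    max_tries = 20000
    tries = 0
    while len(nuclei) < n_nuclei:
        if tries >= max_tries:
            raise InvalidArgumentError(
                f"could not pack {n_nuclei} nuclei of radius ~{nucleus_radius} into {shape}"
            )
        tries += 1
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        a = nucleus_radius * rng.uniform(0.85, 1.15)
        b = nucleus_radius * rng.uniform(0.85, 1.15)
        theta = rng.uniform(0, np.pi)
        rmax = max(a, b)
        if any((cy - y) ** 2 + (cx - x) ** 2 < (rmax + rr + 4) ** 2 for y, x, rr in centres):
            continue
        centres.append((cy, cx, rmax))
        nuclei.append({"center": (cy, cx), "axes": (a, b), "angle": theta})

    yy, xx = np.mgrid[0:h, 0:w]
    labels = np.zeros(shape, dtype=np.int32)
    dna = np.zeros(shape, dtype=float)
    for i, nuc in enumerate(nuclei, start=1):
        cy, cx = nuc["center"]
        a, b = nuc["axes"]
        t = nuc["angle"]
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(t) + dx * np.sin(t)
        v = -dy * np.sin(t) + dx * np.cos(t)
        r2 = (u / a) ** 2 + (v / b) ** 2
        inside = r2 <= 1.0
        labels[inside] = i
        dna[inside] += dna_intensity * (1.0 - 0.4 * r2[inside])

    damage = np.zeros(shape, dtype=float)
    marker = np.zeros(shape, dtype=float) if overlap_fraction is not None else None
    damage_foci: list[np.ndarray] = []
    marker_foci: list[np.ndarray] = []
    shared_counts: list[int] = []

    for i, nuc in enumerate(nuclei, start=1):
        n_foci = int(rng.poisson(foci_per_nucleus))
        inside_idx = np.argwhere(labels == i)
        if n_foci > 0:
            if min_spot_separation > 0:
                chosen: list[np.ndarray] = []
                attempts = 0
                while len(chosen) < n_foci:
                    if attempts > 200 * n_foci:
                        raise InvalidArgumentError(
                            "cannot place the requested foci at the requested separation"
                        )
                    attempts += 1
                    cand = inside_idx[rng.integers(len(inside_idx))].astype(float)
                    if all(
                        np.hypot(*(cand - c)) >= min_spot_separation for c in chosen
                    ):
                        chosen.append(cand)
                spots = np.array(chosen)
            else:
                pick = rng.choice(len(inside_idx), size=n_foci, replace=False)
                spots = inside_idx[pick].astype(float)
        else:
            spots = np.empty((0, 2))
        damage_foci.append(spots)
        _add_gaussian_spots(damage, spots, focus_sigma, focus_intensity)
        if marker is not None:
            n_shared = int(round(overlap_fraction * n_foci))
            shared = spots[:n_shared]
            n_extra = n_foci - n_shared
            if n_extra > 0:
                pick2 = rng.choice(len(inside_idx), size=n_extra, replace=False)
                extra = inside_idx[pick2].astype(float)
            else:
                extra = np.empty((0, 2))
            mspots = np.vstack([shared, extra]) if (len(shared) or len(extra)) else np.empty((0, 2))
            marker_foci.append(mspots)
            shared_counts.append(n_shared)
            _add_gaussian_spots(marker, mspots, focus_sigma, focus_intensity)

    channels = {
        "dna": dna + rng.normal(0.0, noise_sd, shape),
        "damage": damage + rng.normal(0.0, noise_sd, shape),
    }
    if marker is not None:
        channels["marker"] = marker + rng.normal(0.0, noise_sd, shape)
    return ImageBundle(
        channels=channels,
        nuclei_labels=labels,
        nuclei=nuclei,
        damage_foci=damage_foci,
        marker_foci=marker_foci,
        shared_foci_per_nucleus=shared_counts,
    )
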