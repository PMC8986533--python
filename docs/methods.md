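# Methods

## Scope and data model

All genomic computation lives on a `BinGrid`: an ordered, non-overlapping
0-based half-open tiling with per-bin GC content and a blacklist flag. The
toy genome used throughout tests and examples tiles 3 chromosomes × 1,000
bins × 1 Mb — the ~3,000-bin scale of a human genome binned at 1 Mb — with
fixed-width contiguous bins. Mappability-derived variable-width bins and a
500-kb sliding offset would require external genome tracks and change none
of the logic under test here, so fixed-width tiling is used; every
downstream rule is expressed per bin and length-weighted, which makes it
agnostic to the binning scheme. Sex chromosomes are treated as autosomes;
there is no gender model.

## Count simulation

A cell's expected count in bin *b* with true copy number CN(b) is

    μ(b) = depth_per_copy · CN(b) · f(gc_b) · (1 + A · sin(2π b / T))

with `f` a quadratic GC-bias factor (identity by default), and the last
factor a smooth multiplicative "wavy" artifact of amplitude A < 1 and
period T bins (defaults 0 and 100). Counts are negative binomial with
variance = φ·μ, φ ≥ 1 the dispersion (Poisson as φ → 1). Defaults:
10 reads per bin per copy — the boundary depth of the read-depth curation
rule — and φ = 1.3, mild overdispersion typical of sparse single-cell
whole-genome bins. No published per-bin dispersion exists for the cell
lines this emulates, so φ is a modelling choice, not a calibration. The
sinusoid is the minimal smooth bias that reproduces wrongly called ±1-copy
segments at sufficient amplitude; real coverage waves are aperiodic and
asymmetric, so simulation results quantify the filter's operating
characteristic under a clean caricature, not its field performance.
Per-cell seeds in `simulate_population` are spawned from a single
`SeedSequence`, so populations are reproducible cell-by-cell.

## Copy-number calling

Preprocessing: counts are divided by a degree-2 polynomial fit of count
versus GC (non-blacklisted bins only) and rescaled to preserve the mean;
bins whose mean control coverage deviates from the genome median by more
than `mad_factor` × MAD (default 3) are blacklisted; G2/M libraries may be
divided by a matched G1 reference profile and median-rescaled. Blacklisted
bins are interpolated over during segmentation so they neither force nor
forbid breakpoints, and carry state −1 (undefined) in every profile.

Two independent callers segment the corrected signal per chromosome:

* **Changepoint caller** — recursive search for the best sub-interval
  [i, j) to split out of the current segment (the circular-binary-
  segmentation move; a plain single-split scan provably misses an interior
  bump flanked by equal levels). A split is accepted when its squared-error
  gain exceeds `penalty · σ² · log n`, a BIC-style charge with σ estimated
  from the MAD of first differences (level-shift robust). The accepted
  split tree is nested, so raising the penalty can only reduce the segment
  count. Default penalty 6.
* **HMM caller** — Viterbi decode of a Gaussian HMM with states
  0…max_state, emission means pinned at state × d (d = median signal /
  ploidy when the nominal ploidy is known, otherwise the lattice level that
  best explains the signal), a shared noise variance from the same robust
  estimator, and a sticky transition prior (self-transition 0.99). State 0
  emits at 0.05·d rather than zero so the likelihood stays proper. No EM is
  run: the parameterization is closed-form, single-initialization and
  deterministic, so the non-convergence failure mode of an iterative fit
  cannot occur. State indices are mean-ordered by construction.

**Integer-state anchoring.** A global per-copy scale s is grid-searched
(ground-ploidy candidates p at 0.005 resolution across the bounds;
s = anchor / p with the anchor the length-weighted median segment mean).
Feasible scales place the length-weighted *modal* integer state inside the
ploidy bounds — the ground-ploidy constraint, e.g. (3.5, 4.5) for 4n
libraries, (7.5, 8.5) for 8n. Among feasible scales, selection is by
self-consistency of the ground state: in a single cell every bin carries an
integer number of copies, so the modal state's own mean must re-derive its
integer value (|mean_modal/s − modal| ≤ 0.1), and within that tolerance the
scale whose ground ploidy sits nearest the bounds centre wins (tie-breaks:
smaller self-deviation, then smaller length-weighted lattice error). Pure
lattice-error minimization is deliberately avoided: under a symmetric
coverage wave the segment-mean distribution is bimodal and a shifted
lattice can explain it spuriously well, hiding exactly the artifact the
wavy filter must detect. Rounding of mean/s to states is
half-away-from-zero so state boundaries are reproducible. If no scale is
feasible the caller raises a ploidy-constraint error rather than guessing.

## Curation

Three pure predicates; a library is kept iff all pass, so the decision is
independent of evaluation order.

* **Concordance** — length-weighted fraction of non-blacklisted genome on
  which the two callers' integer states agree; thresholds 0.95 (2n) and
  0.90 (4n/8n). Bin-length weighting is used; with near-uniform bins it
  coincides with base-pair weighting.
* **Read depth** — mean over called bins of count/state must be ≥ 10
  (boundary inclusive; state-0 bins excluded). Equivalently ≥ 10·state
  reads per bin (20 for 2-somy, 30 for 3-somy) and ≥ 10 · ploidy · n_bins
  total reads: 60,000 for 2n G1 and 240,000 for 8n G2/M at 3,000 bins.
* **Wavy pattern** — for every state other than the expected one whose
  genome fraction strictly exceeds 1%, the non-rounded copy number
  mean_state/(mean_expected/cn_expected) is computed from the GC-corrected
  counts (whether the published statistic used corrected or raw counts is
  not documented; corrected counts are used here). A deviation strictly
  greater than 0.25 copies from the integer state discards the library
  (5-somy acceptance band [4.75, 5.25], endpoints passing). The statistic
  is evaluated on **both** callers' profiles and either failing discards:
  a smooth wave can slip one caller onto a shifted lattice whose
  non-rounded values look clean while the other caller still exposes the
  artifact. The expected state is the profile's own ground ploidy from
  state anchoring, not a user guess. The filter is armed for all library
  classes by default with a flag to restrict it — the restriction is
  configuration, not code.

Boundary conventions are literal throughout: exactly 10 reads/copy passes,
exactly 0.25 deviation passes, exactly 1% genome fraction does not trigger.

## Karyotype scores

Per cell: aneuploidy score = length-weighted mean |state − ploidy|;
aneuploid fraction = length-weighted fraction of bins off the expected
ploidy. Per population: heterogeneity = per-bin Simpson diversity
1 − Σ_s f_s² across cells, length-weighted genome-wide; zero when all
cells agree, bounded by 1 − 1/n_states. The Simpson form was chosen for
testability as a concrete realization of per-bin cell-to-cell state
variability; numerical parity with any external tool's published score is
not claimed. Heatmaps color integer states through a discrete map, one row
per cell in input order (no silent clustering), and export the underlying
state matrix as the bit-exact test surface.

## Fiber analytics

Fork speed divides the combined CldU+IdU track length by the total
labelling time, 2 × 30 min — the two-pulse convention, declared and
configurable. The stretch factor defaults to 2 kb/µm, the standard
constant-stretching value for molecular combing; all outputs record the
factor used. Asymmetry is CldU/IdU in pulse order (first track over
second), with a max/min variant exposed separately. Inter-origin distances
are consecutive differences of origin positions (kb) on the same fiber;
single-origin fibers contribute nothing. The simulator draws one speed per
pulse from a truncated normal, multiplies the second-pulse speed by a
uniform [0, 0.5] stall factor with the configured probability (no published
stall model exists; this guarantees detectable asymmetry), spaces origins
exponentially, and gives each fiber 1 + Poisson(1) origins. Incomplete
fibers are excluded with a logged reason, never silently dropped.

## Imaging

Images are 2D (projection assumed done). Nuclei: Otsu threshold on the
DNA channel, hole filling, minimum-area filter (default 200 px²) and a
distance-transform watershed to split touching nuclei. Foci: the damage
channel is band-passed with a scale-normalized Laplacian of Gaussian
(σ = 2 px default, matched to the expected focus size); local maxima
inside the nuclear mask above a prominence threshold survive non-maximum
suppression at `min_separation` (default 3 px). The default prominence is
6 × the response noise level, computed as a spot-robust raw-image noise
estimate (MAD of horizontal first differences) propagated through the
filter's l2 norm — estimating noise from the filtered response directly is
biased upward by the spots themselves. Two spots closer than the
suppression radius merge into one detection by design; the detector's
two-point resolution is ≈ 2σ√2 ≈ 5.7 px at σ = 2, so recovery benchmarks
plant spots ≥ 8 px apart (spots below the resolution limit are physically
indistinguishable from single foci). Absolute focus counts are
parameter-dependent; only relative comparisons on matched parameters are
meaningful.

The damage index is coverage (% of nuclear pixels above threshold — Otsu
within the nucleus by default, or a fixed value) × mean intensity of those
positive pixels; zero coverage gives index zero. Counts are normalized to
nuclear area and to integrated DNA-stain intensity. Classification uses
"at least k foci" (k = 10 default, boundary inclusive).

Manders M1 = Σa over pixels where b exceeds its (Otsu) threshold / Σa over
the mask, M2 symmetric; negative pixels are clipped so both stay in [0, 1].
The Costes-style test permutes channel-A pixel values within the nuclear
mask (thresholds held at their observed values so only spatial arrangement
varies) and reports p = (1 + #{randomized M1 ≥ observed}) / (n + 1):
ties count against rejection and the add-one correction makes the p-value
conservative under the null, with resolution 1/(n+1) (default n = 1000).

## Problem sizes and numerical choices

Tests and acceptance checks run at 3,000 bins × 30–50 cells per arm,
300 forks, and 100–200 seeded imaging replicates — sizes at which the
Monte-Carlo error of every recovered parameter is several times smaller
than its acceptance band. Caller recovery and curation retention are
evaluated at 10 and 12 reads/copy respectively: 10 reads/copy sits exactly
on the read-depth boundary (the sample mean then falls below threshold in
half of libraries by symmetry), so retention is measured at the 12
reads/copy condition that the curation rules unambiguously classify as
clean, while recovery — which does not depend on the boundary — is
measured at 10. All randomness flows through explicit integer seeds;
identical seeds give bitwise-identical counts, fibers, images, profiles
and reports.

## Known limitations

* No read-level (FASTQ/BAM-content) simulation; counts are generated at
  bin level. No breakpoint refinement below bin resolution, no sub-clonal
  fractional states, no replication-timing inference.
* The wavy artifact model is a single stationary sinusoid; real waves
  drift in period and amplitude.
* Nuclear segmentation is automated (Otsu + watershed); pipelines built on
  manual segmentation will differ near nucleus boundaries.
* The changepoint caller's interval scan is O(n²) per chromosome per
  recursion — fine at thousands of bins, not tuned for hundreds of
  thousands.
* Fiber input is an annotated track table; image-based fiber detection is
  out of scope.
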