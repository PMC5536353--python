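# Methods

This note documents the models, parameter choices and numerical
decisions behind `rdnamap`, and what the synthetic-data tests do and do
not demonstrate about real data.

## Coordinate model

The rDNA repeat is treated as a circle of `length` bp (default 45,306,
the BK000964v3 unit). Three 1-based frames are rotations of that circle:
native (GenBank numbering), displaced (origin moved to `native_origin`,
default the EcoRI site at 30,493, which places the 47S initiation site
at 14,815) and TSS-relative (+1 at the initiation site). Conversion is
modular arithmetic, hence exactly bijective and circular-distance
preserving; both properties are tested exhaustively at full repeat
length. Intervals are inclusive on both ends and may wrap a frame's end
(`start > end`), which is required to represent printed amplicons such
as the 47S promoter's 45133–40. Conversion to 0-based half-open
coordinates happens only at BED/bedGraph boundaries.

The shipped mouse feature table uses published qPCR amplicon coordinates
for the promoter and terminator elements; the broader working regions
(47S body 1–13,400, IGS 14,500–42,645, Enhancers 43,430–45,100,
TSS-relative) are conventional boundaries chosen once for region
averaging, with ≥300 bp of buffer between the averaged regions and the
chromatin-state transitions they flank so that read-extension and
smoothing bleed (≲140 bp) cannot leak across.

## Enrichment pipeline

The order is fixed: extend → coverage → smooth → RPM → ratio.

* **Extension** replaces each read with a fragment of exactly
  `fragment_length` (default 100 bp, the midpoint of the 75–125 bp
  estimated fragment range) anchored at the 5′ end. Strands are pooled
  afterwards; occupancy is reported unstranded.
* **Smoothing** is a centered mean over an odd window (default 25 bp).
  Linear track ends truncate the window and renormalize the divisor;
  circular mode wraps, which conserves the track total exactly. Both
  modes are available behind a flag; linear is the default, matching a
  single-copy "extra chromosome" reference. Smoothing and RPM scaling
  are both linear, so their order is immaterial (asserted as a test).
* **RPM** divides by the total aligned reads of the whole library, not
  rDNA-only reads, making ChIP/input ratios depth-independent.
* **Normalization** divides ChIP by input per base. The ratio is
  undefined where the input is too shallow; rather than adding a
  pseudocount (which inflates enrichment in dropout regions), bases with
  smoothed input RPM below `input_floor` are masked. The default floor
  is 5% of the median positive input value — low enough to keep
  essentially all bases of a well-covered input, high enough to exclude
  genuine dropouts. Duplicate fragments are retained; no deduplication
  or mappability correction is attempted.

The reason the ratio is informative at all: sequence-dependent coverage
bias is multiplicative and shared between ChIP and input libraries, so
it cancels in the ratio. The test suite verifies this directly — feature
means computed with and without a 5-fold bias field agree within
sampling error.

## Release kinetics

Stochastic release of an initiation factor at constant hazard during
elongation gives an exponential occupancy profile
E(d) = A·exp(−d/L<sub>c</sub>) + B downstream of +1. The fit is
nonlinear least squares (`scipy.optimize.curve_fit`) with bounds A > 0,
L<sub>c</sub> ∈ [1, 10×window], B ≥ 0, initialized at
A = max−min, B = min, L<sub>c</sub> = window/3. A log-linear regression
would be simpler but is ill-posed once B and near-zero values enter, so
it is not used. The default fit window is 200–6,000 bp downstream of +1:
the lower bound excludes the promoter-proximal preinitiation-complex
peak, the upper bound spans several decay lengths of any plausible
L<sub>c</sub> while staying inside the 13.4 kb transcribed region. A fit
is flagged `no_decay` (instead of returning a misleading number) when
L<sub>c</sub> pins within 1% of its bound, when A < 2× residual RMS, or
when A is negligible (≤10⁻⁶) against the overall signal level — the last
case catches exactly constant tracks, which otherwise fit with A ≈ 0
and residual ≈ 0. Temporal conversion uses
t<sub>½</sub> = L<sub>c</sub>·ln 2/v with v = 60 nt/s by default; the
half-life is invariant under positive rescaling of the track.

## Region statistics

Peak calling is deliberately minimal: the argmax of the
already-smoothed enrichment inside a bounded window (default ±200 bp)
around a named anchor, ties broken toward the anchor and then toward the
lower coordinate, no sub-bp interpolation (offsets are reported in
integer bp). A multi-peak variant returns all local maxima for closely
spaced sources. Feature summaries use unmasked bases only; signal
fractions are feature sums over the whole-track sum and therefore sum to
1 over any partition of the repeat. The paired ratio form
(A/B at f1) ÷ (A/B at f2) cancels any common scale between tracks.

## Gel densitometry

A lane trace is decomposed into two Gaussians plus an optional linear
baseline (default on; gels have sloping background). Initial centers are
the two most prominent local maxima of a lightly smoothed copy of the
trace, widths come from the half-width at half-maximum, and the
components are labeled by migration order: the lower-mobility component
is the active band. The active fraction uses component **areas**
(amplitude·σ·√(2π)), not amplitudes, since intensity-profile
quantification conventionally integrates band intensity. Traces with a
single detectable band return a flagged single-component fit with the
missing area set to zero. The standard error is a residual-resampling
bootstrap with a fixed seed; whether a published ± on such a fraction is
replicate scatter or fit uncertainty is generally unknowable from the
number alone, so the bootstrap SE is reported and interpretation left to
the user.

## Synthetic-data generator

The generator defines the conditions under which the pipeline is
validated. The wild-type scenario encodes: uniform polymerase occupancy
over the 47S body ending at the terminator cluster; Rrn3 decaying with
half-life 15 s at 60 nt/s (L<sub>c</sub> ≈ 1,298 bp, half-distance
900 bp); preinitiation peaks at both promoters; a stalled polymerase
24 bp downstream of the Spacer Promoter +1 with the termination-factor
peak 13 bp further downstream; UBF across the Spacer-Promoter-to-
terminator domain only; a CTCF/boundary-nucleosome complex upstream of
the Spacer Promoter that persists in all presets; and histone H3 from a
64%-active repeat mixture in which active repeats are histone-free
across the enhancer/47S domain. Knockout presets zero the appropriate
factors (initiation-factor loss removes the polymerase but keeps the
preinitiation complexes; architectural-factor loss removes the whole
machinery and renucleosomizes the gene, while the boundary complex
persists).

Two generator design choices deserve explanation:

* **Fragment geometry.** Reads are generated by drawing a bound site
  with probability ∝ φ(n)·b(n) and then placing the fragment uniformly
  over that site, mimicking sonication: a protected site is equally
  likely to sit anywhere within the fragment that survives
  immunoprecipitation. This yields the symmetric, peaked pileup that
  fixed-length read extension is designed to recover. The naive
  alternative — putting read 5′ ends *at* the site — produces a ~200 bp
  flat-topped pileup after extension whose maximum is positionally
  undefined, and single-bp peak offsets cannot be recovered from it.
* **Mixture weighting.** Population-average ChIP samples fragments in
  proportion to total epitope mass, so the H3 sampling weight is the
  mass-weighted mixture a·φ_active + (1−a)·φ_inactive. Weighting states
  per-read at equal rates would over-represent the low-H3 active repeats
  and understate the gene-body/IGS ratio by ~10 percentage points.

The bias field is log-normal with a 200 bp-correlated log field
(SD 0.4 ≈ 3–5-fold peak-to-trough), shared by every library of a
scenario. Fragment lengths are uniform on 75–125 bp (the shape of the
real distribution inside that range is unknown; uniform is the neutral
stand-in). The synthetic repeat sequence assigns smoothly varying
per-50-bp-window GC targets so GC-profile machinery can be exercised
with known truth.

**What the synthetic tests do not show.** The generator draws fragments
independently (no PCR duplicates or chromatin contiguity), uses a
smooth stationary bias (real bias tracks sequence composition), has no
mappability structure, no read errors or mapping ambiguity, and its
profiles are piecewise-stylized rather than measured. Passing recovery
tests therefore demonstrates that the *estimators are consistent under
the stated model at realistic depth and noise* — not that real libraries
satisfy the model.

## Problem sizes and reproducibility

Validation uses 2×10⁵ reads per library for profile-level quantities
(half-life, H3 ratio), 10⁴ reads for point-source peak geometry against
a 4×10⁵-read matched input (input libraries are routinely sequenced much
deeper than a single factor's ChIP, and peak positions are read against
the input), 20 seeded replicates for read-level quantities and 50 for
gel traces. At these sizes the full acceptance run completes in well
under a minute on one CPU. All randomness flows from explicit integer
seeds through `numpy.random.default_rng`; identical seeds give
byte-identical BED/bedGraph outputs.

## Known limitations

* No peak calling against a genome-wide background; windows are anchored
  at known elements.
* BAM ingestion is an extension point — the pipeline consumes BED
  positions (alignment and QC are upstream concerns).
* The exponential release model is phenomenological; no mechanistic
  polymerase-translocation simulation is attempted.
* 2-D gel image processing is out of scope; densitometry traces are the
  input.
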