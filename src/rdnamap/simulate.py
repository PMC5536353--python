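"""Synthetic rDNA ChIP-Seq scenarios with known ground truth.

This module generates every input the analysis pipeline consumes — a
repeat sequence, a feature annotation, per-factor aligned-read files
with a matched input library, and psoralen lane traces — from a fully
specified scenario whose parameters are the quantities the pipeline is
later asked to recover.

The "WT" preset emulates occupancy across the active mouse rDNA repeat
in wild-type fibroblasts:

* RNA polymerase I (RPI) uniform across the 47S transcribed region,
  ending at the T1-T10 terminator cluster, plus a stalled complex 24 bp
  downstream of the Spacer Promoter initiation site;
* Rrn3 decaying exponentially from the 47S initiation site with a
  release half-life of 15 s at an elongation rate of 60 nt/s
  (decay length Lc = v * t_half / ln 2 ~ 1299 bp);
* UBF across the Spacer Promoter-to-terminator gene unit only;
* SL1 at both promoters, TTF1 at Tsp/T0 and the T1-T10 sites;
* CTCF and boundary-nucleosome marks at the enhancer boundary upstream
  of the Spacer Promoter, retained in all presets;
* histone H3 drawn from a population mixture: a fraction
  ``active_fraction`` of repeats is histone-free across the enhancer/47S
  gene unit (nucleosomal only in the IGS), the rest nucleosomal
  throughout.

All libraries share one multiplicative, sequence-dependent bias field so
that raw coverage is reproducibly distorted but the ChIP/input ratio is
not — the property the input normalization exists to exploit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .coverage import AlignedReadSet, write_bed_reads
from .gel import LaneProfile
from .reference import (
    BK000964_DISPLACED_ORIGIN,
    BK000964_LENGTH,
    FeatureAnnotation,
    RepeatCoordinateSystem,
    mouse_rdna_features,
    remap_interval,
)

_SQRT2PI = math.sqrt(2.0 * math.pi)

DEFAULT_ACTIVE_FRACTION = 0.64
DEFAULT_HALF_LIFE_S = 15.0
DEFAULT_ELONGATION_RATE = 60.0
DEFAULT_FOOTPRINT = 50
DEFAULT_FRAGMENT_RANGE = (75, 125)

#: Offset of the stalled RPI complex downstream of the SpPr initiation site.
SPPR_STALL_OFFSET = 24
#: The TTF1 (Tsp) peak sits this far downstream of the stalled RPI peak.
TSP_TTF1_OFFSET = 13

PRESETS = ("WT", "Rrn3-KO", "UBF-KO")


@dataclass
class SyntheticScenario:
    """Ground-truth occupancy model for one simulated cell state.

    ``profiles`` maps factor name to either a single occupancy vector
    phi(n) over bases 1..L, or an (active, inactive) pair of vectors for
    factors sampled from the active/inactive repeat mixture.  The bias
    field multiplies the sampling weight of every library, including the
    input.
    """

    repeat_length: int
    cs: RepeatCoordinateSystem
    tss: int                      # displaced frame
    sppr_tss: int                 # displaced frame
    features: list[FeatureAnnotation]
    profiles: dict[str, np.ndarray | tuple[np.ndarray, np.ndarray]]
    bias_field: np.ndarray
    active_fraction: float
    half_life_s: float
    elongation_rate: float
    decay_length_bp: float
    fragment_range: tuple[int, int] = DEFAULT_FRAGMENT_RANGE
    seed: int = 0
    preset: str = "WT"

    def ground_truth(self) -> dict:
        """Scalar ground-truth parameters, JSON-serializable."""
        return {
            "preset": self.preset,
            "seed": self.seed,
            "repeat_length": self.repeat_length,
            "tss_displaced": self.tss,
            "sppr_tss_displaced": self.sppr_tss,
            "active_fraction": self.active_fraction,
            "half_life_s": self.half_life_s,
            "elongation_rate_nt_s": self.elongation_rate,
            "decay_length_bp": self.decay_length_bp,
            "sppr_stall_offset_bp": SPPR_STALL_OFFSET,
            "tsp_ttf1_offset_bp": TSP_TTF1_OFFSET,
            "fragment_range": list(self.fragment_range),
            "factors": sorted(self.profiles),
        }

    def write_ground_truth(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.ground_truth(), fh, indent=1, sort_keys=True)

    @staticmethod
    def read_ground_truth(path: str | Path) -> dict:
        with open(path) as fh:
            return json.load(fh)


def _box(L: int, center: int, width: int, height: float = 1.0) -> np.ndarray:
    """Occupancy box of ``width`` bp centered on ``center`` (1-based)."""
    phi = np.zeros(L)
    lo = center - (width - 1) // 2
    hi = center + width // 2
    idx = np.arange(lo, hi + 1)
    phi[(idx - 1) % L] = height
    return phi


def _interval_mask(L: int, iv: FeatureAnnotation) -> np.ndarray:
    m = np.zeros(L, dtype=bool)
    m[iv.positions(L) - 1] = True
    return m


def make_bias_field(
    L: int, seed: int, strength: float = 0.4, correlation_bp: float = 200.0
) -> np.ndarray:
    """Smooth, positive, multiplicative sequence-bias field.

    Log-normal with a Gaussian-smoothed log field; ``strength`` is the SD
    of the log bias, 0.4 giving roughly 3- to 5-fold peak-to-trough
    variation, comparable to the strong but reproducible coverage bias
    seen on real rDNA libraries.
    """
    rng = np.random.default_rng(seed)
    logb = gaussian_filter1d(
        rng.normal(size=L), sigma=correlation_bp, mode="wrap"
    )
    sd = logb.std()
    if sd > 0:
        logb *= strength / sd
    b = np.exp(logb)
    return b / b.mean()


def build_mef_scenario(
    preset: str = "WT",
    overrides: dict | None = None,
    seed: int = 0,
) -> SyntheticScenario:
    """Build a fully specified scenario for one fibroblast cell state.

    Presets: ``WT`` (active transcription), ``Rrn3-KO`` (initiation factor
    deleted: polymerase and Rrn3 lost, preinitiation complexes and UBF
    retained), ``UBF-KO`` (architectural factor deleted: the whole RPI
    machinery lost and the gene unit renucleosomized; the CTCF boundary
    complex persists).  ``overrides`` may replace any scalar scenario
    parameter (e.g. ``active_fraction``, ``half_life_s``, ``depth``).
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    ov = dict(overrides or {})
    L = int(ov.pop("repeat_length", BK000964_LENGTH))
    cs = RepeatCoordinateSystem(length=L, native_origin=min(BK000964_DISPLACED_ORIGIN, L))
    active_fraction = float(ov.pop("active_fraction", DEFAULT_ACTIVE_FRACTION))
    half_life = float(ov.pop("half_life_s", DEFAULT_HALF_LIFE_S))
    v = float(ov.pop("elongation_rate", DEFAULT_ELONGATION_RATE))
    footprint = int(ov.pop("footprint", DEFAULT_FOOTPRINT))
    if ov:
        raise ValueError(f"unknown scenario overrides: {sorted(ov)}")
    Lc = v * half_life / math.log(2.0)

    features = [remap_interval(f, cs, "displaced") for f in mouse_rdna_features()]
    by_name = {f.name: f for f in features}
    tss = cs.tss_displaced
    # SpPr initiation site: downstream edge of the Spacer Promoter element
    sppr_tss = by_name["SpPr"].end
    gene_body = by_name["47S"]
    t_sites = by_name["T1-T10"]

    gene_mask = _interval_mask(L, gene_body)
    # UBF / histone-free domain: Spacer Promoter through the terminators
    ubf_domain = FeatureAnnotation(
        "UBF-domain", by_name["SpPr"].start, t_sites.end, "displaced"
    )
    ubf_mask = _interval_mask(L, ubf_domain)

    d = (np.arange(1, L + 1) - tss) % L  # downstream distance from +1
    rrn3_decay = np.where(gene_mask, np.exp(-d / Lc), 0.0)
    pic_peak = _box(L, tss, footprint, 3.0)
    stall_pos = sppr_tss + SPPR_STALL_OFFSET
    ttf1_tsp_pos = stall_pos + TSP_TTF1_OFFSET

    active = preset != "UBF-KO"
    transcribing = preset == "WT"

    profiles: dict[str, np.ndarray | tuple[np.ndarray, np.ndarray]] = {}
    profiles["RPI"] = (
        gene_mask.astype(float)
        + _box(L, stall_pos, footprint, 4.0)
        + pic_peak
        if transcribing
        else np.full(L, 1e-3)
    )
    profiles["Rrn3"] = (
        rrn3_decay + pic_peak if transcribing else np.full(L, 1e-3)
    )
    profiles["UBF"] = (
        ubf_mask.astype(float) + pic_peak if active else np.full(L, 1e-3)
    )
    profiles["SL1"] = (
        _box(L, tss, footprint, 1.0) + _box(L, sppr_tss, footprint, 1.0)
        if active
        else np.full(L, 1e-3)
    )
    ttf1 = _box(L, ttf1_tsp_pos, footprint, 1.0) if active else np.zeros(L)
    t_positions = np.linspace(t_sites.start + 25, t_sites.end - 25, 10)
    for k, tp in enumerate(t_positions):
        height = 1.0 if (active or k >= 2) else 0.3  # UBF loss favours late sites
        ttf1 = ttf1 + _box(L, int(round(tp)), footprint, height)
    profiles["TTF1"] = np.maximum(ttf1, 1e-3)

    # boundary complex, retained across presets
    boundary = by_name["SpPr"].start - 60
    profiles["CTCF"] = _box(L, boundary, footprint, 1.0) + 1e-3
    marks = np.zeros(L)
    for k in range(4):  # phased nucleosomes upstream of CTCF, fading out
        marks += _box(L, boundary - 100 - 200 * k, 147, 1.0 - 0.2 * k)
    profiles["H3K4me3"] = np.maximum(marks, 1e-3)

    # histone H3: population mixture of active and inactive repeats
    h3_inactive = np.ones(L)                       # nucleosomal throughout
    h3_active = np.where(ubf_mask, 0.0, 1.0)       # IGS only
    eff_active = active_fraction if active else 0.0
    profiles["H3"] = (h3_active, h3_inactive)

    bias = make_bias_field(L, seed=seed + 1)
    return SyntheticScenario(
        repeat_length=L,
        cs=cs,
        tss=tss,
        sppr_tss=sppr_tss,
        features=features + [ubf_domain],
        profiles=profiles,
        bias_field=bias,
        active_fraction=eff_active,
        half_life_s=half_life,
        elongation_rate=v,
        decay_length_bp=Lc,
        seed=seed,
        preset=preset,
    )


def _empty_reads() -> AlignedReadSet:
    return AlignedReadSet(
        chrom="rDNA",
        starts=np.empty(0, dtype=np.int64),
        ends=np.empty(0, dtype=np.int64),
        strands=np.empty(0, dtype="U1"),
    )


def _fragments_over_sites(
    weights: np.ndarray,
    depth: int,
    rng: np.random.Generator,
    L: int,
    frag_range: tuple[int, int],
    label: str,
) -> AlignedReadSet:
    """Fragments whose covered span includes a site drawn from ``weights``.

    Sonication places a protected site anywhere within the resulting
    fragment with uniform probability, so the fragment start is the site
    minus a uniform offset into the fragment length.  The pooled coverage
    pileup is then symmetric and peaked over the site — the geometry the
    pipeline's fixed-length read extension is designed to recover.
    """
    total = weights.sum()
    if total <= 0:
        raise ValueError(f"all-zero sampling weights for {label!r}")
    sites = rng.choice(L, size=depth, p=weights / total) + 1
    lo, hi = frag_range
    lengths = rng.integers(lo, hi + 1, size=depth)
    offsets = rng.integers(0, lengths)  # uniform position of site in fragment
    starts = sites - offsets
    ends = starts + lengths - 1
    plus = rng.random(depth) < 0.5  # which fragment end was sequenced
    return AlignedReadSet(
        chrom="rDNA",
        starts=np.clip(starts, 1, L),
        ends=np.clip(ends, 1, L),
        strands=np.where(plus, "+", "-"),
    )


def sample_reads(
    scenario: SyntheticScenario,
    factor: str,
    depth: int,
    seed: int,
) -> AlignedReadSet:
    """Draw ``depth`` aligned fragments for one factor (or ``"input"``).

    Each fragment covers a site drawn with probability proportional to
    phi(n) * b(n) (input: b(n) alone, i.e. sheared chromatin with the
    shared sequence bias).  For mixture factors phi is the mass-weighted
    combination of the active and inactive repeat profiles — repeats
    contribute immunoprecipitated fragments in proportion to how much of
    the factor they carry, which is what a population-average ChIP
    library measures.  Fragment lengths are uniform on the configured
    range and the sequenced end (strand) is a fair coin flip.
    Deterministic given the seed.
    """
    if depth < 0:
        raise ValueError(f"depth must be >= 0, got {depth}")
    L = scenario.repeat_length
    rng = np.random.default_rng(seed)
    if depth == 0:
        return _empty_reads()

    if factor == "input":
        weights = [scenario.bias_field]
        counts = [depth]
    else:
        if factor not in scenario.profiles:
            raise KeyError(
                f"unknown factor {factor!r}; scenario has "
                f"{sorted(scenario.profiles)} and 'input'"
            )
        phi = scenario.profiles[factor]
        if isinstance(phi, tuple):
            # Population-average signal from an active/inactive repeat
            # mixture: repeats contribute reads in proportion to their
            # total occupancy, so the sampling weight is the
            # mass-weighted mixture of the two state profiles.
            phi_active, phi_inactive = phi
            af = scenario.active_fraction
            phi = af * phi_active + (1.0 - af) * phi_inactive
        weights = [phi * scenario.bias_field]
        counts = [depth]

    parts = [
        _fragments_over_sites(w, n, rng, L, scenario.fragment_range, factor)
        for w, n in zip(weights, counts)
    ]
    return parts[0]


def sample_point_source(
    scenario: SyntheticScenario,
    center: int,
    depth: int,
    seed: int,
    footprint: int = DEFAULT_FOOTPRINT,
) -> AlignedReadSet:
    """Reads for a single point-bound factor at ``center`` (displaced frame).

    Convenience for peak-geometry experiments: the occupancy is one
    footprint-wide box, modulated by the scenario's bias field like every
    other library.
    """
    if depth == 0:
        return _empty_reads()
    rng = np.random.default_rng(seed)
    phi = _box(scenario.repeat_length, center, footprint)
    return _fragments_over_sites(
        phi * scenario.bias_field, depth, rng,
        scenario.repeat_length, scenario.fragment_range, f"source@{center}",
    )


def simulate_gel_trace(
    active_fraction: float,
    n_points: int = 240,
    centers: tuple[float, float] = (70.0, 150.0),
    sigma: float = 20.0,
    total_area: float = 1000.0,
    baseline: tuple[float, float] = (2.0, 0.01),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> LaneProfile:
    """Simulate a psoralen lane trace as two Gaussians plus baseline.

    The low-mobility (active) band at ``centers[0]`` carries
    ``active_fraction`` of the total band area; the default geometry
    separates the bands by 4 sigma.  ``noise_sd`` is additive Gaussian
    noise in intensity units (for "2% noise", pass 0.02 times the larger
    band's peak amplitude).
    """
    if not 0.0 <= active_fraction <= 1.0:
        raise ValueError("active_fraction must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    x = np.arange(n_points, dtype=float)
    mu_a, mu_i = centers
    amp_a = active_fraction * total_area / (sigma * _SQRT2PI)
    amp_i = (1.0 - active_fraction) * total_area / (sigma * _SQRT2PI)
    y = (
        amp_a * np.exp(-0.5 * ((x - mu_a) / sigma) ** 2)
        + amp_i * np.exp(-0.5 * ((x - mu_i) / sigma) ** 2)
        + baseline[0]
        + baseline[1] * x
    )
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n_points)
    return LaneProfile(positions=x, intensities=y)


def gel_noise_sd(active_fraction: float, noise_frac: float = 0.02,
                 sigma: float = 20.0, total_area: float = 1000.0) -> float:
    """Noise SD equal to ``noise_frac`` of the larger band's peak height."""
    peak = max(active_fraction, 1.0 - active_fraction) * total_area
    return noise_frac * peak / (sigma * _SQRT2PI)


def random_repeat_sequence(
    L: int = BK000964_LENGTH,
    seed: int = 0,
    gc_window: int = 50,
    gc_low: float = 0.45,
    gc_high: float = 0.75,
    gc_field_sigma_windows: float = 10.0,
) -> str:
    """Random repeat sequence with a smoothly varying per-window GC target.

    Assigning each 50 bp window its own GC target reproduces the
    GC-modulated coverage/occupancy structure of the real repeat (the 47S
    body is GC-rich, the spacer closer to neutral) well enough for the
    GC-profile and bias machinery to be exercised with known truth.
    """
    rng = np.random.default_rng(seed)
    n_win = max(1, L // gc_window)
    field = gaussian_filter1d(rng.normal(size=n_win), sigma=gc_field_sigma_windows,
                              mode="wrap")
    if field.std() > 0:
        field = (field - field.min()) / (field.max() - field.min())
    targets = gc_low + (gc_high - gc_low) * field
    targets = np.repeat(targets, gc_window)[:L]
    if len(targets) < L:
        targets = np.pad(targets, (0, L - len(targets)), mode="edge")
    is_gc = rng.random(L) < targets
    gc_choice = rng.integers(0, 2, size=L)
    at_choice = rng.integers(0, 2, size=L)
    bases = np.where(
        is_gc, np.where(gc_choice == 0, "G", "C"),
        np.where(at_choice == 0, "A", "T"),
    )
    return "".join(bases)


def write_scenario(
    scenario: SyntheticScenario,
    outdir: str | Path,
    depth: int = 200_000,
    factors: list[str] | None = None,
    gel_noise_frac: float = 0.02,
    write_sequence: bool = True,
) -> dict[str, str]:
    """Emit a complete simulated dataset to ``outdir``.

    Writes per-factor read BEDs, a matched input BED, features (TSV +
    BED6), ground-truth JSON, a gel trace TSV and optionally the repeat
    FASTA.  Returns {artifact name: path}.
    """
    from .reference import features_to_bed6, features_to_tsv, write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    factors = factors or sorted(scenario.profiles)
    rng = np.random.default_rng(scenario.seed)
    for i, factor in enumerate([*factors, "input"]):
        reads = sample_reads(scenario, factor, depth,
                             seed=scenario.seed * 1000 + i)
        path = outdir / f"{factor}.bed"
        write_bed_reads(reads, path)
        artifacts[factor] = str(path)
    ftsv = outdir / "features.tsv"
    features_to_tsv(scenario.features, ftsv)
    artifacts["features_tsv"] = str(ftsv)
    fbed = outdir / "features.bed"
    features_to_bed6(scenario.features, fbed, scenario.cs)
    artifacts["features_bed"] = str(fbed)
    gt = outdir / "ground_truth.json"
    scenario.write_ground_truth(gt)
    artifacts["ground_truth"] = str(gt)
    trace = simulate_gel_trace(
        scenario.active_fraction,
        noise_sd=gel_noise_sd(scenario.active_fraction, gel_noise_frac),
        seed=scenario.seed + 7,
    )
    gel_path = outdir / "gel_trace.tsv"
    np.savetxt(gel_path, np.column_stack([trace.positions, trace.intensities]),
               delimiter="\t", header="position\tintensity", comments="")
    artifacts["gel_trace"] = str(gel_path)
    if write_sequence:
        seq = random_repeat_sequence(scenario.repeat_length, seed=scenario.seed)
        fa = outdir / "repeat.fa"
        write_fasta({"rDNA": seq}, fa)
        artifacts["repeat_fasta"] = str(fa)
    return artifacts
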