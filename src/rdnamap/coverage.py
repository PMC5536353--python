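"""Read extension, coverage, smoothing, RPM scaling and input normalization.

The pipeline turns aligned read positions on the rDNA repeat into an
input-normalized enrichment track in five fixed steps:

1. extend each read to the estimated fragment length (default 100 bp),
   anchored at its 5' end;
2. compute per-base fragment coverage ``j(n)``;
3. smooth with a centered running mean, ``J(n) = (1/w) sum j`` over a
   ``w`` bp window (default 25 bp);
4. scale to reads per million aligned library reads (RPM);
5. divide the ChIP track by the matched input track,
   ``Jnorm(n) = Jchip(n) / Jinput(n)``.

Sequencing coverage on the rDNA is strongly but *reproducibly* biased by
the underlying sequence, identically in ChIP and input libraries; the
final ratio therefore cancels the bias and estimates relative occupancy.
Bases where the input track is too shallow to support a ratio are masked
rather than given a pseudocount.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

RAW = "raw_counts"
SMOOTHED = "smoothed"
RPM = "rpm"

DEFAULT_FRAGMENT_LENGTH = 100
DEFAULT_SMOOTHING_WINDOW = 25
DEFAULT_INPUT_FLOOR_FRAC = 0.05


@dataclass
class AlignedReadSet:
    """Aligned read positions on one reference, 1-based inclusive.

    ``library_total_reads`` is the total number of aligned reads in the
    whole library (genome plus rDNA), used as the RPM denominator so that
    enrichment ratios are independent of sequencing depth.
    """

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    strands: np.ndarray  # array of '+'/'-'
    library_total_reads: int = 0

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.strands = np.asarray(self.strands, dtype="U1")
        if not (len(self.starts) == len(self.ends) == len(self.strands)):
            raise ValueError("starts, ends, strands must have equal length")
        if np.any(self.starts > self.ends):
            i = int(np.argmax(self.starts > self.ends))
            raise ValueError(
                f"record {i}: start {self.starts[i]} > end {self.ends[i]}"
            )
        if self.library_total_reads == 0:
            self.library_total_reads = len(self.starts)
        if self.library_total_reads < len(self.starts):
            raise ValueError(
                "library_total_reads smaller than the number of records"
            )

    def __len__(self) -> int:
        return len(self.starts)


@dataclass
class CoverageTrack:
    """Per-base non-negative coverage over positions 1..L.

    ``scale`` records the stage of the pipeline the values are at
    (raw fragment counts, smoothed, or RPM); downstream operations check
    it so stages cannot be skipped or reordered silently.
    """

    values: np.ndarray
    scale: str = RAW
    smoothed: bool = False
    chrom: str = "rDNA"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("coverage values must be one-dimensional")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")
        if self.scale not in (RAW, SMOOTHED, RPM):
            raise ValueError(f"unknown scale {self.scale!r}")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class EnrichmentTrack:
    """Input-normalized enrichment with a mask for unevaluable bases.

    ``mask[n]`` is True where the ratio is undefined (input below the
    evaluable floor); the corresponding value is NaN.
    """

    values: np.ndarray
    mask: np.ndarray
    chrom: str = "rDNA"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must have the same shape")
        defined = self.values[~self.mask]
        if np.any(~np.isfinite(defined)) or np.any(defined < 0):
            raise ValueError("unmasked enrichment values must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Pipeline operations
# ---------------------------------------------------------------------------

def extend_reads(
    reads: AlignedReadSet,
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    reference_length: int | None = None,
    circular: bool = False,
) -> AlignedReadSet:
    """Replace each read by a ``fragment_length`` fragment at its 5' end.

    Plus-strand reads extend downstream from ``start``; minus-strand reads
    extend upstream from ``end``.  With ``reference_length`` given,
    fragments are clipped at the reference bounds (linear mode) or left to
    wrap (circular mode; wrapping is resolved in :func:`compute_coverage`).
    Without a reference length, out-of-range coordinates are an error at
    coverage time.
    """
    if fragment_length < 1:
        raise ValueError(f"fragment_length must be >= 1, got {fragment_length}")
    plus = reads.strands == "+"
    minus = reads.strands == "-"
    if not np.all(plus | minus):
        i = int(np.argmax(~(plus | minus)))
        raise ValueError(
            f"record {i} ({reads.starts[i]}-{reads.ends[i]}) has unknown "
            f"strand {reads.strands[i]!r}"
        )
    five_prime = np.where(plus, reads.starts, reads.ends)
    starts = np.where(plus, five_prime, five_prime - fragment_length + 1)
    ends = starts + fragment_length - 1
    if reference_length is not None and not circular:
        starts = np.clip(starts, 1, reference_length)
        ends = np.clip(ends, 1, reference_length)
    return AlignedReadSet(
        chrom=reads.chrom,
        starts=starts,
        ends=ends,
        strands=reads.strands.copy(),
        library_total_reads=reads.library_total_reads,
    )


def compute_coverage(
    reads: AlignedReadSet, reference_length: int, circular: bool = False
) -> CoverageTrack:
    """Per-base count of fragments overlapping each position 1..L.

    In circular mode fragment coordinates are taken modulo the repeat
    length, so a fragment running past the end wraps to position 1.
    """
    L = int(reference_length)
    delta = np.zeros(L + 1)
    if len(reads):
        if circular:
            s0 = (reads.starts - 1) % L
            lengths = reads.ends - reads.starts + 1
            if np.any(lengths > L):
                raise ValueError("fragment longer than the circular reference")
            e = s0 + lengths
            np.add.at(delta, s0, 1)
            np.add.at(delta, np.minimum(e, L), -1)
            wrapped = e > L
            if np.any(wrapped):
                np.add.at(delta, np.zeros(wrapped.sum(), dtype=int), 1)
                np.add.at(delta, e[wrapped] - L, -1)
        else:
            if np.any(reads.starts < 1) or np.any(reads.ends > L):
                raise ValueError(
                    "fragment outside reference; extend with reference_length "
                    "to clip, or use circular mode"
                )
            np.add.at(delta, reads.starts - 1, 1)
            np.add.at(delta, reads.ends, -1)
    j = np.cumsum(delta[:L])
    return CoverageTrack(values=j, scale=RAW, smoothed=False, chrom=reads.chrom)


def smooth_track(
    track: CoverageTrack,
    window: int = DEFAULT_SMOOTHING_WINDOW,
    circular: bool = False,
) -> CoverageTrack:
    """Centered running mean, ``J(n) = (1/w) sum_{n-h}^{n+h} j``.

    ``window`` must be odd so the window is symmetric around ``n``.  At
    linear track ends the window is truncated and the divisor reduced to
    the number of in-range bases; in circular mode it wraps, which
    conserves the track total exactly.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"smoothing window must be odd and >= 1, got {window}")
    j = track.values
    if window == 1:
        out = j.copy()
    elif circular:
        h = window // 2
        padded = np.concatenate([j[-h:], j, j[:h]])
        out = np.convolve(padded, np.ones(window), mode="valid") / window
    else:
        num = np.convolve(j, np.ones(window), mode="same")
        den = np.convolve(np.ones_like(j), np.ones(window), mode="same")
        out = num / den
    # running mean of non-negative values; clip float dust below zero
    out = np.maximum(out, 0.0)
    scale = RPM if track.scale == RPM else SMOOTHED
    return CoverageTrack(values=out, scale=scale, smoothed=True, chrom=track.chrom)


def to_rpm(track: CoverageTrack, library_total_reads: int) -> CoverageTrack:
    """Scale a track to reads per million aligned library reads."""
    if library_total_reads <= 0:
        raise ValueError(
            f"library_total_reads must be positive, got {library_total_reads}"
        )
    return CoverageTrack(
        values=track.values * (1e6 / library_total_reads),
        scale=RPM,
        smoothed=track.smoothed,
        chrom=track.chrom,
    )


def normalize_to_input(
    chip: CoverageTrack,
    input_track: CoverageTrack,
    input_floor: float | None = None,
    input_floor_frac: float = DEFAULT_INPUT_FLOOR_FRAC,
) -> EnrichmentTrack:
    """Per-base ratio ``Jnorm = Jchip / Jinput`` with low-input masking.

    Both tracks must be smoothed and RPM-scaled.  Bases where the input
    falls below ``input_floor`` (default: ``input_floor_frac`` times the
    median of the positive input values) are masked instead of producing
    unstable or infinite ratios.
    """
    if len(chip) != len(input_track):
        raise ValueError(
            f"track lengths differ: chip {len(chip)} vs input {len(input_track)}"
        )
    for name, t in (("chip", chip), ("input", input_track)):
        if t.scale != RPM or not t.smoothed:
            raise ValueError(
                f"{name} track must be smoothed and RPM-scaled "
                f"(got scale={t.scale!r}, smoothed={t.smoothed})"
            )
    inp = input_track.values
    if input_floor is None:
        positive = inp[inp > 0]
        med = np.median(positive) if positive.size else 0.0
        input_floor = input_floor_frac * med
    mask = ~(inp >= input_floor) | (inp <= 0)
    values = np.full(len(chip), np.nan)
    np.divide(chip.values, inp, out=values, where=~mask)
    return EnrichmentTrack(values=values, mask=mask, chrom=chip.chrom)


def enrichment_pipeline(
    chip_reads: AlignedReadSet,
    input_reads: AlignedReadSet,
    reference_length: int,
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    window: int = DEFAULT_SMOOTHING_WINDOW,
    circular: bool = False,
    input_floor: float | None = None,
    input_floor_frac: float = DEFAULT_INPUT_FLOOR_FRAC,
) -> EnrichmentTrack:
    """Run the full extend -> coverage -> smooth -> RPM -> ratio pipeline."""

    def one(reads: AlignedReadSet) -> CoverageTrack:
        ext = extend_reads(reads, fragment_length, reference_length, circular)
        cov = compute_coverage(ext, reference_length, circular)
        sm = smooth_track(cov, window, circular)
        return to_rpm(sm, reads.library_total_reads)

    return normalize_to_input(
        one(chip_reads), one(input_reads), input_floor, input_floor_frac
    )


# ---------------------------------------------------------------------------
# BED / bedGraph I/O (0-based half-open on disk)
# ---------------------------------------------------------------------------

def read_bed_reads(path: str | Path, library_total_reads: int = 0) -> AlignedReadSet:
    """Read aligned reads from a BED6 file (single reference expected)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 5],
        names=["chrom", "start", "end", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
    )
    chroms = df["chrom"].unique()
    if len(chroms) > 1:
        raise ValueError(f"{path}: expected a single reference, found {list(chroms)}")
    return AlignedReadSet(
        chrom=chroms[0] if len(chroms) else "rDNA",
        starts=df["start"].to_numpy() + 1,
        ends=df["end"].to_numpy(),
        strands=df["strand"].to_numpy(dtype="U1"),
        library_total_reads=library_total_reads,
    )


def write_bed_reads(reads: AlignedReadSet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "chrom": reads.chrom,
            "start": reads.starts - 1,
            "end": reads.ends,
            "name": ".",
            "score": 0,
            "strand": reads.strands,
        }
    ).to_csv(path, sep="\t", header=False, index=False)


def _runs(values: np.ndarray) -> list[tuple[int, int, float]]:
    """Compress a per-base vector to (start0, end0, value) runs."""
    if len(values) == 0:
        return []
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(values)]])
    return [(int(s), int(e), float(values[s])) for s, e in zip(starts, ends)]


def write_bedgraph(
    values: np.ndarray, path: str | Path, chrom: str = "rDNA"
) -> None:
    """Write a per-base vector as 4-column bedGraph; NaN runs are omitted."""
    with open(path, "w") as fh:
        for s, e, v in _runs(np.asarray(values, dtype=float)):
            if np.isnan(v):
                continue
            fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_bedgraph(path: str | Path, length: int) -> np.ndarray:
    """Read a bedGraph into a per-base vector of ``length``; gaps are NaN."""
    values = np.full(length, np.nan)
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
    )
    for _, r in df.iterrows():
        values[int(r["start"]) : int(r["end"])] = float(r["value"])
    return values


def write_mask_bed(mask: np.ndarray, path: str | Path, chrom: str = "rDNA") -> None:
    """Write masked intervals (where mask is True) as a BED3 file."""
    with open(path, "w") as fh:
        for s, e, v in _runs(mask.astype(float)):
            if v:
                fh.write(f"{chrom}\t{s}\t{e}\n")
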