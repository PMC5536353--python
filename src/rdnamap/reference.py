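"""Circular rDNA repeat coordinate system, feature annotations and GC tracks.

The mouse rDNA repeat (GenBank BK000964v3, 45,306 bp) is a tandemly repeated
unit that is effectively circular at the scale of one repeat: the intergenic
spacer of one copy runs directly into the promoter of the next.  Analysis
references therefore often *displace* the numbering origin so that the
functional gene unit is contiguous on screen; the convention used here moves
position 30,493 (an EcoRI site) to coordinate 1, which places the 47S
pre-rRNA initiation site at 14,815.

Three coordinate frames are supported, all 1-based and inclusive:

``native``
    the GenBank numbering of the repeat (position 1 = 47S initiation site
    for BK000964v3);
``displaced``
    numbering after rotating the origin to ``native_origin``;
``tss_relative``
    numbering that puts the 47S initiation site at +1 and wraps around the
    repeat (the frame in which ChIP-qPCR amplicons are usually printed,
    e.g. the 47S promoter amplicon "45133-40" wraps the initiation site).

Intervals that wrap the end of a frame are written with ``start > end``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Length of the mouse rDNA repeat reference BK000964v3, in bp.
BK000964_LENGTH = 45306
#: Native position of the EcoRI site used as the displaced origin.
BK000964_DISPLACED_ORIGIN = 30493

FRAMES = ("native", "displaced", "tss_relative")


class CoordinateError(ValueError):
    """A position or interval is outside the repeat or otherwise invalid."""


@dataclass(frozen=True)
class RepeatCoordinateSystem:
    """Circular repeat of ``length`` bp with a displaced numbering origin.

    Parameters
    ----------
    length:
        Repeat unit length in bp.
    native_origin:
        Native 1-based position that becomes position 1 in the displaced
        frame.
    tss_native:
        Native position of the 47S initiation site (+1).  For BK000964v3
        native numbering already starts at the initiation site, so the
        default is 1.
    """

    length: int = BK000964_LENGTH
    native_origin: int = BK000964_DISPLACED_ORIGIN
    tss_native: int = 1

    def __post_init__(self) -> None:
        if self.length < 1:
            raise CoordinateError(f"repeat length must be >= 1, got {self.length}")
        for name in ("native_origin", "tss_native"):
            v = getattr(self, name)
            if not 1 <= v <= self.length:
                raise CoordinateError(
                    f"{name}={v} outside repeat of length {self.length}"
                )

    @property
    def tss_displaced(self) -> int:
        """Displaced-frame position of the 47S initiation site."""
        return int(self.convert(self.tss_native, "native", "displaced"))

    def _check(self, p: np.ndarray | int) -> np.ndarray:
        arr = np.asarray(p)
        bad = (arr < 1) | (arr > self.length)
        if np.any(bad):
            offending = np.atleast_1d(arr)[np.atleast_1d(bad)][0]
            raise CoordinateError(
                f"position {offending} outside repeat of length {self.length}"
            )
        return arr

    def convert(self, p, frame_from: str, frame_to: str):
        """Convert 1-based position(s) between coordinate frames.

        Accepts scalars or arrays; returns the same shape.  All frames are
        rotations of the same circle, so conversion is modular arithmetic.
        """
        for f in (frame_from, frame_to):
            if f not in FRAMES:
                raise CoordinateError(f"unknown frame {f!r}; expected one of {FRAMES}")
        arr = self._check(p)
        # rotate into native frame, then out of it
        shift_in = {
            "native": 0,
            "displaced": self.native_origin - 1,
            "tss_relative": self.tss_native - 1,
        }
        native0 = (arr - 1 + shift_in[frame_from]) % self.length
        out = (native0 - shift_in[frame_to]) % self.length + 1
        if np.isscalar(p):
            return int(out)
        return out

    def remap_position(self, p):
        """Native -> displaced frame (the rotation applied to all tracks)."""
        return self.convert(p, "native", "displaced")

    def circular_distance(self, a: int, b: int) -> int:
        """Shortest distance between two positions around the repeat."""
        self._check(a)
        self._check(b)
        d = abs(int(a) - int(b))
        return min(d, self.length - d)


@dataclass(frozen=True)
class FeatureAnnotation:
    """A named interval on the repeat, 1-based inclusive.

    ``start > end`` denotes an interval wrapping the end of its frame
    (e.g. the 47S promoter amplicon 45133-40 in TSS-relative numbering).
    """

    name: str
    start: int
    end: int
    frame: str = "native"
    strand: str = "."

    def __post_init__(self) -> None:
        if self.frame not in FRAMES:
            raise CoordinateError(f"unknown frame {self.frame!r}")
        if self.strand not in ("+", "-", "."):
            raise CoordinateError(f"invalid strand {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise CoordinateError(
                f"interval {self.name}: coordinates must be >= 1, "
                f"got {self.start}-{self.end}"
            )

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def size(self, length: int) -> int:
        """Interval length in bp, counting across the wrap if needed."""
        if self.wraps:
            return length - self.start + 1 + self.end
        return self.end - self.start + 1

    def positions(self, length: int) -> np.ndarray:
        """All 1-based member positions, in order along the interval."""
        if self.start > length or self.end > length:
            raise CoordinateError(
                f"interval {self.name} {self.start}-{self.end} exceeds "
                f"repeat length {length}"
            )
        if self.wraps:
            return np.concatenate(
                [np.arange(self.start, length + 1), np.arange(1, self.end + 1)]
            )
        return np.arange(self.start, self.end + 1)


def remap_interval(
    iv: FeatureAnnotation, cs: RepeatCoordinateSystem, to_frame: str = "displaced"
) -> FeatureAnnotation:
    """Re-express an interval in another frame, conserving its length.

    Both endpoints are converted; whether the result wraps follows from the
    converted endpoints (an interval wraps a frame exactly when the frame's
    origin falls inside it).
    """
    if iv.start > cs.length or iv.end > cs.length:
        raise CoordinateError(
            f"interval {iv.name} {iv.start}-{iv.end} exceeds repeat "
            f"length {cs.length}"
        )
    new_start = int(cs.convert(iv.start, iv.frame, to_frame))
    new_end = int(cs.convert(iv.end, iv.frame, to_frame))
    out = replace(iv, start=new_start, end=new_end, frame=to_frame)
    if out.size(cs.length) != iv.size(cs.length):
        # start==end after conversion is unambiguous; anything else would be
        # a full-repeat interval, which the wrap convention cannot encode.
        raise CoordinateError(
            f"interval {iv.name} cannot be represented in frame {to_frame}"
        )
    return out


@dataclass(frozen=True)
class GCProfile:
    """Percent G+C per non-overlapping window along a sequence.

    ``values[i]`` covers 1-based positions
    ``start_coordinate + i*window_size .. start_coordinate + (i+1)*window_size - 1``.
    Windows containing only N are NaN.
    """

    window_size: int
    values: np.ndarray
    start_coordinate: int = 1

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("GC percentages must lie in [0, 100]")


def gc_content_profile(seq: str, window: int = 50) -> GCProfile:
    """Percent G+C in non-overlapping windows of ``window`` bp.

    N bases are excluded from the denominator; a window of only N yields
    NaN.  A truncated final window (sequence length not a multiple of the
    window) is dropped.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if len(seq) == 0:
        raise ValueError("empty sequence")
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype="S1")
    valid_chars = np.isin(arr, [b"A", b"C", b"G", b"T", b"N"])
    if not valid_chars.all():
        bad = arr[~valid_chars][0].decode()
        raise ValueError(f"sequence contains invalid character {bad!r}")
    n_win = len(seq) // window
    if n_win == 0:
        raise ValueError(
            f"sequence of length {len(seq)} shorter than window {window}"
        )
    arr = arr[: n_win * window].reshape(n_win, window)
    is_gc = np.isin(arr, [b"G", b"C"]).sum(axis=1).astype(float)
    non_n = (arr != b"N").sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * is_gc / non_n
    pct[non_n == 0] = np.nan
    return GCProfile(window_size=window, values=pct)


# ---------------------------------------------------------------------------
# Feature annotation of the mouse repeat
# ---------------------------------------------------------------------------

def mouse_rdna_features() -> list[FeatureAnnotation]:
    """Feature table for the mouse rDNA repeat in TSS-relative coordinates.

    The promoter/terminator amplicon coordinates follow the published
    ChIP-qPCR amplicons for BK000964v3 (printed relative to the 47S
    initiation site); the extended region features (gene body, enhancers,
    IGS) are conventional working boundaries used for region averaging.
    """
    f = FeatureAnnotation
    return [
        f("47SPr", 45133, 40, "tss_relative"),        # wraps the +1
        f("47S", 1, 13400, "tss_relative"),            # 47S pre-rRNA body
        f("ETS", 650, 4006, "tss_relative"),
        f("18S", 4007, 5876, "tss_relative"),
        f("5.8S", 6877, 7033, "tss_relative"),
        f("28S", 8123, 12836, "tss_relative"),
        f("T1-T10", 13410, 13970, "tss_relative"),
        f("IGS", 14500, 42645, "tss_relative"),
        f("IGS3", 42646, 42903, "tss_relative"),
        f("SpPr", 43089, 43253, "tss_relative"),
        f("Tsp", 43267, 43421, "tss_relative"),
        f("Enhancers", 43430, 45100, "tss_relative"),
    ]


# ---------------------------------------------------------------------------
# On-disk formats: BED6 (0-based half-open), TSV (1-based), bedGraph
# ---------------------------------------------------------------------------

def features_to_bed6(
    features: Iterable[FeatureAnnotation],
    path: str | Path,
    cs: RepeatCoordinateSystem,
    chrom: str = "rDNA",
    frame: str = "displaced",
) -> None:
    """Write features as BED6.  Wrapping intervals are split in two lines."""
    rows = []
    for iv in features:
        riv = remap_interval(iv, cs, frame)
        segments = (
            [(riv.start, cs.length), (1, riv.end)]
            if riv.wraps
            else [(riv.start, riv.end)]
        )
        for s, e in segments:
            rows.append((chrom, s - 1, e, riv.name, 0, riv.strand))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def features_to_tsv(features: Iterable[FeatureAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [(iv.name, iv.start, iv.end, iv.frame, iv.strand) for iv in features],
        columns=["name", "start", "end", "frame", "strand"],
    ).to_csv(path, sep="\t", index=False)


def features_from_tsv(path: str | Path) -> list[FeatureAnnotation]:
    df = pd.read_csv(path, sep="\t")
    return [
        FeatureAnnotation(
            str(r["name"]), int(r["start"]), int(r["end"]),
            str(r.get("frame", "native")), str(r.get("strand", ".")),
        )
        for _, r in df.iterrows()
    ]


def gc_profile_to_bedgraph(
    profile: GCProfile, path: str | Path, chrom: str = "rDNA"
) -> None:
    """Write per-window GC% as 4-column bedGraph (0-based half-open)."""
    w = profile.window_size
    start0 = profile.start_coordinate - 1
    rows = [
        (chrom, start0 + i * w, start0 + (i + 1) * w, v)
        for i, v in enumerate(profile.values)
        if np.isfinite(v)
    ]
    pd.DataFrame(rows).to_csv(
        path, sep="\t", header=False, index=False, float_format="%.6g"
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file as {record id: sequence string}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
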