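"""Feature-level enrichment summaries, windowed peak calls and ratios.

These are the descriptive statistics read off enrichment profiles: mean
and maximum occupancy per annotated element, the fraction of total
repeat signal falling in an element (e.g. "UBF in the IGS is <1% of the
47S region signal"), the position of a local peak relative to a named
anchor (e.g. the stalled polymerase 24 bp downstream of the Spacer
Promoter initiation site, 13 bp upstream of the TTF1 peak at Tsp), and
between-feature or between-factor ratios (e.g. histone H3 over the gene
body at roughly 40% of its IGS level).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coverage import EnrichmentTrack
from .reference import FeatureAnnotation

DEFAULT_PEAK_WINDOW = 200


@dataclass(frozen=True)
class FeatureSummary:
    feature: str
    mean_enrichment: float
    max_enrichment: float
    signal_fraction: float  # share of total unmasked reference signal
    n_unmasked: int

    def __post_init__(self) -> None:
        if self.mean_enrichment > self.max_enrichment + 1e-12:
            raise ValueError("mean enrichment cannot exceed the maximum")
        if not 0.0 <= self.signal_fraction <= 1.0 + 1e-12:
            raise ValueError("signal fraction must lie in [0, 1]")


@dataclass(frozen=True)
class PeakCall:
    position: int             # 1-based, track frame
    offset_from_anchor: int   # signed bp; positive = downstream
    height: float
    anchor: int


def _feature_values(
    track: EnrichmentTrack, feature: FeatureAnnotation
) -> tuple[np.ndarray, np.ndarray]:
    """(positions0, unmasked values) for a feature already in track frame."""
    pos0 = feature.positions(len(track)) - 1
    vals = track.values[pos0]
    ok = ~track.mask[pos0]
    return pos0, vals[ok]


def summarize_feature(
    track: EnrichmentTrack, feature: FeatureAnnotation
) -> FeatureSummary:
    """Mean/max enrichment over a feature and its share of total signal.

    The feature must already be expressed in the track's coordinate frame
    (use :func:`rdnamap.reference.remap_interval`).  Statistics use
    unmasked bases only; the signal fraction is the unmasked feature sum
    over the unmasked whole-track sum.
    """
    _, vals = _feature_values(track, feature)
    if vals.size == 0:
        raise ValueError(f"feature {feature.name} is fully masked")
    total = float(np.nansum(track.values[~track.mask]))
    frac = float(vals.sum() / total) if total > 0 else 0.0
    return FeatureSummary(
        feature=feature.name,
        mean_enrichment=float(vals.mean()),
        max_enrichment=float(vals.max()),
        signal_fraction=frac,
        n_unmasked=int(vals.size),
    )


def find_peak(
    track: EnrichmentTrack,
    anchor: int,
    window: tuple[int, int] = (-DEFAULT_PEAK_WINDOW, DEFAULT_PEAK_WINDOW),
) -> PeakCall:
    """Position of the maximum enrichment in a window around an anchor.

    ``window`` is (lo, hi) in signed bp relative to the anchor, inclusive.
    Ties are broken toward the anchor (then toward the lower position).
    The track is expected to be smoothed upstream; no additional smoothing
    or sub-bp interpolation is applied.
    """
    lo, hi = window
    if lo >= hi:
        raise ValueError(f"empty peak search window ({lo}, {hi})")
    offsets = np.arange(lo, hi + 1)
    pos0 = anchor + offsets - 1
    valid = (pos0 >= 0) & (pos0 < len(track))
    offsets, pos0 = offsets[valid], pos0[valid]
    ok = ~track.mask[pos0]
    if not ok.any():
        raise ValueError("peak search window is fully masked")
    offsets, pos0 = offsets[ok], pos0[ok]
    vals = track.values[pos0]
    best = vals.max()
    ties = np.flatnonzero(vals >= best)
    # tie-break: smallest |offset|, then smallest offset
    order = np.lexsort((offsets[ties], np.abs(offsets[ties])))
    pick = ties[order[0]]
    return PeakCall(
        position=int(pos0[pick] + 1),
        offset_from_anchor=int(offsets[pick]),
        height=float(vals[pick]),
        anchor=int(anchor),
    )


def find_peaks_multi(
    track: EnrichmentTrack,
    anchor: int,
    window: tuple[int, int] = (-DEFAULT_PEAK_WINDOW, DEFAULT_PEAK_WINDOW),
    min_separation: int = 10,
) -> list[PeakCall]:
    """All local maxima in the window, highest first.

    Used to resolve closely spaced sources (e.g. the stalled polymerase
    and the adjacent termination-factor peak) on a single profile.
    """
    from scipy.signal import argrelmax

    lo, hi = window
    pos0 = np.arange(anchor + lo - 1, anchor + hi)
    pos0 = pos0[(pos0 >= 0) & (pos0 < len(track))]
    vals = np.where(track.mask[pos0], -np.inf, track.values[pos0])
    (locs,) = argrelmax(vals, order=max(1, min_separation // 2))
    calls = [
        PeakCall(
            position=int(pos0[i] + 1),
            offset_from_anchor=int(pos0[i] + 1 - anchor),
            height=float(vals[i]),
            anchor=int(anchor),
        )
        for i in locs
    ]
    calls.sort(key=lambda c: -c.height)
    return calls


def ratio_between_features(
    track_a: EnrichmentTrack,
    f1: FeatureAnnotation,
    f2: FeatureAnnotation,
    track_b: EnrichmentTrack | None = None,
) -> float:
    """Mean-enrichment ratio between two features.

    Single-track form (``track_b`` omitted): ``mean_a(f1) / mean_a(f2)``,
    e.g. gene-body H3 relative to the IGS.  Paired form: the f1/f2 ratio
    of the per-feature A:B ratios,
    ``(mean_a(f1)/mean_b(f1)) / (mean_a(f2)/mean_b(f2))``,
    e.g. Rrn3 per polymerase at the Spacer versus the 47S promoter; any
    common scale factor between the tracks cancels.
    """
    m_a1 = summarize_feature(track_a, f1).mean_enrichment
    m_a2 = summarize_feature(track_a, f2).mean_enrichment
    if track_b is None:
        if m_a2 == 0:
            raise ZeroDivisionError(f"mean enrichment over {f2.name} is zero")
        return m_a1 / m_a2
    m_b1 = summarize_feature(track_b, f1).mean_enrichment
    m_b2 = summarize_feature(track_b, f2).mean_enrichment
    if m_b1 == 0 or m_a2 == 0 or m_b2 == 0:
        raise ZeroDivisionError("a denominator feature mean is zero")
    return (m_a1 / m_b1) / (m_a2 / m_b2)
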