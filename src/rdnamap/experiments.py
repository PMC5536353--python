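"""Recovery experiments: simulate at the reference conditions, re-analyze.

Each function here builds scenarios whose ground truth is set to the
reported mouse-fibroblast estimates (release half-life 15 s at 60 nt/s, active
fraction 64%, stalled-polymerase geometry +24/+13 bp), runs the full
read-level pipeline on freshly sampled data and returns the recovered
quantity.  They are used by the acceptance script and the test suite.
"""

from __future__ import annotations

import numpy as np

from .coverage import enrichment_pipeline
from .gel import active_fraction, fit_two_gaussians
from .kinetics import fit_exponential_decay, halflife_from_decay
from .regions import find_peak, summarize_feature
from .simulate import (
    SPPR_STALL_OFFSET,
    TSP_TTF1_OFFSET,
    build_mef_scenario,
    gel_noise_sd,
    sample_point_source,
    sample_reads,
    simulate_gel_trace,
)

WT_DEPTH = 200_000
POINT_SOURCE_DEPTH = 10_000
#: input libraries are sequenced deeper than a single point-source ChIP;
#: peak positions are read against this deeper matched input
GEOMETRY_INPUT_DEPTH = 400_000


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """n reproducible sub-seeds (< 2**31) derived from one master seed."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def recover_half_life(
    seed: int, n_seeds: int = 20, depth: int = WT_DEPTH
) -> list[float]:
    """Recovered Rrn3 release half-lives (s), one per simulated replicate.

    Each replicate simulates a wild-type Rrn3 library and matched input
    at ``depth`` reads, runs extend/smooth/RPM/normalize, fits the
    exponential over 200-6000 bp downstream of +1 and converts the decay
    length to seconds at 60 nt/s.
    """
    out = []
    for s in _child_seeds(seed, n_seeds):
        sc = build_mef_scenario("WT", seed=int(s))
        chip = sample_reads(sc, "Rrn3", depth, seed=int(s) + 1)
        inp = sample_reads(sc, "input", depth, seed=int(s) + 2)
        enr = enrichment_pipeline(chip, inp, sc.repeat_length)
        fit = fit_exponential_decay(enr, sc.tss)
        est = halflife_from_decay(fit, sc.elongation_rate)
        out.append(est.half_life)
    return out


def recover_gel_fractions(
    seed: int, n_seeds: int = 50, truth: float = 0.64, noise_frac: float = 0.02
) -> list[float]:
    """Recovered active fractions from seeded noisy psoralen lane traces."""
    out = []
    for s in _child_seeds(seed, n_seeds):
        trace = simulate_gel_trace(
            truth, noise_sd=gel_noise_sd(truth, noise_frac), seed=int(s)
        )
        fit = fit_two_gaussians(trace)
        out.append(active_fraction(fit).value)
    return out


def recover_h3_ratio(
    seed: int, n_seeds: int = 20, depth: int = WT_DEPTH
) -> list[float]:
    """Gene-region/IGS mean H3 enrichment ratios, one per replicate.

    H3 reads are drawn from the active/inactive repeat mixture (inactive
    fraction 1 - 0.64 nucleosomal throughout; active repeats nucleosomal
    only in the IGS) and the ratio of mean input-normalized enrichment
    over Enhancers+47S to that over the IGS is returned as a fraction.
    """
    out = []
    for s in _child_seeds(seed, n_seeds):
        sc = build_mef_scenario("WT", seed=int(s))
        chip = sample_reads(sc, "H3", depth, seed=int(s) + 3)
        inp = sample_reads(sc, "input", depth, seed=int(s) + 4)
        enr = enrichment_pipeline(chip, inp, sc.repeat_length)
        feats = {f.name: f for f in sc.features}
        sums = {
            name: summarize_feature(enr, feats[name])
            for name in ("Enhancers", "47S", "IGS")
        }
        n_enh = sums["Enhancers"].n_unmasked
        n_47s = sums["47S"].n_unmasked
        gene_mean = (
            sums["Enhancers"].mean_enrichment * n_enh
            + sums["47S"].mean_enrichment * n_47s
        ) / (n_enh + n_47s)
        out.append(gene_mean / sums["IGS"].mean_enrichment)
    return out


def recover_sppr_geometry(
    seed: int,
    n_seeds: int = 20,
    depth: int = POINT_SOURCE_DEPTH,
    input_depth: int = GEOMETRY_INPUT_DEPTH,
) -> tuple[list[int], list[int]]:
    """(stall offsets, stall-to-TTF1 separations) in bp, per replicate.

    A stalled-polymerase point source is placed 24 bp downstream of the
    Spacer Promoter initiation site and a termination-factor source 13 bp
    further downstream; each is sequenced at ``depth`` reads against the
    scenario's standard input library, run through the full pipeline, and
    peak-called in a +/-200 bp window anchored at the SpPr +1.
    """
    offsets, separations = [], []
    for s in _child_seeds(seed, n_seeds):
        sc = build_mef_scenario("WT", seed=int(s))
        inp = sample_reads(sc, "input", input_depth, seed=int(s) + 5)
        stall = sc.sppr_tss + SPPR_STALL_OFFSET
        rpi = sample_point_source(sc, stall, depth, seed=int(s) + 6)
        ttf1 = sample_point_source(
            sc, stall + TSP_TTF1_OFFSET, depth, seed=int(s) + 7
        )
        enr_rpi = enrichment_pipeline(rpi, inp, sc.repeat_length)
        enr_ttf1 = enrichment_pipeline(ttf1, inp, sc.repeat_length)
        pk_rpi = find_peak(enr_rpi, sc.sppr_tss, (-200, 200))
        pk_ttf1 = find_peak(enr_ttf1, sc.sppr_tss, (-200, 200))
        offsets.append(pk_rpi.offset_from_anchor)
        separations.append(pk_ttf1.position - pk_rpi.position)
    return offsets, separations
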