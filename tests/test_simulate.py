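"""Synthetic scenario construction, read sampling and bias cancellation."""

import json
import math

import numpy as np
import pytest

from rdnamap.coverage import enrichment_pipeline, write_bed_reads
from rdnamap.regions import summarize_feature
from rdnamap.simulate import (
    build_mef_scenario,
    make_bias_field,
    random_repeat_sequence,
    sample_reads,
    simulate_gel_trace,
    write_scenario,
)


class TestScenarioPresets:
    def test_unknown_preset_lists_choices(self):
        with pytest.raises(ValueError, match="WT"):
            build_mef_scenario("XYZ")

    def test_wt_decay_half_distance_is_900_bp(self, wt_scenario):
        # 15 s at 60 nt/s: half-distance = v * t_half
        assert wt_scenario.decay_length_bp * math.log(2) == pytest.approx(900.0)
        assert wt_scenario.active_fraction == 0.64

    def test_rrn3_ko_removes_polymerase_but_keeps_pic(self, wt_scenario):
        ko = build_mef_scenario("Rrn3-KO", seed=7)
        assert ko.profiles["RPI"].max() < 0.01 * wt_scenario.profiles["RPI"].max()
        assert ko.profiles["Rrn3"].max() < 0.01 * wt_scenario.profiles["Rrn3"].max()
        np.testing.assert_array_equal(ko.profiles["UBF"], wt_scenario.profiles["UBF"])
        np.testing.assert_array_equal(ko.profiles["SL1"], wt_scenario.profiles["SL1"])

    def test_ubf_ko_removes_machinery_but_keeps_boundary(self, wt_scenario):
        ko = build_mef_scenario("UBF-KO", seed=7)
        for factor in ("UBF", "RPI", "Rrn3", "SL1"):
            assert ko.profiles[factor].max() < 0.01 * wt_scenario.profiles[factor].max()
        np.testing.assert_array_equal(
            ko.profiles["CTCF"], wt_scenario.profiles["CTCF"]
        )
        np.testing.assert_array_equal(
            ko.profiles["H3K4me3"], wt_scenario.profiles["H3K4me3"]
        )
        assert ko.active_fraction == 0.0

    def test_ground_truth_round_trips_through_json(self, wt_scenario, tmp_path):
        path = tmp_path / "gt.json"
        wt_scenario.write_ground_truth(path)
        back = wt_scenario.read_ground_truth(path)
        assert back == wt_scenario.ground_truth()
        json.loads(path.read_text())  # valid JSON on disk


class TestSampleReads:
    def test_same_seed_gives_byte_identical_bed(self, wt_scenario, tmp_path):
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        write_bed_reads(sample_reads(wt_scenario, "RPI", 5000, seed=3), p1)
        write_bed_reads(sample_reads(wt_scenario, "RPI", 5000, seed=3), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_zero_depth_is_empty(self, wt_scenario):
        assert len(sample_reads(wt_scenario, "input", 0, seed=1)) == 0

    def test_unknown_factor_is_an_error(self, wt_scenario):
        with pytest.raises(KeyError, match="input"):
            sample_reads(wt_scenario, "NoSuchFactor", 10, seed=1)

    def test_all_zero_weights_are_an_error(self, wt_scenario):
        sc = build_mef_scenario("WT", seed=1)
        sc.profiles["RPI"] = np.zeros(sc.repeat_length)
        with pytest.raises(ValueError, match="all-zero"):
            sample_reads(sc, "RPI", 10, seed=1)

    def test_uniform_weights_give_uniform_coverage(self):
        """With flat occupancy and no bias the windowed read-start counts
        must be consistent with Poisson sampling noise."""
        sc = build_mef_scenario("WT", seed=0)
        sc.profiles["RPI"] = np.ones(sc.repeat_length)
        sc.bias_field = np.ones(sc.repeat_length)
        reads = sample_reads(sc, "RPI", 200_000, seed=5)
        # clipping at the reference ends distorts the first/last few
        # hundred bp; judge uniformity on the interior
        starts = reads.starts[(reads.starts > 500) & (reads.starts < 44800)]
        counts, edges = np.histogram(starts, bins=40, range=(500, 44800))
        expected = len(starts) / 40
        z = (counts - expected) / np.sqrt(expected)
        assert np.abs(z.mean()) < 1.0  # no systematic trend
        assert (np.abs(z) < 5).all()

    def test_fragment_lengths_span_the_configured_range(self, wt_scenario):
        reads = sample_reads(wt_scenario, "input", 20_000, seed=9)
        lengths = reads.ends - reads.starts + 1
        assert lengths.min() >= 1 and lengths.max() <= 125
        interior = lengths[(reads.starts > 200) & (reads.ends < 45100)]
        assert interior.min() == 75 and interior.max() == 125


class TestBiasCancellation:
    def test_enrichment_is_independent_of_a_strong_bias_field(self):
        """A 5-fold multiplicative coverage bias shared by ChIP and input
        must cancel in the normalized track: feature means with and
        without the bias agree within sampling error."""
        means = {}
        for label, strength in (("flat", 0.0), ("biased", 0.6)):
            sc = build_mef_scenario("WT", seed=11)
            sc.bias_field = make_bias_field(sc.repeat_length, seed=99,
                                            strength=strength)
            if strength:
                assert sc.bias_field.max() / sc.bias_field.min() > 5
            chip = sample_reads(sc, "UBF", 150_000, seed=21)
            inp = sample_reads(sc, "input", 150_000, seed=22)
            enr = enrichment_pipeline(chip, inp, sc.repeat_length)
            feats = {f.name: f for f in sc.features}
            means[label] = {
                name: summarize_feature(enr, feats[name]).mean_enrichment
                for name in ("47S", "IGS", "Enhancers")
            }
        for name in means["flat"]:
            denom = max(means["flat"][name], 0.05)
            assert means["biased"][name] == pytest.approx(
                means["flat"][name], rel=0.10, abs=0.05
            ), (name, means)


class TestGelTraceAndSequence:
    def test_equal_fraction_trace_is_symmetric(self):
        tr = simulate_gel_trace(0.5, noise_sd=0.0, baseline=(0.0, 0.0),
                                centers=(80.0, 160.0), n_points=241)
        y = tr.intensities
        np.testing.assert_allclose(y, y[::-1], atol=1e-9)

    def test_same_seed_reproduces_the_trace(self):
        a = simulate_gel_trace(0.64, noise_sd=1.0, seed=4)
        b = simulate_gel_trace(0.64, noise_sd=1.0, seed=4)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_gel_trace(0.5, noise_sd=-1.0)

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError):
            simulate_gel_trace(1.2)

    def test_random_sequence_has_requested_gc_structure(self):
        seq = random_repeat_sequence(10_000, seed=3, gc_low=0.40, gc_high=0.80)
        assert len(seq) == 10_000
        assert set(seq) <= set("ACGT")
        gc = sum(b in "GC" for b in seq) / len(seq)
        assert 0.40 < gc < 0.80


def test_write_scenario_emits_complete_dataset(tmp_path):
    sc = build_mef_scenario("WT", seed=2)
    artifacts = write_scenario(sc, tmp_path / "sim", depth=2000,
                               factors=["RPI", "H3"])
    for key in ("RPI", "H3", "input", "features_tsv", "features_bed",
                "ground_truth", "gel_trace", "repeat_fasta"):
        assert key in artifacts
        assert (tmp_path / "sim").joinpath(artifacts[key].split("/")[-1]).exists()
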