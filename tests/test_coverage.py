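"""Read extension, coverage, smoothing, RPM and input normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdnamap.coverage import (
    RPM,
    AlignedReadSet,
    CoverageTrack,
    compute_coverage,
    extend_reads,
    normalize_to_input,
    read_bed_reads,
    smooth_track,
    to_rpm,
    write_bed_reads,
)


def _reads(records, total=0):
    starts, ends, strands = zip(*records)
    return AlignedReadSet(
        "rDNA", np.array(starts), np.array(ends), np.array(strands),
        library_total_reads=total,
    )


class TestExtendReads:
    def test_plus_strand_extends_downstream(self):
        out = extend_reads(_reads([(101, 150, "+")]), fragment_length=100)
        assert (out.starts[0], out.ends[0]) == (101, 200)

    def test_minus_strand_extends_upstream(self):
        out = extend_reads(_reads([(101, 150, "-")]), fragment_length=100)
        assert (out.starts[0], out.ends[0]) == (51, 150)

    def test_circular_fragment_wraps_around_origin(self):
        L = 1000
        out = extend_reads(
            _reads([(L - 9, L, "+")]), fragment_length=100,
            reference_length=L, circular=True,
        )
        cov = compute_coverage(out, L, circular=True)
        covered = set(np.flatnonzero(cov.values > 0) + 1)
        expected = set(range(L - 9, L + 1)) | set(range(1, 91))
        assert covered == expected

    def test_linear_fragments_are_clipped(self):
        out = extend_reads(
            _reads([(5, 30, "-")]), fragment_length=100, reference_length=200
        )
        assert (out.starts[0], out.ends[0]) == (1, 30)

    def test_unknown_strand_is_an_error(self):
        with pytest.raises(ValueError, match="strand"):
            extend_reads(_reads([(1, 10, ".")]))


class TestComputeCoverage:
    def test_single_fragment(self):
        cov = compute_coverage(_reads([(101, 200, "+")]), 300)
        assert cov.values.sum() == 100
        assert (cov.values[100:200] == 1).all()

    def test_duplicate_fragments_stack(self):
        cov = compute_coverage(_reads([(10, 19, "+"), (10, 19, "-")]), 50)
        assert (cov.values[9:19] == 2).all()

    @pytest.mark.parametrize("circular", [False, True])
    def test_total_coverage_equals_total_fragment_length(self, rng, circular):
        L = 2000
        starts = rng.integers(1, L + 1, 1000)
        lengths = rng.integers(50, 150, 1000)
        reads = AlignedReadSet(
            "rDNA", starts, starts + lengths - 1,
            np.full(1000, "+"),
        )
        if not circular:
            reads = AlignedReadSet(
                "rDNA", reads.starts, np.minimum(reads.ends, L),
                reads.strands,
            )
        cov = compute_coverage(reads, L, circular=circular)
        assert cov.values.sum() == (reads.ends - reads.starts + 1).sum()


class TestSmoothing:
    @pytest.mark.parametrize("circular", [False, True])
    def test_constant_track_is_unchanged(self, circular):
        track = CoverageTrack(np.full(200, 3.5))
        out = smooth_track(track, 25, circular=circular)
        np.testing.assert_allclose(out.values, 3.5)

    def test_interior_spike_spreads_to_exact_window_mean(self):
        j = np.zeros(500)
        j[249] = 25  # position 250, 1-based
        out = smooth_track(CoverageTrack(j), 25)
        np.testing.assert_allclose(out.values[237:262], 1.0)
        assert out.values[236] == 0 and out.values[262] == 0

    def test_window_one_is_identity(self):
        j = np.arange(50, dtype=float)
        out = smooth_track(CoverageTrack(j), 1)
        np.testing.assert_array_equal(out.values, j)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            smooth_track(CoverageTrack(np.ones(10)), 24)

    def test_circular_smoothing_conserves_total(self, rng):
        j = rng.poisson(5, 1000).astype(float)
        out = smooth_track(CoverageTrack(j), 25, circular=True)
        assert out.values.sum() == pytest.approx(j.sum(), rel=1e-12)

    def test_linear_edge_renormalization_keeps_constant_tracks_flat(self):
        out = smooth_track(CoverageTrack(np.full(100, 2.0)), 25)
        np.testing.assert_allclose(out.values, 2.0)


class TestRPM:
    def test_scaling(self):
        track = CoverageTrack(np.array([5.0]))
        assert to_rpm(track, 10**6).values[0] == 5.0
        assert to_rpm(track, 2 * 10**6).values[0] == 2.5

    def test_total_scales_with_depth(self, rng):
        j = rng.poisson(4, 300).astype(float)
        out = to_rpm(CoverageTrack(j), 12345)
        assert out.values.sum() == pytest.approx(j.sum() * 1e6 / 12345)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            to_rpm(CoverageTrack(np.ones(5)), 0)


class TestNormalization:
    def _rpm(self, values):
        return CoverageTrack(np.asarray(values, float), scale=RPM, smoothed=True)

    def test_self_normalization_is_unity(self, rng):
        v = rng.random(500) + 0.5
        track = self._rpm(v)
        enr = normalize_to_input(track, track)
        np.testing.assert_allclose(enr.values[~enr.mask], 1.0)
        assert not enr.mask.any()

    def test_doubled_chip_gives_two(self):
        v = np.full(100, 4.0)
        enr = normalize_to_input(self._rpm(2 * v), self._rpm(v))
        np.testing.assert_allclose(enr.values, 2.0)

    def test_low_input_bases_are_masked_not_infinite(self):
        inp = np.full(100, 10.0)
        inp[40] = 0.0
        inp[41] = 1e-9
        enr = normalize_to_input(self._rpm(np.ones(100)), self._rpm(inp))
        assert enr.mask[40] and enr.mask[41]
        assert np.isnan(enr.values[40])
        assert np.isfinite(enr.values[~enr.mask]).all()

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            normalize_to_input(self._rpm(np.ones(10)), self._rpm(np.ones(11)))

    def test_unscaled_tracks_rejected(self):
        raw = CoverageTrack(np.ones(10))
        with pytest.raises(ValueError, match="smoothed and RPM"):
            normalize_to_input(raw, raw)


@given(total=st.integers(1000, 10**7))
@settings(max_examples=20, deadline=None)
def test_smoothing_and_rpm_commute(total):
    """Both operations are linear, so their order cannot matter."""
    rng = np.random.default_rng(0)
    j = rng.poisson(3, 400).astype(float)
    a = to_rpm(smooth_track(CoverageTrack(j), 25), total)
    b = smooth_track(to_rpm(CoverageTrack(j), total), 25)
    np.testing.assert_allclose(a.values, b.values, rtol=1e-12)
    assert a.scale == b.scale == RPM


def test_bed_round_trip(tmp_path, rng):
    starts = rng.integers(1, 1000, 50)
    reads = AlignedReadSet(
        "rDNA", starts, starts + 49,
        np.where(rng.random(50) < 0.5, "+", "-"),
    )
    path = tmp_path / "reads.bed"
    write_bed_reads(reads, path)
    back = read_bed_reads(path)
    np.testing.assert_array_equal(back.starts, reads.starts)
    np.testing.assert_array_equal(back.ends, reads.ends)
    np.testing.assert_array_equal(back.strands, reads.strands)
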