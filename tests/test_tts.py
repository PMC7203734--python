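import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pta.coverage import CoverageTrack
from pta.intervals import GenomicInterval, mirror_interval
from pta.tts import (
    STATUS_DECAY,
    STATUS_NO_DECAY,
    STATUS_NO_PEAK,
    BinnedSignal,
    TTSParams,
    UnprocessableRegion,
    bin_signal,
    define_search_region,
    fit_smooth_curve,
    infer_tts,
    locate_decay,
    locate_peak,
)

from conftest import track_from_bases


def uniform_track(chrom, strand, start, end, rate=1):
    return CoverageTrack.from_steps(
        {(chrom, strand): (np.array([start]), np.array([end]), np.array([rate]))}
    )


def binned_from(counts, strand="+", B=100):
    counts = np.asarray(counts, dtype=np.int64)
    n = len(counts)
    if strand == "+":
        edges = np.arange(n, dtype=np.int64) * B
    else:
        edges = (np.arange(n, dtype=np.int64)[::-1] + 1) * B
    return BinnedSignal("chr1", strand, B, edges, counts)


class TestSearchRegion:
    def test_plus_strand_arithmetic(self):
        gene = GenomicInterval("chr1", 0, 10_000, "+", id="g")
        region = define_search_region(gene, 0.2, 5_000)
        assert (region.region_iv.start, region.region_iv.end) == (8_000, 15_000)

    def test_minus_strand_mirror(self):
        gene = GenomicInterval("chr1", 5_000, 10_000, "-", id="g")
        region = define_search_region(gene, 0.2, 1_000)
        assert (region.region_iv.start, region.region_iv.end) == (4_000, 6_000)

    def test_length_formula_on_random_genes(self):
        rng = np.random.default_rng(30)
        for _ in range(100):
            start = int(rng.integers(20_000, 50_000))
            length = int(rng.integers(1_000, 30_000))
            frac = float(rng.uniform(0.05, 1.0))
            ext = int(rng.integers(0, 10_000))
            gene = GenomicInterval("chr1", start, start + length, rng.choice(["+", "-"]), id="g")
            region = define_search_region(gene, frac, ext)
            assert len(region.region_iv) == int(round(frac * length)) + ext

    def test_clipped_at_chromosome_bounds(self):
        gene = GenomicInterval("chr1", 100, 600, "-", id="g")
        region = define_search_region(gene, 1.0, 1_000)
        assert region.region_iv.start == 0
        gene = GenomicInterval("chr1", 100, 600, "+", id="g")
        region = define_search_region(gene, 1.0, 1_000, chrom_len=1_200)
        assert region.region_iv.end == 1_200


class TestBinSignal:
    def test_uniform_coverage_fills_bins(self):
        track = uniform_track("chr1", "+", 0, 20_000)
        gene = GenomicInterval("chr1", 0, 10_000, "+", id="g")
        region = define_search_region(gene, 0.2, 5_000)
        binned = bin_signal(region, track, B=100)
        assert binned.n_bins == 70
        assert np.all(binned.counts == 100)

    def test_trailing_partial_bin_dropped(self):
        track = uniform_track("chr1", "+", 0, 5_000)
        gene = GenomicInterval("chr1", 0, 1_000, "+", id="g")
        region = define_search_region(gene, 0.05, 1_000)  # 1050 bases
        binned = bin_signal(region, track, B=100)
        assert binned.n_bins == 10
        assert int(binned.counts.sum()) == 1_000

    def test_too_few_bins_is_unprocessable(self):
        track = uniform_track("chr1", "+", 0, 5_000)
        gene = GenomicInterval("chr1", 0, 1_000, "+", id="g")
        region = define_search_region(gene, 0.1, 200)
        with pytest.raises(UnprocessableRegion):
            bin_signal(region, track, B=100)

    def test_bin_sums_match_region_counts_on_random_fixtures(self, random_oracle):
        track, oracle = random_oracle(seed=31)
        rng = np.random.default_rng(32)
        for _ in range(200):
            strand = rng.choice(["+", "-"])
            start = int(rng.integers(0, 30_000))
            length = int(rng.integers(2_000, 15_000))
            gene = GenomicInterval("chr1", start + 1, start + length, strand, id="g")
            region = define_search_region(gene, 0.5, 1_000)
            B = int(rng.choice([50, 100, 200]))
            binned = bin_signal(region, track, B=B)
            iv = region.region_iv
            span = (
                GenomicInterval("chr1", iv.start, iv.start + binned.n_bins * B, "+")
                if strand == "+"
                else GenomicInterval("chr1", iv.end - binned.n_bins * B, iv.end, "-")
            )
            assert int(binned.counts.sum()) == oracle.count(span)
            # per-bin agreement with the dense oracle
            for i in range(binned.n_bins):
                edge = binned.bin_edges[i]
                lo, hi = (edge, edge + B) if strand == "+" else (edge - B, edge)
                assert binned.counts[i] == oracle.count(GenomicInterval("chr1", lo, hi, strand))


class TestSmoothCurve:
    def test_constant_counts_reproduced(self):
        binned = binned_from([7] * 20)
        fitted = fit_smooth_curve(binned)
        assert np.max(np.abs(fitted - 7)) < 1e-6 * 7

    def test_linear_ramp_reproduced(self):
        y = np.arange(1, 31) * 3
        fitted = fit_smooth_curve(binned_from(y))
        assert np.max(np.abs(fitted - y)) < 1e-6 * y.max()

    def test_all_zero_counts_fit_zero_and_no_peak(self):
        binned = binned_from([0] * 10)
        fitted = fit_smooth_curve(binned)
        assert np.all(fitted == 0)
        assert locate_peak(binned) is None

    def test_noiseless_triangle_argmax_preserved(self):
        y = np.concatenate([np.arange(0, 200, 10), np.arange(200, -1, -10)])
        binned = binned_from(y)
        fitted = fit_smooth_curve(binned)
        assert int(np.argmax(fitted)) == int(np.argmax(y))

    def test_four_bin_region_fits_counts_exactly(self):
        binned = binned_from([1, 5, 9, 2])
        assert np.allclose(fit_smooth_curve(binned), [1, 5, 9, 2])


class TestPeakAndDecay:
    def test_global_maximum_located(self):
        binned = binned_from([1, 2, 9, 3, 1])
        binned.fitted = binned.counts.astype(float)
        assert locate_peak(binned, floor=0.5) == 2

    def test_peak_below_background_floor_suppressed(self):
        binned = binned_from([4, 4, 4, 4, 4, 4])
        binned.fitted = binned.counts.astype(float)
        # floor = max(1, 0.5 * mean(first 3)) = 2 by default; flat 4 passes
        assert locate_peak(binned) == 0
        # silent region with a 1-read blip stays peakless
        blip = binned_from([0, 0, 0, 1, 0, 0])
        blip.fitted = blip.counts.astype(float)
        assert locate_peak(blip) is None

    def test_decay_threshold_scan(self):
        binned = binned_from([0, 10, 5, 2, 1, 1])
        binned.fitted = np.array([0.0, 10.0, 5.0, 2.0, 0.5, 0.2])
        assert locate_decay(binned, 1, tau=0.1) == 4

    def test_monotone_tail_never_decays(self):
        binned = binned_from([1, 10, 10, 11, 12, 13])
        binned.fitted = binned.counts.astype(float)
        assert locate_decay(binned, 1, tau=0.1) is None

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1_000), min_size=5, max_size=60),
        st.integers(0, 10),
        st.floats(0.01, 0.99),
    )
    def test_decay_agrees_with_linear_scan_oracle(self, fitted, peak, tau):
        fitted = np.asarray(fitted)
        peak = min(peak, len(fitted) - 1)
        binned = binned_from(np.zeros(len(fitted), dtype=int))
        binned.fitted = fitted
        expected = None
        for j in range(peak + 1, len(fitted)):
            if fitted[j] <= tau * fitted[peak]:
                expected = j
                break
        assert locate_decay(binned, peak, tau) == expected

    def test_decreasing_tau_never_moves_decay_5prime(self):
        rng = np.random.default_rng(33)
        fitted = np.sort(rng.uniform(0, 100, 40))[::-1]
        binned = binned_from(np.zeros(40, dtype=int))
        binned.fitted = fitted
        prev = None
        for tau in (0.5, 0.3, 0.1, 0.05):
            j = locate_decay(binned, 0, tau)
            if prev is not None and j is not None:
                assert j >= prev
            prev = j if j is not None else prev


class TestInferTTS:
    def make_profile_track(self):
        """Body at 1 read/base to 10,000; termination ramp decaying to zero
        at 12,000; silence beyond."""
        body = np.ones(10_000)
        ramp_len = 2_000
        ramp = np.rint(6.0 * (1.0 - np.arange(ramp_len) / ramp_len))
        dense = np.concatenate([body, ramp, np.zeros(8_000)])
        return CoverageTrack.from_dense({("chr1", "+"): dense.astype(np.int64)})

    def test_composed_inference_hits_planted_decay(self):
        track = self.make_profile_track()
        gene = GenomicInterval("chr1", 0, 10_000, "+", id="g")
        call = infer_tts(gene, track, TTSParams(0.2, 5_000, 200, 0.1))
        assert call.status == STATUS_DECAY
        assert 11_800 <= call.tts <= 12_400

    def test_sharp_peak_with_silent_downstream(self):
        # a lone narrow spike needs a light explicit penalty: GCV treats a
        # single outlying bin as noise and smears it
        bases = {9_990 + i: 50 for i in range(10)}
        bases.update({i: 1 for i in range(9_000, 9_990, 3)})
        track = track_from_bases("chr1", "+", bases)
        gene = GenomicInterval("chr1", 0, 10_000, "+", id="g")
        call = infer_tts(gene, track, TTSParams(0.1, 4_000, 200, 0.1, smoothness=0.1))
        assert call.status == STATUS_DECAY
        assert call.peak_coordinate == 9_900  # centre of the spike's bin
        assert call.tts <= 10_400  # within a bin past the peak

    def test_all_zero_region_falls_back_to_annotated_end(self):
        track = track_from_bases("chr1", "+", {5: 1})
        gene = GenomicInterval("chr1", 100_000, 110_000, "+", id="g")
        call = infer_tts(gene, track)
        assert call.status == STATUS_NO_PEAK and call.tts == 110_000

    def test_never_decaying_signal_falls_back_to_region_end(self):
        track = uniform_track("chr1", "+", 0, 50_000, rate=5)
        gene = GenomicInterval("chr1", 0, 10_000, "+", id="g")
        call = infer_tts(gene, track, TTSParams(0.2, 5_000, 200, 0.1))
        assert call.status == STATUS_NO_DECAY and call.tts == 15_000

    def test_tts_stays_inside_search_region(self, noisy_study):
        track, truth = noisy_study
        for spec in truth.specs.values():
            call = infer_tts(spec.annotated_iv, track)
            region = define_search_region(spec.annotated_iv)
            assert region.region_iv.start <= call.tts <= region.region_iv.end

    def test_mirror_symmetry_of_full_composition(self, noiseless_study):
        track, truth = noiseless_study
        L = truth.chrom_len
        mirrored = track.mirrored(L)
        for spec in list(truth.specs.values())[:20]:
            c1 = infer_tts(spec.annotated_iv, track)
            c2 = infer_tts(mirror_interval(spec.annotated_iv, L), mirrored)
            assert c2.status == c1.status
            assert c2.tts == L - c1.tts

    def test_readthrough_detected_past_annotated_end(self, noiseless_study):
        track, truth = noiseless_study
        past = 0
        for spec in truth.specs.values():
            call = infer_tts(spec.annotated_iv, track)
            d = (call.tts - spec.body_end if spec.strand == "+"
                 else spec.body_end - call.tts)
            past += d > 0
        assert past >= 95
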