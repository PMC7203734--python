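import numpy as np
import pytest

from pta.intervals import GenomicInterval, mirror_interval
from pta.prep import GeneIntervalSet, collect_first_exons
from pta.synth import default_study, generate_coverage
from pta.tss import candidate_window_count, distance_to_peak, infer_tss

from conftest import track_from_bases


def gene_set(gene_id, chrom, strand, largest, candidates):
    exons = []
    for c in sorted(candidates, reverse=(strand == "-")):
        if strand == "+":
            exons.append(GenomicInterval(chrom, c, c + 100, strand))
        else:
            exons.append(GenomicInterval(chrom, c - 100, c, strand))
    return GeneIntervalSet(gene_id, largest, tuple(exons))


class TestCandidateWindowCount:
    def test_no_signal_is_zero(self):
        track = track_from_bases("chr1", "+", {})
        assert candidate_window_count(track, "chr1", 1000, "+", 500) == 0

    def test_single_base_inside_window(self):
        track = track_from_bases("chr1", "+", {1010: 7})
        assert candidate_window_count(track, "chr1", 1000, "+", 500) == 7
        assert candidate_window_count(track, "chr1", 1000, "+", 5) == 0

    def test_minus_strand_window_extends_upstream_in_coordinates(self):
        track = track_from_bases("chr1", "-", {990: 3})
        assert candidate_window_count(track, "chr1", 1000, "-", 500) == 3
        assert candidate_window_count(track, "chr1", 1000, "-", 5) == 0

    def test_agrees_with_dense_oracle(self, random_oracle):
        track, oracle = random_oracle(seed=20)
        rng = np.random.default_rng(21)
        for _ in range(300):
            tss = int(rng.integers(600, 49_000))
            strand = rng.choice(["+", "-"])
            W = int(rng.integers(1, 600))
            iv = (GenomicInterval("chr1", tss, tss + W, "+") if strand == "+"
                  else GenomicInterval("chr1", tss - W, tss, "-"))
            assert candidate_window_count(track, "chr1", tss, strand, W) == oracle.count(iv)

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            candidate_window_count(track_from_bases("c", "+", {}), "c", 0, "+", 0)


class TestInferTSS:
    def test_single_candidate_returned_regardless_of_signal(self):
        largest = GenomicInterval("chr1", 100, 5_000, "+", id="g")
        gs = gene_set("g", "chr1", "+", largest, [100])
        call = infer_tss(gs, track_from_bases("chr1", "+", {}))
        assert call.tss == 100 and call.zero_signal

    def test_candidate_with_maximal_window_count_wins(self):
        largest = GenomicInterval("chr1", 100, 5_000, "+", id="g")
        gs = gene_set("g", "chr1", "+", largest, [100, 300])
        track = track_from_bases("chr1", "+", {150: 5, 350: 50})
        # window 500: candidate 100 sees 55, candidate 300 sees 50
        assert infer_tss(gs, track, W=500).tss == 100
        # window 100: candidate 100 sees 5, candidate 300 sees 50
        call = infer_tss(gs, track, W=100)
        assert call.tss == 300 and call.window_count == 50

    def test_tie_broken_toward_most_5prime(self):
        largest = GenomicInterval("chr1", 100, 5_000, "+", id="g")
        gs = gene_set("g", "chr1", "+", largest, [100, 1000])
        track = track_from_bases("chr1", "+", {150: 9, 1050: 9})
        call = infer_tss(gs, track, W=500)
        assert call.tss == 100 and call.tie_broken

    def test_invariant_to_candidate_order(self):
        largest = GenomicInterval("chr1", 100, 5_000, "-", id="g")
        track = track_from_bases("chr1", "-", {4_400: 20, 2_000: 3})
        a = gene_set("g", "chr1", "-", largest, [4_500, 3_000, 2_200])
        b = GeneIntervalSet("g", largest, tuple(reversed(a.first_exons)))
        assert infer_tss(a, track).tss == infer_tss(b, track).tss == 4_500

    def test_empty_candidate_set_is_an_error(self):
        largest = GenomicInterval("chr1", 100, 5_000, "+", id="g")
        with pytest.raises(ValueError):
            infer_tss(GeneIntervalSet("g", largest, ()), track_from_bases("chr1", "+", {}))

    def test_planted_pause_peak_recovered_on_every_noiseless_gene(self, noiseless_study):
        track, truth = noiseless_study
        genes = collect_first_exons(truth.isoforms())
        hits = sum(
            infer_tss(genes[g], track).tss == truth.specs[g].true_tss
            for g in genes
        )
        assert hits == len(genes) == 100

    def test_mirror_symmetry(self, noiseless_study):
        track, truth = noiseless_study
        L = truth.chrom_len
        mirrored_track = track.mirrored(L)
        genes = collect_first_exons(truth.isoforms())
        for g in list(sorted(genes))[:20]:
            gs = genes[g]
            m = GeneIntervalSet(
                g, mirror_interval(gs.largest_iv, L),
                tuple(mirror_interval(e, L) for e in gs.first_exons),
            )
            assert infer_tss(m, mirrored_track).tss == L - infer_tss(gs, track).tss


class TestDistanceToPeak:
    def test_single_peak_downstream(self):
        track = track_from_bases("chr1", "+", {1_037: 4})
        assert distance_to_peak(track, "chr1", 1_000, "+") == 37

    def test_no_signal_returns_none(self):
        track = track_from_bases("chr1", "+", {10_000: 4})
        assert distance_to_peak(track, "chr1", 1_000, "+") is None

    def test_equidistant_maxima_resolve_downstream(self):
        track = track_from_bases("chr1", "+", {980: 4, 1_020: 4})
        assert distance_to_peak(track, "chr1", 1_000, "+") == 20

    def test_minus_strand_downstream_is_leftward(self):
        track = track_from_bases("chr1", "-", {962: 4})
        # tss boundary 1000 -> tss base 999; peak 37 bases downstream (leftward)
        assert distance_to_peak(track, "chr1", 1_000, "-") == 37

    def test_inferred_tss_never_farther_from_pause_peak_than_largest_interval(
        self, noiseless_study
    ):
        """The qualitative content of the TSS evaluation: distances from the
        start coordinate to the nearest read peak are collectively smaller
        under inferred TSSs than under largest-interval starts."""
        track, truth = noiseless_study
        genes = collect_first_exons(truth.isoforms())
        inferred_total = 0
        largest_total = 0
        for g, gs in genes.items():
            strand = gs.largest_iv.strand
            call = infer_tss(gs, track)
            d_inf = distance_to_peak(track, call.chrom, call.tss, strand)
            d_large = distance_to_peak(track, call.chrom, gs.largest_iv.five_prime, strand)
            inferred_total += abs(d_inf) if d_inf is not None else 501
            largest_total += abs(d_large) if d_large is not None else 501
        assert inferred_total <= largest_total
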