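"""TTS inference: binned 3' signal, smoothing-spline fit, peak and decay.

RNA polymerase density rises near gene ends (termination is slow) and then
decays to background some distance past the polyadenylation/cleavage site.
The termination site is therefore inferred per gene by

1. defining a search region from the 3'-most fraction of the gene to a
   fixed extension past the most distal annotated end,
2. tiling it with uniform bins and counting reads per bin,
3. fitting a penalized cubic smoothing spline to the binned counts,
4. taking the global maximum of the fitted curve as the terminal peak, and
5. walking 3' from the peak to the first bin whose fitted value falls to a
   fraction ``tau`` of the peak value — the decay point. The TTS is the 5'
   edge of that bin (the conservative choice within the bin's +/-B ambiguity).

Fallbacks keep every gene reportable: no peak above the background floor
maps the TTS to the annotated gene end; a peak that never decays before the
region end maps it to the region end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .coverage import CoverageTrack
from .intervals import GenomicInterval

MIN_BINS = 4  # spline support

STATUS_DECAY = "decay_found"
STATUS_NO_DECAY = "no_decay_region_end"
STATUS_NO_PEAK = "no_peak_gene_end"
STATUS_UNPROCESSABLE = "unprocessable"


class UnprocessableRegion(ValueError):
    """Search region too short to bin and fit."""


@dataclass(frozen=True)
class TTSParams:
    """Tunable knobs of the TTS procedure (all lengths in bases)."""

    gene_fraction: float = 0.2
    downstream_extension: int = 10_000
    bin_width: int = 200
    tau: float = 0.1
    smoothness: float | None = None  # spline penalty; None = GCV-selected

    def __post_init__(self) -> None:
        if not 0 < self.gene_fraction <= 1:
            raise ValueError("gene_fraction must be in (0, 1]")
        if self.downstream_extension < 0:
            raise ValueError("downstream_extension must be >= 0")
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        if not 0 < self.tau < 1:
            raise ValueError("tau must be in (0, 1)")


@dataclass(frozen=True)
class TTSSearchRegion:
    gene_id: str
    region_iv: GenomicInterval
    gene_fraction: float
    downstream_extension: int


@dataclass
class BinnedSignal:
    """Uniform bins over a search region, ordered 5' to 3'.

    ``bin_edges[i]`` is the 5' genomic edge of bin i (for a minus-strand
    region edges decrease with i).
    """

    chrom: str
    strand: str
    bin_width: int
    bin_edges: np.ndarray  # 5' edge per bin, length n
    counts: np.ndarray  # int, length n
    fitted: np.ndarray | None = None
    peak_index: int | None = None
    decay_index: int | None = None

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def bin_five_prime_edge(self, i: int) -> int:
        return int(self.bin_edges[i])

    def bin_center(self, i: int) -> int:
        half = self.bin_width // 2
        return int(self.bin_edges[i]) + (half if self.strand == "+" else -half)


@dataclass(frozen=True)
class TTSCall:
    gene_id: str
    chrom: str
    strand: str
    tts: int
    status: str
    peak_coordinate: int | None = None
    n_bins: int = 0


def define_search_region(
    gene: GenomicInterval,
    gene_fraction: float = 0.2,
    downstream_extension: int = 10_000,
    chrom_len: int | None = None,
) -> TTSSearchRegion:
    """Span the 3'-most ``gene_fraction`` of the gene plus the extension.

    The region starts inside the gene and ends exactly
    ``downstream_extension`` bases past its annotated 3' end, clipped at
    chromosome bounds when ``chrom_len`` is known.
    """
    if not 0 < gene_fraction <= 1:
        raise ValueError("gene_fraction must be in (0, 1]")
    if downstream_extension < 0:
        raise ValueError("downstream_extension must be >= 0")
    flen = int(round(gene_fraction * len(gene)))
    if gene.strand == "+":
        start = gene.end - flen
        end = gene.end + downstream_extension
    else:
        start = gene.start - downstream_extension
        end = gene.start + flen
    start = max(0, start)
    if chrom_len is not None:
        end = min(end, chrom_len)
    iv = GenomicInterval(gene.chrom, start, end, gene.strand, id=gene.id)
    return TTSSearchRegion(gene.id or "", iv, gene_fraction, downstream_extension)


def bin_signal(region: TTSSearchRegion, track: CoverageTrack, B: int = 200) -> BinnedSignal:
    """Tile whole bins of width B from the region's 5' end; count reads.

    ``floor(len/B)`` bins are used; a trailing partial bin is discarded.
    Fewer than four whole bins cannot support the spline fit and raises
    :class:`UnprocessableRegion`.
    """
    if B < 1:
        raise ValueError("bin width must be >= 1")
    iv = region.region_iv
    n = len(iv) // B
    if n < MIN_BINS:
        raise UnprocessableRegion(
            f"{region.gene_id}: region of {len(iv)} bases gives {n} bins (< {MIN_BINS})"
        )
    if iv.strand == "+":
        ascending = iv.start + np.arange(n + 1, dtype=np.int64) * B
        counts = track.bin_counts(iv.chrom, "+", ascending)
        edges = ascending[:-1]
    else:
        ascending = iv.end - (n - np.arange(n + 1, dtype=np.int64)) * B
        counts = track.bin_counts(iv.chrom, "-", ascending)[::-1]
        edges = (iv.end - np.arange(n, dtype=np.int64) * B)
    return BinnedSignal(iv.chrom, iv.strand, B, edges, counts.astype(np.int64))


def fit_smooth_curve(binned: BinnedSignal, smoothness: float | None = None) -> np.ndarray:
    """Penalized cubic smoothing spline through the bin counts.

    Fit in bin-index coordinates so the penalty is bin-width-free;
    ``smoothness`` is the roughness penalty lambda (0 interpolates,
    None lets generalized cross-validation choose). Constant and linear
    profiles are reproduced exactly for any penalty. All-zero counts yield
    an all-zero fit.
    """
    y = binned.counts.astype(np.float64)
    if binned.n_bins < MIN_BINS:
        raise UnprocessableRegion("too few bins for spline fit")
    if not np.any(y > 0):
        fitted = np.zeros_like(y)
    elif binned.n_bins < 5:
        # below the smoother's minimum support: zero-penalty limit, i.e. the
        # interpolating fit, whose values at the bins are the counts themselves
        fitted = y.copy()
    else:
        x = np.arange(binned.n_bins, dtype=np.float64)
        spline = make_smoothing_spline(x, y, lam=smoothness)
        fitted = np.asarray(spline(x), dtype=np.float64)
    binned.fitted = fitted
    return fitted


def background_floor(counts: np.ndarray) -> float:
    """Minimum fitted height for a credible terminal peak.

    Half the mean of the three 5'-most bins, but never below one read:
    prevents peak calls in silent regions while staying permissive for
    genes whose termination signal only modestly exceeds the body level.
    """
    return max(1.0, 0.5 * float(np.mean(counts[:3])))


def locate_peak(binned: BinnedSignal, floor: float | None = None) -> int | None:
    """Index of the fitted curve's global maximum, or None below the floor.

    Ties break toward the most 5' bin.
    """
    if binned.fitted is None:
        raise ValueError("fit_smooth_curve must run before locate_peak")
    if floor is None:
        floor = background_floor(binned.counts)
    idx = int(np.argmax(binned.fitted))
    if binned.fitted[idx] <= floor:
        binned.peak_index = None
        return None
    binned.peak_index = idx
    return idx


def locate_decay(binned: BinnedSignal, peak_index: int, tau: float = 0.1) -> int | None:
    """First bin past the peak whose fitted value is <= tau * peak value."""
    if binned.fitted is None:
        raise ValueError("fit_smooth_curve must run before locate_decay")
    if not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")
    threshold = tau * binned.fitted[peak_index]
    below = np.flatnonzero(binned.fitted[peak_index + 1 :] <= threshold)
    if below.size == 0:
        binned.decay_index = None
        return None
    j = peak_index + 1 + int(below[0])
    binned.decay_index = j
    return j


def infer_tts(
    gene: GenomicInterval,
    track: CoverageTrack,
    params: TTSParams = TTSParams(),
    chrom_len: int | None = None,
) -> TTSCall:
    """Full TTS inference for one gene (region -> bins -> spline -> peak -> decay)."""
    gene_id = gene.id or ""
    region = define_search_region(
        gene, params.gene_fraction, params.downstream_extension, chrom_len
    )
    try:
        binned = bin_signal(region, track, params.bin_width)
    except UnprocessableRegion:
        return TTSCall(gene_id, gene.chrom, gene.strand, gene.three_prime,
                       STATUS_UNPROCESSABLE)
    fit_smooth_curve(binned, params.smoothness)
    peak = locate_peak(binned)
    if peak is None:
        return TTSCall(gene_id, gene.chrom, gene.strand, gene.three_prime,
                       STATUS_NO_PEAK, n_bins=binned.n_bins)
    peak_coord = binned.bin_center(peak)
    decay = locate_decay(binned, peak, params.tau)
    if decay is None:
        return TTSCall(gene_id, gene.chrom, gene.strand,
                       region.region_iv.three_prime, STATUS_NO_DECAY,
                       peak_coordinate=peak_coord, n_bins=binned.n_bins)
    return TTSCall(gene_id, gene.chrom, gene.strand,
                   binned.bin_five_prime_edge(decay), STATUS_DECAY,
                   peak_coordinate=peak_coord, n_bins=binned.n_bins)


def refine_gene_coordinates(
    gene: GenomicInterval, tss: int, tts_call: TTSCall
) -> GenomicInterval:
    """Combine an inferred TSS and TTS into the primary-transcript interval."""
    if gene.strand == "+":
        start, end = tss, max(tts_call.tts, tss + 1)
    else:
        start, end = min(tts_call.tts, tss - 1), tss
    return GenomicInterval(gene.chrom, start, end, gene.strand, id=gene.id)
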