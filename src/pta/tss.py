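"""Dominant-TSS inference from promoter-proximal read density.

RNA polymerase accumulates at promoter-proximal pause sites a short distance
downstream of active start sites, so among a gene's annotated first exons
the one whose 5' end has the most reads in a fixed downstream window marks
the dominant TSS. The window ``W`` (default 500 bases) is measured from the
candidate 5' end in the direction of transcription. Ties, and genes with no
signal in any window, fall back to the most 5' candidate and are flagged.

``distance_to_peak`` scores a chosen start coordinate by its signed distance
to the nearest local read maximum within ``max_dist`` bases, the quantity
used to compare inferred starts against largest-interval starts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coverage import CoverageTrack
from .intervals import GenomicInterval
from .prep import GeneIntervalSet

DEFAULT_WINDOW = 500


@dataclass(frozen=True)
class TSSCall:
    gene_id: str
    chrom: str
    strand: str
    tss: int  # 5' boundary coordinate of the winning first exon
    window_count: int
    n_candidates: int
    tie_broken: bool = False
    zero_signal: bool = False


def candidate_window_count(
    track: CoverageTrack, chrom: str, tss: int, strand: str, W: int
) -> int:
    """Reads in the W-base window downstream of a candidate 5' end.

    Plus strand counts [tss, tss+W); minus strand counts [tss-W, tss), i.e.
    the W bases transcribed first in either orientation.
    """
    if W <= 0:
        raise ValueError("window length W must be positive")
    if strand == "+":
        iv = GenomicInterval(chrom, tss, tss + W, "+")
    else:
        iv = GenomicInterval(chrom, max(0, tss - W), tss, "-")
    return track.region_counts(iv)


def infer_tss(gene: GeneIntervalSet, track: CoverageTrack, W: int = DEFAULT_WINDOW) -> TSSCall:
    """Pick the candidate first exon maximizing the downstream window count.

    With a fixed window length, ranking by count is identical to ranking by
    density. Ties break toward the most 5' candidate (``tie_broken=True``);
    if every window is empty the most 5' candidate is returned with
    ``zero_signal=True``.
    """
    if not gene.first_exons:
        raise ValueError(f"{gene.gene_id}: no candidate first exons")
    chrom = gene.largest_iv.chrom
    strand = gene.largest_iv.strand
    # first_exons are already ordered 5'->3'
    counts = [
        candidate_window_count(track, chrom, exon.five_prime, strand, W)
        for exon in gene.first_exons
    ]
    best = int(np.argmax(counts))  # argmax takes the first (most 5') on ties
    tie = counts.count(counts[best]) > 1
    zero = counts[best] == 0
    if zero:
        best = 0
    return TSSCall(
        gene_id=gene.gene_id,
        chrom=chrom,
        strand=strand,
        tss=gene.first_exons[best].five_prime,
        window_count=counts[best],
        n_candidates=len(counts),
        tie_broken=tie and not zero,
        zero_signal=zero,
    )


def distance_to_peak(
    track: CoverageTrack,
    chrom: str,
    tss: int,
    strand: str,
    max_dist: int = 500,
) -> int | None:
    """Signed distance from a start coordinate to the nearest read peak.

    A peak is a base whose count is positive and >= both neighbours.
    Distances are strand-aware (downstream positive); ties break toward the
    smaller absolute distance, then downstream. Returns None when the
    +/- ``max_dist`` window holds no signal.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    tss_base = tss if strand == "+" else tss - 1
    lo = max(0, tss_base - max_dist)
    hi = tss_base + max_dist + 1
    # pad one base each side for neighbour comparisons
    dense = track.dense(chrom, strand, max(0, lo - 1), hi + 1)
    if lo == 0:
        dense = np.concatenate(([0.0], dense))
    window = dense[1:-1]
    if not np.any(window > 0):
        return None
    is_peak = (window > 0) & (window >= dense[:-2]) & (window >= dense[2:])
    peaks = np.flatnonzero(is_peak)
    if peaks.size == 0:
        return None
    positions = lo + peaks
    if strand == "+":
        dists = positions - tss_base
    else:
        dists = tss_base - positions
    # nearest; ties -> downstream (positive)
    order = np.lexsort((-np.sign(dists), np.abs(dists)))
    return int(dists[order[0]])
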