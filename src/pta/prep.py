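"""Collapse isoform annotations into per-gene candidate structures.

Two per-gene reductions feed the downstream inference: the *largest
interval* (most upstream isoform start to most downstream isoform end) and
the set of candidate first exons (one per distinct first-exon 5' end,
ordered 5' to 3'). Genes whose isoforms disagree on chromosome or strand
are dropped with a warning rather than repaired: their identity is
ambiguous. An expression filter removes genes with too little signal for
coordinate inference to be meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .bedio import IsoformRecord
from .coverage import CoverageTrack
from .intervals import GenomicInterval

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneIntervalSet:
    """Per-gene largest interval plus deduplicated first-exon candidates."""

    gene_id: str
    largest_iv: GenomicInterval
    first_exons: tuple[GenomicInterval, ...]  # 5'->3', dedup by 5' end

    def __post_init__(self) -> None:
        for exon in self.first_exons:
            fp = exon.five_prime
            if not (self.largest_iv.start <= fp <= self.largest_iv.end):
                raise ValueError(
                    f"{self.gene_id}: first-exon 5' end {fp} outside largest interval"
                )


def _consistent_groups(isoforms: list[IsoformRecord]) -> dict[str, list[IsoformRecord]]:
    groups: dict[str, list[IsoformRecord]] = {}
    for rec in isoforms:
        groups.setdefault(rec.gene_id, []).append(rec)
    out = {}
    for gene_id, recs in groups.items():
        keys = {(r.transcript_iv.chrom, r.transcript_iv.strand) for r in recs}
        if len(keys) != 1:
            log.warning(
                "gene %s dropped: isoforms span multiple chromosomes/strands", gene_id
            )
            continue
        out[gene_id] = recs
    return out


def largest_interval(isoforms: list[IsoformRecord]) -> dict[str, GenomicInterval]:
    """Per-gene envelope [min start, max end) over all isoforms."""
    out = {}
    for gene_id, recs in _consistent_groups(isoforms).items():
        chrom = recs[0].transcript_iv.chrom
        strand = recs[0].transcript_iv.strand
        start = min(r.transcript_iv.start for r in recs)
        end = max(r.transcript_iv.end for r in recs)
        out[gene_id] = GenomicInterval(chrom, start, end, strand, id=gene_id)
    return out


def collect_first_exons(isoforms: list[IsoformRecord]) -> dict[str, GeneIntervalSet]:
    """Per-gene candidate first exons, deduplicated by 5' end, ordered 5'->3'."""
    envelopes = largest_interval(isoforms)
    out = {}
    for gene_id, recs in _consistent_groups(isoforms).items():
        strand = recs[0].transcript_iv.strand
        by_5p: dict[int, GenomicInterval] = {}
        for r in recs:
            by_5p.setdefault(r.first_exon_iv.five_prime, r.first_exon_iv)
        ordered = sorted(
            by_5p.values(),
            key=lambda e: e.five_prime,
            reverse=(strand == "-"),
        )
        out[gene_id] = GeneIntervalSet(gene_id, envelopes[gene_id], tuple(ordered))
    return out


def filter_expressed(
    genes: dict[str, GeneIntervalSet],
    track: CoverageTrack,
    min_count: int = 25,
    min_density: float = 1.0,
) -> tuple[dict[str, GeneIntervalSet], pd.DataFrame]:
    """Retain genes whose largest interval carries enough signal.

    A gene passes when its largest interval holds at least ``min_count``
    reads *and* at least ``min_density`` reads per kilobase. Returns the
    retained set and a per-gene report (count, density, retained flag).
    """
    if min_count < 0 or min_density < 0:
        raise ValueError("thresholds must be non-negative")
    rows = []
    kept = {}
    for gene_id in sorted(genes):
        gs = genes[gene_id]
        count = track.region_counts(gs.largest_iv)
        density = count / (len(gs.largest_iv) / 1000.0)
        retained = count >= min_count and density >= min_density
        if retained:
            kept[gene_id] = gs
        rows.append(
            {"gene_id": gene_id, "count": count, "density_per_kb": density,
             "retained": retained}
        )
    report = pd.DataFrame(rows, columns=["gene_id", "count", "density_per_kb", "retained"])
    return kept, report
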