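"""Assign gene identifiers to de novo transcription units (TUs).

TU callers such as groHMM segment coverage into contiguous transcribed
intervals without names. Given inferred gene coordinates, each TU is
annotated by overlap: a TU covering at least ``min_frac`` of exactly one
gene inherits that gene's name; a TU spanning several qualifying genes is
split at the midpoints between the facing boundaries of adjacent genes,
one segment per gene; a TU covering no gene is marked ``UNANNOTATED``.
The threshold applies to the fraction of the *gene* covered, so a long TU
engulfing a short gene still inherits its name.

Split segments of a parent TU always tile the parent exactly. When one
gene is covered by several TUs, each record keeps the plain ``gene_id``
and its display label gains a segment ordinal (``geneA_1``, ``geneA_2``)
in 5'-to-3' order.
"""

from __future__ import annotations

from dataclasses import dataclass

from .intervals import GenomicInterval

UNANNOTATED = "UNANNOTATED"

ORIGIN_WHOLE = "whole_tu"
ORIGIN_SPLIT = "split_segment"
ORIGIN_INTERGENIC = "intergenic"


@dataclass(frozen=True)
class TranscriptionUnit:
    iv: GenomicInterval
    source_id: str


@dataclass(frozen=True)
class AnnotatedTU:
    iv: GenomicInterval
    gene_id: str  # UNANNOTATED iff origin == intergenic
    origin: str
    overlap_fraction_of_gene: float
    parent_tu: str
    label: str  # gene_id, possibly with a segment ordinal suffix

    def __post_init__(self) -> None:
        if (self.gene_id == UNANNOTATED) != (self.origin == ORIGIN_INTERGENIC):
            raise ValueError("gene_id is UNANNOTATED exactly for intergenic TUs")


def overlap_fraction(tu: GenomicInterval, gene: GenomicInterval) -> tuple[float, float]:
    """(fraction of TU covered, fraction of gene covered) by their intersection."""
    ov = tu.overlap_length(gene)
    return ov / len(tu), ov / len(gene)


def _resolve_gene_overlaps(genes: list[GenomicInterval]) -> list[GenomicInterval]:
    """Trim overlapping genes on one chromosome/strand into a disjoint set.

    Contested bases go to the longer gene; ties to the more 5' gene. The
    inferred coordinates are normally already disjoint, so this is a
    safety net, not a modelling step.
    """
    genes = sorted(genes, key=lambda g: (g.start, g.end))
    out: list[GenomicInterval] = []
    for g in genes:
        if out and g.start < out[-1].end:
            prev = out[-1]
            prev_wins = len(prev) > len(g) or (
                len(prev) == len(g)
                and (prev.five_prime <= g.five_prime) == (g.strand == "+")
            )
            if prev_wins:
                if g.end <= prev.end:
                    continue  # fully shadowed
                g = GenomicInterval(g.chrom, prev.end, g.end, g.strand, id=g.id)
            else:
                out[-1] = GenomicInterval(
                    prev.chrom, prev.start, g.start, prev.strand, id=prev.id
                )
        out.append(g)
    return out


def annotate_tus(
    tus: list[TranscriptionUnit],
    genes: list[GenomicInterval],
    min_frac: float = 0.5,
) -> list[AnnotatedTU]:
    """Annotate every TU against the inferred gene set.

    Output order is deterministic (chrom, start, end) and independent of
    input order. Zero-length segments that can arise from degenerate
    midpoints are dropped.
    """
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    by_key: dict[tuple[str, str], list[GenomicInterval]] = {}
    for g in genes:
        if g.id is None:
            raise ValueError("every gene needs an id")
        by_key.setdefault((g.chrom, g.strand), []).append(g)
    by_key = {k: _resolve_gene_overlaps(v) for k, v in by_key.items()}

    records: list[AnnotatedTU] = []
    for tu in sorted(tus, key=lambda t: (t.iv.chrom, t.iv.start, t.iv.end, t.source_id)):
        candidates = by_key.get((tu.iv.chrom, tu.iv.strand), [])
        qualifying = []
        for g in candidates:
            _, frac_gene = overlap_fraction(tu.iv, g)
            if frac_gene >= min_frac and frac_gene > 0:
                qualifying.append((g, frac_gene))
        qualifying.sort(key=lambda t: t[0].start)

        if not qualifying:
            records.append(
                AnnotatedTU(tu.iv, UNANNOTATED, ORIGIN_INTERGENIC, 0.0,
                            tu.source_id, UNANNOTATED)
            )
        elif len(qualifying) == 1:
            g, frac = qualifying[0]
            records.append(
                AnnotatedTU(tu.iv.with_id(g.id), g.id, ORIGIN_WHOLE, frac,
                            tu.source_id, g.id)
            )
        else:
            cuts = [tu.iv.start]
            for (a, _), (b, _) in zip(qualifying, qualifying[1:]):
                # odd boundary sums round toward the TU's 5' side so that
                # splitting is exactly mirror-symmetric between strands
                mid = (a.end + b.start + (1 if tu.iv.strand == "-" else 0)) // 2
                cuts.append(min(max(mid, tu.iv.start), tu.iv.end))
            cuts.append(tu.iv.end)
            for (g, frac), lo, hi in zip(qualifying, cuts, cuts[1:]):
                if hi <= lo:
                    continue
                seg = GenomicInterval(tu.iv.chrom, lo, hi, tu.iv.strand, id=g.id)
                records.append(
                    AnnotatedTU(seg, g.id, ORIGIN_SPLIT, frac, tu.source_id, g.id)
                )

    # ordinal suffixes for genes split across several records
    counts: dict[str, int] = {}
    for r in records:
        if r.gene_id != UNANNOTATED:
            counts[r.gene_id] = counts.get(r.gene_id, 0) + 1
    labelled: list[AnnotatedTU] = []
    for r in sorted(records, key=lambda r: (r.iv.chrom, r.iv.start, r.iv.end)):
        label = r.gene_id
        if r.gene_id != UNANNOTATED and counts[r.gene_id] > 1:
            order = sorted(
                (x for x in records if x.gene_id == r.gene_id),
                key=lambda x: (x.iv.start if r.iv.strand == "+" else -x.iv.end),
            )
            ordinal = order.index(r) + 1
            label = f"{r.gene_id}_{ordinal}"
        labelled.append(
            AnnotatedTU(r.iv, r.gene_id, r.origin, r.overlap_fraction_of_gene,
                        r.parent_tu, label)
        )
    return labelled
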