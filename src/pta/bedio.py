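"""BED reading and writing (BED6, BED12, and a 6+2-column isoform table).

Isoform-level annotation enters either as BED12 (exon blocks supply the
first exon, strand-aware) or as an 8-column table: the six standard BED
fields followed by ``gene_id`` and ``transcript_id`` and, optionally, the
first exon as ``first_exon_start``/``first_exon_end``. All coordinates are
0-based half-open on read and on write.
"""

from __future__ import annotations

from dataclasses import dataclass

from .intervals import GenomicInterval


class BedFormatError(ValueError):
    pass


@dataclass(frozen=True)
class IsoformRecord:
    """One transcript isoform with its first exon.

    The first exon's 5' end coincides with the transcript 5' end, and the
    exon lies within the transcript span.
    """

    gene_id: str
    transcript_id: str
    transcript_iv: GenomicInterval
    first_exon_iv: GenomicInterval

    def __post_init__(self) -> None:
        if not self.transcript_iv.contains(self.first_exon_iv):
            raise BedFormatError(
                f"{self.transcript_id}: first exon outside transcript span"
            )
        if self.first_exon_iv.five_prime != self.transcript_iv.five_prime:
            raise BedFormatError(
                f"{self.transcript_id}: first exon 5' end != transcript 5' end"
            )


def _parse_fields(line: str, lineno: int, path: str, min_cols: int) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) == 1:  # tolerate space-separated files
        fields = line.split()
    if len(fields) < min_cols:
        raise BedFormatError(
            f"{path}:{lineno}: expected >= {min_cols} columns, got {len(fields)}"
        )
    return fields


def _strand(fields: list[str], lineno: int, path: str) -> str:
    if len(fields) < 6 or fields[5] not in ("+", "-"):
        raise BedFormatError(
            f"{path}:{lineno}: strand column required and must be + or -"
        )
    return fields[5]


def _iter_lines(path: str):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            yield lineno, stripped


def read_bed(path: str, dialect: str = "bed6"):
    """Read a BED file.

    dialect ``bed6`` returns :class:`GenomicInterval` records; ``bed12`` and
    ``isoform_table`` return :class:`IsoformRecord` records with the first
    exon extracted strand-aware (for a minus-strand transcript the first exon
    is the block with the largest end coordinate).
    """
    if dialect == "bed6":
        out_iv: list[GenomicInterval] = []
        for lineno, line in _iter_lines(path):
            f = _parse_fields(line, lineno, path, 6)
            strand = _strand(f, lineno, path)
            out_iv.append(
                GenomicInterval(f[0], int(f[1]), int(f[2]), strand, id=f[3])
            )
        return out_iv

    out: list[IsoformRecord] = []
    for lineno, line in _iter_lines(path):
        if dialect == "bed12":
            f = _parse_fields(line, lineno, path, 12)
            strand = _strand(f, lineno, path)
            chrom, start, end = f[0], int(f[1]), int(f[2])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = [
                (start + o, start + o + s) for o, s in zip(offsets, sizes)
            ]
            first = min(blocks)[0:2] if strand == "+" else max(blocks, key=lambda b: b[1])
            name = f[3]
            gene_id = name.split("|")[0]
            transcript_id = name.split("|")[-1]
            tiv = GenomicInterval(chrom, start, end, strand, id=transcript_id)
            eiv = GenomicInterval(chrom, first[0], first[1], strand)
        elif dialect == "isoform_table":
            f = _parse_fields(line, lineno, path, 8)
            strand = _strand(f, lineno, path)
            chrom, start, end = f[0], int(f[1]), int(f[2])
            gene_id, transcript_id = f[6], f[7]
            tiv = GenomicInterval(chrom, start, end, strand, id=transcript_id)
            if len(f) >= 10:
                eiv = GenomicInterval(chrom, int(f[8]), int(f[9]), strand)
            else:
                # no exon structure given: the transcript 5' end stands in,
                # with a nominal 1-base first exon
                if strand == "+":
                    eiv = GenomicInterval(chrom, start, start + 1, strand)
                else:
                    eiv = GenomicInterval(chrom, end - 1, end, strand)
        else:
            raise ValueError(f"unknown BED dialect {dialect!r}")
        out.append(IsoformRecord(gene_id, transcript_id, tiv, eiv))
    return out


def write_bed(records, path: str, header: str | None = None) -> None:
    """Write BED6 with deterministic (chrom, start, end, id) record order.

    ``records`` may be :class:`GenomicInterval` objects or (interval, score)
    pairs; an optional ``header`` comment line is prefixed with ``#``.
    """
    rows = []
    for rec in records:
        iv, score = rec if isinstance(rec, tuple) else (rec, 0)
        rows.append((iv.chrom, iv.start, iv.end, iv.id or ".", score, iv.strand))
    rows.sort(key=lambda r: (r[0], r[1], r[2], str(r[3])))
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_isoform_table(records: list[IsoformRecord], path: str, header: str | None = None) -> None:
    """Write isoforms in the 10-column table ``read_bed`` round-trips."""
    rows = sorted(
        records,
        key=lambda r: (r.transcript_iv.chrom, r.transcript_iv.start,
                       r.transcript_iv.end, r.transcript_id),
    )
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for r in rows:
            t, e = r.transcript_iv, r.first_exon_iv
            fh.write(
                "\t".join(
                    str(x)
                    for x in (t.chrom, t.start, t.end, r.transcript_id, 0,
                              t.strand, r.gene_id, r.transcript_id, e.start, e.end)
                )
                + "\n"
            )
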