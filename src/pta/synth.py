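"""Synthetic PRO-seq coverage with ground-truth transcript structure.

The generator emulates the signal features nascent run-on data shows over
an expressed gene:

* a sharp promoter-proximal *pause peak* a few tens of bases downstream of
  the true TSS (``pause_reads`` placed in a narrow window),
* uniform *gene-body* density (per-base Poisson draws with mean
  ``body_rate``) from the TSS to the annotated 3' end,
* *readthrough* at body density past the annotated end, then an elevated
  *termination peak* decaying linearly to zero over
  ``termination_decay_len`` bases — the true TTS is where that decay ends,
* optional genome-wide Poisson *background* at ``noise_rate``.

Every draw comes from one seeded generator, so output is deterministic,
and a :class:`TruthTable` records per-gene truth (TSS, TTS, isoforms,
largest interval, expected TU span) for recovery tests. What the
generator does *not* emulate: mappability gaps, GC bias, enhancer
bidirectional transcription, or overlapping genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bedio import IsoformRecord, write_bed, write_isoform_table
from .coverage import CoverageTrack, write_bedgraph
from .intervals import GenomicInterval
from .tu import TranscriptionUnit

PAUSE_WIDTH = 50  # bases over which pause reads are spread
FIRST_EXON_LEN = 150


@dataclass(frozen=True)
class SyntheticGeneSpec:
    """Ground-truth parameters for one synthetic gene.

    Coordinates are boundary coordinates in the half-open convention:
    ``true_tss`` is the 5' boundary of transcription and ``body_end`` the
    annotated 3' boundary (for a minus-strand gene ``body_end < true_tss``).
    """

    gene_id: str
    chrom: str
    strand: str
    candidate_tss_positions: tuple[int, ...]  # 5' boundaries of first exons
    true_tss: int
    pause_offset: int  # bases 3' of true_tss where the pause window starts
    pause_reads: int
    body_rate: float  # mean reads/base over the gene body
    body_end: int  # annotated 3' boundary
    readthrough_len: int
    termination_peak_reads: int
    termination_decay_len: int
    noise_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.true_tss not in self.candidate_tss_positions:
            raise ValueError(f"{self.gene_id}: true_tss not among candidates")
        if min(self.pause_reads, self.body_rate, self.noise_rate,
               self.readthrough_len, self.termination_peak_reads) < 0:
            raise ValueError(f"{self.gene_id}: rates and lengths must be >= 0")
        if self.termination_decay_len < 1:
            raise ValueError(f"{self.gene_id}: termination_decay_len must be >= 1")
        if self._dir * (self.body_end - self.true_tss) <= 0:
            raise ValueError(f"{self.gene_id}: body_end must be 3' of true_tss")

    @property
    def _dir(self) -> int:
        return 1 if self.strand == "+" else -1

    @property
    def body_len(self) -> int:
        return abs(self.body_end - self.true_tss)

    @property
    def true_tts(self) -> int:
        """Boundary coordinate where the termination decay reaches zero."""
        return self.body_end + self._dir * (
            self.readthrough_len + self.termination_decay_len
        )

    @property
    def annotated_iv(self) -> GenomicInterval:
        """Largest interval implied by the candidate isoforms."""
        if self.strand == "+":
            start = min(self.candidate_tss_positions)
            end = self.body_end
        else:
            start = self.body_end
            end = max(self.candidate_tss_positions)
        return GenomicInterval(self.chrom, start, end, self.strand, id=self.gene_id)

    @property
    def true_span(self) -> GenomicInterval:
        lo = min(self.true_tss, self.true_tts)
        hi = max(self.true_tss, self.true_tts)
        return GenomicInterval(self.chrom, lo, hi, self.strand, id=self.gene_id)

    def isoforms(self) -> list[IsoformRecord]:
        """One isoform per candidate TSS, sharing the annotated 3' end."""
        out = []
        for i, cand in enumerate(sorted(self.candidate_tss_positions)):
            tid = f"{self.gene_id}.{i + 1}"
            if self.strand == "+":
                tiv = GenomicInterval(self.chrom, cand, self.body_end, "+", id=tid)
                exon_end = min(cand + FIRST_EXON_LEN, self.body_end)
                eiv = GenomicInterval(self.chrom, cand, exon_end, "+")
            else:
                tiv = GenomicInterval(self.chrom, self.body_end, cand, "-", id=tid)
                exon_start = max(cand - FIRST_EXON_LEN, self.body_end)
                eiv = GenomicInterval(self.chrom, exon_start, cand, "-")
            out.append(IsoformRecord(self.gene_id, tid, tiv, eiv))
        return out


@dataclass
class TruthTable:
    """Per-gene ground truth consistent with the generated coverage."""

    specs: dict[str, SyntheticGeneSpec]
    chrom_len: int

    def isoforms(self) -> list[IsoformRecord]:
        return [r for s in self.specs.values() for r in s.isoforms()]

    def largest_intervals(self) -> dict[str, GenomicInterval]:
        return {g: s.annotated_iv for g, s in self.specs.items()}

    def frame(self) -> pd.DataFrame:
        rows = []
        for s in sorted(self.specs.values(), key=lambda s: (s.chrom, s.true_span.start)):
            rows.append({
                "gene_id": s.gene_id, "chrom": s.chrom, "strand": s.strand,
                "true_tss": s.true_tss, "true_tts": s.true_tts,
                "annotated_start": s.annotated_iv.start,
                "annotated_end": s.annotated_iv.end,
                "n_candidates": len(s.candidate_tss_positions),
            })
        return pd.DataFrame(rows)


def _place(dense: np.ndarray, spec: SyntheticGeneSpec, rng: np.random.Generator) -> None:
    d = spec._dir
    tss_base = spec.true_tss if d == 1 else spec.true_tss - 1

    def offsets_to_slice(o0: int, n: int) -> tuple[slice, int]:
        """Genomic slice for transcribed offsets [o0, o0+n); step always +1."""
        if d == 1:
            return slice(tss_base + o0, tss_base + o0 + n), 1
        return slice(tss_base - o0 - n + 1, tss_base - o0 + 1), -1

    # gene body (uniform density)
    if spec.body_rate > 0:
        sl, step = offsets_to_slice(0, spec.body_len)
        dense[sl] += rng.poisson(spec.body_rate, spec.body_len)
    # promoter-proximal pause peak
    if spec.pause_reads > 0:
        sl, step = offsets_to_slice(spec.pause_offset, PAUSE_WIDTH)
        alloc = rng.multinomial(spec.pause_reads, np.full(PAUSE_WIDTH, 1 / PAUSE_WIDTH))
        dense[sl] += alloc[::step]
    # readthrough past the annotated end, at body density
    if spec.readthrough_len > 0 and spec.body_rate > 0:
        sl, step = offsets_to_slice(spec.body_len, spec.readthrough_len)
        dense[sl] += rng.poisson(spec.body_rate, spec.readthrough_len)
    # termination peak decaying linearly to zero; total mass = peak reads
    if spec.termination_peak_reads > 0:
        L = spec.termination_decay_len
        peak_rate = 2.0 * spec.termination_peak_reads / L
        rates = peak_rate * (1.0 - np.arange(L) / L)
        sl, step = offsets_to_slice(spec.body_len + spec.readthrough_len, L)
        dense[sl] += rng.poisson(rates)[::step]


def generate_coverage(
    specs: list[SyntheticGeneSpec],
    chrom_len: int,
    seed: int,
) -> tuple[CoverageTrack, TruthTable]:
    """Simulate a strand pair of coverage for non-overlapping gene specs."""
    by_strand: dict[tuple[str, str], np.ndarray] = {}
    chroms = sorted({s.chrom for s in specs})
    noise_rates = {s.noise_rate for s in specs}
    if len(noise_rates) > 1:
        raise ValueError("all gene specs must share one background noise_rate")
    noise = noise_rates.pop() if noise_rates else 0.0

    spans: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for s in specs:
        lo = min(s.true_span.start, s.annotated_iv.start)
        hi = max(s.true_span.end, s.annotated_iv.end)
        spans.setdefault((s.chrom, s.strand), []).append((lo, hi, s.gene_id))
        if hi > chrom_len:
            raise ValueError(f"{s.gene_id}: extends past chrom_len")
    for key, ivs in spans.items():
        ivs.sort()
        for (l0, h0, g0), (l1, h1, g1) in zip(ivs, ivs[1:]):
            if l1 < h0:
                raise ValueError(f"overlapping gene specs {g0} and {g1} on {key}")

    rng = np.random.default_rng(seed)
    for chrom in chroms:
        for strand in ("+", "-"):
            arr = np.zeros(chrom_len, dtype=np.int64)
            if noise > 0:
                arr += rng.poisson(noise, chrom_len)
            by_strand[(chrom, strand)] = arr
    for s in specs:  # spec order fixed -> deterministic under seed
        _place(by_strand[(s.chrom, s.strand)], s, rng)

    track = CoverageTrack.from_dense(by_strand)
    return track, TruthTable({s.gene_id: s for s in specs}, chrom_len)


def generate_tu_calls(
    truth: TruthTable,
    merge_gap: int = 0,
    jitter: int = 0,
    seed: int = 0,
) -> list[TranscriptionUnit]:
    """Synthetic de novo TU calls: true transcribed spans with jittered
    boundaries; same-strand neighbours closer than ``merge_gap`` merge into
    one TU, exercising the TU-splitting path downstream."""
    rng = np.random.default_rng(seed)
    per_key: dict[tuple[str, str], list[GenomicInterval]] = {}
    for s in sorted(truth.specs.values(), key=lambda s: (s.chrom, s.strand, s.true_span.start)):
        per_key.setdefault((s.chrom, s.strand), []).append(s.true_span)
    out: list[TranscriptionUnit] = []
    n = 0
    for (chrom, strand), spans in sorted(per_key.items()):
        spans.sort(key=lambda iv: iv.start)
        merged: list[list[int]] = []
        for iv in spans:
            if merged and iv.start - merged[-1][1] < merge_gap:
                merged[-1][1] = iv.end
            else:
                merged.append([iv.start, iv.end])
        for lo, hi in merged:
            if jitter > 0:
                lo = max(0, lo + int(rng.integers(-jitter, jitter + 1)))
                hi = min(truth.chrom_len, hi + int(rng.integers(-jitter, jitter + 1)))
            n += 1
            out.append(TranscriptionUnit(
                GenomicInterval(chrom, lo, hi, strand, id=f"TU{n:04d}"), f"TU{n:04d}"
            ))
    return out


def write_fixture_files(
    track: CoverageTrack,
    truth: TruthTable,
    tus: list[TranscriptionUnit],
    outdir: str | Path,
) -> dict[str, Path]:
    """Serialize a synthetic dataset in the formats the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "plus": outdir / "coverage_plus.bedgraph",
        "minus": outdir / "coverage_minus.bedgraph",
        "isoforms": outdir / "isoforms.bed",
        "tus": outdir / "tus.bed",
        "truth": outdir / "truth.tsv",
    }
    write_bedgraph(track, str(paths["plus"]), str(paths["minus"]))
    write_isoform_table(truth.isoforms(), str(paths["isoforms"]))
    write_bed([t.iv for t in tus], str(paths["tus"]))
    truth.frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths


# -- a standard study layout ----------------------------------------------


def default_study(
    n_genes: int = 100,
    seed: int = 0,
    noise_rate: float = 0.0,
    body_rate: float = 0.5,
    pause_reads: int = 300,
    termination_peak_reads: int = 600,
    termination_decay_len: int = 600,
    readthrough_len: int = 2000,
    min_upstream_candidate_offset: int = 600,
    spacing: int = 26_000,
    chrom: str = "chrS",
) -> tuple[list[SyntheticGeneSpec], int]:
    """A realistic layout of well-separated expressed genes.

    Genes alternate strands along one chromosome with ``spacing`` bases
    between footprints (same-strand neighbours are two spacings apart, so
    3' search regions never reach the next gene). Each gene gets 2-4
    candidate first exons; the true TSS is the most 3' candidate, the
    decoys lying 0.6-3 kb upstream — so the largest-interval start always
    sits 5' of the true start, as curated annotations tend to.
    """
    rng = np.random.default_rng(seed)
    specs = []
    cursor = 15_000
    for i in range(n_genes):
        strand = "+" if i % 2 == 0 else "-"
        gene_len = int(rng.integers(8_000, 15_001))
        n_cand = int(rng.integers(2, 5))
        ups = np.sort(rng.integers(min_upstream_candidate_offset, 3_001, size=n_cand - 1))
        if strand == "+":
            tss = cursor + 3_200
            cands = tuple(int(tss - u) for u in ups[::-1]) + (tss,)
            body_end = tss + gene_len
        else:
            body_end = cursor + 200
            tss = body_end + gene_len
            cands = (tss,) + tuple(int(tss + u) for u in ups)
        specs.append(SyntheticGeneSpec(
            gene_id=f"gene{i + 1:03d}", chrom=chrom, strand=strand,
            candidate_tss_positions=cands, true_tss=tss,
            pause_offset=int(rng.integers(20, 61)), pause_reads=pause_reads,
            body_rate=body_rate, body_end=body_end,
            readthrough_len=readthrough_len,
            termination_peak_reads=termination_peak_reads,
            termination_decay_len=termination_decay_len,
            noise_rate=noise_rate,
        ))
        cursor += spacing
    chrom_len = cursor + 15_000
    return specs, chrom_len
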