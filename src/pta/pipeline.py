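"""End-to-end composition: prep -> TSS -> TTS -> TU annotation -> counts.

``run_pipeline`` is the library entry point the CLI wraps; every stage is
also callable on its own. All outputs are BED6/TSV with a one-line
provenance header (tool version, parameters, input checksums), so a rerun
on identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bedio import read_bed, write_bed
from .coverage import read_coverage
from .intervals import GenomicInterval
from .prep import collect_first_exons, filter_expressed, largest_interval
from .quantify import count_matrix, pause_index_table
from .tss import infer_tss
from .tts import STATUS_DECAY, TTSParams, infer_tts, refine_gene_coordinates
from .tu import TranscriptionUnit, annotate_tus

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Validated parameter set for a pipeline run."""

    isoforms: str = ""
    plus: str = ""
    minus: str = ""
    tus: str | None = None
    outdir: str = "pta_out"
    coverage_format: str = "bedgraph"
    bed_dialect: str = "isoform_table"
    window: int = 500
    min_count: int = 25
    min_density: float = 1.0
    gene_fraction: float = 0.2
    downstream_extension: int = 10_000
    bin_width: int = 200
    tau: float = 0.1
    smoothness: float | None = None
    min_frac: float = 0.5
    pause_len: int = 50
    body_gap: int = 0
    seed: int = 0
    skip_tus: bool = False
    keep_fallbacks: bool = False

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.min_count < 0 or self.min_density < 0:
            raise ValueError("expression thresholds must be >= 0")
        if not 0 < self.min_frac <= 1:
            raise ValueError("min_frac must be in (0, 1]")
        if self.pause_len <= 0 or self.body_gap < 0:
            raise ValueError("pause_len must be positive, body_gap >= 0")
        self.tts_params()  # validates the TTS knobs

    def tts_params(self) -> TTSParams:
        return TTSParams(self.gene_fraction, self.downstream_extension,
                         self.bin_width, self.tau, self.smoothness)

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        """Flat key-value YAML; explicit keyword overrides win."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _md5(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


def _provenance(config: RunConfig, stage: str) -> str:
    inputs = [p for p in (config.isoforms, config.plus, config.minus, config.tus) if p]
    sums = ",".join(f"{Path(p).name}:{_md5(p)}" for p in inputs)
    params = (
        f"window={config.window} fraction={config.gene_fraction} "
        f"extension={config.downstream_extension} bin={config.bin_width} "
        f"tau={config.tau} min_frac={config.min_frac} "
        f"pause_len={config.pause_len} seed={config.seed}"
    )
    return f"pta v{__version__} stage={stage} {params} inputs=[{sums}]"


def _write_tsv(df: pd.DataFrame, path: Path, header: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full annotation pipeline; returns output paths by stage."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def stage(name):
        log.info("stage %s", name)
        return _provenance(config, name)

    # -- prep: collapse isoforms, filter unexpressed ----------------------
    head = stage("prep")
    isoforms = read_bed(config.isoforms, dialect=config.bed_dialect)
    track = read_coverage(config.plus, config.minus, format=config.coverage_format)
    envelopes = largest_interval(isoforms)
    gene_sets = collect_first_exons(isoforms)
    kept, report = filter_expressed(gene_sets, track, config.min_count, config.min_density)
    outputs["largest"] = outdir / "largest_intervals.bed"
    write_bed([envelopes[g] for g in sorted(kept)], outputs["largest"], header=head)
    outputs["expression_report"] = outdir / "expression_report.tsv"
    _write_tsv(report, outputs["expression_report"], head)

    # -- TSS --------------------------------------------------------------
    head = stage("tss")
    tss_calls = {g: infer_tss(kept[g], track, config.window) for g in sorted(kept)}
    tss_rows = [
        {"gene_id": c.gene_id, "chrom": c.chrom, "strand": c.strand, "tss": c.tss,
         "window_count": c.window_count, "n_candidates": c.n_candidates,
         "tie_broken": c.tie_broken, "zero_signal": c.zero_signal}
        for c in tss_calls.values()
    ]
    outputs["tss_report"] = outdir / "tss_report.tsv"
    _write_tsv(pd.DataFrame(tss_rows), outputs["tss_report"], head)
    tss_bed = [
        GenomicInterval(c.chrom, c.tss if c.strand == "+" else c.tss - 1,
                        (c.tss + 1) if c.strand == "+" else c.tss,
                        c.strand, id=c.gene_id)
        for c in tss_calls.values()
    ]
    outputs["tss"] = outdir / "tss.bed"
    write_bed(tss_bed, outputs["tss"], header=head)

    # -- TTS + refined coordinates ---------------------------------------
    head = stage("tts")
    params = config.tts_params()
    inferred: list[GenomicInterval] = []
    tts_rows = []
    for g in sorted(kept):
        gene_iv = envelopes[g]
        call = infer_tts(gene_iv, track, params)
        tts_rows.append({
            "gene_id": g, "chrom": call.chrom, "strand": call.strand,
            "tts": call.tts, "status": call.status,
            "peak_coordinate": call.peak_coordinate, "n_bins": call.n_bins,
        })
        if call.status == STATUS_DECAY or config.keep_fallbacks:
            inferred.append(refine_gene_coordinates(gene_iv, tss_calls[g].tss, call))
    outputs["tts_report"] = outdir / "tts_report.tsv"
    _write_tsv(pd.DataFrame(tts_rows), outputs["tts_report"], head)
    outputs["inferred"] = outdir / "inferred_genes.bed"
    write_bed(inferred, outputs["inferred"], header=head)

    # -- TU annotation ----------------------------------------------------
    if config.tus and not config.skip_tus:
        head = stage("annotate-tus")
        tu_ivs = read_bed(config.tus, dialect="bed6")
        tus = [TranscriptionUnit(iv, iv.id or f"TU{i}") for i, iv in enumerate(tu_ivs)]
        annotated = annotate_tus(tus, inferred, config.min_frac)
        outputs["annotated_tus"] = outdir / "annotated_tus.bed"
        write_bed([a.iv.with_id(a.label) for a in annotated],
                  outputs["annotated_tus"], header=head)
        tu_rows = [
            {"label": a.label, "gene_id": a.gene_id, "chrom": a.iv.chrom,
             "start": a.iv.start, "end": a.iv.end, "strand": a.iv.strand,
             "origin": a.origin, "overlap_fraction_of_gene": a.overlap_fraction_of_gene,
             "parent_tu": a.parent_tu}
            for a in annotated
        ]
        outputs["annotated_tus_report"] = outdir / "annotated_tus.tsv"
        _write_tsv(pd.DataFrame(tu_rows), outputs["annotated_tus_report"], head)

    # -- quantification ---------------------------------------------------
    head = stage("quantify")
    if inferred:
        counts = count_matrix(inferred, {"sample": track})
        outputs["counts"] = outdir / "counts.tsv"
        _write_tsv(counts, outputs["counts"], head, index=True)
        pause = pause_index_table(inferred, track, config.pause_len, config.body_gap)
        outputs["pause"] = outdir / "pause_index.tsv"
        _write_tsv(pause, outputs["pause"], head)

    return outputs
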