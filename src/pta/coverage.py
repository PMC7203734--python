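"""Strand-specific read-coverage tracks and fast region-count queries.

A :class:`CoverageTrack` holds, per (chromosome, strand), a run-length
("step") representation of non-negative per-base read counts: sorted,
non-overlapping intervals with a positive value each; zero runs are implicit.
Region queries are answered from a precomputed cumulative-mass vector, so a
count over ``[s, e)`` costs two binary searches.

Minus-strand signal files in the PRO-seq world routinely carry negative
values; magnitudes are taken on read so the track always stores counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .intervals import STRANDS, GenomicInterval

log = logging.getLogger(__name__)


class CoverageFormatError(ValueError):
    """Raised for malformed or internally inconsistent coverage files."""


@dataclass
class _StepVector:
    """Sorted non-overlapping intervals with positive values on one strand."""

    starts: np.ndarray  # int64
    ends: np.ndarray  # int64
    values: np.ndarray  # float64 magnitudes (integral in practice)
    cummass: np.ndarray = field(init=False)  # cumulative mass before interval i

    def __post_init__(self) -> None:
        mass = self.values * (self.ends - self.starts)
        self.cummass = np.concatenate(([0.0], np.cumsum(mass)))

    @property
    def total(self) -> float:
        return float(self.cummass[-1])

    def mass_before(self, pos) -> np.ndarray:
        """Total signal in [0, pos) for scalar or array ``pos``."""
        pos = np.asarray(pos, dtype=np.int64)
        if self.starts.size == 0:
            return np.zeros(pos.shape, dtype=np.float64)
        j = np.searchsorted(self.starts, pos, side="right") - 1
        jc = np.clip(j, 0, None)
        inside = np.clip(
            np.minimum(pos, self.ends[jc]) - self.starts[jc], 0, None
        ) * self.values[jc]
        base = self.cummass[jc]
        return np.where(j < 0, 0.0, base + inside)

    def count(self, start: int, end: int) -> int:
        m = self.mass_before(np.array([start, end]))
        return int(round(m[1] - m[0]))

    def dense(self, start: int, end: int) -> np.ndarray:
        """Per-base counts over [start, end) as a dense array."""
        out = np.zeros(end - start, dtype=np.float64)
        i0 = int(np.searchsorted(self.ends, start, side="right"))
        i1 = int(np.searchsorted(self.starts, end, side="left"))
        for s, e, v in zip(self.starts[i0:i1], self.ends[i0:i1], self.values[i0:i1]):
            out[max(s, start) - start : min(e, end) - start] += v
        return out


def _build_step(starts, ends, values, context: str) -> _StepVector:
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    values = np.abs(np.asarray(values, dtype=np.float64))
    keep = values > 0
    starts, ends, values = starts[keep], ends[keep], values[keep]
    order = np.argsort(starts, kind="stable")
    starts, ends, values = starts[order], ends[order], values[order]
    if np.any(ends <= starts):
        raise CoverageFormatError(f"{context}: interval with end <= start")
    if len(starts) > 1 and np.any(starts[1:] < ends[:-1]):
        i = int(np.argmax(starts[1:] < ends[:-1]))
        raise CoverageFormatError(
            f"{context}: overlapping intervals near position {int(starts[i + 1])}"
        )
    return _StepVector(starts, ends, values)


class CoverageTrack:
    """Strand-specific sparse per-base read counts with region queries."""

    def __init__(self) -> None:
        self._data: dict[tuple[str, str], _StepVector] = {}
        self._warned: set[tuple[str, str]] = set()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_steps(cls, steps: dict[tuple[str, str], tuple]) -> "CoverageTrack":
        """Build from {(chrom, strand): (starts, ends, values)} arrays."""
        track = cls()
        for (chrom, strand), (starts, ends, values) in steps.items():
            if strand not in STRANDS:
                raise ValueError(f"bad strand {strand!r}")
            track._data[(chrom, strand)] = _build_step(
                starts, ends, values, f"{chrom}({strand})"
            )
        return track

    @classmethod
    def from_dense(cls, arrays: dict[tuple[str, str], np.ndarray]) -> "CoverageTrack":
        """Build from {(chrom, strand): per-base count array} (run-compressed)."""
        steps = {}
        for key, arr in arrays.items():
            arr = np.asarray(arr)
            change = np.flatnonzero(np.diff(arr) != 0) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            values = arr[starts]
            steps[key] = (starts, ends, values)
        return cls.from_steps(steps)

    # -- queries ----------------------------------------------------------

    def chromosomes(self) -> set[str]:
        return {chrom for chrom, _ in self._data}

    def total_reads(self, strand: str | None = None) -> int:
        total = 0.0
        for (c, s), sv in self._data.items():
            if strand is None or s == strand:
                total += sv.total
        return int(round(total))

    def region_counts(self, iv: GenomicInterval) -> int:
        """Reads falling in ``iv`` on ``iv.strand``; 0 where there is no signal.

        Unknown chromosomes return 0 with a logged warning: annotation builds
        commonly contain scaffolds absent from signal tracks.
        """
        sv = self._data.get((iv.chrom, iv.strand))
        if sv is None:
            key = (iv.chrom, iv.strand)
            if key not in self._warned:
                log.warning("no coverage for chromosome %s strand %s", *key)
                self._warned.add(key)
            return 0
        return sv.count(iv.start, iv.end)

    def bin_counts(self, chrom: str, strand: str, edges: np.ndarray) -> np.ndarray:
        """Counts between consecutive coordinates ``edges`` (ascending)."""
        sv = self._data.get((chrom, strand))
        if sv is None:
            return np.zeros(len(edges) - 1, dtype=np.int64)
        m = sv.mass_before(np.asarray(edges, dtype=np.int64))
        return np.rint(np.diff(m)).astype(np.int64)

    def dense(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        """Dense per-base counts over [start, end) (zeros off-track)."""
        sv = self._data.get((chrom, strand))
        if sv is None:
            return np.zeros(end - start)
        return sv.dense(start, end)

    def steps(self, chrom: str, strand: str):
        """(starts, ends, values) arrays for one chromosome/strand, or None."""
        sv = self._data.get((chrom, strand))
        if sv is None:
            return None
        return sv.starts, sv.ends, sv.values

    def mirrored(self, chrom_len: int) -> "CoverageTrack":
        """Reflect all coordinates through ``chrom_len`` and swap strands."""
        steps = {}
        for (chrom, strand), sv in self._data.items():
            flip = "-" if strand == "+" else "+"
            steps[(chrom, flip)] = (
                chrom_len - sv.ends[::-1],
                chrom_len - sv.starts[::-1],
                sv.values[::-1],
            )
        return CoverageTrack.from_steps(steps)


# -- file IO ---------------------------------------------------------------


def _read_bedgraph(path: str) -> dict[str, list]:
    """Parse a 4-column bedGraph into per-chromosome (start, end, value) lists."""
    per_chrom: dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise CoverageFormatError(
                    f"{path}:{lineno}: expected 4 bedGraph columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise CoverageFormatError(f"{path}:{lineno}: {exc}") from exc
            per_chrom.setdefault(chrom, []).append((start, end, value))
    return per_chrom


def _read_bigwig(path: str) -> dict[str, list]:
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("bigWig input requires the pyBigWig package") from exc
    per_chrom: dict[str, list] = {}
    with pyBigWig.open(path) as bw:
        for chrom in bw.chroms():
            ivs = bw.intervals(chrom)
            if ivs:
                per_chrom[chrom] = [tuple(t) for t in ivs]
    return per_chrom


def read_coverage(plus_path: str, minus_path: str, format: str = "bedgraph") -> CoverageTrack:
    """Read a strand pair of signal files into one :class:`CoverageTrack`.

    Minus-strand values may be negative (a common PRO-seq convention);
    magnitudes are stored. Intervals within one file must be non-overlapping
    per chromosome.
    """
    if format == "bedgraph":
        reader = _read_bedgraph
    elif format == "bigwig":
        reader = _read_bigwig
    else:
        raise ValueError(f"unknown coverage format {format!r}")
    steps = {}
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        for chrom, rows in reader(path).items():
            arr = np.asarray(rows, dtype=np.float64)
            steps[(chrom, strand)] = (arr[:, 0], arr[:, 1], arr[:, 2])
    return CoverageTrack.from_steps(steps)


def write_bedgraph(track: CoverageTrack, plus_path: str, minus_path: str) -> None:
    """Serialize a track to one bedGraph per strand (minus values negated)."""
    for path, strand, sign in ((plus_path, "+", 1), (minus_path, "-", -1)):
        with open(path, "w") as fh:
            for chrom in sorted(c for c, s in track._data if s == strand):
                sv = track._data[(chrom, strand)]
                for s, e, v in zip(sv.starts, sv.ends, sv.values):
                    fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{sign * int(v)}\n")
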