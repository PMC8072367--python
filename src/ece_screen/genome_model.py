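"""Core genomic coordinate types and text-format I/O.

Everything downstream of the parsers works in 0-based half-open (BED-native)
coordinates. UCSC-style 1-based inclusive spans, as printed by genome
browsers, are converted at the parse/format boundary only, so no
off-by-one reasoning is ever needed inside the pipeline.

Missing data in a conservation track is a first-class value (NaN), distinct
from a low score: a base with no alignment information is not a base with
probability zero of being conserved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "FormatError",
    "GenomicInterval",
    "ConservationTrack",
    "IntervalSet",
    "parse_ucsc_interval",
    "format_interval",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_wiggle",
]


class FormatError(ValueError):
    """A malformed record in a genomic text format.

    Carries the 1-based line number of the offending record when known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome-anchored half-open span [start, end).

    ``start`` is 0-based inclusive, ``end`` is 0-based exclusive, so
    ``length == end - start`` and adjacent intervals share no base.
    Strand is one of ``+``, ``-`` or ``.`` (unstranded); the screen itself
    is strand-blind, only motif scanning consumes strand.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def intersection(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def with_name(self, name: str) -> "GenomicInterval":
        return replace(self, name=name)


_UCSC_RE = re.compile(
    r"^\s*(?P<chrom>[A-Za-z0-9_.]+)\s*:\s*(?P<a>[\d,]+)\s*[-–]\s*(?P<b>[\d,]+)\s*$"
)


def parse_ucsc_interval(text: str, dialect: str = "ucsc1") -> GenomicInterval:
    """Parse a browser-style span such as ``"Chr2: 118000000-118880000"``.

    Parameters
    ----------
    dialect
        ``"ucsc1"`` — coordinates are 1-based inclusive (the convention of
        printed browser spans): (A, B) maps to half-open (A-1, B).
        ``"bed0"`` — coordinates are already 0-based half-open.

    The dialect is an explicit flag because published coordinate spans do
    not declare their convention.
    """
    m = _UCSC_RE.match(text)
    if m is None:
        raise FormatError(f"cannot parse interval from {text!r}")
    a = int(m.group("a").replace(",", ""))
    b = int(m.group("b").replace(",", ""))
    if dialect == "ucsc1":
        start, end = a - 1, b
    elif dialect == "bed0":
        start, end = a, b
    else:
        raise ValueError(f"unknown coordinate dialect {dialect!r}")
    if end <= start or start < 0:
        raise FormatError(f"empty or negative span in {text!r} ({dialect})")
    return GenomicInterval(m.group("chrom"), start, end)


def format_interval(interval: GenomicInterval, dialect: str = "ucsc1") -> str:
    """Inverse of :func:`parse_ucsc_interval` for the same dialect."""
    if dialect == "ucsc1":
        return f"{interval.chrom}:{interval.start + 1}-{interval.end}"
    if dialect == "bed0":
        return f"{interval.chrom}:{interval.start}-{interval.end}"
    raise ValueError(f"unknown coordinate dialect {dialect!r}")


@dataclass
class ConservationTrack:
    """Per-base conservation probabilities over one region.

    ``values`` holds one float per base of ``region``; NaN marks missing
    data (no record covered that base). All non-missing values must be
    probabilities in [0, 1].
    """

    region: GenomicInterval
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.region.length,):
            raise ValueError(
                f"track has {self.values.size} values for a "
                f"{self.region.length} bp region"
            )
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("conservation values must lie in [0, 1]")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    @property
    def n_covered(self) -> int:
        return self.region.length - self.n_missing

    def slice(self, interval: GenomicInterval) -> np.ndarray:
        """Values for a sub-interval of the track region (a view)."""
        if not self.region.contains(interval):
            raise ValueError(f"{interval} is not contained in {self.region}")
        off = interval.start - self.region.start
        return self.values[off : off + interval.length]


class IntervalSet:
    """A labelled, queryable collection of intervals (an evidence track,
    an exon mask, ...).

    Backed by one interval tree per chromosome, so overlap queries are
    O(log n + k) rather than a linear scan. ``genome`` optionally declares
    the coordinate space (assembly) the intervals live in; the prioritizer
    refuses to mix declared spaces.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        label: str = "",
        genome: str | None = None,
    ):
        self.label = label
        self.genome = genome
        self._intervals: list[GenomicInterval] = sorted(
            intervals, key=GenomicInterval.sort_key
        )
        self._trees: dict[str, IntervalTree] = {}
        for iv in self._intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, iv
            )

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __bool__(self) -> bool:
        return bool(self._intervals)

    def overlapping(self, query: GenomicInterval) -> list[GenomicInterval]:
        """All stored intervals sharing >= 1 bp with ``query``, sorted."""
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        hits = [hit.data for hit in tree.overlap(query.start, query.end)]
        return sorted(hits, key=GenomicInterval.sort_key)

    def overlap_bp(self, query: GenomicInterval) -> int:
        """Total bases of ``query`` covered by the set (union, no double
        counting where stored intervals overlap each other)."""
        spans = [
            (max(query.start, iv.start), min(query.end, iv.end))
            for iv in self.overlapping(query)
        ]
        if not spans:
            return 0
        spans.sort()
        total = 0
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        return total + (cur_e - cur_s)


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path, label: str | None = None,
             genome: str | None = None) -> IntervalSet:
    """Read a BED3+ file into an :class:`IntervalSet`.

    Column 4 (name) and column 6 (strand) are kept when present; track,
    browser and comment lines are skipped.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"expected >= 3 BED columns, got {len(fields)}",
                                  line=lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"non-integer coordinates: {exc}", line=lineno)
            if start >= end or start < 0:
                raise FormatError(
                    f"invalid BED span {fields[0]}:{start}-{end}", line=lineno
                )
            name = fields[3] if len(fields) >= 4 and fields[3] != "." else None
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            intervals.append(
                GenomicInterval(fields[0], start, end, name=name, strand=strand)
            )
    return IntervalSet(intervals, label=label or path.stem, genome=genome)


def write_bed(
    intervals: Iterable[GenomicInterval] | IntervalSet,
    path: str | Path,
    scores: Sequence[int] | None = None,
) -> None:
    """Write intervals as sorted BED records.

    Emits BED4 (chrom, start, end, name) by default; with ``scores`` a
    BED6 with the given integer scores and stored strands.
    """
    ivs = sorted(intervals, key=GenomicInterval.sort_key)
    if scores is not None and len(scores) != len(ivs):
        raise ValueError("scores length must match interval count")
    with Path(path).open("w") as fh:
        for i, iv in enumerate(ivs):
            name = iv.name if iv.name is not None else "."
            if scores is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")
            else:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t"
                    f"{scores[i]}\t{iv.strand}\n"
                )


# ---------------------------------------------------------------------------
# bedGraph / wiggle


def read_bedgraph(path: str | Path, region: GenomicInterval) -> ConservationTrack:
    """Read a 4-column bedGraph into a per-base track over ``region``.

    Bases of ``region`` not covered by any record are missing (NaN).
    Records on the region's chromosome may not overlap one another —
    a per-base track must be single-valued.
    """
    path = Path(path)
    records: list[tuple[int, int, float, int]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise FormatError(
                    f"expected 4 bedGraph columns, got {len(fields)}", line=lineno
                )
            if fields[0] != region.chrom:
                continue
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise FormatError(f"bad bedGraph record: {exc}", line=lineno)
            if start >= end or start < 0:
                raise FormatError(f"invalid span {start}-{end}", line=lineno)
            records.append((start, end, value, lineno))
    records.sort(key=lambda r: (r[0], r[1]))
    for (s1, e1, _, l1), (s2, e2, _, l2) in zip(records, records[1:]):
        if s2 < e1:
            raise FormatError(
                f"overlapping bedGraph records [{s1},{e1}) (line {l1}) and "
                f"[{s2},{e2})",
                line=l2,
            )
    values = np.full(region.length, np.nan)
    for start, end, value, _ in records:
        s = max(start, region.start)
        e = min(end, region.end)
        if s < e:
            values[s - region.start : e - region.start] = value
    return ConservationTrack(region, values)


def write_bedgraph(track: ConservationTrack, path: str | Path) -> None:
    """Run-length-encode a track back to bedGraph. Missing bases emit no
    record, so read_bedgraph(write_bedgraph(t)) reproduces t."""
    vals = track.values
    region = track.region
    with Path(path).open("w") as fh:
        i = 0
        n = vals.size
        while i < n:
            if np.isnan(vals[i]):
                i += 1
                continue
            j = i + 1
            while j < n and vals[j] == vals[i]:
                j += 1
            fh.write(
                f"{region.chrom}\t{region.start + i}\t{region.start + j}\t"
                f"{vals[i]:.6g}\n"
            )
            i = j


def read_wiggle(path: str | Path, region: GenomicInterval) -> ConservationTrack:
    """Read fixedStep/variableStep wiggle (1-based, per UCSC) over a region.

    Provided for tracks distributed as wiggle; bedGraph is the primary
    format. Re-covering a base is an error, mirroring the bedGraph rule.
    """
    path = Path(path)
    values = np.full(region.length, np.nan)
    covered = np.zeros(region.length, dtype=bool)

    def fill(pos0: int, span: int, value: float, lineno: int) -> None:
        s = max(pos0, region.start)
        e = min(pos0 + span, region.end)
        if s >= e:
            return
        sl = slice(s - region.start, e - region.start)
        if covered[sl].any():
            raise FormatError("wiggle records re-cover a base", line=lineno)
        values[sl] = value
        covered[sl] = True

    mode: str | None = None
    chrom = ""
    step = span = 1
    pos = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith(("fixedStep", "variableStep")):
                kv = dict(
                    f.split("=", 1) for f in line.split()[1:] if "=" in f
                )
                mode = line.split()[0]
                chrom = kv.get("chrom", "")
                span = int(kv.get("span", 1))
                if mode == "fixedStep":
                    pos = int(kv["start"]) - 1  # wiggle is 1-based
                    step = int(kv.get("step", 1))
                continue
            if mode is None:
                raise FormatError("data line before any step declaration",
                                  line=lineno)
            if chrom != region.chrom:
                continue
            fields = line.split()
            try:
                if mode == "fixedStep":
                    fill(pos, span, float(fields[0]), lineno)
                    pos += step
                else:
                    fill(int(fields[0]) - 1, span, float(fields[1]), lineno)
            except (ValueError, IndexError) as exc:
                raise FormatError(f"bad wiggle data line: {exc}", line=lineno)
    return ConservationTrack(region, values)
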