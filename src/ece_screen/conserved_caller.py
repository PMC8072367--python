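"""Segment a conservation track into conserved elements.

The screen calls elements as maximal runs of consecutive bases whose
conservation probability is at or above a cutoff (default >= 0.98),
at least ``min_length`` bp long (default 50), restricted to a TAD,
excluding coding-exon bases, and tolerating short interior gaps of
missing data.

Rules, stated precisely:

* A base is GOOD if its score is >= threshold (the comparison is
  inclusive) and it does not overlap the exon mask.
* A base with missing data (and outside the exon mask) is a GAP base.
  A run may bridge an interior stretch of consecutive GAP bases of
  length <= ``max_gap``; bridged bases count toward element length but
  not toward the mean score.
* Any other base — sub-threshold score, or inside the exon mask — is a
  hard BREAK. Low scores are never bridged: the gap allowance is for
  absent data, not weak conservation.
* Elements start and end on GOOD bases (gaps are interior-only) and are
  maximal: no called element is contained in a longer legal run.

Note that element *count* is not monotone in threshold or max_gap:
raising the threshold can split one long element into two shorter ones,
and raising max_gap can fuse two elements across a gap. Only min_length
acts as a pure filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome_model import (
    ConservationTrack,
    GenomicInterval,
    IntervalSet,
    write_bed,
)

__all__ = ["CallerParams", "ConservedElement", "call_elements",
           "mask_intersect", "write_elements_bed"]

# per-base states
_GOOD, _GAP, _BREAK = 0, 1, 2


@dataclass(frozen=True)
class CallerParams:
    """Tunable constants of the element caller.

    threshold : conservation probability cutoff, inclusive (default 0.98)
    min_length : minimum element length in bp (default 50)
    max_gap : longest bridgeable interior stretch of missing data, bp
        (default 10)
    tad : the search interval; elements are called only inside it
    exon_mask : coding intervals whose bases are hard breaks
    """

    tad: GenomicInterval
    threshold: float = 0.98
    min_length: int = 50
    max_gap: int = 10
    exon_mask: IntervalSet | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


@dataclass(frozen=True)
class ConservedElement:
    """A called conserved element.

    mean_score averages the non-missing bases only; n_gap_bases counts
    the bridged missing bases inside the element.
    """

    interval: GenomicInterval
    mean_score: float
    n_gap_bases: int
    id: str

    @property
    def length(self) -> int:
        return self.interval.length


def _classify(track: ConservationTrack, region: GenomicInterval,
              params: CallerParams) -> np.ndarray:
    vals = track.slice(region)
    state = np.full(region.length, _BREAK, dtype=np.int8)
    missing = np.isnan(vals)
    state[missing] = _GAP
    state[~missing & (vals >= params.threshold)] = _GOOD
    if params.exon_mask is not None:
        for exon in params.exon_mask.overlapping(region):
            s = max(exon.start, region.start) - region.start
            e = min(exon.end, region.end) - region.start
            state[s:e] = _BREAK
    return state


def _maximal_runs(state: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    """Maximal legal runs as (start, end) offsets. Linear scan: extend
    each run through GOOD bases, bridging GAP stretches <= max_gap that
    are followed by another GOOD base."""
    runs: list[tuple[int, int]] = []
    n = state.size
    i = 0
    while i < n:
        if state[i] != _GOOD:
            i += 1
            continue
        start = i
        end = i + 1
        j = i + 1
        while j < n:
            if state[j] == _GOOD:
                end = j + 1
                j += 1
                continue
            if state[j] == _GAP:
                g = j
                while g < n and state[g] == _GAP:
                    g += 1
                if g < n and state[g] == _GOOD and (g - j) <= max_gap:
                    j = g  # bridge the gap
                    continue
            break
        runs.append((start, end))
        i = max(j, end)
    return runs


def call_elements(track: ConservationTrack,
                  params: CallerParams) -> list[ConservedElement]:
    """Call conserved elements on ``track`` restricted to ``params.tad``.

    Returns disjoint, sorted, maximal elements of length >= min_length.
    Element ids are ordinals in genomic order (``CE1``, ``CE2``, ...).
    """
    region = params.tad.intersection(track.region)
    if region is None:
        raise ValueError(
            f"TAD {params.tad.chrom}:{params.tad.start}-{params.tad.end} lies "
            f"outside the track region "
            f"{track.region.chrom}:{track.region.start}-{track.region.end}"
        )
    state = _classify(track, region, params)
    vals = track.slice(region)
    elements: list[ConservedElement] = []
    for start, end in _maximal_runs(state, params.max_gap):
        if end - start < params.min_length:
            continue
        seg_state = state[start:end]
        seg_vals = vals[start:end]
        good = seg_state == _GOOD
        mean_score = float(seg_vals[good].mean())
        n_gap = int((seg_state == _GAP).sum())
        interval = GenomicInterval(
            region.chrom, region.start + start, region.start + end
        )
        elements.append(ConservedElement(interval, mean_score, n_gap, id=""))
    return [
        ConservedElement(e.interval.with_name(f"CE{k}"), e.mean_score,
                         e.n_gap_bases, id=f"CE{k}")
        for k, e in enumerate(elements, start=1)
    ]


def mask_intersect(
    intervals: Iterable[GenomicInterval],
    mask: IntervalSet,
    min_length: int = 1,
) -> list[GenomicInterval]:
    """Subtract ``mask`` from each interval, keeping the resulting pieces
    of length >= ``min_length``.

    This is the hard-break rule as pure interval arithmetic: any base
    overlapping the mask is removed and the flanks survive on their own
    merits. Inside :func:`call_elements` the same exclusion happens at
    the per-base classification stage.
    """
    out: list[GenomicInterval] = []
    for iv in intervals:
        cuts = sorted(
            (max(m.start, iv.start), min(m.end, iv.end))
            for m in mask.overlapping(iv)
        )
        pos = iv.start
        pieces: list[tuple[int, int]] = []
        for s, e in cuts:
            if s > pos:
                pieces.append((pos, s))
            pos = max(pos, e)
        if pos < iv.end:
            pieces.append((pos, iv.end))
        for s, e in pieces:
            if e - s >= min_length:
                out.append(GenomicInterval(iv.chrom, s, e, name=iv.name,
                                           strand=iv.strand))
    return sorted(out, key=GenomicInterval.sort_key)


def write_elements_bed(elements: Sequence[ConservedElement],
                       path: str | Path) -> None:
    """BED6 output: name = element id, score = round(1000 * mean_score)."""
    write_bed(
        [e.interval for e in elements],
        path,
        scores=[round(1000 * e.mean_score) for e in elements],
    )
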