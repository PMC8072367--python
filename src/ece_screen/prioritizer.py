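"""Annotate conserved elements with evidence-track overlap and select
priority elements.

An element is *priority* if it overlaps at least one evidence track by at
least ``min_overlap`` bp (default 1). Ranking is by the number of distinct
evidence tracks hit, descending, with coordinate ties broken by
(chrom, start) — the element hitting the most independent epigenomic
signatures ranks first.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .conserved_caller import ConservedElement
from .genome_model import IntervalSet

__all__ = ["EvidenceCatalog", "PrioritizedElement", "annotate",
           "select_priority", "annotation_table"]


@dataclass
class EvidenceCatalog:
    """An ordered collection of evidence interval sets.

    The catalog refuses to combine tracks whose declared coordinate
    spaces (assemblies) differ, unless ``assume_same_space`` is set:
    evidence lifted from another genome must be projected into one space
    by the user, and the tool will not silently guess that it was.
    """

    tracks: Sequence[IntervalSet]
    min_overlap: int = 1
    assume_same_space: bool = False

    def __post_init__(self) -> None:
        labels = [t.label for t in self.tracks]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate evidence track labels in {labels}")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1 bp")
        spaces = {t.genome for t in self.tracks if t.genome is not None}
        if len(spaces) > 1 and not self.assume_same_space:
            raise ValueError(
                f"evidence tracks declare mixed coordinate spaces {sorted(spaces)}; "
                "project them to one space or pass assume_same_space=True"
            )

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.tracks]


@dataclass
class PrioritizedElement:
    """A conserved element with per-track overlap annotations.

    ``overlap_bp`` maps track label -> intersected bases (union within a
    track, so self-overlapping peaks are not double counted).
    """

    element: ConservedElement
    overlap_bp: Mapping[str, int]
    min_overlap: int = 1

    def hit(self, label: str) -> bool:
        return self.overlap_bp[label] >= self.min_overlap

    @property
    def evidence_count(self) -> int:
        return sum(1 for label in self.overlap_bp if self.hit(label))

    @property
    def is_priority(self) -> bool:
        return self.evidence_count >= 1


def annotate(elements: Iterable[ConservedElement],
             catalog: EvidenceCatalog) -> list[PrioritizedElement]:
    """Per-element, per-track overlap in bp; flag true iff >= min_overlap."""
    out = []
    for element in elements:
        bp = {
            track.label: track.overlap_bp(element.interval)
            for track in catalog.tracks
        }
        out.append(PrioritizedElement(element, bp, catalog.min_overlap))
    return out


def select_priority(
    annotated: Sequence[PrioritizedElement],
) -> list[PrioritizedElement]:
    """Priority subset (evidence_count >= 1), ranked by evidence_count
    descending, ties by (chrom, start). Deterministic."""
    if not annotated:
        raise ValueError("nothing to select from: annotated is empty")
    priority = [a for a in annotated if a.is_priority]
    return sorted(
        priority,
        key=lambda a: (
            -a.evidence_count,
            a.element.interval.chrom,
            a.element.interval.start,
        ),
    )


def annotation_table(annotated: Sequence[PrioritizedElement]) -> pd.DataFrame:
    """Tidy per-element table: coordinates, per-track overlap bp,
    evidence_count, priority flag."""
    rows = []
    for a in annotated:
        iv = a.element.interval
        row: dict = {
            "id": a.element.id,
            "chrom": iv.chrom,
            "start": iv.start,
            "end": iv.end,
        }
        for label, bp in a.overlap_bp.items():
            row[f"overlap_bp:{label}"] = bp
        row["evidence_count"] = a.evidence_count
        row["priority"] = a.is_priority
        rows.append(row)
    return pd.DataFrame(rows)


def write_annotation_tsv(annotated: Sequence[PrioritizedElement],
                         path: str | Path) -> None:
    annotation_table(annotated).to_csv(path, sep="\t", index=False)
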