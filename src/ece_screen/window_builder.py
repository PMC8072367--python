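"""Expand priority elements into candidate enhancer test windows and
collapse overlapping windows.

Known enhancers tend to be hundreds of base pairs long, so each priority
kernel is expanded symmetrically about its midpoint to a test window of
``target_length`` bp (default 1000), never beyond ``max_length`` (default
1500). Windows running past the TAD boundary are clipped with the deficit
pushed to the opposite side. Windows sharing >= 1 bp are unioned
transitively into single candidates; abutting windows (zero overlap) stay
separate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .conserved_caller import ConservedElement
from .genome_model import GenomicInterval

__all__ = ["WindowParams", "CandidateEnhancer", "expand", "merge",
           "build_windows", "write_windows_bed"]


@dataclass(frozen=True)
class WindowParams:
    tad: GenomicInterval
    target_length: int = 1000
    max_length: int = 1500

    def __post_init__(self) -> None:
        if not (1 <= self.target_length <= self.max_length):
            raise ValueError(
                f"require 1 <= target_length <= max_length, got "
                f"{self.target_length}/{self.max_length}"
            )


@dataclass(frozen=True)
class CandidateEnhancer:
    """A merged candidate test window with the ids of the conserved
    elements (kernels) it grew from."""

    interval: GenomicInterval
    kernel_ids: tuple[str, ...]
    id: str

    @property
    def length(self) -> int:
        return self.interval.length


def expand(kernel: GenomicInterval, params: WindowParams) -> GenomicInterval:
    """Expand one kernel to a test window.

    Symmetric about the kernel midpoint to ``target_length``; kernels
    already longer than the target are kept as-is (a kernel longer than
    ``max_length`` is returned unchanged with a warning). Clipping at the
    TAD boundary compensates on the opposite side where room allows.
    """
    tad = params.tad
    if not tad.contains(kernel):
        raise ValueError(f"kernel {kernel} is not inside the TAD {tad}")
    k = kernel.length
    if k > params.max_length:
        warnings.warn(
            f"kernel {kernel.name or ''} ({k} bp) exceeds max window length "
            f"{params.max_length}; window equals kernel",
            stacklevel=2,
        )
        return GenomicInterval(kernel.chrom, kernel.start, kernel.end,
                               name=kernel.name)
    if k >= params.target_length:
        return GenomicInterval(kernel.chrom, kernel.start, kernel.end,
                               name=kernel.name)
    target = params.target_length
    mid = (kernel.start + kernel.end) // 2
    start = mid - target // 2
    end = start + target
    if start < tad.start:  # push the deficit to the right
        end = min(tad.end, end + (tad.start - start))
        start = tad.start
    if end > tad.end:  # push the deficit to the left
        start = max(tad.start, start - (end - tad.end))
        end = tad.end
    return GenomicInterval(kernel.chrom, start, end, name=kernel.name)


def merge(windows: Sequence[GenomicInterval]) -> list[CandidateEnhancer]:
    """Union transitively overlapping windows into candidates.

    Overlap means >= 1 shared base; abutting windows are not merged. A
    merged union may exceed ``max_length`` — it is not re-clipped, the
    cap applies to single-kernel windows only. Kernel ids (window names)
    are concatenated in genomic order; candidate ids are ordinals in
    genomic order (``ECE1``, ``ECE2``, ...).
    """
    if not windows:
        return []
    ordered = sorted(windows, key=GenomicInterval.sort_key)
    groups: list[tuple[str, int, int, list[str]]] = []
    chrom, start, end = ordered[0].chrom, ordered[0].start, ordered[0].end
    names = [ordered[0].name or ""]
    for w in ordered[1:]:
        if w.chrom == chrom and w.start < end:  # strict overlap only
            end = max(end, w.end)
            names.append(w.name or "")
        else:
            groups.append((chrom, start, end, names))
            chrom, start, end, names = w.chrom, w.start, w.end, [w.name or ""]
    groups.append((chrom, start, end, names))
    return [
        CandidateEnhancer(
            GenomicInterval(c, s, e, name=f"ECE{i}"),
            kernel_ids=tuple(n for n in ns if n),
            id=f"ECE{i}",
        )
        for i, (c, s, e, ns) in enumerate(groups, start=1)
    ]


def build_windows(priority_elements: Sequence[ConservedElement],
                  params: WindowParams) -> list[CandidateEnhancer]:
    """expand + merge over a set of priority kernels."""
    windows = [expand(e.interval, params) for e in priority_elements]
    return merge(windows)


def write_windows_bed(candidates: Sequence[CandidateEnhancer],
                      path: str | Path) -> None:
    """BED with a kernel-provenance column (comma-joined kernel ids)."""
    with Path(path).open("w") as fh:
        for c in candidates:
            iv = c.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.id}\t"
                f"{','.join(c.kernel_ids)}\n"
            )
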