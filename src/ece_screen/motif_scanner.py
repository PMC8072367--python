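"""Position-weight-matrix motif scoring and cross-species affinity
comparison.

A position frequency matrix (PFM, e.g. the SP1 GC-box model JASPAR
MA0079.3) is converted to a log-odds position weight matrix (PWM) with
background-distributed pseudocounts:

    w(b, i) = log2( (n(b, i) + p * q(b)) / (N(i) + p) / q(b) )

where n(b, i) is the count of base b at column i, N(i) the column total,
q the background distribution and p the total pseudocount (default 0.8,
a common convention in the JASPAR ecosystem). A window's raw score is the
sum of its per-position weights; the *relative* score rescales raw to
[0, 1] between the minimal and maximal achievable site scores, so 1.0 is
the consensus site. Relative scores are invariant to affine rescaling of
the raw scores, which makes them comparable across matrices.

The cross-species comparison scores the same anchored motif site in each
ortholog and reports the predicted-affinity ranking together with which
positions diverge from a chosen reference species — the computation behind
asking whether derived bases in one lineage strengthened a binding site.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

__all__ = [
    "ALPHABET",
    "PositionFrequencyMatrix",
    "PositionWeightMatrix",
    "MotifHit",
    "Variant",
    "read_jaspar_pfm",
    "write_jaspar_pfm",
    "pfm_to_pwm",
    "scan",
    "compare_orthologs",
    "apply_variants",
    "reverse_complement",
]

ALPHABET = "ACGT"
_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Base counts per motif column, rows ordered A, C, G, T."""

    counts: np.ndarray  # (4, L)
    identifier: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError(f"PFM must be 4 x L with L >= 1, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("PFM counts must be nonnegative")
        if (counts.sum(axis=0) <= 0).any():
            raise ValueError("every PFM column must have a positive total")

    @property
    def length(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class PositionWeightMatrix:
    """log2-odds weights derived from a PFM (see module docstring)."""

    log_odds: np.ndarray  # (4, L)
    background: np.ndarray  # (4,)
    pseudocount: float
    identifier: str = ""

    @property
    def length(self) -> int:
        return self.log_odds.shape[1]

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.log_odds.argmax(axis=0))

    def score_site(self, site: str) -> float:
        """Raw log-odds score of one L-length site on the given strand."""
        site = site.upper()
        if len(site) != self.length:
            raise ValueError(
                f"site length {len(site)} != motif length {self.length}"
            )
        try:
            rows = [_INDEX[b] for b in site]
        except KeyError as exc:
            raise ValueError(f"non-ACGT base {exc} in site {site!r}")
        return float(self.log_odds[rows, range(self.length)].sum())

    def rel_score(self, raw: float) -> float:
        lo, hi = self.min_score, self.max_score
        if hi == lo:  # information-free matrix: every site is maximal
            return 1.0
        return (raw - lo) / (hi - lo)


@dataclass(frozen=True)
class MotifHit:
    """One scored motif occurrence in a query sequence.

    offset is the 0-based window start in the query (always in query
    coordinates, also for minus-strand hits); rel_score is 1.0 iff the
    window is the consensus site on that strand.
    """

    offset: int
    strand: str
    raw_score: float
    rel_score: float


def pfm_to_pwm(
    pfm: PositionFrequencyMatrix,
    background: Sequence[float] | None = None,
    pseudocount: float = 0.8,
) -> PositionWeightMatrix:
    """Convert counts to log2-odds weights with background-distributed
    pseudocounts. Deterministic: same inputs, same matrix."""
    bg = (
        np.full(4, 0.25)
        if background is None
        else np.asarray(background, dtype=float)
    )
    if bg.shape != (4,) or (bg <= 0).any():
        raise ValueError("background must be 4 strictly positive probabilities")
    if abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background must sum to 1")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    totals = pfm.counts.sum(axis=0)
    prob = (pfm.counts + pseudocount * bg[:, None]) / (totals + pseudocount)
    log_odds = np.log2(prob / bg[:, None])
    return PositionWeightMatrix(log_odds, bg, pseudocount,
                                identifier=pfm.identifier)


def scan(sequence: str, pwm: PositionWeightMatrix) -> list[MotifHit]:
    """Score every window of the query on both strands.

    One hit per (offset, strand); windows containing N (or any non-ACGT
    base) are skipped rather than scored at background — an ambiguous
    base voids the window. A query shorter than the motif yields no hits.
    The minus-strand score is the plus-strand score of the window's
    reverse complement.
    """
    seq = sequence.upper()
    L = pwm.length
    hits: list[MotifHit] = []
    for offset in range(0, len(seq) - L + 1):
        window = seq[offset : offset + L]
        if any(b not in _INDEX for b in window):
            continue
        for strand, site in (("+", window), ("-", reverse_complement(window))):
            raw = pwm.score_site(site)
            hits.append(MotifHit(offset, strand, raw, pwm.rel_score(raw)))
    return hits


def compare_orthologs(
    aligned_sites: Mapping[str, str],
    pwm: PositionWeightMatrix,
    reference: str,
) -> pd.DataFrame:
    """Score one anchored motif site across species orthologs.

    ``aligned_sites`` maps species -> the gapless L-length site string in
    motif orientation. Returns a table sorted by predicted affinity
    (rel_score, descending) with, per species, the 0-based positions at
    which its site differs from the reference species' site.
    """
    if reference not in aligned_sites:
        raise ValueError(f"reference species {reference!r} not in sites")
    L = pwm.length
    for species, site in aligned_sites.items():
        if len(site) != L:
            raise ValueError(
                f"site for {species!r} has length {len(site)}, expected {L}"
            )
    ref_site = aligned_sites[reference].upper()
    rows = []
    for species, site in aligned_sites.items():
        site = site.upper()
        raw = pwm.score_site(site)
        diffs = [i for i in range(L) if site[i] != ref_site[i]]
        rows.append(
            {
                "species": species,
                "site": site,
                "raw_score": raw,
                "rel_score": pwm.rel_score(raw),
                "n_diff_from_ref": len(diffs),
                "diff_positions": ",".join(map(str, diffs)),
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        "rel_score", ascending=False, kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# in-silico mutagenesis


@dataclass(frozen=True)
class Variant:
    """A sequence edit: substitution (ref and alt both one base),
    insertion (ref empty) or deletion (alt empty). ``pos`` is 0-based in
    the sequence the variant is applied to."""

    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("variant position must be >= 0")
        if self.ref == self.alt:
            raise ValueError(f"variant at {self.pos} is a no-op")

    @property
    def inverse(self) -> "Variant":
        return Variant(self.pos, self.alt, self.ref)


def apply_variants(sequence: str, variants: Iterable[Variant]) -> str:
    """Apply edits sequentially, each positioned in the current sequence.

    The reference allele is checked before every edit; a mismatch raises
    with the offending position. Applying a variant and then its
    ``inverse`` is the identity.
    """
    seq = sequence
    for v in variants:
        end = v.pos + len(v.ref)
        if end > len(seq) or seq[v.pos : end] != v.ref:
            found = seq[v.pos : end] if end <= len(seq) else "<past end>"
            raise ValueError(
                f"reference mismatch at position {v.pos}: expected "
                f"{v.ref!r}, found {found!r}"
            )
        seq = seq[: v.pos] + v.alt + seq[end:]
    return seq


# ---------------------------------------------------------------------------
# JASPAR text I/O (delegated to Bio.motifs)


def read_jaspar_pfm(path: str | Path) -> PositionFrequencyMatrix:
    """Read the first motif from a JASPAR-format text file."""
    with Path(path).open() as fh:
        motif = bio_motifs.read(fh, "jaspar")
    counts = np.array([motif.counts[b] for b in ALPHABET], dtype=float)
    return PositionFrequencyMatrix(
        counts, identifier=motif.matrix_id or "", name=motif.name or ""
    )


def write_jaspar_pfm(pfm: PositionFrequencyMatrix, path: str | Path) -> None:
    counts = {b: list(pfm.counts[_INDEX[b]]) for b in ALPHABET}
    motif = bio_motifs.Motif(alphabet="ACGT", counts=counts)
    motif.matrix_id = pfm.identifier
    motif.name = pfm.name or pfm.identifier
    with Path(path).open("w") as fh:
        fh.write(bio_motifs.write([motif], "jaspar"))
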