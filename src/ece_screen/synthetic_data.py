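"""Synthetic fixtures with planted ground truth for every pipeline stage.

Nothing in this package downloads data: the generator emulates the study
conditions instead. The screen fixture mirrors the published funnel — an
880 kb TAD-sized region carrying 209 planted conserved blocks, 41 of which
overlap evidence peaks spread over six tracks — with conservation
background drawn strictly below the calling threshold (margin 0.01, so no
boundary flakiness), interior missing-data gaps no longer than the
caller's bridgeable maximum, exon decoys that must be excluded, and
evidence peaks that never touch non-priority blocks. The motif fixture
plants ortholog motif sites of graded PWM affinity, including a derived
set of 12 variants (2 single-base insertions + 10 substitutions) on the
highest-affinity species. The assay fixture generates Ct, luminescence,
allelic-ratio and gland-count tables at declared effect sizes.

Every expected output in a truth manifest is computed by a brute-force
oracle inside this module (pairwise union-find for window merging, direct
arithmetic for expansion), never by the pipeline under test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import (
    ConservationTrack,
    GenomicInterval,
    IntervalSet,
    write_bed,
    write_bedgraph,
)
from .motif_scanner import (
    ALPHABET,
    PositionFrequencyMatrix,
    PositionWeightMatrix,
    Variant,
    apply_variants,
    pfm_to_pwm,
    write_jaspar_pfm,
)

__all__ = [
    "EVIDENCE_LABELS",
    "ScreenTruth",
    "MotifTruth",
    "AssayTruth",
    "gc_box_pfm",
    "random_track",
    "make_screen_fixture",
    "make_motif_fixture",
    "make_assay_fixture",
]

# the six evidence-dataset roles of the published screen
EVIDENCE_LABELS = (
    "DNase_mouse_limb",
    "CaptureC_mouse_limb",
    "H3K27ac_mouse_limb",
    "H3K27ac_NHEK",
    "HAR_catalog",
    "DEAF1_ChIP",
)

_DEFAULT_TAD = GenomicInterval("chr2", 118_000_000, 118_880_000)


def gc_box_pfm() -> PositionFrequencyMatrix:
    """A synthetic GC-box position frequency matrix.

    Shaped like an SP1-class motif (consensus GGGGCGGGGC) but with soft,
    unequal column preferences so that single-base substitutions move the
    relative score in small, varied steps — which is what lets the motif
    fixture hit arbitrary target affinities. Synthetic: these counts are
    not any database matrix.
    """
    consensus = "GGGGCGGGGC"
    minors = [
        (12, 8, 6), (10, 9, 5), (14, 7, 4), (11, 10, 6), (13, 8, 5),
        (9, 8, 7), (12, 10, 4), (10, 6, 5), (14, 9, 6), (11, 7, 4),
    ]
    counts = np.zeros((4, len(consensus)))
    idx = {b: i for i, b in enumerate(ALPHABET)}
    for col, base in enumerate(consensus):
        others = [b for b in ALPHABET if b != base]
        counts[idx[base], col] = 70
        for b, c in zip(others, minors[col]):
            counts[idx[b], col] = c
    return PositionFrequencyMatrix(counts, identifier="SYN0001",
                                   name="GCbox_synthetic")


def random_track(
    seed: int | np.random.Generator,
    length: int,
    chrom: str = "chrT",
    start: int = 0,
    p_missing: float = 0.1,
    p_high: float = 0.3,
    threshold: float = 0.98,
) -> ConservationTrack:
    """An unstructured random track for oracle-equivalence testing:
    each base independently missing, above-threshold, or background."""
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    u = rng.random(length)
    values = rng.uniform(0.0, threshold - 1e-6, size=length)
    values[u < p_missing + p_high] = rng.uniform(
        threshold, 1.0, size=int((u < p_missing + p_high).sum())
    )
    values[u < p_missing] = np.nan
    region = GenomicInterval(chrom, start, start + length)
    return ConservationTrack(region, values)


# ---------------------------------------------------------------------------
# screen fixture


@dataclass
class ScreenTruth:
    """Planted inputs and oracle-derived expected outputs of the screen."""

    tad: GenomicInterval
    threshold: float
    min_length: int
    max_gap: int
    elements: list[GenomicInterval]          # expected called elements, sorted
    element_ids: list[str]                   # CE1.. in genomic order
    element_gap_bases: list[int]             # bridged missing bases per element
    exons: list[GenomicInterval]
    decoy_blocks: list[GenomicInterval]      # conserved-looking, exon-covered
    evidence: dict[str, list[GenomicInterval]]
    priority_ids: list[str]
    top_id: str                              # hits every evidence track
    expected_windows: list[dict]             # {start, end, kernel_ids}

    def to_dict(self) -> dict:
        iv = lambda i: [i.chrom, i.start, i.end]
        return {
            "tad": iv(self.tad),
            "threshold": self.threshold,
            "min_length": self.min_length,
            "max_gap": self.max_gap,
            "elements": [iv(e) for e in self.elements],
            "element_ids": self.element_ids,
            "element_gap_bases": self.element_gap_bases,
            "exons": [iv(e) for e in self.exons],
            "decoy_blocks": [iv(e) for e in self.decoy_blocks],
            "evidence": {k: [iv(p) for p in v] for k, v in self.evidence.items()},
            "priority_ids": self.priority_ids,
            "top_id": self.top_id,
            "expected_windows": self.expected_windows,
        }


def _expand_oracle(start: int, end: int, tad: GenomicInterval,
                   target: int, max_length: int) -> tuple[int, int]:
    """Window expansion as plain arithmetic, independent of the pipeline."""
    k = end - start
    if k >= target:
        return start, end if k <= max_length else end
    mid = (start + end) // 2
    ws = mid - target // 2
    we = ws + target
    if ws < tad.start:
        we = min(tad.end, we + (tad.start - ws))
        ws = tad.start
    if we > tad.end:
        ws = max(tad.start, ws - (we - tad.end))
        we = tad.end
    return ws, we


def _merge_oracle(windows: list[tuple[int, int, str]]) -> list[dict]:
    """Union-find over all pairwise strict overlaps — the brute-force
    merge oracle used to compute expected windows."""
    n = len(windows)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            si, ei, _ = windows[i]
            sj, ej, _ = windows[j]
            if si < ej and sj < ei:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    merged = []
    for members in groups.values():
        s = min(windows[i][0] for i in members)
        e = max(windows[i][1] for i in members)
        ids = [windows[i][2] for i in
               sorted(members, key=lambda i: (windows[i][0], windows[i][1]))]
        merged.append({"start": s, "end": e, "kernel_ids": ids})
    return sorted(merged, key=lambda d: d["start"])


def _segment_records(rng: np.random.Generator, start: int, end: int,
                     lo: float, hi: float,
                     run_range: tuple[int, int]) -> list[tuple[int, int, float]]:
    """Piecewise-constant random values over [start, end)."""
    records = []
    pos = start
    while pos < end:
        run = min(int(rng.integers(*run_range)), end - pos)
        records.append((pos, pos + run, round(float(rng.uniform(lo, hi)), 6)))
        pos += run
    return records


def make_screen_fixture(
    outdir: str | Path,
    seed: int,
    tad: GenomicInterval | None = None,
    n_elements: int = 209,
    n_priority: int = 41,
    element_length_range: tuple[int, int] = (50, 250),
    gap_rate: float = 0.2,
    n_evidence_tracks: int = 6,
    n_exons: int = 8,
    n_decoy_peaks: int = 5,
    threshold: float = 0.98,
    min_length: int = 50,
    max_gap: int = 10,
) -> tuple[dict[str, Path], ScreenTruth]:
    """Generate the full screen fixture and its truth manifest.

    Defaults mirror the study funnel: an 880 kb TAD, 209 conserved
    blocks, 41 of them carrying evidence over 6 tracks. Files written:
    ``track.bedGraph``, ``exons.bed``, one ``evidence_<label>.bed`` per
    track, and ``truth.json``. Deterministic given ``seed``.
    """
    if not (0 <= n_priority <= n_elements):
        raise ValueError("need 0 <= n_priority <= n_elements")
    if not (1 <= n_evidence_tracks <= len(EVIDENCE_LABELS)):
        raise ValueError(f"n_evidence_tracks must be in [1, {len(EVIDENCE_LABELS)}]")
    tad = tad or _DEFAULT_TAD
    rng = np.random.default_rng(seed)
    lo_len, hi_len = element_length_range
    if lo_len < min_length:
        raise ValueError("planted elements must satisfy the caller min_length")
    lengths = rng.integers(lo_len, hi_len + 1, size=n_elements)
    min_sep = 150  # room for hard-break flanks, decoys and peak slop
    slack = tad.length - int(lengths.sum()) - (n_elements + 1) * min_sep
    if slack < 0:
        raise ValueError(
            f"infeasible packing: {n_elements} elements of up to {hi_len} bp "
            f"plus spacing exceed the {tad.length} bp TAD"
        )
    weights = rng.random(n_elements + 1)
    gaps = (min_sep + np.floor(weights / weights.sum() * slack)).astype(int)
    # pull some interior gaps below the window diameter so that expanded
    # test windows of neighbouring kernels genuinely overlap and merge
    n_close = n_elements // 16
    if n_close and n_elements >= 2:
        close_at = rng.choice(np.arange(1, n_elements), size=n_close,
                              replace=False)
        gaps[close_at] = rng.integers(min_sep, 701, size=n_close)
    gaps[-1] += tad.length - int(lengths.sum()) - int(gaps.sum())

    starts = []
    pos = tad.start
    for g, ln in zip(gaps[:-1], lengths):
        pos += int(g)
        starts.append(pos)
        pos += int(ln)

    records: list[tuple[int, int, float]] = []
    elements: list[GenomicInterval] = []
    element_gaps: list[int] = []
    exons: list[GenomicInterval] = []
    decoys: list[GenomicInterval] = []

    # choose which inter-element regions host an exon + decoy block
    bg_regions = []
    prev_end = tad.start
    for s, ln in zip(starts, lengths):
        bg_regions.append((prev_end, s))
        prev_end = s + int(ln)
    bg_regions.append((prev_end, tad.end))
    wide = [i for i, (a, b) in enumerate(bg_regions) if b - a >= 400]
    exon_regions = set(
        rng.choice(wide, size=min(n_exons, len(wide)), replace=False).tolist()
    )

    for i, (a, b) in enumerate(bg_regions):
        if i in exon_regions:
            # background | exon [ decoy conserved block inside ] | background
            exon_len = int(rng.integers(200, min(350, b - a - 40)))
            ex_start = a + int(rng.integers(15, b - a - exon_len - 15))
            exon = GenomicInterval(tad.chrom, ex_start, ex_start + exon_len,
                                   name=f"exon{len(exons) + 1}")
            exons.append(exon)
            d_len = int(rng.integers(60, min(130, exon_len - 10)))
            d_start = ex_start + int(rng.integers(5, exon_len - d_len - 4))
            decoy = GenomicInterval(tad.chrom, d_start, d_start + d_len)
            decoys.append(decoy)
            records += _segment_records(rng, a, d_start, 0.02, threshold - 0.01,
                                        (10, 50))
            records += _segment_records(rng, d_start, decoy.end, threshold + 0.001,
                                        0.999, (10, 40))
            records += _segment_records(rng, decoy.end, b, 0.02, threshold - 0.01,
                                        (10, 50))
        else:
            # plain background, sometimes with an uncovered (missing) hole
            if b - a >= 40 and rng.random() < 0.3:
                hole_len = int(rng.integers(1, 31))
                hole_start = a + int(rng.integers(3, b - a - hole_len - 2))
                records += _segment_records(rng, a, hole_start, 0.02,
                                            threshold - 0.01, (10, 50))
                records += _segment_records(rng, hole_start + hole_len, b, 0.02,
                                            threshold - 0.01, (10, 50))
            elif b > a:
                records += _segment_records(rng, a, b, 0.02, threshold - 0.01,
                                            (10, 50))

    for s, ln in zip(starts, lengths):
        ln = int(ln)
        e = s + ln
        elements.append(GenomicInterval(tad.chrom, s, e))
        # optional interior missing gap, bridgeable by construction
        if ln >= min_length + max_gap + 4 and rng.random() < gap_rate:
            g_len = int(rng.integers(1, max_gap + 1))
            g_start = s + int(rng.integers(2, ln - g_len - 1))
            element_gaps.append(g_len)
            records += _segment_records(rng, s, g_start, threshold + 0.001,
                                        0.999, (8, 40))
            records += _segment_records(rng, g_start + g_len, e,
                                        threshold + 0.001, 0.999, (8, 40))
        else:
            element_gaps.append(0)
            records += _segment_records(rng, s, e, threshold + 0.001, 0.999,
                                        (8, 40))

    element_ids = [f"CE{k}" for k in range(1, n_elements + 1)]

    # evidence: a designated top element hits every track, the other
    # priority elements hit 1..n-1 random tracks; decoy peaks sit in
    # background, never touching any element
    labels = list(EVIDENCE_LABELS[:n_evidence_tracks])
    forced: list[int] = []
    if n_close and n_elements >= 2 and n_priority >= 4:
        # gap index j separates elements j-1 and j; making both priority
        # guarantees their expanded windows overlap and must merge
        for j in sorted(close_at.tolist())[: n_priority // 4]:
            forced += [j - 1, j]
    forced = sorted(set(forced))[:n_priority]
    remaining = [i for i in range(n_elements) if i not in forced]
    extra = rng.choice(len(remaining), size=n_priority - len(forced),
                       replace=False)
    priority_idx = np.sort(
        np.array(forced + [remaining[int(i)] for i in extra], dtype=int)
    )
    top_pos = int(rng.integers(0, n_priority)) if n_priority else 0
    evidence: dict[str, list[GenomicInterval]] = {lab: [] for lab in labels}

    def _peak_over(el: GenomicInterval) -> GenomicInterval:
        s = el.start - int(rng.integers(0, 61))
        e = el.end + int(rng.integers(0, 61))
        return GenomicInterval(el.chrom, max(0, s), e)

    for rank, idx in enumerate(priority_idx):
        el = elements[int(idx)]
        if rank == top_pos:
            chosen = labels
        else:
            k = int(rng.integers(1, n_evidence_tracks)) \
                if n_evidence_tracks > 1 else 1
            chosen = [labels[j] for j in
                      rng.choice(n_evidence_tracks, size=k, replace=False)]
        for lab in chosen:
            evidence[lab].append(_peak_over(el))

    plain_bg = [i for i, (a, b) in enumerate(bg_regions)
                if i not in exon_regions and b - a >= 200]
    for lab in labels if plain_bg else []:
        for _ in range(n_decoy_peaks):
            i = int(rng.choice(plain_bg))
            a, b = bg_regions[i]
            p_len = int(rng.integers(80, min(150, b - a - 40)))
            p_start = a + int(rng.integers(15, b - a - p_len - 14))
            evidence[lab].append(
                GenomicInterval(tad.chrom, p_start, p_start + p_len)
            )

    priority_ids = [element_ids[int(i)] for i in priority_idx]
    top_id = element_ids[int(priority_idx[top_pos])] if n_priority else ""

    # expected windows from the brute-force expansion + union-find oracle
    kernels = [
        (elements[int(i)].start, elements[int(i)].end, element_ids[int(i)])
        for i in priority_idx
    ]
    expanded = [
        (*_expand_oracle(s, e, tad, 1000, 1500), kid) for s, e, kid in kernels
    ]
    expected_windows = _merge_oracle(expanded)

    truth = ScreenTruth(
        tad=tad, threshold=threshold, min_length=min_length, max_gap=max_gap,
        elements=elements, element_ids=element_ids,
        element_gap_bases=element_gaps, exons=exons, decoy_blocks=decoys,
        evidence=evidence, priority_ids=priority_ids, top_id=top_id,
        expected_windows=expected_windows,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    records.sort()
    values = np.full(tad.length, np.nan)
    for s, e, v in records:
        values[s - tad.start : e - tad.start] = v
    track = ConservationTrack(tad, values)
    paths["track"] = outdir / "track.bedGraph"
    write_bedgraph(track, paths["track"])

    paths["exons"] = outdir / "exons.bed"
    write_bed(exons, paths["exons"])
    for lab in labels:
        p = outdir / f"evidence_{lab}.bed"
        write_bed(sorted(evidence[lab], key=GenomicInterval.sort_key), p)
        paths[f"evidence_{lab}"] = p
    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps(truth.to_dict(), indent=1) + "\n")
    return paths, truth


# ---------------------------------------------------------------------------
# motif fixture


@dataclass
class MotifTruth:
    """Planted ortholog sequences with per-species variant provenance."""

    ancestral: str
    species_seqs: dict[str, str]
    species_variants: dict[str, list[Variant]]
    site_offsets: dict[str, int]
    site_length: int
    target_scores: dict[str, float]
    achieved_scores: dict[str, float]
    derived_species: str


def _plant_site(pwm: PositionWeightMatrix, target: float,
                rng: np.random.Generator, tolerance: float) -> str:
    """Greedy walk from the consensus toward a target relative score:
    repeatedly apply the single substitution landing closest to the
    target until within tolerance."""
    if not (0.0 <= target <= 1.0):
        raise ValueError(f"target rel_score {target} outside [0, 1]")
    site = list(pwm.consensus)
    L = pwm.length
    rel = 1.0
    for _ in range(4 * L):  # each position can only be rewritten so often
        if abs(rel - target) <= tolerance:
            return "".join(site)
        candidates = []
        for pos in range(L):
            for base in ALPHABET:
                if base == site[pos]:
                    continue
                trial = site.copy()
                trial[pos] = base
                r = pwm.rel_score(pwm.score_site("".join(trial)))
                if r < rel:  # only walk downhill
                    candidates.append((abs(r - target), r, pos, base))
        if not candidates:
            break
        rng.shuffle(candidates)
        candidates.sort(key=lambda c: c[0])
        _, rel, pos, base = candidates[0]
        site[pos] = base
    if abs(rel - target) <= tolerance:
        return "".join(site)
    raise ValueError(
        f"target rel_score {target} unreachable within tolerance {tolerance} "
        f"for this matrix (best {rel:.3f})"
    )


_DEFAULT_SPECIES = (
    ("human", 1.0),
    ("chimpanzee", 0.85),
    ("macaque", 0.72),
    ("marmoset", 0.60),
    ("mouse", 0.35),
)


def make_motif_fixture(
    seed: int,
    pfm: PositionFrequencyMatrix | None = None,
    species_spec: Sequence[tuple[str, float]] | None = None,
    seq_length: int = 300,
    tolerance: float = 0.05,
    outdir: str | Path | None = None,
) -> tuple[dict[str, Path], MotifTruth]:
    """Ortholog FASTA with one anchored motif site per species at a
    graded target affinity.

    The lowest-affinity site defines the ancestral sequence; every other
    species is that sequence plus its recorded variant list. The
    highest-affinity ("derived") species carries exactly 12 variants —
    two single-base insertions in the flanks plus 10 substitutions —
    mirroring a derived-haplotype comparison; its site substitutions are
    part of the 10, the remainder are neutral flank edits.
    """
    pfm = pfm or gc_box_pfm()
    spec = list(species_spec or _DEFAULT_SPECIES)
    if len(spec) < 2:
        raise ValueError("need at least two species")
    rng = np.random.default_rng(seed)
    pwm = pfm_to_pwm(pfm)
    L = pwm.length

    sites = {name: _plant_site(pwm, t, rng, tolerance) for name, t in spec}
    targets = dict(spec)
    derived = max(spec, key=lambda nt: nt[1])[0]
    ancestral_name = min(spec, key=lambda nt: nt[1])[0]

    site_off = seq_length // 2 - L // 2
    flank = "".join(rng.choice(list(ALPHABET), size=seq_length))
    ancestral = (
        flank[:site_off] + sites[ancestral_name] + flank[site_off + L :]
    )

    species_seqs: dict[str, str] = {}
    species_variants: dict[str, list[Variant]] = {}
    site_offsets: dict[str, int] = {}
    anc_site = sites[ancestral_name]
    for name, _ in spec:
        subs = [
            Variant(site_off + i, anc_site[i], sites[name][i])
            for i in range(L)
            if sites[name][i] != anc_site[i]
        ]
        variants = list(subs)
        offset = site_off
        if name == derived:
            # pad to 10 substitutions with neutral flank edits, then add
            # two single-base insertions (one per flank)
            seq_now = apply_variants(ancestral, variants)
            flank_pos = [p for p in range(len(ancestral))
                         if p < site_off - 2 or p >= site_off + L + 2]
            rng.shuffle(flank_pos)
            for p in flank_pos:
                if len(variants) >= 10:
                    break
                ref = seq_now[p]
                alt = ALPHABET[(ALPHABET.index(ref) + 1) % 4]
                variants.append(Variant(p, ref, alt))
                seq_now = seq_now[:p] + alt + seq_now[p + 1 :]
            if len(variants) < 10:
                raise ValueError("sequence too short to pad the derived set")
            left_ins = int(rng.integers(2, site_off - 2))
            right_ins = int(rng.integers(site_off + L + 2, len(seq_now) - 2))
            variants.append(Variant(left_ins, "", str(rng.choice(list(ALPHABET)))))
            # the left insertion shifted everything downstream by one
            variants.append(
                Variant(right_ins + 1, "", str(rng.choice(list(ALPHABET))))
            )
            offset = site_off + 1
        seq = apply_variants(ancestral, variants)
        species_seqs[name] = seq
        species_variants[name] = variants
        site_offsets[name] = offset
        assert seq[offset : offset + L] == sites[name]

    achieved = {
        name: pwm.rel_score(pwm.score_site(sites[name])) for name, _ in spec
    }
    truth = MotifTruth(
        ancestral=ancestral, species_seqs=species_seqs,
        species_variants=species_variants, site_offsets=site_offsets,
        site_length=L, target_scores=targets, achieved_scores=achieved,
        derived_species=derived,
    )

    paths: dict[str, Path] = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths["fasta"] = outdir / "orthologs.fa"
        with paths["fasta"].open("w") as fh:
            for name, _ in spec:
                fh.write(f">{name}\n")
                seq = species_seqs[name]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        paths["pfm"] = outdir / f"{pfm.identifier or 'motif'}.pfm"
        write_jaspar_pfm(pfm, paths["pfm"])
        paths["sites"] = outdir / "anchored_sites.tsv"
        with paths["sites"].open("w") as fh:
            fh.write("species\tsite_offset\tsite\ttarget_rel_score\n")
            for name, t in spec:
                fh.write(f"{name}\t{site_offsets[name]}\t{sites[name]}\t{t}\n")
    return paths, truth


# ---------------------------------------------------------------------------
# assay fixture


@dataclass
class AssayTruth:
    luciferase_folds: dict[str, float]
    chip_percent_input: dict[tuple[str, str], float]
    allelic_imbalance: dict[str, float]
    gland_group_means: dict[str, float]
    gland_effect_pct: float


_DEFAULT_EFFECTS = {
    # headline reporter readouts: human ortholog 13-fold over empty vector,
    # 2.6-fold over chimpanzee, 1.4-fold over macaque
    "luciferase_folds": {
        "hECE18": 13.0,
        "macECE18": 13.0 / 1.4,
        "cECE18": 13.0 / 2.6,
        "Control": 1.0,
    },
    # percent-input enrichment: antibody enriched at the two motif sites,
    # IgG and the negative-control promoter flat
    "chip_percent_input": {
        ("SP1_siteA", "IP_SP1"): 1.5,
        ("SP1_siteA", "IP_IgG"): 0.08,
        ("SP1_siteB", "IP_SP1"): 1.2,
        ("SP1_siteB", "IP_IgG"): 0.07,
        ("HBG2_promoter", "IP_SP1"): 0.09,
        ("HBG2_promoter", "IP_IgG"): 0.08,
    },
    # cis-regulatory allelic imbalance of the knock-in allele
    "allelic_imbalance": {"WT": 1.0, "KI": 1.6},
    # sensitized gland counts: +17% in carriers
    "gland_base_mean": 14.0,
    "gland_effect_pct": 17.0,
}


def make_assay_fixture(
    seed: int,
    effect_sizes: Mapping | None = None,
    noise_sd: float = 0.05,
    n_replicates: int = 3,
    n_animals: int = 8,
    outdir: str | Path | None = None,
) -> tuple[dict[str, pd.DataFrame], AssayTruth]:
    """Tidy assay tables generated at declared effect sizes.

    ``noise_sd`` is the standard deviation of multiplicative (log-scale)
    noise on luminescence, ratios and Ct offsets; gland counts use an
    additive count noise of ``30 * noise_sd`` glands before rounding, so
    the noiseless limit is exact for the continuous assays and exact up
    to integer rounding for counts. ``n_replicates`` mirrors biological
    triplicates; technical qPCR triplicates are generated within each.
    """
    if n_replicates < 3:
        raise ValueError("n_replicates must be >= 3 (biological triplicate)")
    rng = np.random.default_rng(seed)
    eff = dict(_DEFAULT_EFFECTS)
    if effect_sizes:
        eff.update(effect_sizes)

    # --- luciferase ---------------------------------------------------
    base_activity = 0.05  # control normalized firefly/renilla activity
    luc_rows = []
    for construct, fold in eff["luciferase_folds"].items():
        for rep in range(1, n_replicates + 1):
            renilla = 1e5 * float(np.exp(rng.normal(0, 0.2)))
            normalized = base_activity * fold * float(
                np.exp(rng.normal(0, noise_sd))
            )
            luc_rows.append(
                {
                    "construct": construct,
                    "replicate": rep,
                    "firefly": normalized * renilla,
                    "renilla": renilla,
                }
            )
    luciferase = pd.DataFrame(luc_rows)

    # --- ChIP-qPCR ----------------------------------------------------
    targets = sorted({t for t, _ in eff["chip_percent_input"]})
    chip_rows = []
    for target in targets:
        for rep in range(1, n_replicates + 1):
            ct_input = 24.0 + float(rng.normal(0, 0.5))
            conds = {"input": ct_input}
            for (t, cond), pct in eff["chip_percent_input"].items():
                if t == target:
                    conds[cond] = (
                        ct_input
                        - float(np.log2(pct / 100.0))
                        + float(rng.normal(0, noise_sd))
                    )
            for cond, ct in conds.items():
                for tech in range(1, 4):
                    chip_rows.append(
                        {
                            "target": target,
                            "condition": cond,
                            "replicate": rep,
                            "tech": tech,
                            "ct": ct + float(rng.normal(0, noise_sd / 2)),
                        }
                    )
    chip = pd.DataFrame(chip_rows)

    # --- allelic ratios ----------------------------------------------
    al_rows = []
    for genotype, imbalance in eff["allelic_imbalance"].items():
        for rep in range(1, n_replicates + 1):
            gdna = float(np.exp(rng.normal(0, noise_sd)))
            cdna = imbalance * gdna * float(np.exp(rng.normal(0, noise_sd)))
            sample = f"{genotype}_{rep}"
            al_rows.append({"sample": sample, "genotype": genotype,
                            "template": "gDNA", "ratio_raw": gdna})
            al_rows.append({"sample": sample, "genotype": genotype,
                            "template": "cDNA", "ratio_raw": cdna})
    allelic = pd.DataFrame(al_rows)

    # --- gland counts -------------------------------------------------
    base = eff["gland_base_mean"]
    means = {
        "sensitized": base,
        "sensitized_KI": base * (1.0 + eff["gland_effect_pct"] / 100.0),
    }
    count_sd = 30.0 * noise_sd
    gl_rows = []
    for group, m in means.items():
        for a in range(1, n_animals + 1):
            left = m + float(rng.normal(0, count_sd))
            right = m + float(rng.normal(0, count_sd))
            gl_rows.append(
                {
                    "group": group,
                    "animal": f"{group}_{a}",
                    "left": max(0, round(left)),
                    "right": max(0, round(right)),
                }
            )
    glands = pd.DataFrame(gl_rows)

    tables = {"luciferase": luciferase, "chip": chip, "allelic": allelic,
              "glands": glands}
    truth = AssayTruth(
        luciferase_folds=dict(eff["luciferase_folds"]),
        chip_percent_input=dict(eff["chip_percent_input"]),
        allelic_imbalance=dict(eff["allelic_imbalance"]),
        gland_group_means=means,
        gland_effect_pct=eff["gland_effect_pct"],
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    return tables, truth
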