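"""Orchestrate the screen as one reproducible run.

A run reads a conservation track, calls conserved elements inside the
TAD, annotates them against the evidence catalog, selects the priority
set, expands and merges candidate windows, and (optionally) scans
ortholog sequences with a PWM — writing each stage's output plus a run
log of the stage counts (the elements → priority → windows funnel) and a
snapshot of the fully resolved configuration. Re-running from the
snapshot reproduces every output byte for byte: nothing in a run
depends on wall-clock time or unseeded randomness.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .conserved_caller import CallerParams, call_elements, write_elements_bed
from .genome_model import (
    GenomicInterval,
    parse_ucsc_interval,
    read_bed,
    read_bedgraph,
)
from .motif_scanner import read_jaspar_pfm, pfm_to_pwm, scan
from .prioritizer import (
    EvidenceCatalog,
    annotate,
    annotation_table,
    select_priority,
)
from .window_builder import WindowParams, build_windows, write_windows_bed

__all__ = ["RunConfig", "RunResult", "run_screen"]


@dataclass
class RunConfig:
    """Every knob of a screen run, serializable to YAML.

    ``tad`` is a browser-style span string interpreted under
    ``coord_dialect`` (``ucsc1`` = 1-based inclusive, ``bed0`` = 0-based
    half-open). ``evidence`` maps track label to BED path; an optional
    ``genome`` per label may be declared as ``label=path@assembly``-style
    entries in the YAML by using a two-element list ``[path, assembly]``.
    """

    track: str
    tad: str
    outdir: str
    coord_dialect: str = "ucsc1"
    threshold: float = 0.98
    min_length: int = 50
    max_gap: int = 10
    exon_mask: str | None = None
    evidence: dict = field(default_factory=dict)
    min_overlap: int = 1
    assume_same_space: bool = False
    target_length: int = 1000
    max_length: int = 1500
    motif_pfm: str | None = None
    motif_fasta: str | None = None
    motif_rel_threshold: float = 0.8

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        _atomic_write(path, yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class RunResult:
    n_elements: int
    n_priority: int
    n_windows: int
    n_motif_hits: int | None
    elements: list
    priority: list
    windows: list
    outputs: dict[str, Path]


def _atomic_write(path: str | Path, text: str) -> None:
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def run_screen(config: RunConfig) -> RunResult:
    """Execute call -> prioritize -> build-windows (-> scan-motifs).

    Any stage failure aborts the run with the stage named in the error.
    Outputs land in ``config.outdir``: elements.bed, priority.tsv,
    windows.bed, optionally motif_hits.tsv, plus run_log.txt and
    config_snapshot.yaml.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        return _Ctx()

    with stage("load-track"):
        tad = parse_ucsc_interval(config.tad, dialect=config.coord_dialect)
        track = read_bedgraph(config.track, tad)

    with stage("call-elements"):
        exon_mask = (
            read_bed(config.exon_mask, label="exons")
            if config.exon_mask
            else None
        )
        params = CallerParams(
            tad=tad,
            threshold=config.threshold,
            min_length=config.min_length,
            max_gap=config.max_gap,
            exon_mask=exon_mask,
        )
        elements = call_elements(track, params)
        outputs["elements"] = outdir / "elements.bed"
        write_elements_bed(elements, outputs["elements"])

    with stage("prioritize"):
        tracks = []
        # canonical label order: output identical no matter how the
        # evidence mapping was ordered in the config
        for label, entry in sorted(config.evidence.items()):
            path, genome = (
                (entry[0], entry[1]) if isinstance(entry, (list, tuple))
                else (entry, None)
            )
            tracks.append(read_bed(path, label=label, genome=genome))
        catalog = EvidenceCatalog(
            tracks,
            min_overlap=config.min_overlap,
            assume_same_space=config.assume_same_space,
        )
        annotated = annotate(elements, catalog)
        priority = select_priority(annotated) if annotated else []
        outputs["priority"] = outdir / "priority.tsv"
        _atomic_write(
            outputs["priority"],
            annotation_table(annotated).to_csv(sep="\t", index=False),
        )

    with stage("build-windows"):
        wparams = WindowParams(
            tad=tad,
            target_length=config.target_length,
            max_length=config.max_length,
        )
        windows = build_windows([p.element for p in priority], wparams)
        outputs["windows"] = outdir / "windows.bed"
        write_windows_bed(windows, outputs["windows"])

    n_motif_hits: int | None = None
    if config.motif_pfm and config.motif_fasta:
        with stage("scan-motifs"):
            pwm = pfm_to_pwm(read_jaspar_pfm(config.motif_pfm))
            lines = ["sequence\toffset\tstrand\traw_score\trel_score"]
            n_motif_hits = 0
            for name, seq in _read_fasta(config.motif_fasta):
                for hit in scan(seq, pwm):
                    if hit.rel_score >= config.motif_rel_threshold:
                        lines.append(
                            f"{name}\t{hit.offset}\t{hit.strand}\t"
                            f"{hit.raw_score:.6f}\t{hit.rel_score:.6f}"
                        )
                        n_motif_hits += 1
            outputs["motif_hits"] = outdir / "motif_hits.tsv"
            _atomic_write(outputs["motif_hits"], "\n".join(lines) + "\n")

    log_lines = [
        f"tad\t{config.tad}",
        f"elements_called\t{len(elements)}",
        f"priority_selected\t{len(priority)}",
        f"windows_after_merge\t{len(windows)}",
    ]
    if n_motif_hits is not None:
        log_lines.append(f"motif_hits\t{n_motif_hits}")
    outputs["log"] = outdir / "run_log.txt"
    _atomic_write(outputs["log"], "\n".join(log_lines) + "\n")
    outputs["config"] = outdir / "config_snapshot.yaml"
    config.to_yaml(outputs["config"])

    return RunResult(
        n_elements=len(elements),
        n_priority=len(priority),
        n_windows=len(windows),
        n_motif_hits=n_motif_hits,
        elements=elements,
        priority=priority,
        windows=windows,
        outputs=outputs,
    )


def _read_fasta(path: str | Path):
    name, chunks = None, []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    yield name, "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        yield name, "".join(chunks)
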