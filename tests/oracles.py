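"""Brute-force oracles, independent of the implementations they check.

Everything here favours obviousness over speed: per-base scans, all-pairs
loops, union-find over explicit pairwise overlap tests. Tests compare
pipeline output against these, never the other way round.
"""

from __future__ import annotations

import numpy as np

GOOD, GAP, BAD = "G", "M", "B"


def classify_states(values, threshold, exon_spans=(), offset=0):
    """Per-base state string from raw values (NaN = missing) and exon
    spans given in the same coordinate frame as ``offset``."""
    states = []
    for v in values:
        if np.isnan(v):
            states.append(GAP)
        elif v >= threshold:
            states.append(GOOD)
        else:
            states.append(BAD)
    for s, e in exon_spans:
        for i in range(max(0, s - offset), min(len(states), e - offset)):
            states[i] = BAD
    return "".join(states)


def is_legal(states: str, s: int, e: int, max_gap: int) -> bool:
    """A legal run: starts and ends on GOOD, contains no BAD base, and
    every maximal interior missing stretch is <= max_gap."""
    if s >= e or states[s] != GOOD or states[e - 1] != GOOD:
        return False
    run = 0
    for i in range(s, e):
        if states[i] == BAD:
            return False
        if states[i] == GAP:
            run += 1
            if run > max_gap:
                return False
        else:
            run = 0
    return True


def elements_exhaustive(states: str, min_length: int, max_gap: int):
    """Every (start, end) pair tested for legality; maximal = not
    contained in a longer legal run. Only for tiny inputs."""
    n = len(states)
    legal = [
        (s, e)
        for s in range(n)
        for e in range(s + 1, n + 1)
        if is_legal(states, s, e, max_gap)
    ]
    maximal = [
        (s, e)
        for (s, e) in legal
        if not any(
            (s2, e2) != (s, e) and s2 <= s and e <= e2 for (s2, e2) in legal
        )
    ]
    return sorted((s, e) for (s, e) in maximal if e - s >= min_length)


def elements_scan(states: str, min_length: int, max_gap: int):
    """Per-base scan oracle: from every GOOD base, greedily extend to the
    farthest legal end; keep runs not contained in a longer one."""
    n = len(states)
    candidates = []
    for s in range(n):
        if states[s] != GOOD:
            continue
        end = s + 1
        j = s + 1
        while j < n:
            if states[j] == GOOD:
                end = j + 1
                j += 1
            elif states[j] == GAP:
                g = j
                while g < n and states[g] == GAP:
                    g += 1
                if g < n and states[g] == GOOD and g - j <= max_gap:
                    j = g
                else:
                    break
            else:
                break
        candidates.append((s, end))
    maximal = [
        (s, e)
        for (s, e) in candidates
        if not any(
            (s2, e2) != (s, e) and s2 <= s and e <= e2
            for (s2, e2) in candidates
        )
    ]
    return sorted((s, e) for (s, e) in maximal if e - s >= min_length)


def overlap_allpairs(element_spans, track_peaks, min_overlap=1):
    """All-pairs per-element, per-track overlap in bp (union within a
    track computed by per-base set arithmetic)."""
    out = []
    for (es, ee) in element_spans:
        row = {}
        for label, peaks in track_peaks.items():
            covered = set()
            for (ps, pe) in peaks:
                covered.update(range(max(es, ps), min(ee, pe)))
            row[label] = len(covered)
        out.append(
            {
                "overlap": row,
                "count": sum(1 for bp in row.values() if bp >= min_overlap),
            }
        )
    return out


def merge_unionfind(spans):
    """Union-find over explicit pairwise strict-overlap tests; returns
    sorted merged (start, end, member_indices)."""
    n = len(spans)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            si, ei = spans[i]
            sj, ej = spans[j]
            if si < ej and sj < ei:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    merged = [
        (
            min(spans[i][0] for i in g),
            max(spans[i][1] for i in g),
            sorted(g, key=lambda i: spans[i]),
        )
        for g in groups.values()
    ]
    return sorted(merged)


def scan_exhaustive(sequence, log_odds, alphabet="ACGT"):
    """Per-window, per-position motif scoring on both strands with plain
    Python loops. Returns {(offset, strand): raw_score}."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    idx = {b: i for i, b in enumerate(alphabet)}
    L = log_odds.shape[1]
    seq = sequence.upper()
    scores = {}
    for off in range(len(seq) - L + 1):
        window = seq[off : off + L]
        if any(b not in idx for b in window):
            continue
        rc = "".join(comp[b] for b in reversed(window))
        for strand, site in (("+", window), ("-", rc)):
            raw = 0.0
            for i, b in enumerate(site):
                raw += log_odds[idx[b], i]
            scores[(off, strand)] = raw
    return scores
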