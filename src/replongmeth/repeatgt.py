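"""Tandem-repeat copy-number genotyping, phasing and composition analysis.

Per-read copy-number change at a repeat locus is measured from the net
inserted-minus-deleted bases of the alignment within the locus (plus a
flank margin), divided by the motif length — the approach of
tandem-genotypes-style callers.  Reads phase into non-expanded
(relative change < 50) and expanded (>= 50) allele groups, the rule used
to haplotype-sort methylation at the NOTCH2NLC GGC locus.  Repeat tracts
decompose losslessly into ordered motif runs (GGC units, GGA
interruptions, named insertions) for waterfall rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .io_model import AlignedRead, GenomicInterval

#: GGC repeat disease-causing range in copies (inclusive bounds)
DISEASE_RANGE = (41, 300)
PHASE_THRESHOLD = 50
DEFAULT_FLANK_MARGIN = 100

NON_EXPANDED = "non-expanded"
EXPANDED = "expanded"

INSERTION_PREFIX = "INS:"


class SpanningError(ValueError):
    """Read does not span the repeat locus plus its flank margin."""


@dataclass(frozen=True)
class RepeatLocus:
    interval: GenomicInterval
    unit: str
    ref_copies: int
    flank_margin: int = DEFAULT_FLANK_MARGIN

    def __post_init__(self) -> None:
        if len(self.unit) < 1:
            raise ValueError("repeat unit must be non-empty")
        if len(self.interval) < len(self.unit):
            raise ValueError("locus interval shorter than one repeat unit")


@dataclass(frozen=True)
class RepeatCall:
    read_id: str
    rel_change: int
    abs_copies: int


@dataclass(frozen=True)
class RepeatComposition:
    """Ordered motif-run decomposition of one repeat tract (lossless)."""

    read_id: str
    runs: Tuple[Tuple[str, int], ...]
    total_len: int


@dataclass(frozen=True)
class AlleleSummary:
    label: str
    n_reads: int
    median: float
    sd: float
    iqr: float
    sd_defined: bool = True


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def copy_number_change(read: AlignedRead, locus: RepeatLocus) -> RepeatCall:
    """Per-read copy-number call from net indels within the margined locus.

    The read must span ``interval`` widened by ``flank_margin`` on both
    sides; soft-clipped bases never count.  ``rel_change`` is the net
    inserted-minus-deleted base count divided by the unit length, rounded
    half away from zero; ``abs_copies = rel_change + ref_copies``
    (floored at zero).
    """
    w_start = locus.interval.start - locus.flank_margin
    w_end = locus.interval.end + locus.flank_margin
    if read.chrom != locus.interval.chrom:
        raise SpanningError(f"{read.read_id}: read on {read.chrom}, locus on {locus.interval.chrom}")
    if read.ref_start > w_start or read.ref_end < w_end:
        raise SpanningError(
            f"{read.read_id}: alignment [{read.ref_start},{read.ref_end}) does not span "
            f"locus window [{w_start},{w_end})"
        )
    net = 0
    rpos = read.ref_start
    for op, n in read.cigar:
        if op == "M":
            rpos += n
        elif op == "I":
            if w_start <= rpos <= w_end:
                net += n
        elif op == "D":
            overlap = min(rpos + n, w_end) - max(rpos, w_start)
            if overlap > 0:
                net -= overlap
            rpos += n
        # soft clips excluded by design
    rel = _round_half_away(net / len(locus.unit))
    return RepeatCall(read_id=read.read_id, rel_change=rel, abs_copies=max(0, rel + locus.ref_copies))


def genotype_reads(
    reads: Iterable[AlignedRead], locus: RepeatLocus
) -> Tuple[List[RepeatCall], List[str]]:
    """Call every spanning read; non-spanning read ids are returned, not dropped silently."""
    calls: List[RepeatCall] = []
    rejected: List[str] = []
    for read in reads:
        try:
            calls.append(copy_number_change(read, locus))
        except SpanningError:
            rejected.append(read.read_id)
    return calls, rejected


def phase_by_copy_number(
    calls: Sequence[RepeatCall], threshold: int = PHASE_THRESHOLD
) -> Dict[str, List[RepeatCall]]:
    """Split calls into non-expanded (< threshold) and expanded (>= threshold) groups."""
    if not calls:
        raise ValueError("no repeat calls to phase")
    groups: Dict[str, List[RepeatCall]] = {NON_EXPANDED: [], EXPANDED: []}
    for call in calls:
        groups[EXPANDED if call.rel_change >= threshold else NON_EXPANDED].append(call)
    return groups


def allele_summary(label: str, calls: Sequence[RepeatCall]) -> AlleleSummary:
    """Median / sample SD / interpolated IQR of absolute copies in a group."""
    if not calls:
        raise ValueError(f"allele group {label!r} is empty")
    vals = np.array([c.abs_copies for c in calls], dtype=float)
    median = float(np.median(vals))
    if len(vals) >= 2:
        sd, sd_defined = float(np.std(vals, ddof=1)), True
    else:
        sd, sd_defined = 0.0, False
    q1, q3 = np.percentile(vals, [25, 75], method="linear")
    return AlleleSummary(
        label=label,
        n_reads=len(vals),
        median=median,
        sd=sd,
        iqr=float(q3 - q1),
        sd_defined=sd_defined,
    )


def disease_range_classify(
    abs_copies: int, lo: int = DISEASE_RANGE[0], hi: int = DISEASE_RANGE[1]
) -> str:
    """Classify a copy number against the disease-causing range (41-300)."""
    if abs_copies < 0:
        raise ValueError("copy number must be non-negative")
    if abs_copies < lo:
        return "normal"
    if abs_copies <= hi:
        return "disease-causing range"
    return "beyond range"


# ---------------------------------------------------------------------------
# Repeat composition (waterfall)


def decompose_repeat(
    seq: str,
    unit: str,
    interruptions: Optional[Set[str]] = None,
    insertions: Optional[Set[str]] = None,
    read_id: str = "",
) -> RepeatComposition:
    """Greedy left-to-right decomposition into motif runs.

    Match priority at each position: longest named insertion, then the
    repeat unit, then interruption motifs (longest first), else a
    single-base "other" run.  Adjacent identical motifs merge into
    (motif, count) runs.  Concatenating the runs reproduces *seq* exactly.
    """
    if not seq:
        raise ValueError("cannot decompose an empty sequence")
    interruptions = interruptions or set()
    ins_sorted = sorted(insertions or set(), key=lambda s: (-len(s), s))
    int_sorted = sorted(interruptions, key=lambda s: (-len(s), s))
    runs: List[Tuple[str, int]] = []

    def push(label: str) -> None:
        if runs and runs[-1][0] == label:
            runs[-1] = (label, runs[-1][1] + 1)
        else:
            runs.append((label, 1))

    pos = 0
    n = len(seq)
    while pos < n:
        matched = False
        for ins in ins_sorted:
            if seq.startswith(ins, pos):
                push(INSERTION_PREFIX + ins)
                pos += len(ins)
                matched = True
                break
        if matched:
            continue
        if seq.startswith(unit, pos):
            push(unit)
            pos += len(unit)
            continue
        for motif in int_sorted:
            if seq.startswith(motif, pos):
                push(motif)
                pos += len(motif)
                matched = True
                break
        if matched:
            continue
        push(seq[pos])
        pos += 1
    return RepeatComposition(read_id=read_id, runs=tuple(runs), total_len=n)


def reconstruct(comp: RepeatComposition) -> str:
    """Inverse of :func:`decompose_repeat`."""
    parts = []
    for label, count in comp.runs:
        motif = label[len(INSERTION_PREFIX):] if label.startswith(INSERTION_PREFIX) else label
        parts.append(motif * count)
    return "".join(parts)


def motif_class(label: str, unit: str, interruptions: Set[str]) -> str:
    if label.startswith(INSERTION_PREFIX):
        return "insertion"
    if label == unit:
        return "unit"
    if label in interruptions:
        return "interruption"
    return "other"


def waterfall_table(
    compositions: Sequence[RepeatComposition],
    unit: str = "GGC",
    interruptions: Optional[Set[str]] = None,
) -> pd.DataFrame:
    """Plot-ready segment table: rows sorted by tract length descending.

    Columns: read_id, total_len, row (0 = longest tract), motif, cls,
    start (base offset within the tract), length.
    """
    interruptions = interruptions or set()
    ordered = sorted(compositions, key=lambda c: (-c.total_len, c.read_id))
    records = []
    for row, comp in enumerate(ordered):
        offset = 0
        for label, count in comp.runs:
            motif = label[len(INSERTION_PREFIX):] if label.startswith(INSERTION_PREFIX) else label
            seg_len = len(motif) * count
            records.append(
                {
                    "read_id": comp.read_id,
                    "total_len": comp.total_len,
                    "row": row,
                    "motif": label,
                    "cls": motif_class(label, unit, interruptions),
                    "start": offset,
                    "length": seg_len,
                }
            )
            offset += seg_len
    return pd.DataFrame.from_records(
        records,
        columns=["read_id", "total_len", "row", "motif", "cls", "start", "length"],
    )


def extract_repeat_tract(read: AlignedRead, locus: RepeatLocus) -> str:
    """Read bases aligned within the locus interval, including insertions.

    The tract covers every read base whose alignment column falls inside
    ``locus.interval`` (matches) or attaches to it (insertions at or
    inside the interval), giving the expanded repeat sequence as carried
    by the read.
    """
    start, end = locus.interval.start, locus.interval.end
    parts: List[str] = []
    rpos = read.ref_start
    qpos = 0
    for op, n in read.cigar:
        if op == "M":
            lo = max(rpos, start)
            hi = min(rpos + n, end)
            if lo < hi:
                parts.append(read.seq[qpos + (lo - rpos): qpos + (hi - rpos)])
            rpos += n
            qpos += n
        elif op == "I":
            if start <= rpos <= end:
                parts.append(read.seq[qpos: qpos + n])
            qpos += n
        elif op == "S":
            qpos += n
        elif op == "D":
            rpos += n
    return "".join(parts)
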