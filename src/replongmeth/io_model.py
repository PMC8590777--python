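"""Core data model and I/O for long reads carrying 5-mC modification scores.

The central record is :class:`AlignedRead`: one aligned long read with its
placement on the reference, CIGAR, stored (aligned-orientation) sequence,
a sparse map of per-cytosine modification scores, and optional per-base
polymerase-kinetics arrays.

Modification scores are basecaller likelihoods scaled to the integer range
0-255 (``score/255`` is the probability the base is 5-methylcytosine).  A
score strictly greater than 128 classifies the base as modified.

Coordinate conventions
----------------------
Internally everything is 0-based half-open.  User-facing text output
(CLI, reports) is 1-based inclusive.

``mod_scores`` is keyed by offsets into the *stored* sequence (the
reference-forward orientation written in SAM).  For a forward read the
scored base is a ``C``; for a reverse read the template cytosine appears
as ``G`` in the stored sequence, so scored offsets address ``G`` bases.
This matches the coordinate convention of ``pysam``'s ``modified_bases``.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

SCORE_MAX = 255
#: scores strictly greater than this are called 5-mC
MOD_THRESHOLD = 128

CIGAR_OPS = "MIDS"
_CIGAR_RE = re.compile(r"(\d+)([MIDS=X])")

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FormatError(ValueError):
    """Malformed input record (bad tag, inconsistent field, bad TSV)."""


class AlignmentError(ValueError):
    """Read alignment is inconsistent with the reference it claims."""


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def score_to_likelihood(score: int) -> float:
    """Map an integer modification score to a likelihood fraction.

    ``score/255`` exactly: 255 -> 1.0 (100%), 192 -> 0.7529... (75% when
    rounded to integer percent), 0 -> 0.0.
    """
    _check_score(score)
    return score / SCORE_MAX


def is_modified(score: int, threshold: int = MOD_THRESHOLD) -> bool:
    """True iff *score* calls the base 5-mC (strictly ``> threshold``)."""
    _check_score(score)
    return score > threshold


def _check_score(score: int) -> None:
    if not (0 <= int(score) <= SCORE_MAX):
        raise FormatError(f"modification score {score} outside [0, {SCORE_MAX}]")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return chrom == self.chrom and start < self.end and self.start < end

    @classmethod
    def from_region_string(cls, region: str) -> "GenomicInterval":
        """Parse a 1-based inclusive ``chrom:start-end`` region string."""
        m = re.fullmatch(r"([^:]+):([\d,]+)-([\d,]+)", region)
        if m is None:
            raise ValueError(f"cannot parse region {region!r}")
        start1 = int(m.group(2).replace(",", ""))
        end1 = int(m.group(3).replace(",", ""))
        return cls(m.group(1), start1 - 1, end1)

    def to_region_string(self) -> str:
        return f"{self.chrom}:{self.start + 1}-{self.end}"


@dataclass
class Kinetics:
    """Per-base kinetics arrays in frames, one entry per stored base.

    ``ipd_fwd``/``pw_fwd`` correspond to the PacBio ``fi``/``fp`` tags
    (forward template orientation, st=0), ``ipd_rev``/``pw_rev`` to
    ``ri``/``rp`` (st=1).
    """

    ipd_fwd: Optional[np.ndarray] = None
    pw_fwd: Optional[np.ndarray] = None
    ipd_rev: Optional[np.ndarray] = None
    pw_rev: Optional[np.ndarray] = None

    def arrays(self) -> Dict[str, Optional[np.ndarray]]:
        return {
            "ipd_fwd": self.ipd_fwd,
            "pw_fwd": self.pw_fwd,
            "ipd_rev": self.ipd_rev,
            "pw_rev": self.pw_rev,
        }

    def for_strand(self, strand_tag: int) -> Tuple[Optional[np.ndarray], Optional[np.ndarray]]:
        if strand_tag == 0:
            return self.ipd_fwd, self.pw_fwd
        if strand_tag == 1:
            return self.ipd_rev, self.pw_rev
        raise ValueError(f"strand tag must be 0 or 1, got {strand_tag}")


@dataclass
class AlignedRead:
    """One aligned long read with modification scores and optional kinetics.

    ``seq`` is stored in aligned (reference-forward) orientation, as in SAM.
    ``strand`` is ``'+'`` or ``'-'``; ``strand_tag`` mirrors it as 0/1.
    """

    read_id: str
    chrom: str
    ref_start: int
    strand: str
    cigar: List[Tuple[str, int]]
    seq: str
    mod_scores: Dict[int, int] = field(default_factory=dict)
    kinetics: Optional[Kinetics] = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def strand_tag(self) -> int:
        return 0 if self.strand == "+" else 1

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.cigar if op in "MD")

    @property
    def aligned_length(self) -> int:
        """Read bases consumed by the alignment (M+I, excluding clips)."""
        return sum(n for op, n in self.cigar if op in "MI")

    def validate(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"{self.read_id}: strand must be '+' or '-'")
        for op, n in self.cigar:
            if op not in CIGAR_OPS or n <= 0:
                raise FormatError(f"{self.read_id}: bad CIGAR element ({op},{n})")
        consumed = sum(n for op, n in self.cigar if op in "MIS")
        if consumed != len(self.seq):
            raise FormatError(
                f"{self.read_id}: CIGAR consumes {consumed} read bases "
                f"but sequence has {len(self.seq)}"
            )
        scored_base = "C" if self.strand == "+" else "G"
        for off, score in self.mod_scores.items():
            _check_score(score)
            if not (0 <= off < len(self.seq)):
                raise FormatError(f"{self.read_id}: scored offset {off} out of range")
            if self.seq[off].upper() != scored_base:
                raise FormatError(
                    f"{self.read_id}: scored offset {off} is "
                    f"{self.seq[off]!r}, expected {scored_base!r} "
                    f"(read-sense cytosine on {self.strand} strand)"
                )
        if self.kinetics is not None:
            for name, arr in self.kinetics.arrays().items():
                if arr is not None and len(arr) != len(self.seq):
                    raise FormatError(
                        f"{self.read_id}: kinetics array {name} has length "
                        f"{len(arr)}, sequence has {len(self.seq)}"
                    )

    def overlaps(self, region: GenomicInterval) -> bool:
        return region.overlaps(self.chrom, self.ref_start, self.ref_end)

    def copy(self) -> "AlignedRead":
        return replace(
            self,
            cigar=list(self.cigar),
            mod_scores=dict(self.mod_scores),
            kinetics=None
            if self.kinetics is None
            else Kinetics(**{k: None if v is None else v.copy() for k, v in self.kinetics.arrays().items()}),
        )


# ---------------------------------------------------------------------------
# CIGAR helpers


def cigar_to_string(cigar: Sequence[Tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


def cigar_from_string(text: str) -> List[Tuple[str, int]]:
    pos = 0
    out: List[Tuple[str, int]] = []
    for m in _CIGAR_RE.finditer(text):
        if m.start() != pos:
            raise FormatError(f"cannot parse CIGAR {text!r}")
        op = m.group(2)
        out.append(("M" if op in "=X" else op, int(m.group(1))))
        pos = m.end()
    if pos != len(text) or not out:
        raise FormatError(f"cannot parse CIGAR {text!r}")
    return out


# ---------------------------------------------------------------------------
# MM/ML-style tag conversion (stored-offset <-> read-sense delta encoding)


def mod_scores_to_mm_ml(read: AlignedRead) -> Tuple[str, List[int]]:
    """Encode ``mod_scores`` as SAM ``MM``/``ML`` tag payloads.

    MM deltas count skipped cytosines along the read in its *original*
    orientation; for reverse reads stored offsets are mirrored first.
    """
    original = read.seq if read.strand == "+" else revcomp(read.seq)
    c_positions = [i for i, b in enumerate(original) if b.upper() == "C"]
    index_of = {p: i for i, p in enumerate(c_positions)}
    items = []
    for off, score in read.mod_scores.items():
        read_sense = off if read.strand == "+" else len(read.seq) - 1 - off
        items.append((index_of[read_sense], score))
    items.sort()
    deltas, scores = [], []
    prev = -1
    for idx, score in items:
        deltas.append(idx - prev - 1)
        scores.append(score)
        prev = idx
    mm = "C+m?," + ",".join(map(str, deltas)) + ";" if deltas else "C+m?;"
    return mm, scores


def mm_ml_to_mod_scores(
    seq: str, strand: str, mm: str, ml: Sequence[int], read_id: str = "?"
) -> Dict[int, int]:
    """Decode ``MM``/``ML`` payloads into stored-offset scores.

    Only the ``C+m`` item is interpreted; other modification items raise.
    Raises :class:`FormatError` when the score list length disagrees with
    the position list.
    """
    mm = mm.strip().rstrip(";")
    if not mm:
        return {}
    parts = mm.split(";")
    if len(parts) != 1:
        raise FormatError(f"{read_id}: multiple MM items not supported: {mm!r}")
    fields = parts[0].split(",")
    head = fields[0]
    if not re.fullmatch(r"C\+m[.?]?", head):
        raise FormatError(f"{read_id}: unsupported MM item {head!r}")
    deltas = [int(x) for x in fields[1:]]
    if len(deltas) != len(ml):
        raise FormatError(
            f"{read_id}: MM lists {len(deltas)} positions but ML carries "
            f"{len(ml)} scores"
        )
    original = seq if strand == "+" else revcomp(seq)
    c_positions = [i for i, b in enumerate(original) if b.upper() == "C"]
    out: Dict[int, int] = {}
    idx = -1
    for delta, score in zip(deltas, ml):
        idx += delta + 1
        if idx >= len(c_positions):
            raise FormatError(f"{read_id}: MM positions exceed cytosine count")
        read_sense = c_positions[idx]
        stored = read_sense if strand == "+" else len(seq) - 1 - read_sense
        _check_score(score)
        out[stored] = int(score)
    return out


# ---------------------------------------------------------------------------
# TSV dialect

TSV_COLUMNS = [
    "read_id",
    "chrom",
    "ref_start",
    "strand",
    "cigar",
    "seq",
    "mod_offsets",
    "mod_scores",
    "ipd_fwd",
    "pw_fwd",
    "ipd_rev",
    "pw_rev",
]


def _ints(cell: str) -> Optional[np.ndarray]:
    if not cell:
        return None
    return np.array([int(x) for x in cell.split(",")], dtype=np.int64)


def _cell(arr: Optional[np.ndarray]) -> str:
    if arr is None:
        return ""
    return ",".join(str(int(x)) for x in arr)


def write_alignments_tsv(reads: Iterable[AlignedRead], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for r in reads:
            offs = sorted(r.mod_scores)
            kin = r.kinetics or Kinetics()
            writer.writerow(
                [
                    r.read_id,
                    r.chrom,
                    r.ref_start,
                    r.strand,
                    cigar_to_string(r.cigar),
                    r.seq,
                    ",".join(map(str, offs)),
                    ",".join(str(r.mod_scores[o]) for o in offs),
                    _cell(kin.ipd_fwd),
                    _cell(kin.pw_fwd),
                    _cell(kin.ipd_rev),
                    _cell(kin.pw_rev),
                ]
            )


def _read_tsv(path) -> List[AlignedRead]:
    out: List[AlignedRead] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if header[: len(TSV_COLUMNS)] != TSV_COLUMNS and header[:8] != TSV_COLUMNS[:8]:
            raise FormatError(f"{path}: unexpected TSV header {header[:4]}...")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            row = row + [""] * (len(TSV_COLUMNS) - len(row))
            try:
                offs = [int(x) for x in row[6].split(",")] if row[6] else []
                scores = [int(x) for x in row[7].split(",")] if row[7] else []
                if len(offs) != len(scores):
                    raise FormatError(
                        f"{row[0]}: {len(offs)} offsets but {len(scores)} scores"
                    )
                kin_arrays = {
                    name: _ints(cell)
                    for name, cell in zip(
                        ("ipd_fwd", "pw_fwd", "ipd_rev", "pw_rev"), row[8:12]
                    )
                }
                kinetics = (
                    Kinetics(**kin_arrays)
                    if any(v is not None for v in kin_arrays.values())
                    else None
                )
                out.append(
                    AlignedRead(
                        read_id=row[0],
                        chrom=row[1],
                        ref_start=int(row[2]),
                        strand=row[3],
                        cigar=cigar_from_string(row[4]),
                        seq=row[5],
                        mod_scores=dict(zip(offs, scores)),
                        kinetics=kinetics,
                    )
                )
            except FormatError:
                raise
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# SAM dialect (via pysam)

_PYSAM_OPS = {0: "M", 1: "I", 2: "D", 4: "S", 7: "M", 8: "M"}
_OP_TO_PYSAM = {"M": 0, "I": 1, "D": 2, "S": 4}


def _read_sam(path, keep_tags: bool = False):
    import pysam

    out: List[AlignedRead] = []
    extra: List[Dict[str, object]] = []
    n_unmapped = 0
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped or rec.query_sequence is None:
                    n_unmapped += 1
                    continue
                strand = "-" if rec.is_reverse else "+"
                cigar = []
                for code, n in rec.cigartuples or []:
                    if code not in _PYSAM_OPS:
                        if code == 5:  # hard clip consumes nothing we track
                            continue
                        raise FormatError(
                            f"{rec.query_name}: unsupported CIGAR op code {code}"
                        )
                    cigar.append((_PYSAM_OPS[code], n))
                mm = None
                for tag in ("MM", "Mm"):
                    if rec.has_tag(tag):
                        mm = rec.get_tag(tag)
                        break
                ml: Sequence[int] = []
                for tag in ("ML", "Ml"):
                    if rec.has_tag(tag):
                        ml = list(rec.get_tag(tag))
                        break
                mod_scores = (
                    mm_ml_to_mod_scores(rec.query_sequence, strand, mm, ml, rec.query_name)
                    if mm is not None
                    else {}
                )
                kin_arrays = {}
                for tag, name in (("fi", "ipd_fwd"), ("fp", "pw_fwd"), ("ri", "ipd_rev"), ("rp", "pw_rev")):
                    if rec.has_tag(tag):
                        kin_arrays[name] = np.asarray(rec.get_tag(tag), dtype=np.int64)
                out.append(
                    AlignedRead(
                        read_id=rec.query_name,
                        chrom=rec.reference_name,
                        ref_start=rec.reference_start,
                        strand=strand,
                        cigar=cigar,
                        seq=rec.query_sequence,
                        mod_scores=mod_scores,
                        kinetics=Kinetics(**kin_arrays) if kin_arrays else None,
                    )
                )
                if keep_tags:
                    tags = {}
                    for tag in ("XO", "XC"):
                        if rec.has_tag(tag):
                            tags[tag] = rec.get_tag(tag)
                    extra.append(tags)
    finally:
        pysam.set_verbosity(save)
    if n_unmapped:
        logger.info("skipped %d unmapped read(s) in %s", n_unmapped, path)
    if keep_tags:
        return out, extra
    return out


def write_alignments_sam(
    reads: Sequence[AlignedRead],
    path,
    ref_lengths: Optional[Mapping[str, int]] = None,
    extra_tags: Optional[Sequence[Mapping[str, object]]] = None,
) -> None:
    """Write reads as SAM with MM/ML modification tags and fi/fp/ri/rp kinetics."""
    import array as _array

    import pysam

    if ref_lengths is None:
        ref_lengths = {}
        for r in reads:
            ref_lengths[r.chrom] = max(ref_lengths.get(r.chrom, 0), r.ref_end)
    names = list(ref_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": int(ref_lengths[n])} for n in names],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for i, r in enumerate(reads):
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = r.read_id
            rec.query_sequence = r.seq
            rec.flag = 16 if r.strand == "-" else 0
            rec.reference_id = names.index(r.chrom)
            rec.reference_start = r.ref_start
            rec.mapping_quality = 60
            rec.cigartuples = [(_OP_TO_PYSAM[op], n) for op, n in r.cigar]
            if r.mod_scores:
                mm, ml = mod_scores_to_mm_ml(r)
                rec.set_tag("MM", mm)
                rec.set_tag("ML", _array.array("B", ml))
            if r.kinetics is not None:
                for tag, arr in (
                    ("fi", r.kinetics.ipd_fwd),
                    ("fp", r.kinetics.pw_fwd),
                    ("ri", r.kinetics.ipd_rev),
                    ("rp", r.kinetics.pw_rev),
                ):
                    if arr is not None:
                        rec.set_tag(tag, _array.array("H", [int(x) for x in arr]))
            if extra_tags is not None:
                for tag, val in extra_tags[i].items():
                    rec.set_tag(tag, val)
            fh.write(rec)


# ---------------------------------------------------------------------------
# Front door


def load_alignments(path, region: Optional[GenomicInterval] = None) -> List[AlignedRead]:
    """Load aligned reads from SAM/BAM (MM/ML tags) or the package TSV dialect.

    Returns reads overlapping *region* (all mapped reads when *region* is
    None); unmapped reads are skipped with a logged count.
    """
    path = Path(path)
    if path.suffix.lower() in {".sam", ".bam", ".cram"}:
        reads = _read_sam(path)
    else:
        reads = _read_tsv(path)
    if region is not None:
        reads = [r for r in reads if r.overlaps(region)]
    return reads
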