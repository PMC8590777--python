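"""In-silico bisulfite-like conversion of reads for browser visualization.

Cytosines with modification score <= 128 are rewritten as the base a
bisulfite protocol would report for an unmethylated cytosine: T on
forward reads, A (in stored reference orientation) on reverse reads.
Scores > 128 (5-mC) leave the base untouched.  Unscored cytosines in CpG
context default to "converted" (treated as score 0), since the absence
of a modification call is evidence of canonical C; this is configurable.
Non-CpG cytosines without scores are never touched.

The emitted SAM preserves placement and CIGAR so IGV's bisulfite mode
colors methylation; the original sequence is retained losslessly in the
``XO`` tag and the substitution count in ``XC``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .io_model import (
    MOD_THRESHOLD,
    AlignedRead,
    Kinetics,
    _read_sam,
    write_alignments_sam,
)


@dataclass
class ConvertedRead:
    """An :class:`AlignedRead` with its bisulfite-converted sequence.

    Same length as the original; ``conversion_count`` is the number of
    substituted bases and ``original_seq`` restores the input exactly.
    """

    read: AlignedRead
    conversion_count: int
    original_seq: str


def convert_read(
    read: AlignedRead,
    threshold: int = MOD_THRESHOLD,
    convert_unscored_cpg: bool = True,
) -> ConvertedRead:
    """Apply the conversion rules to one read.

    Idempotent: positions already rewritten to T/A are no longer
    cytosines in read sense and are skipped on a second pass.
    """
    seq = list(read.seq)
    upper = read.seq.upper()
    n = len(seq)
    converted = 0
    # read-sense C appears as stored C (forward) or stored G (reverse);
    # read-sense CpG appears as stored "CG" either way.
    if read.strand == "+":
        target, sub = "C", "T"

        def in_cpg(i: int) -> bool:
            return i + 1 < n and upper[i + 1] == "G"

    else:
        target, sub = "G", "A"

        def in_cpg(i: int) -> bool:
            return i >= 1 and upper[i - 1] == "C"

    kept_scores: Dict[int, int] = {}
    for i, base in enumerate(upper):
        if base != target:
            continue
        score = read.mod_scores.get(i)
        if score is None:
            if not (convert_unscored_cpg and in_cpg(i)):
                continue
            score = 0
        if score <= threshold:
            seq[i] = sub
            converted += 1
        else:
            # base survives as a cytosine; keep its score so a second
            # pass sees it as methylated again (idempotence)
            kept_scores[i] = score
    new = read.copy()
    new.seq = "".join(seq)
    new.mod_scores = kept_scores
    new.validate()
    return ConvertedRead(read=new, conversion_count=converted, original_seq=read.seq)


def write_converted(
    converted: Sequence[ConvertedRead],
    path,
    ref_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Emit converted reads as SAM; XO holds the original sequence."""
    reads = [c.read for c in converted]
    tags = [{"XO": c.original_seq, "XC": c.conversion_count} for c in converted]
    write_alignments_sam(reads, path, ref_lengths=ref_lengths, extra_tags=tags)


def read_converted(path) -> List[ConvertedRead]:
    """Load a converted SAM, restoring original sequences from XO tags."""
    reads, extras = _read_sam(path, keep_tags=True)
    out = []
    for read, tags in zip(reads, extras):
        out.append(
            ConvertedRead(
                read=read,
                conversion_count=int(tags.get("XC", 0)),
                original_seq=str(tags.get("XO", read.seq)),
            )
        )
    return out
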