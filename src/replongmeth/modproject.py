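"""Project read-level modification scores onto reference CpG positions.

Walks each read's CIGAR and emits one :class:`SiteObservation` per scored
read cytosine that aligns onto a match column whose *reference* context is
CpG on the read's strand.  Insertions contribute nothing; scored cytosines
falling in deletions or soft clips are dropped.  CpG context is defined on
the reference, so a mismatched read base over a reference CpG still counts
when it carries a score.

This is the reference-based half of haplotype-resolved methylation
profiling; :func:`project_against_consensus` applies the same logic with an
expansion-allele consensus sequence as the reference (decoy contigs
excluded and counted), which is how within-repeat CpGs become addressable.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .io_model import AlignedRead, AlignmentError, GenomicInterval

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SiteObservation:
    """One read's modification score at one reference CpG cytosine.

    ``pos`` is the 0-based coordinate of the cytosine on its own strand;
    ``cpg_anchor`` is the forward-strand coordinate of the CpG's C
    (``pos`` for forward-strand observations, ``pos - 1`` for reverse).
    """

    chrom: str
    pos: int
    strand: str
    cpg_anchor: int
    score: int
    read_id: str


def _contig(ref, chrom: str) -> str:
    """Fetch a whole contig as an upper-case string from dict-like refs."""
    try:
        seq = ref[chrom]
    except KeyError as exc:
        raise AlignmentError(f"contig {chrom!r} not in reference") from exc
    if not isinstance(seq, str):
        seq = str(seq[:])  # pyfaidx.FastaRecord and friends
    return seq.upper()


def project_read(
    read: AlignedRead,
    ref,
    include_unscored: bool = False,
) -> List[SiteObservation]:
    """Project one read's scores onto reference CpG positions.

    *ref* is any mapping from contig name to sequence (plain dict of
    strings, or a ``pyfaidx.Fasta``).  With ``include_unscored`` every
    covered reference-CpG column without a score also yields a score-0
    (canonical) observation; by default only scored cytosines are emitted,
    so the observation count never exceeds ``len(read.mod_scores)``.
    """
    contig = _contig(ref, read.chrom)
    if read.ref_end > len(contig):
        raise AlignmentError(
            f"{read.read_id}: alignment ends at {read.ref_end} but contig "
            f"{read.chrom} has length {len(contig)}"
        )
    scored = sorted(read.mod_scores)
    out: List[SiteObservation] = []

    def emit(ref_pos: int, score: int) -> None:
        if read.strand == "+":
            if ref_pos + 1 < len(contig) and contig[ref_pos] == "C" and contig[ref_pos + 1] == "G":
                out.append(
                    SiteObservation(read.chrom, ref_pos, "+", ref_pos, score, read.read_id)
                )
        else:
            if ref_pos >= 1 and contig[ref_pos] == "G" and contig[ref_pos - 1] == "C":
                out.append(
                    SiteObservation(read.chrom, ref_pos, "-", ref_pos - 1, score, read.read_id)
                )

    rpos = read.ref_start
    qpos = 0
    for op, n in read.cigar:
        if op == "M":
            if include_unscored:
                for q in range(qpos, qpos + n):
                    emit(rpos + (q - qpos), read.mod_scores.get(q, 0))
            else:
                lo = bisect_left(scored, qpos)
                hi = bisect_right(scored, qpos + n - 1)
                for q in scored[lo:hi]:
                    emit(rpos + (q - qpos), read.mod_scores[q])
            rpos += n
            qpos += n
        elif op == "I" or op == "S":
            qpos += n
        elif op == "D":
            rpos += n
    out.sort(key=lambda o: o.pos)
    return out


def project_sample(
    reads: Iterable[AlignedRead],
    ref,
    region: Optional[GenomicInterval] = None,
    include_unscored: bool = False,
) -> List[SiteObservation]:
    """Concatenate :func:`project_read` over reads, clipped to *region*.

    Per-read alignment errors become warnings; a final count is logged.
    Output order is deterministic: read order, then position.
    """
    out: List[SiteObservation] = []
    n_failed = 0
    for read in reads:
        try:
            obs = project_read(read, ref, include_unscored=include_unscored)
        except AlignmentError as exc:
            logger.warning("%s", exc)
            n_failed += 1
            continue
        if region is not None:
            obs = [o for o in obs if region.start <= o.pos < region.end and o.chrom == region.chrom]
        out.extend(obs)
    if n_failed:
        logger.warning("projection failed for %d read(s)", n_failed)
    return out


def project_against_consensus(
    reads: Iterable[AlignedRead],
    consensus: Dict[str, str],
    decoys: Optional[Dict[str, str]] = None,
    include_unscored: bool = False,
) -> Tuple[List[SiteObservation], int]:
    """Project reads aligned to an expansion-allele consensus.

    *consensus* maps allele name(s) to sequence; *decoys* holds homologous
    decoy contigs.  Reads placed on decoy contigs contribute nothing and
    are counted in the returned tally.  Consensus coordinates are allele
    positions.  A consensus without any CpG yields a warning and empty
    output.
    """
    decoys = decoys or {}
    ref = {**consensus, **decoys}
    reads = list(reads)
    if not any("CG" in seq.upper() for seq in consensus.values()):
        logger.warning("consensus contains no CpG dinucleotide")
        return [], sum(1 for r in reads if r.chrom in decoys)
    n_decoy = 0
    kept: List[AlignedRead] = []
    for r in reads:
        if r.chrom in decoys:
            n_decoy += 1
        else:
            kept.append(r)
    obs = project_sample(kept, ref, include_unscored=include_unscored)
    return obs, n_decoy
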