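"""Polymerase-kinetics aggregation over allele-aligned reads.

Average replication cycle time per base is the mean over reads of
(inter-pulse duration + pulse width), in frames, by strand (fi/fp for
the forward template, st=0; ri/rp for the reverse, st=1).  The
cumulative curve along the allele is the running sum of per-base means;
a methylation-driven slowdown shows up as a steeper segment over the
repeat.  Rates in bases/second require the sequencer frame rate, which
must be supplied explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .io_model import AlignedRead

logger = logging.getLogger(__name__)


class KineticsShapeError(ValueError):
    """A read's kinetics array length disagrees with the allele length."""


@dataclass
class KineticsTrack:
    """Per-position mean replication cycle time for one allele and strand.

    ``cycle_time`` is NaN at positions with zero coverage; ``cumulative``
    (filled by :func:`cumulative_cycle_time`) imputes those as 0.
    """

    allele: str
    strand: int
    cycle_time: np.ndarray
    n_reads: np.ndarray
    cumulative: Optional[np.ndarray] = None

    @property
    def length(self) -> int:
        return len(self.cycle_time)


def per_position_cycle_time(
    reads: Iterable[AlignedRead],
    allele_len: int,
    strand: int,
    allele: str = "",
) -> KineticsTrack:
    """Mean per-position (IPD + PW) over reads carrying kinetics for *strand*.

    Every contributing read must provide IPD and PW arrays of exactly
    *allele_len* entries (reads are assumed pre-assigned and aligned to
    the allele); a mismatched length raises :class:`KineticsShapeError`
    naming the read.
    """
    total = np.zeros(allele_len, dtype=float)
    n = np.zeros(allele_len, dtype=np.int64)
    for read in reads:
        if read.kinetics is None:
            continue
        ipd, pw = read.kinetics.for_strand(strand)
        if ipd is None or pw is None:
            continue
        if len(ipd) != allele_len or len(pw) != allele_len:
            raise KineticsShapeError(
                f"{read.read_id}: kinetics arrays of length {len(ipd)}/{len(pw)} "
                f"for allele of length {allele_len}"
            )
        total += np.asarray(ipd, dtype=float) + np.asarray(pw, dtype=float)
        n += 1
    cycle = np.full(allele_len, np.nan)
    covered = n > 0
    cycle[covered] = total[covered] / n[covered]
    return KineticsTrack(allele=allele, strand=strand, cycle_time=cycle, n_reads=n)


def cumulative_cycle_time(track: KineticsTrack) -> KineticsTrack:
    """Fill the running sum of per-base means; missing positions count as 0."""
    missing = int(np.isnan(track.cycle_time).sum())
    if missing:
        logger.info(
            "allele %s strand %d: imputing %d uncovered position(s) as 0",
            track.allele, track.strand, missing,
        )
    filled = np.nan_to_num(track.cycle_time, nan=0.0)
    return KineticsTrack(
        allele=track.allele,
        strand=track.strand,
        cycle_time=track.cycle_time,
        n_reads=track.n_reads,
        cumulative=np.cumsum(filled),
    )


def replication_rate(
    track: KineticsTrack,
    frame_rate: float,
    window: Tuple[int, int],
) -> float:
    """Bases/second over *window* (0-based half-open allele coordinates).

    ``rate = window_length / (total_cycle_time / frame_rate)``; uncovered
    positions contribute 0 frames.  Raises on an empty window, a
    non-positive frame rate, or zero total cycle time.
    """
    start, end = window
    if not (0 <= start < end <= track.length):
        raise ValueError(f"window [{start},{end}) outside allele of length {track.length}")
    if frame_rate <= 0:
        raise ValueError("frame rate must be positive")
    total = float(np.nan_to_num(track.cycle_time[start:end], nan=0.0).sum())
    if total <= 0:
        raise ValueError("total cycle time over window is zero; rate undefined")
    return (end - start) / (total / frame_rate)
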