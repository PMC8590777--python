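"""Per-site methylation calling from projected CpG observations.

Observations are piled into per-site modified/canonical counts (a score
strictly above 128 counts as 5-mC), then called either by a percent
cutoff (rate mode, default 20%, inclusive) or by a one-sided Fisher's
exact test against a small pseudo-count null population that encodes the
basecaller's false-positive floor.  Calls can be exported in the
methylKit per-base dialect for downstream differential analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from scipy.stats import fisher_exact

from .io_model import MOD_THRESHOLD, is_modified
from .modproject import SiteObservation

logger = logging.getLogger(__name__)

#: per-site reporting default, aligned with common methylKit practice
DEFAULT_MIN_COVERAGE = 10
DEFAULT_RATE_CUTOFF = 0.20
DEFAULT_NULL_ERROR = 0.05
DEFAULT_NULL_N = 1000
DEFAULT_ALPHA = 0.01

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"


@dataclass(frozen=True)
class SiteCounts:
    """Counts of modified vs canonical cytosine observations at one site.

    ``strand`` is None when the two strands of a CpG are combined onto the
    forward-strand anchor.
    """

    chrom: str
    cpg_anchor: int
    n_mod: int
    n_canon: int
    strand: Optional[str] = None

    @property
    def coverage(self) -> int:
        return self.n_mod + self.n_canon

    @property
    def percent(self) -> float:
        return self.n_mod / self.coverage


@dataclass(frozen=True)
class MethylCall:
    site: SiteCounts
    percent: float
    status: str
    p_value: Optional[float] = None


def pileup(
    observations: Iterable[SiteObservation],
    min_coverage: int = 1,
    combine_strands: bool = False,
    threshold: int = MOD_THRESHOLD,
) -> List[SiteCounts]:
    """Summarize one sample's observations into per-site counts.

    One :class:`SiteCounts` per (chrom, anchor, strand), or per
    (chrom, anchor) with ``combine_strands``; sites below *min_coverage*
    are dropped.  Output sorted by chrom, anchor, strand.
    """
    counts: Dict[Tuple, List[int]] = {}
    for obs in observations:
        key = (obs.chrom, obs.cpg_anchor, None if combine_strands else obs.strand)
        cell = counts.setdefault(key, [0, 0])
        if is_modified(obs.score, threshold):
            cell[0] += 1
        else:
            cell[1] += 1
    out = [
        SiteCounts(chrom=k[0], cpg_anchor=k[1], strand=k[2], n_mod=v[0], n_canon=v[1])
        for k, v in counts.items()
        if v[0] + v[1] >= min_coverage
    ]
    out.sort(key=lambda s: (s.chrom, s.cpg_anchor, s.strand or ""))
    return out


def call_rate(site: SiteCounts, cutoff: float = DEFAULT_RATE_CUTOFF) -> MethylCall:
    """Percent-methylation call: methylated iff percent >= cutoff (inclusive).

    The reported percent is rounded to 4 decimals; the comparison uses the
    exact ratio so the 20% boundary is deterministic.
    """
    if site.coverage < 1:
        raise ValueError(f"site {site.chrom}:{site.cpg_anchor} has zero coverage")
    percent = site.percent
    status = METHYLATED if percent >= cutoff else UNMETHYLATED
    return MethylCall(site=site, percent=round(percent, 4), status=status)


def call_fisher(
    site: SiteCounts,
    null_error: float = DEFAULT_NULL_ERROR,
    null_n: int = DEFAULT_NULL_N,
    alpha: float = DEFAULT_ALPHA,
) -> MethylCall:
    """One-sided Fisher's exact test against a pseudo-count null population.

    Tests ``[[n_mod, n_canon], [round(null_error*null_n), rest]]`` against
    the alternative that the site's modified fraction exceeds the null
    error rate; methylated iff ``p < alpha``.
    """
    if not (0 <= null_error < 1):
        raise ValueError(f"null_error {null_error} outside [0, 1)")
    if site.coverage < 1:
        raise ValueError(f"site {site.chrom}:{site.cpg_anchor} has zero coverage")
    null_mod = round(null_error * null_n)
    _, p = fisher_exact(
        [[site.n_mod, site.n_canon], [null_mod, null_n - null_mod]],
        alternative="greater",
    )
    status = METHYLATED if p < alpha else UNMETHYLATED
    return MethylCall(site=site, percent=round(site.percent, 4), status=status, p_value=float(p))


def call_sample(
    observations: Iterable[SiteObservation],
    mode: str = "rate",
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    combine_strands: bool = False,
    cutoff: float = DEFAULT_RATE_CUTOFF,
    null_error: float = DEFAULT_NULL_ERROR,
    null_n: int = DEFAULT_NULL_N,
    alpha: float = DEFAULT_ALPHA,
) -> List[MethylCall]:
    """Pile up one sample and call every site in the chosen mode."""
    sites = pileup(observations, min_coverage=min_coverage, combine_strands=combine_strands)
    if mode == "rate":
        return [call_rate(s, cutoff=cutoff) for s in sites]
    if mode == "fisher":
        return [call_fisher(s, null_error=null_error, null_n=null_n, alpha=alpha) for s in sites]
    raise ValueError(f"unknown calling mode {mode!r}")


def export_methylkit(calls: Sequence[MethylCall], sample_id: str, path) -> None:
    """Write calls in the methylKit per-base dialect.

    Tab-separated columns chrBase, chr, base (1-based), strand (F/R),
    coverage, freqC, freqT; freqC is the percent methylated (the
    bisulfite-protected-C analogue), fixed 2-decimal format.
    """
    with open(path, "w") as fh:
        fh.write("chrBase\tchr\tbase\tstrand\tcoverage\tfreqC\tfreqT\n")
        for call in calls:
            s = call.site
            base1 = s.cpg_anchor + 1
            strand = "R" if s.strand == "-" else "F"
            freq_c = 100.0 * s.n_mod / s.coverage
            fh.write(
                f"{s.chrom}.{base1}\t{s.chrom}\t{base1}\t{strand}\t"
                f"{s.coverage}\t{freq_c:.2f}\t{100.0 - freq_c:.2f}\n"
            )
    logger.info("wrote %d methylKit rows for %s", len(calls), sample_id)


# ---------------------------------------------------------------------------
# Block-structure helpers used for boundary and transitional-zone analysis


def unmethylated_block(calls: Sequence[MethylCall]) -> Optional[Tuple[int, int]]:
    """Longest contiguous run of unmethylated calls along anchor order.

    Returns (first_anchor, last_anchor) of the run, or None when no site
    is unmethylated.  This recovers the unmethylated core of a normal
    allele whose flanks are hypermethylated.
    """
    ordered = sorted(calls, key=lambda c: (c.site.chrom, c.site.cpg_anchor))
    best: Optional[Tuple[int, int]] = None
    best_len = 0
    run_start: Optional[int] = None
    run_len = 0
    prev_anchor = None
    for c in ordered:
        if c.status == UNMETHYLATED:
            if run_start is None:
                run_start, run_len = c.site.cpg_anchor, 1
            else:
                run_len += 1
            prev_anchor = c.site.cpg_anchor
            if run_len > best_len:
                best, best_len = (run_start, prev_anchor), run_len
        else:
            run_start, run_len = None, 0
    return best


def mosaic_sites(
    calls: Sequence[MethylCall], lo: float = 0.25, hi: float = 0.75
) -> List[MethylCall]:
    """Sites whose percent methylation lies in [lo, hi] (mixed states).

    Transitional-zone CpGs between fully methylated and unmethylated
    blocks show this mosaic pattern.
    """
    return [c for c in calls if lo <= c.percent <= hi]
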