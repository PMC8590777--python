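"""End-to-end trio analysis: simulate -> genotype -> phase -> call -> compare.

Convenience layer used by the CLI and the reproduction script; each step
is a thin composition of the stage modules, with the per-step results
kept so callers can drill in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import diffmeth, kinetics, methylcall, modproject, repeatgt
from .io_model import AlignedRead
from .synthfix import CHROM, TrioConfig, TrioResult, default_trio_config, simulate_trio


@dataclass
class TrioAnalysis:
    trio: TrioResult
    calls: Dict[str, List[repeatgt.RepeatCall]] = field(default_factory=dict)
    groups: Dict[str, Dict[str, List[repeatgt.RepeatCall]]] = field(default_factory=dict)
    summaries: Dict[Tuple[str, str], repeatgt.AlleleSummary] = field(default_factory=dict)
    methyl_calls: Dict[str, List[methylcall.MethylCall]] = field(default_factory=dict)
    site_counts: Dict[str, List[methylcall.SiteCounts]] = field(default_factory=dict)
    phasing_accuracy: float = float("nan")


def genotype_and_phase(analysis: TrioAnalysis) -> None:
    """Per-read copy-number calls and <50 / >=50 phasing for every person."""
    trio = analysis.trio
    for person, reads in trio.nanopore.items():
        calls, rejected = repeatgt.genotype_reads(reads, trio.locus)
        analysis.calls[person] = calls
        groups = repeatgt.phase_by_copy_number(calls)
        analysis.groups[person] = groups
        for label, group in groups.items():
            if group:
                analysis.summaries[(person, label)] = repeatgt.allele_summary(label, group)
    truth = trio.read_truth.set_index("read_id")
    correct = total = 0
    for person, groups in analysis.groups.items():
        for label, group in groups.items():
            for call in group:
                hap = truth.loc[call.read_id, "hap"]
                spec = next(h.spec for h in trio.hap_truth if h.hap == hap)
                true_label = (
                    repeatgt.EXPANDED
                    if spec.copies.median - trio.locus.ref_copies >= repeatgt.PHASE_THRESHOLD
                    else repeatgt.NON_EXPANDED
                )
                correct += int(label == true_label)
                total += 1
    analysis.phasing_accuracy = correct / total if total else float("nan")


def call_methylation(
    analysis: TrioAnalysis,
    min_coverage: int = 20,
    mode: str = "rate",
) -> None:
    """Project every person's reads and call CpG methylation (strand-combined)."""
    trio = analysis.trio
    ref = {CHROM: trio.reference}
    for person, reads in trio.nanopore.items():
        obs = modproject.project_sample(reads, ref)
        analysis.site_counts[person] = methylcall.pileup(
            obs, min_coverage=min_coverage, combine_strands=True
        )
        analysis.methyl_calls[person] = [
            methylcall.call_rate(s) if mode == "rate" else methylcall.call_fisher(s)
            for s in analysis.site_counts[person]
        ]


def haplotype_methylation(
    trio: TrioResult,
    person: str,
    calls: List[repeatgt.RepeatCall],
    min_coverage: int = 10,
) -> Dict[str, List[methylcall.MethylCall]]:
    """Rate-mode calls per phased allele group of one person."""
    groups = repeatgt.phase_by_copy_number(calls)
    by_id = {r.read_id: r for r in trio.nanopore[person]}
    ref = {CHROM: trio.reference}
    out = {}
    for label, group in groups.items():
        reads = [by_id[c.read_id] for c in group]
        obs = modproject.project_sample(reads, ref)
        sites = methylcall.pileup(obs, min_coverage=min_coverage, combine_strands=True)
        out[label] = [methylcall.call_rate(s) for s in sites]
    return out


def boundary_recovery(analysis: TrioAnalysis, person: str = "mother") -> Dict[str, float]:
    """Recover the unmethylated-core boundaries from one sample's calls.

    Returns recovered and true first/last core CpG anchors and their
    offsets measured in CpG steps (0 = exact).
    """
    trio = analysis.trio
    calls = analysis.methyl_calls[person]
    block = methylcall.unmethylated_block(calls)
    if block is None:
        raise ValueError(f"no unmethylated block recovered in {person}")
    anchors = sorted(c.site.cpg_anchor for c in calls)
    core = trio.core_interval
    true_in_core = [a for a in anchors if core.start <= a < core.end]
    true_start, true_end = true_in_core[0], true_in_core[-1]
    idx = {a: i for i, a in enumerate(anchors)}
    return {
        "recovered_start": block[0],
        "recovered_end": block[1],
        "true_start": true_start,
        "true_end": true_end,
        "start_offset_cpgs": abs(idx[block[0]] - idx[true_start]),
        "end_offset_cpgs": abs(idx[block[1]] - idx[true_end]),
    }


def transitional_zone_counts(analysis: TrioAnalysis, person: str = "mother") -> Tuple[int, int]:
    """Count mosaic-methylation CpGs upstream/downstream of the core."""
    trio = analysis.trio
    mosaic = methylcall.mosaic_sites(analysis.methyl_calls[person])
    core = trio.core_interval
    up = sum(1 for c in mosaic if c.site.cpg_anchor < core.start)
    down = sum(1 for c in mosaic if c.site.cpg_anchor >= core.end)
    return up, down


def kinetics_rates(trio: TrioResult, person: str = "father") -> Dict[str, float]:
    """Replication rate (bases/s) over the repeat tract per allele group."""
    reads = trio.kinetics_reads[person]
    truth = trio.read_truth.set_index("read_id")
    spec_of = {h.hap: h.spec for h in trio.hap_truth}
    by_group: Dict[str, List[AlignedRead]] = {}
    for read in reads:
        hap = truth.loc[read.read_id, "hap"]
        spec = spec_of[hap]
        label = (
            repeatgt.EXPANDED
            if spec.copies.median - trio.locus.ref_copies >= repeatgt.PHASE_THRESHOLD
            else repeatgt.NON_EXPANDED
        )
        by_group.setdefault(label, []).append(read)
    out = {}
    fl = trio.config.flank_len
    for label, group in by_group.items():
        L = len(group[0].seq)
        track = kinetics.per_position_cycle_time(group, L, strand=0, allele=label)
        window = (fl, L - fl)
        out[label] = kinetics.replication_rate(track, trio.config.kinetics.frame_rate, window)
    return out


def sample_comparison(analysis: TrioAnalysis, min_coverage: int = 10):
    """Percent matrix, pairwise Pearson, PCA and Ward clustering for the trio."""
    matrix = diffmeth.build_percent_matrix(analysis.site_counts, min_coverage=min_coverage)
    people = matrix.samples
    pearson = {
        (a, b): diffmeth.pairwise_pearson(matrix, a, b)
        for i, a in enumerate(people)
        for b in people[i + 1:]
    }
    coords, evr = diffmeth.pca_samples(matrix)
    Z, ids = diffmeth.ward_clustering(matrix)
    return matrix, pearson, coords, evr, (Z, ids)


def run_default_trio(seed: int = 1, config: Optional[TrioConfig] = None) -> TrioAnalysis:
    """Simulate the default trio and run genotyping, phasing and calling."""
    trio = simulate_trio(config or default_trio_config(seed))
    analysis = TrioAnalysis(trio=trio)
    genotype_and_phase(analysis)
    call_methylation(analysis)
    return analysis
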