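"""Synthetic trio generator for a GGC repeat-expansion methylation locus.

Emulates the study design the toolkit targets: a ~4 kb Cas9-excised
locus containing a GGC tandem repeat (13 copies in the reference), read
by two long-read cohorts per family member:

* a "nanopore" cohort carrying per-cytosine 5-mC scores (0-255) with
  substitution/indel noise, used for genotyping, phasing and methylation
  calling; and
* a "kinetics" cohort of error-free allele-length reads carrying
  per-base IPD and pulse-width arrays (fi/fp/ri/rp), emulating HiFi
  consensus kinetics, plus a small error-free "hifi" cohort with
  per-read repeat tracts for composition/waterfall analysis.

The default trio encodes the headline biology: the mother carries two
non-expanded (~13 copy) unmethylated-core alleles; the father carries an
extremely long, highly variable expansion (median 520 copies, SD 170)
hypermethylated en bloc over the 2.2 kb region spanning 700 bp upstream
of the repeat through 1,000 bp downstream (with ~10% of expanded reads
escaping methylation — epigenetic mosaicism); the patient inherits a
contracted disease-range expansion (median 140, SD 15) that keeps the
unmethylated core.  Four upstream and eight downstream transitional-zone
CpGs flank the core with mosaic (p = 0.5) methylation.  Methylated CpGs
emit scores > 128 with probability 0.95; unmethylated CpGs emit <= 128
with probability 0.95.  All randomness flows from a single seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_model import AlignedRead, GenomicInterval, Kinetics, write_alignments_sam, write_alignments_tsv
from .repeatgt import RepeatLocus

CHROM = "chrS"
BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CopySpec:
    """Per-read repeat copy-number distribution: normal (median, sd),
    truncated at zero, with an optional second mode for bimodal somatic
    mosaicism."""

    median: float
    sd: float
    second_median: Optional[float] = None
    second_weight: float = 0.0


@dataclass(frozen=True)
class HaplotypeSpec:
    name: str
    copies: CopySpec
    profile: str = "normal"  # "normal" | "hypermethylated"
    gga_units: int = 0
    insertion: Optional[str] = None
    mosaic_fraction: float = 0.0  # expanded reads escaping hypermethylation
    n_reads: int = 100
    n_hifi: int = 15
    n_kinetics: int = 20

    def __post_init__(self) -> None:
        if self.profile not in ("normal", "hypermethylated"):
            raise ValueError(f"haplotype {self.name}: unknown profile {self.profile!r}")
        if not (0.0 <= self.mosaic_fraction <= 1.0):
            raise ValueError(f"haplotype {self.name}: mosaic_fraction outside [0,1]")
        if self.copies.sd < 0:
            raise ValueError(f"haplotype {self.name}: negative copy-number SD")


@dataclass(frozen=True)
class ScoreEmission:
    p_hi: float = 0.95  # methylated CpG emits score > 128
    p_lo: float = 0.95  # unmethylated CpG emits score <= 128

    def __post_init__(self) -> None:
        for name, v in (("p_hi", self.p_hi), ("p_lo", self.p_lo)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"emission {name} outside [0,1]")


@dataclass(frozen=True)
class KineticsSpec:
    """Frames/base baselines and the methylation slowdown multiplier.

    With frame_rate 100 frames/s the defaults give ~2.0 bases/s outside
    and ~0.9 bases/s inside a methylated repeat."""

    base_ipd: float = 35.0
    base_pw: float = 15.0
    slowdown: float = 2.2
    frame_rate: float = 100.0


@dataclass(frozen=True)
class ReadNoise:
    sub_rate: float = 0.01
    indel_rate: float = 0.002

    def __post_init__(self) -> None:
        for name, v in (("sub_rate", self.sub_rate), ("indel_rate", self.indel_rate)):
            if not (0.0 <= v < 1.0):
                raise ValueError(f"noise {name} outside [0,1)")


@dataclass(frozen=True)
class TrioConfig:
    seed: int
    unit: str = "GGC"
    ref_copies: int = 13
    flank_len: int = 2000
    core_upstream: int = 700
    core_downstream: int = 1000
    n_transitional_up: int = 4
    n_transitional_down: int = 8
    transitional_p: float = 0.5
    emission: ScoreEmission = field(default_factory=ScoreEmission)
    kinetics: KineticsSpec = field(default_factory=KineticsSpec)
    noise: ReadNoise = field(default_factory=ReadNoise)
    persons: Tuple[Tuple[str, Tuple[HaplotypeSpec, HaplotypeSpec]], ...] = ()

    @property
    def locus(self) -> RepeatLocus:
        start = self.flank_len
        end = start + self.ref_copies * len(self.unit)
        return RepeatLocus(
            interval=GenomicInterval(CHROM, start, end, name="repeat"),
            unit=self.unit,
            ref_copies=self.ref_copies,
        )


def default_trio_config(seed: int = 1) -> TrioConfig:
    """The default study conditions: mother, father, patient (see module docs)."""
    non_expanded = CopySpec(median=13, sd=1)
    return TrioConfig(
        seed=seed,
        persons=(
            (
                "mother",
                (
                    HaplotypeSpec("mother_hap1", non_expanded),
                    HaplotypeSpec("mother_hap2", non_expanded),
                ),
            ),
            (
                "father",
                (
                    HaplotypeSpec("father_hap1", non_expanded),
                    HaplotypeSpec(
                        "father_hap2",
                        CopySpec(median=520, sd=170),
                        profile="hypermethylated",
                        gga_units=2,
                        mosaic_fraction=0.10,
                    ),
                ),
            ),
            (
                "patient",
                (
                    HaplotypeSpec("patient_hap1", non_expanded),
                    HaplotypeSpec(
                        "patient_hap2",
                        CopySpec(median=140, sd=15),
                        gga_units=2,
                    ),
                ),
            ),
        ),
    )


@dataclass
class HaplotypeTruth:
    person: str
    hap: str
    spec: HaplotypeSpec
    true_median_copies: float  # median of the per-read draws actually emitted


@dataclass
class TrioResult:
    config: TrioConfig
    reference: str
    locus: RepeatLocus
    core_interval: GenomicInterval
    transitional_up: List[int]
    transitional_down: List[int]
    nanopore: Dict[str, List[AlignedRead]]
    hifi: Dict[str, List[AlignedRead]]
    kinetics_reads: Dict[str, List[AlignedRead]]
    read_truth: pd.DataFrame
    hap_truth: List[HaplotypeTruth]

    def save(self, out_dir) -> None:
        """Write reference FASTA, per-person TSV+SAM alignments, BED
        annotations and truth tables."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "reference.fa", "w") as fh:
            fh.write(f">{CHROM}\n")
            for i in range(0, len(self.reference), 80):
                fh.write(self.reference[i: i + 80] + "\n")
        ref_lengths = {CHROM: len(self.reference)}
        for person, reads in self.nanopore.items():
            write_alignments_tsv(reads, out / f"{person}.nanopore.tsv")
            write_alignments_sam(reads, out / f"{person}.nanopore.sam", ref_lengths)
        for person, reads in self.kinetics_reads.items():
            write_alignments_tsv(reads, out / f"{person}.kinetics.tsv")
        with open(out / "annotations.bed", "w") as fh:
            iv = self.locus.interval
            fh.write(f"{CHROM}\t{iv.start}\t{iv.end}\trepeat\n")
            fh.write(f"{CHROM}\t{self.core_interval.start}\t{self.core_interval.end}\tunmethylated_core\n")
            for a in self.transitional_up:
                fh.write(f"{CHROM}\t{a}\t{a + 2}\ttransitional_up\n")
            for a in self.transitional_down:
                fh.write(f"{CHROM}\t{a}\t{a + 2}\ttransitional_down\n")
        self.read_truth.to_csv(out / "truth_reads.tsv", sep="\t", index=False)
        hap_rows = [
            {
                "person": h.person,
                "hap": h.hap,
                "profile": h.spec.profile,
                "config_median": h.spec.copies.median,
                "true_median_copies": h.true_median_copies,
                "gga_units": h.spec.gga_units,
            }
            for h in self.hap_truth
        ]
        pd.DataFrame(hap_rows).to_csv(out / "truth_haplotypes.tsv", sep="\t", index=False)
        with open(out / "truth_locus.json", "w") as fh:
            json.dump(
                {
                    "chrom": CHROM,
                    "repeat_start": self.locus.interval.start,
                    "repeat_end": self.locus.interval.end,
                    "core_start": self.core_interval.start,
                    "core_end": self.core_interval.end,
                    "transitional_up": self.transitional_up,
                    "transitional_down": self.transitional_down,
                },
                fh,
                indent=1,
            )


# ---------------------------------------------------------------------------
# Emission primitives


def emit_score(methylated: bool, emission: ScoreEmission, rng: np.random.Generator) -> int:
    """Draw one modification score for a CpG of known state."""
    if methylated:
        high = rng.random() < emission.p_hi
    else:
        high = rng.random() >= emission.p_lo
    if high:
        return int(rng.integers(129, 256))
    return int(rng.integers(0, 129))


def draw_copies(spec: CopySpec, rng: np.random.Generator) -> int:
    if spec.second_median is not None and rng.random() < spec.second_weight:
        center = spec.second_median
    else:
        center = spec.median
    return max(0, int(round(rng.normal(center, spec.sd))))


def _random_flank(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def build_tract(copies: int, spec: HaplotypeSpec, unit: str) -> str:
    """Repeat tract: pure units, optional named insertion, then GGA
    interruption units alternating with the unit at the 3' end.

    GGA interruptions are stable in count and position across reads of a
    haplotype; each interruption unit is followed by one plain unit."""
    gga = min(spec.gga_units, copies // 2)
    pure = copies - 2 * gga
    tract = unit * pure
    if spec.insertion:
        tract += spec.insertion
    tract += ("GGA" + unit) * gga
    return tract


def _cpg_anchors(seq: str) -> List[int]:
    return [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]


# ---------------------------------------------------------------------------
# The generator


def simulate_trio(config: TrioConfig, out_dir=None) -> TrioResult:
    """Generate the full synthetic trio; identical seeds give identical output."""
    if not config.persons:
        raise ValueError("config.persons is empty")
    rng = np.random.default_rng(config.seed)
    unit = config.unit.upper()

    flank_left = _random_flank(config.flank_len, rng)
    flank_right = _random_flank(config.flank_len, rng)
    ref_tract = unit * config.ref_copies
    reference = flank_left + ref_tract + flank_right
    locus = config.locus
    core = GenomicInterval(
        CHROM,
        locus.interval.start - config.core_upstream,
        locus.interval.end + config.core_downstream,
        name="unmethylated_core",
    )
    ref_anchors = _cpg_anchors(reference)
    upstream = [a for a in ref_anchors if a < core.start]
    downstream = [a for a in ref_anchors if a >= core.end]
    trans_up = sorted(upstream[-config.n_transitional_up:]) if config.n_transitional_up else []
    trans_down = sorted(downstream[: config.n_transitional_down]) if config.n_transitional_down else []
    trans_set = set(trans_up) | set(trans_down)

    def meth_probability(ref_anchor: Optional[int], profile: str) -> float:
        """Methylation probability for a CpG; None anchor = inside the
        repeat tract (part of the core block)."""
        if profile == "hypermethylated":
            return 1.0
        if ref_anchor is None:
            return 0.0
        if ref_anchor in trans_set:
            return config.transitional_p
        if core.start <= ref_anchor < core.end:
            return 0.0
        return 1.0

    nanopore: Dict[str, List[AlignedRead]] = {}
    hifi: Dict[str, List[AlignedRead]] = {}
    kin_reads: Dict[str, List[AlignedRead]] = {}
    truth_rows: List[dict] = []
    hap_truth: List[HaplotypeTruth] = []

    for person, haps in config.persons:
        nanopore[person] = []
        hifi[person] = []
        kin_reads[person] = []
        for hap_idx, spec in enumerate(haps):
            emitted_copies: List[int] = []
            for i in range(spec.n_reads):
                copies = draw_copies(spec.copies, rng)
                emitted_copies.append(copies)
                profile = spec.profile
                if profile == "hypermethylated" and rng.random() < spec.mosaic_fraction:
                    profile = "normal"
                strand = "+" if rng.random() < 0.5 else "-"
                read = _make_nanopore_read(
                    read_id=f"{spec.name}_np{i:04d}",
                    copies=copies,
                    spec=spec,
                    profile=profile,
                    strand=strand,
                    config=config,
                    unit=unit,
                    flank_left=flank_left,
                    flank_right=flank_right,
                    meth_probability=meth_probability,
                    rng=rng,
                )
                nanopore[person].append(read)
                truth_rows.append(
                    {
                        "read_id": read.read_id,
                        "person": person,
                        "hap": spec.name,
                        "cohort": "nanopore",
                        "true_copies": copies,
                        "profile": profile,
                        "strand": strand,
                    }
                )
            for i in range(spec.n_hifi):
                copies = draw_copies(spec.copies, rng)
                read = _make_clean_read(
                    read_id=f"{spec.name}_ccs{i:04d}",
                    copies=copies,
                    spec=spec,
                    config=config,
                    unit=unit,
                    flank_left=flank_left,
                    flank_right=flank_right,
                )
                hifi[person].append(read)
                truth_rows.append(
                    {
                        "read_id": read.read_id,
                        "person": person,
                        "hap": spec.name,
                        "cohort": "hifi",
                        "true_copies": copies,
                        "profile": spec.profile,
                        "strand": "+",
                    }
                )
            # kinetics cohort: every read at the consensus (median) copy
            # number, emulating reads aligned to the per-allele consensus
            consensus_copies = max(0, int(round(spec.copies.median)))
            for i in range(spec.n_kinetics):
                read = _make_kinetics_read(
                    read_id=f"{spec.name}_kin{i:04d}",
                    copies=consensus_copies,
                    spec=spec,
                    config=config,
                    unit=unit,
                    flank_left=flank_left,
                    flank_right=flank_right,
                    rng=rng,
                )
                kin_reads[person].append(read)
                truth_rows.append(
                    {
                        "read_id": read.read_id,
                        "person": person,
                        "hap": spec.name,
                        "cohort": "kinetics",
                        "true_copies": consensus_copies,
                        "profile": spec.profile,
                        "strand": "+",
                    }
                )
            hap_truth.append(
                HaplotypeTruth(
                    person=person,
                    hap=spec.name,
                    spec=spec,
                    true_median_copies=float(np.median(emitted_copies)) if emitted_copies else float("nan"),
                )
            )

    result = TrioResult(
        config=config,
        reference=reference,
        locus=locus,
        core_interval=core,
        transitional_up=trans_up,
        transitional_down=trans_down,
        nanopore=nanopore,
        hifi=hifi,
        kinetics_reads=kin_reads,
        read_truth=pd.DataFrame(truth_rows),
        hap_truth=hap_truth,
    )
    if out_dir is not None:
        result.save(out_dir)
    return result


def _hap_layout(
    copies: int,
    spec: HaplotypeSpec,
    config: TrioConfig,
    unit: str,
    flank_left: str,
    flank_right: str,
):
    """Haplotype sequence plus the map from hap CpG anchors to reference
    anchors (None inside the tract)."""
    tract = build_tract(copies, spec, unit)
    hap_seq = flank_left + tract + flank_right
    tract_start = len(flank_left)
    tract_end = tract_start + len(tract)
    ref_tract_len = config.ref_copies * len(unit)

    def to_ref(pos: int) -> Optional[int]:
        if pos < tract_start:
            return pos
        if pos >= tract_end:
            return pos - len(tract) + ref_tract_len
        return None

    anchors = _cpg_anchors(hap_seq)
    return hap_seq, tract, anchors, to_ref


def _alignment_columns(
    hap_seq: str, tract_len: int, config: TrioConfig, unit: str
) -> Tuple[List[str], List[Optional[str]]]:
    """Canonical alignment of the haplotype to the reference as parallel
    op/base column lists (D columns carry base None)."""
    ref_tract_len = config.ref_copies * len(unit)
    fl = config.flank_len
    ops: List[str] = ["M"] * fl
    matched = min(tract_len, ref_tract_len)
    ops += ["M"] * matched
    if tract_len > ref_tract_len:
        ops += ["I"] * (tract_len - ref_tract_len)
    elif tract_len < ref_tract_len:
        ops += ["D"] * (ref_tract_len - tract_len)
    ops += ["M"] * fl
    bases: List[Optional[str]] = []
    qi = 0
    for op in ops:
        if op == "D":
            bases.append(None)
        else:
            bases.append(hap_seq[qi])
            qi += 1
    return ops, bases


def _finalize_read(
    read_id: str,
    strand: str,
    ops: List[str],
    bases: List[Optional[str]],
    scores: Dict[int, int],
    kinetics: Optional[Kinetics] = None,
) -> AlignedRead:
    """Collapse column lists into an AlignedRead; *scores* is keyed by
    column index and re-keyed to stored-sequence offsets."""
    seq_parts: List[str] = []
    mod_scores: Dict[int, int] = {}
    cigar: List[Tuple[str, int]] = []
    qoff = 0
    for col, (op, base) in enumerate(zip(ops, bases)):
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
        if op == "D":
            continue
        seq_parts.append(base)
        if col in scores:
            mod_scores[qoff] = scores[col]
        qoff += 1
    return AlignedRead(
        read_id=read_id,
        chrom=CHROM,
        ref_start=0,
        strand=strand,
        cigar=cigar,
        seq="".join(seq_parts),
        mod_scores=mod_scores,
        kinetics=kinetics,
    )


def _make_nanopore_read(
    read_id: str,
    copies: int,
    spec: HaplotypeSpec,
    profile: str,
    strand: str,
    config: TrioConfig,
    unit: str,
    flank_left: str,
    flank_right: str,
    meth_probability,
    rng: np.random.Generator,
) -> AlignedRead:
    hap_seq, tract, anchors, to_ref = _hap_layout(
        copies, spec, config, unit, flank_left, flank_right
    )
    ops, bases = _alignment_columns(hap_seq, len(tract), config, unit)
    # map hap offset -> column index (M/I columns in order)
    col_of: List[int] = [i for i, op in enumerate(ops) if op != "D"]

    scores: Dict[int, int] = {}
    for anchor in anchors:
        p = meth_probability(to_ref(anchor), profile)
        state = rng.random() < p
        score = emit_score(state, config.emission, rng)
        # template cytosine: hap C at anchor (forward) / hap G at anchor+1 (reverse)
        hap_off = anchor if strand == "+" else anchor + 1
        scores[col_of[hap_off]] = score

    # substitution noise away from scored columns
    n_cols = len(ops)
    sub_mask = rng.random(n_cols) < config.noise.sub_rate
    for col in np.nonzero(sub_mask)[0]:
        if ops[col] == "D" or int(col) in scores:
            continue
        old = bases[col]
        choices = [b for b in "ACGT" if b != old]
        bases[col] = choices[int(rng.integers(0, 3))]

    # indel noise: single-base insertions/deletions at random columns
    n_indels = int(rng.binomial(n_cols, config.noise.indel_rate))
    positions = sorted(rng.integers(0, n_cols, size=n_indels), reverse=True)
    for col in positions:
        col = int(col)
        if rng.random() < 0.5:
            ops.insert(col, "I")
            bases.insert(col, str(BASES[int(rng.integers(0, 4))]))
            scores = {c + 1 if c >= col else c: s for c, s in scores.items()}
        else:
            if ops[col] == "D" or col in scores:
                continue
            if ops[col] == "M":
                bases[col] = None
                ops[col] = "D"
            else:  # drop an inserted base entirely
                del ops[col]
                del bases[col]
                scores = {c - 1 if c > col else c: s for c, s in scores.items()}
    return _finalize_read(read_id, strand, ops, bases, scores)


def _make_clean_read(
    read_id: str,
    copies: int,
    spec: HaplotypeSpec,
    config: TrioConfig,
    unit: str,
    flank_left: str,
    flank_right: str,
) -> AlignedRead:
    hap_seq, tract, _, _ = _hap_layout(copies, spec, config, unit, flank_left, flank_right)
    ops, bases = _alignment_columns(hap_seq, len(tract), config, unit)
    return _finalize_read(read_id, "+", ops, bases, {})


def _make_kinetics_read(
    read_id: str,
    copies: int,
    spec: HaplotypeSpec,
    config: TrioConfig,
    unit: str,
    flank_left: str,
    flank_right: str,
    rng: np.random.Generator,
) -> AlignedRead:
    """Error-free read at consensus length carrying fi/fp/ri/rp arrays.

    The methylation slowdown multiplies mean IPD and PW over the repeat
    tract of hypermethylated haplotypes, on both strands."""
    read = _make_clean_read(read_id, copies, spec, config, unit, flank_left, flank_right)
    L = len(read.seq)
    tract_len = L - 2 * config.flank_len
    mult = np.ones(L)
    if spec.profile == "hypermethylated" and tract_len > 0:
        mult[config.flank_len: config.flank_len + tract_len] = config.kinetics.slowdown
    ks = config.kinetics
    kin = Kinetics(
        ipd_fwd=rng.poisson(ks.base_ipd * mult).astype(np.int64),
        pw_fwd=rng.poisson(ks.base_pw * mult).astype(np.int64),
        ipd_rev=rng.poisson(ks.base_ipd * mult).astype(np.int64),
        pw_rev=rng.poisson(ks.base_pw * mult).astype(np.int64),
    )
    read.kinetics = kin
    read.validate()
    return read
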