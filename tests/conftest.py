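import numpy as np
import pytest

from replongmeth import workflow
from replongmeth.io_model import AlignedRead


@pytest.fixture(scope="session")
def trio_analysis():
    """Default synthetic trio (~600 nanopore reads) with genotyping,
    phasing and strand-combined rate-mode methylation calls."""
    return workflow.run_default_trio(seed=1)


@pytest.fixture(scope="session")
def trio(trio_analysis):
    return trio_analysis.trio


# ---------------------------------------------------------------------------
# Random toy alignments for projection-oracle tests


def random_toy_alignment(rng: np.random.Generator, ref: str, chrom: str = "c") -> AlignedRead:
    """A random short read over *ref* exercising every CIGAR op mix.

    Scored offsets address stored C (forward reads) or stored G
    (reverse), as the data model requires.
    """
    ref_len = len(ref)
    ref_start = int(rng.integers(0, max(1, ref_len - 5)))
    strand = "+" if rng.random() < 0.5 else "-"
    ops = []
    seq = []
    bases = "ACGT"
    if rng.random() < 0.3:
        n = int(rng.integers(1, 4))
        ops.append(("S", n))
        seq.append("".join(bases[rng.integers(0, 4)] for _ in range(n)))
    rpos = ref_start
    n_segments = int(rng.integers(1, 6))
    for i in range(n_segments):
        room = ref_len - rpos
        if room <= 0:
            break
        op = "M" if i == 0 else ("M", "I", "D")[rng.integers(0, 3)]
        if op == "M":
            n = int(rng.integers(1, min(8, room) + 1))
            frag = list(ref[rpos: rpos + n])
            for j in range(n):  # occasional mismatch
                if rng.random() < 0.15:
                    frag[j] = bases[rng.integers(0, 4)]
            seq.append("".join(frag))
            ops.append(("M", n))
            rpos += n
        elif op == "I":
            n = int(rng.integers(1, 4))
            seq.append("".join(bases[rng.integers(0, 4)] for _ in range(n)))
            ops.append(("I", n))
        else:
            n = int(rng.integers(1, min(4, room) + 1))
            ops.append(("D", n))
            rpos += n
    if ops[-1][0] != "M":  # end on a match so the alignment is well formed
        if rpos < ref_len:
            ops.append(("M", 1))
            seq.append(ref[rpos])
            rpos += 1
        else:
            while ops and ops[-1][0] in "ID":
                op, n = ops.pop()
                if op == "I":
                    last = seq.pop()
                    assert len(last) == n
    if rng.random() < 0.3:
        n = int(rng.integers(1, 4))
        ops.append(("S", n))
        seq.append("".join(bases[rng.integers(0, 4)] for _ in range(n)))
    # merge adjacent identical ops
    merged = []
    for op, n in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    full = "".join(seq)
    target = "C" if strand == "+" else "G"
    candidates = [i for i, b in enumerate(full) if b == target]
    rng.shuffle(candidates)
    n_scored = int(rng.integers(0, len(candidates) + 1))
    scores = {int(i): int(rng.integers(0, 256)) for i in candidates[:n_scored]}
    return AlignedRead(
        read_id=f"toy{rng.integers(1e9)}",
        chrom=chrom,
        ref_start=ref_start,
        strand=strand,
        cigar=[(op, n) for op, n in merged],
        seq=full,
        mod_scores=scores,
    )


def brute_force_projection(read: AlignedRead, ref: str):
    """Independent projection oracle: render the explicit column map of
    the alignment, then scan every scored offset for reference CpG
    context on the read's strand."""
    colmap = {}  # stored offset -> reference position (match columns only)
    rpos, qpos = read.ref_start, 0
    for op, n in read.cigar:
        if op == "M":
            for k in range(n):
                colmap[qpos + k] = rpos + k
            rpos += n
            qpos += n
        elif op in "IS":
            qpos += n
        elif op == "D":
            rpos += n
    out = []
    for q in sorted(read.mod_scores):
        if q not in colmap:
            continue
        p = colmap[q]
        if read.strand == "+":
            if p + 1 < len(ref) and ref[p: p + 2] == "CG":
                out.append((p, "+", p, read.mod_scores[q]))
        else:
            if p >= 1 and ref[p - 1: p + 1] == "CG":
                out.append((p, "-", p - 1, read.mod_scores[q]))
    out.sort()
    return out
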