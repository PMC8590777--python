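"""Multi-sample methylation comparison.

Builds a CpG-by-sample percent-methylation matrix from per-sample pileup
counts, then: pairwise Pearson correlation with a simple regression
line, centered PCA over samples, Ward hierarchical clustering, per-base
differential methylation by two-sided Fisher's exact test with
Benjamini-Hochberg q-values (q < 0.01 significant by default), and
feature-context summaries (repeat-class annotation, signed distance to
the nearest transcription start site).

Complete-case analysis throughout: a site enters PCA, clustering or a
pairwise correlation only where every sample involved meets the
coverage floor.  No imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .io_model import FormatError, GenomicInterval
from .methylcall import SiteCounts

logger = logging.getLogger(__name__)

DEFAULT_Q_CUTOFF = 0.01
DEFAULT_MIN_COVERAGE = 10


@dataclass
class PercentMatrix:
    """CpG-site by sample matrix of percent methylation (0-100).

    ``percent`` and ``coverage`` share a (chrom, pos1, strand) MultiIndex;
    cells below the coverage floor are NaN in ``percent``.
    """

    percent: pd.DataFrame
    coverage: pd.DataFrame
    min_coverage: int

    @property
    def samples(self) -> List[str]:
        return list(self.percent.columns)

    def complete(self, samples: Optional[Sequence[str]] = None) -> pd.DataFrame:
        """Rows complete (non-missing) in the given samples (default: all)."""
        sub = self.percent if samples is None else self.percent[list(samples)]
        return sub.dropna(axis=0, how="any")


@dataclass(frozen=True)
class DiffBase:
    chrom: str
    pos1: int
    strand: str
    percent_a: float
    percent_b: float
    meth_diff: float
    p_value: float
    q_value: float
    significant: bool


SampleCounts = Union[Mapping[str, Sequence[SiteCounts]], Iterable[Tuple[str, Sequence[SiteCounts]]]]


def _site_key(site: SiteCounts) -> Tuple[str, int, str]:
    return (site.chrom, site.cpg_anchor + 1, site.strand or "*")


def build_percent_matrix(
    samples: SampleCounts,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> PercentMatrix:
    """Union of sites across >= 2 samples; cells are 100*n_mod/coverage."""
    pairs = list(samples.items()) if isinstance(samples, Mapping) else list(samples)
    ids = [sid for sid, _ in pairs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample id in percent-matrix input")
    if len(ids) < 2:
        raise ValueError("at least two samples required")
    percent: Dict[str, Dict[Tuple, float]] = {}
    coverage: Dict[str, Dict[Tuple, int]] = {}
    for sid, counts in pairs:
        pcol, ccol = {}, {}
        for site in counts:
            key = _site_key(site)
            ccol[key] = site.coverage
            if site.coverage >= min_coverage:
                pcol[key] = 100.0 * site.n_mod / site.coverage
        percent[sid] = pcol
        coverage[sid] = ccol
    all_keys = sorted({k for col in coverage.values() for k in col})
    if not all_keys:
        raise ValueError("no sites in any sample")
    pdf = pd.DataFrame(percent, columns=ids).reindex(all_keys)
    cdf = pd.DataFrame(coverage, columns=ids).reindex(all_keys).fillna(0).astype(int)
    pdf.index = pd.MultiIndex.from_tuples(all_keys, names=["chrom", "pos1", "strand"])
    cdf.index = pdf.index
    pdf = pdf.sort_index()
    cdf = cdf.sort_index()
    return PercentMatrix(percent=pdf, coverage=cdf, min_coverage=min_coverage)


def pairwise_pearson(matrix: PercentMatrix, sample_a: str, sample_b: str) -> Dict[str, float]:
    """Pearson r and p over complete cases, plus the regression line.

    Returns r, p_value, n_sites, slope, intercept (percent-on-percent
    simple linear regression, as drawn through sample-vs-sample dot
    plots).
    """
    sub = matrix.complete([sample_a, sample_b])
    if len(sub) < 3:
        raise ValueError(f"only {len(sub)} complete sites for {sample_a} vs {sample_b}; need >= 3")
    x, y = sub[sample_a].to_numpy(), sub[sample_b].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one sample; correlation undefined")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return {
        "r": float(r),
        "p_value": float(p),
        "n_sites": int(len(sub)),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
    }


def pca_samples(matrix: PercentMatrix, n_components: int = 2) -> Tuple[pd.DataFrame, np.ndarray]:
    """Centered (unscaled) PCA with samples as observations.

    Percent scales are already commensurate across sites, so no
    unit-variance scaling is applied.  Sign convention: each component is
    flipped so its largest-magnitude loading is positive.  Returns
    (coordinates DataFrame indexed by sample, explained-variance
    fractions).
    """
    from sklearn.decomposition import PCA

    complete = matrix.complete()
    if len(matrix.samples) < 3:
        raise ValueError("PCA requires at least 3 samples")
    if len(complete) < 2:
        raise ValueError(f"only {len(complete)} complete site(s); PCA needs >= 2")
    X = complete.to_numpy().T  # samples x sites
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    for j in range(k):
        lead = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, lead] < 0:
            pca.components_[j] *= -1
            coords[:, j] *= -1
    frame = pd.DataFrame(
        coords, index=matrix.samples, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return frame, pca.explained_variance_ratio_


def ward_clustering(matrix: PercentMatrix) -> Tuple[np.ndarray, List[str]]:
    """Ward-criterion agglomerative clustering on Euclidean distances.

    Samples are ordered by id before linkage so ties resolve
    deterministically.  Returns (scipy linkage matrix, sample ids in the
    order used).
    """
    ids = sorted(matrix.samples)
    complete = matrix.complete(ids)
    if len(ids) < 2:
        raise ValueError("clustering requires at least 2 samples")
    X = complete[ids].to_numpy().T
    Z = hierarchy.linkage(X, method="ward")
    return Z, ids


def leaf_order(Z: np.ndarray, ids: Sequence[str]) -> List[str]:
    return [ids[i] for i in hierarchy.leaves_list(Z)]


def first_bipartition(Z: np.ndarray, ids: Sequence[str]) -> Tuple[frozenset, frozenset]:
    """The two clusters produced by cutting the tree at its last merge."""
    labels = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    a = frozenset(i for i, lab in zip(ids, labels) if lab == 1)
    b = frozenset(i for i, lab in zip(ids, labels) if lab == 2)
    return a, b


def diff_methyl_bases(
    counts_a: Sequence[SiteCounts],
    counts_b: Sequence[SiteCounts],
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    q_cutoff: float = DEFAULT_Q_CUTOFF,
) -> List[DiffBase]:
    """Per-base differential methylation between two samples.

    Two-sided Fisher's exact test on ``[[n_modA, n_canonA],
    [n_modB, n_canonB]]`` at every site covered >= *min_coverage* in both
    samples; Benjamini-Hochberg q-values; significant iff q < q_cutoff.
    """
    a_by_key = { _site_key(s): s for s in counts_a if s.coverage >= min_coverage }
    b_by_key = { _site_key(s): s for s in counts_b if s.coverage >= min_coverage }
    shared = sorted(set(a_by_key) & set(b_by_key))
    if not shared:
        raise ValueError("no shared sites at the required coverage")
    pvals = np.empty(len(shared))
    for i, key in enumerate(shared):
        sa, sb = a_by_key[key], b_by_key[key]
        _, pvals[i] = stats.fisher_exact(
            [[sa.n_mod, sa.n_canon], [sb.n_mod, sb.n_canon]], alternative="two-sided"
        )
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out = []
    for key, p, q in zip(shared, pvals, qvals):
        sa, sb = a_by_key[key], b_by_key[key]
        pa = 100.0 * sa.n_mod / sa.coverage
        pb = 100.0 * sb.n_mod / sb.coverage
        out.append(
            DiffBase(
                chrom=key[0],
                pos1=key[1],
                strand=key[2],
                percent_a=pa,
                percent_b=pb,
                meth_diff=pa - pb,
                p_value=float(p),
                q_value=float(q),
                significant=bool(q < q_cutoff),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Feature-context annotation


def read_bed(path) -> List[GenomicInterval]:
    """Parse a BED file (0-based half-open) into named intervals.

    Malformed lines raise :class:`FormatError` with the line number.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 else None
            out.append(GenomicInterval(fields[0], start, end, name=name))
    return out


def annotate_features(
    diffs: Sequence[DiffBase],
    features: Sequence[GenomicInterval],
    tss: Optional[pd.DataFrame] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each differential base its covering feature class and TSS context.

    *features* are half-open intervals whose ``name`` is the class label
    (e.g. RepeatMasker classes); a site outside every feature gets class
    "none".  *tss* is a table with columns gene, chrom, pos1, strand;
    the signed distance is negative upstream of the TSS on the gene
    strand, ties broken by lexicographic gene name.

    Returns (per-site table, per-class summary with mean meth_diff and
    significant-site counts).
    """
    from intervaltree import IntervalTree

    trees: Dict[str, IntervalTree] = {}
    for feat in features:
        trees.setdefault(feat.chrom, IntervalTree()).addi(
            feat.start, feat.end, feat.name or "feature"
        )
    rows = []
    for d in diffs:
        pos0 = d.pos1 - 1
        hits = sorted(iv.data for iv in trees.get(d.chrom, IntervalTree()).at(pos0))
        cls = ",".join(hits) if hits else "none"
        gene, dist = None, None
        if tss is not None and len(tss):
            sub = tss[tss["chrom"] == d.chrom]
            if len(sub):
                deltas = (d.pos1 - sub["pos1"]).abs()
                best = sub.assign(_d=deltas).sort_values(["_d", "gene"]).iloc[0]
                gene = best["gene"]
                raw = d.pos1 - int(best["pos1"])
                dist = raw if best["strand"] == "+" else -raw
        rows.append(
            {
                "chrom": d.chrom,
                "pos1": d.pos1,
                "feature": cls,
                "meth_diff": d.meth_diff,
                "q_value": d.q_value,
                "significant": d.significant,
                "nearest_gene": gene,
                "tss_distance": dist,
            }
        )
    per_site = pd.DataFrame(rows)
    summary = (
        per_site.groupby("feature")
        .agg(
            n_sites=("meth_diff", "size"),
            mean_meth_diff=("meth_diff", "mean"),
            n_significant=("significant", "sum"),
        )
        .reset_index()
    )
    return per_site, summary
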