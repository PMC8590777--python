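from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from replongmeth.diffmeth import (
    annotate_features,
    build_percent_matrix,
    diff_methyl_bases,
    first_bipartition,
    pairwise_pearson,
    pca_samples,
    read_bed,
    ward_clustering,
)
from replongmeth.io_model import FormatError, GenomicInterval
from replongmeth.methylcall import SiteCounts


def site(anchor, n_mod, n_canon, chrom="c"):
    return SiteCounts(chrom=chrom, cpg_anchor=anchor, n_mod=n_mod, n_canon=n_canon)


def matrix_from(columns, coverage=20):
    """Build a PercentMatrix from {sample: [percent, ...]} over shared sites."""
    samples = {}
    for sid, percents in columns.items():
        counts = []
        for i, p in enumerate(percents):
            n_mod = round(coverage * p / 100)
            counts.append(site(i * 10, n_mod, coverage - n_mod))
        samples[sid] = counts
    return build_percent_matrix(samples, min_coverage=10)


class TestPercentMatrix:
    def test_union_of_sites_with_incomplete_rows(self):
        samples = {
            "a": [site(i, 5, 5) for i in range(6)],
            "b": [site(i, 5, 5) for i in range(5)],
        }
        m = build_percent_matrix(samples, min_coverage=5)
        assert len(m.percent) == 6
        assert len(m.complete()) == 5

    def test_low_coverage_cell_missing(self):
        samples = {"a": [site(0, 5, 4)], "b": [site(0, 5, 5)]}
        m = build_percent_matrix(samples, min_coverage=10)
        assert np.isnan(m.percent.loc[("c", 1, "*"), "a"])
        assert m.percent.loc[("c", 1, "*"), "b"] == pytest.approx(50.0)

    def test_duplicate_sample_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_percent_matrix([("a", [site(0, 5, 5)]), ("a", [site(0, 5, 5)])])

    def test_identical_inputs_identical_columns(self):
        counts = [site(i, i, 10 - i) for i in range(1, 6)]
        m = build_percent_matrix({"a": counts, "b": counts}, min_coverage=5)
        pd.testing.assert_series_equal(m.percent["a"], m.percent["b"], check_names=False)


class TestPearson:
    def test_identical_columns_r_one(self):
        m = matrix_from({"a": [0, 30, 80, 100], "b": [0, 30, 80, 100]})
        assert pairwise_pearson(m, "a", "b")["r"] == pytest.approx(1.0)

    def test_antisymmetric_columns_r_minus_one(self):
        m = matrix_from({"a": [0, 50, 100], "b": [100, 50, 0]})
        res = pairwise_pearson(m, "a", "b")
        assert res["r"] == pytest.approx(-1.0)
        assert res["slope"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        xs, ys = [10.0, 40.0, 55.0, 95.0], [20.0, 35.0, 70.0, 80.0]
        m = matrix_from({"a": xs, "b": ys})
        n = len(xs)
        sx, sy = sum(xs), sum(ys)
        sxy = sum(x * y for x, y in zip(xs, ys))
        sxx = sum(x * x for x in xs)
        syy = sum(y * y for y in ys)
        r = (n * sxy - sx * sy) / ((n * sxx - sx**2) ** 0.5 * (n * syy - sy**2) ** 0.5)
        assert pairwise_pearson(m, "a", "b")["r"] == pytest.approx(r, abs=1e-9)

    def test_zero_variance_rejected(self):
        m = matrix_from({"a": [50, 50, 50], "b": [0, 50, 100]})
        with pytest.raises(ValueError, match="variance"):
            pairwise_pearson(m, "a", "b")


class TestPcaWard:
    def two_cluster_matrix(self):
        rng = np.random.default_rng(5)
        base_lo = rng.uniform(0, 10, 30)
        base_hi = base_lo + 80
        cols = {}
        for sid in ["f1", "f2"]:
            cols[sid] = np.clip(base_hi + rng.normal(0, 2, 30), 0, 100)
        for sid in ["m1", "m2", "p1", "p2"]:
            cols[sid] = np.clip(base_lo + rng.normal(0, 2, 30), 0, 100)
        return matrix_from(cols, coverage=200)

    def test_two_groups_separate_on_pc1(self):
        m = self.two_cluster_matrix()
        coords, evr = pca_samples(m)
        pc1 = coords["PC1"]
        hi = {"f1", "f2"}
        assert pc1[list(hi)].min() * pc1.drop(list(hi)).max() < 0  # opposite sides
        assert evr[0] > 0.9

    def test_identical_samples_coordinates_zero(self):
        counts = [site(i, 5, 5) for i in range(5)]
        m = build_percent_matrix({"a": counts, "b": counts, "c": counts}, min_coverage=5)
        coords, _ = pca_samples(m)
        np.testing.assert_allclose(coords.to_numpy(), 0.0, atol=1e-9)

    def test_explained_variance_sums_below_one(self):
        _, evr = pca_samples(self.two_cluster_matrix())
        assert evr.sum() <= 1.0 + 1e-12

    def test_ward_first_bipartition_separates_groups(self):
        m = self.two_cluster_matrix()
        Z, ids = ward_clustering(m)
        a, b = first_bipartition(Z, ids)
        assert {frozenset({"f1", "f2"})} == {g for g in (a, b) if len(g) == 2 and "f1" in g}

    def test_two_samples_single_merge_height(self):
        # Ward height for a pair is the plain Euclidean distance
        m = matrix_from({"a": [0, 0, 0], "b": [30, 40, 0]})
        Z, ids = ward_clustering(m)
        assert Z.shape[0] == 1
        assert Z[0, 2] == pytest.approx(50.0)

    def test_identical_samples_merge_at_zero(self):
        counts = [site(i, 5, 5) for i in range(4)]
        m = build_percent_matrix({"a": counts, "b": counts, "c": counts}, min_coverage=5)
        Z, _ = ward_clustering(m)
        np.testing.assert_allclose(Z[:, 2], 0.0, atol=1e-12)


def fisher_two_sided(a, b, c, d) -> float:
    """Exact two-sided Fisher p by hypergeometric enumeration: sum of all
    table probabilities not exceeding the observed one."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        if col1 - x < 0 or col1 - x > n - row1 or x > row1:
            return Fraction(0)
        return Fraction(comb(row1, x) * comb(n - row1, col1 - x), comb(n, col1))

    p_obs = prob(a)
    total = sum((p for x in range(0, min(row1, col1) + 1) if (p := prob(x)) <= p_obs), Fraction(0))
    return float(total)


class TestDiffBases:
    def test_identical_counts_p_one(self):
        diffs = diff_methyl_bases([site(0, 5, 5)], [site(0, 5, 5)], min_coverage=5)
        assert diffs[0].p_value == pytest.approx(1.0)
        assert not diffs[0].significant

    def test_extreme_table_matches_enumeration(self):
        diffs = diff_methyl_bases([site(0, 10, 0)], [site(0, 0, 10)], min_coverage=10)
        want = 2 / comb(20, 10)
        assert diffs[0].p_value == pytest.approx(want, abs=1e-12)
        assert diffs[0].significant

    def test_random_tables_match_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        counts_a, counts_b = [], []
        for i in range(20):
            counts_a.append(site(i, int(rng.integers(0, 15)), int(rng.integers(1, 15))))
            counts_b.append(site(i, int(rng.integers(0, 15)), int(rng.integers(1, 15))))
        diffs = diff_methyl_bases(counts_a, counts_b, min_coverage=1)
        for d, sa, sb in zip(diffs, counts_a, counts_b):
            want = fisher_two_sided(sa.n_mod, sa.n_canon, sb.n_mod, sb.n_canon)
            assert d.p_value == pytest.approx(want, rel=1e-7, abs=1e-12)

    def test_q_values_monotone_and_bh_bounded(self):
        rng = np.random.default_rng(4)
        counts_a = [site(i, int(rng.integers(0, 20)), 20) for i in range(50)]
        counts_b = [site(i, int(rng.integers(0, 20)), 20) for i in range(50)]
        diffs = diff_methyl_bases(counts_a, counts_b, min_coverage=10)
        ordered = sorted(diffs, key=lambda d: d.p_value)
        qs = [d.q_value for d in ordered]
        assert all(q1 <= q2 + 1e-12 for q1, q2 in zip(qs, qs[1:]))
        assert all(d.q_value >= d.p_value - 1e-12 for d in diffs)

    def test_null_family_false_positive_control(self):
        """100 sites simulated at equal rates: expect <= 1 false positive
        at q < 0.01."""
        rng = np.random.default_rng(12)
        counts_a = [site(i, int(rng.binomial(30, 0.3)), 30) for i in range(100)]
        counts_b = [site(i, int(rng.binomial(30, 0.3)), 30) for i in range(100)]
        diffs = diff_methyl_bases(counts_a, counts_b, min_coverage=10)
        assert sum(d.significant for d in diffs) <= 1

    def test_detects_simulated_hypermethylated_block(self):
        """>= 95% of truly differential CpGs flagged at coverage 30 and an
        80-point methylation difference."""
        rng = np.random.default_rng(21)
        n_diff, n_null = 40, 60
        counts_a, counts_b = [], []
        for i in range(n_diff + n_null):
            pa, pb = (0.9, 0.1) if i < n_diff else (0.1, 0.1)
            counts_a.append(site(i, int(rng.binomial(30, pa)), 30))
            counts_b.append(site(i, int(rng.binomial(30, pb)), 30))
        diffs = diff_methyl_bases(counts_a, counts_b, min_coverage=10)
        hits = sum(d.significant for d in diffs[:n_diff])
        assert hits >= 0.95 * n_diff

    def test_no_shared_sites_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            diff_methyl_bases([site(0, 5, 5)], [site(1, 5, 5)], min_coverage=5)


class TestAnnotation:
    def make_diffs(self):
        return diff_methyl_bases(
            [site(100, 28, 2), site(200, 3, 27), site(300, 15, 15)],
            [site(100, 2, 28), site(200, 3, 27), site(300, 14, 16)],
            min_coverage=10,
        )

    def test_feature_assignment_and_none_class(self):
        diffs = self.make_diffs()
        features = [GenomicInterval("c", 90, 150, name="SINE")]
        per_site, summary = annotate_features(diffs, features)
        by_pos = per_site.set_index("pos1")["feature"]
        assert by_pos[101] == "SINE"
        assert by_pos[201] == "none"
        assert set(summary["feature"]) == {"SINE", "none"}

    def test_tss_distance_signed_by_gene_strand(self):
        diffs = self.make_diffs()
        tss = pd.DataFrame(
            [
                {"gene": "minus", "chrom": "c", "pos1": 211, "strand": "-"},
                {"gene": "plus", "chrom": "c", "pos1": 96, "strand": "+"},
            ]
        )
        per_site, _ = annotate_features(diffs, [], tss=tss)
        row = per_site.set_index("pos1")
        assert row.loc[101, "nearest_gene"] == "plus"
        assert row.loc[101, "tss_distance"] == 5  # downstream of + TSS
        assert row.loc[201, "nearest_gene"] == "minus"
        assert row.loc[201, "tss_distance"] == 10  # downstream of - TSS at 211

    def test_equidistant_tss_tie_breaks_lexicographic(self):
        diffs = self.make_diffs()
        tss = pd.DataFrame(
            [
                {"gene": "zeta", "chrom": "c", "pos1": 91, "strand": "+"},
                {"gene": "alpha", "chrom": "c", "pos1": 111, "strand": "+"},
            ]
        )
        per_site, _ = annotate_features(diffs, [], tss=tss)
        assert per_site.set_index("pos1").loc[101, "nearest_gene"] == "alpha"


class TestBed:
    def test_valid_bed(self, tmp_path):
        bed = tmp_path / "f.bed"
        bed.write_text("c\t10\t20\tSINE\nc\t30\t40\tLINE\n")
        ivs = read_bed(bed)
        assert [(iv.start, iv.end, iv.name) for iv in ivs] == [(10, 20, "SINE"), (30, 40, "LINE")]

    def test_malformed_bed_reports_line_number(self, tmp_path):
        bed = tmp_path / "f.bed"
        bed.write_text("c\t10\t20\tok\nc\tx\t40\n")
        with pytest.raises(FormatError, match=":2"):
            read_bed(bed)
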