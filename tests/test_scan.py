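"""Window construction, testing burden, tabulation, and the exact test."""

import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats

from unionscan import (
    CASE,
    CONTROL,
    MISSING,
    CodingScheme,
    ContingencyTable2x2,
    GenotypeTable,
    MarkerInfo,
    UnionSpec,
    UntestableUnionError,
    build_windows,
    count_tests,
    fisher_exact_2x2,
    run_scan,
    tabulate_union,
)
from conftest import random_genotype_table

DOM = CodingScheme.DOMINANT


def _markers(n, chrom="1", start=0):
    return [
        MarkerInfo(f"rs{start + j}", chrom, 100 * (start + j + 1), "A", "B", "b")
        for j in range(n)
    ]


class TestBuildWindows:
    def test_partition_sizes_with_remainder(self):
        specs = build_windows(_markers(10), 3, DOM)
        assert [s.size for s in specs] == [3, 3, 3, 1]
        covered = [i for s in specs for i in s.marker_indices]
        assert covered == list(range(10))

    def test_k1_gives_singletons(self):
        specs = build_windows(_markers(5), 1, DOM)
        assert [s.marker_indices for s in specs] == [(i,) for i in range(5)]

    def test_windows_never_span_chromosomes(self):
        markers = _markers(4, "1") + _markers(3, "2", start=4)
        specs = build_windows(markers, 2, DOM)
        assert [s.size for s in specs] == [2, 2, 2, 1]
        assert [s.chromosome for s in specs] == ["1", "1", "2", "2"]

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            build_windows(_markers(3), 0, DOM)


class TestCountTests:
    def test_genome_wide_burden_and_threshold(self):
        """319,813 markers, k 1-5, both codings: burden 1,460,484, α/burden 3.42e-8."""
        burden = count_tests(319813, range(1, 6), 2)
        assert burden == 1_460_484
        assert f"{0.05 / burden:.3g}" == "3.42e-08"

    @pytest.mark.parametrize(
        "n,ks,schemes,expected",
        [(10, {3}, 1, 4), (7, {2, 3}, 2, 14), (5, {1}, 1, 5)],
    )
    def test_ceiling_sums(self, n, ks, schemes, expected):
        assert count_tests(n, ks, schemes) == expected

    def test_empty_k_sizes_rejected(self):
        with pytest.raises(ValueError):
            count_tests(10, set(), 1)


class TestTabulateUnion:
    def test_full_separation(self):
        dosage = np.array([[1], [2], [0], [0]], dtype=np.int8)
        table = GenotypeTable(
            dosage, _markers(1), np.array([CASE, CASE, CONTROL, CONTROL])
        )
        spec = UnionSpec(0, DOM, (0,), "1")
        t = tabulate_union(table, spec)
        assert (t.cases_1, t.cases_0, t.controls_1, t.controls_0) == (2, 0, 0, 2)
        assert t.n_excluded == 0

    def test_missing_indicator_excluded(self):
        # case with dominant-coded (0, ?) has a missing union indicator
        dosage = np.array([[0, MISSING], [1, 0], [0, 0]], dtype=np.int8)
        table = GenotypeTable(
            dosage, _markers(2), np.array([CASE, CASE, CONTROL])
        )
        t = tabulate_union(table, UnionSpec(0, DOM, (0, 1), "1"))
        assert t.n_excluded == 1
        assert t.cases_1 == 1 and t.controls_0 == 1

    @pytest.mark.parametrize("missing_rate", [0.0, 0.2])
    def test_cell_conservation(self, rng, missing_rate):
        table = random_genotype_table(rng, n=50, m=6, missing_rate=missing_rate)
        for spec in build_windows(table.markers, 3, DOM):
            t = tabulate_union(table, spec)
            assert t.total_tested + t.n_excluded == table.n_individuals


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------


def oracle_two_sided_p(a, b, c, d):
    """Brute-force enumeration over all tables at the observed margins.

    Point probabilities are exact rationals built from factorials; the
    two-sided p sums every table whose probability is <= the observed one.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    probs = {}
    for aa in range(0, min(r1, c1) + 1):
        bb, cc = r1 - aa, c1 - aa
        dd = r2 - cc
        if cc < 0 or dd < 0:
            continue
        num = (
            math.factorial(r1) * math.factorial(r2)
            * math.factorial(c1) * math.factorial(n - c1)
        )
        den = (
            math.factorial(n) * math.factorial(aa) * math.factorial(bb)
            * math.factorial(cc) * math.factorial(dd)
        )
        probs[aa] = Fraction(num, den)
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestFisherExact:
    def test_symmetric_table(self):
        p, oratio, lo, hi = fisher_exact_2x2(ContingencyTable2x2(5, 5, 5, 5))
        assert p == 1.0 and oratio == 1.0
        assert lo < 1.0 < hi

    def test_against_enumeration_oracle(self):
        p, *_ = fisher_exact_2x2(ContingencyTable2x2(1, 9, 11, 3))
        assert p == pytest.approx(oracle_two_sided_p(1, 9, 11, 3), abs=1e-14)

    @pytest.mark.parametrize("seed", range(3))
    def test_random_tables_match_oracle_and_scipy(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            a, b, c, d = rng.integers(0, 15, size=4)
            t = ContingencyTable2x2(int(a), int(b) + 1, int(c), int(d) + 1)
            p, *_ = fisher_exact_2x2(t)
            assert p == pytest.approx(
                oracle_two_sided_p(t.cases_1, t.cases_0, t.controls_1, t.controls_0),
                abs=1e-13,
            )
            p_scipy = scipy.stats.fisher_exact(
                [[t.cases_1, t.cases_0], [t.controls_1, t.controls_0]]
            ).pvalue
            assert p == pytest.approx(p_scipy, abs=1e-10)

    def test_large_tables_consistent_with_small_path(self):
        """The scipy branch for big tables agrees with exact enumeration."""
        for cells in [(120, 818, 80, 783), (400, 538, 350, 513)]:
            t = ContingencyTable2x2(*cells)
            p, *_ = fisher_exact_2x2(t)
            assert p == pytest.approx(oracle_two_sided_p(*cells), rel=1e-9)

    def test_odds_ratio_cross_product_and_woolf_ci(self):
        t = ContingencyTable2x2(20, 10, 10, 20)
        _, oratio, lo, hi = fisher_exact_2x2(t)
        assert oratio == pytest.approx(4.0)
        se = math.sqrt(1 / 20 + 1 / 10 + 1 / 10 + 1 / 20)
        assert lo == pytest.approx(math.exp(math.log(4) - 1.959963984540054 * se))
        assert hi == pytest.approx(math.exp(math.log(4) + 1.959963984540054 * se))
        assert lo <= oratio <= hi

    def test_zero_cell_haldane_anscombe(self):
        _, oratio, lo, hi = fisher_exact_2x2(ContingencyTable2x2(0, 10, 5, 5))
        assert oratio == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))
        assert lo < oratio < hi

    def test_degenerate_column_margin(self):
        p, oratio, lo, hi = fisher_exact_2x2(ContingencyTable2x2(0, 10, 0, 12))
        assert p == 1.0
        assert math.isnan(oratio) and math.isnan(lo) and math.isnan(hi)
        p2, *_ = fisher_exact_2x2(ContingencyTable2x2(10, 0, 12, 0))
        assert p2 == 1.0

    def test_empty_row_margin_untestable(self):
        with pytest.raises(UntestableUnionError):
            fisher_exact_2x2(ContingencyTable2x2(0, 0, 5, 5))


# ---------------------------------------------------------------------------
# Scan driver
# ---------------------------------------------------------------------------


class TestRunScan:
    def test_k1_equals_per_marker_fisher(self, rng):
        """A k=1 scan is exactly single-marker analysis under the same coding."""
        table = random_genotype_table(rng, n=70, m=9, maf=0.3, missing_rate=0.1)
        result = run_scan(table, k_sizes=(1,), schemes=(DOM,), alpha=0.05)
        assert len(result.results) == 9
        for res in result.results:
            j = res.spec.marker_indices[0]
            t = tabulate_union(table, UnionSpec(0, DOM, (j,), "1"))
            p, *_ = fisher_exact_2x2(t)
            assert res.p_value == p

    def test_threshold_and_burden(self, rng):
        table = random_genotype_table(rng, n=40, m=10)
        result = run_scan(table, k_sizes=(2,), schemes=(DOM,), alpha=0.05)
        assert result.n_tests == 5
        assert result.threshold == pytest.approx(0.01)
        assert len(result.results) + len(result.skipped) == 5

    def test_phenotype_permutation_preserves_table_multiset(self, rng):
        """Re-labelling phenotypes permutes tables; no hidden state leaks."""
        table = random_genotype_table(rng, n=40, m=6, missing_rate=0.1)
        res_a = run_scan(table, k_sizes=(1, 2), schemes=(DOM,))
        perm = rng.permutation(table.n_individuals)
        permuted = GenotypeTable(
            table.dosage[perm], table.markers, table.phenotype[perm]
        )
        res_b = run_scan(permuted, k_sizes=(1, 2), schemes=(DOM,))
        tables_a = sorted(
            (r.spec.scheme, r.spec.marker_indices, r.table) for r in res_a.results
        )
        tables_b = sorted(
            (r.spec.scheme, r.spec.marker_indices, r.table) for r in res_b.results
        )
        assert tables_a == tables_b

    def test_collapsing_method_identity_scan(self, rng):
        """Dominant unions on complete rare-variant data = collapsing test."""
        dosage = rng.binomial(2, 0.04, size=(120, 8)).astype(np.int8)
        table = GenotypeTable(
            dosage,
            _markers(8),
            np.array([CASE] * 60 + [CONTROL] * 60, dtype=np.int8),
        )
        result = run_scan(table, k_sizes=(4,), schemes=(DOM,))
        for res in result.results:
            idx = list(res.spec.marker_indices)
            collapsed = (dosage[:, idx] > 0).any(axis=1)
            a = int((collapsed & (table.phenotype == CASE)).sum())
            c = int((collapsed & (table.phenotype == CONTROL)).sum())
            assert (res.table.cases_1, res.table.controls_1) == (a, c)

    def test_untestable_unions_counted_in_burden(self):
        # the only control is missing at marker 1 -> that union has no
        # control row and is skipped, but the burden still counts it
        dosage = np.array([[1, 1], [0, 0], [MISSING, 1]], dtype=np.int8)
        table = GenotypeTable(
            dosage, _markers(2), np.array([CASE, CASE, CONTROL])
        )
        result = run_scan(table, k_sizes=(1,), schemes=(DOM,))
        assert result.n_tests == 2
        assert len(result.skipped) == 1 and len(result.results) == 1
        assert result.threshold == pytest.approx(0.05 / 2)
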