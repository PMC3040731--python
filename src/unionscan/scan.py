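"""Genome-wide union testing.

Markers are partitioned, chromosome by chromosome, into consecutive
non-overlapping windows of k markers (the last window on a chromosome may
be short).  Each window defines one union; each individual contributes one
three-valued indicator to that union (see :mod:`unionscan.coding`), and the
resulting 2×2 case/control table of 0/1 indicators is tested with Fisher's
exact test.  The test has one degree of freedom regardless of k, so the
family-wise error is controlled by a Bonferroni correction over the testing
burden

    n_tests = n_schemes × Σ_k ⌈M / k⌉

for M markers — which *shrinks* as k grows.  With M = 319,813 markers,
k ∈ {1..5} and both codings, the per-test threshold is
0.05 / 1,460,484 ≈ 3.42e-8.

The two-sided p-value follows the standard convention (the one used by R's
``fisher.test`` and SciPy): the sum of probabilities, under the
hypergeometric null at fixed margins, of all tables whose point probability
does not exceed that of the observed table.  For small tables the sum is
computed in exact integer arithmetic; large tables are delegated to
:func:`scipy.stats.fisher_exact` (the two agree to ~1e-15).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.stats

from .coding import MISSING, CodingScheme, code_dosage, union_indicator_matrix
from .io_formats import CASE, GenotypeTable, MarkerInfo

__all__ = [
    "UnionSpec",
    "ContingencyTable2x2",
    "UnionTestResult",
    "ScanResult",
    "UntestableUnionError",
    "build_windows",
    "count_tests",
    "tabulate_union",
    "fisher_exact_2x2",
    "run_scan",
]

# Above this table total, exact integer enumeration of the hypergeometric
# null is slower than scipy's float implementation; below it, it is much
# faster and exact to the last bit.
_EXACT_TOTAL_LIMIT = 200


class UntestableUnionError(ValueError):
    """A union whose table has an empty case or control row after exclusions."""


@dataclass(frozen=True)
class UnionSpec:
    """One union: a coding scheme plus consecutive marker indices."""

    union_id: int
    scheme: CodingScheme
    marker_indices: tuple[int, ...]
    chromosome: str

    def __post_init__(self) -> None:
        idx = self.marker_indices
        if not idx:
            raise ValueError("union must contain at least one marker")
        if any(b - a != 1 for a, b in zip(idx, idx[1:])):
            raise ValueError("marker indices must be strictly increasing consecutive")

    @property
    def size(self) -> int:
        return len(self.marker_indices)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Case/control × indicator counts for one union.

    ``n_excluded`` counts individuals removed because their union indicator
    was missing; the five numbers always add up to the sample size.
    """

    cases_1: int
    cases_0: int
    controls_1: int
    controls_0: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.cases_1, self.cases_0, self.controls_1, self.controls_0,
               self.n_excluded) < 0:
            raise ValueError("table counts must be non-negative")

    @property
    def total_tested(self) -> int:
        return self.cases_1 + self.cases_0 + self.controls_1 + self.controls_0


@dataclass(frozen=True)
class UnionTestResult:
    spec: UnionSpec
    table: ContingencyTable2x2
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    degrees_of_freedom: int = 1


@dataclass
class ScanResult:
    """All union tests of one scan plus its multiplicity bookkeeping."""

    results: list[UnionTestResult]
    markers: list[MarkerInfo]
    alpha: float
    threshold: float
    n_tests: int
    k_sizes: tuple[int, ...]
    schemes: tuple[CodingScheme, ...]
    skipped: list[UnionSpec] = field(default_factory=list)

    def significant(self) -> list[UnionTestResult]:
        return [r for r in self.results if r.p_value <= self.threshold]


# ---------------------------------------------------------------------------
# Windows and testing burden
# ---------------------------------------------------------------------------


def build_windows(
    markers: Sequence[MarkerInfo], k: int, scheme: CodingScheme
) -> list[UnionSpec]:
    """Partition markers into consecutive non-overlapping k-windows.

    Windows never span a chromosome boundary; the last window on each
    chromosome may hold fewer than k markers.  Markers are assumed sorted
    by (chromosome, position).
    """
    if k < 1:
        raise ValueError(f"window size k must be >= 1, got {k}")
    scheme = CodingScheme(scheme)
    specs: list[UnionSpec] = []
    uid = 0
    start = 0
    n = len(markers)
    while start < n:
        chrom = markers[start].chromosome
        end = start
        while end < n and markers[end].chromosome == chrom:
            end += 1
        for lo in range(start, end, k):
            hi = min(lo + k, end)
            specs.append(UnionSpec(uid, scheme, tuple(range(lo, hi)), chrom))
            uid += 1
        start = end
    return specs


def count_tests(n_markers: int, k_sizes: Iterable[int], n_schemes: int) -> int:
    """Total testing burden: n_schemes × Σ_k ⌈n_markers / k⌉."""
    ks = sorted(set(int(k) for k in k_sizes))
    if not ks:
        raise ValueError("k_sizes must be non-empty")
    if ks[0] < 1:
        raise ValueError("all union sizes must be >= 1")
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    return n_schemes * sum(math.ceil(n_markers / k) for k in ks)


# ---------------------------------------------------------------------------
# Tabulation
# ---------------------------------------------------------------------------


def tabulate_union(genotypes: GenotypeTable, spec: UnionSpec) -> ContingencyTable2x2:
    """Count union indicators among cases and controls for one union.

    Individuals with a missing indicator are excluded from the table and
    counted in ``n_excluded``.
    """
    cols = genotypes.dosage[:, list(spec.marker_indices)]
    coded = code_dosage(cols, spec.scheme)
    ind = union_indicator_matrix(coded)
    return _tabulate_indicator(ind, genotypes.phenotype)


def _tabulate_indicator(ind: np.ndarray, phenotype: np.ndarray) -> ContingencyTable2x2:
    is_case = phenotype == CASE
    excluded = ind == MISSING
    return ContingencyTable2x2(
        cases_1=int((is_case & (ind == 1)).sum()),
        cases_0=int((is_case & (ind == 0)).sum()),
        controls_1=int((~is_case & (ind == 1)).sum()),
        controls_0=int((~is_case & (ind == 0)).sum()),
        n_excluded=int(excluded.sum()),
    )


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------


def _exact_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact integer enumeration of the support."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    num = sum(w for w in weights if w <= w_obs)
    return min(1.0, num / math.comb(r1 + r2, c1))


def fisher_exact_2x2(
    table: ContingencyTable2x2,
) -> tuple[float, float, float, float]:
    """Two-sided Fisher's exact test on a union's 2×2 table.

    Returns ``(p_value, odds_ratio, ci_low, ci_high)``.  The odds ratio is
    the sample cross-product ratio (cases_1·controls_0)/(cases_0·controls_1)
    with the Haldane–Anscombe +0.5 applied to all four cells only when some
    cell is zero, and a Woolf 95% CI, exp(log OR ± 1.96·sqrt(Σ 1/cell)), on
    the possibly-corrected cells.  A degenerate indicator (a zero column
    margin: everybody 0 or everybody 1) yields p = 1 with OR and CI NaN.

    Raises :class:`UntestableUnionError` when a row margin (all cases or all
    controls) is empty after missing-data exclusions.
    """
    a, b = table.cases_1, table.cases_0
    c, d = table.controls_1, table.controls_0
    if a + b == 0 or c + d == 0:
        raise UntestableUnionError(
            "union untestable: no cases or no controls remain after exclusions"
        )
    if a + c == 0 or b + d == 0:
        return 1.0, float("nan"), float("nan"), float("nan")

    if a + b + c + d <= _EXACT_TOTAL_LIMIT:
        p = _exact_two_sided_p(a, b, c, d)
    else:
        p = float(scipy.stats.fisher_exact([[a, b], [c, d]]).pvalue)

    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    log_or = math.log(cells[0] * cells[3] / (cells[1] * cells[2]))
    se = math.sqrt((1.0 / cells).sum())
    odds_ratio = math.exp(log_or)
    ci_low = math.exp(log_or - 1.959963984540054 * se)
    ci_high = math.exp(log_or + 1.959963984540054 * se)
    return p, odds_ratio, ci_low, ci_high


# ---------------------------------------------------------------------------
# Scan driver
# ---------------------------------------------------------------------------


def run_scan(
    genotypes: GenotypeTable,
    k_sizes: Iterable[int],
    schemes: Iterable[CodingScheme] = (CodingScheme.DOMINANT, CodingScheme.RECESSIVE),
    alpha: float = 0.05,
) -> ScanResult:
    """Test every (scheme, k, window) union and apply the Bonferroni rule.

    The per-test threshold is alpha divided by the testing burden computed
    from the scanned marker count — not from any external catalogue.
    Untestable unions (an empty case or control row) are recorded as
    skipped but still count toward the burden, which depends only on the
    marker count.  Deterministic: no randomness anywhere.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    ks = tuple(sorted(set(int(k) for k in k_sizes)))
    scheme_tuple = tuple(CodingScheme(s) for s in schemes)
    if genotypes.n_cases == 0 or genotypes.n_controls == 0:
        raise ValueError("scan requires at least one case and one control")
    n_tests = count_tests(genotypes.n_markers, ks, len(scheme_tuple))
    threshold = alpha / n_tests

    results: list[UnionTestResult] = []
    skipped: list[UnionSpec] = []
    for scheme in scheme_tuple:
        coded_all = code_dosage(genotypes.dosage, scheme)
        for k in ks:
            for spec in build_windows(genotypes.markers, k, scheme):
                ind = union_indicator_matrix(coded_all[:, list(spec.marker_indices)])
                table = _tabulate_indicator(ind, genotypes.phenotype)
                try:
                    p, oratio, lo, hi = fisher_exact_2x2(table)
                except UntestableUnionError:
                    skipped.append(spec)
                    continue
                results.append(UnionTestResult(spec, table, p, oratio, lo, hi))
    if not results:
        raise ValueError("scan produced no testable unions")
    return ScanResult(
        results=results,
        markers=list(genotypes.markers),
        alpha=alpha,
        threshold=threshold,
        n_tests=n_tests,
        k_sizes=ks,
        schemes=scheme_tuple,
        skipped=skipped,
    )
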