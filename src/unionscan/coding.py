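"""Logical-union genotype coding.

An individual's genotype at a biallelic marker, written with A the major and
B the minor allele, is reduced to a binary indicator under one of two genetic
models:

* dominant:  (AA, AB, BB) -> (0, 1, 1)  — "at least one copy of B"
* recessive: (AA, AB, BB) -> (0, 0, 1)  — "homozygous BB"

Additive coding (0, 1, 2) is the sum of the two and is never needed as a
separate scheme.  A *union* over a set of markers scores an individual 1 if
any member marker's coded value is 1, 0 if every member is 0, and missing
("?") otherwise.  Missingness propagates by Kleene three-valued OR:
``1 OR ? = 1`` (one observed hit settles the union) while ``0 OR ? = ?``
(an unobserved marker could still carry the hit).

The module also provides the closed-form union probability

    P(X ∪ Y) = P(X) + P(Y) − P(X)P(Y) − r·sqrt(P(X)(1−P(X))P(Y)(1−P(Y)))

where r is the pairwise correlation of the two event indicators.  The
counting implementation of the test never estimates these quantities; the
algebra is used for feasibility checks when simulating correlated markers
and as a reference identity (P(X ∪ X) = P(X)).
"""

from __future__ import annotations

import enum
import math
from typing import Sequence

import numpy as np

__all__ = [
    "MISSING",
    "CodingScheme",
    "InfeasibleCorrelationError",
    "code_marker",
    "code_dosage",
    "union_indicator",
    "union_indicator_matrix",
    "intersection_probability",
    "union_probability",
    "frechet_bounds",
]

#: Sentinel for a missing dosage or coded value.  Dosage and coded matrices
#: are small integer arrays; -1 marks "?" so that {0, 1, 2} stay as counts.
MISSING: int = -1


class CodingScheme(str, enum.Enum):
    """Genetic model used to binarize a minor-allele dosage."""

    DOMINANT = "dominant"
    RECESSIVE = "recessive"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class InfeasibleCorrelationError(ValueError):
    """A requested (P(X), P(Y), r) triple implies an impossible joint law."""


# ---------------------------------------------------------------------------
# Per-marker coding
# ---------------------------------------------------------------------------

# dosage -> coded value lookup, indexed by dosage+1 so MISSING=-1 maps to slot 0
_DOM_LUT = np.array([MISSING, 0, 1, 1], dtype=np.int8)
_REC_LUT = np.array([MISSING, 0, 0, 1], dtype=np.int8)


def _lut(scheme: CodingScheme) -> np.ndarray:
    scheme = CodingScheme(scheme)
    return _DOM_LUT if scheme is CodingScheme.DOMINANT else _REC_LUT


def code_marker(dosage: int, scheme: CodingScheme) -> int:
    """Binarize a single minor-allele dosage under the given scheme.

    Parameters
    ----------
    dosage
        Copies of the minor allele: 0, 1, 2, or :data:`MISSING`.
    scheme
        Dominant ((0,1,1)) or recessive ((0,0,1)) coding.

    Returns
    -------
    int
        0, 1, or :data:`MISSING`.
    """
    if dosage not in (0, 1, 2, MISSING):
        raise ValueError(f"invalid dosage {dosage!r}; expected 0, 1, 2 or MISSING")
    return int(_lut(scheme)[dosage + 1])


def code_dosage(dosage: np.ndarray, scheme: CodingScheme) -> np.ndarray:
    """Vectorized :func:`code_marker` over a dosage array.

    Accepts any integer array with entries in {0, 1, 2, MISSING} and returns
    an int8 array of the same shape with entries in {0, 1, MISSING}.
    """
    arr = np.asarray(dosage)
    if arr.size and (arr.min() < MISSING or arr.max() > 2):
        bad = arr[(arr < MISSING) | (arr > 2)].flat[0]
        raise ValueError(f"invalid dosage {bad!r}; expected 0, 1, 2 or MISSING")
    return _lut(scheme)[arr.astype(np.int64) + 1]


# ---------------------------------------------------------------------------
# Union indicator (Kleene three-valued OR)
# ---------------------------------------------------------------------------


def union_indicator(coded: Sequence[int]) -> int:
    """Collapse coded values over a union's markers into one indicator.

    Returns 1 if any element is 1; 0 if all elements are 0 with none
    missing; :data:`MISSING` otherwise.  A single-element union returns its
    input unchanged, so a union of one marker is single-marker analysis.
    """
    vals = list(coded)
    if not vals:
        raise ValueError("union_indicator requires at least one coded value")
    saw_missing = False
    for v in vals:
        if v == 1:
            return 1
        if v == MISSING:
            saw_missing = True
        elif v != 0:
            raise ValueError(f"invalid coded value {v!r}")
    return MISSING if saw_missing else 0


def union_indicator_matrix(coded: np.ndarray) -> np.ndarray:
    """Row-wise union indicator for an (n_individuals, n_markers) coded array.

    Vectorized equivalent of applying :func:`union_indicator` to each row.
    """
    arr = np.asarray(coded)
    if arr.ndim != 2 or arr.shape[1] == 0:
        raise ValueError("expected a non-empty 2-d coded array")
    any_hit = (arr == 1).any(axis=1)
    any_missing = (arr == MISSING).any(axis=1)
    out = np.zeros(arr.shape[0], dtype=np.int8)
    out[any_missing] = MISSING
    out[any_hit] = 1
    return out


# ---------------------------------------------------------------------------
# Union probability algebra
# ---------------------------------------------------------------------------


def frechet_bounds(p_x: float, p_y: float) -> tuple[float, float]:
    """Feasible range of P(X ∩ Y) given the two marginals."""
    return max(0.0, p_x + p_y - 1.0), min(p_x, p_y)


def intersection_probability(p_x: float, p_y: float, r: float) -> float:
    """P(X ∩ Y) implied by the marginals and the correlation coefficient.

    Raises :class:`InfeasibleCorrelationError` if the implied joint
    probability falls outside the Fréchet bounds.
    """
    for name, p in (("p_x", p_x), ("p_y", p_y)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}={p} outside [0, 1]")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"r={r} outside [-1, 1]")
    p11 = p_x * p_y + r * math.sqrt(p_x * (1.0 - p_x) * p_y * (1.0 - p_y))
    lo, hi = frechet_bounds(p_x, p_y)
    tol = 1e-12
    if p11 < lo - tol:
        raise InfeasibleCorrelationError(
            f"P(X∩Y)={p11:.6g} below lower Fréchet bound max(0, p_x+p_y-1)={lo:.6g} "
            f"for p_x={p_x}, p_y={p_y}, r={r}"
        )
    if p11 > hi + tol:
        raise InfeasibleCorrelationError(
            f"P(X∩Y)={p11:.6g} above upper Fréchet bound min(p_x, p_y)={hi:.6g} "
            f"for p_x={p_x}, p_y={p_y}, r={r}"
        )
    return min(max(p11, lo), hi)


def union_probability(p_x: float, p_y: float, r: float = 0.0) -> float:
    """Closed-form P(X ∪ Y) for correlated binary events.

    P(X ∪ Y) = P(X) + P(Y) − P(X)P(Y) − r·sqrt(P(X)(1−P(X))P(Y)(1−P(Y))).

    With r = 1 and p_x = p_y this reduces to P(X ∪ X) = P(X): a union of
    one marker is single-marker analysis.
    """
    p11 = intersection_probability(p_x, p_y, r)
    return min(1.0, max(0.0, p_x + p_y - p11))
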