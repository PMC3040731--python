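"""Reading and writing case-control genotype data in PLINK text format.

The in-memory currency for the whole package is :class:`GenotypeTable`: an
individuals × markers matrix of minor-allele dosages (0/1/2, with
:data:`~unionscan.coding.MISSING` for untyped cells), a marker map, and a
binary case/control phenotype.  Alleles are oriented so that dosage counts
the *minor* allele B, determined from the pooled sample (cases + controls);
an exact frequency tie is broken toward the lexicographically smaller allele
character so orientation is deterministic.

PLINK dialect: PED rows are family, individual, father, mother, sex,
phenotype, then two allele columns per marker; allele "0" is missing and a
half-missing genotype ("A 0") is treated as fully missing; phenotype 1 is
control, 2 is case, anything else drops the individual.  MAP rows are
chromosome, rsid, genetic distance, base-pair position.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .coding import MISSING

__all__ = [
    "FormatError",
    "MarkerInfo",
    "GenotypeTable",
    "orient_minor_allele",
    "read_ped_map",
    "write_ped_map",
    "write_scan_results",
    "CONTROL",
    "CASE",
]

logger = logging.getLogger(__name__)

CONTROL: int = 0
CASE: int = 1

_MISSING_ALLELE = "0"


class FormatError(ValueError):
    """Malformed PED/MAP input."""


@dataclass(frozen=True)
class MarkerInfo:
    """One biallelic marker on the map.

    ``allele_a``/``allele_b`` are the two allele characters in the order
    they were first observed; ``minor_is`` records which of the two is the
    minor allele after orientation ("a" or "b"), or None for a monomorphic
    marker whose second allele was never observed.
    """

    rsid: str
    chromosome: str
    position: int
    allele_a: str
    allele_b: str
    minor_is: str | None
    genetic_distance: float = 0.0

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"marker {self.rsid}: negative position {self.position}")
        if self.minor_is not in (None, "a", "b"):
            raise ValueError(f"marker {self.rsid}: minor_is must be 'a', 'b' or None")

    @property
    def monomorphic(self) -> bool:
        return self.minor_is is None

    @property
    def minor_allele(self) -> str | None:
        if self.minor_is is None:
            return None
        return self.allele_a if self.minor_is == "a" else self.allele_b

    @property
    def major_allele(self) -> str | None:
        if self.minor_is is None:
            return self.allele_a
        return self.allele_b if self.minor_is == "a" else self.allele_a


@dataclass
class GenotypeTable:
    """Individuals × markers minor-allele dosage matrix with phenotype.

    ``dosage`` is an int8 array with entries in {0, 1, 2, MISSING};
    column j counts copies of marker j's minor allele.  ``phenotype`` is an
    int8 array with entries CONTROL (0) / CASE (1).
    """

    dosage: np.ndarray
    markers: list[MarkerInfo]
    phenotype: np.ndarray
    sample_ids: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        n, m = self.dosage.shape
        if m != len(self.markers):
            raise ValueError(
                f"dosage has {m} columns but {len(self.markers)} markers given"
            )
        if self.phenotype.shape != (n,):
            raise ValueError("phenotype length does not match dosage rows")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage entries must be 0, 1, 2 or MISSING")
        if not np.isin(self.phenotype, (CONTROL, CASE)).all():
            raise ValueError("phenotype entries must be CONTROL or CASE")
        if not self.sample_ids:
            self.sample_ids = [("FAM", f"ID{i + 1}") for i in range(n)]

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    @property
    def n_cases(self) -> int:
        return int((self.phenotype == CASE).sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotype == CONTROL).sum())


# ---------------------------------------------------------------------------
# Orientation
# ---------------------------------------------------------------------------


def orient_minor_allele(raw_counts: dict[str, int], rsid: str = "?") -> str | None:
    """Pick the minor allele from pooled allele tallies (missing excluded).

    The minor allele is the strictly less frequent of the two observed
    alleles; an exact tie goes to the lexicographically smaller character.
    Returns None for a monomorphic marker (one observed allele): the minor
    allele is unknown and every dosage is 0.
    """
    counts = {a: c for a, c in raw_counts.items() if a != _MISSING_ALLELE and c > 0}
    if len(counts) > 2:
        raise FormatError(
            f"marker {rsid} is not biallelic: alleles {sorted(counts)} observed"
        )
    if not counts or len(counts) == 1:
        return None
    (a1, c1), (a2, c2) = sorted(counts.items())
    if c1 == c2:
        return a1  # tie: lexicographically smaller character
    return a1 if c1 < c2 else a2


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_map(map_path: Path) -> list[tuple[str, str, float, int]]:
    rows = []
    with open(map_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 4:
                raise FormatError(
                    f"{map_path}:{lineno}: expected 4 MAP columns, got {len(fields)}"
                )
            chrom, rsid, cm, pos = fields[0], fields[1], fields[2], fields[3]
            try:
                rows.append((chrom, rsid, float(cm), int(pos)))
            except ValueError as exc:
                raise FormatError(f"{map_path}:{lineno}: {exc}") from None
    return rows


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> GenotypeTable:
    """Load a PED/MAP pair into a minor-allele-oriented :class:`GenotypeTable`.

    Individuals with phenotype codes other than 1 (control) / 2 (case) are
    excluded with a logged count.  Raises :class:`FormatError` on a
    PED/MAP marker-count mismatch or a non-biallelic marker.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    map_rows = _read_map(map_path)
    m = len(map_rows)

    sample_ids: list[tuple[str, str]] = []
    phenos: list[int] = []
    genos: list[list[str]] = []  # per individual: 2m allele characters
    n_dropped = 0
    with open(ped_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} columns for "
                    f"{m} markers, got {len(fields)}"
                )
            pheno_code = fields[5]
            if pheno_code not in ("1", "2"):
                n_dropped += 1
                continue
            sample_ids.append((fields[0], fields[1]))
            phenos.append(CONTROL if pheno_code == "1" else CASE)
            genos.append(fields[6:])
    if n_dropped:
        logger.info(
            "excluded %d individual(s) with phenotype codes other than 1/2", n_dropped
        )
    if not genos:
        raise FormatError(f"{ped_path}: no individuals with phenotype 1/2")

    alleles = np.array(genos, dtype="U8").reshape(len(genos), m, 2)
    n = alleles.shape[0]
    dosage = np.full((n, m), MISSING, dtype=np.int8)
    markers: list[MarkerInfo] = []
    for j, (chrom, rsid, cm, pos) in enumerate(map_rows):
        col = alleles[:, j, :]
        half = (col == _MISSING_ALLELE).any(axis=1)  # half-missing -> missing
        observed = col[~half]
        tallies = Counter(observed.ravel().tolist())
        minor = orient_minor_allele(tallies, rsid=rsid)
        distinct = sorted(a for a in tallies if a != _MISSING_ALLELE)
        if minor is None:
            a_char = distinct[0] if distinct else _MISSING_ALLELE
            markers.append(
                MarkerInfo(rsid, chrom, pos, a_char, _MISSING_ALLELE, None, cm)
            )
            dosage[~half, j] = 0
            continue
        major = next(a for a in distinct if a != minor)
        # allele_a/allele_b in first-observed order within this column
        first = observed.ravel()[0]
        a_char = first
        b_char = major if first == minor else minor
        minor_is = "a" if a_char == minor else "b"
        markers.append(MarkerInfo(rsid, chrom, pos, a_char, b_char, minor_is, cm))
        dosage[~half, j] = (col[~half] == minor).sum(axis=1)

    return GenotypeTable(dosage, markers, np.array(phenos), sample_ids)


def write_ped_map(
    table: GenotypeTable, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write a :class:`GenotypeTable` back out as a PED/MAP pair.

    Dosage d is expanded as d copies of the minor allele plus 2-d copies of
    the major allele; MISSING becomes "0 0".  Monomorphic markers (minor
    allele unknown) are written as homozygous for their single allele.
    """
    with open(map_path, "w", encoding="utf-8") as fh:
        for mk in table.markers:
            fh.write(
                f"{mk.chromosome}\t{mk.rsid}\t{mk.genetic_distance:g}\t{mk.position}\n"
            )
    allele_pairs = []
    for mk in table.markers:
        minor = mk.minor_allele or mk.allele_a
        major = mk.major_allele or mk.allele_a
        allele_pairs.append(
            {
                0: f"{major} {major}",
                1: f"{major} {minor}",
                2: f"{minor} {minor}",
                MISSING: "0 0",
            }
        )
    with open(ped_path, "w", encoding="utf-8") as fh:
        for i in range(table.n_individuals):
            fam, iid = table.sample_ids[i]
            code = "2" if table.phenotype[i] == CASE else "1"
            cells = [fam, iid, "0", "0", "0", code]
            cells.extend(
                allele_pairs[j][int(table.dosage[i, j])]
                for j in range(table.n_markers)
            )
            fh.write(" ".join(cells) + "\n")


def write_scan_results(results: "ScanResult", out_path: str | Path) -> None:
    """Write scan results as a TSV, one row per union, sorted by p-value.

    Columns mirror the per-union test: coding scheme, union size, member
    rsids, location, the 2×2 counts with the missing-exclusion count, the
    exact p-value, odds ratio with 95% CI, and a significance flag at the
    scan's Bonferroni threshold.
    """
    if not results.results:
        raise ValueError("write_scan_results: empty result set")
    rows = []
    for res in results.results:
        spec = res.spec
        member = [results.markers[i] for i in spec.marker_indices]
        rows.append(
            {
                "coding": spec.scheme.value,
                "size": len(spec.marker_indices),
                "rsids": ",".join(mk.rsid for mk in member),
                "chromosome": spec.chromosome,
                "start_bp": member[0].position,
                "end_bp": member[-1].position,
                "cases_1": res.table.cases_1,
                "cases_0": res.table.cases_0,
                "controls_1": res.table.controls_1,
                "controls_0": res.table.controls_0,
                "n_excluded_missing": res.table.n_excluded,
                "p_value": res.p_value,
                "OR": res.odds_ratio,
                "CI_low": res.ci_low,
                "CI_high": res.ci_high,
                "significant": bool(res.p_value <= results.threshold),
            }
        )
    frame = pd.DataFrame(rows).sort_values("p_value", kind="stable", na_position="last")
    frame.to_csv(out_path, sep="\t", index=False, na_rep="NA")
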