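import numpy as np
import pytest

from unionscan import MISSING, CASE, CONTROL, GenotypeTable, MarkerInfo


@pytest.fixture
def four_individual_files(tmp_path):
    """2 cases (T C / T T) and 2 controls (C C / C C) at one marker.

    Pooled tallies are T:3, C:5, so T is the minor allele; case dosages are
    (1, 2) and control dosages (0, 0).
    """
    ped = tmp_path / "four.ped"
    ped.write_text(
        "F1 I1 0 0 1 2 T C\n"
        "F1 I2 0 0 1 2 T T\n"
        "F2 I3 0 0 2 1 C C\n"
        "F2 I4 0 0 2 1 C C\n"
    )
    map_ = tmp_path / "four.map"
    map_.write_text("1 rs1 0 100\n")
    return ped, map_


def random_genotype_table(
    rng: np.random.Generator,
    n: int = 40,
    m: int = 12,
    maf: float = 0.3,
    missing_rate: float = 0.0,
    chromosomes: tuple[str, ...] = ("1",),
) -> GenotypeTable:
    """Random table with Hardy-Weinberg-ish dosages and a balanced phenotype."""
    dosage = rng.binomial(2, maf, size=(n, m)).astype(np.int8)
    if missing_rate > 0:
        dosage[rng.random((n, m)) < missing_rate] = MISSING
    markers = []
    per_chrom = (m + len(chromosomes) - 1) // len(chromosomes)
    for j in range(m):
        chrom = chromosomes[min(j // per_chrom, len(chromosomes) - 1)]
        markers.append(MarkerInfo(f"rs{j + 1}", chrom, 1000 * (j + 1), "A", "B", "b"))
    phenotype = np.array([CASE, CONTROL] * (n // 2) + [CASE] * (n % 2), dtype=np.int8)
    return GenotypeTable(dosage, markers, phenotype)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
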