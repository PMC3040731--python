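"""Monte-Carlo validity and power study for the union test.

The generator reproduces the study design of the simulation experiments:
coded genotypes (already-binarized marker indicators) are drawn Bernoulli
with given per-marker frequencies for 938 cases and 863 controls, disease
status follows a logistic model

    P(disease | x) = expit( Σ_j log(OR_j)·x_j + Σ_(i,j) log(OR_epi)·x_i·x_j )

with intercept 0, and each experiment runs 1,000 independent replicates.
Correlated marker pairs are drawn from the bivariate Bernoulli law whose
joint probability comes from the union algebra,
p11 = f_i·f_j + r·sqrt(f_i(1−f_i)·f_j(1−f_j)); when only r² is given the
coupling phase r = +sqrt(r²) is assumed.  Differential correlation (the
case group correlated differently from the control group, with identical
marginal frequencies) is realized by drawing each group directly from its
own joint law, with logistic retention applied on top when any odds ratio
differs from 1.

Group quotas are filled by rejection: individuals are generated in batches
and assigned to whichever group their sampled status belongs to until both
quotas are met; overflow is discarded.  With intercept 0 roughly half of
all draws become cases, so filling 938 cases / 863 controls costs about
2,000 draws per replicate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .coding import (
    CodingScheme,
    code_dosage,
    intersection_probability,
    union_indicator_matrix,
)
from .io_formats import CASE, CONTROL, GenotypeTable, MarkerInfo
from .scan import _tabulate_indicator, fisher_exact_2x2

__all__ = [
    "SimulationSpec",
    "PowerEstimate",
    "GenerationError",
    "sample_coded_genotypes",
    "assign_status_and_fill_quota",
    "estimate_rejection_rate",
    "run_figure1_suite",
    "replicate_to_genotype_table",
    "read_spec_file",
    "FIGURE1_PANELS",
    "DEFAULT_FREQ_GRID",
]

_BATCH = 4096

#: Minor multi-locus genotype frequencies swept by the panel suite.
DEFAULT_FREQ_GRID: tuple[float, ...] = (0.01, 0.02, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)

FIGURE1_PANELS = ("A", "B", "C", "D", "E", "F", "G", "H")


class GenerationError(RuntimeError):
    """Quota filling failed within the draw budget (degenerate spec)."""


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one simulation experiment.

    Correlations are given as signed correlation coefficients r; use
    ``r = +sqrt(r2)`` for designs stated in terms of r².  Each marker may
    appear in at most one (plain or differential) correlated pair.
    ``differential_correlation`` entries are ((i, j), r_cases, r_controls).
    """

    n_cases: int = 938
    n_controls: int = 863
    marker_freqs: tuple[float, ...] = (0.5,)
    odds_ratios: tuple[float, ...] | None = None
    epistasis_pairs: tuple[tuple[tuple[int, int], float], ...] = ()
    correlation_pairs: tuple[tuple[tuple[int, int], float], ...] = ()
    differential_correlation: tuple[tuple[tuple[int, int], float, float], ...] = ()
    replicates: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("both group sizes must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not all(0.0 < f < 1.0 for f in self.marker_freqs):
            raise ValueError("marker frequencies must lie strictly in (0, 1)")
        ors = self.effective_odds_ratios()
        if len(ors) != self.n_markers:
            raise ValueError("odds_ratios length must match marker_freqs")
        if not all(r > 0 for r in ors):
            raise ValueError("odds ratios must be positive")
        paired: set[int] = set()
        for (i, j), *_ in (*self.correlation_pairs, *self.differential_correlation):
            if i == j:
                raise ValueError("a correlated pair needs two distinct markers")
            if i in paired or j in paired:
                raise ValueError(f"marker {i if i in paired else j} in two pairs")
            paired.update((i, j))
        # every implied joint law must satisfy the Fréchet bounds
        for (i, j), r in self.correlation_pairs:
            intersection_probability(self.marker_freqs[i], self.marker_freqs[j], r)
        for (i, j), r_ca, r_co in self.differential_correlation:
            intersection_probability(self.marker_freqs[i], self.marker_freqs[j], r_ca)
            intersection_probability(self.marker_freqs[i], self.marker_freqs[j], r_co)

    @property
    def n_markers(self) -> int:
        return len(self.marker_freqs)

    def effective_odds_ratios(self) -> tuple[float, ...]:
        if self.odds_ratios is None:
            return (1.0,) * self.n_markers
        return tuple(self.odds_ratios)

    def is_null(self) -> bool:
        return (
            all(o == 1.0 for o in self.effective_odds_ratios())
            and all(o == 1.0 for _, o in self.epistasis_pairs)
            and not self.differential_correlation
        )


@dataclass(frozen=True)
class PowerEstimate:
    """Monte-Carlo rejection proportion with its binomial standard error."""

    rejection_rate: float
    mc_stderr: float
    replicates_used: int

    @classmethod
    def from_rejections(cls, n_reject: int, replicates: int) -> "PowerEstimate":
        rate = n_reject / replicates
        return cls(rate, math.sqrt(rate * (1.0 - rate) / replicates), replicates)


# ---------------------------------------------------------------------------
# Genotype sampling
# ---------------------------------------------------------------------------


def _pair_r(spec: SimulationSpec, group: str) -> dict[tuple[int, int], float]:
    """Per-pair correlation coefficient effective for the given stream."""
    rs = {pair: r for pair, r in spec.correlation_pairs}
    for pair, r_cases, r_controls in spec.differential_correlation:
        rs[pair] = r_cases if group == "case-stream" else r_controls
    return rs


def sample_coded_genotypes(
    spec: SimulationSpec,
    group: str,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw an n × m matrix of coded genotypes in {0, 1}.

    Unpaired markers are independent Bernoulli(f_j).  Each correlated pair
    (i, j) is drawn from the bivariate Bernoulli law with
    p11 = f_i f_j + r·sqrt(f_i(1−f_i) f_j(1−f_j)); the stream argument
    selects the group-specific r for differential-correlation pairs.
    """
    if group not in ("case-stream", "control-stream"):
        raise ValueError(f"unknown stream {group!r}")
    f = np.asarray(spec.marker_freqs)
    x = (rng.random((n, spec.n_markers)) < f).astype(np.int8)
    for (i, j), r in _pair_r(spec, group).items():
        if r == 0.0:
            continue
        p11 = intersection_probability(f[i], f[j], r)
        # conditional law of x_j given x_i keeps the marginals exact
        p_j_given_1 = p11 / f[i]
        p_j_given_0 = (f[j] - p11) / (1.0 - f[i])
        cond = np.where(x[:, i] == 1, p_j_given_1, p_j_given_0)
        x[:, j] = rng.random(n) < cond
    return x


def _disease_probability(spec: SimulationSpec, x: np.ndarray) -> np.ndarray:
    beta = np.log(spec.effective_odds_ratios())
    eta = x @ beta
    for (i, j), or_epi in spec.epistasis_pairs:
        eta = eta + math.log(or_epi) * (x[:, i] * x[:, j])
    return expit(eta)


def assign_status_and_fill_quota(
    spec: SimulationSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one replicate: exactly n_cases cases and n_controls controls.

    Returns ``(x, phenotype)`` with cases stacked before controls.  Without
    differential correlation, individuals are drawn from the common joint
    law, status is sampled from the logistic model, and each draw fills
    whichever quota its status belongs to.  With differential correlation,
    each group's genotypes are drawn from its own joint law and the
    logistic model acts by retention within the stream (accept a case-stream
    draw with probability P(disease | x), a control-stream draw with the
    complement), which leaves the marginal frequencies of the two groups
    equal when all odds ratios are 1.
    """
    quota = {"case-stream": spec.n_cases, "control-stream": spec.n_controls}
    pools: dict[str, list[np.ndarray]] = {k: [] for k in quota}
    filled = {k: 0 for k in quota}
    differential = bool(spec.differential_correlation)
    pure_null = spec.is_null()

    max_draws = max(200_000, 400 * (spec.n_cases + spec.n_controls))
    drawn = 0
    while any(filled[k] < quota[k] for k in quota):
        if drawn > max_draws:
            rates = {k: filled[k] / max(drawn, 1) for k in quota}
            raise GenerationError(
                f"quota unreachable after {drawn} draws; acceptance rates {rates}"
            )
        if not differential:
            x = sample_coded_genotypes(spec, "case-stream", _BATCH, rng)
            drawn += _BATCH
            p = 0.5 if pure_null else _disease_probability(spec, x)
            is_case = rng.random(_BATCH) < p
            for key, mask in (("case-stream", is_case), ("control-stream", ~is_case)):
                need = quota[key] - filled[key]
                if need > 0:
                    take = x[mask][:need]
                    pools[key].append(take)
                    filled[key] += take.shape[0]
        else:
            for key in quota:
                need = quota[key] - filled[key]
                if need <= 0:
                    continue
                x = sample_coded_genotypes(spec, key, _BATCH, rng)
                drawn += _BATCH
                if pure_null:
                    keep = x
                else:
                    p = _disease_probability(spec, x)
                    accept = p if key == "case-stream" else 1.0 - p
                    keep = x[rng.random(_BATCH) < accept]
                pools[key].append(keep[:need])
                filled[key] += min(keep.shape[0], need)

    cases = np.concatenate(pools["case-stream"])
    controls = np.concatenate(pools["control-stream"])
    x_all = np.concatenate([cases, controls])
    phenotype = np.concatenate(
        [
            np.full(spec.n_cases, CASE, dtype=np.int8),
            np.full(spec.n_controls, CONTROL, dtype=np.int8),
        ]
    )
    return x_all, phenotype


def replicate_to_genotype_table(
    x: np.ndarray, phenotype: np.ndarray, chromosome: str = "1"
) -> GenotypeTable:
    """Package a coded replicate as a GenotypeTable.

    Convention: coded value 1 becomes the minor-allele homozygote (dosage
    2) and coded value 0 the major-allele homozygote (dosage 0), so both
    dominant and recessive coding recover the coded value exactly.
    """
    x = np.asarray(x, dtype=np.int8)
    markers = [
        MarkerInfo(f"sim{j + 1}", chromosome, j + 1, "A", "B", "b")
        for j in range(x.shape[1])
    ]
    return GenotypeTable(2 * x, markers, phenotype)


# ---------------------------------------------------------------------------
# Rejection-rate estimation
# ---------------------------------------------------------------------------


def estimate_rejection_rate(
    spec: SimulationSpec,
    union_size: int | None = None,
    scheme: CodingScheme = CodingScheme.DOMINANT,
) -> PowerEstimate:
    """Monte-Carlo rejection rate of the single union over the spec's markers.

    For each replicate one dataset is generated, the k-marker union over
    the first ``union_size`` markers (default: all of them) is formed, and
    Fisher's exact test is applied at the spec's per-comparison alpha.
    Deterministic given ``spec.seed``.
    """
    k = spec.n_markers if union_size is None else int(union_size)
    if not 1 <= k <= spec.n_markers:
        raise ValueError(f"union_size {k} outside 1..{spec.n_markers}")
    rng = np.random.default_rng(spec.seed)
    n_reject = 0
    for rep in range(spec.replicates):
        try:
            x, phenotype = assign_status_and_fill_quota(spec, rng)
        except GenerationError as exc:
            raise GenerationError(f"replicate {rep}: {exc}") from exc
        coded = code_dosage(2 * x[:, :k], scheme)
        ind = union_indicator_matrix(coded)
        table = _tabulate_indicator(ind, phenotype)
        p, *_ = fisher_exact_2x2(table)
        if p <= spec.alpha:
            n_reject += 1
    return PowerEstimate.from_rejections(n_reject, spec.replicates)


# ---------------------------------------------------------------------------
# Panel suite
# ---------------------------------------------------------------------------

_R08 = math.sqrt(0.8)  # coupling-phase r for r² = 0.8


def _panel_configs(panel: str) -> list[dict]:
    """Parameterizations for each validity/power panel (A..H).

    Every config dict holds the union size k, per-marker odds ratios (or a
    callable-free constant), optional correlation / epistasis settings, and
    a human-readable label for the output table.
    """
    if panel == "A":
        return [{"label": f"null k={k}", "k": k, "ors": (1.0,) * k} for k in range(1, 6)]
    if panel == "B":
        return [{"label": f"OR=1.5 k={k}", "k": k, "ors": (1.5,) * k} for k in range(1, 6)]
    if panel == "C":
        return [{"label": f"OR=2 k={k}", "k": k, "ors": (2.0,) * k} for k in range(1, 6)]
    if panel == "D":
        return [
            {"label": f"opposing {a}/{b}", "k": 2, "ors": (a, b)}
            for a, b in ((2.0, 0.5), (1.5, 0.67), (1.0, 1.0))
        ]
    if panel == "E":
        return [
            {"label": f"one OR={o} + 4 null", "k": 5, "ors": (o, 1.0, 1.0, 1.0, 1.0)}
            for o in (2.0, 1.5, 1.0)
        ]
    if panel == "F":
        out = []
        for o in (2.0, 1.5, 1.0):
            for r2 in (0.0, 0.8):
                out.append(
                    {
                        "label": f"OR={o} r2={r2}",
                        "k": 2,
                        "ors": (o, o),
                        "corr": (((0, 1), math.sqrt(r2)),) if r2 else (),
                    }
                )
        return out
    if panel == "G":
        return [
            {
                "label": f"epistasis OR_epi={oe}",
                "k": 2,
                "ors": (1.0, 1.0),
                "epi": (((0, 1), oe),),
            }
            for oe in (1.0, 2.0, 0.5)
        ]
    if panel == "H":
        out = []
        for o in (2.0, 1.0):
            for r2_ca, r2_co in ((0.8, 0.0), (0.0, 0.8)):
                out.append(
                    {
                        "label": f"OR={o} case r2={r2_ca} control r2={r2_co}",
                        "k": 2,
                        "ors": (o, o),
                        "diff": (((0, 1), math.sqrt(r2_ca), math.sqrt(r2_co)),),
                    }
                )
        return out
    raise ValueError(f"unknown panel {panel!r}; expected one of {FIGURE1_PANELS}")


def run_figure1_suite(
    panel: str,
    grid: Sequence[float] = DEFAULT_FREQ_GRID,
    replicates: int = 1000,
    seed: int = 0,
    n_cases: int = 938,
    n_controls: int = 863,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run one validity/power panel over a minor-genotype-frequency grid.

    Returns a tidy frame with one row per (configuration, frequency):
    columns panel, config, f, k, rejection_rate, mc_stderr, replicates.
    Per-configuration seeds are spawned from ``seed`` so results are
    reproducible and configurations are independent.
    """
    panel = panel.upper()
    configs = _panel_configs(panel)
    seeds = np.random.SeedSequence(seed).generate_state(len(configs) * len(grid))
    rows = []
    idx = 0
    for cfg in configs:
        for f in grid:
            spec = SimulationSpec(
                n_cases=n_cases,
                n_controls=n_controls,
                marker_freqs=(float(f),) * cfg["k"],
                odds_ratios=cfg["ors"],
                correlation_pairs=cfg.get("corr", ()),
                epistasis_pairs=cfg.get("epi", ()),
                differential_correlation=cfg.get("diff", ()),
                replicates=replicates,
                alpha=alpha,
                seed=int(seeds[idx] % (2**31)),
            )
            est = estimate_rejection_rate(spec)
            rows.append(
                {
                    "panel": panel,
                    "config": cfg["label"],
                    "f": float(f),
                    "k": cfg["k"],
                    "rejection_rate": est.rejection_rate,
                    "mc_stderr": est.mc_stderr,
                    "replicates": est.replicates_used,
                }
            )
            idx += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spec files
# ---------------------------------------------------------------------------


def read_spec_file(path: str | Path) -> SimulationSpec:
    """Load a SimulationSpec from a JSON file.

    Keys mirror the dataclass fields; pair lists use plain nested arrays,
    e.g. ``"correlation_pairs": [[[0, 1], 0.894]]``.
    """
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)

    def _pairs(key: str, width: int):
        out = []
        for entry in raw.get(key, []):
            (i, j), *rest = entry[0], *entry[1:]
            if len(rest) != width:
                raise ValueError(f"{key} entries need {width} value(s) after the pair")
            out.append(((int(i), int(j)), *map(float, rest)))
        return tuple(out)

    return SimulationSpec(
        n_cases=int(raw.get("n_cases", 938)),
        n_controls=int(raw.get("n_controls", 863)),
        marker_freqs=tuple(map(float, raw["marker_freqs"])),
        odds_ratios=(
            tuple(map(float, raw["odds_ratios"])) if "odds_ratios" in raw else None
        ),
        epistasis_pairs=_pairs("epistasis_pairs", 1),
        correlation_pairs=_pairs("correlation_pairs", 1),
        differential_correlation=_pairs("differential_correlation", 2),
        replicates=int(raw.get("replicates", 1000)),
        alpha=float(raw.get("alpha", 0.05)),
        seed=int(raw.get("seed", 0)),
    )
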