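"""Synthetic Ct matrices with controlled stability structure, plus embedded
benchmark fixtures.

The simulator emulates the motivating study design: nine candidate reference
genes measured in four goat tissues under two dietary treatments, with
biological replicates and within-run technical triplicates.  Each well's Ct is

    Ct = baseline_g + tissueShift_g(tissue) + treatmentEffect_g * 1[treated]
         + bioNoise + techNoise

with the tissue shift drawn once per (gene, tissue), biological noise per
(gene, tissue, treatment, animal) and technical noise per well, all Gaussian
on the Ct scale (log-scale expression noise, the conventional qPCR error
model).  A ground-truth record retains every drawn effect and the implied
total-variation order of the genes, so recovery of the designed stability
ranking can be tested end to end.

Two fixture families are embedded verbatim as plain literals:

* :func:`table3_fixture` — the published per-(gene, tissue, treatment) mean
  Ct table (9 genes x 8 condition columns) from the goat study, for smoke
  tests and documentation examples;
* :func:`tables4to8_fixture` — the six stability-program ranking columns per
  tissue from the same study (9 genes x 6 lists), the benchmark inputs for
  consensus aggregation, plus the published consensus orderings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ct_data import CtMatrix, SampleAnnotation
from .rank_aggregation import RankMatrix

GENES = ["GAPDH", "ACTB", "18s rRNA", "RPS18", "HSP-90", "ALAS", "HMBS", "ACAC", "B2M"]
TISSUES = ["liver", "visceral_fat", "subcutaneous_fat", "ll_muscle"]
TREATMENTS = ["control", "chromium"]

# ---------------------------------------------------------------------------
# Embedded fixtures: mean Ct +/- SEM per (gene, treatment) across the four
# tissues (liver, visceral fat, subcutaneous fat, longissimus muscle).
# ---------------------------------------------------------------------------

_TABLE3_MEANS: dict[str, dict[str, list[float]]] = {
    "HSP-90": {"control": [30.47, 29.06, 27.11, 30.83], "chromium": [30.13, 30.13, 27.33, 28.81]},
    "ALAS": {"control": [31.37, 28.63, 26.58, 30.01], "chromium": [30.15, 29.91, 27.56, 28.50]},
    "B2M": {"control": [32.10, 25.70, 26.82, 29.60], "chromium": [29.43, 27.79, 26.46, 25.67]},
    "RPS18": {"control": [28.85, 24.23, 25.62, 27.53], "chromium": [28.58, 25.63, 23.96, 25.65]},
    "GAPDH": {"control": [23.82, 26.14, 22.83, 26.42], "chromium": [25.72, 26.90, 23.94, 23.54]},
    "ACAC": {"control": [30.12, 27.99, 26.36, 29.01], "chromium": [30.04, 30.35, 26.58, 29.76]},
    "ACTB": {"control": [31.27, 28.94, 25.91, 28.07], "chromium": [29.43, 29.27, 27.38, 23.74]},
    "18s rRNA": {"control": [26.71, 25.27, 23.44, 25.85], "chromium": [26.97, 24.70, 23.09, 25.87]},
    "HMBS": {"control": [28.12, 27.33, 24.69, 27.31], "chromium": [26.64, 28.35, 25.75, 26.12]},
}

_TABLE3_SEMS: dict[str, dict[str, list[float]]] = {
    "HSP-90": {"control": [0.067, 0.116, 0.179, 0.009], "chromium": [0.055, 0.283, 0.223, 0.087]},
    "ALAS": {"control": [0.378, 0.167, 0.104, 0.032], "chromium": [0.544, 0.196, 0.095, 0.046]},
    "B2M": {"control": [0.237, 0.012, 0.038, 0.179], "chromium": [0.450, 0.153, 0.144, 0.058]},
    "RPS18": {"control": [0.381, 0.023, 0.012, 0.095], "chromium": [0.029, 0.026, 0.023, 0.061]},
    "GAPDH": {"control": [0.061, 0.020, 0.286, 0.251], "chromium": [0.017, 0.185, 0.023, 0.066]},
    "ACAC": {"control": [0.009, 0.153, 0.092, 0.156], "chromium": [0.061, 0.294, 0.078, 0.346]},
    "ACTB": {"control": [0.785, 0.393, 0.110, 0.014], "chromium": [0.012, 0.147, 0.081, 0.026]},
    "18s rRNA": {"control": [0.153, 0.003, 0.058, 0.084], "chromium": [0.101, 0.300, 0.306, 0.052]},
    "HMBS": {"control": [0.222, 0.196, 0.052, 0.121], "chromium": [0.534, 0.274, 0.081, 0.064]},
}

# ---------------------------------------------------------------------------
# Embedded fixtures: the six stability-program ranking columns per tissue
# (most stable first) and the published consensus orderings.  The pooled
# table's "ACT-B" spelling is normalized to "ACTB".
# ---------------------------------------------------------------------------

PROGRAM_COLUMNS = [
    "genex_normfinder", "genex_genorm", "normfinder", "bestkeeper", "genorm", "qbaseplus",
]

_RANK_TABLES: dict[str, dict[str, list[str]]] = {
    "liver": {
        "genex_normfinder": ["HSP-90", "ACAC", "HMBS", "ALAS", "18s rRNA", "ACTB", "B2M", "RPS18", "GAPDH"],
        "genex_genorm": ["HSP-90", "ACAC", "18s rRNA", "ALAS", "HMBS", "ACTB", "B2M", "RPS18", "GAPDH"],
        "normfinder": ["HSP-90", "ACAC", "HMBS", "ALAS", "18s rRNA", "ACTB", "B2M", "RPS18", "GAPDH"],
        "bestkeeper": ["ACAC", "HSP-90", "18s rRNA", "ALAS", "HMBS", "GAPDH", "ACTB", "B2M", "RPS18"],
        "genorm": ["ACAC", "HSP-90", "18s rRNA", "ALAS", "HMBS", "ACTB", "B2M", "RPS18", "GAPDH"],
        "qbaseplus": ["ALAS", "HMBS", "HSP-90", "ACTB", "ACAC", "18s rRNA", "B2M", "RPS18", "GAPDH"],
    },
    "visceral_fat": {
        "genex_normfinder": ["RPS18", "ALAS", "HSP-90", "HMBS", "GAPDH", "B2M", "ACTB", "ACAC", "18s rRNA"],
        "genex_genorm": ["ALAS", "HMBS", "HSP-90", "RPS18", "GAPDH", "B2M", "ACAC", "ACTB", "18s rRNA"],
        "normfinder": ["ALAS", "HSP-90", "GAPDH", "HMBS", "RPS18", "ACTB", "B2M", "ACAC", "18s rRNA"],
        "bestkeeper": ["18s rRNA", "ACTB", "GAPDH", "HMBS", "HSP-90", "ALAS", "RPS18", "B2M", "ACAC"],
        "genorm": ["HSP-90", "HMBS", "ALAS", "RPS18", "GAPDH", "ACTB", "B2M", "ACAC", "18s rRNA"],
        "qbaseplus": ["HSP-90", "HMBS", "ALAS", "RPS18", "GAPDH", "ACTB", "B2M", "ACAC", "18s rRNA"],
    },
    "subcutaneous_fat": {
        "genex_normfinder": ["ALAS", "HSP-90", "HMBS", "18s rRNA", "ACAC", "B2M", "GAPDH", "ACTB", "RPS18"],
        "genex_genorm": ["HSP-90", "ALAS", "ACAC", "18s rRNA", "HMBS", "GAPDH", "B2M", "ACTB", "RPS18"],
        "normfinder": ["ALAS", "HSP-90", "HMBS", "ACAC", "18s rRNA", "B2M", "GAPDH", "ACTB", "RPS18"],
        "bestkeeper": ["HMBS", "18s rRNA", "HSP-90", "ALAS", "ACAC", "GAPDH", "ACTB", "B2M", "RPS18"],
        "genorm": ["HSP-90", "ALAS", "HMBS", "ACAC", "B2M", "18s rRNA", "GAPDH", "ACTB", "RPS18"],
        "qbaseplus": ["ALAS", "HSP-90", "HMBS", "18s rRNA", "ACAC", "B2M", "GAPDH", "ACTB", "RPS18"],
    },
    "ll_muscle": {
        "genex_normfinder": ["ACAC", "HSP-90", "B2M", "ALAS", "HMBS", "18s rRNA", "GAPDH", "ACTB", "RPS18"],
        "genex_genorm": ["ALAS", "GAPDH", "ACTB", "HMBS", "ACAC", "HSP-90", "B2M", "18s rRNA", "RPS18"],
        "normfinder": ["ACAC", "HSP-90", "B2M", "ALAS", "HMBS", "18s rRNA", "GAPDH", "ACTB", "RPS18"],
        "bestkeeper": ["ACAC", "B2M", "HSP-90", "18s rRNA", "ALAS", "HMBS", "GAPDH", "ACTB", "RPS18"],
        "genorm": ["HMBS", "GAPDH", "ALAS", "HSP-90", "ACAC", "18s rRNA", "B2M", "ACTB", "RPS18"],
        "qbaseplus": ["HSP-90", "ACAC", "ALAS", "HMBS", "GAPDH", "18s rRNA", "B2M", "ACTB", "RPS18"],
    },
    "all": {
        "genex_normfinder": ["ALAS", "HSP-90", "HMBS", "18s rRNA", "ACAC", "B2M", "GAPDH", "ACTB", "RPS18"],
        "genex_genorm": ["HSP-90", "ALAS", "ACAC", "18s rRNA", "HMBS", "GAPDH", "B2M", "ACTB", "RPS18"],
        "normfinder": ["ALAS", "HSP-90", "HMBS", "ACAC", "18s rRNA", "B2M", "GAPDH", "ACTB", "RPS18"],
        "bestkeeper": ["HMBS", "18s rRNA", "HSP-90", "ALAS", "ACAC", "GAPDH", "ACTB", "B2M", "RPS18"],
        "genorm": ["HSP-90", "ALAS", "HMBS", "ACAC", "B2M", "18s rRNA", "GAPDH", "ACTB", "RPS18"],
        "qbaseplus": ["ALAS", "HSP-90", "HMBS", "18s rRNA", "ACAC", "B2M", "GAPDH", "ACTB", "RPS18"],
    },
}

_PUBLISHED_CONSENSUS: dict[str, list[str]] = {
    "liver": ["HSP-90", "ACAC", "18s rRNA", "ALAS", "HMBS", "ACTB", "B2M", "RPS18", "GAPDH"],
    "visceral_fat": ["HSP-90", "HMBS", "ALAS", "RPS18", "GAPDH", "ACTB", "B2M", "ACAC", "18s rRNA"],
    "subcutaneous_fat": ["ALAS", "HSP-90", "HMBS", "18s rRNA", "ACAC", "B2M", "GAPDH", "ACTB", "RPS18"],
    "ll_muscle": ["ACAC", "HSP-90", "ALAS", "B2M", "HMBS", "18s rRNA", "GAPDH", "ACTB", "RPS18"],
    "all": ["ALAS", "HSP-90", "HMBS", "18s rRNA", "ACAC", "B2M", "GAPDH", "ACTB", "RPS18"],
}

FIXTURE_TISSUES = list(_RANK_TABLES)


def table3_fixture() -> CtMatrix:
    """The benchmark mean-Ct table: 9 genes x 8 (tissue, treatment) columns.

    Values are replicate-collapsed condition means, useful for smoke tests
    and worked examples; they do not stand in for replicate-level data.
    """
    samples = []
    cols: dict[str, list[float]] = {}
    for tissue in TISSUES:
        for treatment in TREATMENTS:
            sid = f"{tissue}:{treatment}"
            samples.append(SampleAnnotation(sid, tissue, treatment, 1, 0))
            ti = TISSUES.index(tissue)
            cols[sid] = [_TABLE3_MEANS[g][treatment][ti] for g in GENES]
    values = pd.DataFrame(cols, index=pd.Index(GENES, name="gene"))
    return CtMatrix(values, samples)


def table3_sems() -> pd.DataFrame:
    """Printed SEMs matching :func:`table3_fixture`'s layout."""
    cols = {}
    for tissue in TISSUES:
        for treatment in TREATMENTS:
            ti = TISSUES.index(tissue)
            cols[f"{tissue}:{treatment}"] = [_TABLE3_SEMS[g][treatment][ti] for g in GENES]
    return pd.DataFrame(cols, index=pd.Index(GENES, name="gene"))


def tables4to8_fixture(tissue: str, with_genorm_tie: bool = False) -> RankMatrix:
    """The six program ranking columns for one tissue (or ``'all'`` pooled).

    ``with_genorm_tie=True`` declares the top two positions of the geNorm
    column interchangeable, reflecting that the pairwise-variation model
    cannot separate its final two genes.
    """
    if tissue not in _RANK_TABLES:
        raise KeyError(f"unknown tissue {tissue!r}; expected one of {FIXTURE_TISSUES}")
    table = _RANK_TABLES[tissue]
    lists = [list(table[c]) for c in PROGRAM_COLUMNS]
    tie_groups = {}
    if with_genorm_tie:
        tie_groups = {PROGRAM_COLUMNS.index("genorm"): [(1, 2)]}
    return RankMatrix(items=sorted(lists[0]), lists=lists, names=list(PROGRAM_COLUMNS),
                      tie_groups=tie_groups)


def published_consensus(tissue: str) -> list[str]:
    """The benchmark's published consensus ordering for one tissue."""
    return list(_PUBLISHED_CONSENSUS[tissue])


# ---------------------------------------------------------------------------
# Simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSimSpec:
    """Generative parameters for one gene, all in Ct cycles."""

    name: str
    baseline_ct: float
    tissue_effect_sd: float
    treatment_effect: float
    residual_sd: float

    def __post_init__(self) -> None:
        if self.tissue_effect_sd < 0 or self.residual_sd < 0:
            raise ValueError(f"gene {self.name!r}: SDs must be >= 0")


@dataclass(frozen=True)
class SimSpec:
    """Full design of a simulated Ct experiment."""

    genes: tuple[GeneSimSpec, ...]
    tissues: tuple[str, ...] = tuple(TISSUES)
    treatments: tuple[str, ...] = tuple(TREATMENTS)
    biological_replicates: int = 3
    technical_replicates: int = 3
    technical_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.biological_replicates < 1 or self.technical_replicates < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.technical_sd < 0:
            raise ValueError("technical_sd must be >= 0")

    def implied_total_sd(self, gene: GeneSimSpec) -> float:
        """SD of a gene's replicate-collapsed Ct implied by the generative
        model: tissue, treatment, biological and averaged technical noise in
        quadrature.  The balanced two-point treatment contrast contributes
        ``effect**2 * p * (1 - p)`` with p the treated fraction."""
        p = 1.0 - 1.0 / len(self.treatments)
        treat_var = gene.treatment_effect**2 * p * (1.0 - p)
        return float(np.sqrt(
            gene.tissue_effect_sd**2 + treat_var + gene.residual_sd**2
            + self.technical_sd**2 / self.technical_replicates))


def default_sim_spec(seed: int = 0) -> SimSpec:
    """The study-condition simulator defaults, derived from the benchmark
    mean-Ct table: per-gene baseline = grand mean Ct; tissue-effect SD = SD
    of the gene's four tissue means; treatment effect = mean chromium-minus-
    control shift; biological residual SD = sqrt(3) x mean printed SEM
    (triplicate SEM back-converted to per-replicate SD).  3 biological x 3
    technical replicates per condition, 0.15-cycle technical scatter."""
    genes = []
    for g in GENES:
        ctrl = np.array(_TABLE3_MEANS[g]["control"])
        chrom = np.array(_TABLE3_MEANS[g]["chromium"])
        sems = np.concatenate([_TABLE3_SEMS[g]["control"], _TABLE3_SEMS[g]["chromium"]])
        tissue_means = (ctrl + chrom) / 2.0
        genes.append(GeneSimSpec(
            name=g,
            baseline_ct=float(np.mean([ctrl, chrom])),
            tissue_effect_sd=float(np.std(tissue_means, ddof=1)),
            treatment_effect=float(np.mean(chrom - ctrl)),
            residual_sd=float(np.sqrt(3.0) * np.mean(sems)),
        ))
    return SimSpec(genes=tuple(genes), seed=seed)


def designed_best_gene_spec(seed: int = 0, best_gene: str = "HSP-90",
                            sd_ratio: float = 10.0,
                            noisy_residual_sd: float = 1.0) -> SimSpec:
    """The controlled rank-recovery benchmark: one gene with ``sd_ratio``
    times smaller noise SD than every other gene.

    The separation is placed entirely in the per-sample residual component
    (tissue and treatment effects zero), for two reasons.  First, per-gene
    tissue shifts are drawn from only four tissues, so a gene's realized
    between-tissue spread is a 3-degree-of-freedom random quantity and the
    generated data's true stability order would frequently contradict the
    designed one — a broken benchmark rather than a harder one.  Second, a
    deterministic treatment response shared by the unstable genes makes them
    co-regulated, which pairwise-ratio methods cancel by construction (the
    well-known co-regulation blind spot), again decoupling the designed
    order from what any stability method could see.  Independent residual
    noise is the component every method is supposed to measure, with
    high-degree-of-freedom realized SDs that concentrate near their design
    values.
    """
    genes = []
    for i, g in enumerate(GENES):
        scale = 1.0 / sd_ratio if g == best_gene else 1.0
        genes.append(GeneSimSpec(
            name=g,
            baseline_ct=24.0 + i,
            tissue_effect_sd=0.0,
            treatment_effect=0.0,
            residual_sd=noisy_residual_sd * scale,
        ))
    return SimSpec(genes=tuple(genes), seed=seed)


@dataclass
class GroundTruth:
    """Everything the simulator drew, plus the implied stability order."""

    tissue_shifts: dict[str, dict[str, float]]  # gene -> tissue -> shift
    implied_sd: dict[str, float]
    stability_order: list[str]  # most stable first
    spec: SimSpec = field(repr=False, default=None)

    def to_json(self) -> str:
        return json.dumps(
            {"tissue_shifts": self.tissue_shifts, "implied_sd": self.implied_sd,
             "stability_order": self.stability_order},
            indent=2, sort_keys=True)


def generate_ct_matrix(spec: SimSpec) -> tuple[CtMatrix, GroundTruth]:
    """Draw a full raw Ct matrix (one column per well) from the spec.

    Deterministic for a fixed seed.  Sample ids are
    ``{tissue}:{treatment}:b{animal}:t{well}``; collapse the technical
    replicates to get the analysis-ready matrix.
    """
    rng = np.random.default_rng(spec.seed)
    shifts = {
        g.name: {t: float(rng.normal(0.0, g.tissue_effect_sd)) for t in spec.tissues}
        for g in spec.genes
    }
    samples = []
    cols: dict[str, np.ndarray] = {}
    for tissue in spec.tissues:
        for it, treatment in enumerate(spec.treatments):
            for bio in range(1, spec.biological_replicates + 1):
                bio_noise = {g.name: rng.normal(0.0, g.residual_sd) for g in spec.genes}
                for tech in range(1, spec.technical_replicates + 1):
                    sid = f"{tissue}:{treatment}:b{bio}:t{tech}"
                    samples.append(SampleAnnotation(sid, tissue, treatment, bio, tech))
                    col = np.empty(len(spec.genes))
                    for i, g in enumerate(spec.genes):
                        col[i] = (
                            g.baseline_ct
                            + shifts[g.name][tissue]
                            + (g.treatment_effect if it > 0 else 0.0)
                            + bio_noise[g.name]
                            + rng.normal(0.0, spec.technical_sd)
                        )
                    cols[sid] = col
    values = pd.DataFrame(cols, index=pd.Index([g.name for g in spec.genes], name="gene"))
    implied = {g.name: spec.implied_total_sd(g) for g in spec.genes}
    order = sorted(implied, key=lambda g: (implied[g], g))
    truth = GroundTruth(tissue_shifts=shifts, implied_sd=implied,
                        stability_order=order, spec=spec)
    return CtMatrix(values, samples), truth
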