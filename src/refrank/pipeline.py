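"""End-to-end orchestration: Ct table -> per-group stability rankings ->
footrule consensus report.

For every group (tissue) in the annotations — and once for all groups pooled —
the pipeline collapses technical replicates, converts Ct values to
efficiency-corrected relative quantities, runs each enabled stability
algorithm, assembles the resulting ordered lists into a rank matrix, and
aggregates them into a consensus ordering with tie-aware footrule
minimization.  The report mirrors the familiar published layout: one column
per algorithm plus a Consensus column, positions 1..k.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .ct_data import (
    CtDataError,
    CtMatrix,
    EfficiencyRecord,
    QuantityMatrix,
    collapse_technical_replicates,
    ct_to_quantity,
    read_ct_table,
    read_efficiency_table,
)
from .rank_aggregation import (
    CeConfig,
    ConsensusResult,
    RankMatrix,
    RankAggregationError,
    read_rank_csv,
    resolve_ties_and_aggregate,
    write_rank_csv,
)
from .stability_metrics import (
    OptimalRefCount,
    StabilityError,
    StabilityResult,
    bestkeeper,
    expression_cv,
    genorm,
    normfinder,
    write_stability_result,
)

logger = logging.getLogger(__name__)

ALL_METHODS = ["genorm", "normfinder", "bestkeeper", "expression_cv"]
POOLED_GROUP = "all"

#: tie groups larger than this are recorded but not expanded during
#: aggregation (the expansion budget would explode factorially)
MAX_EXPANDED_TIE = 3


class PipelineError(RuntimeError):
    """A pipeline stage failed for one analysis group."""


@dataclass
class StudyConfig:
    """Declarative study description (YAML-loadable).

    ``treatment_as_subgroup`` controls whether the model-based algorithm sees
    the treatment arms of a tissue as its sample subgroups (the alternative
    treats each tissue as one homogeneous group).  The pooled analysis always
    uses the tissue as the subgroup variable.
    """

    input_path: str | None = None
    dialect: str = "long"
    annotations_path: str | None = None
    efficiency_path: str | None = None
    methods: list[str] = field(default_factory=lambda: list(ALL_METHODS))
    treatment_as_subgroup: bool = True
    pooled: bool = True
    calibrator: str = "per_gene_min_ct"
    default_efficiency: float = 1.0
    aggregation: str = "brute_force"
    ce: CeConfig | None = None
    emulate_six_columns: bool = False
    output_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [m for m in self.methods if m not in ALL_METHODS]
        if unknown:
            raise PipelineError(f"unknown methods {unknown}; choose from {ALL_METHODS}")
        if not self.methods:
            raise PipelineError("at least one stability method must be enabled")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "ce" in raw and raw["ce"] is not None:
            raw["ce"] = CeConfig(**raw["ce"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class GroupReport:
    """All per-group artifacts: method results, rank matrix, consensus."""

    group: str
    stability: dict[str, StabilityResult]
    optimal_ref_count: OptimalRefCount | None
    rank_matrix: RankMatrix
    consensus: ConsensusResult
    table: pd.DataFrame  # one column per method + Consensus


@dataclass
class StudyResult:
    reports: dict[str, GroupReport]
    errors: dict[str, str]
    manifest: dict


def _result_tie_groups(results: Sequence[StabilityResult]) -> dict[int, list[tuple[int, ...]]]:
    """Convert declared score ties into positional tie groups per list.

    Only contiguous tie groups of size <= MAX_EXPANDED_TIE are declared for
    expansion; larger ones (degenerate data) are left to the deterministic
    lexicographic order already present in the ranking.
    """
    tie_groups: dict[int, list[tuple[int, ...]]] = {}
    for li, res in enumerate(results):
        groups = []
        for grp in res.ties:
            if len(grp) > MAX_EXPANDED_TIE:
                continue
            positions = tuple(sorted(res.ranking.index(g) + 1 for g in grp))
            # ties from a common score are always contiguous in the ranking
            groups.append(positions)
        if groups:
            tie_groups[li] = groups
    return tie_groups


def analyze_group(
    m: CtMatrix,
    methods: Sequence[str],
    efficiencies: Sequence[EfficiencyRecord] | Mapping[str, float] | None = None,
    subgroups: Mapping[str, str] | None = None,
    default_efficiency: float = 1.0,
    calibrator: str = "per_gene_min_ct",
    aggregation: str = "brute_force",
    ce: CeConfig | None = None,
    emulate_six_columns: bool = False,
    group: str = "group",
) -> GroupReport:
    """Run the enabled stability algorithms on one sample group and aggregate.

    ``m`` is the group's raw Ct matrix (technical replicates are collapsed
    here); ``subgroups`` maps collapsed sample ids to the subgroup labels the
    model-based algorithm should compare (None = single group).  Genes with
    any missing collapsed Ct are excluded from the analysis with a warning.
    """
    collapsed = collapse_technical_replicates(m)
    complete = collapsed.complete_genes()
    dropped = [g for g in collapsed.genes if g not in complete]
    if dropped:
        warnings.warn(f"group {group!r}: excluding genes with missing values: {dropped}",
                      stacklevel=2)
        collapsed = collapsed.subset_genes(complete)
    q = ct_to_quantity(collapsed, efficiencies, calibrator=calibrator,
                       default_efficiency=default_efficiency)

    results: dict[str, StabilityResult] = {}
    optimal: OptimalRefCount | None = None
    for name in methods:
        if name == "genorm":
            results[name], optimal = genorm(q)
        elif name == "normfinder":
            groups_map = None
            if subgroups is not None:
                groups_map = {s: subgroups[s] for s in q.sample_ids}
            results[name] = normfinder(q, groups_map)
        elif name == "bestkeeper":
            results[name] = bestkeeper(collapsed)
        elif name == "expression_cv":
            results[name] = expression_cv(q)
        else:  # pragma: no cover - guarded by StudyConfig
            raise PipelineError(f"unknown method {name!r}")

    if emulate_six_columns:
        # second preprocessing path: uncorrected quantities (E = 1), mirroring
        # suites that re-run the same two algorithms on differently prepared data
        q_raw = ct_to_quantity(collapsed, None, calibrator=calibrator,
                               default_efficiency=1.0)
        if "genorm" in methods:
            res2, _ = genorm(q_raw)
            results["genorm_uncorrected"] = dataclasses.replace(
                res2, method="genorm_uncorrected")
        if "normfinder" in methods:
            groups_map = None
            if subgroups is not None:
                groups_map = {s: subgroups[s] for s in q_raw.sample_ids}
            res2 = normfinder(q_raw, groups_map)
            results["normfinder_uncorrected"] = dataclasses.replace(
                res2, method="normfinder_uncorrected")

    names = list(results)
    lists = [results[n].ranking for n in names]
    rank_matrix = RankMatrix(
        items=sorted(lists[0]),
        lists=[list(l) for l in lists],
        names=names,
        tie_groups=_result_tie_groups([results[n] for n in names]),
    )
    consensus = resolve_ties_and_aggregate(rank_matrix, method=aggregation, ce_config=ce)
    table = pd.DataFrame({n: results[n].ranking for n in names})
    table.insert(len(table.columns), "Consensus", consensus.ordering)
    table.index = pd.RangeIndex(1, len(consensus.ordering) + 1, name="rank")
    return GroupReport(group=group, stability=results, optimal_ref_count=optimal,
                       rank_matrix=rank_matrix, consensus=consensus, table=table)


def run_study(cfg: StudyConfig, ct: CtMatrix | None = None) -> StudyResult:
    """Execute the full study: per-group analysis plus the pooled analysis.

    ``ct`` may be passed directly (e.g. from the simulator); otherwise the
    configured input file is read.  A failing group is recorded in
    ``errors`` and does not abort the remaining groups.  When
    ``cfg.output_dir`` is set, all artifacts are written beneath it.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    if ct is None:
        if cfg.input_path is None:
            raise PipelineError("no input: provide cfg.input_path or a CtMatrix")
        ct = read_ct_table(cfg.input_path, cfg.dialect, annotations=cfg.annotations_path)
    efficiencies = None
    if cfg.efficiency_path:
        efficiencies = read_efficiency_table(cfg.efficiency_path)

    ce = cfg.ce
    if cfg.aggregation == "ce_monte_carlo" and ce is None:
        ce = CeConfig(seed=cfg.seed)

    groups = list(dict.fromkeys(s.group for s in ct.samples))
    reports: dict[str, GroupReport] = {}
    errors: dict[str, str] = {}
    tasks: list[tuple[str, CtMatrix, Mapping[str, str] | None]] = []
    for g in groups:
        ids = [s.sample_id for s in ct.samples if s.group == g]
        sub = ct.subset_samples(ids)
        subgroup_map = None
        if cfg.treatment_as_subgroup:
            treatments = {s.treatment for s in sub.samples}
            if len(treatments) > 1:
                subgroup_map = {
                    f"{s.group}:{s.treatment}:b{s.biological_replicate}": s.treatment
                    for s in sub.samples
                }
        tasks.append((g, sub, subgroup_map))
    if cfg.pooled and len(groups) > 1:
        pooled_map = {
            f"{s.group}:{s.treatment}:b{s.biological_replicate}": s.group
            for s in ct.samples
        }
        tasks.append((POOLED_GROUP, ct, pooled_map))

    for name, sub, subgroup_map in tasks:
        try:
            reports[name] = analyze_group(
                sub, cfg.methods, efficiencies=efficiencies, subgroups=subgroup_map,
                default_efficiency=cfg.default_efficiency, calibrator=cfg.calibrator,
                aggregation=cfg.aggregation, ce=ce,
                emulate_six_columns=cfg.emulate_six_columns, group=name)
        except (CtDataError, StabilityError, RankAggregationError, PipelineError) as exc:
            logger.error(json.dumps({"group": name, "error": type(exc).__name__,
                                     "message": str(exc)}))
            errors[name] = f"{type(exc).__name__}: {exc}"

    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "version": __version__,
        "groups_analyzed": sorted(reports),
        "groups_failed": dict(sorted(errors.items())),
    }
    result = StudyResult(reports=reports, errors=errors, manifest=manifest)
    if cfg.output_dir:
        write_study_outputs(result, cfg.output_dir)
    return result


def write_study_outputs(result: StudyResult, output_dir) -> None:
    """Serialize every report: per-method score tables (CSV + JSON detail),
    the rank matrix, the consensus, the combined report table, and a run
    manifest.  Deterministic layout and ordering."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for gname in sorted(result.reports):
        rep = result.reports[gname]
        gdir = out / gname.replace(" ", "_")
        gdir.mkdir(exist_ok=True)
        for mname in sorted(rep.stability):
            write_stability_result(rep.stability[mname],
                                   gdir / f"{mname}.csv", gdir / f"{mname}.json")
        write_rank_csv(rep.rank_matrix, gdir / "rank_matrix.csv")
        rep.consensus.to_frame().to_csv(gdir / "consensus.csv", index=False)
        (gdir / "consensus.json").write_text(rep.consensus.to_json(), encoding="utf-8")
        rep.table.to_csv(gdir / "report.csv")
        if rep.optimal_ref_count is not None:
            oc = rep.optimal_ref_count
            (gdir / "optimal_ref_count.json").write_text(
                json.dumps({"v_curve": oc.v_curve, "acc_sd": oc.acc_sd,
                            "recommended_n": oc.recommended_n,
                            "threshold": oc.threshold},
                           indent=2, sort_keys=True),
                encoding="utf-8")
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True, default=str),
        encoding="utf-8")


def aggregate_only(
    rank_csv,
    method: str = "brute_force",
    ce: CeConfig | None = None,
    tie_top2_columns: Sequence[str] = (),
) -> ConsensusResult:
    """Aggregate a ready-made rank-matrix CSV (one column per ranking, rows =
    positions 1..k) without any Ct data.

    ``tie_top2_columns`` names columns whose top two positions should be
    treated as interchangeable before aggregation.
    """
    r = read_rank_csv(rank_csv)
    if tie_top2_columns:
        names = r.names or []
        tie_groups = {}
        for col in tie_top2_columns:
            if col not in names:
                raise RankAggregationError(f"no such column {col!r} in rank CSV")
            tie_groups[names.index(col)] = [(1, 2)]
        r.tie_groups = tie_groups
    return resolve_ties_and_aggregate(r, method=method, ce_config=ce)
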