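"""Consensus ranking by Spearman-footrule minimization.

Given m ordered lists over the same k items (here: stability rankings of
candidate reference genes from different algorithms), the consensus is the
ordering minimizing the total weighted Spearman footrule distance

    F(c) = sum_l w_l * sum_items |pos_c(item) - pos_l(item)|

with 1-based positions.  Three solvers are provided:

* :func:`aggregate_brute_force` — streaming enumeration of all k! orderings
  (the definitive answer for small panels, k <= 10);
* :func:`aggregate_assignment` — exact solution in milliseconds via the
  equivalent k x k linear assignment problem with
  ``cost(item, position) = sum_l w_l |rank_l(item) - position|``;
* :func:`aggregate_ce` — Cross-Entropy Monte Carlo search for large k,
  sampling orderings from an iteratively refitted position-probability
  matrix (not guaranteed optimal, seeded and reproducible).

:func:`resolve_ties_and_aggregate` implements tie handling for input lists
whose adjacent positions are declared interchangeable (e.g. a stability
algorithm that cannot separate its two top genes): every within-group
permutation of the affected lists is aggregated and the variant with the
lowest objective wins.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

BRUTE_FORCE_CAP = 10
TIE_EXPANSION_BUDGET = 64
_CHUNK = 20000


class RankAggregationError(ValueError):
    """Invalid rank matrix or solver configuration."""


@dataclass
class RankMatrix:
    """m ordered lists over the same k items.

    ``lists[l]`` is a full permutation of ``items`` (most stable first).
    ``weights`` default to all 1 (unweighted aggregation).  ``tie_groups``
    optionally declares, per list index, groups of 1-based positions whose
    items are interchangeable.
    """

    items: list[str]
    lists: list[list[str]]
    names: list[str] | None = None
    weights: list[float] | None = None
    tie_groups: dict[int, list[tuple[int, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.items = list(self.items)
        if len(set(self.items)) != len(self.items):
            raise RankAggregationError("items must be unique")
        if not self.lists:
            raise RankAggregationError("at least one input list required")
        universe = sorted(self.items)
        for i, lst in enumerate(self.lists):
            if sorted(lst) != universe:
                raise RankAggregationError(
                    f"list {i} ({self._name(i)}) is not a permutation of the item set")
        if self.weights is None:
            self.weights = [1.0] * len(self.lists)
        if len(self.weights) != len(self.lists):
            raise RankAggregationError("one weight per list required")
        if any(w < 0 for w in self.weights) or not any(w > 0 for w in self.weights):
            raise RankAggregationError("weights must be >= 0 and not all zero")
        if self.names is not None and len(self.names) != len(self.lists):
            raise RankAggregationError("one name per list required")
        for li, groups in self.tie_groups.items():
            if not 0 <= li < len(self.lists):
                raise RankAggregationError(f"tie group refers to unknown list {li}")
            for grp in groups:
                if any(not 1 <= p <= len(self.items) for p in grp):
                    raise RankAggregationError(f"tie positions out of range: {grp}")

    def _name(self, i: int) -> str:
        return self.names[i] if self.names else f"list{i}"

    @property
    def k(self) -> int:
        return len(self.items)

    @property
    def m(self) -> int:
        return len(self.lists)

    def rank_of(self, list_index: int) -> dict[str, int]:
        """Item -> 1-based position in the given list."""
        return {item: pos + 1 for pos, item in enumerate(self.lists[list_index])}

    def cost_matrix(self, items: Sequence[str] | None = None) -> np.ndarray:
        """``cost[i, p] = sum_l w_l |rank_l(items[i]) - (p+1)|``."""
        items = list(items) if items is not None else sorted(self.items)
        k = len(items)
        positions = np.arange(1, k + 1)
        cost = np.zeros((k, k))
        for lst, w in zip(self.lists, self.weights):
            rank = {item: pos + 1 for pos, item in enumerate(lst)}
            for i, item in enumerate(items):
                cost[i] += w * np.abs(rank[item] - positions)
        return cost


@dataclass
class ConsensusResult:
    """An aggregated ordering with its footrule objective.

    ``objective`` is exactly ``sum_l w_l * footrule(ordering, list_l)``;
    ``per_list_distance`` holds the unweighted footrule distance to each
    input list.  ``co_optima`` counts orderings attaining the optimum when
    the solver enumerates them (brute force), else 0 = unknown.
    """

    ordering: list[str]
    objective: float
    per_list_distance: list[float]
    method: str
    seed: int | None = None
    guaranteed_optimal: bool = True
    co_optima: int = 0
    detail: dict = field(default_factory=dict)

    def position(self, item: str) -> int:
        """1-based consensus rank of an item."""
        return self.ordering.index(item) + 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "ordering": self.ordering,
                "objective": self.objective,
                "per_list_distance": self.per_list_distance,
                "method": self.method,
                "seed": self.seed,
                "guaranteed_optimal": self.guaranteed_optimal,
                "co_optima": self.co_optima,
            },
            indent=2, sort_keys=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rank": np.arange(1, len(self.ordering) + 1), "gene": self.ordering})


@dataclass
class CeConfig:
    """Cross-Entropy Monte Carlo settings.

    ``sample_size`` None means ``max(100, 10 * k**2)`` at run time; the elite
    fraction ``elite_quantile`` of each iteration's samples refits the
    position-probability matrix with smoothing weight ``smoothing_weight``.
    The search stops when the incumbent objective is unchanged for
    ``convergence_window`` consecutive iterations.
    """

    sample_size: int | None = None
    elite_quantile: float = 0.1
    smoothing_weight: float = 0.25
    max_iterations: int = 1000
    convergence_window: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_size is not None and self.sample_size <= 0:
            raise RankAggregationError("sample_size must be positive")
        if not 0 < self.elite_quantile < 1:
            raise RankAggregationError("elite_quantile must be in (0, 1)")
        if not 0 < self.smoothing_weight <= 1:
            raise RankAggregationError("smoothing_weight must be in (0, 1]")
        if self.max_iterations < 0 or self.convergence_window <= 0:
            raise RankAggregationError("iteration budgets must be positive")


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _positions(lst: Sequence[str]) -> dict[str, int]:
    return {item: i + 1 for i, item in enumerate(lst)}


def spearman_footrule(a: Sequence[str], b: Sequence[str]) -> int:
    """Sum over items of the absolute difference of their 1-based positions.

    A metric on permutations with maximum ``floor(k**2 / 2)`` attained by the
    reversal.
    """
    pa, pb = _positions(a), _positions(b)
    if set(pa) != set(pb) or len(a) != len(b):
        raise RankAggregationError("lists must be permutations of the same item set")
    return sum(abs(pa[x] - pb[x]) for x in pa)


def kendall_tau_distance(a: Sequence[str], b: Sequence[str]) -> int:
    """Number of discordant pairs between two permutations (alternative
    objective; not used by the consensus solvers here)."""
    pa, pb = _positions(a), _positions(b)
    if set(pa) != set(pb) or len(a) != len(b):
        raise RankAggregationError("lists must be permutations of the same item set")
    items = list(pa)
    n = 0
    for x, y in itertools.combinations(items, 2):
        n += (pa[x] - pa[y]) * (pb[x] - pb[y]) < 0
    return n


def _finalize(r: RankMatrix, ordering: list[str], method: str,
              seed: int | None = None, guaranteed: bool = True,
              co_optima: int = 0, detail: dict | None = None) -> ConsensusResult:
    per_list = [float(spearman_footrule(ordering, lst)) for lst in r.lists]
    objective = float(sum(w * d for w, d in zip(r.weights, per_list)))
    return ConsensusResult(
        ordering=ordering, objective=objective, per_list_distance=per_list,
        method=method, seed=seed, guaranteed_optimal=guaranteed,
        co_optima=co_optima, detail=detail or {})


# ---------------------------------------------------------------------------
# Exact solvers
# ---------------------------------------------------------------------------

def aggregate_brute_force(r: RankMatrix, cap: int = BRUTE_FORCE_CAP) -> ConsensusResult:
    """Global minimizer by streaming enumeration of all k! orderings.

    Permutations of the lexicographically sorted item list are generated in
    lexicographic order and scored in vectorized chunks, so the first optimum
    found is the lexicographically smallest; the number of co-optimal
    orderings is reported.  Memory stays flat (no materialized k! list).
    """
    if r.k > cap:
        raise RankAggregationError(
            f"brute force capped at k <= {cap} (got k = {r.k}); use aggregate_ce")
    items = sorted(r.items)
    cost = r.cost_matrix(items)
    pos_idx = np.arange(r.k)
    best = math.inf
    best_perm: tuple[int, ...] | None = None
    n_opt = 0
    perms = itertools.permutations(range(r.k))
    while True:
        chunk = list(itertools.islice(perms, _CHUNK))
        if not chunk:
            break
        arr = np.array(chunk)  # (n, k): arr[c, p] = item index at position p
        obj = cost[arr, pos_idx[None, :]].sum(axis=1)
        cmin = obj.min()
        if cmin < best - 1e-9:
            best = float(cmin)
            best_perm = chunk[int(np.argmin(obj))]
            n_opt = int(np.sum(np.isclose(obj, cmin)))
        elif cmin < best + 1e-9:
            n_opt += int(np.sum(np.isclose(obj, best)))
    assert best_perm is not None
    ordering = [items[i] for i in best_perm]
    return _finalize(r, ordering, "brute_force", co_optima=n_opt)


def aggregate_assignment(r: RankMatrix) -> ConsensusResult:
    """Exact consensus via the linear assignment formulation.

    Footrule aggregation decomposes over (item, position) pairs, so a
    minimum-cost perfect matching between items and positions with
    ``cost(item, p) = sum_l w_l |rank_l(item) - p|`` yields a global optimum;
    its objective always equals the brute-force objective, though among
    co-optimal orderings the matching solver's choice is arbitrary.
    """
    items = sorted(r.items)
    cost = r.cost_matrix(items)
    row, col = linear_sum_assignment(cost)
    ordering: list[str | None] = [None] * r.k
    for i, p in zip(row, col):
        ordering[p] = items[i]
    return _finalize(r, list(ordering), "assignment")


# ---------------------------------------------------------------------------
# Cross-Entropy Monte Carlo
# ---------------------------------------------------------------------------

def _sample_permutations(prob: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n permutations; position p's item is drawn from column p of the
    (k x k) probability matrix restricted to items not yet placed."""
    k = prob.shape[0]
    out = np.empty((n, k), dtype=np.int64)
    avail = np.ones((n, k), dtype=bool)
    rows = np.arange(n)
    for p in range(k):
        w = np.where(avail, prob[:, p][None, :], 0.0)
        tot = w.sum(axis=1, keepdims=True)
        flat = np.where(tot > 0, w, avail.astype(float))
        flat = flat / flat.sum(axis=1, keepdims=True)
        cum = np.cumsum(flat, axis=1)
        u = rng.random((n, 1))
        choice = (u > cum).sum(axis=1)
        np.clip(choice, 0, k - 1, out=choice)
        out[:, p] = choice
        avail[rows, choice] = False
    return out


def aggregate_ce(r: RankMatrix, cfg: CeConfig | None = None) -> ConsensusResult:
    """Cross-Entropy Monte Carlo consensus search.

    Orderings are sampled from a position-probability matrix (initialized
    uniform), scored by the footrule objective, and the matrix is refitted to
    the elite fraction with multiplicative smoothing.  Deterministic for a
    fixed seed; the result is flagged not-guaranteed-optimal.  A zero
    iteration budget returns the best of a single uniform sample.
    """
    cfg = cfg or CeConfig()
    items = sorted(r.items)
    k = r.k
    cost = r.cost_matrix(items)
    pos_idx = np.arange(k)
    n = cfg.sample_size or max(100, 10 * k * k)
    n_elite = max(1, int(round(cfg.elite_quantile * n)))
    rng = np.random.default_rng(cfg.seed)
    prob = np.full((k, k), 1.0 / k)

    perms = _sample_permutations(prob, n, rng)
    obj = cost[perms, pos_idx[None, :]].sum(axis=1)
    ibest = int(np.argmin(obj))
    best_obj = float(obj[ibest])
    best_perm = perms[ibest].copy()
    stale = 0
    iterations = 0
    for _ in range(cfg.max_iterations):
        elite = perms[np.argsort(obj, kind="stable")[:n_elite]]
        freq = np.zeros((k, k))
        for p in range(k):
            freq[:, p] = np.bincount(elite[:, p], minlength=k)
        freq /= n_elite
        prob = (1 - cfg.smoothing_weight) * prob + cfg.smoothing_weight * freq
        perms = _sample_permutations(prob, n, rng)
        obj = cost[perms, pos_idx[None, :]].sum(axis=1)
        iterations += 1
        imin = int(np.argmin(obj))
        if obj[imin] < best_obj - 1e-9:
            best_obj = float(obj[imin])
            best_perm = perms[imin].copy()
            stale = 0
        else:
            stale += 1
            if stale >= cfg.convergence_window:
                break
    ordering = [items[i] for i in best_perm]
    return _finalize(r, ordering, "ce_monte_carlo", seed=cfg.seed, guaranteed=False,
                     detail={"iterations": iterations, "sample_size": n})


# ---------------------------------------------------------------------------
# Tie resolution
# ---------------------------------------------------------------------------

def aggregate(r: RankMatrix, method: str = "brute_force",
              ce_config: CeConfig | None = None) -> ConsensusResult:
    """Dispatch to a solver by name."""
    if method == "brute_force":
        return aggregate_brute_force(r)
    if method == "assignment":
        return aggregate_assignment(r)
    if method == "ce_monte_carlo":
        return aggregate_ce(r, ce_config)
    raise RankAggregationError(f"unknown aggregation method {method!r}")


def _tie_variants(r: RankMatrix, budget: int):
    """Yield concrete RankMatrix variants with tie groups expanded."""
    per_list_options: list[list[list[str]]] = []
    affected: list[int] = []
    for li, groups in sorted(r.tie_groups.items()):
        base = r.lists[li]
        variants = [list(base)]
        for grp in groups:
            idx = [p - 1 for p in sorted(grp)]
            new_variants = []
            for v in variants:
                for perm in itertools.permutations(idx):
                    w = list(v)
                    for src, dst in zip(idx, perm):
                        w[dst] = v[src]
                    new_variants.append(w)
            variants = new_variants
        # deduplicate while preserving order
        seen, uniq = set(), []
        for v in variants:
            t = tuple(v)
            if t not in seen:
                seen.add(t)
                uniq.append(v)
        per_list_options.append(uniq)
        affected.append(li)
    total = math.prod(len(o) for o in per_list_options)
    if total > budget:
        raise RankAggregationError(
            f"tie-group expansion yields {total} variants, exceeding budget {budget}")
    for combo in itertools.product(*per_list_options):
        lists = [list(l) for l in r.lists]
        for li, v in zip(affected, combo):
            lists[li] = list(v)
        yield replace(r, lists=lists, tie_groups={})


def resolve_ties_and_aggregate(
    r: RankMatrix,
    method: str = "brute_force",
    ce_config: CeConfig | None = None,
    budget: int = TIE_EXPANSION_BUDGET,
) -> ConsensusResult:
    """Aggregate every concretization of the declared ties; keep the best.

    Each tie group of a list is expanded to all within-group permutations
    (Cartesian product across lists, bounded by ``budget``); each variant is
    aggregated and the result with the lowest objective is returned, with
    co-optimal variants broken toward the lexicographically smallest ordering
    and all of them reported in ``detail['co_optimal_variants']``.  Without
    tie groups this is identical to plain aggregation.
    """
    if not r.tie_groups:
        return aggregate(r, method, ce_config)
    best: ConsensusResult | None = None
    co_optimal: list[list[str]] = []
    n_variants = 0
    for variant in _tie_variants(r, budget):
        res = aggregate(variant, method, ce_config)
        n_variants += 1
        if best is None or res.objective < best.objective - 1e-9:
            best = res
            co_optimal = [res.ordering]
        elif abs(res.objective - best.objective) <= 1e-9:
            if res.ordering not in co_optimal:
                co_optimal.append(res.ordering)
            if res.ordering < best.ordering:
                best = res
    assert best is not None
    best.detail = dict(best.detail)
    best.detail["variants_evaluated"] = n_variants
    best.detail["co_optimal_variants"] = sorted(co_optimal)
    return best


# ---------------------------------------------------------------------------
# I/O: the printed-table layout (one column per method, rows = positions)
# ---------------------------------------------------------------------------

def read_rank_csv(path) -> RankMatrix:
    """Read a rank matrix CSV: one column per input list (header = method
    name), row i = the item at 1-based position i+1."""
    df = pd.read_csv(path, comment="#", dtype=str)
    if df.empty or df.shape[1] < 1:
        raise RankAggregationError("rank CSV must have at least one column")
    lists = []
    names = list(df.columns)
    items: list[str] | None = None
    for col in names:
        lst = [str(x).strip() for x in df[col]]
        if items is None:
            items = sorted(lst)
        if sorted(lst) != items:
            dup = [x for x in lst if lst.count(x) > 1]
            offender = dup[0] if dup else sorted(set(items) ^ set(lst))[0]
            raise RankAggregationError(
                f"column {col!r} is not a permutation of the item set "
                f"(offending item {offender!r})")
        lists.append(lst)
    return RankMatrix(items=list(lists[0]), lists=lists, names=names)


def write_rank_csv(r: RankMatrix, path) -> None:
    names = r.names or [f"list{i}" for i in range(r.m)]
    pd.DataFrame({n: lst for n, lst in zip(names, r.lists)}).to_csv(path, index=False)
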