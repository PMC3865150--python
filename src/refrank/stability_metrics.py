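"""The four reference-gene stability algorithms.

Each algorithm scores every candidate gene (lower = more stable) and derives
an ordered list:

* :func:`genorm` — mean pairwise log-ratio variation ``M`` with stepwise
  exclusion of the least stable gene, plus the pairwise-variation curve
  ``V(n, n+1)`` for choosing how many reference genes suffice;
* :func:`normfinder` — model-based decomposition into intra-group variance and
  inter-group bias on the log scale;
* :func:`bestkeeper` — descriptive SD/CV of raw Ct values and correlation of
  each gene with the all-gene geometric-mean index;
* :func:`expression_cv` — coefficient of variation of normalized relative
  quantities, the simple quality measure used alongside ``M`` by qBase-style
  tools.

All sample standard deviations use the unbiased n−1 denominator.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ct_data import CtDataError, CtMatrix, QuantityMatrix, normalization_factor

logger = logging.getLogger(__name__)

#: canonical pairwise-variation cutoff below which adding a further reference
#: gene is judged unnecessary
GENORM_V_THRESHOLD = 0.15


class StabilityError(ValueError):
    """Input unsuitable for a stability algorithm."""


@dataclass
class StabilityResult:
    """Per-gene stability scores from one algorithm.

    ``scores`` are oriented so that lower = more stable; ``ranking`` lists
    genes from most to least stable.  ``ties`` holds groups of genes whose
    scores are indistinguishable (ordered lexicographically within the
    ranking and flagged here).  ``detail`` carries method-specific extras.
    """

    method: str
    scores: dict[str, float]
    ranking: list[str]
    ties: list[tuple[str, ...]] = field(default_factory=list)
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sorted(self.ranking) != sorted(self.scores):
            raise StabilityError("ranking must be a permutation of the scored genes")

    def tied_genes(self) -> set[str]:
        return {g for grp in self.ties for g in grp}

    def to_frame(self) -> pd.DataFrame:
        tied = self.tied_genes()
        return pd.DataFrame(
            {
                "gene": self.ranking,
                "score": [self.scores[g] for g in self.ranking],
                "rank": np.arange(1, len(self.ranking) + 1),
                "tied": [g in tied for g in self.ranking],
            }
        )


@dataclass
class OptimalRefCount:
    """How many reference genes are enough.

    ``v_curve[n]`` is the pairwise variation V(n, n+1): the SD over samples of
    ``log2(NF_n / NF_{n+1})`` where ``NF_n`` is the normalization factor built
    from the n best-ranked genes.  ``acc_sd[n]`` is the accumulated standard
    deviation of ``log2(NF_n)`` across samples.  ``recommended_n`` is the
    smallest n with V below the threshold (falling back to the n minimising
    the accumulated SD when no V clears it).
    """

    v_curve: dict[int, float]
    acc_sd: dict[int, float]
    recommended_n: int
    threshold: float = GENORM_V_THRESHOLD


def rank_from_scores(
    scores: Mapping[str, float], direction: str = "ascending"
) -> tuple[list[str], list[tuple[str, ...]]]:
    """Order genes by score (ascending = most stable first), breaking ties
    lexicographically by gene id and reporting tie groups."""
    if direction != "ascending":
        raise StabilityError(f"unsupported direction {direction!r}")
    for g, v in scores.items():
        if not np.isfinite(v):
            raise StabilityError(f"non-finite score for gene {g!r}")
    ranking = sorted(scores, key=lambda g: (scores[g], g))
    ties = []
    for _, grp in itertools.groupby(ranking, key=lambda g: scores[g]):
        grp = tuple(grp)
        if len(grp) > 1:
            ties.append(grp)
    return ranking, ties


def _require_complete(values: pd.DataFrame, method: str) -> np.ndarray:
    arr = values.to_numpy(dtype=float)
    if np.any(~np.isfinite(arr)):
        bad = list(values.index[np.any(~np.isfinite(arr), axis=1)])
        raise StabilityError(f"{method} requires complete values; missing in genes {bad}")
    return arr


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------

def _pairwise_m(logq: np.ndarray) -> np.ndarray:
    """M_j = mean over partners k≠j of SD_samples(logq_j − logq_k)."""
    k = logq.shape[0]
    m = np.zeros(k)
    for j in range(k):
        diffs = logq[j] - logq  # (k, n)
        sds = np.std(np.delete(diffs, j, axis=0), axis=1, ddof=1)
        m[j] = sds.mean()
    return m


def genorm(q: QuantityMatrix) -> tuple[StabilityResult, OptimalRefCount]:
    """Gene-stability measure M with stepwise exclusion.

    The pairwise variation of genes j,k is the SD over samples of
    ``log2(q_j / q_k)``; M_j is its mean over all partners k.  The least
    stable gene (largest M) is removed and M recomputed on the survivors,
    until two genes remain; these cannot be separated by the pairwise model
    and are reported as a tied most-stable pair (ordered lexicographically).

    The reported score for each gene is its M value at the step it was
    excluded (the shared final-pair M for the last two), and the
    pairwise-variation curve V(n, n+1) is computed from normalization factors
    over the top-n ranked genes.
    """
    genes = q.genes
    if len(genes) < 3:
        raise StabilityError("geNorm requires at least 3 genes")
    if q.shape[1] < 2:
        raise StabilityError("geNorm requires at least 2 samples")
    arr = _require_complete(q.values, "geNorm")
    logq = np.log2(arr)

    survivors = list(range(len(genes)))
    scores: dict[str, float] = {}
    exclusion_order: list[str] = []
    m_trajectory: dict[str, float] = {}
    while len(survivors) > 2:
        m = _pairwise_m(logq[survivors])
        m_by_gene = {genes[i]: m[pos] for pos, i in enumerate(survivors)}
        # remove the largest M; among exact ties drop the lexicographically
        # greatest so the retained ranking is deterministic
        worst = max(m_by_gene, key=lambda g: (m_by_gene[g], g))
        scores[worst] = m_by_gene[worst]
        exclusion_order.append(worst)
        survivors = [i for i in survivors if genes[i] != worst]
    final_pair = sorted(genes[i] for i in survivors)
    final_m = float(np.std(logq[survivors[0]] - logq[survivors[1]], ddof=1))
    for g in final_pair:
        scores[g] = final_m
    ranking = final_pair + list(reversed(exclusion_order))

    full_m = _pairwise_m(logq)
    m_trajectory = {genes[i]: float(full_m[i]) for i in range(len(genes))}

    result = StabilityResult(
        method="genorm",
        scores={g: float(scores[g]) for g in genes},
        ranking=ranking,
        ties=[tuple(final_pair)],
        detail={
            "ranking_rule": "stepwise_exclusion",
            "log_base": 2,
            "m_full_panel": m_trajectory,
            "exclusion_order": exclusion_order,
        },
    )

    v_curve: dict[int, float] = {}
    acc_sd: dict[int, float] = {}
    k = len(genes)
    nf = {n: normalization_factor(q, ranking[:n]).to_numpy() for n in range(1, k + 1)}
    for n in range(1, k + 1):
        lognf = np.log2(nf[n])
        acc_sd[n] = float(np.std(lognf, ddof=1)) if len(lognf) > 1 else 0.0
    for n in range(2, k):
        v_curve[n] = float(np.std(np.log2(nf[n] / nf[n + 1]), ddof=1))
    below = [n for n, v in v_curve.items() if v < GENORM_V_THRESHOLD]
    if below:
        recommended = min(below)
    else:
        recommended = min(acc_sd, key=lambda n: (acc_sd[n], n))
        logger.info("no V(n, n+1) below %.2f; recommending n=%d by accumulated SD",
                    GENORM_V_THRESHOLD, recommended)
    opt = OptimalRefCount(v_curve=v_curve, acc_sd=acc_sd, recommended_n=recommended)
    return result, opt


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------

def normfinder(
    q: QuantityMatrix,
    groups: Mapping[str, str] | None = None,
) -> StabilityResult:
    """Model-based stability value combining intra- and inter-group variation.

    Works on natural-log quantities ``y``.  Within each group the expression
    of gene i in sample j is modelled as ``y_ij = a_i + b_j + e_ij`` with
    sample effect b_j and gene-specific error variance s2_i.  Two-way
    centering gives residuals whose mean square per gene estimates a biased
    mixture of the error variances; the shared term is subtracted
    (``s2_i = (ms_i − mean(ms)/(k−1)) · k/(k−2)``, floored at 0).  With two or
    more groups, the per-gene group deviation d_ig (from sample-centered
    means) estimates inter-group bias; it is shrunk toward 0 in proportion to
    its sampling variance ``c_ig = s2_ig/n_g`` relative to the between-gene
    spread of deviations, and the stability value is the mean over groups of
    ``|d̃_ig| + sqrt(c_ig)``.  With a single group the value reduces to the
    estimated intra-group SD.  Lower = more stable.
    """
    genes = q.genes
    k = len(genes)
    if k < 3:
        raise StabilityError("NormFinder requires at least 3 genes")
    arr = _require_complete(q.values, "NormFinder")
    y = np.log(arr)  # genes × samples, natural log

    if groups is None:
        labels = [q.annotation(s).group for s in q.sample_ids]
    else:
        labels = [groups[s] for s in q.sample_ids]
    group_names = list(dict.fromkeys(labels))
    cols_by_group = {g: [i for i, l in enumerate(labels) if l == g] for g in group_names}
    n_groups = len(group_names)
    if n_groups >= 2:
        for g, cols in cols_by_group.items():
            if len(cols) < 2:
                raise StabilityError(f"group {g!r} has fewer than 2 samples")

    sigma2 = np.zeros((k, n_groups))
    zbar = np.zeros((k, n_groups))
    nsamp = np.zeros(n_groups, dtype=int)
    for gi, gname in enumerate(group_names):
        sub = y[:, cols_by_group[gname]]
        n = sub.shape[1]
        nsamp[gi] = n
        z = sub - sub.mean(axis=0, keepdims=True)  # center each sample across genes
        zbar[:, gi] = z.mean(axis=1)
        if n > 1:
            resid = z - z.mean(axis=1, keepdims=True)
            ms = np.sum(resid**2, axis=1) / (n - 1)
            if k > 2:
                s2 = (ms - ms.mean() / (k - 1)) * k / (k - 2)
            else:
                s2 = ms
            sigma2[:, gi] = np.maximum(s2, 0.0)
        else:
            sigma2[:, gi] = 0.0

    if n_groups == 1:
        stab = np.sqrt(sigma2[:, 0])
        detail = {"groups": group_names, "intra_sd": dict(zip(genes, stab.tolist()))}
    else:
        d = zbar - zbar.mean(axis=1, keepdims=True)  # per-gene group deviation
        c = sigma2 / nsamp[None, :]  # sampling variance of d̂
        # between-gene spread of the raw deviations, beyond sampling noise
        gamma2 = max(float(np.sum(d**2) / ((k - 1) * max(n_groups - 1, 1)) - c.mean()), 0.0)
        if gamma2 > 0:
            d_shrunk = d * gamma2 / (gamma2 + c)
        else:
            d_shrunk = np.zeros_like(d)
        stab = np.mean(np.abs(d_shrunk) + np.sqrt(c), axis=1)
        detail = {
            "groups": group_names,
            "group_deviation": {g: d[i].tolist() for i, g in enumerate(genes)},
            "shrunk_deviation": {g: d_shrunk[i].tolist() for i, g in enumerate(genes)},
            "intra_group_variance": {g: sigma2[i].tolist() for i, g in enumerate(genes)},
            "gamma2": gamma2,
        }

    scores = {g: float(stab[i]) for i, g in enumerate(genes)}
    ranking, ties = rank_from_scores(scores)
    if len(ties) == 1 and len(ties[0]) == k:
        warnings.warn("all NormFinder stability values identical; ranking is the "
                      "lexicographic tie-break order", stacklevel=2)
    return StabilityResult(method="normfinder", scores=scores, ranking=ranking,
                           ties=ties, detail=detail)


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------

def bestkeeper(m: CtMatrix, sd_exclusion: float = 1.0) -> StabilityResult:
    """Descriptive stability on the raw Ct scale.

    Per gene: SD of Ct (n−1 denominator) and CV = 100·SD/mean.  The
    BestKeeper index is the per-sample geometric mean of Ct over the genes
    retained after excluding any with SD > 1 cycle (exclusion applies to
    index construction only, not ranking eligibility); each gene is then
    correlated (Pearson r, two-sided p) against the index.  The primary
    ranking score is the SD, ascending.
    """
    genes = m.genes
    if len(genes) < 2:
        raise StabilityError("BestKeeper requires at least 2 genes")
    if m.shape[1] < 3:
        raise StabilityError("BestKeeper requires at least 3 samples")
    arr = _require_complete(m.values, "BestKeeper")

    sd = np.std(arr, axis=1, ddof=1)
    mean = arr.mean(axis=1)
    cv = 100.0 * sd / mean
    retained = [g for g, s in zip(genes, sd) if s <= sd_exclusion]
    if not retained:
        warnings.warn(
            f"all genes exceed the SD > {sd_exclusion:g} cycle rule; "
            "building the BestKeeper index over all genes", stacklevel=2)
        retained = list(genes)
    idx_rows = [genes.index(g) for g in retained]
    index = np.exp(np.mean(np.log(arr[idx_rows]), axis=0))

    r = np.full(len(genes), np.nan)
    p = np.full(len(genes), np.nan)
    for i in range(len(genes)):
        if sd[i] > 0 and np.std(index) > 0:
            r[i], p[i] = stats.pearsonr(arr[i], index)

    scores = {g: float(s) for g, s in zip(genes, sd)}
    ranking, ties = rank_from_scores(scores)
    detail = {
        "sd": dict(zip(genes, sd.tolist())),
        "cv_percent": dict(zip(genes, cv.tolist())),
        "index": index.tolist(),
        "index_genes": retained,
        "excluded_from_index": [g for g in genes if g not in retained],
        "r_vs_index": dict(zip(genes, r.tolist())),
        "p_vs_index": dict(zip(genes, p.tolist())),
    }
    return StabilityResult(method="bestkeeper", scores=scores, ranking=ranking,
                           ties=ties, detail=detail)


# ---------------------------------------------------------------------------
# Expression CV
# ---------------------------------------------------------------------------

def expression_cv(q: QuantityMatrix) -> StabilityResult:
    """Coefficient of variation of normalized relative quantities.

    Each gene's quantities are divided by the all-gene normalization factor
    (per-sample geometric mean); the score is the CV (percent, n−1 SD) of the
    normalized values, ascending.  A gene exactly proportional to the
    normalization factor has CV 0.
    """
    genes = q.genes
    _require_complete(q.values, "expression CV")
    nf = normalization_factor(q, genes)
    normalized = q.values.div(nf, axis=1)
    arr = normalized.to_numpy(dtype=float)
    sd = np.std(arr, axis=1, ddof=1) if arr.shape[1] > 1 else np.zeros(len(genes))
    cv = 100.0 * sd / arr.mean(axis=1)
    scores = {g: float(c) for g, c in zip(genes, cv)}
    ranking, ties = rank_from_scores(scores)
    return StabilityResult(
        method="expression_cv",
        scores=scores,
        ranking=ranking,
        ties=ties,
        detail={"normalized_mean": dict(zip(genes, arr.mean(axis=1).tolist()))},
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_stability_result(res: StabilityResult, csv_path, json_path=None) -> None:
    """CSV (gene, score, rank, tied) plus optional JSON sidecar with detail."""
    res.to_frame().to_csv(csv_path, index=False)
    if json_path is not None:
        import json

        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(
                {"method": res.method, "ties": [list(t) for t in res.ties],
                 "detail": res.detail},
                fh, indent=2, sort_keys=True, default=float)
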