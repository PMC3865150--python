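"""The four stability algorithms against independent oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from refrank.ct_data import ct_to_quantity
from refrank.stability_metrics import (
    StabilityError,
    bestkeeper,
    expression_cv,
    genorm,
    normfinder,
    rank_from_scores,
)
from refrank.synthetic_data import GeneSimSpec, SimSpec, generate_ct_matrix

from conftest import make_annotations, make_ct, make_quantity


# ---------------------------------------------------------------------------
# rank_from_scores
# ---------------------------------------------------------------------------

def test_rank_from_scores_orders_ascending():
    ranking, ties = rank_from_scores({"A": 0.2, "B": 0.5, "C": 0.1})
    assert ranking == ["C", "A", "B"]
    assert ties == []


def test_rank_from_scores_breaks_ties_lexicographically():
    ranking, ties = rank_from_scores({"B": 0.2, "A": 0.2, "C": 0.3})
    assert ranking == ["A", "B", "C"]
    assert ties == [("A", "B")]


def test_rank_from_scores_matches_oracle_sort(rng):
    scores = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=9))}
    ranking, _ = rank_from_scores(scores)
    assert ranking == sorted(scores, key=scores.get)


def test_rank_from_scores_rejects_nonfinite():
    with pytest.raises(StabilityError):
        rank_from_scores({"A": float("nan")})


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------

def _oracle_m(arr):
    """Independent brute-force M: mean over partners of SD(log2 ratio)."""
    k = arr.shape[0]
    logq = np.log2(arr)
    m = []
    for j in range(k):
        sds = [np.std(logq[j] - logq[l], ddof=1) for l in range(k) if l != j]
        m.append(np.mean(sds))
    return np.array(m)


def test_genorm_m_matches_pairwise_oracle(rng):
    arr = rng.uniform(0.05, 1.0, size=(4, 6))
    q = make_quantity(arr)
    res, _ = genorm(q)
    oracle = _oracle_m(arr)
    for i, g in enumerate(q.genes):
        assert res.detail["m_full_panel"][g] == pytest.approx(oracle[i], rel=1e-9)


def test_genorm_proportional_pair_wins(rng):
    """Gene A = c * gene B exactly => V(A, B) = 0 and the noisy gene C leaves first."""
    b = rng.uniform(0.1, 1.0, size=8)
    arr = np.vstack([0.5 * b, b, rng.uniform(0.05, 1.0, size=8)])
    q = make_quantity(arr, genes=["A", "B", "C"])
    res, _ = genorm(q)
    assert np.std(np.log2(arr[0] / arr[1]), ddof=1) == pytest.approx(0.0, abs=1e-12)
    assert res.ranking == ["A", "B", "C"]
    assert res.ties == [("A", "B")]


def test_genorm_constant_genes_all_zero():
    arr = np.array([[0.5] * 4, [1.0] * 4, [0.25] * 4])
    res, opt = genorm(make_quantity(arr))
    assert all(v == pytest.approx(0.0, abs=1e-12) for v in res.scores.values())
    assert all(v == pytest.approx(0.0, abs=1e-12) for v in opt.v_curve.values())


@given(c=st.floats(0.05, 20.0))
def test_genorm_invariant_under_per_gene_scaling(c):
    arr = np.array([[0.2, 0.8, 1.0, 0.5],
                    [1.0, 0.4, 0.9, 0.6],
                    [0.7, 1.0, 0.3, 0.9],
                    [0.9, 0.2, 0.6, 1.0]])
    scaled = arr.copy()
    scaled[1] *= c
    r1, _ = genorm(make_quantity(arr))
    r2, _ = genorm(make_quantity(scaled))
    for g in r1.scores:
        assert r1.scores[g] == pytest.approx(r2.scores[g], rel=1e-9, abs=1e-12)


def test_genorm_three_genes_equals_direct_ranking(rng):
    """With k = 3 stepwise exclusion cannot differ from ranking by full-panel M."""
    for _ in range(25):
        arr = rng.uniform(0.05, 1.0, size=(3, 7))
        q = make_quantity(arr)
        res, _ = genorm(q)
        oracle = _oracle_m(arr)
        worst = q.genes[int(np.argmax(oracle))]
        if sorted(oracle)[1] != sorted(oracle)[2]:  # skip exact ties
            assert res.ranking[-1] == worst


def test_genorm_requires_three_genes():
    with pytest.raises(StabilityError):
        genorm(make_quantity([[1.0, 0.5], [0.5, 1.0]]))


def test_genorm_v_curve_spans_2_to_k_minus_1(rng):
    arr = rng.uniform(0.05, 1.0, size=(5, 8))
    _, opt = genorm(make_quantity(arr))
    assert sorted(opt.v_curve) == [2, 3, 4]
    assert opt.recommended_n in range(1, 6)


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------

def _two_group_quantity(rng, n_per_group, sds, biases):
    """Log-normal quantities: gene i has group bias +/- biases[i]/2 and
    residual SD sds[i] on the natural-log scale."""
    k = len(sds)
    cols = []
    for g, sign in (("g1", -0.5), ("g2", 0.5)):
        y = sign * np.asarray(biases)[:, None] + rng.normal(
            0.0, np.asarray(sds)[:, None], size=(k, n_per_group))
        cols.append(y)
    y = np.concatenate(cols, axis=1)
    samples = (make_annotations(n_per_group, group="g1")
               + [s for s in make_annotations(2 * n_per_group, group="g2")[n_per_group:]])
    q = make_quantity(np.exp(y), samples=samples)
    groups = {s.sample_id: s.group for s in samples}
    return q, groups


def test_normfinder_recovers_designed_best_gene():
    """Zero group effect + smallest residual SD => rank 1 in >= 95% of 100 sims."""
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(1000 + seed)
        sds = [0.05] + [0.5] * 8
        # mixed-sign group effects: a common bias direction would shift the
        # per-sample centering frame instead of the biased genes themselves
        biases = [0.0] + [1.0 if i % 2 else -1.0 for i in range(8)]
        q, groups = _two_group_quantity(rng, 20, sds, biases)
        res = normfinder(q, groups)
        hits += res.ranking[0] == "G0"
    assert hits >= 95


def test_normfinder_identical_groups_kill_intergroup_component():
    rng = np.random.default_rng(7)
    sds = np.linspace(0.1, 0.6, 6)
    q, groups = _two_group_quantity(rng, 400, sds, np.zeros(6))
    res = normfinder(q, groups)
    for g, dev in res.detail["shrunk_deviation"].items():
        assert np.max(np.abs(dev)) < 0.05
    # ranking then tracks the intra-group SD order
    assert res.ranking[0] == "G0"
    assert res.ranking[-1] == "G5"


def test_normfinder_single_group_is_intra_sd():
    rng = np.random.default_rng(11)
    sds = [0.05, 0.3, 0.6, 0.9]
    y = rng.normal(0.0, np.asarray(sds)[:, None], size=(4, 500))
    q = make_quantity(np.exp(y))
    res = normfinder(q)
    intra = [res.scores[g] for g in q.genes]
    assert intra == sorted(intra)
    # the bias correction floors near-zero variances at 0, so only the
    # clearly-nonzero SDs are compared to their generative values
    np.testing.assert_allclose(intra[1:], sds[1:], rtol=0.2)


def test_normfinder_degenerate_constants_tie():
    arr = np.tile([[0.5], [1.0], [0.25]], (1, 5))
    with pytest.warns(UserWarning, match="identical"):
        res = normfinder(make_quantity(arr))
    assert len(set(res.scores.values())) == 1
    assert res.ranking == sorted(res.ranking)


def test_normfinder_rejects_singleton_group():
    samples = make_annotations(3, group="a")
    samples[2] = type(samples[2])("s2", "b", "ctrl", 1, 0)
    q = make_quantity(np.full((3, 3), 0.5), samples=samples)
    with pytest.raises(StabilityError, match="fewer than 2"):
        normfinder(q, {s.sample_id: s.group for s in samples})


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------

def test_bestkeeper_matches_direct_formulas(rng):
    cts = 25.0 + rng.uniform(-1.2, 1.2, size=(3, 5))
    m = make_ct(cts)
    res = bestkeeper(m)
    sd = cts.std(axis=1, ddof=1)
    cv = 100.0 * sd / cts.mean(axis=1)
    retained = [i for i in range(3) if sd[i] <= 1.0] or [0, 1, 2]
    index = np.exp(np.log(cts[retained]).mean(axis=0))
    for i, g in enumerate(m.genes):
        assert res.scores[g] == pytest.approx(sd[i], rel=1e-12)
        assert res.detail["cv_percent"][g] == pytest.approx(cv[i], rel=1e-12)
        r = np.corrcoef(cts[i], index)[0, 1]
        assert res.detail["r_vs_index"][g] == pytest.approx(r, rel=1e-9)
    np.testing.assert_allclose(res.detail["index"], index)


def test_bestkeeper_constant_gene_ranks_first(rng):
    cts = np.vstack([np.full(6, 25.0), rng.uniform(24, 28, size=(2, 6))])
    res = bestkeeper(make_ct(cts))
    assert res.ranking[0] == "G0"
    assert res.scores["G0"] == 0.0
    assert res.detail["cv_percent"]["G0"] == 0.0


def test_bestkeeper_gene_equal_to_index_has_r_one():
    base = np.array([24.0, 24.5, 25.0, 25.5, 24.2])
    m = make_ct(np.vstack([base, base]), genes=["A", "B"])
    res = bestkeeper(m)
    # index = geometric mean of two identical genes = the gene itself
    assert res.detail["r_vs_index"]["A"] == pytest.approx(1.0)


def test_bestkeeper_translation_and_reorder_invariance(rng):
    cts = rng.uniform(22, 30, size=(4, 7))
    res = bestkeeper(make_ct(cts))
    shifted = cts.copy()
    shifted[2] += 3.0
    res_shift = bestkeeper(make_ct(shifted))
    assert res_shift.scores["G2"] == pytest.approx(res.scores["G2"], rel=1e-12)
    perm = rng.permutation(7)
    res_perm = bestkeeper(make_ct(cts[:, perm]))
    for g in res.scores:
        assert res_perm.scores[g] == pytest.approx(res.scores[g], rel=1e-12)


def test_bestkeeper_all_excluded_falls_back_to_all(rng):
    cts = np.cumsum(rng.uniform(1, 3, size=(3, 8)), axis=1) + 20  # SD >> 1
    with pytest.warns(UserWarning, match="SD > 1"):
        res = bestkeeper(make_ct(cts))
    assert res.detail["index_genes"] == ["G0", "G1", "G2"]


# ---------------------------------------------------------------------------
# expression CV
# ---------------------------------------------------------------------------

def test_expression_cv_proportional_gene_has_zero_cv(rng):
    # with g0 = sqrt(g1 * g2) the 3-gene geometric mean equals g0 exactly,
    # so g0 is proportional to the normalization factor and scores CV = 0
    g1 = rng.uniform(0.1, 1.0, size=6)
    g2 = rng.uniform(0.1, 1.0, size=6)
    q = make_quantity(np.vstack([np.sqrt(g1 * g2), g1, g2]))
    res = expression_cv(q)
    assert res.scores["G0"] == pytest.approx(0.0, abs=1e-9)
    assert res.ranking[0] == "G0"


def test_expression_cv_constant_genes_beat_varying_gene(rng):
    arr = np.vstack([np.full(5, 0.8), np.full(5, 0.6), rng.uniform(0.05, 1.0, size=5)])
    res = expression_cv(make_quantity(arr))
    assert set(res.ranking[:2]) == {"G0", "G1"}


def test_expression_cv_matches_direct_evaluation(rng):
    arr = rng.uniform(0.05, 1.0, size=(3, 4))
    res = expression_cv(make_quantity(arr))
    nf = np.exp(np.log(arr).mean(axis=0))
    norm = arr / nf
    cv = 100.0 * norm.std(axis=1, ddof=1) / norm.mean(axis=1)
    for i, g in enumerate(["G0", "G1", "G2"]):
        assert res.scores[g] == pytest.approx(cv[i], rel=1e-12)


# ---------------------------------------------------------------------------
# cross-method invariant: ordered noise magnitudes are recovered
# ---------------------------------------------------------------------------

def test_all_methods_follow_designed_noise_order():
    """Strictly ordered per-gene noise SDs with no group effects yield rankings
    positively correlated with the truth, improving as separation grows."""
    from scipy.stats import spearmanr

    seps = [1.3, 1.6, 2.0]
    mean_rho = []
    for sep in seps:
        rhos = []
        for seed in range(5):
            sds = [0.1 * sep**i for i in range(6)]
            genes = tuple(
                GeneSimSpec(f"G{i}", 24.0 + i, 0.0, 0.0, sds[i]) for i in range(6))
            spec = SimSpec(genes=genes, tissues=("t1",), treatments=("ctrl",),
                           biological_replicates=30, technical_replicates=1,
                           technical_sd=0.02, seed=seed)
            ct, truth = generate_ct_matrix(spec)
            from refrank.ct_data import collapse_technical_replicates
            collapsed = collapse_technical_replicates(ct)
            q = ct_to_quantity(collapsed)
            true_rank = {g: i for i, g in enumerate(truth.stability_order)}
            for res in (genorm(q)[0], normfinder(q), bestkeeper(collapsed),
                        expression_cv(q)):
                obs = [true_rank[g] for g in res.ranking]
                rhos.append(spearmanr(obs, range(6)).statistic)
        mean_rho.append(np.mean(rhos))
    assert all(r > 0 for r in mean_rho)
    assert mean_rho[-1] > 0.9
    assert mean_rho[0] <= mean_rho[-1]
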