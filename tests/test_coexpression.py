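"""Co-expression core: adjacency, scale-free fit, TOM, modules, eigengenes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from dignet import coexpression as cx
from dignet.coexpression import AdjacencyMatrix
from dignet.errors import DegenerateInputError, InsufficientDataError
from dignet.synthetic import ExpressionTruth, simulate_expression_profiles


def random_matrix(n_genes, n_profiles, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n_genes, n_profiles)),
        index=[f"g{i:03d}" for i in range(n_genes)],
        columns=[f"p{j}" for j in range(n_profiles)],
    )


def planted_profiles(n_modules=4, module_size=50, noise_sd=0.3, seed=7,
                     n_drugs=20, loading_range=(0.7, 1.0)):
    assignment = {
        f"G{m:02d}_{i:03d}": m + 1 for m in range(n_modules) for i in range(module_size)
    }
    truth = ExpressionTruth(
        module_assignment=assignment,
        group_a_drugs=[f"dA{i}" for i in range(n_drugs // 2)],
        group_b_drugs=[f"dB{i}" for i in range(n_drugs - n_drugs // 2)],
        noise_sd=noise_sd,
        loading_range=loading_range,
    )
    sim = simulate_expression_profiles(truth, n_genes=len(assignment),
                                       n_profiles_per_drug=1, seed=seed)
    labels_true = pd.Series({g: assignment[g] for g in sim.profiles.genes})
    return sim, labels_true


# -------------------------------------------------------------- adjacency

def test_perfect_correlation_gives_one():
    g = np.arange(10.0)
    mat = pd.DataFrame([g, 2 * g + 1], index=["g1", "g2"])
    adj = cx.soft_adjacency(mat, beta=5)
    assert adj.values[0, 1] == pytest.approx(1.0)


def test_power_of_correlation():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([2.0, 1.0, 4.0, 3.0])  # pearson r = 0.6 exactly
    mat = pd.DataFrame([x, y], index=["g1", "g2"])
    adj = cx.soft_adjacency(mat, beta=5)
    assert adj.values[0, 1] == pytest.approx(0.6 ** 5)
    # the printed half-correlation case: r = 0.5 at beta = 5 -> 0.03125
    assert 0.5 ** 5 == pytest.approx(0.03125)


def test_adjacency_matches_brute_force_oracle():
    mat = random_matrix(20, 10, seed=3)
    adj = cx.soft_adjacency(mat, beta=5)
    X = mat.to_numpy()
    for i in range(20):
        for j in range(20):
            expected = 0.0 if i == j else abs(sps.pearsonr(X[i], X[j])[0]) ** 5
            assert abs(adj.values[i, j] - expected) < 1e-10


def test_adjacency_constant_gene_zero():
    mat = random_matrix(3, 6, seed=0)
    mat.iloc[1] = 4.2
    adj = cx.soft_adjacency(mat, beta=5)
    assert adj.values[1].sum() == 0.0


def test_adjacency_few_profiles_raises():
    with pytest.raises(InsufficientDataError):
        cx.soft_adjacency(random_matrix(5, 2), beta=5)


def test_adjacency_affine_invariance():
    mat = random_matrix(10, 8, seed=4)
    adj1 = cx.soft_adjacency(mat, beta=5)
    transformed = mat.mul(np.linspace(0.5, 3, 10), axis=0).add(
        np.linspace(-2, 2, 10), axis=0)
    adj2 = cx.soft_adjacency(transformed, beta=5)
    np.testing.assert_allclose(adj1.values, adj2.values, atol=1e-10)


# ---------------------------------------------------------- scale-free fit

def test_two_bins_give_r2_one():
    mat = random_matrix(30, 10, seed=5)
    adj = cx.soft_adjacency(mat, beta=3)
    assert cx.scale_free_fit(adj, n_bins=2) == pytest.approx(1.0)


def test_scale_free_matches_regression_oracle():
    mat = random_matrix(100, 12, seed=6)
    adj = cx.soft_adjacency(mat, beta=5)
    got = cx.scale_free_fit(adj, n_bins=10)
    # brute-force oracle
    k = adj.values.sum(axis=1)
    edges = np.linspace(k.min(), k.max(), 11)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
    xs, ys = [], []
    for b in range(10):
        sel = idx == b
        if sel.any() and k[sel].mean() > 0:
            xs.append(np.log10(k[sel].mean()))
            ys.append(np.log10(sel.sum() / k.size))
    slope, intercept = np.polyfit(xs, ys, 1)
    ss_res = sum((y - (slope * x + intercept)) ** 2 for x, y in zip(xs, ys))
    ss_tot = sum((y - np.mean(ys)) ** 2 for y in ys)
    assert abs(got - (1 - ss_res / ss_tot)) < 1e-8


def test_scale_free_degenerate_raises():
    values = np.ones((4, 4)) - np.eye(4)
    adj = AdjacencyMatrix(values, pd.Index(list("abcd")), beta=1)
    with pytest.raises(DegenerateInputError):
        cx.scale_free_fit(adj)


# -------------------------------------------------------------------- TOM

def _adj(values, beta=5.0):
    values = np.asarray(values, dtype=float)
    return AdjacencyMatrix(values, pd.Index([f"g{i}" for i in range(len(values))]), beta)


def test_tom_all_ones():
    adj = _adj(np.ones((3, 3)) - np.eye(3))
    tom = cx.topological_overlap(adj)
    assert tom[0, 1] == pytest.approx(1.0)  # (1 + 1) / (2 + 1 - 1)
    assert np.allclose(tom, 1.0)


def test_tom_zero_adjacency():
    tom = cx.topological_overlap(_adj(np.zeros((4, 4))))
    assert np.allclose(tom - np.eye(4), 0.0)


def test_tom_matches_triple_loop_oracle(rng):
    n = 15
    r = rng.uniform(0, 1, size=(n, n))
    A = (r + r.T) / 2
    np.fill_diagonal(A, 0.0)
    tom = cx.topological_overlap(_adj(A))
    k = A.sum(axis=1)
    for i in range(n):
        for j in range(n):
            if i == j:
                expected = 1.0
            else:
                shared = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
                expected = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
            assert abs(tom[i, j] - expected) < 1e-10


def test_tom_bounds_and_symmetry(rng):
    r = rng.uniform(0, 1, size=(25, 25))
    A = (r + r.T) / 2
    np.fill_diagonal(A, 0.0)
    tom = cx.topological_overlap(_adj(A))
    assert (tom >= 0).all() and (tom <= 1).all()
    dissim = 1 - tom
    np.testing.assert_allclose(dissim, dissim.T, atol=1e-12)
    assert np.allclose(np.diag(dissim), 0.0)


# ------------------------------------------------------- module detection

def test_two_perfect_blocks():
    n = 8
    D = np.ones((n, n))
    D[:4, :4] = 0.0
    D[4:, 4:] = 0.0
    np.fill_diagonal(D, 0.0)
    genes = pd.Index([f"g{i}" for i in range(n)])
    ms = cx.detect_modules(D, genes, min_module_size=2, cut_height_quantile=0.99)
    labels = ms.labels.to_numpy()
    assert len(set(labels)) == 2
    assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
    assert set(labels[:4]) != set(labels[4:])


def test_all_equal_dissimilarity_single_module():
    n = 10
    D = np.full((n, n), 0.6)
    np.fill_diagonal(D, 0.0)
    genes = pd.Index([f"g{i}" for i in range(n)])
    ms = cx.detect_modules(D, genes, min_module_size=2, cut_height_quantile=0.99)
    assert ms.labels.nunique() == 1
    ms2 = cx.detect_modules(D, genes, min_module_size=2, cut_height_quantile=0.99)
    pd.testing.assert_series_equal(ms.labels, ms2.labels)


def test_planted_four_module_recovery():
    sim, truth_labels = planted_profiles(noise_sd=0.3, seed=7)
    adj = cx.soft_adjacency(sim.profiles.matrix, beta=5)
    tom = cx.topological_overlap(adj)
    ms = cx.detect_modules(1 - tom, sim.profiles.genes, min_module_size=30,
                           cut_height_quantile=0.9875)
    ari = adjusted_rand_score(truth_labels[ms.labels.index], ms.labels)
    assert ari >= 0.9


def test_gene_order_permutation_invariance(rng):
    sim, _ = planted_profiles(n_modules=2, module_size=20, seed=3, n_drugs=12)
    mat = sim.profiles.matrix
    perm = rng.permutation(len(mat))
    shuffled = mat.iloc[perm]
    adj1 = cx.soft_adjacency(mat, beta=5)
    adj2 = cx.soft_adjacency(shuffled, beta=5)
    tom1 = cx.topological_overlap(adj1)
    tom2 = cx.topological_overlap(adj2)
    ms1 = cx.detect_modules(1 - tom1, mat.index, min_module_size=5, cut_height_quantile=0.97)
    ms2 = cx.detect_modules(1 - tom2, shuffled.index, min_module_size=5, cut_height_quantile=0.97)
    # same partition on the same genes, up to label renaming
    assert adjusted_rand_score(ms1.labels[mat.index], ms2.labels[mat.index]) == pytest.approx(1.0)


# ------------------------------------------------------------- eigengenes

def test_identical_pair_eigengene():
    rng = np.random.default_rng(1)
    g = rng.normal(size=12)
    mat = pd.DataFrame([g, g.copy()], index=["g1", "g2"],
                       columns=[f"p{i}" for i in range(12)])
    labels = pd.Series([1, 1], index=["g1", "g2"])
    mes = cx.module_eigengenes(mat, labels)
    r = np.corrcoef(mes.loc[1], g)[0, 1]
    assert abs(r) == pytest.approx(1.0)
    assert np.linalg.norm(mes.loc[1]) == pytest.approx(1.0)


def test_sign_flip_orientation():
    sim, _ = planted_profiles(n_modules=1, module_size=10, seed=5, n_drugs=12)
    mat = sim.profiles.matrix
    labels = pd.Series(1, index=mat.index)
    me1 = cx.module_eigengenes(mat, labels).loc[1]
    me2 = cx.module_eigengenes(-mat, labels).loc[1]
    # eigengene flips with the data ...
    assert np.corrcoef(me1, me2)[0, 1] == pytest.approx(-1.0, abs=1e-6)
    # ... but each is positively oriented to its own module mean
    for m, me in ((mat, me1), (-mat, me2)):
        z = (m.sub(m.mean(axis=1), axis=0)).div(m.std(axis=1, ddof=1), axis=0)
        assert np.corrcoef(me, z.mean(axis=0))[0, 1] > 0


def test_factor_recovery():
    sim, _ = planted_profiles(n_modules=1, module_size=10, noise_sd=0.3, seed=9, n_drugs=20)
    mat = sim.profiles.matrix
    mes = cx.module_eigengenes(mat, pd.Series(1, index=mat.index))
    factor = sim.factors.loc[1].to_numpy()
    r = np.corrcoef(mes.loc[1], factor)[0, 1]
    assert r ** 2 >= 0.9


# ---------------------------------------------------------------- merging

def test_identical_modules_merge():
    rng = np.random.default_rng(2)
    f = rng.normal(size=15)
    rows = [f + rng.normal(0, 0.05, 15) for _ in range(6)]
    mat = pd.DataFrame(rows, index=[f"g{i}" for i in range(6)],
                       columns=[f"p{i}" for i in range(15)])
    labels = pd.Series([1, 1, 1, 2, 2, 2], index=mat.index)
    merged = cx.merge_modules(mat, labels, dissim_threshold=0.3)
    assert len(merged.module_ids()) == 1


def test_threshold_zero_is_identity():
    sim, truth_labels = planted_profiles(n_modules=3, module_size=15, seed=4, n_drugs=12)
    mat = sim.profiles.matrix
    merged = cx.merge_modules(mat, truth_labels, dissim_threshold=0.0)
    assert adjusted_rand_score(truth_labels[mat.index], merged.labels[mat.index]) == 1.0
    assert len(merged.module_ids()) == 3


def test_duplicated_factors_merge_to_three():
    # 6 labelled modules but only 3 distinct latent factors
    rng = np.random.default_rng(11)
    n_p = 25
    factors = rng.normal(size=(3, n_p))
    rows, labels = [], []
    for module in range(6):
        f = factors[module % 3]
        for g in range(8):
            rows.append(f * rng.uniform(0.8, 1.0) + rng.normal(0, 0.15, n_p))
            labels.append(module + 1)
    mat = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                       columns=[f"p{i}" for i in range(n_p)])
    merged = cx.merge_modules(mat, pd.Series(labels, index=mat.index),
                              dissim_threshold=0.3)
    assert len(merged.module_ids()) == 3


def test_merge_monotone_in_threshold():
    sim, truth_labels = planted_profiles(n_modules=4, module_size=12, seed=6, n_drugs=12)
    mat = sim.profiles.matrix
    counts = []
    for thr in (0.0, 0.3, 0.8, 1.2, 2.0):
        merged = cx.merge_modules(mat, truth_labels, dissim_threshold=thr)
        counts.append(len(merged.module_ids()))
    assert counts == sorted(counts, reverse=True)


# -------------------------------------------------------------- membership

def _membership_setup(seed=13):
    sim, _ = planted_profiles(n_modules=2, module_size=12, seed=seed, n_drugs=14)
    mat = sim.profiles.matrix
    labels = pd.Series([1] * 12 + [2] * 12, index=mat.index)
    ms = cx.merge_modules(mat, labels, dissim_threshold=0.0)
    mm = cx.module_membership(mat, ms)
    return mat, ms, mm


def test_gene_equal_to_eigengene_mm_one():
    mat, ms, _ = _membership_setup()
    with_me = pd.concat(
        [mat, pd.DataFrame([ms.eigengenes.loc[1]], index=["me_gene"])]
    )
    labels2 = pd.Series(list(ms.labels) + [1], index=with_me.index)
    ms2 = cx.ModuleSet(labels2, eigengenes=ms.eigengenes)
    mm = cx.module_membership(with_me, ms2)
    assert mm.loc["me_gene", 1] == pytest.approx(1.0, abs=1e-6)
    assert "me_gene" in cx.select_core_genes(mm, 1, mm_min=0.99)


def test_mm_min_one_empty_selection():
    _, _, mm = _membership_setup()
    assert cx.select_core_genes(mm, 1, mm_min=1.0) == []


def test_membership_matches_correlation_oracle():
    mat, ms, mm = _membership_setup()
    for gene in list(mat.index)[:6]:
        for module in ms.eigengenes.index:
            expected = sps.pearsonr(mat.loc[gene], ms.eigengenes.loc[module])[0]
            assert mm.loc[gene, module] == pytest.approx(expected, abs=1e-10)


def test_high_loading_genes_selected():
    rng = np.random.default_rng(21)
    n_p = 30
    f = rng.normal(size=n_p)
    high = [0.99 * f + rng.normal(0, 0.05, n_p) for _ in range(6)]
    low = [0.5 * f + rng.normal(0, 0.8, n_p) for _ in range(6)]
    mat = pd.DataFrame(high + low, index=[f"h{i}" for i in range(6)] + [f"l{i}" for i in range(6)],
                       columns=[f"p{i}" for i in range(n_p)])
    labels = pd.Series(1, index=mat.index)
    ms = cx.merge_modules(mat, labels, dissim_threshold=0.0)
    mm = cx.module_membership(mat, ms)
    core = cx.select_core_genes(mm, 1, mm_min=0.95)
    assert set(core) >= {f"h{i}" for i in range(6)} or len(set(core) & {f"h{i}" for i in range(6)}) >= 5
    assert not any(g.startswith("l") for g in core)


def test_mm_affine_invariance():
    mat, ms, mm1 = _membership_setup()
    transformed = mat.mul(np.linspace(1, 4, len(mat)), axis=0).add(3.0)
    mm2 = cx.module_membership(transformed, ms)
    np.testing.assert_allclose(mm1.to_numpy(), mm2.to_numpy(), atol=1e-10)
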