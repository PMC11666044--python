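"""Edge-assignment rules, standardization, fusion, and edge accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popgcn import popgraph as pg
from popgcn.popgraph import (
    FeatureBlock,
    GraphConfig,
    blend_affinity,
    build_population_graph,
    concat_features,
    cosine_affinity,
    edge_composition,
    euclidean_affinity,
    fit_standardizer,
    normalize_adjacency,
    threshold_cosine,
    threshold_euclidean,
)


# ---------------------------------------------------------------------------
# standardization and fusion
# ---------------------------------------------------------------------------

def test_standardizer_hand_computed_population_sd():
    block = FeatureBlock(np.array([[2.0], [4.0], [6.0]]), kind="non-imaging")
    std = fit_standardizer(block, np.arange(3))
    out = std.transform(block.matrix)[:, 0]
    np.testing.assert_allclose(out, [-1.2247, 0.0, 1.2247], atol=1e-4)


def test_standardizer_constant_column_flagged_and_zeroed():
    block = FeatureBlock(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]), kind="imaging")
    std = fit_standardizer(block, np.arange(3))
    assert std.zero_sd.tolist() == [False, True]
    assert np.all(std.transform(block.matrix)[:, 1] == 0.0)


def test_standardizer_train_statistics_apply_to_test_rows():
    rng = np.random.default_rng(0)
    block = FeatureBlock(rng.normal(5, 3, size=(20, 4)), kind="imaging")
    std = fit_standardizer(block, np.arange(10))
    # a test row equal to the training mean maps to the zero vector
    out = std.transform(block.matrix[:10].mean(axis=0, keepdims=True))
    np.testing.assert_allclose(out, 0.0, atol=1e-12)
    # training rows have column mean 0, SD 1
    z = std.transform(block.matrix[:10])
    np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-12)


def test_fusion_width_and_ordering():
    rng = np.random.default_rng(1)
    img = FeatureBlock(rng.normal(size=(5, 256)), kind="imaging")
    nimg = FeatureBlock(rng.normal(size=(5, 6)), kind="non-imaging")
    X = concat_features(img, nimg)
    assert X.shape == (5, 262)
    np.testing.assert_array_equal(X[:, 0], img.matrix[:, 0])
    np.testing.assert_array_equal(X[:, 256:], nimg.matrix)
    # empty non-imaging block: fusion is the identity (ablation mode)
    np.testing.assert_array_equal(concat_features(img.matrix, np.empty((5, 0))), img.matrix)
    with pytest.raises(ValueError):
        concat_features(img.matrix, rng.normal(size=(4, 6)))


# ---------------------------------------------------------------------------
# affinities
# ---------------------------------------------------------------------------

def test_cosine_affinity_hand_cases():
    Z = np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 2.0], [3.0, 0.0]])
    A = cosine_affinity(Z)
    assert A == pytest.approx(A.T)
    np.testing.assert_allclose(np.diag(A), 1.0)
    assert A[0, 1] == pytest.approx(0.7071, abs=1e-4)
    assert A[0, 2] == pytest.approx(0.0, abs=1e-12)  # orthogonal
    assert A[0, 3] == pytest.approx(1.0)  # parallel


def test_cosine_zero_norm_guard():
    Z = np.array([[0.0, 0.0], [1.0, 2.0]])
    A = cosine_affinity(Z)
    assert A[0, 1] == 0.0 and A[1, 0] == 0.0
    assert A[0, 0] == 1.0  # diagonal convention survives the guard


def test_euclidean_affinity_hand_case_and_homogeneity():
    Z = np.array([[0.0, 0.0], [3.0, 4.0]])
    A = euclidean_affinity(Z, 2)
    assert A[0, 1] == pytest.approx(2.5)  # 5 / p with p = 2
    assert A[0, 0] == 0.0
    np.testing.assert_allclose(euclidean_affinity(3.0 * Z, 2), 3.0 * A)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    beta=st.floats(0.0, 1.0),
    seed=st.integers(0, 1000),
)
def test_blend_is_convex_combination(beta, seed):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(6, 6))
    A = (A + A.T) / 2
    B = rng.normal(size=(6, 6))
    B = (B + B.T) / 2
    M = blend_affinity(A, B, beta)
    np.testing.assert_allclose(M, beta * A + (1 - beta) * B, atol=1e-12)
    np.testing.assert_allclose(M, M.T, atol=1e-12)


def test_blend_endpoints_exact():
    A = np.full((3, 3), 2.0)
    B = np.full((3, 3), -1.0)
    np.testing.assert_array_equal(blend_affinity(A, B, 0.0), B)
    np.testing.assert_array_equal(blend_affinity(A, B, 1.0), A)
    assert blend_affinity(np.array([[1.0]]), np.array([[0.5]]), 0.2)[0, 0] == pytest.approx(0.6)
    with pytest.raises(ValueError):
        blend_affinity(A, B, 1.1)


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

def test_threshold_cosine_inclusive_boundary_and_extremes():
    M = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.5], [0.2, 0.5, 1.0]])
    A = threshold_cosine(M, 0.5)
    assert A[0, 1] == 0.5  # entry exactly at the threshold is retained
    assert A[0, 2] == 0.0
    assert np.all(np.diag(A) == 0.0)  # stored diagonal zeroed
    assert np.count_nonzero(threshold_cosine(M, 1.5)) == 0  # above max: empty
    A_full = threshold_cosine(M, -1.0)  # below min: complete graph
    assert np.count_nonzero(A_full) == 6


def test_threshold_euclidean_toy_quantile():
    """Six pairwise distances 1..6: the 50th percentile is 3.5 -> 3 edges."""
    M = np.zeros((4, 4))
    iu = np.triu_indices(4, 1)
    M[iu] = [1, 2, 3, 4, 5, 6]
    M += M.T
    A, q = threshold_euclidean(M, 50.0)
    assert q == pytest.approx(3.5)
    assert int(A.sum()) // 2 == 3
    # a pair at exactly q_ED is connected (inclusive <=)
    M2 = M.copy()
    M2[0, 1] = M2[1, 0] = q
    A2, q2 = threshold_euclidean(M2, 50.0)
    assert A2[0, 1] == 1.0
    # alpha = 100: everything connected
    A3, _ = threshold_euclidean(M, 100.0)
    assert int(A3.sum()) // 2 == 6
    with pytest.raises(ValueError):
        threshold_euclidean(M, 0.0)
    with pytest.raises(ValueError):
        threshold_euclidean(np.zeros((1, 1)), 50.0)


def test_threshold_euclidean_quantile_calibration():
    """Connected-pair fraction tracks alpha/100 within one quantile step."""
    rng = np.random.default_rng(0)
    Z = rng.normal(size=(40, 5))
    M = euclidean_affinity(Z, 5)
    n_pairs = 40 * 39 // 2
    for alpha in (10.0, 25.0, 50.0, 90.0):
        A, _ = threshold_euclidean(M, alpha)
        frac = (A.sum() / 2) / n_pairs
        assert abs(frac - alpha / 100.0) <= 1.0 / n_pairs + 1e-12


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_normalize_adjacency_hand_cases_and_spectrum():
    np.testing.assert_array_equal(normalize_adjacency(np.zeros((3, 3))), np.eye(3))
    A = np.array([[0.0, 1.0], [1.0, 0.0]])
    np.testing.assert_allclose(normalize_adjacency(A), [[0.5, 0.5], [0.5, 0.5]])
    rng = np.random.default_rng(3)
    for _ in range(5):
        B = rng.random((8, 8)) < 0.4
        B = np.triu(B, 1).astype(float)
        B = B + B.T
        Ah = normalize_adjacency(B)
        np.testing.assert_allclose(Ah, Ah.T, atol=1e-12)
        eig = np.linalg.eigvalsh(Ah)
        assert eig.min() >= -1.0 - 1e-10 and eig.max() <= 1.0 + 1e-10
    with pytest.raises(ValueError):
        normalize_adjacency(np.array([[0.0, 1.0], [0.0, 0.0]]))


# ---------------------------------------------------------------------------
# brute-force oracle equivalence
# ---------------------------------------------------------------------------

def brute_force_adjacency(z_img, z_nimg, measure, beta, alpha):
    """Entrywise double-loop evaluation of the edge-assignment rules."""
    n = len(z_img)

    def cos(u, v):
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-12 or nv < 1e-12:
            return 0.0
        return float(u @ v / (nu * nv))

    A_img = np.zeros((n, n))
    A_nimg = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if measure == "cosine":
                A_img[i, j] = 1.0 if i == j else cos(z_img[i], z_img[j])
                A_nimg[i, j] = 1.0 if i == j else cos(z_nimg[i], z_nimg[j])
            else:
                A_img[i, j] = np.linalg.norm(z_img[i] - z_img[j]) / z_img.shape[1]
                A_nimg[i, j] = np.linalg.norm(z_nimg[i] - z_nimg[j]) / z_nimg.shape[1]
    M = beta * A_img + (1 - beta) * A_nimg
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if measure == "cosine":
                A[i, j] = M[i, j] if M[i, j] >= alpha else 0.0
            else:
                iu = np.triu_indices(n, 1)
                q = np.percentile(M[iu], alpha)
                A[i, j] = 1.0 if M[i, j] <= q else 0.0
    return A


@pytest.mark.parametrize("measure", ["cosine", "euclidean"])
def test_vectorized_adjacency_equals_brute_force(measure):
    rng = np.random.default_rng(12345)
    for trial in range(50):
        n = int(rng.integers(5, 31))
        z_img = rng.normal(size=(n, 7))
        z_nimg = rng.normal(size=(n, 3))
        beta = float(rng.random())
        if measure == "cosine":
            alpha = float(rng.uniform(-0.2, 0.9))
            M = blend_affinity(cosine_affinity(z_img), cosine_affinity(z_nimg), beta)
            A = threshold_cosine(M, alpha)
            ref = brute_force_adjacency(z_img, z_nimg, measure, beta, alpha)
            np.testing.assert_allclose(A, ref, atol=1e-10)
        else:
            alpha = float(rng.uniform(5, 95))
            M = blend_affinity(
                euclidean_affinity(z_img, 7), euclidean_affinity(z_nimg, 3), beta
            )
            A, _ = threshold_euclidean(M, alpha)
            ref = brute_force_adjacency(z_img, z_nimg, measure, beta, alpha)
            np.testing.assert_array_equal(A, ref)


# ---------------------------------------------------------------------------
# graph builder
# ---------------------------------------------------------------------------

def _blocks(seed=0, n=24):
    rng = np.random.default_rng(seed)
    img = FeatureBlock(rng.normal(size=(n, 10)), kind="imaging")
    nimg = FeatureBlock(rng.normal(size=(n, 4)), kind="non-imaging")
    return img, nimg


def test_build_population_graph_shapes_and_masks():
    img, nimg = _blocks()
    labels = np.repeat([0, 1, 2], 8)
    cfg = GraphConfig(measure="euclidean", beta=0.4, alpha_ed=30.0)
    g = build_population_graph(
        img, nimg, labels, cfg, np.arange(12), np.arange(12, 18), np.arange(18, 24)
    )
    assert g.X.shape == (24, 14)
    assert cfg.q_ed is not None
    assert g.train_mask.sum() == 12 and g.val_mask.sum() == 6 and g.test_mask.sum() == 6
    assert not (g.train_mask & g.test_mask).any()
    np.testing.assert_allclose(g.A_hat, g.A_hat.T, atol=1e-12)


@pytest.mark.parametrize(
    "measure,beta,varies",
    [("cosine", 0.0, "img"), ("cosine", 1.0, "nimg"),
     ("euclidean", 0.0, "img"), ("euclidean", 1.0, "nimg")],
)
def test_beta_endpoints_ignore_the_other_block(measure, beta, varies):
    """At beta=0 (1) the adjacency is invariant to the imaging (clinical) block."""
    img, nimg = _blocks(seed=1)
    labels = np.repeat([0, 1, 2], 8)
    kw = dict(alpha_cs=0.1) if measure == "cosine" else dict(alpha_ed=40.0)
    tr, va, te = np.arange(12), np.arange(12, 18), np.arange(18, 24)

    def adj(i_blk, n_blk):
        cfg = GraphConfig(measure=measure, beta=beta, **kw)
        return build_population_graph(i_blk, n_blk, labels, cfg, tr, va, te).A

    rng = np.random.default_rng(99)
    img2 = FeatureBlock(rng.normal(size=img.matrix.shape) * 10, kind="imaging")
    nimg2 = FeatureBlock(rng.normal(size=nimg.matrix.shape) * 10, kind="non-imaging")
    if varies == "img":
        np.testing.assert_array_equal(adj(img, nimg), adj(img2, nimg))
    else:
        np.testing.assert_array_equal(adj(img, nimg), adj(img, nimg2))


def test_graph_config_validation():
    with pytest.raises(ValueError):
        GraphConfig(measure="cosine", beta=0.5)  # missing alpha_cs
    with pytest.raises(ValueError):
        GraphConfig(measure="euclidean", beta=0.5, alpha_cs=0.3)
    with pytest.raises(ValueError):
        GraphConfig(measure="euclidean", beta=-0.1, alpha_ed=10.0)


# ---------------------------------------------------------------------------
# edge composition
# ---------------------------------------------------------------------------

def test_edge_composition_published_denominators():
    """Class sizes 76/155/237 give the six documented possible-edge counts."""
    labels = np.repeat([0, 1, 2], (76, 155, 237))
    n = len(labels)
    A = np.ones((n, n)) - np.eye(n)
    table = edge_composition(A, labels)
    expected = {
        "0-0": 2926, "0-1": 11780, "0-2": 18012,
        "1-1": 12090, "1-2": 36735, "2-2": 28203,
    }
    got = dict(zip(table["pair"], table["n_possible"]))
    assert got == expected
    # fully connected: numerators equal denominators
    assert (table["n_edges"] == table["n_possible"]).all()
    assert (table["percentage"] == 100.0).all()


def test_edge_composition_empty_graph_counts_self_edges():
    labels = np.repeat([0, 1, 2], (76, 155, 237))
    table = edge_composition(np.zeros((468, 468)), labels)
    got = dict(zip(table["pair"], table["n_edges"]))
    assert got == {"0-0": 76, "0-1": 0, "0-2": 0, "1-1": 155, "1-2": 0, "2-2": 237}


def test_edge_composition_enumerated_toy():
    labels = np.array([0, 0, 2, 2])
    A = np.zeros((4, 4))
    A[1, 2] = A[2, 1] = 1.0  # one NC-AD edge
    A[0, 1] = A[1, 0] = 1.0  # one NC-NC edge
    table = edge_composition(A, labels).set_index("pair")
    assert table.loc["0-2", "n_edges"] == 1 and table.loc["0-2", "n_possible"] == 4
    assert table.loc["0-0", "n_edges"] == 3  # 1 edge + 2 self-edges
    assert table.loc["0-0", "n_possible"] == 3  # 2 + C(2,2)=1
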