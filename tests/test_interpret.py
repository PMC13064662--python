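"""Attribution exactness, variant-map conservation, clustering, monotonicity."""

import numpy as np
import pytest
from scipy.stats import rankdata

from molmm import (ShapMap, extract_clusters, lattice_distances,
                   rank_monotonicity, relative_coefficients,
                   shapley_attribution, variant_shap)


# ---------------------------------------------------------------------
# attribution
# ---------------------------------------------------------------------

def test_constant_model_gets_zero_attributions():
    f = lambda z: np.full(len(z), 0.7)
    rng = np.random.default_rng(0)
    phi = shapley_attribution(f, rng.normal(size=(2, 5)),
                              rng.normal(size=(4, 5)), n_permutations=2)
    assert np.allclose(phi, 0.0)


def test_linear_model_attributions_are_exact_shapley_values():
    rng = np.random.default_rng(1)
    w = rng.normal(size=8)
    f = lambda z: z.reshape(len(z), -1) @ w
    x = rng.normal(size=(3, 8))
    bg = rng.normal(size=(12, 8))
    phi = shapley_attribution(f, x, bg, n_permutations=1, seed=0)
    assert np.allclose(phi, w * (x - bg.mean(axis=0)), atol=1e-12)


def test_local_accuracy_on_trained_network(tiny_trained_model):
    from molmm.model import predict_proba

    params, fmaps, _ = tiny_trained_model
    x = fmaps[:3]
    bg = fmaps[10:30]
    f = lambda z: predict_proba(params, z, task="L")
    phi = shapley_attribution(f, x, bg, n_permutations=2, seed=0)
    residual = phi.reshape(3, -1).sum(axis=1) - (f(x) - f(bg).mean())
    assert np.abs(residual).max() < 1e-3


def test_empty_background_rejected():
    with pytest.raises(ValueError):
        shapley_attribution(lambda z: z.sum(axis=1), np.ones((1, 3)),
                            np.empty((0, 3)))


# ---------------------------------------------------------------------
# variant maps
# ---------------------------------------------------------------------

def test_two_pixel_variant_hand_computation():
    s = np.array([[0.4, 0.2]])
    v = variant_shap(s, shap_alpha=1.0, cutoff_c=1.0)
    assert np.allclose(v, [[0.6, 0.0]])
    assert v.sum() == pytest.approx(0.6)


def test_cutoff_zero_and_uniform_grid_are_identities():
    rng = np.random.default_rng(2)
    g = rng.normal(size=(5, 5))
    assert np.allclose(variant_shap(g, cutoff_c=0.0), g)
    flat = np.full((4, 4), 1.3)
    assert np.allclose(variant_shap(flat, cutoff_c=2.0), flat)


@pytest.mark.parametrize("seed", range(10))
def test_sum_conservation_on_random_grids(seed):
    rng = np.random.default_rng(seed)
    g = rng.normal(size=(8, 8))
    v = variant_shap(g, shap_alpha=0.7, cutoff_c=2.0)
    assert abs(v.sum() - g.sum()) < 1e-9


def test_variant_is_translation_equivariant_away_from_borders():
    g1 = np.zeros((12, 12))
    g1[3:6, 3:6] = [[1, 2, 1], [2, 5, 2], [1, 2, 1]]
    g2 = np.zeros((12, 12))
    g2[5:8, 6:9] = [[1, 2, 1], [2, 5, 2], [1, 2, 1]]
    v1 = variant_shap(g1, cutoff_c=2.0)
    v2 = variant_shap(g2, cutoff_c=2.0)
    assert np.allclose(v1[2:7, 2:7], v2[4:9, 5:10])


def test_invalid_parameters_rejected():
    g = np.ones((3, 3))
    with pytest.raises(ValueError):
        variant_shap(g, shap_alpha=0.0)
    with pytest.raises(ValueError):
        variant_shap(g, cutoff_c=-1.0)


def test_shapmap_aggregation_modes():
    per_mol = np.array([[[1.0, -1.0]], [[3.0, -3.0]]])   # 2 molecules, 1x2
    signed = ShapMap.from_attributions(per_mol, mode="signed_mean")
    intensity = ShapMap.from_attributions(per_mol, mode="abs_mean")
    assert np.allclose(signed.shap, [[2.0, -2.0]])
    assert np.allclose(intensity.shap, [[2.0, 2.0]])


# ---------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------

def test_single_peak_yields_one_cluster_of_its_neighborhood():
    grid = np.zeros((3, 3))
    grid[1, 1] = 1.0
    tree = extract_clusters(grid, cutoff_c=1.0)
    assert len(tree.clusters) == 1
    cl = tree.clusters[0]
    assert cl.seed == (1, 1)
    assert set(cl.members) == {(1, 1), (0, 1), (1, 0), (1, 2), (2, 1)}
    assert cl.members[0] == (1, 1)            # sorted by value descending


def test_two_distant_peaks_yield_two_disjoint_clusters():
    g = np.zeros((9, 9))
    g[1, 1] = 1.0
    g[7, 7] = 2.0
    tree = extract_clusters(g, cutoff_c=2.0)
    assert {c.seed for c in tree.clusters} == {(1, 1), (7, 7)}
    members = [set(c.members) for c in tree.clusters]
    assert not members[0] & members[1]


def test_flat_grid_collapses_to_single_row_major_seed():
    tree = extract_clusters(np.ones((3, 3)), cutoff_c=1.0)
    assert [c.seed for c in tree.clusters] == [(0, 0)]


@pytest.mark.parametrize("seed", range(5))
def test_members_never_exceed_cutoff_from_seed(seed):
    rng = np.random.default_rng(seed)
    g = rng.normal(size=(8, 8))
    tree = extract_clusters(g, cutoff_c=2.0)
    for cl in tree.clusters:
        for m in cl.members:
            assert np.hypot(m[0] - cl.seed[0], m[1] - cl.seed[1]) <= 2.0


def test_cluster_values_sorted_descending_with_linkage():
    rng = np.random.default_rng(7)
    g = rng.normal(size=(6, 6))
    tree = extract_clusters(g, cutoff_c=2.0)
    assert tree.clusters
    for cl in tree.clusters:
        assert cl.values == sorted(cl.values, reverse=True)
        if len(cl.members) > 1:
            assert cl.linkage is not None
            assert cl.linkage.shape == (len(cl.members) - 1, 4)


# ---------------------------------------------------------------------
# monotonicity and relative coefficients
# ---------------------------------------------------------------------

def test_strictly_increasing_pairs_get_asterisk():
    rho, sign, mark = rank_monotonicity([1, 2, 3, 4], [10, 20, 30, 40])
    assert rho == pytest.approx(1.0)
    assert (sign, mark) == ("p", "asterisk")


def test_rank_invariance_under_monotone_transform():
    x = np.linspace(-2, 2, 12)
    rho, _, _ = rank_monotonicity(x, np.exp(x))
    assert rho == pytest.approx(1.0)


def test_spearman_matches_rank_then_pearson_oracle():
    rng = np.random.default_rng(3)
    for _ in range(20):
        x = np.round(rng.random(15), 1)    # ties likely
        s = np.round(rng.random(15), 1)
        if np.all(x == x[0]) or np.all(s == s[0]):
            continue
        rho, _, _ = rank_monotonicity(x, s)
        rx, rs = rankdata(x), rankdata(s)
        oracle = np.corrcoef(rx, rs)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)


def test_monotonicity_marks_thresholds():
    # rho just above each threshold in magnitude, negative direction
    x = np.arange(10.0)
    rng = np.random.default_rng(5)
    for target, expected in ((0.5, "none"), (0.85, "labeled"),
                             (0.95, "asterisk")):
        # binary search is overkill: construct by mixing a perfect ranking
        # with noise until the band is hit
        for _ in range(200):
            s = -(x + rng.normal(0, 3.0, 10))
            rho, sign, mark = rank_monotonicity(x, s)
            lo, hi = {"none": (0, 0.8), "labeled": (0.8, 0.9),
                      "asterisk": (0.9, 1.01)}[expected]
            if lo < abs(rho) <= hi and not (abs(rho) in (0.8, 0.9)):
                assert sign == ("n" if rho < 0 else "p")
                assert mark == expected
                break
        else:
            pytest.skip("band not hit; construction failure, not a defect")


def test_rank_monotonicity_preconditions():
    with pytest.raises(ValueError):
        rank_monotonicity([1, 2], [3, 4])
    with pytest.raises(ValueError):
        rank_monotonicity([1, 1, 1], [1, 2, 3])


def test_relative_coefficients_affine_and_conventions():
    assert np.allclose(relative_coefficients([2, 4, 6]), [0, 0.5, 1])
    assert np.allclose(relative_coefficients([5]), [1])
    assert np.allclose(relative_coefficients([3, 3, 3]), [1, 1, 1])
    v = np.array([1.0, 2.0, 5.0])
    assert np.allclose(relative_coefficients(v),
                       relative_coefficients(10 * v + 7))
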