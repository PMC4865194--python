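"""MEM construction, AICc neighbourhood selection, forward selection,
scale classification and geomorphology pruning."""

import numpy as np
import pytest

import betascape as b
from betascape.mem import aicc
from oracles import prim_mst_max_edge, sequential_forward_selection


def chain_coords(n):
    return np.column_stack([np.arange(n, dtype=float), np.zeros(n)])


class TestCandidateThresholds:
    def test_three_collinear_sites(self):
        c = b.candidate_thresholds(chain_coords(3), 5)
        assert c[0] == pytest.approx(1.0)
        assert c[-1] == pytest.approx(2.0)

    def test_lattice_mst_matches_prim_oracle(self):
        xx, yy = np.meshgrid(np.arange(5.0), np.arange(5.0))
        coords = np.column_stack([xx.ravel(), yy.ravel()])
        c = b.candidate_thresholds(coords, 10)
        assert c[0] == pytest.approx(1.0)
        assert c[0] == pytest.approx(prim_mst_max_edge(coords))

    def test_random_sites_match_prim_oracle(self):
        rng = np.random.default_rng(2)
        coords = rng.random((30, 2)) * 10
        c = b.candidate_thresholds(coords, 50)
        assert c[0] == pytest.approx(prim_mst_max_edge(coords), abs=1e-10)
        assert len(c) == 50
        assert np.allclose(np.diff(c), np.diff(c)[0])

    def test_coincident_sites_rejected(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="coincident"):
            b.candidate_thresholds(coords, 5)


class TestMemBasis:
    def test_complete_graph_has_no_positive_structure(self):
        # direct eigendecomposition at n=4: centred complete graph is -C,
        # whose nonzero eigenvalues are all negative
        W = np.ones((4, 4)) - np.eye(4)
        C = np.eye(4) - np.ones((4, 4)) / 4
        evals = np.linalg.eigvalsh(C @ W @ C)
        assert evals.max() < 1e-12
        with pytest.raises(ValueError, match="no positive spatial structure"):
            b.mem_basis(b.SpatialWeightMatrix(W, 1.0))

    def test_three_site_chain_has_no_positive_vector(self):
        # the only zero-mean contrast along a 3-chain, (-1,0,1)/sqrt(2),
        # has Wz = 0 hence Moran's I exactly 0: no positive structure exists
        W = np.array([[0.0, 1, 0], [1, 0, 1], [0, 1, 0]])
        z = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2)
        assert float(z @ W @ z) == 0.0
        with pytest.raises(ValueError, match="no positive spatial structure"):
            b.mem_basis(b.SpatialWeightMatrix(W, 1.0))

    def test_four_site_chain_single_gradient_vector(self):
        # hand eigendecomposition: one positive eigenvalue (golden-ratio
        # conjugate 0.618...) with an antisymmetric monotone gradient vector
        W = np.zeros((4, 4))
        for i in range(3):
            W[i, i + 1] = W[i + 1, i] = 1
        basis = b.mem_basis(b.SpatialWeightMatrix(W, 1.0))
        assert basis.n_vectors == 1
        assert basis.eigenvalues[0] == pytest.approx((np.sqrt(5) - 1) / 2, abs=1e-10)
        v = basis.vectors[:, 0] * np.sign(basis.vectors[0, 0])
        assert v[0] > v[1] > 0 > v[2] > v[3]
        assert np.allclose(v, -v[::-1], atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_orthonormality_and_moran_identity(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.random((40, 2)) * 10
        W = b.distance_band_weights(coords, 3.0)
        basis = b.mem_basis(W)
        V = basis.vectors
        assert np.allclose(V.T @ V, np.eye(basis.n_vectors), atol=1e-10)
        assert np.abs(V.sum(axis=0)).max() < 1e-10
        for k in range(basis.n_vectors):
            I = b.morans_i(V[:, k], W)
            assert I == pytest.approx((W.n / W.total_weight) * basis.eigenvalues[k],
                                      abs=1e-10)

    def test_chain_vectors_are_sinusoids_of_increasing_frequency(self):
        # binary-adjacency chain MEMs match the sine family sin((k+1)*pi*x/(n+1));
        # the constant-vector projection demotes the half-wave, so vector k has
        # k+1 antinodes
        n = 30
        basis = b.mem_basis(b.distance_band_weights(chain_coords(n), 1.0))
        i = np.arange(1, n + 1)
        for k in (1, 2, 3):
            ref = np.sin((k + 1) * np.pi * i / (n + 1))
            c = abs(np.corrcoef(basis.vectors[:, k - 1], ref)[0, 1])
            assert c > 0.99


class TestAicc:
    def test_hand_formula_univariate_toy(self):
        # n=20, hand least-squares fit of y on one regressor
        rng = np.random.default_rng(3)
        x = rng.standard_normal(20)
        y = 2 * x + rng.standard_normal(20)
        xc, yc = x - x.mean(), y - y.mean()
        beta = (xc @ yc) / (xc @ xc)
        rss = float(((yc - beta * xc) ** 2).sum())
        k = 1
        expected = 20 * np.log(rss / 20) + 2 * (k + 1) + 2 * (k + 1) * (k + 2) / (20 - k - 2)
        assert aicc(20, rss, 1) == pytest.approx(expected, abs=1e-8)

    def test_undefined_df_raises(self):
        with pytest.raises(ValueError):
            aicc(10, 1.0, 8)


class TestSelectWeightMatrix:
    def test_single_candidate_trivially_selected(self):
        rng = np.random.default_rng(4)
        coords = rng.random((25, 2)) * 5
        Y = rng.random((25, 3))
        W, table = b.select_weight_matrix(Y, [2.0], coords)
        assert W.d_max_km == 2.0
        assert len(table) == 1 and np.isfinite(table["aicc"]).all()

    def test_planted_threshold_recovered(self):
        rng = np.random.default_rng(5)
        coords = rng.random((80, 2)) * 10
        cands = b.candidate_thresholds(coords, 6)
        true_d = cands[2]
        basis = b.mem_basis(b.distance_band_weights(coords, true_d))
        signal = basis.vectors[:, :3] @ rng.standard_normal((3, 4))
        noise = rng.standard_normal(signal.shape)
        noise *= np.sqrt((signal ** 2).sum() / 5.0 / (noise ** 2).sum())
        W, _ = b.select_weight_matrix(signal + noise, cands, coords)
        assert W.d_max_km == pytest.approx(true_d)


class TestForwardSelect:
    def test_orthogonal_response_selects_nothing(self):
        basis = b.mem_basis(b.distance_band_weights(chain_coords(20), 1.0))
        rng = np.random.default_rng(6)
        Y = rng.standard_normal((20, 3))
        # project out every MEM and the constant: response orthogonal to basis
        V = np.column_stack([np.ones(20) / np.sqrt(20), basis.vectors])
        Y = Y - V @ (V.T @ Y)
        sel = b.forward_select(Y, basis, n_perm=99, seed=1)
        assert sel == []

    def test_single_true_mem_selected_then_stop(self):
        basis = b.mem_basis(b.distance_band_weights(chain_coords(40), 1.0))
        rng = np.random.default_rng(7)
        Y = np.outer(basis.vectors[:, 2], [1.0, 2.0]) + 1e-4 * rng.standard_normal((40, 2))
        sel = b.forward_select(Y, basis, n_perm=99, seed=2)
        assert sel == [2]

    def test_matches_independent_sequential_oracle(self):
        # p <= 6 candidate vectors, explicit-least-squares oracle
        mismatches = 0
        for trial in range(30):
            rng = np.random.default_rng(100 + trial)
            coords = rng.random((30, 2)) * 6
            basis = b.mem_basis(b.distance_band_weights(coords, 2.5))
            V = basis.vectors[:, :6]
            sub = b.MEMBasis(V, basis.eigenvalues[:6], basis.morans_i[:6],
                             basis.d_max_km, basis.total_weight)
            k = rng.integers(0, 3)
            Y = V[:, :k] @ rng.standard_normal((k, 3)) + rng.standard_normal((30, 3))
            got = b.forward_select(Y, sub, alpha=0.05, n_perm=99, seed=trial)
            want = sequential_forward_selection(Y, V, 0.05, 99, trial)
            if got != want:
                mismatches += 1
        assert mismatches == 0

    def test_never_selects_more_than_response_rank(self):
        basis = b.mem_basis(b.distance_band_weights(chain_coords(30), 1.0))
        rng = np.random.default_rng(8)
        Y = np.outer(basis.vectors[:, 0] + basis.vectors[:, 1], [1.0])  # rank 1
        sel = b.forward_select(Y, basis, n_perm=99, seed=3)
        assert len(sel) <= 1 + 1  # rank of projection space plus entry slack


class TestClassifyScales:
    def test_eigenvalue_split_q1(self):
        basis = b.mem_basis(b.distance_band_weights(chain_coords(10), 1.0))
        out = b.classify_scales(basis, [0, 3], rule="eigenvalue_split", param=1)
        assert out.scale_class[0] == "broad"
        assert out.scale_class[3] == "fine"

    def test_explicit_lists(self):
        basis = b.mem_basis(b.distance_band_weights(chain_coords(10), 1.0))
        out = b.classify_scales(basis, [0, 1, 2], rule="explicit",
                                param=([0, 2], [1]))
        assert list(out.scale_class[:3]) == ["broad", "fine", "broad"]

    def test_leading_chain_vector_is_broad_by_period(self):
        # the leading chain MEM is one full wave: two sign runs of length n/2
        n = 30
        basis = b.mem_basis(b.distance_band_weights(chain_coords(n), 1.0))
        out = b.classify_scales(basis, [0, basis.n_vectors - 1],
                                rule="period_threshold", param=10,
                                coords=chain_coords(n))
        assert out.scale_class[0] == "broad"
        assert out.scale_class[basis.n_vectors - 1] == "fine"

    def test_unknown_rule_rejected(self):
        basis = b.mem_basis(b.distance_band_weights(chain_coords(10), 1.0))
        with pytest.raises(ValueError):
            b.classify_scales(basis, [0], rule="nope")


class TestPruneVsGeo:
    def test_mem_equal_to_dummy_dropped(self):
        units = np.repeat(["A", "B"], 10)
        geo = b.dummy_code(units)
        col = geo.columns[:, 0]
        v = (col - col.mean())
        v /= np.linalg.norm(v)
        vectors = np.column_stack([v, np.random.default_rng(1).standard_normal(20)])
        vectors[:, 1] -= vectors[:, 1].mean()
        vectors[:, 1] /= np.linalg.norm(vectors[:, 1])
        basis = b.MEMBasis(vectors, np.array([1.0, 0.5]), np.array([1.0, 0.5]), 1.0, 10.0)
        retained, report = b.prune_vs_geo(basis, [0, 1], geo)
        assert 0 not in retained
        assert report.loc[report["mem"] == "MEM1", "r"].abs().iloc[0] == pytest.approx(1.0)

    def test_no_unit_structure_rarely_prunes(self):
        # a landscape with one block: MEMs should rarely exceed |r|=0.3 with
        # dummies of a random, non-spatial labelling
        removals = 0
        total = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            coords = rng.random((60, 2)) * 10
            basis = b.mem_basis(b.distance_band_weights(coords, 3.0))
            units = rng.choice(["A", "B", "C", "D"], size=60)
            geo = b.dummy_code(units)
            sel = list(range(min(10, basis.n_vectors)))
            retained, _ = b.prune_vs_geo(basis, sel, geo)
            removals += len(sel) - len(retained)
            total += len(sel)
        assert removals / total < 0.3
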