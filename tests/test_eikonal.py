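import heapq

import numpy as np
import pytest
from scipy.sparse.csgraph import breadth_first_order

from graphtow import (
    EikonalSpec,
    LabelSeeds,
    SimilarityConfig,
    WeightedGraph,
    classify_semi_supervised,
    local_update,
    propagate_labels,
    solve_eikonal,
    superpixels,
)
from graphtow.estimators import EikonalClassifier
from graphtow.synthetic import FixtureConfig, generate_blob_features
from conftest import path_graph, random_connected_graph


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def relaxation_oracle(graph, spec, sweeps=None):
    """Exhaustive Gauss-Jacobi relaxation of the discrete eikonal fixed
    point; independent of the label-setting solver."""
    n = graph.n_vertices
    h = spec.potential(n)
    u = np.full(n, np.inf)
    u[spec.seeds] = spec.seed_values
    for _ in range(sweeps or 3 * n):
        prev = u.copy()
        for x in range(n):
            if x in set(spec.seeds.tolist()):
                continue
            nbrs = graph.neighbors(x)
            k = 1.0 / np.sqrt(graph.neighbor_weights(x))
            if np.isfinite(prev[nbrs]).any():
                u[x] = min(u[x], local_update(prev[nbrs], k, float(h[x]), spec.p))
        if np.array_equal(prev, u):
            break
    return u


def fmm_grid_oracle(H, W, seed_rc):
    """Independent fast-marching reimplementation on a unit 4-grid with
    h = 1: array-based, offset neighbours, quadratic Osher-Sethian update."""
    u = np.full((H, W), np.inf)
    done = np.zeros((H, W), bool)
    heap = [(0.0, seed_rc)]
    u[seed_rc] = 0.0

    def update(r, c):
        # axis-wise upwind minima; quadratic when the gap is within h = 1
        ax = sorted([min(u[r + dr, c] if 0 <= r + dr < H and done[r + dr, c]
                         else np.inf for dr in (-1, 1)),
                     min(u[r, c + dc] if 0 <= c + dc < W and done[r, c + dc]
                         else np.inf for dc in (-1, 1))])
        a1, a2 = ax
        if a2 - a1 < 1.0:
            return 0.5 * (a1 + a2 + np.sqrt(2.0 - (a2 - a1) ** 2))
        return a1 + 1.0

    while heap:
        val, (r, c) = heapq.heappop(heap)
        if done[r, c]:
            continue
        done[r, c] = True
        u[r, c] = val
        for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W and not done[rr, cc]:
                heapq.heappush(heap, (update(rr, cc), (rr, cc)))
    return u


# ---------------------------------------------------------------------------
# local update
# ---------------------------------------------------------------------------

class TestLocalUpdate:
    @pytest.mark.parametrize("a,k,C,p,expected", [
        ((1, 3), (1, 1), 1.0, np.inf, 2.0),
        ((0, 0), (1, 1), 1.0, 2, 1 / np.sqrt(2)),
        ((0,), (1,), 1.0, np.inf, 1.0),
        ((0,), (1,), 1.0, 1, 1.0),
        ((0,), (1,), 1.0, 2, 1.0),
        ((0, 10), (1, 1), 1.0, 2, 1.0),       # far neighbour inactive
        ((0, 0), (1, 1), 1.0, 1, 0.5),        # L1: x/1 + x/1 = 1
        ((2, 3), (2, 1), 4.0, np.inf, 7.0),   # min(2 + 8, 3 + 4)
    ])
    def test_closed_forms(self, a, k, C, p, expected):
        assert local_update(a, k, C, p) == pytest.approx(expected, abs=1e-12)

    def test_empty_neighbour_list_rejected(self):
        with pytest.raises(ValueError):
            local_update([], [], 1.0)

    def test_infinite_neighbours_inactive(self):
        assert local_update([np.inf, 2.0], [1.0, 1.0], 1.0, 2) == pytest.approx(3.0)
        assert local_update([np.inf], [1.0], 1.0, 2) == np.inf

    @pytest.mark.parametrize("p", [1, 2, np.inf])
    def test_homogeneity_in_C(self, p, rng):
        a = np.sort(rng.uniform(0, 2, 4))
        k = rng.uniform(0.5, 2, 4)
        C = 0.8
        base = local_update(a * 3, k, C * 3, p)
        assert local_update(a, k, C, p) * 3 == pytest.approx(base, rel=1e-12)

    @pytest.mark.parametrize("p", [1, 2, np.inf])
    def test_solves_discrete_equation(self, p, rng):
        # substitute x* back into sum k^-p ((x - a)^+)^p = C^p
        for _ in range(30):
            m = int(rng.integers(1, 6))
            a = rng.uniform(0, 3, m)
            k = rng.uniform(0.5, 2, m)
            C = float(rng.uniform(0.2, 2))
            x = local_update(a, k, C, p)
            if np.isinf(p):
                resid = np.max((np.maximum(x - a, 0)) / k) - C
            else:
                resid = (k ** (-p) * np.maximum(x - a, 0) ** p).sum() ** (1 / p) - C
            assert abs(resid) < 1e-10


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

class TestSolveEikonal:
    def test_path_hop_distance(self):
        g = path_graph(4)
        u = solve_eikonal(g, EikonalSpec(seeds=[0]))
        assert np.array_equal(u, [0, 1, 2, 3])

    @pytest.mark.parametrize("seed", range(10))
    def test_unit_weights_exact_hop_distance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        g = random_connected_graph(rng, n, unit_weights=True)
        src = int(rng.integers(n))
        u = solve_eikonal(g, EikonalSpec(seeds=[src]))
        # BFS oracle
        order, preds = breadth_first_order(g.adj, src, directed=False)
        hops = np.full(n, np.inf)
        hops[src] = 0
        for v in order[1:]:
            hops[v] = hops[preds[v]] + 1
        assert np.array_equal(u, hops)

    @pytest.mark.parametrize("p", [1, 2, np.inf])
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_relaxation_oracle(self, p, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(8, 50))
        g = random_connected_graph(rng, n)
        seeds = rng.choice(n, size=max(1, n // 8), replace=False)
        h = rng.uniform(0.5, 2.0, n)
        spec = EikonalSpec(seeds=seeds, h=h, p=p)
        u = solve_eikonal(g, spec)
        oracle = relaxation_oracle(g, spec)
        assert np.max(np.abs(u - oracle)) < 1e-9

    def test_grid_p2_matches_independent_fmm(self):
        H = W = 11
        g = WeightedGraph.from_edges(
            H * W, [(r * W + c, r * W + c + 1, 1.0)
                    for r in range(H) for c in range(W - 1)] +
                   [(r * W + c, (r + 1) * W + c, 1.0)
                    for r in range(H - 1) for c in range(W)])
        centre = (H // 2) * W + W // 2
        u = solve_eikonal(g, EikonalSpec(seeds=[centre], p=2))
        oracle = fmm_grid_oracle(H, W, (H // 2, W // 2))
        assert np.max(np.abs(u.reshape(H, W) - oracle)) < 1e-9

    def test_potential_scaling_scales_values(self, rng):
        g = random_connected_graph(rng, 20)
        base = solve_eikonal(g, EikonalSpec(seeds=[0], h=1.0, p=2))
        scaled = solve_eikonal(g, EikonalSpec(seeds=[0], h=3.0, p=2))
        assert np.allclose(scaled, 3 * base, atol=1e-10)

    def test_unreachable_vertices_flagged_inf(self):
        g = WeightedGraph.from_edges(4, [(0, 1, 1.0), (2, 3, 1.0)])
        u = solve_eikonal(g, EikonalSpec(seeds=[0]))
        assert u[1] == 1.0 and np.isinf(u[2]) and np.isinf(u[3])

    def test_nonzero_seed_values(self):
        g = path_graph(4)
        u = solve_eikonal(g, EikonalSpec(seeds=[0, 3], seed_values=[0.0, 0.5]))
        assert np.allclose(u, [0, 1, 1.5, 0.5])

    def test_nonpositive_potential_rejected(self):
        with pytest.raises(ValueError):
            solve_eikonal(path_graph(3), EikonalSpec(seeds=[0], h=0.0))


class TestPropagateLabels:
    def test_five_path_tie_to_smaller_label(self):
        g = path_graph(5)
        seeds = LabelSeeds(labels=["A", "B"], seed_sets=[[0], [4]])
        labels, arrival = propagate_labels(g, seeds)
        assert labels.tolist() == [0, 0, 0, 1, 1]  # tie at 2 -> label A
        assert np.array_equal(arrival, [0, 1, 2, 1, 0])

    def test_single_label_covers_graph(self, rng):
        g = random_connected_graph(rng, 15)
        labels, _ = propagate_labels(g, LabelSeeds(labels=[7], seed_sets=[[3]]))
        assert np.all(labels == 0)

    def test_disjoint_components_keep_own_seed(self):
        g = WeightedGraph.from_edges(4, [(0, 1, 1.0), (2, 3, 1.0)])
        seeds = LabelSeeds(labels=[0, 1], seed_sets=[[0], [2]])
        labels, _ = propagate_labels(g, seeds)
        assert labels.tolist() == [0, 0, 1, 1]

    def test_overlapping_seed_sets_rejected(self):
        with pytest.raises(ValueError):
            LabelSeeds(labels=[0, 1], seed_sets=[[0, 1], [1, 2]])

    def test_each_region_contains_its_seeds(self, rng):
        g = random_connected_graph(rng, 30)
        sets = [[0, 1], [5], [9, 17]]
        labels, _ = propagate_labels(g, LabelSeeds(labels=[0, 1, 2], seed_sets=sets))
        for li, s in enumerate(sets):
            assert np.all(labels[s] == li)

    def test_invariant_to_vertex_relabeling(self, rng):
        n = 18
        g = random_connected_graph(rng, n)
        perm = rng.permutation(n)
        padj = g.adj[perm][:, perm]
        gp = WeightedGraph(padj)
        seeds = LabelSeeds(labels=[0, 1], seed_sets=[[2], [11]])
        inv = np.argsort(perm)
        seeds_p = LabelSeeds(labels=[0, 1], seed_sets=[[inv[2]], [inv[11]]])
        l1, a1 = propagate_labels(g, seeds, p=2)
        l2, a2 = propagate_labels(gp, seeds_p, p=2)
        # arrival values are permutation-equivariant
        assert np.allclose(a1[perm], a2, atol=1e-12)
        assert np.array_equal(l1[perm], l2)


class TestSuperpixels:
    def test_constant_image_counts(self):
        # odd spacing keeps every pixel strictly closer to one seed, so the
        # hop-distance Voronoi cells are exact equal rectangles
        regions = superpixels(np.full((10, 10), 0.5), spacing=5)
        assert regions.shape == (10, 10)
        assert regions.max() + 1 == 4
        counts = np.bincount(regions.ravel())
        assert np.all(counts == 25)

    def test_regions_contain_their_seeds(self):
        rng = np.random.default_rng(5)
        img = rng.random((15, 15))
        regions = superpixels(img, spacing=5)
        rs = np.arange(2, 15, 5)
        for i, r in enumerate(rs):
            for j, c in enumerate(rs):
                assert regions[r, c] == i * 3 + j

    def test_no_region_straddles_strong_edge(self):
        img = np.zeros((10, 10))
        img[:, 5:] = 1.0
        regions = superpixels(img, spacing=5,
                              cfg=SimilarityConfig(kind="exponential", sigma=0.05,
                                                   distance="sqeuclidean"))
        left = regions[:, :5].ravel()
        right = regions[:, 5:].ravel()
        assert set(left) & set(right) == set()

    def test_spacing_bounds(self):
        with pytest.raises(ValueError):
            superpixels(np.zeros((8, 8)), spacing=1)
        with pytest.raises(ValueError):
            superpixels(np.zeros((8, 8)), spacing=20)


class TestClassification:
    def test_far_separated_blobs_perfect(self):
        X, y = generate_blob_features(FixtureConfig(kind="blob_features", seed=2,
                                                    n_samples=120, n_classes=2,
                                                    separation=100.0))
        _, acc, _ = classify_semi_supervised(X, y, 0.1, k=5, p=1, seed=0)
        assert acc == 1.0

    def test_all_seeded_trivial(self):
        X, y = generate_blob_features(FixtureConfig(kind="blob_features", seed=2,
                                                    n_samples=60, n_classes=3))
        _, acc, _ = classify_semi_supervised(X, y, 1.0, k=5, p=1, seed=0)
        assert acc == 1.0

    @pytest.mark.parametrize("p", [1, 2])
    def test_default_fixture_accuracy(self, p):
        X, y = generate_blob_features(FixtureConfig(kind="blob_features", seed=11))
        _, acc, per_class = classify_semi_supervised(X, y, 0.1, k=10, p=p, seed=11)
        assert acc >= 0.95
        assert set(per_class) == set(np.unique(y))


class TestEikonalClassifier:
    def test_sklearn_contract(self):
        from sklearn.utils.estimator_checks import check_estimator  # noqa: F401
        clf = EikonalClassifier(n_neighbors=3)
        params = clf.get_params()
        assert params["n_neighbors"] == 3
        clf.set_params(p=2)
        assert clf.p == 2

    def test_transduction_and_predict(self):
        X, y = generate_blob_features(FixtureConfig(kind="blob_features", seed=4,
                                                    n_samples=100, n_classes=2,
                                                    separation=10.0))
        y_train = np.where(np.arange(100) % 10 == 0, y, -1)
        clf = EikonalClassifier(n_neighbors=6, p=1).fit(X, y_train)
        assert np.mean(clf.transduction_ == y) > 0.95
        assert np.array_equal(clf.predict(X[:5]), clf.transduction_[:5])

    def test_requires_labelled_samples(self):
        with pytest.raises(ValueError):
            EikonalClassifier().fit(np.zeros((20, 2)), -np.ones(20))
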