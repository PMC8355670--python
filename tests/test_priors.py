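"""Dirichlet pseudocounts, MST/geo-prior, size prior and the joint log-prior."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln
from scipy.stats import dirichlet as scipy_dirichlet

from areabayes.core_io import CostMatrix, Entity, build_cost_matrix
from areabayes.likelihood import AreaConfiguration, ModelParameters
from areabayes.priors import (
    DirichletSpec,
    GeoPriorSpec,
    PriorSpec,
    SizePriorSpec,
    area_cost,
    dirichlet_logpdf,
    empirical_prior_from_sample,
    geo_prior_log,
    log_prior,
    minimum_spanning_tree_edges,
    pseudocounts_from_prior,
    size_prior_log,
)
from .conftest import random_dataset


class TestPseudocounts:
    @pytest.mark.parametrize(
        "mu, rho, expected",
        [
            ((0.5, 0.5), 0.0, (1.0, 1.0)),
            ((0.2, 0.8), 10.0, (3.0, 9.0)),
            ((1 / 3, 1 / 3, 1 / 3), 30.0, (11.0, 11.0, 11.0)),
        ],
    )
    def test_mean_precision_arithmetic(self, mu, rho, expected):
        np.testing.assert_allclose(pseudocounts_from_prior(np.array(mu), rho), expected)

    def test_off_simplex_mean_rejected(self):
        with pytest.raises(ValueError, match="simplex"):
            pseudocounts_from_prior(np.array([0.5, 0.6]), 1.0)


class TestEmpiricalPrior:
    def test_counts_to_frequencies_then_pseudocounts(self):
        psi, warns = empirical_prior_from_sample(
            {"f": np.array([8.0, 2.0])}, rho=10.0, feature_names=["f"]
        )
        np.testing.assert_allclose(psi["f"], [9.0, 3.0])
        assert warns == []

    def test_symmetric_counts_symmetric_psi(self):
        psi, _ = empirical_prior_from_sample(
            {"f": np.array([5.0, 5.0])}, rho=7.0, feature_names=["f"]
        )
        assert psi["f"][0] == psi["f"][1]

    def test_empty_counts_fall_back_uniform_with_warning(self):
        with pytest.warns(UserWarning, match="empty counts"):
            psi, warns = empirical_prior_from_sample(
                {"f": np.array([0.0, 0.0])}, rho=10.0, feature_names=["f"]
            )
        np.testing.assert_allclose(psi["f"], [1.0, 1.0])
        assert warns

    def test_absent_feature_warns(self):
        with pytest.warns(UserWarning, match="absent"):
            psi, _ = empirical_prior_from_sample({}, rho=10.0, feature_names=["g"])
        assert "g" not in psi


def test_dirichlet_logpdf_matches_scipy(rng):
    for _ in range(10):
        n = int(rng.integers(2, 5))
        psi = rng.uniform(0.5, 5.0, size=n)
        x = rng.dirichlet(psi)
        assert dirichlet_logpdf(x, psi) == pytest.approx(
            scipy_dirichlet.logpdf(x, psi), abs=1e-9
        )


def _prufer_spanning_trees(n):
    """All n^(n-2) spanning trees on n labelled nodes via Prüfer sequences."""
    import heapq

    if n == 2:
        yield [(0, 1)]
        return
    for seq in itertools.product(range(n), repeat=n - 2):
        degree = [1] * n
        for v in seq:
            degree[v] += 1
        heap = [i for i in range(n) if degree[i] == 1]
        heapq.heapify(heap)
        edges = []
        for v in seq:
            leaf = heapq.heappop(heap)
            edges.append((leaf, v))
            degree[v] -= 1
            if degree[v] == 1:
                heapq.heappush(heap, v)
        edges.append((heapq.heappop(heap), heapq.heappop(heap)))
        yield edges


class TestAreaCost:
    def test_collinear_mst_mean(self):
        ents = [Entity("a", (0.0, 0.0)), Entity("b", (1.0, 0.0)), Entity("c", (3.0, 0.0))]
        cm = build_cost_matrix(ents, metric="euclidean")
        assert area_cost({0, 1, 2}, cm, "mst") == pytest.approx(1.5)

    def test_two_points_any_linkage(self):
        ents = [Entity("a", (0.0, 0.0)), Entity("b", (0.0, 2.5))]
        cm = build_cost_matrix(ents, metric="euclidean")
        for linkage in ("mst", "complete"):
            assert area_cost({0, 1}, cm, linkage) == pytest.approx(2.5)

    def test_singleton_costs_zero(self):
        cm = CostMatrix(np.zeros((3, 3)))
        assert area_cost({1}, cm, "mst") == 0.0

    @pytest.mark.parametrize("n", [4, 5])
    def test_mst_matches_prufer_enumeration(self, n, rng):
        for _ in range(25):
            pts = rng.uniform(0, 10, size=(n, 2))
            ents = [Entity(f"e{i}", tuple(map(float, p))) for i, p in enumerate(pts)]
            cm = build_cost_matrix(ents, metric="euclidean")
            edges = minimum_spanning_tree_edges(np.arange(n), cm.costs)
            total = sum(cm.costs[i, j] for i, j in edges)
            best = min(
                sum(cm.costs[i, j] for i, j in tree)
                for tree in _prufer_spanning_trees(n)
            )
            assert total == pytest.approx(best, abs=1e-12)

    def test_mst_mean_never_exceeds_complete_mean(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 8))
            pts = rng.uniform(0, 10, size=(n, 2))
            ents = [Entity(f"e{i}", tuple(map(float, p))) for i, p in enumerate(pts)]
            cm = build_cost_matrix(ents, metric="euclidean")
            assert area_cost(set(range(n)), cm, "mst") <= area_cost(
                set(range(n)), cm, "complete"
            ) + 1e-12

    def test_delaunay_linkage_and_collinear_fallback(self, rng):
        pts = rng.uniform(0, 10, size=(6, 2))
        ents = [Entity(f"e{i}", tuple(map(float, p))) for i, p in enumerate(pts)]
        cm = build_cost_matrix(ents, metric="euclidean")
        c = area_cost(set(range(6)), cm, "delaunay", locations=pts)
        assert c > 0
        col = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        ents2 = [Entity(f"e{i}", tuple(map(float, p))) for i, p in enumerate(col)]
        cm2 = build_cost_matrix(ents2, metric="euclidean")
        with pytest.warns(UserWarning, match="degenerate"):
            c2 = area_cost(set(range(4)), cm2, "delaunay", locations=col)
        assert c2 == pytest.approx(1.0)  # falls back to the MST mean


class TestGeoPrior:
    def _cm(self, pts):
        ents = [Entity(f"e{i}", tuple(map(float, p))) for i, p in enumerate(pts)]
        return build_cost_matrix(ents, metric="euclidean")

    def test_rate_zero_is_flat(self):
        cm = self._cm([[0, 0], [1, 0], [5, 5], [6, 5]])
        spec = GeoPriorSpec(type="cost_based", rate=0.0, cost_matrix=cm)
        areas = AreaConfiguration([{0, 1}, {2, 3}], 4)
        assert geo_prior_log(areas, spec) == 0.0

    def test_exponential_decay_hand_value(self):
        cm = self._cm([[0, 0], [1, 0], [3, 0]])
        spec = GeoPriorSpec(type="cost_based", rate=2.0, cost_matrix=cm)
        areas = AreaConfiguration([{0, 1, 2}], 3)
        assert geo_prior_log(areas, spec) == pytest.approx(-3.0)  # c_k = 1.5

    def test_strictly_decreasing_in_rate(self):
        cm = self._cm([[0, 0], [2, 0]])
        areas = AreaConfiguration([{0, 1}], 2)
        vals = [
            geo_prior_log(areas, GeoPriorSpec(type="cost_based", rate=lam, cost_matrix=cm))
            for lam in (0.5, 1.0, 2.0)
        ]
        assert vals[0] > vals[1] > vals[2]

    def test_far_entity_never_increases_prior(self):
        cm = self._cm([[0, 0], [1, 0], [50, 0]])
        spec = GeoPriorSpec(type="cost_based", rate=1.0, cost_matrix=cm)
        near = geo_prior_log(AreaConfiguration([{0, 1}], 3), spec)
        far = geo_prior_log(AreaConfiguration([{0, 1, 2}], 3), spec)
        assert far < near

    def test_relabeling_invariance(self, rng):
        pts = rng.uniform(0, 10, size=(8, 2))
        cm = self._cm(pts)
        spec = GeoPriorSpec(type="cost_based", rate=1.3, cost_matrix=cm)
        a = geo_prior_log(AreaConfiguration([{0, 1, 2}, {5, 6}], 8), spec)
        b = geo_prior_log(AreaConfiguration([{5, 6}, {0, 1, 2}], 8), spec)
        assert a == pytest.approx(b)


class TestSizePrior:
    def test_bounds(self):
        spec = SizePriorSpec(m_min=3, m_max=5)
        assert size_prior_log(AreaConfiguration([{0, 1, 2}], 10), spec) == 0.0
        assert size_prior_log(AreaConfiguration([{0, 1}], 10), spec) == -np.inf
        assert size_prior_log(AreaConfiguration([set(range(6))], 10), spec) == -np.inf

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            SizePriorSpec(m_min=1, m_max=5)


class TestLogPrior:
    def test_uniform_psi_gives_constant_normalizers(self, rng):
        ds = random_dataset(rng, n_entities=9, n_features=3, families=(None,))
        priors = PriorSpec.default(ds)
        ns = ds.n_states
        k = 1
        smax = int(ns.max())
        alpha = np.zeros((3, smax))
        gamma = np.zeros((k, 3, smax))
        for f in range(3):
            alpha[f, : ns[f]] = rng.dirichlet(np.ones(ns[f]))
            gamma[0, f, : ns[f]] = rng.dirichlet(np.ones(ns[f]))
        params = ModelParameters(
            weights=np.stack([rng.dirichlet(np.ones(3)) for _ in range(3)]),
            alpha=alpha,
            beta=np.zeros((0, 3, smax)),
            gamma=gamma,
            areas=AreaConfiguration([{0, 1, 2}], 9),
        )
        # no families -> weight prior lives on the 2-simplex (universal,
        # contact): each feature contributes ln Gamma(2) = 0; alpha and
        # gamma contribute ln Gamma(N_f) each
        params.weights[:, 1] = 0.0
        params.weights /= params.weights.sum(axis=1, keepdims=True)
        expected = float(sum(2 * gammaln(ns[f]) for f in range(3)))
        assert log_prior(params, priors, ds) == pytest.approx(expected)

    def test_nonuniform_psi_hand_value(self, rng):
        ds = random_dataset(rng, n_entities=6, n_features=1, families=(None,))
        # force a binary feature
        while ds.n_states[0] != 2:
            ds = random_dataset(np.random.default_rng(int(rng.integers(1 << 30))), 6, 1, (None,))
        priors = PriorSpec.default(ds)
        priors.dirichlet.alpha[0] = np.array([2.0, 2.0])
        params = ModelParameters(
            weights=np.array([[0.5, 0.0, 0.5]]),
            alpha=np.array([[0.5, 0.5]]),
            beta=np.zeros((0, 1, 2)),
            gamma=np.zeros((0, 1, 2)),
            areas=AreaConfiguration([], 6),
        )
        base = PriorSpec.default(ds)
        diff = log_prior(params, priors, ds) - log_prior(params, base, ds)
        # Dir(2,2) at (0.5, 0.5) has density 1.5; Dir(1,1) has density 1
        assert diff == pytest.approx(np.log(1.5))

    def test_size_violation_is_minus_inf(self, rng):
        ds = random_dataset(rng, n_entities=8, n_features=2, families=(None,))
        priors = PriorSpec.default(ds)
        ns = ds.n_states
        smax = int(ns.max())
        alpha = np.zeros((2, smax))
        gamma = np.zeros((1, 2, smax))
        for f in range(2):
            alpha[f, : ns[f]] = rng.dirichlet(np.ones(ns[f]))
            gamma[0, f, : ns[f]] = rng.dirichlet(np.ones(ns[f]))
        params = ModelParameters(
            weights=np.tile([0.5, 0.0, 0.5], (2, 1)),
            alpha=alpha,
            beta=np.zeros((0, 2, smax)),
            gamma=gamma,
            areas=AreaConfiguration([{0, 1}], 8),  # below m_min = 3
        )
        assert log_prior(params, priors, ds) == -np.inf
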