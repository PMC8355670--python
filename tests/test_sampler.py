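"""MH sampler: proposals, Hastings ratios, caches, chain correctness."""

import itertools

import numpy as np
import pytest

from areabayes.core_io import Dataset, Entity, FeatureSpec, build_cost_matrix
from areabayes.likelihood import AreaConfiguration, ModelParameters, data_log_likelihood
from areabayes.priors import (
    DirichletSpec,
    GeoPriorSpec,
    PriorSpec,
    SizePriorSpec,
    dirichlet_logpdf,
)
from areabayes.sampler import (
    SamplerConfig,
    active_weight_components,
    init_state,
    mh_step,
    propose_area_move,
    propose_simplex,
    run_chain,
    _applicable_operators,
)
from .conftest import random_dataset


class TestProposeSimplex:
    def test_support_and_antisymmetry(self, rng):
        x = rng.dirichlet(np.ones(3))
        out = propose_simplex(x, kappa=30.0, rng=rng)
        assert out is not None
        y, log_hr = out
        assert y.sum() == pytest.approx(1.0)
        assert (y > 0).all()
        # recompute the reverse ratio by hand: it must negate
        fwd = dirichlet_logpdf(y, 30.0 * x + 1e-4)
        rev = dirichlet_logpdf(x, 30.0 * y + 1e-4)
        assert log_hr == pytest.approx(rev - fwd)

    def test_invalid_kappa(self, rng):
        with pytest.raises(ValueError):
            propose_simplex(np.array([0.5, 0.5]), kappa=0.0, rng=rng)

    def test_mh_targets_dirichlet_3_1(self, rng):
        # MH with this proposal targeting Dir(3,1): E[x_0] = 0.75
        target = np.array([3.0, 1.0])
        x = np.array([0.5, 0.5])
        total, count = 0.0, 0
        for i in range(20_000):
            out = propose_simplex(x, kappa=20.0, rng=rng)
            if out is not None:
                y, log_hr = out
                delta = dirichlet_logpdf(y, target) - dirichlet_logpdf(x, target)
                if np.log(rng.random()) < delta + log_hr:
                    x = y
            if i > 2000:
                total += x[0]
                count += 1
        assert total / count == pytest.approx(0.75, abs=0.02)


def _fixed_params_dataset(rng, n_entities=4, n_features=2):
    feats = [FeatureSpec(f"f{j}", ("a", "b")) for j in range(n_features)]
    ents = [
        Entity(f"e{i}", (float(rng.uniform(0, 4)), float(rng.uniform(0, 4))))
        for i in range(n_entities)
    ]
    data = rng.integers(0, 2, size=(n_entities, n_features)).astype(np.int16)
    return Dataset(ents, feats, data)


def _enumerate_legal_areas(n, m_min, m_max):
    out = []
    for m in range(m_min, m_max + 1):
        out.extend(frozenset(c) for c in itertools.combinations(range(n), m))
    return out


def _params_with_area(ds, area, alpha, gamma, w):
    F = ds.n_features
    return ModelParameters(
        weights=np.tile(w, (F, 1)),
        alpha=np.tile(alpha, (F, 1)),
        beta=np.zeros((0, F, 2)),
        gamma=np.tile(gamma, (1, F, 1)),
        areas=AreaConfiguration([set(area)], ds.n_entities),
    )


def _area_only_chain(ds, priors, params, n_steps, seed, g=10):
    """Drive mh_step with only area moves; return visited area sets."""
    from areabayes.sampler import ModelState

    rng = np.random.default_rng(seed)
    cost = build_cost_matrix(ds, metric="euclidean")
    cfg = SamplerConfig(
        n_steps=n_steps, burn_in=0.0, n_retained=1,
        operator_weights={"area": 1.0}, g=g, seed=seed,
    )
    state = ModelState(params.copy(), ds, priors)
    ops, op_probs = _applicable_operators(cfg, 1, ds.n_families)
    stats = {op: [0, 0] for op in ops}
    visits = []
    for _ in range(n_steps):
        state = mh_step(state, ds, priors, cfg, rng, cost, ops, op_probs, stats)
        visits.append(frozenset(state.params.areas.areas[0]))
    return visits


class TestAreaMoves:
    def test_uniform_over_legal_states_under_flat_target(self, rng):
        # identical alpha and gamma -> likelihood constant in Z; uniform
        # geo/size priors -> every legal area state equally likely
        ds = _fixed_params_dataset(rng)
        priors = PriorSpec(
            dirichlet=DirichletSpec.uniform(ds),
            geo=GeoPriorSpec(type="uniform"),
            size=SizePriorSpec(m_min=2, m_max=3),
        )
        half = np.array([0.5, 0.5])
        params = _params_with_area(ds, {0, 1}, half, half, np.array([0.3, 0.0, 0.7]))
        visits = _area_only_chain(ds, priors, params, 120_000, seed=5)
        legal = _enumerate_legal_areas(4, 2, 3)
        counts = np.array([sum(v == s for v in visits[20_000:]) for s in legal])
        expected = counts.sum() / len(legal)
        # thin to near-independent draws for the chi-square scale
        thin = visits[20_000::50]
        tcounts = np.array([sum(v == s for v in thin) for s in legal])
        texp = len(thin) / len(legal)
        chi2 = ((tcounts - texp) ** 2 / texp).sum()
        from scipy.stats import chi2 as chi2_dist

        assert chi2 < chi2_dist.ppf(0.999, df=len(legal) - 1)
        assert np.abs(counts / counts.sum() - 1 / len(legal)).max() < 0.05

    def test_size_bounds_never_violated(self, rng):
        ds = _fixed_params_dataset(rng, n_entities=6)
        priors = PriorSpec(
            dirichlet=DirichletSpec.uniform(ds),
            geo=GeoPriorSpec(type="uniform"),
            size=SizePriorSpec(m_min=2, m_max=4),
        )
        half = np.array([0.5, 0.5])
        params = _params_with_area(ds, {0, 1}, half, half, np.array([0.5, 0.0, 0.5]))
        visits = _area_only_chain(ds, priors, params, 20_000, seed=7)
        sizes = {len(v) for v in visits}
        assert sizes <= {2, 3, 4}

    def test_proposal_respects_disjointness(self, rng):
        ds = random_dataset(rng, n_entities=12, n_features=3, families=(None,))
        cost = build_cost_matrix(ds, metric="euclidean")
        areas = AreaConfiguration([{0, 1, 2}, {3, 4, 5}], 12)
        for _ in range(200):
            prop = propose_area_move(areas, cost, 3, 6, 5, rng)
            if prop is None:
                continue
            new_areas, k, touched, log_hr = prop
            assert np.isfinite(log_hr)
            # disjointness is structural: rebuilding must not raise
            AreaConfiguration([set(a) for a in new_areas.areas], 12)


class TestInitState:
    def test_k0_pure_confounder_model(self, rng):
        ds = random_dataset(rng, n_entities=10, families=(None,))
        priors = PriorSpec.default(ds)
        st = init_state(ds, priors, 0, np.random.default_rng(0))
        assert st.params.areas.k == 0
        np.testing.assert_allclose(st.params.weights[:, 0], 1.0)

    def test_seed_determinism(self, rng):
        ds = random_dataset(rng, n_entities=20)
        priors = PriorSpec.default(ds)
        a = init_state(ds, priors, 2, np.random.default_rng(9))
        b = init_state(ds, priors, 2, np.random.default_rng(9))
        assert a.params.areas.areas == b.params.areas.areas
        np.testing.assert_array_equal(a.params.alpha, b.params.alpha)

    def test_seeded_areas_disjoint_at_m_min(self, rng):
        ds = random_dataset(rng, n_entities=100)
        priors = PriorSpec.default(ds)
        st = init_state(ds, priors, 2, np.random.default_rng(3))
        sizes = st.params.areas.sizes
        assert sizes == [3, 3]

    def test_infeasible_k_rejected(self, rng):
        ds = random_dataset(rng, n_entities=5)
        priors = PriorSpec.default(ds)
        with pytest.raises(ValueError, match="disjoint"):
            init_state(ds, priors, 2, np.random.default_rng(0))


class TestActiveComponents:
    def test_masks(self):
        np.testing.assert_array_equal(active_weight_components(0, 0), [True, False, False])
        np.testing.assert_array_equal(active_weight_components(2, 0), [True, True, False])
        np.testing.assert_array_equal(active_weight_components(0, 1), [True, False, True])
        np.testing.assert_array_equal(active_weight_components(1, 3), [True, True, True])


class TestRunChain:
    def test_bit_identical_traces_from_same_seed(self, rng):
        ds = random_dataset(rng, n_entities=15, n_features=3)
        priors = PriorSpec.default(ds)
        cfg = SamplerConfig(n_steps=3000, n_retained=50, seed=42)
        t1 = run_chain(ds, priors, 1, cfg)
        t2 = run_chain(ds, priors, 1, cfg)
        np.testing.assert_array_equal(t1.assignment, t2.assignment)
        np.testing.assert_array_equal(t1.log_likelihood, t2.log_likelihood)
        np.testing.assert_array_equal(t1.weights, t2.weights)

    def test_trace_length_and_deviance(self, rng):
        ds = random_dataset(rng, n_entities=10, n_features=2)
        priors = PriorSpec.default(ds)
        cfg = SamplerConfig(n_steps=2000, n_retained=77, seed=1)
        tr = run_chain(ds, priors, 1, cfg)
        assert tr.n_samples == 77
        np.testing.assert_allclose(tr.deviance, -2 * tr.log_likelihood)

    def test_conjugate_posterior_mean_k0(self, rng):
        # K=0, no families, uniform psi: alpha posterior is Dirichlet
        # (1 + counts); compare posterior means
        ds = random_dataset(rng, n_entities=40, n_features=3, families=(None,))
        priors = PriorSpec.default(ds)
        cfg = SamplerConfig(n_steps=40_000, n_retained=1000, seed=11)
        tr = run_chain(ds, priors, 0, cfg)
        for f in range(3):
            nsf = ds.n_states[f]
            counts = np.bincount(ds.data[:, f], minlength=nsf)
            expected = (counts + 1) / (counts.sum() + nsf)
            got = tr.alpha[:, f, :nsf].mean(axis=0)
            np.testing.assert_allclose(got, expected, atol=0.02)

    def test_simplex_draws_stay_positive(self, rng):
        ds = random_dataset(rng, n_entities=12, n_features=3)
        priors = PriorSpec.default(ds)
        tr = run_chain(ds, priors, 1, SamplerConfig(n_steps=4000, n_retained=100, seed=2))
        ns = ds.n_states
        for f in range(3):
            assert (tr.alpha[:, f, : ns[f]] > 0).all()
            assert (tr.gamma[:, :, f, : ns[f]] > 0).all()
        active = tr.weights[:, :, [0, 2]] if ds.n_families == 0 else tr.weights
        # weight rows sum to one on their active components
        np.testing.assert_allclose(tr.weights.sum(axis=2), 1.0, atol=1e-9)

    def test_cache_consistency_after_many_steps(self, rng):
        from areabayes.sampler import ModelState, _applicable_operators

        ds = random_dataset(rng, n_entities=20, n_features=4, missing_rate=0.1)
        priors = PriorSpec.default(ds)
        cfg = SamplerConfig(n_steps=1000, n_retained=10, seed=3)
        cost = build_cost_matrix(ds, metric="euclidean")
        r = np.random.default_rng(3)
        st = init_state(ds, priors, 1, r, cost)
        ops, op_probs = _applicable_operators(cfg, 1, ds.n_families)
        stats = {op: [0, 0] for op in ops}
        for _ in range(1000):
            st = mh_step(st, ds, priors, cfg, r, cost, ops, op_probs, stats)
        fresh = st.recompute()
        assert st.log_likelihood == pytest.approx(fresh.log_likelihood, abs=1e-9)
        assert st.log_prior == pytest.approx(fresh.log_prior, abs=1e-9)
        assert st.log_likelihood == pytest.approx(
            data_log_likelihood(ds, st.params), abs=1e-9
        )


class TestDetailedBalanceSmoke:
    def test_area_posterior_matches_enumeration(self, rng):
        # 4 entities, 2 binary features, fixed vectors: the chain over area
        # configurations alone must match the enumerated posterior
        ds = _fixed_params_dataset(rng)
        priors = PriorSpec(
            dirichlet=DirichletSpec.uniform(ds),
            geo=GeoPriorSpec(type="uniform"),
            size=SizePriorSpec(m_min=2, m_max=3),
        )
        alpha = np.array([0.6, 0.4])
        gamma = np.array([[0.15, 0.85]])
        w = np.array([0.3, 0.0, 0.7])
        params = _params_with_area(ds, {0, 1}, alpha, gamma, w)
        legal = _enumerate_legal_areas(4, 2, 3)
        log_post = []
        for s in legal:
            p = _params_with_area(ds, set(s), alpha, gamma, w)
            log_post.append(data_log_likelihood(ds, p))
        log_post = np.array(log_post)
        exact = np.exp(log_post - log_post.max())
        exact /= exact.sum()
        visits = _area_only_chain(ds, priors, params, 150_000, seed=21)
        counts = np.array([sum(v == s for v in visits[30_000:]) for s in legal])
        emp = counts / counts.sum()
        assert np.abs(emp - exact).sum() / 2 < 0.03  # total variation
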