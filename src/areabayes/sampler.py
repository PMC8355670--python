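"""Metropolis–Hastings sampler for the contact-area mixture posterior.

The posterior P(Theta | D) is proportional to likelihood times prior and is
explored with two kinds of proposals:

* Dirichlet proposals for every simplex-valued parameter (mixture weight
  triples and the categorical probability vectors alpha/beta/gamma): the
  proposal is ``Dirichlet(kappa * current + eps)``, a random walk on the
  simplex whose step size shrinks as ``kappa`` grows, with the exact
  Hastings correction from both proposal densities.

* Discrete, spatially informed moves for the area configuration Z: an area
  grows by an unassigned entity drawn with probability decaying
  exponentially in its cost rank to the area (scale ``g``), shrinks by a
  uniformly chosen member, or swaps (shrink then grow). The proposal has
  full support over unassigned entities, and the Hastings ratio accounts
  for menu sizes and candidate probabilities in both directions, so the
  chain is correct regardless of how well the heuristic guesses good
  moves. Moves that would violate the size bounds are auto-rejected.

Likelihood and prior are cached per cell / per parameter block and updated
incrementally; cached and recomputed values agree to ~1e-9 (asserted in
tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import CostMatrix, Dataset, build_cost_matrix
from .likelihood import AreaConfiguration, ModelParameters, cell_log_matrix
from .priors import PriorSpec, area_cost, dirichlet_logpdf

__all__ = [
    "SamplerConfig",
    "ModelState",
    "Trace",
    "init_state",
    "propose_simplex",
    "propose_area_move",
    "mh_step",
    "run_chain",
    "write_samples",
    "write_areas",
]

def active_weight_components(n_families: int, k: int) -> np.ndarray:
    """Which mixture components carry a free weight in this run.

    The universal component always applies. Inheritance carries weight only
    when the dataset declares families (confounder granularity above
    "none"); contact only when K >= 1. Inactive components are pinned to
    weight zero — a confounder with no groups cannot absorb any
    explanatory load, and leaving its weight free would only report back
    the prior.
    """
    return np.array([True, n_families > 0, k > 0])


DEFAULT_OPERATOR_WEIGHTS = {
    "area": 0.40,
    "weights": 0.20,
    "alpha": 0.10,
    "beta": 0.15,
    "gamma": 0.15,
}


@dataclass
class SamplerConfig:
    """Run-length and proposal tuning for one chain.

    ``n_retained`` posterior samples are kept, evenly thinned over the
    post-burn-in stretch. ``kappa`` is the Dirichlet proposal concentration
    (larger = smaller steps), ``g`` the neighbourhood size of the spatial
    grow proposal, ``operator_weights`` the relative frequency of each
    proposal kind (re-normalized over the operators applicable to the run:
    no area/gamma moves when K = 0, no beta moves without families).
    """

    n_steps: int = 100_000
    burn_in: float = 0.2
    n_retained: int = 1000
    operator_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OPERATOR_WEIGHTS)
    )
    kappa: float = 30.0
    eps: float = 1e-4
    g: int = 10
    warmup_chains: int = 10
    warmup_steps: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps <= 0:
            raise ValueError("n_steps must be > 0")
        if not (0.0 <= self.burn_in < 1.0):
            raise ValueError("burn_in fraction must be in [0, 1)")
        post = self.n_steps - int(self.burn_in * self.n_steps)
        if self.n_retained > post:
            raise ValueError(
                f"n_retained={self.n_retained} exceeds post-burn-in steps {post}"
            )
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")


class ModelState:
    """Parameters plus incrementally maintained log-likelihood/log-prior.

    ``cell_log[l, f]`` caches the log mixture probability of each cell
    (0 for missing cells); prior terms are cached per parameter block and
    per area. ``log_likelihood``/``log_prior`` are their sums.
    """

    def __init__(self, params: ModelParameters, dataset: Dataset, priors: PriorSpec):
        self.params = params
        self._dataset = dataset
        self._priors = priors
        self.cell_log = cell_log_matrix(
            dataset.data, dataset.family_index, params.areas.assignment, params
        )
        self.log_likelihood = float(self.cell_log.sum())
        ns = dataset.n_states
        d = priors.dirichlet
        F = dataset.n_features
        self.active = active_weight_components(dataset.n_families, params.areas.k)
        if self.active.sum() > 1:
            self.prior_w = np.array(
                [
                    dirichlet_logpdf(
                        params.weights[f][self.active],
                        np.asarray(d.weights[f])[self.active],
                    )
                    for f in range(F)
                ]
            )
        else:
            self.prior_w = np.zeros(F)
        self.prior_alpha = np.array(
            [dirichlet_logpdf(params.alpha[f, : ns[f]], d.alpha[f]) for f in range(F)]
        )
        self.prior_beta = np.array(
            [
                [
                    dirichlet_logpdf(params.beta[phi, f, : ns[f]], d.beta[(phi, f)])
                    for f in range(F)
                ]
                for phi in range(dataset.n_families)
            ]
        ).reshape(dataset.n_families, F)
        self.prior_gamma = np.array(
            [
                [
                    dirichlet_logpdf(params.gamma[k, f, : ns[f]], d.gamma[f])
                    for f in range(F)
                ]
                for k in range(params.areas.k)
            ]
        ).reshape(params.areas.k, F)
        self.geo_terms = np.array(
            [self._geo_term(members) for members in params.areas.areas]
        )

    def _geo_term(self, members: set[int]) -> float:
        geo = self._priors.geo
        if geo.type == "uniform" or geo.rate == 0.0:
            return 0.0
        return -geo.rate * area_cost(members, geo.cost_matrix, geo.linkage, geo.locations)

    @property
    def log_prior(self) -> float:
        return float(
            self.prior_w.sum()
            + self.prior_alpha.sum()
            + self.prior_beta.sum()
            + self.prior_gamma.sum()
            + self.geo_terms.sum()
        )

    @property
    def log_posterior(self) -> float:
        return self.log_likelihood + self.log_prior

    def recompute(self) -> "ModelState":
        """Fresh state from the same parameters (cache-consistency oracle)."""
        return ModelState(self.params.copy(), self._dataset, self._priors)

    # -- incremental updates ------------------------------------------------

    def _refresh_cells(self, rows: np.ndarray, cols: np.ndarray) -> None:
        new = cell_log_matrix(
            self._dataset.data,
            self._dataset.family_index,
            self.params.areas.assignment,
            self.params,
            rows=rows,
            cols=cols,
        )
        block = np.ix_(np.atleast_1d(rows), np.atleast_1d(cols))
        self.log_likelihood += float(new.sum() - self.cell_log[block].sum())
        self.cell_log[block] = new


def _draw_simplex(psi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    x = rng.dirichlet(np.asarray(psi, dtype=float))
    # numerically exact zeros break the strictly-positive contract; nudge
    while (x <= 0).any():
        x = rng.dirichlet(np.asarray(psi, dtype=float))
    return x


def init_state(
    dataset: Dataset,
    priors: PriorSpec,
    k: int,
    rng: np.random.Generator,
    cost_matrix: CostMatrix | None = None,
) -> ModelState:
    """Initial state: parameters from their priors, compact seeded areas.

    Each area starts as a random unassigned entity plus its ``m_min − 1``
    nearest unassigned neighbours by cost, keeping areas disjoint. The
    first seed is uniform; later seeds are drawn with probability
    proportional to their cost to the already-seeded areas, spreading
    initial areas across the region so that chains do not start with
    several slots contesting the same neighbourhood.
    """
    L, F = dataset.n_entities, dataset.n_features
    m_init = priors.size.m_min
    if k * m_init > L:
        raise ValueError(f"cannot seed {k} disjoint areas of size {m_init} among {L} entities")
    if cost_matrix is None:
        cost_matrix = priors.geo.cost_matrix or build_cost_matrix(dataset)
    ns = dataset.n_states
    smax = int(ns.max()) if F else 0
    d = priors.dirichlet
    active = active_weight_components(dataset.n_families, k)
    weights = np.zeros((F, 3))
    for f in range(F):
        if active.sum() > 1:
            weights[f, active] = _draw_simplex(np.asarray(d.weights[f])[active], rng)
        else:
            weights[f, 0] = 1.0
    alpha = np.zeros((F, smax))
    for f in range(F):
        alpha[f, : ns[f]] = _draw_simplex(d.alpha[f], rng)
    beta = np.zeros((dataset.n_families, F, smax))
    for phi in range(dataset.n_families):
        for f in range(F):
            beta[phi, f, : ns[f]] = _draw_simplex(d.beta[(phi, f)], rng)
    gamma = np.zeros((k, F, smax))
    for kk in range(k):
        for f in range(F):
            gamma[kk, f, : ns[f]] = _draw_simplex(d.gamma[f], rng)

    assigned = np.zeros(L, dtype=bool)
    areas: list[set[int]] = []
    for _ in range(k):
        free = np.flatnonzero(~assigned)
        if not areas:
            seed_entity = int(free[rng.integers(len(free))])
        else:
            taken = sorted(set().union(*areas))
            d = cost_matrix.costs[np.ix_(free, taken)].min(axis=1)
            if d.sum() <= 0:
                seed_entity = int(free[rng.integers(len(free))])
            else:
                seed_entity = int(free[rng.choice(len(free), p=d / d.sum())])
        assigned[seed_entity] = True
        members = {seed_entity}
        for _ in range(m_init - 1):
            free = np.flatnonzero(~assigned)
            dists = cost_matrix.costs[free, seed_entity]
            nxt = int(free[np.lexsort((free, dists))[0]])
            assigned[nxt] = True
            members.add(nxt)
        areas.append(members)
    params = ModelParameters(
        weights=weights,
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        areas=AreaConfiguration(areas, L),
    )
    return ModelState(params, dataset, priors)


def propose_simplex(
    current: np.ndarray,
    kappa: float,
    rng: np.random.Generator,
    eps: float = 1e-4,
) -> tuple[np.ndarray, float] | None:
    """Dirichlet random-walk proposal on the simplex with Hastings log-ratio.

    Returns ``(proposal, log q(cur|prop) − log q(prop|cur))`` or None when
    the draw lands on the simplex boundary in floating point (auto-reject).
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    current = np.asarray(current, dtype=float)
    conc_fwd = kappa * current + eps
    prop = rng.dirichlet(conc_fwd)
    if (prop <= 0).any():
        return None
    conc_rev = kappa * prop + eps
    log_hr = dirichlet_logpdf(current, conc_rev) - dirichlet_logpdf(prop, conc_fwd)
    return prop, log_hr


def _propose_vector(
    current: np.ndarray,
    psi: np.ndarray,
    counts: np.ndarray,
    kappa: float,
    eps: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float] | None:
    """Mixture proposal for a probability vector: random walk + quasi-Gibbs.

    With probability 1/2 a Dirichlet random-walk step around the current
    vector, otherwise an independence draw from ``Dirichlet(psi + counts)``
    — the conditional posterior the block would have if every cell in its
    scope were attributed to this component alone. The independence part
    lets a vector jump straight to the sharp profile its members support
    instead of diffusing there; the Hastings ratio uses the full mixture
    kernel density in both directions, so the approximation in the
    attribution costs nothing in correctness.
    """
    conc_ind = psi + counts
    if rng.random() < 0.5:
        prop = rng.dirichlet(kappa * current + eps)
    else:
        prop = rng.dirichlet(conc_ind)
    if (prop <= 0).any():
        return None
    rw_fwd = dirichlet_logpdf(prop, kappa * current + eps)
    rw_rev = dirichlet_logpdf(current, kappa * prop + eps)
    ind_fwd = dirichlet_logpdf(prop, conc_ind)
    ind_rev = dirichlet_logpdf(current, conc_ind)
    log_hr = np.logaddexp(rw_rev, ind_rev) - np.logaddexp(rw_fwd, ind_fwd)
    return prop, float(log_hr)


def _state_counts(
    data: np.ndarray, rows: np.ndarray, f: int, n_states: int
) -> np.ndarray:
    col = data[rows, f]
    return np.bincount(col[col >= 0], minlength=n_states).astype(float)


def _grow_distribution(
    costs: np.ndarray, pool: np.ndarray, members: list[int], g: int
) -> np.ndarray:
    """Spatially informed grow proposal over all unassigned entities.

    Pool entities are ranked by cost to the area (min cost to any member;
    ties broken by index) and weighted ``exp(-rank / g)``: the g nearest
    dominate, but every unassigned entity keeps positive probability, so
    the reverse of any shrink exists and no move needs auto-rejection for
    unreachability. Returns probabilities aligned with ``pool``.
    """
    d = costs[np.ix_(pool, members)].min(axis=1)
    order = np.lexsort((pool, d))
    ranks = np.empty(len(pool))
    ranks[order] = np.arange(len(pool))
    w = np.exp(-ranks / g)
    return w / w.sum()


def _area_menu(m: int, n_unassigned: int, m_min: int, m_max: int) -> list[str]:
    menu = []
    if m < m_max and n_unassigned > 0:
        menu.append("grow")
    if m > m_min:
        menu.append("shrink")
    if n_unassigned > 0 and m >= 1:
        menu.append("swap")
    return menu


def propose_area_move(
    areas: AreaConfiguration,
    cost_matrix: CostMatrix,
    m_min: int,
    m_max: int,
    g: int,
    rng: np.random.Generator,
) -> tuple[AreaConfiguration, int, list[int], float] | None:
    """One grow/shrink/swap move on a uniformly chosen area.

    Returns ``(new_areas, area_index, touched_entities, hastings_log_ratio)``
    or None when no legal move exists (counts as a rejected proposal).
    """
    if areas.k == 0:
        return None
    k = int(rng.integers(areas.k))
    members = sorted(areas.areas[k])
    m = len(members)
    costs = cost_matrix.costs
    unassigned = np.flatnonzero(areas.assignment == -1)
    menu = _area_menu(m, len(unassigned), m_min, m_max)
    if not menu:
        return None
    move = menu[int(rng.integers(len(menu)))]
    log_fwd = -np.log(len(menu))
    new_areas = areas.copy()

    if move == "grow":
        p = _grow_distribution(costs, unassigned, members, g)
        e = int(unassigned[rng.choice(len(unassigned), p=p)])
        log_fwd += float(np.log(p[np.searchsorted(unassigned, e)]))
        new_areas.areas[k].add(e)
        new_areas.assignment[e] = k
        rev_menu = _area_menu(m + 1, len(unassigned) - 1, m_min, m_max)
        if "shrink" not in rev_menu:
            return None
        log_rev = -np.log(len(rev_menu)) - np.log(m + 1)
        touched = [e]

    elif move == "shrink":
        e = members[int(rng.integers(m))]
        log_fwd += -np.log(m)
        new_areas.areas[k].discard(e)
        new_areas.assignment[e] = -1
        new_members = sorted(new_areas.areas[k])
        new_unassigned = np.flatnonzero(new_areas.assignment == -1)
        rev_menu = _area_menu(m - 1, len(new_unassigned), m_min, m_max)
        if "grow" not in rev_menu:
            return None
        p_rev = _grow_distribution(costs, new_unassigned, new_members, g)
        log_rev = -np.log(len(rev_menu)) + float(
            np.log(p_rev[np.searchsorted(new_unassigned, e)])
        )
        touched = [e]

    else:  # swap
        u = members[int(rng.integers(m))]
        mid_members = sorted(set(members) - {u})
        mid_unassigned = np.sort(np.append(unassigned, u))
        p = _grow_distribution(costs, mid_unassigned, mid_members, g)
        v = int(mid_unassigned[rng.choice(len(mid_unassigned), p=p)])
        log_fwd += -np.log(m) + float(np.log(p[np.searchsorted(mid_unassigned, v)]))
        new_areas.areas[k].discard(u)
        new_areas.areas[k].add(v)
        new_areas.assignment[u] = -1
        new_areas.assignment[v] = k
        new_members = sorted(new_areas.areas[k])
        new_unassigned = np.flatnonzero(new_areas.assignment == -1)
        rev_menu = _area_menu(m, len(new_unassigned), m_min, m_max)
        if "swap" not in rev_menu:
            return None
        rev_mid_members = sorted(set(new_members) - {v})
        rev_mid_unassigned = np.sort(np.append(new_unassigned, v))
        p_rev = _grow_distribution(costs, rev_mid_unassigned, rev_mid_members, g)
        log_rev = (
            -np.log(len(rev_menu))
            - np.log(m)
            + float(np.log(p_rev[np.searchsorted(rev_mid_unassigned, u)]))
        )
        touched = [u, v] if u != v else [u]

    return new_areas, k, touched, float(log_rev - log_fwd)


def _applicable_operators(
    config: SamplerConfig, k: int, n_families: int
) -> tuple[list[str], np.ndarray]:
    n_active = int(active_weight_components(n_families, k).sum())
    ops, w = [], []
    for name, weight in config.operator_weights.items():
        if weight <= 0:
            continue
        if name in ("area", "gamma") and k == 0:
            continue
        if name == "beta" and n_families == 0:
            continue
        if name == "weights" and n_active < 2:
            continue
        ops.append(name)
        w.append(weight)
    if not ops:
        raise ValueError("no applicable operator has positive weight")
    w = np.asarray(w, dtype=float)
    return ops, w / w.sum()


def mh_step(
    state: ModelState,
    dataset: Dataset,
    priors: PriorSpec,
    config: SamplerConfig,
    rng: np.random.Generator,
    cost_matrix: CostMatrix,
    ops: list[str],
    op_probs: np.ndarray,
    stats: dict[str, list[int]],
) -> ModelState:
    """One Metropolis–Hastings update in place; returns the (same) state."""
    op = ops[int(rng.choice(len(ops), p=op_probs))]
    stats[op][0] += 1
    params = state.params
    ns = dataset.n_states
    F = dataset.n_features
    d = priors.dirichlet

    if op == "area":
        proposal = propose_area_move(
            params.areas, cost_matrix, priors.size.m_min, priors.size.m_max, config.g, rng
        )
        if proposal is None:
            return state
        new_areas, k, touched, log_hr = proposal
        rows = np.asarray(touched)
        cols = np.arange(F)
        old_block = state.cell_log[np.ix_(rows, cols)].copy()
        new_block = cell_log_matrix(
            dataset.data, dataset.family_index, new_areas.assignment, params,
            rows=rows, cols=cols,
        )
        delta_ll = float(new_block.sum() - old_block.sum())
        new_geo = state._geo_term(new_areas.areas[k])
        delta_lp = new_geo - state.geo_terms[k]
        if np.log(rng.random()) < delta_ll + delta_lp + log_hr:
            params.areas = new_areas
            state.cell_log[np.ix_(rows, cols)] = new_block
            state.log_likelihood += delta_ll
            state.geo_terms[k] = new_geo
            stats[op][1] += 1
        return state

    f = int(rng.integers(F))
    if op == "weights":
        active = state.active
        current = params.weights[f][active]
        psi = np.asarray(d.weights[f])[active]
        rows = np.arange(dataset.n_entities)
        setter = ("weights", f)
    elif op == "alpha":
        current = params.alpha[f, : ns[f]]
        psi = d.alpha[f]
        rows = np.arange(dataset.n_entities)
        setter = ("alpha", f)
    elif op == "beta":
        phi = int(rng.integers(dataset.n_families))
        current = params.beta[phi, f, : ns[f]]
        psi = d.beta[(phi, f)]
        rows = np.flatnonzero(dataset.family_index == phi)
        setter = ("beta", phi, f)
    else:  # gamma
        k = int(rng.integers(params.areas.k))
        current = params.gamma[k, f, : ns[f]]
        psi = d.gamma[f]
        rows = np.asarray(sorted(params.areas.areas[k]), dtype=np.intp)
        setter = ("gamma", k, f)

    if op == "weights":
        prop = propose_simplex(current, config.kappa, rng, config.eps)
    else:
        counts = _state_counts(dataset.data, rows, f, int(ns[f]))
        prop = _propose_vector(
            current, np.asarray(psi, dtype=float), counts, config.kappa, config.eps, rng
        )
    if prop is None:
        return state
    new_vec, log_hr = prop
    old_vec = current.copy()
    delta_prior_new = dirichlet_logpdf(new_vec, psi)
    cols = np.array([f])
    if len(rows) > 0:
        old_block = state.cell_log[np.ix_(rows, cols)].copy()
    # write proposal into params, evaluate, roll back on rejection
    if setter[0] == "weights":
        params.weights[f][state.active] = new_vec
        old_term = state.prior_w[f]
    elif setter[0] == "alpha":
        params.alpha[f, : ns[f]] = new_vec
        old_term = state.prior_alpha[f]
    elif setter[0] == "beta":
        params.beta[setter[1], f, : ns[f]] = new_vec
        old_term = state.prior_beta[setter[1], f]
    else:
        params.gamma[setter[1], f, : ns[f]] = new_vec
        old_term = state.prior_gamma[setter[1], f]

    if len(rows) > 0:
        new_block = cell_log_matrix(
            dataset.data, dataset.family_index, params.areas.assignment, params,
            rows=rows, cols=cols,
        )
        delta_ll = float(new_block.sum() - old_block.sum())
    else:
        delta_ll = 0.0
    delta_lp = delta_prior_new - old_term

    if np.log(rng.random()) < delta_ll + delta_lp + log_hr:
        if len(rows) > 0:
            state.cell_log[np.ix_(rows, cols)] = new_block
            state.log_likelihood += delta_ll
        if setter[0] == "weights":
            state.prior_w[f] = delta_prior_new
        elif setter[0] == "alpha":
            state.prior_alpha[f] = delta_prior_new
        elif setter[0] == "beta":
            state.prior_beta[setter[1], f] = delta_prior_new
        else:
            state.prior_gamma[setter[1], f] = delta_prior_new
        stats[op][1] += 1
    else:  # roll back
        if setter[0] == "weights":
            params.weights[f][state.active] = old_vec
        elif setter[0] == "alpha":
            params.alpha[f, : ns[f]] = old_vec
        elif setter[0] == "beta":
            params.beta[setter[1], f, : ns[f]] = old_vec
        else:
            params.gamma[setter[1], f, : ns[f]] = old_vec
    return state


@dataclass
class Trace:
    """Ordered posterior samples from one chain.

    ``assignment[i]`` is the area assignment vector of sample ``i`` (−1 =
    in no area); ``deviance = −2 * log_likelihood`` feeds the DIC.
    """

    log_likelihood: np.ndarray
    log_prior: np.ndarray
    weights: np.ndarray  # (n, F, 3)
    alpha: np.ndarray  # (n, F, S)
    beta: np.ndarray  # (n, n_fam, F, S)
    gamma: np.ndarray  # (n, K, F, S)
    assignment: np.ndarray  # (n, L)
    k: int
    seed: int
    acceptance: dict[str, tuple[int, int]]  # op -> (proposed, accepted)

    @property
    def n_samples(self) -> int:
        return len(self.log_likelihood)

    @property
    def deviance(self) -> np.ndarray:
        return -2.0 * self.log_likelihood


def run_chain(
    dataset: Dataset,
    priors: PriorSpec,
    k: int,
    config: SamplerConfig,
    initial: ModelParameters | None = None,
    cost_matrix: CostMatrix | None = None,
) -> Trace:
    """Run one chain and return the thinned post-burn-in trace.

    When no explicit initial state is given and K >= 1, a warm-up phase
    precedes the main chain: ``warmup_chains`` short independent chains are
    run from random initializations and the main chain continues from the
    end state with the highest log-posterior. The area posterior is highly
    multimodal (an area can sit anywhere in space), and a single random
    initialization often equilibrates into a local mode; competing
    warm-up chains give the sampler several independent chances to land in
    the dominant one. Warm-up only chooses the starting point, so the
    stationary distribution is untouched; the burn-in fraction is still
    discarded from the main chain.

    Fully reproducible from ``config.seed``: the same seed yields a
    bit-identical trace.
    """
    rng = np.random.default_rng(config.seed)
    if cost_matrix is None:
        cost_matrix = priors.geo.cost_matrix or build_cost_matrix(dataset)
    ops, op_probs = _applicable_operators(config, k, dataset.n_families)
    if initial is None:
        state = init_state(dataset, priors, k, rng, cost_matrix)
        warm_steps = min(config.warmup_steps, config.n_steps // 10)
        if k >= 1 and config.warmup_chains > 1 and warm_steps > 0:
            seeds = np.random.SeedSequence(config.seed).spawn(config.warmup_chains)
            best, best_lp = None, -np.inf
            for ss in seeds:
                wrng = np.random.default_rng(ss)
                wstate = init_state(dataset, priors, k, wrng, cost_matrix)
                wstats = {op: [0, 0] for op in ops}
                for _ in range(warm_steps):
                    wstate = mh_step(
                        wstate, dataset, priors, config, wrng, cost_matrix,
                        ops, op_probs, wstats,
                    )
                if wstate.log_posterior > best_lp:
                    best, best_lp = wstate, wstate.log_posterior
            state = best
    else:
        state = ModelState(initial.copy(), dataset, priors)
    stats = {op: [0, 0] for op in ops}

    burn = int(config.burn_in * config.n_steps)
    retain_at = np.unique(
        np.linspace(burn, config.n_steps - 1, config.n_retained).astype(np.int64)
    )
    if len(retain_at) < config.n_retained:
        raise ValueError("cannot retain that many distinct samples after burn-in")
    retain_set = set(retain_at.tolist())

    n = config.n_retained
    L, F = dataset.n_entities, dataset.n_features
    smax = state.params.alpha.shape[1]
    out = Trace(
        log_likelihood=np.empty(n),
        log_prior=np.empty(n),
        weights=np.empty((n, F, 3)),
        alpha=np.empty((n, F, smax)),
        beta=np.empty((n, dataset.n_families, F, smax)),
        gamma=np.empty((n, k, F, smax)),
        assignment=np.empty((n, L), dtype=np.int16),
        k=k,
        seed=config.seed,
        acceptance={},
    )
    j = 0
    for i in range(config.n_steps):
        state = mh_step(state, dataset, priors, config, rng, cost_matrix, ops, op_probs, stats)
        if i in retain_set:
            out.log_likelihood[j] = state.log_likelihood
            out.log_prior[j] = state.log_prior
            out.weights[j] = state.params.weights
            out.alpha[j] = state.params.alpha
            out.beta[j] = state.params.beta
            out.gamma[j] = state.params.gamma
            out.assignment[j] = state.params.areas.assignment
            j += 1
    out.acceptance = {op: (v[0], v[1]) for op, v in stats.items()}
    return out


# ---------------------------------------------------------------------------
# Trace files (line-oriented, ingestible by external diagnostic tools)
# ---------------------------------------------------------------------------


def write_samples(trace: Trace, dataset: Dataset, path) -> None:
    """Scalar sample file: one row per retained sample, tab-separated."""
    import pandas as pd

    ns = dataset.n_states
    cols: dict[str, np.ndarray] = {
        "sample": np.arange(trace.n_samples),
        "log_likelihood": trace.log_likelihood,
        "log_prior": trace.log_prior,
        "deviance": trace.deviance,
    }
    for f, feat in enumerate(dataset.features):
        for c, name in enumerate(("universal", "inherit", "contact")):
            cols[f"w_{feat.name}_{name}"] = trace.weights[:, f, c]
        for s in range(ns[f]):
            cols[f"alpha_{feat.name}_{feat.states[s]}"] = trace.alpha[:, f, s]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_areas(trace: Trace, dataset: Dataset, path) -> None:
    """Area membership file: one row per sample per area, member ids joined."""
    ids = dataset.entity_ids
    with open(path, "w") as fh:
        fh.write("sample\tarea\tmembers\n")
        for i in range(trace.n_samples):
            for k in range(trace.k):
                members = np.flatnonzero(trace.assignment[i] == k)
                fh.write(f"{i}\t{k}\t" + ",".join(ids[m] for m in members) + "\n")
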