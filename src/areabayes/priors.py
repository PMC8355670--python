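"""Log-priors: Dirichlet priors on simplex parameters, geo-prior, size prior.

The joint prior factorizes as

    P(Theta) = P(Z) * P(alpha) * P(beta) * P(gamma) * P(w)

where ``P(Z)`` combines the geographic prior on each area with an implicit
prior on area sizes, and every weight triple / probability vector carries an
independent Dirichlet prior parameterized by pseudocounts ``psi``. The
default is uniform (``psi = (1, ..., 1)``); informative priors are encoded
as ``psi_n = 1 + mu_n * rho`` from a prior mean ``mu`` and precision ``rho``,
optionally derived from an empirical count table.

The geo-prior connects an area's members with a linkage graph (minimum
spanning tree by default) over a symmetric cost matrix and lets the prior
probability decay exponentially in the mean edge cost, truncated to
configurations whose areas are pairwise disjoint. Using the mean rather
than the total keeps the prior agnostic to area size. Normalizing constants
are omitted (fixed within a run): posteriors from runs with different
lambda or cost matrices are not comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError
from scipy.special import gammaln

from .core_io import CostMatrix, Dataset
from .likelihood import AreaConfiguration, ModelParameters

__all__ = [
    "DirichletSpec",
    "GeoPriorSpec",
    "SizePriorSpec",
    "PriorSpec",
    "pseudocounts_from_prior",
    "empirical_prior_from_sample",
    "dirichlet_logpdf",
    "minimum_spanning_tree_edges",
    "area_cost",
    "geo_prior_log",
    "size_prior_log",
    "log_prior",
]


def pseudocounts_from_prior(mu: np.ndarray, rho: float) -> np.ndarray:
    """Dirichlet pseudocounts from a prior mean ``mu`` and precision ``rho``.

    ``psi_n = 1 + mu_n * rho``. With ``rho = 0`` this is the uniform prior
    ``(1, ..., 1)``; large ``rho`` concentrates the prior around ``mu``.
    """
    mu = np.asarray(mu, dtype=float)
    if rho < 0:
        raise ValueError("precision rho must be >= 0")
    if (mu < 0).any() or abs(mu.sum() - 1.0) > 1e-9:
        raise ValueError("prior mean mu must lie on the simplex")
    return 1.0 + mu * rho


def empirical_prior_from_sample(
    counts: dict[str, np.ndarray], rho: float, feature_names: list[str]
) -> tuple[dict[str, np.ndarray], list[str]]:
    """Pseudocounts per feature from an empirical count table.

    For each feature the prior mean is the relative state frequency in the
    sample; features absent from the table (or with all-zero counts) fall
    back to the uniform prior with a warning.

    Returns
    -------
    (psi, warnings)
        ``psi`` maps feature name to its pseudocount vector; features not
        present map to None-free uniform handling by the caller is not
        needed because a vector is always returned when the feature appears
        in ``feature_names`` with a known state count in ``counts``.
    """
    psi: dict[str, np.ndarray] = {}
    warns: list[str] = []
    for name in feature_names:
        c = counts.get(name)
        if c is None:
            warns.append(f"feature {name!r} absent from empirical sample; uniform prior used")
            continue
        c = np.asarray(c, dtype=float)
        if (c < 0).any():
            raise ValueError(f"feature {name!r}: negative counts")
        total = c.sum()
        if total <= 0:
            warns.append(f"feature {name!r} has empty counts; uniform prior used")
            psi[name] = np.ones_like(c)
            continue
        psi[name] = pseudocounts_from_prior(c / total, rho)
    for w in warns:
        warnings.warn(w, stacklevel=2)
    return psi, warns


def dirichlet_logpdf(x: np.ndarray, psi: np.ndarray) -> float:
    """Log-density of Dirichlet(psi) at x (x strictly inside the simplex)."""
    x = np.asarray(x, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if (x <= 0).any():
        return -np.inf
    return float(
        gammaln(psi.sum()) - gammaln(psi).sum() + ((psi - 1.0) * np.log(x)).sum()
    )


@dataclass
class DirichletSpec:
    """Pseudocounts for every simplex-valued parameter block.

    ``alpha[f]`` has length N_f; ``beta[(phi, f)]`` likewise; ``gamma[f]``
    is shared across area slots (areas are exchangeable a priori);
    ``weights[f]`` has length 3. All entries strictly positive.
    """

    alpha: dict[int, np.ndarray]
    beta: dict[tuple[int, int], np.ndarray]
    gamma: dict[int, np.ndarray]
    weights: dict[int, np.ndarray]

    @classmethod
    def uniform(cls, dataset: Dataset) -> "DirichletSpec":
        ns = dataset.n_states
        alpha = {f: np.ones(ns[f]) for f in range(dataset.n_features)}
        beta = {
            (phi, f): np.ones(ns[f])
            for phi in range(dataset.n_families)
            for f in range(dataset.n_features)
        }
        gamma = {f: np.ones(ns[f]) for f in range(dataset.n_features)}
        w = {f: np.ones(3) for f in range(dataset.n_features)}
        return cls(alpha=alpha, beta=beta, gamma=gamma, weights=w)

    def validate(self, dataset: Dataset) -> None:
        ns = dataset.n_states
        for f in range(dataset.n_features):
            for block, psi in (("alpha", self.alpha[f]), ("gamma", self.gamma[f])):
                if len(psi) != ns[f] or (np.asarray(psi) <= 0).any():
                    raise ValueError(f"{block} pseudocounts invalid for feature {f}")
            if len(self.weights[f]) != 3 or (np.asarray(self.weights[f]) <= 0).any():
                raise ValueError(f"weight pseudocounts invalid for feature {f}")
        for (phi, f), psi in self.beta.items():
            if len(psi) != ns[f] or (np.asarray(psi) <= 0).any():
                raise ValueError(f"beta pseudocounts invalid for family {phi}, feature {f}")


@dataclass
class GeoPriorSpec:
    """Geographic prior on a single area.

    ``type`` is ``"uniform"`` (all disjoint configurations equally likely)
    or ``"cost_based"`` (log-prior −lambda * mean linkage edge cost).
    """

    type: str = "uniform"
    rate: float = 0.0
    linkage: str = "mst"
    cost_matrix: CostMatrix | None = None
    locations: np.ndarray | None = None  # needed for delaunay linkage

    def __post_init__(self) -> None:
        if self.type not in ("uniform", "cost_based"):
            raise ValueError(f"unknown geo-prior type {self.type!r}")
        if self.linkage not in ("mst", "delaunay", "complete"):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if not np.isfinite(self.rate) or self.rate < 0:
            raise ValueError("rate lambda must be finite and >= 0")
        if self.type == "cost_based" and self.cost_matrix is None:
            raise ValueError("cost_based geo-prior requires a cost matrix")


@dataclass
class SizePriorSpec:
    """Uniform prior on area sizes within ``[m_min, m_max]`` (−inf outside)."""

    m_min: int = 3
    m_max: int = 50

    def __post_init__(self) -> None:
        if not (2 <= self.m_min <= self.m_max):
            raise ValueError(f"need 2 <= m_min <= m_max, got [{self.m_min}, {self.m_max}]")

    @classmethod
    def default(cls, n_entities: int) -> "SizePriorSpec":
        return cls(m_min=3, m_max=max(3, min(50, n_entities - 1)))


@dataclass
class PriorSpec:
    """All prior blocks for one run."""

    dirichlet: DirichletSpec
    geo: GeoPriorSpec
    size: SizePriorSpec

    @classmethod
    def default(cls, dataset: Dataset, cost_matrix: CostMatrix | None = None) -> "PriorSpec":
        geo = GeoPriorSpec(type="uniform", cost_matrix=cost_matrix, locations=dataset.locations)
        return cls(
            dirichlet=DirichletSpec.uniform(dataset),
            geo=geo,
            size=SizePriorSpec.default(dataset.n_entities),
        )


# ---------------------------------------------------------------------------
# Geo-prior
# ---------------------------------------------------------------------------


def minimum_spanning_tree_edges(
    members: np.ndarray, costs: np.ndarray
) -> list[tuple[int, int]]:
    """Kruskal MST over the induced subgraph, deterministic under ties.

    Edges are scanned in (cost, min index, max index) order so degenerate
    inputs with tied costs always yield the same tree. The multiset of edge
    costs — hence the mean — is identical across all MSTs regardless.
    """
    members = np.asarray(sorted(int(m) for m in members))
    n = len(members)
    if n <= 1:
        return []
    ii, jj = np.triu_indices(n, k=1)
    w = costs[members[ii], members[jj]]
    order = np.lexsort((jj, ii, w))
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    edges: list[tuple[int, int]] = []
    for e in order:
        a, b = find(int(ii[e])), find(int(jj[e]))
        if a != b:
            parent[a] = b
            edges.append((int(members[ii[e]]), int(members[jj[e]])))
            if len(edges) == n - 1:
                break
    return edges


def _delaunay_edges(members: np.ndarray, locations: np.ndarray) -> list[tuple[int, int]] | None:
    """Delaunay edges among members, or None when degenerate (e.g. collinear)."""
    members = np.asarray(sorted(int(m) for m in members))
    if len(members) < 3:
        return None
    pts = locations[members]
    try:
        tri = Delaunay(pts)
    except QhullError:
        return None
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                i, j = sorted((int(members[simplex[a]]), int(members[simplex[b]])))
                edges.add((i, j))
    return sorted(edges)


def area_cost(
    members: set[int] | np.ndarray,
    cost_matrix: CostMatrix,
    linkage: str = "mst",
    locations: np.ndarray | None = None,
) -> float:
    """Mean linkage edge cost ``c_k`` of an area; singleton areas cost 0.

    ``mst``: mean edge cost of the minimum spanning tree over the members
    (the least total effort to physically connect the area). ``complete``:
    mean over all pairs. ``delaunay``: mean over Delaunay edges restricted
    to the members, falling back to the MST (with a warning) on degenerate
    point sets.
    """
    members = np.asarray(sorted(int(m) for m in members))
    n = len(members)
    if n <= 1:
        return 0.0
    c = cost_matrix.costs
    if linkage == "complete":
        ii, jj = np.triu_indices(n, k=1)
        return float(c[members[ii], members[jj]].mean())
    if linkage == "delaunay":
        if locations is None:
            raise ValueError("delaunay linkage requires locations")
        edges = _delaunay_edges(members, locations)
        if edges is None:
            warnings.warn(
                "degenerate point set for Delaunay linkage; falling back to MST",
                stacklevel=2,
            )
        else:
            return float(np.mean([c[i, j] for i, j in edges]))
    elif linkage != "mst":
        raise ValueError(f"unknown linkage {linkage!r}")
    edges = minimum_spanning_tree_edges(members, c)
    return float(np.mean([c[i, j] for i, j in edges]))


def geo_prior_log(areas: AreaConfiguration, spec: GeoPriorSpec) -> float:
    """Unnormalized log geo-prior of a configuration.

    −inf whenever two areas overlap; otherwise 0 for the uniform type and
    ``sum_k (−lambda * c_k)`` for the cost-based type.
    """
    sizes = sum(len(a) for a in areas.areas)
    assigned = int((areas.assignment >= 0).sum())
    if assigned != sizes:  # defensive; AreaConfiguration already enforces this
        return -np.inf
    if spec.type == "uniform" or spec.rate == 0.0:
        return 0.0
    total = 0.0
    for members in areas.areas:
        total -= spec.rate * area_cost(
            members, spec.cost_matrix, spec.linkage, spec.locations
        )
    return total


def size_prior_log(areas: AreaConfiguration, spec: SizePriorSpec) -> float:
    for m in areas.sizes:
        if not (spec.m_min <= m <= spec.m_max):
            return -np.inf
    return 0.0


def log_prior(params: ModelParameters, priors: PriorSpec, dataset: Dataset) -> float:
    """Joint log-prior: Dirichlet terms + geo-prior + size prior.

    The weight prior lives on the active component sub-simplex: inheritance
    carries no free weight without families, contact none when K = 0.
    """
    d = priors.dirichlet
    ns = dataset.n_states
    active = np.array([True, dataset.n_families > 0, params.areas.k > 0])
    total = 0.0
    for f in range(dataset.n_features):
        if active.sum() > 1:
            total += dirichlet_logpdf(
                params.weights[f][active], np.asarray(d.weights[f])[active]
            )
        total += dirichlet_logpdf(params.alpha[f, : ns[f]], d.alpha[f])
        for phi in range(dataset.n_families):
            total += dirichlet_logpdf(params.beta[phi, f, : ns[f]], d.beta[(phi, f)])
        for k in range(params.areas.k):
            total += dirichlet_logpdf(params.gamma[k, f, : ns[f]], d.gamma[f])
    total += geo_prior_log(params.areas, priors.geo)
    total += size_prior_log(params.areas, priors.size)
    return float(total)
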