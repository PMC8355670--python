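"""Synthetic trait datasets with planted families and contact areas.

The generator mirrors the statistical structure the model assumes: entities
scattered uniformly over a planar region; categorical features with 2–4
states; per-feature probability vectors for universal preference (alpha),
inheritance in each planted family (beta) and contact in each planted area
(gamma), drawn from symmetric Dirichlet distributions whose concentration
controls the expected entropy (small concentration = low entropy = strong
signal); and per-feature mixture weights. Each cell is sampled by first
choosing a component from the entity's effective weights and then a state
from that component — equivalent in law to the marginal mixture.

``make_experiment`` packages four canonical study designs: planted areas of
varying size and signal strength (exp1), a family confounder next to a
weaker contact area (exp2), a known number of areas for a DIC scan (exp3),
and a small spatially biased subsample with matching empirical prior count
tables (exp4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import Dataset, Entity
from .likelihood import effective_weights

__all__ = [
    "ScenarioSpec",
    "SyntheticDataset",
    "simulate_locations",
    "simulate_probability_vectors",
    "simulate_features",
    "simulate_dataset",
    "spatial_cluster",
    "make_experiment",
]


@dataclass
class ScenarioSpec:
    """Ground-truth design of one simulated dataset.

    ``weights`` may be a single triple (tied across features) or an
    (n_features, 3) array. Concentrations are symmetric-Dirichlet
    parameters for drawing the probability vectors; lower values yield
    lower-entropy (more decisive) vectors. Features listed in
    ``gamma_equals_alpha`` get contact vectors identical to their
    universal vector — deliberately indecisive features whose data cannot
    favour one component over the other. Features in ``gamma_decisive``
    get a fixed near-deterministic contact vector (0.96 on the modal
    state) instead of a random draw — guaranteed-decisive features for
    weight-recovery analyses.
    """

    n_entities: int
    n_features: int
    n_states: list[int]
    weights: np.ndarray
    families: list[set[int]] = field(default_factory=list)
    areas: list[set[int]] = field(default_factory=list)
    alpha_concentration: float = 1.0
    beta_concentration: float = 0.1
    gamma_concentration: float = 0.3
    gamma_concentration_overrides: dict[int, float] = field(default_factory=dict)
    gamma_equals_alpha: tuple[int, ...] = ()
    gamma_decisive: tuple[int, ...] = ()
    distinct_signals: bool = True
    region: tuple[float, float, float, float] = (0.0, 0.0, 10.0, 10.0)
    locations: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_states) != self.n_features:
            raise ValueError("n_states must list one state count per feature")
        if any(s < 2 for s in self.n_states):
            raise ValueError("every feature needs at least 2 states")
        w = np.asarray(self.weights, dtype=float)
        if w.ndim == 1:
            w = np.tile(w, (self.n_features, 1))
        if w.shape != (self.n_features, 3) or (w < 0).any():
            raise ValueError("weights must be a (F, 3) array of non-negative triples")
        if not np.allclose(w.sum(axis=1), 1.0):
            raise ValueError("each weight triple must sum to 1")
        self.weights = w
        for conc in (self.alpha_concentration, self.beta_concentration, self.gamma_concentration):
            if conc <= 0:
                raise ValueError("Dirichlet concentrations must be > 0")
        seen: set[int] = set()
        for a in self.areas:
            if seen & a:
                raise ValueError("planted areas must be disjoint")
            seen |= a


@dataclass
class SyntheticDataset:
    """A generated dataset plus the ground truth that produced it."""

    dataset: Dataset
    spec: ScenarioSpec
    alpha: np.ndarray  # (F, S)
    beta: np.ndarray  # (n_families, F, S)
    gamma: np.ndarray  # (n_areas, F, S)
    weights: np.ndarray  # (F, 3)
    families: list[set[int]]
    areas: list[set[int]]
    empirical_counts: dict[str, np.ndarray] | None = None


def simulate_locations(
    n: int,
    region: tuple[float, float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform locations in the rectangle (x0, y0, x1, y1)."""
    x0, y0, x1, y1 = region
    if not (x1 > x0 and y1 > y0):
        raise ValueError("degenerate region")
    if n < 1:
        raise ValueError("need n >= 1")
    pts = rng.uniform(size=(n, 2))
    pts[:, 0] = x0 + pts[:, 0] * (x1 - x0)
    pts[:, 1] = y0 + pts[:, 1] * (y1 - y0)
    return pts


def simulate_probability_vectors(
    n_states: int, concentration: float, rng: np.random.Generator
) -> np.ndarray:
    """One draw from a symmetric Dirichlet; strictly positive."""
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    x = rng.dirichlet(np.full(n_states, concentration))
    while (x <= 0).any():
        x = rng.dirichlet(np.full(n_states, concentration))
    return x


def place_modal(vector: np.ndarray, target_state: int) -> np.ndarray:
    """Permute a probability vector so its largest entry sits at ``target_state``.

    The remaining entries keep their descending order over the remaining
    states in ascending state order, making the permutation deterministic.
    A planted signal permuted onto a state the confounders dis-prefer is
    what makes it decisive evidence: low entropy *and* different from the
    confounder distributions.
    """
    v = np.sort(np.asarray(vector, dtype=float))[::-1]
    out = np.empty_like(v)
    out[target_state] = v[0]
    rest = [s for s in range(len(v)) if s != target_state]
    out[rest] = v[1:]
    return out


def spatial_cluster(
    locations: np.ndarray,
    size: int,
    rng: np.random.Generator,
    exclude: set[int] | None = None,
    center: np.ndarray | None = None,
) -> set[int]:
    """The ``size`` available entities nearest a (random) centre point."""
    exclude = exclude or set()
    avail = np.array([i for i in range(len(locations)) if i not in exclude])
    if len(avail) < size:
        raise ValueError(f"cannot plant a cluster of {size} among {len(avail)} entities")
    if center is None:
        center = locations[avail[rng.integers(len(avail))]]
    d = np.linalg.norm(locations[avail] - center, axis=1)
    order = np.lexsort((avail, d))
    return set(int(i) for i in avail[order[:size]])


def simulate_features(
    spec: ScenarioSpec,
    alpha: np.ndarray,
    beta: np.ndarray,
    gamma: np.ndarray,
    fam_of: np.ndarray,
    area_of: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw the data matrix: component from effective weights, then state."""
    L, F = spec.n_entities, spec.n_features
    data = np.zeros((L, F), dtype=np.int16)
    for l in range(L):
        in_fam = fam_of[l] >= 0
        in_area = area_of[l] >= 0
        for f in range(F):
            w = effective_weights(spec.weights[f], in_fam, in_area)
            comp = rng.choice(3, p=w)
            ns = spec.n_states[f]
            if comp == 0:
                p = alpha[f, :ns]
            elif comp == 1:
                p = beta[fam_of[l], f, :ns]
            else:
                p = gamma[area_of[l], f, :ns]
            data[l, f] = rng.choice(ns, p=p / p.sum())
    return data


def simulate_dataset(spec: ScenarioSpec) -> SyntheticDataset:
    """Realize a scenario: locations, probability vectors, data matrix.

    Fully deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    locations = (
        spec.locations
        if spec.locations is not None
        else simulate_locations(spec.n_entities, spec.region, rng)
    )
    F = spec.n_features
    smax = max(spec.n_states)
    alpha = np.zeros((F, smax))
    for f in range(F):
        alpha[f, : spec.n_states[f]] = simulate_probability_vectors(
            spec.n_states[f], spec.alpha_concentration, rng
        )
    beta = np.zeros((len(spec.families), F, smax))
    for phi in range(len(spec.families)):
        for f in range(F):
            ns = spec.n_states[f]
            vec = simulate_probability_vectors(ns, spec.beta_concentration, rng)
            if spec.distinct_signals:
                vec = place_modal(vec, int(np.argmin(alpha[f, :ns])))
            beta[phi, f, :ns] = vec
    gamma = np.zeros((len(spec.areas), F, smax))
    for k in range(len(spec.areas)):
        for f in range(F):
            ns = spec.n_states[f]
            if f in spec.gamma_equals_alpha:
                gamma[k, f, :ns] = alpha[f, :ns]
                continue
            if f in spec.gamma_decisive:
                vec = np.full(ns, 0.02)
                vec[0] = 1.0 - 0.02 * (ns - 1)
            else:
                conc = spec.gamma_concentration_overrides.get(f, spec.gamma_concentration)
                vec = simulate_probability_vectors(ns, conc, rng)
            if spec.distinct_signals:
                # the contact signal should sit on states dis-preferred by
                # both confounders, so it cannot be explained away
                score = alpha[f, :ns].copy()
                if len(spec.families):
                    score = score + beta[:, f, :ns].mean(axis=0)
                # distinct areas take distinct modal states where the state
                # inventory allows, so their profiles stay distinguishable
                vec = place_modal(vec, int(np.argsort(score)[k % ns]))
            gamma[k, f, :ns] = vec

    fam_of = np.full(spec.n_entities, -1, dtype=int)
    for phi, members in enumerate(spec.families):
        for l in members:
            fam_of[l] = phi
    area_of = np.full(spec.n_entities, -1, dtype=int)
    for k, members in enumerate(spec.areas):
        for l in members:
            area_of[l] = k

    data = simulate_features(spec, alpha, beta, gamma, fam_of, area_of, rng)

    width = len(str(spec.n_entities - 1))
    from .core_io import FeatureSpec

    entities = [
        Entity(
            id=f"L{l:0{width}d}",
            location=(float(locations[l, 0]), float(locations[l, 1])),
            family=f"fam{fam_of[l]}" if fam_of[l] >= 0 else None,
        )
        for l in range(spec.n_entities)
    ]
    features = [
        FeatureSpec(
            name=f"f{f}",
            states=tuple(f"s{s}" for s in range(spec.n_states[f])),
        )
        for f in range(F)
    ]
    dataset = Dataset(entities=entities, features=features, data=data)
    return SyntheticDataset(
        dataset=dataset,
        spec=spec,
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        weights=spec.weights,
        families=[set(a) for a in spec.families],
        areas=[set(a) for a in spec.areas],
    )


def _scaled(n: int, scale: float, minimum: int = 2) -> int:
    v = int(round(n * scale))
    if v < minimum:
        raise ValueError(f"scale {scale} shrinks a planted structure below size {minimum}")
    return v


def make_experiment(name: str, scale: float = 1.0, seed: int = 0) -> SyntheticDataset:
    """Canonical simulation designs.

    exp1
        951 entities (scaled), 30 features with 2–4 states, three planted
        areas of decreasing size and signal strength, no families.
    exp2
        100 entities (scaled), a 20-member low-entropy family and a
        disjoint, weaker 12-member contact area.
    exp3
        100 entities (scaled), exactly two planted areas, for DIC scans.
    exp4
        A spatially biased 40-entity subsample of a 200-entity population
        (scaled), with empirical prior count tables from the entities left
        out of the sample.

    ``scale`` shrinks entity counts and planted structures proportionally;
    feature counts are preserved.
    """
    rng = np.random.default_rng(seed)
    states30 = [2 + (i % 3) for i in range(30)]

    if name == "exp1":
        n = _scaled(951, scale, minimum=20)
        locations = simulate_locations(n, (0.0, 0.0, 10.0, 10.0), rng)
        sizes = [max(3, _scaled(40, scale)), max(3, _scaled(25, scale)), max(3, _scaled(15, scale))]
        taken: set[int] = set()
        areas = []
        for size in sizes:
            a = spatial_cluster(locations, size, rng, exclude=taken)
            taken |= a
            areas.append(a)
        spec = ScenarioSpec(
            n_entities=n,
            n_features=30,
            n_states=states30,
            weights=np.array([0.4, 0.0, 0.6]),
            areas=areas,
            gamma_concentration=0.1,
            locations=locations,
            seed=seed,
        )
        return simulate_dataset(spec)

    if name == "exp2":
        n = _scaled(100, scale, minimum=40)
        locations = simulate_locations(n, (0.0, 0.0, 10.0, 10.0), rng)
        family = spatial_cluster(locations, max(5, _scaled(20, scale)), rng)
        area = spatial_cluster(locations, max(3, _scaled(12, scale)), rng, exclude=family)
        spec = ScenarioSpec(
            n_entities=n,
            n_features=30,
            n_states=states30,
            weights=np.array([0.2, 0.3, 0.5]),
            families=[family],
            areas=[area],
            beta_concentration=0.05,
            gamma_concentration=0.3,
            locations=locations,
            seed=seed,
        )
        return simulate_dataset(spec)

    if name == "exp3":
        n = _scaled(100, scale, minimum=30)
        locations = simulate_locations(n, (0.0, 0.0, 10.0, 10.0), rng)
        size = max(3, _scaled(15, scale))
        a1 = spatial_cluster(locations, size, rng)
        a2 = spatial_cluster(locations, size, rng, exclude=a1)
        spec = ScenarioSpec(
            n_entities=n,
            n_features=30,
            n_states=states30,
            weights=np.array([0.4, 0.0, 0.6]),
            areas=[a1, a2],
            gamma_concentration=0.1,
            locations=locations,
            seed=seed,
        )
        return simulate_dataset(spec)

    if name == "exp4":
        n_pop = _scaled(200, scale, minimum=60)
        n_sub = max(20, _scaled(40, scale))
        locations = simulate_locations(n_pop, (0.0, 0.0, 10.0, 10.0), rng)
        # biased sample: entities nearest one corner of the region
        subsample = spatial_cluster(
            locations, n_sub, rng, center=np.array([1.0, 1.0])
        )
        area_pop = spatial_cluster(
            locations, max(3, _scaled(10, scale)), rng,
            exclude=set(range(n_pop)) - subsample,
        )
        spec = ScenarioSpec(
            n_entities=n_pop,
            n_features=30,
            n_states=states30,
            weights=np.array([0.4, 0.0, 0.6]),
            areas=[area_pop],
            gamma_concentration=0.1,
            locations=locations,
            seed=seed,
        )
        full = simulate_dataset(spec)
        sub_idx = sorted(subsample)
        remap = {old: new for new, old in enumerate(sub_idx)}
        outside = sorted(set(range(n_pop)) - subsample)
        counts: dict[str, np.ndarray] = {}
        for f, feat in enumerate(full.dataset.features):
            col = full.dataset.data[outside, f]
            counts[feat.name] = np.bincount(
                col[col >= 0], minlength=feat.n_states
            ).astype(float)
        sub_dataset = Dataset(
            entities=[full.dataset.entities[i] for i in sub_idx],
            features=full.dataset.features,
            data=full.dataset.data[sub_idx],
        )
        sub_spec = ScenarioSpec(
            n_entities=len(sub_idx),
            n_features=30,
            n_states=states30,
            weights=spec.weights,
            areas=[{remap[i] for i in area_pop if i in remap}],
            gamma_concentration=0.1,
            locations=locations[sub_idx],
            seed=seed,
        )
        return SyntheticDataset(
            dataset=sub_dataset,
            spec=sub_spec,
            alpha=full.alpha,
            beta=full.beta,
            gamma=full.gamma,
            weights=full.weights,
            families=[],
            areas=sub_spec.areas,
            empirical_counts=counts,
        )

    raise ValueError(f"unknown experiment {name!r} (expected exp1|exp2|exp3|exp4)")
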