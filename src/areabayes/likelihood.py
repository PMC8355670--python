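"""Mixture likelihood: universal preference, inheritance and contact.

Each observed cell — the state of feature ``f`` in entity ``l`` — is modelled
as a draw from a three-component mixture of categorical distributions:

    P(X_lf = s) = w_u,f * alpha_{f,s} + w_i,f * beta_{f,phi(l),s}
                  + w_c,f * gamma_{f,Z(l),s}

where ``alpha`` is the universal (baseline) distribution of feature ``f``,
``beta`` the distribution inside the entity's family ``phi(l)``, ``gamma``
the distribution inside the entity's contact area ``Z(l)``, and ``w_f`` a
per-feature weight triple on the simplex. For an entity outside any area the
contact weight is zeroed and the remaining weights re-normalized; entities
with no family are handled symmetrically for the inheritance weight. The
joint log-likelihood is the sum of log cell probabilities over all
non-missing cells (missing cells contribute a factor 1).

Parameter arrays are padded to ``max(N_f)`` states; entries beyond a
feature's own state count are never addressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import MISSING, Dataset

__all__ = [
    "AreaConfiguration",
    "ModelParameters",
    "effective_weights",
    "cell_likelihood",
    "data_log_likelihood",
    "cell_log_matrix",
]


@dataclass
class AreaConfiguration:
    """K pairwise-disjoint entity subsets (candidate contact areas).

    Stored both as explicit member-index sets and as a dense assignment
    vector ``assignment`` with ``assignment[l] = k`` for members of area
    ``k`` and −1 for unassigned entities.
    """

    areas: list[set[int]]
    n_entities: int

    assignment: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.areas = [set(int(i) for i in a) for a in self.areas]
        z = np.full(self.n_entities, -1, dtype=np.int32)
        for k, members in enumerate(self.areas):
            for l in members:
                if not (0 <= l < self.n_entities):
                    raise ValueError(f"entity index {l} out of range")
                if z[l] != -1:
                    raise ValueError(
                        f"entity {l} assigned to areas {z[l]} and {k}: areas must be disjoint"
                    )
                z[l] = k
        self.assignment = z

    @property
    def k(self) -> int:
        return len(self.areas)

    @property
    def sizes(self) -> list[int]:
        return [len(a) for a in self.areas]

    def copy(self) -> "AreaConfiguration":
        return AreaConfiguration([set(a) for a in self.areas], self.n_entities)

    @classmethod
    def from_assignment(cls, z: np.ndarray, k: int) -> "AreaConfiguration":
        areas = [set(np.flatnonzero(z == kk).tolist()) for kk in range(k)]
        return cls(areas, len(z))


@dataclass
class ModelParameters:
    """Full parameter vector of the mixture model.

    Attributes
    ----------
    weights : (F, 3) array
        Per-feature mixture weight triples (universal, inherit, contact),
        each on the simplex.
    alpha : (F, S) array
        Universal categorical distributions, padded to S = max states.
    beta : (n_families, F, S) array
        Per-family distributions. Empty first axis when no families.
    gamma : (K, F, S) array
        Per-area distributions, one slot per area. Empty first axis when
        K = 0.
    areas : AreaConfiguration
    """

    weights: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    areas: AreaConfiguration

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            weights=self.weights.copy(),
            alpha=self.alpha.copy(),
            beta=self.beta.copy(),
            gamma=self.gamma.copy(),
            areas=self.areas.copy(),
        )


def effective_weights(
    weights_f: np.ndarray, in_family: bool, in_area: bool
) -> np.ndarray:
    """Re-normalized weight triple for one entity and feature.

    Components whose effect does not apply to the entity (inheritance for
    entities with no family, contact for entities outside every area) are
    set to zero and the remaining weights re-normalized to sum to one. If
    no applicable weight is positive all mass falls back on the universal
    component.

    Parameters
    ----------
    weights_f
        Weight triple (universal, inherit, contact) on the simplex.
    in_family, in_area
        Whether the inheritance / contact component applies.
    """
    w = np.asarray(weights_f, dtype=float)
    if (w < 0).any():
        raise ValueError("negative mixture weight")
    mask = np.array([1.0, 1.0 if in_family else 0.0, 1.0 if in_area else 0.0])
    w = w * mask
    total = w.sum()
    if total <= 0.0:
        return np.array([1.0, 0.0, 0.0])
    return w / total


def cell_likelihood(
    state: int,
    alpha_f: np.ndarray,
    beta_f: np.ndarray | None,
    gamma_f: np.ndarray | None,
    eff_weights: np.ndarray,
) -> float:
    """Mixture probability of observing ``state`` in one cell.

    ``beta_f`` / ``gamma_f`` may be None when the corresponding effective
    weight is zero (entity outside any family / area).
    """
    n_states = len(alpha_f)
    if not (0 <= state < n_states):
        raise IndexError(f"state index {state} out of range for {n_states} states")
    w = np.asarray(eff_weights, dtype=float)
    p = w[0] * float(alpha_f[state])
    if w[1] > 0:
        p += w[1] * float(beta_f[state])
    if w[2] > 0:
        p += w[2] * float(gamma_f[state])
    return p


def cell_log_matrix(
    data: np.ndarray,
    family_index: np.ndarray,
    assignment: np.ndarray,
    params: ModelParameters,
    rows: np.ndarray | None = None,
    cols: np.ndarray | None = None,
) -> np.ndarray:
    """Log cell probabilities for a block of entities x features.

    Missing cells contribute 0 (log of the empty-product factor 1). A cell
    with probability zero yields −inf. This is the vectorized workhorse
    behind :func:`data_log_likelihood` and the sampler's incremental cache.
    """
    L, F = data.shape
    rows = np.arange(L) if rows is None else np.atleast_1d(rows).astype(np.intp)
    cols = np.arange(F) if cols is None else np.atleast_1d(cols).astype(np.intp)
    x = data[np.ix_(rows, cols)]
    miss = x == MISSING
    xs = np.where(miss, 0, x).astype(np.intp)

    fam = family_index[rows]
    z = assignment[rows]
    mi = (fam >= 0).astype(float)[:, None]
    mc = (z >= 0).astype(float)[:, None]

    c_idx = cols[None, :]
    A = params.alpha[c_idx, xs]
    if params.beta.shape[0] > 0:
        fam_safe = np.where(fam >= 0, fam, 0).astype(np.intp)
        B = params.beta[fam_safe[:, None], c_idx, xs]
    else:
        B = np.zeros_like(A)
    if params.gamma.shape[0] > 0:
        z_safe = np.where(z >= 0, z, 0).astype(np.intp)
        G = params.gamma[z_safe[:, None], c_idx, xs]
    else:
        G = np.zeros_like(A)

    w = params.weights[cols]  # (C, 3)
    wu, wi, wc = w[:, 0][None, :], w[:, 1][None, :], w[:, 2][None, :]
    denom = wu + wi * mi + wc * mc
    num = wu * A + wi * mi * B + wc * mc * G
    # all applicable weights zero -> all mass on the universal component
    degen = denom <= 0.0
    if degen.any():
        num = np.where(degen, A, num)
        denom = np.where(degen, 1.0, denom)
    with np.errstate(divide="ignore"):
        logp = np.log(num / denom)
    logp[miss] = 0.0
    return logp


def data_log_likelihood(dataset: Dataset, params: ModelParameters) -> float:
    """Joint log-likelihood of all observed cells under the mixture.

    Returns −inf when some cell has probability zero under every applicable
    component (possible only with user-fixed probability vectors; the
    sampler keeps all vectors strictly positive).
    """
    logs = cell_log_matrix(
        dataset.data, dataset.family_index, params.areas.assignment, params
    )
    return float(logs.sum())
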