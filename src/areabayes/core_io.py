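"""Domain types and file I/O for categorical trait datasets.

The central container is :class:`Dataset`: a matrix of categorical feature
states observed for geographically situated entities (languages, in the
original application), together with per-feature state inventories, entity
locations and an optional family (or clade) assignment per entity. Files are
plain delimited text; state inventories are YAML/JSON.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MISSING",
    "EARTH_RADIUS_KM",
    "FeatureSpec",
    "Entity",
    "Dataset",
    "CostMatrix",
    "ValidationReport",
    "read_feature_table",
    "write_feature_table",
    "read_locations",
    "write_locations",
    "read_state_inventory",
    "write_state_inventory",
    "read_cost_matrix",
    "write_cost_matrix",
    "load_dataset",
    "build_cost_matrix",
    "validate_dataset",
]

#: Sentinel for a missing cell in the integer data matrix.
MISSING: int = -1

#: Mean Earth radius in kilometres, used for great-circle distances.
EARTH_RADIUS_KM: float = 6371.0


@dataclass(frozen=True)
class FeatureSpec:
    """A categorical feature with a fixed, ordered inventory of states.

    Parameters
    ----------
    name
        Feature identifier, unique within a dataset.
    states
        Ordered state labels. The position of a label in this tuple is the
        integer code used in ``Dataset.data``; the ordering is part of the
        contract and never changes after construction.
    """

    name: str
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ValueError(
                f"feature {self.name!r} needs at least 2 states, got {len(self.states)}"
            )
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"feature {self.name!r} has duplicate state labels")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, label: str) -> int:
        """Integer code of a state label."""
        return self.states.index(label)


@dataclass(frozen=True)
class Entity:
    """A geographically situated entity (one row of the dataset).

    ``location`` is a point: planar (x, y) or spherical (lon, lat) in
    degrees. ``family`` is a family/clade label or ``None`` for isolates and
    unclassified entities.
    """

    id: str
    location: tuple[float, float]
    family: str | None = None

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.location):
            raise ValueError(f"entity {self.id!r} has non-finite coordinates")


class Dataset:
    """Entities x features matrix of categorical state codes.

    ``data[l, f]`` holds the state index of feature ``f`` in entity ``l``
    (an index into ``features[f].states``) or :data:`MISSING`.

    Families are exposed both as labels (``Entity.family``) and as a dense
    integer vector ``family_index`` (−1 for no family) over the sorted
    family name list ``family_names``.
    """

    def __init__(
        self,
        entities: list[Entity],
        features: list[FeatureSpec],
        data: np.ndarray,
    ) -> None:
        data = np.asarray(data, dtype=np.int16)
        if data.shape != (len(entities), len(features)):
            raise ValueError(
                f"data shape {data.shape} does not match "
                f"{len(entities)} entities x {len(features)} features"
            )
        ids = [e.id for e in entities]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate entity ids")
        names = [f.name for f in features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names")
        for j, feat in enumerate(features):
            col = data[:, j]
            bad = (col != MISSING) & ((col < 0) | (col >= feat.n_states))
            if bad.any():
                raise ValueError(
                    f"feature {feat.name!r}: state index out of range in data"
                )
        self.entities = list(entities)
        self.features = list(features)
        self.data = data
        self.family_names: tuple[str, ...] = tuple(
            sorted({e.family for e in entities if e.family is not None})
        )
        fam_pos = {name: k for k, name in enumerate(self.family_names)}
        self.family_index = np.array(
            [fam_pos.get(e.family, -1) for e in entities], dtype=np.int32
        )
        self.locations = np.array([e.location for e in entities], dtype=float)

    @property
    def n_entities(self) -> int:
        return len(self.entities)

    @property
    def n_families(self) -> int:
        return len(self.family_names)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_states(self) -> np.ndarray:
        """Number of states per feature, shape (n_features,)."""
        return np.array([f.n_states for f in self.features], dtype=np.int32)

    @property
    def entity_ids(self) -> list[str]:
        return [e.id for e in self.entities]

    def family_members(self, family: str) -> list[int]:
        """Entity indices belonging to ``family``."""
        k = self.family_names.index(family)
        return list(np.flatnonzero(self.family_index == k))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Dataset({self.n_entities} entities x {self.n_features} features, "
            f"{self.n_families} families)"
        )


@dataclass
class CostMatrix:
    """Symmetric pairwise cost of traversing space between entities.

    Invariants: symmetric, zero diagonal, finite, non-negative.
    """

    costs: np.ndarray
    metric: str = "custom"

    def __post_init__(self) -> None:
        c = np.asarray(self.costs, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("cost matrix must be square")
        if not np.isfinite(c).all():
            raise ValueError("cost matrix has non-finite entries")
        if (c < 0).any():
            raise ValueError("cost matrix has negative entries")
        if not np.allclose(c, c.T):
            raise ValueError("cost matrix must be symmetric")
        if not np.allclose(np.diag(c), 0.0):
            raise ValueError("cost matrix diagonal must be zero")
        c = 0.5 * (c + c.T)  # remove floating-point asymmetry
        np.fill_diagonal(c, 0.0)
        self.costs = c

    @property
    def n(self) -> int:
        return self.costs.shape[0]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _sniff_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_feature_table(
    path: str | Path,
    missing_token: str = "?",
    state_inventory: dict[str, list[str]] | None = None,
    sep: str | None = None,
) -> tuple[list[str], list[FeatureSpec], np.ndarray]:
    """Read a delimited feature table: one row per entity, one column per feature.

    The first column holds entity ids. State inventories are taken from
    ``state_inventory`` when given (file order preserved); otherwise they are
    inferred from the observed labels with stable alphabetical ordering.

    Returns
    -------
    (entity_ids, features, data)
        ``data`` is an int matrix with :data:`MISSING` for missing cells.

    Raises
    ------
    ValueError
        On duplicate entity ids, a feature with fewer than two observed
        states and no declared inventory, or an observed label absent from a
        declared inventory.
    """
    path = Path(path)
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    id_col = df.columns[0]
    entity_ids = df[id_col].tolist()
    if len(set(entity_ids)) != len(entity_ids):
        raise ValueError(f"duplicate entity ids in {path}")
    features: list[FeatureSpec] = []
    cols = []
    for name in df.columns[1:]:
        raw = df[name].tolist()
        observed = sorted({v for v in raw if v != missing_token and v != ""})
        if state_inventory is not None and name in state_inventory:
            states = list(state_inventory[name])
            unknown = set(observed) - set(states)
            if unknown:
                raise ValueError(
                    f"feature {name!r}: labels {sorted(unknown)} not in declared inventory"
                )
        else:
            if len(observed) < 2:
                raise ValueError(
                    f"feature {name!r} has {len(observed)} observed state(s) "
                    "and no declared inventory"
                )
            states = observed  # alphabetical, stable
        spec = FeatureSpec(name=name, states=tuple(states))
        idx = {s: i for i, s in enumerate(states)}
        col = np.array(
            [MISSING if v in (missing_token, "") else idx[v] for v in raw],
            dtype=np.int16,
        )
        features.append(spec)
        cols.append(col)
    data = (
        np.stack(cols, axis=1)
        if cols
        else np.empty((len(entity_ids), 0), dtype=np.int16)
    )
    return entity_ids, features, data


def write_feature_table(
    dataset: Dataset,
    path: str | Path,
    missing_token: str = "?",
    sep: str | None = None,
) -> None:
    """Write the feature table so that :func:`read_feature_table` round-trips."""
    path = Path(path)
    sep = sep or _sniff_sep(path)
    out = {"id": dataset.entity_ids}
    for j, feat in enumerate(dataset.features):
        col = dataset.data[:, j]
        out[feat.name] = [
            missing_token if v == MISSING else feat.states[v] for v in col
        ]
    pd.DataFrame(out).to_csv(path, sep=sep, index=False)


def read_locations(
    path: str | Path, sep: str | None = None
) -> tuple[list[str], np.ndarray, list[str | None]]:
    """Read entity locations and optional family labels.

    Expects columns ``id``, ``x``/``lon``, ``y``/``lat`` and optionally
    ``family`` (empty cell = no family).
    """
    path = Path(path)
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"id": str, "family": str}, keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    xcol = cols.get("x", cols.get("lon"))
    ycol = cols.get("y", cols.get("lat"))
    if xcol is None or ycol is None:
        raise ValueError(f"{path}: need columns x/lon and y/lat")
    ids = df[cols["id"]].astype(str).tolist()
    coords = df[[xcol, ycol]].astype(float).to_numpy()
    if "family" in cols:
        fams = [f if f != "" else None for f in df[cols["family"]].tolist()]
    else:
        fams = [None] * len(ids)
    return ids, coords, fams


def write_locations(dataset: Dataset, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    sep = sep or _sniff_sep(path)
    df = pd.DataFrame(
        {
            "id": dataset.entity_ids,
            "x": dataset.locations[:, 0],
            "y": dataset.locations[:, 1],
            "family": [e.family if e.family is not None else "" for e in dataset.entities],
        }
    )
    df.to_csv(path, sep=sep, index=False)


def read_state_inventory(path: str | Path) -> dict[str, list[str]]:
    """Read a feature -> ordered state list mapping from YAML (or JSON)."""
    with open(path) as fh:
        inv = yaml.safe_load(fh)
    if not isinstance(inv, dict):
        raise ValueError(f"{path}: state inventory must map feature -> state list")
    return {str(k): [str(s) for s in v] for k, v in inv.items()}


def write_state_inventory(dataset: Dataset, path: str | Path) -> None:
    inv = {f.name: list(f.states) for f in dataset.features}
    with open(path, "w") as fh:
        yaml.safe_dump(inv, fh, sort_keys=False)


def read_cost_matrix(path: str | Path, entity_ids: list[str], sep: str | None = None) -> CostMatrix:
    """Read a square cost matrix with a header row/column of entity ids.

    Rows/columns are reordered to match ``entity_ids``; asymmetric input is
    symmetrized by averaging.
    """
    path = Path(path)
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    missing = set(entity_ids) - set(df.index)
    if missing:
        raise ValueError(f"cost matrix missing entities: {sorted(missing)[:5]}")
    m = df.loc[entity_ids, entity_ids].to_numpy(dtype=float)
    if (m < 0).any():
        raise ValueError("cost matrix has negative entries")
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    return CostMatrix(costs=m, metric="custom")


def write_cost_matrix(cost: CostMatrix, entity_ids: list[str], path: str | Path) -> None:
    path = Path(path)
    sep = _sniff_sep(path)
    pd.DataFrame(cost.costs, index=entity_ids, columns=entity_ids).to_csv(path, sep=sep)


def load_dataset(
    features_path: str | Path,
    locations_path: str | Path,
    missing_token: str = "?",
    state_inventory_path: str | Path | None = None,
) -> Dataset:
    """Assemble a :class:`Dataset` from a feature table and a locations file."""
    inv = read_state_inventory(state_inventory_path) if state_inventory_path else None
    feat_ids, features, data = read_feature_table(
        features_path, missing_token=missing_token, state_inventory=inv
    )
    loc_ids, coords, fams = read_locations(locations_path)
    pos = {i: k for k, i in enumerate(loc_ids)}
    missing = [i for i in feat_ids if i not in pos]
    if missing:
        raise ValueError(f"entities missing from locations file: {missing[:5]}")
    entities = [
        Entity(
            id=i,
            location=(float(coords[pos[i], 0]), float(coords[pos[i], 1])),
            family=fams[pos[i]],
        )
        for i in feat_ids
    ]
    return Dataset(entities=entities, features=features, data=data)


# ---------------------------------------------------------------------------
# Cost matrices
# ---------------------------------------------------------------------------


def _great_circle_km(coords: np.ndarray) -> np.ndarray:
    """Pairwise haversine distance in km; coords are (lon, lat) degrees."""
    lon = np.radians(coords[:, 0])[:, None]
    lat = np.radians(coords[:, 1])[:, None]
    dlat = lat - lat.T
    dlon = lon - lon.T
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def build_cost_matrix(
    entities: list[Entity] | Dataset,
    metric: str = "auto",
    user_matrix: np.ndarray | None = None,
) -> CostMatrix:
    """Pairwise traversal costs between entity locations.

    ``metric`` is one of ``"euclidean"``, ``"great_circle"``, ``"custom"``
    (requires ``user_matrix``) or ``"auto"``: great-circle when every
    coordinate is a plausible lon/lat pair (|lon| <= 180, |lat| <= 90),
    euclidean otherwise. Pass the metric explicitly when planar coordinates
    happen to fall in that range. A user matrix is symmetrized by averaging
    ``(c_ij + c_ji) / 2``.
    """
    coords = entities.locations if isinstance(entities, Dataset) else np.array(
        [e.location for e in entities], dtype=float
    )
    if user_matrix is not None or metric == "custom":
        if user_matrix is None:
            raise ValueError("metric='custom' requires user_matrix")
        m = np.asarray(user_matrix, dtype=float)
        if (m < 0).any():
            raise ValueError("user cost matrix has negative entries")
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 0.0)
        return CostMatrix(costs=m, metric="custom")
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinates")
    if metric == "auto":
        lonlat = (np.abs(coords[:, 0]) <= 180).all() and (np.abs(coords[:, 1]) <= 90).all()
        metric = "great_circle" if lonlat else "euclidean"
    if metric == "euclidean":
        diff = coords[:, None, :] - coords[None, :, :]
        m = np.sqrt((diff**2).sum(axis=2))
    elif metric == "great_circle":
        m = _great_circle_km(coords)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    return CostMatrix(costs=m, metric=metric)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

#: Families smaller than this cannot support a stable per-family probability
#: vector; the validator warns about them.
MIN_FAMILY_SIZE = 5


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    family_members: dict[str, list[str]] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_dataset(
    dataset: Dataset,
    cost_matrix: CostMatrix | None = None,
    low_coverage: float = 0.5,
) -> ValidationReport:
    """Consistency report for a dataset (report only; never raises).

    Hard errors: a feature missing in every entity; a cost matrix of the
    wrong size. Warnings: families with fewer than five members (too small
    to estimate a family probability vector reliably) and features observed
    in less than ``low_coverage`` of entities.
    """
    rep = ValidationReport()
    for fam in dataset.family_names:
        members = [dataset.entities[i].id for i in dataset.family_members(fam)]
        rep.family_members[fam] = members
        if len(members) < MIN_FAMILY_SIZE:
            rep.warnings.append(
                f"family {fam!r} has only {len(members)} members (< {MIN_FAMILY_SIZE}); "
                "its probability vector will be weakly informed"
            )
    n = dataset.n_entities
    for j, feat in enumerate(dataset.features):
        observed = int((dataset.data[:, j] != MISSING).sum())
        if observed == 0:
            rep.errors.append(f"feature {feat.name!r} is missing in all entities")
        elif n > 0 and observed / n < low_coverage:
            rep.warnings.append(
                f"feature {feat.name!r} observed in only {observed}/{n} entities"
            )
    if cost_matrix is not None and cost_matrix.n != n:
        rep.errors.append(
            f"cost matrix size {cost_matrix.n} does not match {n} entities"
        )
    return rep
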