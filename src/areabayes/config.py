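"""Run configuration: YAML/JSON schema, validation, reproducibility manifest."""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_io import Dataset, build_cost_matrix, load_dataset, read_cost_matrix
from .priors import (
    DirichletSpec,
    GeoPriorSpec,
    PriorSpec,
    SizePriorSpec,
    empirical_prior_from_sample,
)
from .sampler import DEFAULT_OPERATOR_WEIGHTS, SamplerConfig


class ConfigError(ValueError):
    """A configuration schema violation, carrying the offending field path."""

    def __init__(self, path: str, message: str):
        self.field_path = path
        super().__init__(f"{path}: {message}")


@dataclass
class RunConfig:
    """Parsed, validated run configuration."""

    features_path: Path
    locations_path: Path
    missing_token: str = "?"
    state_inventory_path: Path | None = None
    cost_matrix_path: Path | None = None
    metric: str = "auto"

    geo_type: str = "uniform"
    geo_rate: float = 0.0
    geo_linkage: str = "mst"
    m_min: int = 3
    m_max: int | None = None
    alpha_empirical_counts: Path | None = None
    alpha_empirical_rho: float = 10.0
    weights_pseudocounts: list[float] | None = None

    n_steps: int = 100_000
    burn_in: float = 0.2
    n_retained: int = 1000
    kappa: float = 30.0
    g: int = 10
    warmup_chains: int = 10
    warmup_steps: int = 5000
    operator_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OPERATOR_WEIGHTS)
    )

    k: int | None = None
    k_list: list[int] | None = None
    tau: float = 0.02
    output_dir: Path = Path("output")
    seed: int = 0
    log_level: str = "INFO"
    raw: dict = field(default_factory=dict)


def _get(doc: dict, path: str, default=None, required=False, cast=None):
    node = doc
    for part in path.split("."):
        if not isinstance(node, dict) or part not in node:
            if required:
                raise ConfigError(path, "required field missing")
            return default
        node = node[part]
    if cast is not None:
        try:
            node = cast(node)
        except (TypeError, ValueError) as exc:
            raise ConfigError(path, f"invalid value {node!r}: {exc}") from exc
    return node


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError("<root>", "configuration must be a mapping")
    base = path.parent

    def respath(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    cfg = RunConfig(
        features_path=respath(_get(doc, "data.features", required=True)),
        locations_path=respath(_get(doc, "data.locations", required=True)),
        missing_token=_get(doc, "data.missing_token", "?", cast=str),
        state_inventory_path=(
            respath(p) if (p := _get(doc, "data.state_inventory")) else None
        ),
        cost_matrix_path=(respath(p) if (p := _get(doc, "data.cost_matrix")) else None),
        metric=_get(doc, "data.metric", "auto", cast=str),
        geo_type=_get(doc, "prior.geo.type", "uniform", cast=str),
        geo_rate=_get(doc, "prior.geo.rate", 0.0, cast=float),
        geo_linkage=_get(doc, "prior.geo.linkage", "mst", cast=str),
        m_min=_get(doc, "prior.size.m_min", 3, cast=int),
        m_max=_get(doc, "prior.size.m_max", None),
        alpha_empirical_counts=(
            respath(p) if (p := _get(doc, "prior.alpha_empirical.counts")) else None
        ),
        alpha_empirical_rho=_get(doc, "prior.alpha_empirical.rho", 10.0, cast=float),
        weights_pseudocounts=_get(doc, "prior.weights_pseudocounts", None),
        n_steps=_get(doc, "sampler.n_steps", 100_000, cast=int),
        burn_in=_get(doc, "sampler.burn_in", 0.2, cast=float),
        n_retained=_get(doc, "sampler.n_retained", 1000, cast=int),
        kappa=_get(doc, "sampler.kappa", 30.0, cast=float),
        g=_get(doc, "sampler.g", 10, cast=int),
        warmup_chains=_get(doc, "sampler.warmup_chains", 10, cast=int),
        warmup_steps=_get(doc, "sampler.warmup_steps", 5000, cast=int),
        operator_weights=_get(
            doc, "sampler.operator_weights", dict(DEFAULT_OPERATOR_WEIGHTS)
        ),
        k=_get(doc, "model.k"),
        k_list=_get(doc, "model.k_list"),
        tau=_get(doc, "model.tau", 0.02, cast=float),
        output_dir=Path(_get(doc, "output", "output", cast=str)),
        seed=_get(doc, "seed", 0, cast=int),
        log_level=_get(doc, "log_level", "INFO", cast=str),
        raw=doc,
    )
    if cfg.geo_type not in ("uniform", "cost_based"):
        raise ConfigError("prior.geo.type", f"unknown type {cfg.geo_type!r}")
    if cfg.geo_linkage not in ("mst", "delaunay", "complete"):
        raise ConfigError("prior.geo.linkage", f"unknown linkage {cfg.geo_linkage!r}")
    if not (0.0 <= cfg.burn_in < 1.0):
        raise ConfigError("sampler.burn_in", "must be in [0, 1)")
    if cfg.weights_pseudocounts is not None and (
        not isinstance(cfg.weights_pseudocounts, list)
        or len(cfg.weights_pseudocounts) != 3
        or any(float(p) <= 0 for p in cfg.weights_pseudocounts)
    ):
        raise ConfigError(
            "prior.weights_pseudocounts", "must be three positive pseudocounts"
        )
    if cfg.k_list is not None:
        if not isinstance(cfg.k_list, list) or any(
            b <= a for a, b in zip(cfg.k_list, cfg.k_list[1:])
        ):
            raise ConfigError("model.k_list", "must be a strictly ascending list")
    for p_attr, field_path in (
        ("features_path", "data.features"),
        ("locations_path", "data.locations"),
        ("state_inventory_path", "data.state_inventory"),
        ("cost_matrix_path", "data.cost_matrix"),
        ("alpha_empirical_counts", "prior.alpha_empirical.counts"),
    ):
        p = getattr(cfg, p_attr)
        if p is not None and not Path(p).exists():
            raise ConfigError(field_path, f"file not found: {p}")
    return cfg


def build_dataset(cfg: RunConfig) -> Dataset:
    return load_dataset(
        cfg.features_path,
        cfg.locations_path,
        missing_token=cfg.missing_token,
        state_inventory_path=cfg.state_inventory_path,
    )


def read_empirical_counts(path: Path, dataset: Dataset) -> dict[str, np.ndarray]:
    """Long-format CSV (feature,state,count) -> per-feature count vectors."""
    df = pd.read_csv(path, dtype={"feature": str, "state": str})
    counts: dict[str, np.ndarray] = {}
    by_name = {f.name: f for f in dataset.features}
    for name, grp in df.groupby("feature"):
        feat = by_name.get(str(name))
        if feat is None:
            continue
        vec = np.zeros(feat.n_states)
        for _, row in grp.iterrows():
            vec[feat.index(str(row["state"]))] = float(row["count"])
        counts[feat.name] = vec
    return counts


def build_priors(cfg: RunConfig, dataset: Dataset) -> PriorSpec:
    if cfg.cost_matrix_path is not None:
        cost = read_cost_matrix(cfg.cost_matrix_path, dataset.entity_ids)
    else:
        cost = build_cost_matrix(dataset, metric=cfg.metric)
    geo = GeoPriorSpec(
        type=cfg.geo_type,
        rate=cfg.geo_rate,
        linkage=cfg.geo_linkage,
        cost_matrix=cost,
        locations=dataset.locations,
    )
    m_max = cfg.m_max if cfg.m_max is not None else max(3, min(50, dataset.n_entities - 1))
    size = SizePriorSpec(m_min=cfg.m_min, m_max=int(m_max))
    dirichlet = DirichletSpec.uniform(dataset)
    if cfg.alpha_empirical_counts is not None:
        counts = read_empirical_counts(cfg.alpha_empirical_counts, dataset)
        psi, _ = empirical_prior_from_sample(
            counts, cfg.alpha_empirical_rho, [f.name for f in dataset.features]
        )
        for f, feat in enumerate(dataset.features):
            if feat.name in psi:
                dirichlet.alpha[f] = psi[feat.name]
    if cfg.weights_pseudocounts is not None:
        wpsi = np.asarray([float(p) for p in cfg.weights_pseudocounts])
        for f in range(dataset.n_features):
            dirichlet.weights[f] = wpsi.copy()
    return PriorSpec(dirichlet=dirichlet, geo=geo, size=size)


def build_sampler_config(cfg: RunConfig, seed: int | None = None) -> SamplerConfig:
    return SamplerConfig(
        n_steps=cfg.n_steps,
        burn_in=cfg.burn_in,
        n_retained=cfg.n_retained,
        operator_weights=dict(cfg.operator_weights),
        kappa=cfg.kappa,
        g=cfg.g,
        warmup_chains=cfg.warmup_chains,
        warmup_steps=cfg.warmup_steps,
        seed=cfg.seed if seed is None else seed,
    )


def write_manifest(out_dir: Path, cfg: RunConfig, extra: dict | None = None) -> None:
    """Record everything needed to reproduce the run bit-identically."""
    import scipy

    from . import __version__

    manifest = {
        "config": cfg.raw,
        "seed": cfg.seed,
        "versions": {
            "areabayes": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
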