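"""Model selection and posterior summaries.

Covers the DIC scan over the number of areas K, label matching across
posterior samples (area slots are exchangeable, so labels may switch along
the chain), per-entity membership frequencies, area ranking, Gabriel-graph
edge frequencies and a basic effective-sample-size diagnostic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import Dataset
from .likelihood import ModelParameters, AreaConfiguration, cell_log_matrix
from .priors import PriorSpec
from .sampler import SamplerConfig, Trace, run_chain

__all__ = [
    "DicScanResult",
    "AreaSummary",
    "dic",
    "scan_k",
    "match_area_labels",
    "membership_frequencies",
    "gabriel_graph",
    "ess",
    "rank_areas",
    "summarize",
]


def dic(trace: Trace | np.ndarray) -> tuple[float, float, float]:
    """Deviance information criterion from a posterior deviance sample.

    ``D_bar`` is the posterior mean deviance, the effective number of
    parameters is estimated as half the posterior deviance variance
    (p_D = var(D)/2; the classical D_bar − D(theta_bar) variant is
    unavailable because the posterior mean of the discrete area assignment
    is undefined), and ``DIC = D_bar + p_D``.
    """
    dev = trace.deviance if isinstance(trace, Trace) else np.asarray(trace, dtype=float)
    if dev.size < 2:
        raise ValueError("DIC needs at least two posterior samples")
    d_bar = float(dev.mean())
    p_d = float(dev.var(ddof=1) / 2.0)
    return d_bar, p_d, d_bar + p_d


@dataclass
class DicScanResult:
    """DIC table over candidate numbers of areas."""

    k_list: list[int]
    d_bar: list[float]
    p_d: list[float]
    dic: list[float]
    selected_k: int
    levelled: bool
    traces: dict[int, Trace] = field(default_factory=dict)

    def as_table(self) -> list[dict[str, float]]:
        return [
            {"K": k, "D_bar": d, "p_D": p, "DIC": c}
            for k, d, p, c in zip(self.k_list, self.d_bar, self.p_d, self.dic)
        ]


def select_k(k_list: list[int], dics: list[float], tau: float = 0.02) -> tuple[int, bool]:
    """Smallest K where the DIC levels off.

    K is selected at the first index where DIC(next) >= DIC(K) − tau*|DIC(K)|,
    i.e. where adding an area no longer buys a relative improvement of at
    least ``tau``. If the curve keeps dropping through the whole list, the
    largest K is returned with ``levelled=False``.
    """
    for i in range(len(k_list) - 1):
        if dics[i + 1] >= dics[i] - tau * abs(dics[i]):
            return k_list[i], True
    return k_list[-1], len(k_list) == 1


def scan_k(
    dataset: Dataset,
    priors: PriorSpec,
    config: SamplerConfig,
    k_list: list[int],
    tau: float = 0.02,
) -> DicScanResult:
    """Run one chain per K and select K where the DIC levels off.

    Each run derives its seed as ``config.seed + K`` so runs are independent
    but the whole scan is reproducible.
    """
    if not k_list or any(b <= a for a, b in zip(k_list, k_list[1:])):
        raise ValueError("k_list must be non-empty and strictly ascending")
    rows_d, rows_p, rows_c = [], [], []
    traces = {}
    from dataclasses import replace

    for k in k_list:
        cfg = replace(
            config, operator_weights=dict(config.operator_weights), seed=config.seed + k
        )
        trace = run_chain(dataset, priors, k, cfg)
        d_bar, p_d, d_val = dic(trace)
        rows_d.append(d_bar)
        rows_p.append(p_d)
        rows_c.append(d_val)
        traces[k] = trace
    selected, levelled = select_k(k_list, rows_c, tau)
    if not levelled and len(k_list) > 1:
        warnings.warn(
            f"DIC still decreasing at K={k_list[-1]}; consider extending the scan",
            stacklevel=2,
        )
    return DicScanResult(
        k_list=list(k_list),
        d_bar=rows_d,
        p_d=rows_p,
        dic=rows_c,
        selected_k=selected,
        levelled=levelled,
        traces=traces,
    )


def _jaccard(a: set[int], b: set[int]) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def match_area_labels(trace: Trace) -> Trace:
    """Undo label switching: permute each sample's area labels for coherence.

    Greedy maximum-Jaccard matching of each sample's areas against a running
    reference (the previous matched sample, initialized from the first
    retained sample). Only labels are permuted; memberships are unchanged.
    """
    if trace.k <= 1:
        return trace
    n, k = trace.n_samples, trace.k
    new_assignment = trace.assignment.copy()
    new_gamma = trace.gamma.copy()
    ref = [set(np.flatnonzero(trace.assignment[0] == kk).tolist()) for kk in range(k)]
    if all(not r for r in ref):
        warnings.warn("all areas empty in the first sample; labels left as-is", stacklevel=2)
        return trace
    for i in range(1, n):
        cur = [set(np.flatnonzero(trace.assignment[i] == kk).tolist()) for kk in range(k)]
        scores = np.array([[_jaccard(c, r) for r in ref] for c in cur])
        perm = np.full(k, -1)
        used_cur, used_ref = set(), set()
        flat = np.dstack(np.unravel_index(np.argsort(-scores, axis=None), scores.shape))[0]
        for c_idx, r_idx in flat:
            if c_idx in used_cur or r_idx in used_ref:
                continue
            perm[c_idx] = r_idx
            used_cur.add(int(c_idx))
            used_ref.add(int(r_idx))
            if len(used_cur) == k:
                break
        remap = np.concatenate(([-1], perm))  # old label -> new label, -1 fixed
        new_assignment[i] = remap[trace.assignment[i] + 1]
        new_gamma[i] = trace.gamma[i][np.argsort(perm)]
        ref = [set(np.flatnonzero(new_assignment[i] == kk).tolist()) for kk in range(k)]
    return Trace(
        log_likelihood=trace.log_likelihood,
        log_prior=trace.log_prior,
        weights=trace.weights,
        alpha=trace.alpha,
        beta=trace.beta,
        gamma=new_gamma,
        assignment=new_assignment,
        k=trace.k,
        seed=trace.seed,
        acceptance=trace.acceptance,
    )


def membership_frequencies(trace: Trace) -> np.ndarray:
    """Posterior membership frequency, shape (K, L).

    ``freq[k, l]`` is the fraction of retained samples in which entity ``l``
    belongs to area slot ``k``. Columns need not sum to one: an entity may
    be in no area.
    """
    n = trace.n_samples
    L = trace.assignment.shape[1]
    freq = np.zeros((trace.k, L))
    for k in range(trace.k):
        freq[k] = (trace.assignment == k).mean(axis=0)
    return freq


def gabriel_graph(locations: np.ndarray) -> list[tuple[int, int]]:
    """Gabriel graph edges over planar points.

    Edge (a, b) is present iff no third point lies inside or on the circle
    with diameter ab: d²(a,b) < d²(a,c) + d²(b,c) for every other c (strict,
    so cocircular degeneracies drop the edge). Duplicate coordinates act as
    a point at distance zero and suppress all edges of their twins; a
    warning is emitted.
    """
    pts = np.asarray(locations, dtype=float)
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 points")
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    off_diag = d2 + np.where(np.eye(n, dtype=bool), np.inf, 0.0)
    if (off_diag == 0).any():
        warnings.warn("duplicate coordinates suppress Gabriel edges of their twins", stacklevel=2)
    edges = []
    for a in range(n):
        for b in range(a + 1, n):
            others = np.delete(np.arange(n), [a, b])
            if len(others) == 0 or (d2[a, b] < d2[a, others] + d2[b, others]).all():
                edges.append((a, b))
    return edges


def ess(chain: np.ndarray) -> float:
    """Effective sample size of a scalar chain.

    ``n / (1 + 2 * sum(rho_t))`` with the autocorrelation sum truncated at
    the first non-positive adjacent pair (initial-positive-sequence rule).
    A constant chain is reported as ESS = n with a warning. Antithetic
    chains can legitimately report ESS > n.
    """
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("chain too short")
    v = x.var()
    if v == 0:
        warnings.warn("degenerate (constant) chain; reporting ESS = n", stacklevel=2)
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (v * n)
    s = 0.0
    t = 1
    while t + 1 < n:
        pair = acf[t] + acf[t + 1]
        if pair <= 0:
            break
        s += pair
        t += 2
    return float(n / (1.0 + 2.0 * s))


def rank_areas(trace: Trace, dataset: Dataset) -> list[int]:
    """Rank area slots by mean posterior contribution (descending).

    The contribution of slot k in a sample is the summed log cell
    probability over the slot's members — how much of the data the area's
    contact component accounts for. Ties break on mean size.
    """
    n, k = trace.n_samples, trace.k
    contrib = np.zeros(k)
    sizes = np.zeros(k)
    for i in range(n):
        params = ModelParameters(
            weights=trace.weights[i],
            alpha=trace.alpha[i],
            beta=trace.beta[i],
            gamma=trace.gamma[i],
            areas=AreaConfiguration.from_assignment(trace.assignment[i], k),
        )
        for kk in range(k):
            rows = np.flatnonzero(trace.assignment[i] == kk)
            sizes[kk] += len(rows) / n
            if len(rows) == 0:
                continue
            logs = cell_log_matrix(
                dataset.data, dataset.family_index, params.areas.assignment, params,
                rows=rows, cols=np.arange(dataset.n_features),
            )
            contrib[kk] += float(logs.sum()) / n
    order = np.lexsort((-sizes, -contrib))
    return [int(o) for o in order]


@dataclass
class AreaSummary:
    """Posterior summary of one area slot."""

    rank: int
    membership_frequency: dict[str, float]
    mean_size: float
    mean_gamma: np.ndarray  # (F, S)
    mean_weights: np.ndarray  # (F, 3)
    gabriel_edges: list[tuple[str, str, float]]  # (id_a, id_b, posterior edge freq)


def summarize(
    trace: Trace, dataset: Dataset, membership_threshold: float = 0.5
) -> list[AreaSummary]:
    """Per-area posterior summaries from a label-matched trace.

    Gabriel edges connect the consensus members (posterior membership
    frequency above ``membership_threshold``); the edge attribute is the
    fraction of samples in which both endpoints sit in the slot together.
    """
    matched = match_area_labels(trace)
    freq = membership_frequencies(matched)
    ranks = rank_areas(matched, dataset)
    ids = dataset.entity_ids
    out = []
    for position, k in enumerate(ranks):
        members = np.flatnonzero(freq[k] > membership_threshold)
        edges: list[tuple[str, str, float]] = []
        if len(members) >= 2:
            for a, b in gabriel_graph(dataset.locations[members]):
                ia, ib = int(members[a]), int(members[b])
                together = float(
                    ((matched.assignment[:, ia] == k) & (matched.assignment[:, ib] == k)).mean()
                )
                edges.append((ids[ia], ids[ib], together))
        out.append(
            AreaSummary(
                rank=position + 1,
                membership_frequency={ids[l]: float(freq[k, l]) for l in range(len(ids))},
                mean_size=float((matched.assignment == k).sum(axis=1).mean()),
                mean_gamma=matched.gamma[:, k].mean(axis=0),
                mean_weights=matched.weights.mean(axis=0),
                gabriel_edges=edges,
            )
        )
    return out


def write_summary_json(
    path,
    scan: DicScanResult | None = None,
    summaries: list[AreaSummary] | None = None,
    extra: dict | None = None,
) -> None:
    """JSON summary output (DIC table, selected K, per-area summaries)."""
    doc: dict = {}
    if scan is not None:
        doc["dic_table"] = scan.as_table()
        doc["selected_k"] = scan.selected_k
        doc["levelled"] = scan.levelled
    if summaries is not None:
        doc["areas"] = [
            {
                "rank": s.rank,
                "mean_size": s.mean_size,
                "membership_frequency": s.membership_frequency,
                "gabriel_edges": [
                    {"a": a, "b": b, "frequency": f} for a, b, f in s.gabriel_edges
                ],
                "ranking_statistic": "mean member log-likelihood share (substitute; "
                "see methods note)",
            }
            for s in summaries
        ]
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def write_gabriel_geojson(path, dataset: Dataset, summary: AreaSummary) -> None:
    """GeoJSON LineString features of one area's Gabriel edges."""
    idx = {e: i for i, e in enumerate(dataset.entity_ids)}
    features = []
    for a, b, f in summary.gabriel_edges:
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [
                        list(map(float, dataset.locations[idx[a]])),
                        list(map(float, dataset.locations[idx[b]])),
                    ],
                },
                "properties": {"a": a, "b": b, "frequency": f},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
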