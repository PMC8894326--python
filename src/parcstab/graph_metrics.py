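"""Registry of the 27 graph-theoretical measures.

Measures span eight classes — centrality, clustering, core, degree, distance,
modularity, physical connectivity, similarity — and are *local* (one value per
node) or *global* (one scalar per network).  Most are weighted; three
centralities with no weighted counterpart (subgraph centrality, flow
coefficient, k-coreness) are computed on the binary adjacency matrix at the
same threshold.

Conventions (the field has no single standard; these are documented choices):

* Weighted path length of an edge is the reciprocal of its weight (strong
  correlations = short distances); all distance-based measures (characteristic
  path length, closeness, global/local efficiency, weighted betweenness) use
  this mapping.
* Disconnected graphs: characteristic path length and closeness average over
  reachable pairs only; global efficiency handles disconnection naturally via
  1/d = 0.
* Katz centrality uses attenuation ``alpha = 0.9 / lambda_max`` with ``beta=1``
  (convergence guaranteed); Bonacich power centrality uses exponent
  ``beta = 0.5 / lambda_max``.  Both attenuations are recorded in the result.
* Louvain-family modularity measures are stochastic; they take an explicit
  seed and return the modularity Q of the final partition.
* Measures that are undefined on a degenerate input (e.g. path length of an
  edgeless graph) raise :class:`UndefinedMetricError` rather than returning a
  silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import dijkstra
from scipy.sparse import csr_matrix

from .connectome import AdjacencyMatrix

__all__ = [
    "MetricSpec",
    "MetricResult",
    "UndefinedMetricError",
    "REGISTRY",
    "list_metrics",
    "compute_metric",
    "compute_all",
    "shortest_path_oracle",
    "GLOBAL_MEASURES",
    "BINARY_MEASURES",
]


class UndefinedMetricError(ValueError):
    """The measure is mathematically undefined on this graph."""


@dataclass(frozen=True)
class MetricSpec:
    name: str
    level: str            # 'local' | 'global'
    matrix_domain: str    # 'weighted' | 'binary'
    metric_class: str
    func: Callable = field(repr=False)
    stochastic: bool = False


@dataclass
class MetricResult:
    name: str
    level: str
    value: float | np.ndarray
    params: dict = field(default_factory=dict)
    seed: int | None = None


# ---------------------------------------------------------------- helpers

def _matrix(a: AdjacencyMatrix | np.ndarray) -> np.ndarray:
    w = a.values if isinstance(a, AdjacencyMatrix) else np.asarray(a, float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("adjacency must be square")
    return w


def _graph(w: np.ndarray, with_length: bool = False) -> nx.Graph:
    g = nx.from_numpy_array(w)
    if with_length:
        for _, _, d in g.edges(data=True):
            d["length"] = 1.0 / d["weight"]
    return g


def _distance_matrix(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances with edge length 1/weight."""
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    return dijkstra(csr_matrix(lengths), directed=False)


def _require_edges(w: np.ndarray, name: str) -> None:
    if not (w != 0).any():
        raise UndefinedMetricError(f"{name} is undefined on an edgeless graph")


def _lambda_max(w: np.ndarray) -> float:
    lam = float(np.max(np.abs(np.linalg.eigvalsh(w))))
    if lam == 0:
        raise UndefinedMetricError("spectral radius is zero (edgeless graph)")
    return lam


def _as_vector(d: dict, n: int) -> np.ndarray:
    return np.array([d[i] for i in range(n)], dtype=float)


def _seed_int(rng: np.random.Generator | None) -> int:
    rng = rng if rng is not None else np.random.default_rng(0)
    return int(rng.integers(2**31))


# ---------------------------------------------------------------- centrality

def _bonacich(w, params, rng):
    """Bonacich power centrality c = alpha * (I - beta*W)^-1 W 1, ||c||^2 = n."""
    _require_edges(w, "bonacich centrality")
    n = len(w)
    beta = params.get("beta", 0.5 / _lambda_max(w))
    c = np.linalg.solve(np.eye(n) - beta * w, w @ np.ones(n))
    norm = float(c @ c)
    if norm > 0:
        c = c * np.sqrt(n / norm)
    return c, {"beta": beta}


def _betweenness(w, params, rng):
    g = _graph(w, with_length=True)
    return _as_vector(nx.betweenness_centrality(g, weight="length", normalized=True),
                      len(w)), {}


def _eigenvector(w, params, rng):
    """Principal eigenvector of W, sign-fixed non-negative, unit L2 norm.

    Computed directly from the symmetric adjacency so disconnected graphs are
    handled (mass concentrates on the dominant component).
    """
    _require_edges(w, "eigenvector centrality")
    vals, vecs = np.linalg.eigh(w)
    v = vecs[:, np.argmax(vals)]
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return np.maximum(v, 0.0) / np.linalg.norm(v), {}


def _shortcuts(w, params, rng):
    """Fraction of a node's edges that are shortcuts (edge range > 2).

    The range of an edge (u, v) is the shortest-path hop distance between u
    and v once the edge is removed; a range above 2 means the edge is not
    backed up by any common neighbour.
    """
    g = _graph(w)
    n = len(w)
    shortcut_count = np.zeros(n)
    degree = np.zeros(n)
    for u, v in list(g.edges()):
        degree[u] += 1
        degree[v] += 1
        # range > 2 iff u and v share no neighbour
        if not (set(g[u]) & set(g[v])) - {u, v}:
            shortcut_count[u] += 1
            shortcut_count[v] += 1
    with np.errstate(invalid="ignore"):
        frac = np.where(degree > 0, shortcut_count / np.maximum(degree, 1), 0.0)
    return frac, {}


def _pagerank(w, params, rng):
    alpha = params.get("alpha", 0.85)
    g = _graph(w)
    return _as_vector(nx.pagerank(g, alpha=alpha, weight="weight"), len(w)), {"alpha": alpha}


def _closeness(w, params, rng):
    """Closeness over reachable pairs only: (n_reach - 1) / sum of distances."""
    d = _distance_matrix(w)
    n = len(w)
    out = np.zeros(n)
    for i in range(n):
        finite = np.isfinite(d[i]) & (np.arange(n) != i)
        if finite.any():
            out[i] = finite.sum() / d[i, finite].sum()
    return out, {}


def _katz(w, params, rng):
    _require_edges(w, "katz centrality")
    alpha = params.get("alpha", 0.9 / _lambda_max(w))
    beta = params.get("beta", 1.0)
    g = _graph(w)
    vec = nx.katz_centrality_numpy(g, alpha=alpha, beta=beta, weight="weight")
    return _as_vector(vec, len(w)), {"alpha": alpha, "beta": beta}


def _communicability_betweenness(w, params, rng):
    _require_edges(w, "communicability betweenness")
    g = _graph(w)
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        vec = _as_vector(nx.communicability_betweenness_centrality(g), len(w))
    # isolated nodes mediate no walks; networkx leaves them as 0/0
    return np.nan_to_num(vec, nan=0.0), {}


def _subgraph_centrality(w, params, rng):
    _require_edges(w, "subgraph centrality")
    g = _graph(w)
    return _as_vector(nx.subgraph_centrality(g), len(w)), {}


def _flow_coefficient(w, params, rng):
    """Fraction of a node's neighbour pairs not directly connected.

    Paths of length two through the node that are not short-circuited by a
    direct edge; complementary to the local clustering coefficient.
    """
    a = (w != 0).astype(float)
    n = len(a)
    out = np.zeros(n)
    for v in range(n):
        nb = np.flatnonzero(a[v])
        k = len(nb)
        if k >= 2:
            sub = a[np.ix_(nb, nb)]
            connected_pairs = sub.sum() / 2.0
            out[v] = 1.0 - connected_pairs / (k * (k - 1) / 2.0)
    return out, {}


def _kcoreness(w, params, rng):
    g = _graph((w != 0).astype(float))
    g.remove_edges_from(nx.selfloop_edges(g))
    return _as_vector(nx.core_number(g), len(w)), {}


# ---------------------------------------------------------------- clustering

def _get_components(w, params, rng):
    """Size of the connected component containing each node."""
    g = _graph(w)
    out = np.zeros(len(w))
    for comp in nx.connected_components(g):
        for v in comp:
            out[v] = len(comp)
    return out, {}


def _clustering_coefficient(w, params, rng):
    g = _graph(w)
    return _as_vector(nx.clustering(g, weight="weight"), len(w)), {}


def _transitivity(w, params, rng):
    """Weighted transitivity: geometric-mean triangle intensity over connected triples."""
    a = (w != 0).astype(float)
    k = a.sum(axis=1)
    denom = (k * (k - 1)).sum()
    if denom == 0:
        raise UndefinedMetricError("transitivity is undefined without connected triples")
    wmax = w.max()
    wn = w / wmax if wmax > 0 else w
    cube = np.linalg.matrix_power(np.cbrt(wn), 3)
    return float(np.trace(cube) / denom), {}


# ---------------------------------------------------------------- core

def _assortativity(w, params, rng):
    _require_edges(w, "assortativity")
    g = _graph(w)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # regular graphs: constant degrees
        r = nx.degree_pearson_correlation_coefficient(g, weight="weight")
    if not np.isfinite(r):
        raise UndefinedMetricError("assortativity is undefined (degenerate degrees)")
    return float(r), {}


def _core_periphery(w, params, rng):
    """Discrete core/periphery assignment (1 = core) by seeded greedy search.

    Maximises the correlation between the adjacency and the ideal pattern in
    which every edge touches the core, starting from a random assignment and
    flipping single nodes until no flip improves the quality.
    """
    _require_edges(w, "core-periphery")
    n = len(w)
    rng = rng if rng is not None else np.random.default_rng(0)
    seed = int(rng.integers(2**31))
    local = np.random.default_rng(seed)
    core = local.integers(0, 2, size=n).astype(bool)
    triu = np.triu_indices(n, k=1)
    wv = w[triu]

    def quality(c):
        pattern = (c[triu[0]] | c[triu[1]]).astype(float)
        if pattern.std() == 0 or wv.std() == 0:
            return -np.inf
        return float(np.corrcoef(wv, pattern)[0, 1])

    q = quality(core)
    improved = True
    while improved:
        improved = False
        for v in local.permutation(n):
            core[v] = ~core[v]
            q_new = quality(core)
            if q_new > q:
                q = q_new
                improved = True
            else:
                core[v] = ~core[v]
    return core.astype(float), {"seed": seed}


# ---------------------------------------------------------------- degree

def _degree(w, params, rng):
    return (w != 0).sum(axis=1).astype(float), {}


def _strength(w, params, rng):
    return w.sum(axis=1), {}


# ---------------------------------------------------------------- distance

def _global_efficiency(w, params, rng):
    n = len(w)
    if n < 2:
        raise UndefinedMetricError("global efficiency needs >= 2 nodes")
    d = _distance_matrix(w)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1))), {}


def _local_efficiency(w, params, rng):
    n = len(w)
    out = np.zeros(n)
    for v in range(n):
        nb = np.flatnonzero(w[v])
        if len(nb) < 2:
            continue
        sub = w[np.ix_(nb, nb)]
        m = len(nb)
        d = _distance_matrix(sub)
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        np.fill_diagonal(inv, 0.0)
        inv[~np.isfinite(inv)] = 0.0
        out[v] = inv.sum() / (m * (m - 1))
    return out, {}


def _char_path_length(w, params, rng):
    """Mean shortest-path distance over reachable ordered pairs."""
    d = _distance_matrix(w)
    n = len(w)
    mask = np.isfinite(d) & ~np.eye(n, dtype=bool)
    if not mask.any():
        raise UndefinedMetricError("characteristic path length undefined: no reachable pairs")
    return float(d[mask].mean()), {}


# ---------------------------------------------------------------- modularity

def _louvain_q(g: nx.Graph, seed: int, threshold: float = 1e-7,
               single_level: bool = False) -> float:
    if g.number_of_edges() == 0:
        raise UndefinedMetricError("modularity is undefined on an edgeless graph")
    if single_level:
        parts = nx.community.louvain_partitions(g, weight="weight", seed=seed,
                                                threshold=threshold)
        partition = next(iter(parts))
    else:
        partition = nx.community.louvain_communities(g, weight="weight", seed=seed,
                                                     threshold=threshold)
    return float(nx.community.modularity(g, partition, weight="weight"))


def _modularity_louvain(w, params, rng):
    seed = _seed_int(rng)
    return _louvain_q(_graph(w), seed, single_level=True), {"seed": seed}


def _community_louvain(w, params, rng):
    seed = _seed_int(rng)
    return _louvain_q(_graph(w), seed, single_level=False), {"seed": seed}


def _modularity_finetune(w, params, rng):
    """Louvain partition refined by greedy single-node moves; returns Q."""
    seed = _seed_int(rng)
    g = _graph(w)
    if g.number_of_edges() == 0:
        raise UndefinedMetricError("modularity is undefined on an edgeless graph")
    comms = nx.community.louvain_communities(g, weight="weight", seed=seed)
    label = {}
    for c, nodes in enumerate(comms):
        for v in nodes:
            label[v] = c
    q = nx.community.modularity(g, comms, weight="weight")
    local = np.random.default_rng(seed)
    improved = True
    while improved:
        improved = False
        for v in local.permutation(len(w)):
            v = int(v)
            current = label[v]
            neighbour_comms = {label[u] for u in g[v]} - {current}
            for cand in sorted(neighbour_comms):
                label[v] = cand
                groups: dict[int, set] = {}
                for node, c in label.items():
                    groups.setdefault(c, set()).add(node)
                q_new = nx.community.modularity(g, groups.values(), weight="weight")
                if q_new > q + 1e-12:
                    q = q_new
                    current = cand
                    improved = True
                else:
                    label[v] = current
    return float(q), {"seed": seed}


# ------------------------------------------------- physical connectivity

def _density(w, params, rng):
    n = len(w)
    if n < 2:
        raise UndefinedMetricError("density needs >= 2 nodes")
    edges = np.count_nonzero(np.triu(w, k=1))
    return float(2.0 * edges / (n * (n - 1))), {}


# ---------------------------------------------------------------- similarity

def _topological_overlap(w, params, rng):
    """Mean weighted topological overlap of each node with all others.

    TO_ij = (sum_k w_ik w_jk + w_ij) / (min(s_i, s_j) + 1 - w_ij), with
    weights normalised to [0, 1]; high overlap = shared neighbourhoods.
    """
    _require_edges(w, "topological overlap")
    wmax = w.max()
    wn = w / wmax if wmax > 0 else w
    s = wn.sum(axis=1)
    num = wn @ wn + wn
    n = len(w)
    denom = np.minimum.outer(s, s) + 1.0 - wn
    with np.errstate(divide="ignore", invalid="ignore"):
        to = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(to, 0.0)
    return to.sum(axis=1) / (n - 1), {}


def _matching_index(w, params, rng):
    """Mean matching index: shared neighbours relative to total neighbours.

    M_ij = 2 * |N(i) ∩ N(j) \\ {i,j}| / (|N(i) \\ {j}| + |N(j) \\ {i}|),
    computed on the binary connection pattern.
    """
    a = (w != 0).astype(float)
    n = len(a)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ni = set(np.flatnonzero(a[i])) - {j}
            nj = set(np.flatnonzero(a[j])) - {i}
            denom = len(ni) + len(nj)
            if denom > 0:
                out[i, j] = out[j, i] = 2.0 * len(ni & nj) / denom
    return out.sum(axis=1) / (n - 1), {}


# ---------------------------------------------------------------- registry

GLOBAL_MEASURES = frozenset({
    "assortativity", "characteristic path length", "community louvain",
    "density", "global efficiency", "modularity louvain",
    "modularity finetune", "transitivity",
})

BINARY_MEASURES = frozenset({
    "subgraph centrality", "flow coefficient", "k-coreness centrality",
})


def _spec(name, metric_class, func, stochastic=False):
    return MetricSpec(
        name=name,
        level="global" if name in GLOBAL_MEASURES else "local",
        matrix_domain="binary" if name in BINARY_MEASURES else "weighted",
        metric_class=metric_class, func=func, stochastic=stochastic)


REGISTRY: dict[str, MetricSpec] = {s.name: s for s in [
    # centrality (weighted)
    _spec("bonacich centrality", "centrality", _bonacich),
    _spec("betweenness centrality", "centrality", _betweenness),
    _spec("eigenvector centrality", "centrality", _eigenvector),
    _spec("shortcuts centrality", "centrality", _shortcuts),
    _spec("pagerank centrality", "centrality", _pagerank),
    _spec("closeness centrality", "centrality", _closeness),
    _spec("katz centrality", "centrality", _katz),
    _spec("communicability betweenness centrality", "centrality",
          _communicability_betweenness),
    # centrality (binary only)
    _spec("subgraph centrality", "centrality", _subgraph_centrality),
    _spec("flow coefficient", "centrality", _flow_coefficient),
    _spec("k-coreness centrality", "centrality", _kcoreness),
    # clustering
    _spec("get components", "clustering", _get_components),
    _spec("clustering coefficient", "clustering", _clustering_coefficient),
    _spec("transitivity", "clustering", _transitivity),
    # core
    _spec("assortativity", "core", _assortativity),
    _spec("core periphery", "core", _core_periphery, stochastic=True),
    # degree
    _spec("degree", "degree", _degree),
    _spec("strength", "degree", _strength),
    # distance
    _spec("global efficiency", "distance", _global_efficiency),
    _spec("local efficiency", "distance", _local_efficiency),
    _spec("characteristic path length", "distance", _char_path_length),
    # modularity
    _spec("modularity finetune", "modularity", _modularity_finetune, stochastic=True),
    _spec("modularity louvain", "modularity", _modularity_louvain, stochastic=True),
    _spec("community louvain", "modularity", _community_louvain, stochastic=True),
    # physical connectivity
    _spec("density", "physical-connectivity", _density),
    # similarity
    _spec("topological overlap", "similarity", _topological_overlap),
    _spec("matching index", "similarity", _matching_index),
]}


def list_metrics() -> dict[str, MetricSpec]:
    """The full registry: 27 measures, keyed by name."""
    return dict(REGISTRY)


def compute_metric(name: str, a: AdjacencyMatrix | np.ndarray,
                   params: dict | None = None,
                   rng: np.random.Generator | None = None) -> MetricResult:
    """Compute one measure on an adjacency matrix.

    Binary-only measures must receive the binary matrix; weighted measures
    accept either (on a binary matrix the weighted definitions reduce to the
    binary ones).
    """
    if name not in REGISTRY:
        raise KeyError(f"unknown measure {name!r}")
    spec = REGISTRY[name]
    if isinstance(a, AdjacencyMatrix) and spec.matrix_domain == "binary" \
            and a.mode != "binary":
        raise ValueError(f"{name} requires a binary adjacency matrix")
    w = _matrix(a)
    value, used = spec.func(w, params or {}, rng)
    if not np.isfinite(np.atleast_1d(np.asarray(value, float))).all():
        raise UndefinedMetricError(f"{name} produced non-finite values")
    seed = used.pop("seed", None)
    return MetricResult(name=name, level=spec.level, value=value,
                        params=used, seed=seed)


def compute_all(a_weighted: AdjacencyMatrix, a_binary: AdjacencyMatrix,
                params: dict[str, dict] | None = None,
                rng: np.random.Generator | None = None
                ) -> tuple[dict[str, MetricResult], dict[str, Exception]]:
    """All 27 measures, routed by matrix domain; per-measure errors collected."""
    if a_weighted.threshold != a_binary.threshold:
        raise ValueError("weighted and binary matrices must share the threshold")
    params = params or {}
    # one independent child seed per measure so ordering never matters
    ss = np.random.SeedSequence(_seed_int(rng))
    children = ss.spawn(len(REGISTRY))
    results: dict[str, MetricResult] = {}
    errors: dict[str, Exception] = {}
    for child, (name, spec) in zip(children, REGISTRY.items()):
        a = a_binary if spec.matrix_domain == "binary" else a_weighted
        try:
            results[name] = compute_metric(
                name, a, params.get(name), np.random.default_rng(child))
        except (UndefinedMetricError, ValueError, nx.NetworkXError) as err:
            errors[name] = err
    return results, errors


def shortest_path_oracle(a: AdjacencyMatrix | np.ndarray, source: int) -> np.ndarray:
    """Independent single-source distances (edge length = 1/weight) for validation.

    Uses networkx Dijkstra, a separate route from the scipy-based distance
    machinery behind the distance measures; intended for small-graph checks.
    """
    w = _matrix(a)
    if (w < 0).any():
        raise ValueError("negative weights are not supported")
    g = _graph(w, with_length=True)
    dist = nx.single_source_dijkstra_path_length(g, source, weight="length")
    out = np.full(len(w), np.inf)
    for node, d in dist.items():
        out[node] = d
    return out
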