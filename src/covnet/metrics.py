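"""Graph parameters of binary undirected networks.

Global: clustering coefficient (Cp), characteristic path length (Lp),
global/local efficiency, transitivity, Newman modularity (Q), and the
small-world indices gamma = Cp/Cp_rand, lambda = Lp/Lp_rand, sigma =
gamma/lambda, where the rand terms are means over an ensemble of
degree-matched (edge-swap randomized) networks.

Nodal: degree, clustering coefficient, betweenness centrality, each also
divided by its network-wide mean ("normalized").  Hubs are nodes whose
betweenness exceeds the network mean by at least 1.5 population SDs.

Conventions (shared with the standard connectome toolboxes): nodes with
degree < 2 score 0 for nodal clustering and local efficiency; Lp averages
over connected pairs only, so permuted or randomized networks that
fragment still get a finite value; betweenness splits credit fractionally
among equal-length shortest paths.
"""
from __future__ import annotations

import logging
import random as _pyrandom
import warnings
from dataclasses import dataclass

from functools import lru_cache

import igraph as ig
import numpy as np


@lru_cache(maxsize=8)
def _triu(n: int):
    return np.triu_indices(n, 1)

__all__ = [
    "nodal_clustering",
    "clustering_coefficient",
    "distance_matrix",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "transitivity",
    "modularity",
    "betweenness",
    "degrees",
    "is_connected",
    "match_random_ensemble",
    "small_world",
    "detect_hubs",
    "nodal_metrics",
    "global_metrics",
    "GLOBAL_METRICS",
    "NODAL_METRICS",
    "RandomEnsemble",
    "SmallWorld",
    "HubSet",
]

logger = logging.getLogger(__name__)

GLOBAL_METRICS = (
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "transitivity",
    "modularity",
    "gamma",
    "lambda",
    "sigma",
)
SMALL_WORLD_METRICS = ("gamma", "lambda", "sigma")
NODAL_METRICS = ("degree", "clustering", "betweenness")


def _adj(net) -> np.ndarray:
    """Accept a BinaryNetwork or a plain 0/1 adjacency array."""
    a = getattr(net, "adjacency", net)
    return np.asarray(a)


def degrees(net) -> np.ndarray:
    return _adj(net).sum(axis=1).astype(np.int64)


def nodal_clustering(net) -> np.ndarray:
    """Fraction of each node's neighbor pairs that are connected.

    Nodes with fewer than two neighbors contribute 0.
    """
    a = _adj(net).astype(np.float64)
    k = a.sum(axis=1)
    tri2 = ((a @ a) * a).sum(axis=1)  # 2x triangles through each node
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri2 / denom, 0.0)
    return c


def clustering_coefficient(net) -> float:
    """Network clustering coefficient: unweighted mean over all nodes."""
    return float(nodal_clustering(net).mean())


def distance_matrix(net) -> np.ndarray:
    """All-pairs shortest-path edge counts; inf for disconnected pairs.

    BFS by repeated boolean matrix products — fastest option at the 68-node
    scale this package works at.
    """
    a = _adj(net).astype(bool)
    n = a.shape[0]
    d = np.where(a, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    reached = a | np.eye(n, dtype=bool)
    frontier = a.astype(np.float64)
    length = 1
    while True:
        length += 1
        frontier = (frontier @ a) > 0
        new = frontier & ~reached
        if not new.any():
            return d
        d[new] = length
        reached |= new
        frontier = frontier.astype(np.float64)


def characteristic_path_length(net) -> float:
    """Mean shortest path length over connected, distinct node pairs."""
    a = _adj(net)
    if a.sum() == 0:
        raise ValueError("characteristic path length undefined: graph has no edges")
    d = distance_matrix(a)
    iu = _triu(a.shape[0])
    vals = d[iu]
    finite = vals[np.isfinite(vals)]
    return float(finite.mean())


def is_connected(net) -> bool:
    a = _adj(net)
    if a.shape[0] == 1:
        return True
    return bool(np.isfinite(distance_matrix(a)).all())


def global_efficiency(net) -> float:
    """Mean inverse shortest path length over distinct pairs (0 if disconnected)."""
    a = _adj(net)
    n = a.shape[0]
    if n < 2:
        return 0.0
    d = distance_matrix(a)
    iu = _triu(n)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[iu]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def nodal_local_efficiency(net) -> np.ndarray:
    """Global efficiency of each node's neighbor-induced subgraph."""
    a = _adj(net)
    n = a.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nb = np.nonzero(a[v])[0]
        if nb.size < 2:
            continue
        out[v] = global_efficiency(a[np.ix_(nb, nb)])
    return out


def local_efficiency(net) -> float:
    return float(nodal_local_efficiency(net).mean())


def transitivity(net) -> float:
    """3 x triangles / connected triples, normalized at whole-network level."""
    a = _adj(net).astype(np.float64)
    k = a.sum(axis=1)
    triples2 = (k * (k - 1)).sum()  # 2x number of connected triples
    if triples2 == 0:
        warnings.warn("transitivity undefined (no connected triples); reporting 0")
        return 0.0
    tri6 = ((a @ a) * a).sum()  # 6x number of triangles
    return float(tri6 / triples2)


def _igraph(a: np.ndarray) -> ig.Graph:
    i, j = np.nonzero(np.triu(a, 1))
    return ig.Graph(a.shape[0], np.column_stack([i, j]))


def modularity(net, seed: int = 0, restarts: int = 1) -> tuple[float, np.ndarray]:
    """Newman modularity Q of the best partition found by seeded Leiden runs.

    Returns (Q, membership).  The reported Q is the maximum over
    ``restarts`` independent seeded runs; identical seed gives identical
    output.
    """
    a = _adj(net)
    if a.sum() == 0:
        raise ValueError("modularity undefined: graph has no edges")
    g = _igraph(a)
    best_q, best_m = -np.inf, None
    for t in range(restarts):
        # igraph delegates randomness to Python's random module
        _pyrandom.seed((seed + t) % 2**31)
        comm = g.community_leiden(objective_function="modularity", n_iterations=2)
        q = g.modularity(comm.membership)
        if q > best_q:
            best_q, best_m = q, np.asarray(comm.membership)
    return float(best_q), best_m


def betweenness(net) -> np.ndarray:
    """Betweenness centrality with fractional credit among equal-length
    shortest paths; each unordered pair counted once."""
    a = _adj(net)
    return np.asarray(_igraph(a).betweenness(), dtype=float)


@dataclass
class RandomEnsemble:
    """Degree-matched randomized ensemble summaries for one network."""

    n_random: int
    rewires_per_edge: int
    seed: int
    cp_rand: np.ndarray  # clustering coefficient per member
    lp_rand: np.ndarray  # characteristic path length per member

    @property
    def mean_cp(self) -> float:
        return float(self.cp_rand.mean())

    @property
    def mean_lp(self) -> float:
        return float(self.lp_rand.mean())


def _edge_swap(
    a: np.ndarray, n_swaps: int, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Maslov-Sneppen degree-preserving rewiring.

    Attempts random double-edge swaps until ``n_swaps`` succeed or the
    attempt budget (20x) runs out; returns the rewired adjacency and the
    number of successful swaps.
    """
    a = a.copy()
    ea, eb = map(np.array, np.nonzero(np.triu(a, 1)))
    m = len(ea)
    if m < 2:
        return a, 0
    edge_set = {(int(x), int(y)) for x, y in zip(ea, eb)}
    successes = 0
    budget = 20 * n_swaps
    # draw randomness in bulk: (edge1, edge2, orientation) per attempt
    picks = rng.integers(0, m, size=(budget, 2))
    flips = rng.integers(0, 2, size=budget)
    for t in range(budget):
        if successes >= n_swaps:
            break
        i1, i2 = picks[t]
        if i1 == i2:
            continue
        x1, y1 = int(ea[i1]), int(eb[i1])
        x2, y2 = int(ea[i2]), int(eb[i2])
        if flips[t]:
            x2, y2 = y2, x2
        # propose (x1, y2) and (x2, y1)
        if x1 == y2 or x2 == y1:
            continue
        n1 = (min(x1, y2), max(x1, y2))
        n2 = (min(x2, y1), max(x2, y1))
        if n1 in edge_set or n2 in edge_set:
            continue
        edge_set.discard((min(x1, y1), max(x1, y1)))
        edge_set.discard((min(x2, y2), max(x2, y2)))
        edge_set.add(n1)
        edge_set.add(n2)
        a[x1, y1] = a[y1, x1] = 0
        a[x2, y2] = a[y2, x2] = 0
        a[n1[0], n1[1]] = a[n1[1], n1[0]] = 1
        a[n2[0], n2[1]] = a[n2[1], n2[0]] = 1
        ea[i1], eb[i1] = n1
        ea[i2], eb[i2] = n2
        successes += 1
    return a, successes


def match_random_ensemble(
    net, n_random: int = 100, rewires_per_edge: int = 10, seed: int = 0
) -> RandomEnsemble:
    """Ensemble of degree-matched randomized versions of ``net``.

    Every member has exactly the source network's degree sequence.  If no
    admissible swap is found within the budget for a member (rigid graphs
    such as K3), that member is the source network unchanged, with a
    warning.
    """
    a = _adj(net)
    m = int(a.sum()) // 2
    rng = np.random.default_rng(seed)
    cp = np.empty(n_random)
    lp = np.empty(n_random)
    for r in range(n_random):
        rewired, successes = _edge_swap(a, rewires_per_edge * m, rng)
        if successes == 0:
            warnings.warn(
                f"ensemble member {r}: no admissible edge swap found; "
                "member equals the source network"
            )
        cp[r] = clustering_coefficient(rewired)
        lp[r] = characteristic_path_length(rewired)
    return RandomEnsemble(n_random, rewires_per_edge, seed, cp, lp)


@dataclass
class SmallWorld:
    gamma: float
    lam: float
    sigma: float


def small_world(net, ensemble: RandomEnsemble) -> SmallWorld:
    """gamma = Cp/<Cp_rand>, lambda = Lp/<Lp_rand>, sigma = gamma/lambda."""
    if ensemble.mean_cp <= 0 or ensemble.mean_lp <= 0:
        raise ValueError(
            "small-world indices undefined: random ensemble has zero mean "
            f"Cp ({ensemble.mean_cp}) or Lp ({ensemble.mean_lp})"
        )
    gamma = clustering_coefficient(net) / ensemble.mean_cp
    lam = characteristic_path_length(net) / ensemble.mean_lp
    return SmallWorld(gamma, lam, gamma / lam)


@dataclass
class HubSet:
    """Regions whose betweenness is >= mean + n_sd x SD (population SD)."""

    regions: list[str]
    mean: float
    sd: float
    n_sd: float = 1.5


def detect_hubs(bc: np.ndarray, regions: list[str] | None = None, n_sd: float = 1.5) -> HubSet:
    """Hub set from a betweenness vector.

    Zero spread (SD = 0) yields no hubs: a hub must stand out from the
    network, not merely tie it.
    """
    bc = np.asarray(bc, dtype=float)
    if bc.size < 2:
        raise ValueError("hub detection needs at least 2 nodes")
    if regions is None:
        regions = [f"node_{i}" for i in range(bc.size)]
    mean, sd = float(bc.mean()), float(bc.std())
    if sd == 0:
        return HubSet([], mean, sd, n_sd)
    idx = np.nonzero(bc >= mean + n_sd * sd)[0]
    return HubSet([regions[i] for i in idx], mean, sd, n_sd)


def _normalize(v: np.ndarray) -> np.ndarray:
    m = v.mean()
    return v / m if m != 0 else np.zeros_like(v, dtype=float)


def nodal_metrics(net, which=NODAL_METRICS) -> dict[str, np.ndarray]:
    """Per-node degree / clustering / betweenness, raw and mean-normalized.

    Keys: ``<name>`` and ``<name>_normalized``.  The normalized vector has
    mean 1 whenever the raw network mean is nonzero.
    """
    a = _adj(net)
    out: dict[str, np.ndarray] = {}
    fns = {
        "degree": lambda: degrees(a).astype(float),
        "clustering": lambda: nodal_clustering(a),
        "betweenness": lambda: betweenness(a),
    }
    for name in which:
        if name not in fns:
            raise ValueError(f"unknown nodal metric {name!r}")
        v = fns[name]()
        out[name] = v
        out[f"{name}_normalized"] = _normalize(v)
    return out


def global_metrics(
    net,
    which=GLOBAL_METRICS,
    seed: int = 0,
    modularity_restarts: int = 1,
    n_random: int = 100,
    rewires_per_edge: int = 10,
    ensemble: RandomEnsemble | None = None,
) -> dict[str, float]:
    """Bundle of requested global metrics for one network.

    A shared distance matrix and (when gamma/lambda/sigma are requested) a
    single random ensemble back all dependent quantities.
    """
    a = _adj(net)
    out: dict[str, float] = {}
    need_sw = any(m in which for m in SMALL_WORLD_METRICS)
    if need_sw and ensemble is None:
        ensemble = match_random_ensemble(
            a, n_random=n_random, rewires_per_edge=rewires_per_edge, seed=seed
        )
    d = None
    if {"characteristic_path_length", "global_efficiency"} & set(which) or need_sw:
        d = distance_matrix(a)
        iu = _triu(a.shape[0])
        pair_d = d[iu]
    for name in which:
        if name == "clustering_coefficient":
            out[name] = clustering_coefficient(a)
        elif name == "characteristic_path_length":
            finite = pair_d[np.isfinite(pair_d)]
            if finite.size == 0:
                raise ValueError("graph has no edges")
            out[name] = float(finite.mean())
        elif name == "global_efficiency":
            with np.errstate(divide="ignore"):
                inv = 1.0 / pair_d
            inv[~np.isfinite(inv)] = 0.0
            out[name] = float(inv.mean())
        elif name == "local_efficiency":
            out[name] = local_efficiency(a)
        elif name == "transitivity":
            out[name] = transitivity(a)
        elif name == "modularity":
            out[name] = modularity(a, seed=seed, restarts=modularity_restarts)[0]
        elif name in SMALL_WORLD_METRICS:
            pass  # filled in below from the shared ensemble
        else:
            raise ValueError(f"unknown global metric {name!r}")
    if need_sw:
        cp = out.get("clustering_coefficient", clustering_coefficient(a))
        finite = pair_d[np.isfinite(pair_d)]
        lp = float(finite.mean())
        gamma = cp / ensemble.mean_cp
        lam = lp / ensemble.mean_lp
        vals = {"gamma": gamma, "lambda": lam, "sigma": gamma / lam}
        for name in which:
            if name in vals:
                out[name] = vals[name]
    return out
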