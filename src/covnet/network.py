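"""Group correlation matrices and density-thresholded binary networks.

The structural covariance network of a group is the Pearson correlation
matrix of corrected regional thickness across the group's subjects,
binarized at a target density D: the E = round(D * N(N-1)/2) strongest
positive correlations become edges of an undirected, unweighted graph with
zero diagonal.  Negative correlations are never edges.  Analysing a fixed
density (rather than a fixed correlation threshold) keeps the edge count —
and hence most metric baselines — identical between the groups being
compared.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics as _metrics

__all__ = [
    "CorrelationMatrix",
    "BinaryNetwork",
    "DensityRange",
    "correlation_matrix",
    "threshold_at_density",
    "select_density_range",
    "edge_table",
    "EdgeRanking",
]

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Symmetric region-by-region Pearson matrix; diagonal stored as 0."""

    values: np.ndarray
    regions: list[str]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"correlation matrix must be square, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix is not symmetric")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if off.size and (np.abs(off) > 1 + 1e-12).any():
            raise ValueError("off-diagonal correlations outside [-1, 1]")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = v
        if len(self.regions) != v.shape[0]:
            raise ValueError("region names do not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.regions, columns=self.regions)


@dataclass
class BinaryNetwork:
    """Undirected, unweighted graph at a fixed density; zero diagonal."""

    adjacency: np.ndarray
    density: float
    regions: list[str]

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.diag(a).any():
            raise ValueError("adjacency must have a zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        self.adjacency = a.astype(np.uint8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_list(self) -> list[tuple[str, str]]:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return [(self.regions[a], self.regions[b]) for a, b in zip(i, j)]


@dataclass
class DensityRange:
    """Analysis density interval with its evaluation grid."""

    d_min: float
    d_max: float
    step: float = 0.01

    def __post_init__(self):
        if not (0 < self.d_min <= self.d_max < 1):
            raise ValueError(
                f"need 0 < d_min <= d_max < 1, got [{self.d_min}, {self.d_max}]"
            )
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.d_max - self.d_min) / self.step))
        return np.round(self.d_min + self.step * np.arange(n + 1), 10)


def correlation_matrix(residuals) -> CorrelationMatrix:
    """Pearson correlations of corrected thickness across subjects.

    Accepts the DataFrame returned by :func:`covnet.preprocess.residualize`
    (region columns; an optional ``group`` column is ignored) or a plain
    subjects x regions array.
    """
    if isinstance(residuals, pd.DataFrame):
        regions = [c for c in residuals.columns if c != "group"]
        x = residuals[regions].to_numpy(dtype=float)
    else:
        x = np.asarray(residuals, dtype=float)
        regions = [f"region_{i}" for i in range(x.shape[1])]
    if x.shape[0] < 3:
        raise ValueError(f"need at least 3 subjects, got {x.shape[0]}")
    sd = x.std(axis=0)
    dead = np.nonzero(sd == 0)[0]
    if dead.size:
        raise ValueError(
            f"zero-variance regions: {[regions[i] for i in dead]}"
        )
    r = np.corrcoef(x, rowvar=False)
    return CorrelationMatrix(r, regions)


class EdgeRanking:
    """Pre-sorted edge order of a correlation matrix for fast thresholding.

    Edges are ranked by descending r; ties broken by lexicographic region
    pair so binarization is deterministic.  Only positive correlations are
    admissible.
    """

    def __init__(self, corr: CorrelationMatrix):
        n = corr.n_regions
        self.n = n
        self.regions = corr.regions
        iu = np.triu_indices(n, 1)
        r = corr.values[iu]
        order = np.lexsort((iu[1], iu[0], -r))
        self.i = iu[0][order]
        self.j = iu[1][order]
        self.r = r[order]
        self.n_positive = int((self.r > 0).sum())
        self.n_pairs = len(self.r)

    @property
    def max_density(self) -> float:
        return self.n_positive / self.n_pairs

    def edge_count(self, density: float) -> int:
        return int(round(density * self.n_pairs))

    def adjacency(self, density: float) -> np.ndarray:
        if not (0 < density < 1):
            raise ValueError(f"density must lie in (0, 1), got {density}")
        e = self.edge_count(density)
        if e > self.n_positive:
            raise ValueError(
                f"density {density} needs {e} edges but only {self.n_positive} "
                f"positive correlations exist (maximum achievable density "
                f"{self.max_density:.4f})"
            )
        a = np.zeros((self.n, self.n), dtype=np.uint8)
        a[self.i[:e], self.j[:e]] = 1
        a[self.j[:e], self.i[:e]] = 1
        return a


def threshold_at_density(corr: CorrelationMatrix, density: float) -> BinaryNetwork:
    """Binarize a correlation matrix at a target density."""
    ranking = EdgeRanking(corr)
    return BinaryNetwork(ranking.adjacency(density), density, corr.regions)


def edge_table(net: BinaryNetwork, corr: CorrelationMatrix | None = None) -> pd.DataFrame:
    """Edge list of a network as (region_a, region_b[, r]) rows."""
    i, j = np.nonzero(np.triu(net.adjacency, 1))
    out = pd.DataFrame(
        {
            "region_a": [net.regions[a] for a in i],
            "region_b": [net.regions[b] for b in j],
        }
    )
    if corr is not None:
        out["r"] = corr.values[i, j]
    return out


def select_density_range(
    corr_g1: CorrelationMatrix,
    corr_g2: CorrelationMatrix,
    sigma_rule: float = 1.2,
    probe_step: float = 0.01,
    n_random: int = 100,
    rewires_per_edge: int = 10,
    seed: int = 0,
    step: float | None = None,
) -> DensityRange:
    """Data-driven analysis density range.

    The lower limit is the smallest probed density at which the networks
    of *both* groups are connected (a single component spanning all
    regions); the upper limit is the largest probed density at which both
    groups remain small-world (sigma > ``sigma_rule``, computed against a
    seeded degree-matched random ensemble).  Probing runs on a grid of
    ``probe_step``; ``step`` sets the grid of the returned range (defaults
    to ``probe_step``).
    """
    if corr_g1.regions != corr_g2.regions:
        raise ValueError("correlation matrices use different parcellations")
    rank1, rank2 = EdgeRanking(corr_g1), EdgeRanking(corr_g2)
    top = min(rank1.max_density, rank2.max_density)
    grid = np.round(np.arange(probe_step, min(top, 1.0), probe_step), 10)
    if grid.size == 0:
        raise ValueError("no feasible probe densities (too few positive correlations)")

    def connected_both(d: float) -> bool:
        return all(
            _metrics.is_connected(rank.adjacency(d)) for rank in (rank1, rank2)
        )

    d_min = next((d for d in grid if connected_both(d)), None)
    if d_min is None:
        raise ValueError(
            f"no probed density in [{grid[0]}, {grid[-1]}] yields connected "
            "networks for both groups"
        )

    def small_world_both(d: float) -> bool:
        for rank in (rank1, rank2):
            net = BinaryNetwork(rank.adjacency(d), d, rank.regions)
            ens = _metrics.match_random_ensemble(
                net, n_random=n_random, rewires_per_edge=rewires_per_edge, seed=seed
            )
            if _metrics.small_world(net, ens).sigma <= sigma_rule:
                return False
        return True

    d_max = next((d for d in grid[::-1] if d >= d_min and small_world_both(d)), None)
    if d_max is None:
        raise ValueError(
            f"connectivity holds from density {d_min} but no density >= {d_min} "
            f"gives sigma > {sigma_rule} for both groups"
        )
    logger.info("selected density range [%.3f, %.3f]", d_min, d_max)
    return DensityRange(float(d_min), float(d_max), step or probe_step)
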