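"""Group comparison of network parameters by label permutation.

For every metric, the two groups' values are computed at each density of
the analysis grid; the area under the metric-versus-density curve (AUC,
trapezoid rule) summarizes each group across the whole range.  Statistical
significance of the group difference (group1 - group2, groups in order of
appearance) comes from a non-parametric permutation test: subjects are
repeatedly reassigned to two pseudo-groups of the original sizes, the full
per-group pipeline (residualization within pseudo-groups when scope is
"per-group", correlation, thresholding, metrics) is re-run, and the
observed difference is located in the resulting null distribution.
Two-sided p-values use the add-one rule (b + 1)/(m + 1), which never
reports p = 0; 95% null bands are the 2.5/97.5 percentiles per density.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics as gm
from .network import CorrelationMatrix, DensityRange, EdgeRanking
from .preprocess import encode_sex, residualize_matrix

__all__ = [
    "ComparisonSettings",
    "MetricCurve",
    "PermutationResult",
    "HubComparison",
    "metric_curves",
    "permute_groups",
    "compare_nodal",
    "compare_hubs",
]

logger = logging.getLogger(__name__)

DEFAULT_GLOBAL_METRICS = (
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "transitivity",
    "modularity",
)


@dataclass
class ComparisonSettings:
    """Settings shared by the observed and permuted pipeline runs.

    ``global_metrics`` may include "gamma"/"lambda"/"sigma"; note these
    rebuild a random ensemble per network per density, which is costly
    inside permutation loops.  ``scope`` controls whether residualization
    is refit within each (pseudo-)group or once on the pooled sample.
    """

    scope: str = "per-group"
    global_metrics: tuple[str, ...] = DEFAULT_GLOBAL_METRICS
    nodal_metrics: tuple[str, ...] = ()
    modularity_restarts: int = 1
    n_random: int = 100
    rewires_per_edge: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.scope not in ("per-group", "pooled"):
            raise ValueError(f"unknown scope {self.scope!r}")
        for m in self.global_metrics:
            if m not in gm.GLOBAL_METRICS:
                raise ValueError(f"unknown global metric {m!r}")
        for m in self.nodal_metrics:
            if m not in gm.NODAL_METRICS:
                raise ValueError(f"unknown nodal metric {m!r}")


@dataclass
class MetricCurve:
    """One metric across the density grid for both groups, plus its AUC.

    ``values[group]`` is a vector over the grid for global metrics or a
    (grid x regions) array for nodal metrics; ``auc`` follows suit.
    """

    metric: str
    grid: np.ndarray
    values: dict[str, np.ndarray]
    auc: dict[str, float | np.ndarray]


@dataclass
class PermutationResult:
    """Observed group difference with its permutation null."""

    metric: str
    grid: np.ndarray
    observed: np.ndarray  # difference per density
    observed_auc: float | np.ndarray
    null: np.ndarray  # (n_perm, n_densities[, n_regions])
    null_auc: np.ndarray  # (n_perm[, n_regions])
    p_auc: float | np.ndarray
    p_per_density: np.ndarray
    band_low: np.ndarray  # 2.5th null percentile per density
    band_high: np.ndarray  # 97.5th
    n_perm: int
    n_valid_auc: int | np.ndarray
    seed: int


@dataclass
class HubComparison:
    groups: tuple[str, str]
    hub_sets: dict[str, gm.HubSet]
    density: float | None
    mode: str

    @property
    def shared(self) -> list[str]:
        a, b = (set(self.hub_sets[g].regions) for g in self.groups)
        return sorted(a & b)

    def only_in(self, group: str) -> list[str]:
        other = [g for g in self.groups if g != group][0]
        return sorted(
            set(self.hub_sets[group].regions) - set(self.hub_sets[other].regions)
        )


def _extract(table: pd.DataFrame, regions: list[str] | None = None):
    """Pull numpy arrays out of a thickness table; groups in order of appearance."""
    if regions is None:
        regions = [
            c for c in table.columns if c not in ("subject_id", "group", "age", "sex")
        ]
    groups = list(dict.fromkeys(table["group"]))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    thick = table[regions].to_numpy(dtype=float)
    age = table["age"].to_numpy(dtype=float)
    sex = encode_sex(table["sex"])
    labels = table["group"].to_numpy()
    idx = tuple(np.nonzero(labels == g)[0] for g in groups)
    return regions, groups, thick, age, sex, idx


def _curves_from_residuals(
    resid: np.ndarray,
    grid: np.ndarray,
    settings: ComparisonSettings,
    strict: bool = False,
    group: str = "",
):
    """Metric values across the density grid for one set of residuals.

    Returns (global dict metric -> vector, nodal dict metric -> grid x N
    array).  Densities whose edge demand exceeds the number of positive
    correlations are NaN (or an error when ``strict``, i.e. for observed
    groups).
    """
    sd = resid.std(axis=0)
    if (sd == 0).any():
        raise ValueError(f"zero-variance residual region in group {group!r}")
    r = np.corrcoef(resid, rowvar=False)
    n = r.shape[0]
    iu = gm._triu(n)
    rv = r[iu]
    order = np.lexsort((iu[1], iu[0], -rv))
    ei, ej, er = iu[0][order], iu[1][order], rv[order]
    n_pairs = len(er)
    n_pos = int((er > 0).sum())

    gvals = {m: np.full(len(grid), np.nan) for m in settings.global_metrics}
    nvals = {m: np.full((len(grid), n), np.nan) for m in settings.nodal_metrics}
    a = np.zeros((n, n), dtype=np.uint8)
    prev_e = 0
    for gi, d in enumerate(grid):
        e = int(round(d * n_pairs))
        if e > n_pos:
            if strict:
                raise ValueError(
                    f"density {d} infeasible for group {group!r}: needs {e} "
                    f"edges, only {n_pos} positive correlations"
                )
            logger.debug("density %s infeasible (needs %d of %d)", d, e, n_pos)
            continue
        # the ranking is shared across densities, so grow the adjacency
        a[ei[prev_e:e], ej[prev_e:e]] = 1
        a[ej[prev_e:e], ei[prev_e:e]] = 1
        prev_e = e
        g = gm.global_metrics(
            a,
            which=settings.global_metrics,
            seed=settings.seed,
            modularity_restarts=settings.modularity_restarts,
            n_random=settings.n_random,
            rewires_per_edge=settings.rewires_per_edge,
        )
        for m, v in g.items():
            gvals[m][gi] = v
        if settings.nodal_metrics:
            nm = gm.nodal_metrics(a, which=settings.nodal_metrics)
            for m in settings.nodal_metrics:
                nvals[m][gi] = nm[f"{m}_normalized"]
    return gvals, nvals


def _group_curves(thick, age, sex, idx, grid, settings, groups, strict=False):
    """Per-group metric curves, honouring the residualization scope."""
    if settings.scope == "pooled":
        resid_all = residualize_matrix(thick, age, sex)
        parts = [
            _curves_from_residuals(resid_all[i], grid, settings, strict, g)
            for i, g in zip(idx, groups)
        ]
    else:
        parts = [
            _curves_from_residuals(
                residualize_matrix(thick[i], age[i], sex[i]),
                grid,
                settings,
                strict,
                g,
            )
            for i, g in zip(idx, groups)
        ]
    return parts


def _auc(grid: np.ndarray, values: np.ndarray):
    """Trapezoidal AUC along the density axis; NaN if any value is missing."""
    return np.trapezoid(values, grid, axis=0)


def metric_curves(
    table: pd.DataFrame,
    density_range: DensityRange,
    settings: ComparisonSettings | None = None,
    regions: list[str] | None = None,
) -> dict[str, MetricCurve]:
    """Global (and requested nodal) metric curves for both groups.

    Any infeasible grid density raises, naming the group and density.
    """
    settings = settings or ComparisonSettings()
    regions, groups, thick, age, sex, idx = _extract(table, regions)
    grid = density_range.grid
    parts = _group_curves(thick, age, sex, idx, grid, settings, groups, strict=True)
    out: dict[str, MetricCurve] = {}
    for m in settings.global_metrics:
        values = {g: parts[k][0][m] for k, g in enumerate(groups)}
        auc = {g: float(_auc(grid, values[g])) for g in groups}
        out[m] = MetricCurve(m, grid, values, auc)
    for m in settings.nodal_metrics:
        values = {g: parts[k][1][m] for k, g in enumerate(groups)}
        auc = {g: _auc(grid, values[g]) for g in groups}
        out[f"nodal_{m}"] = MetricCurve(f"nodal_{m}", grid, values, auc)
    return out


def _null_distributions(
    thick, age, sex, sizes, grid, settings, groups, n_perm, seed
):
    """Pseudo-group difference arrays for every permutation repetition.

    Each repetition reassigns subjects to groups of the original sizes and
    reruns the full pipeline.  Sub-seeds derive from (seed, repetition) so
    results do not depend on execution order.
    """
    n = len(age)
    n1 = sizes[0]
    g_null = {m: np.full((n_perm, len(grid)), np.nan) for m in settings.global_metrics}
    n_null = {
        m: np.full((n_perm, len(grid), thick.shape[1]), np.nan)
        for m in settings.nodal_metrics
    }
    for t in range(n_perm):
        rng = np.random.default_rng([seed, t])
        perm = rng.permutation(n)
        idx = (perm[:n1], perm[n1:])
        parts = _group_curves(thick, age, sex, idx, grid, settings, groups)
        for m in settings.global_metrics:
            g_null[m][t] = parts[0][0][m] - parts[1][0][m]
        for m in settings.nodal_metrics:
            n_null[m][t] = parts[0][1][m] - parts[1][1][m]
    return g_null, n_null


def _add_one_p(null_abs, obs_abs, axis=0):
    """(b + 1)/(m + 1) two-sided p over non-missing repetitions."""
    valid = np.isfinite(null_abs)
    b = ((null_abs >= obs_abs) & valid).sum(axis=axis)
    m = valid.sum(axis=axis)
    return (b + 1) / (m + 1), m


def _result_for(metric, grid, obs, obs_auc, null, seed, n_perm) -> PermutationResult:
    null_auc = _auc(grid, np.moveaxis(null, 1, 0))  # integrate density axis
    p_auc, m_auc = _add_one_p(np.abs(null_auc), np.abs(obs_auc))
    p_dens, _ = _add_one_p(np.abs(null), np.abs(obs))
    with np.errstate(invalid="ignore"):
        band_low = np.nanpercentile(null, 2.5, axis=0)
        band_high = np.nanpercentile(null, 97.5, axis=0)
    return PermutationResult(
        metric=metric,
        grid=grid,
        observed=obs,
        observed_auc=obs_auc,
        null=null,
        null_auc=null_auc,
        p_auc=p_auc if np.ndim(p_auc) else float(p_auc),
        p_per_density=p_dens,
        band_low=band_low,
        band_high=band_high,
        n_perm=n_perm,
        n_valid_auc=m_auc if np.ndim(m_auc) else int(m_auc),
        seed=seed,
    )


def permute_groups(
    table: pd.DataFrame,
    density_range: DensityRange,
    settings: ComparisonSettings | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    regions: list[str] | None = None,
) -> dict[str, PermutationResult]:
    """Permutation test of global-metric group differences (per density and AUC)."""
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    settings = settings or ComparisonSettings()
    regions, groups, thick, age, sex, idx = _extract(table, regions)
    grid = density_range.grid
    parts = _group_curves(thick, age, sex, idx, grid, settings, groups, strict=True)
    sizes = tuple(len(i) for i in idx)
    g_null, _ = _null_distributions(
        thick, age, sex, sizes, grid, settings, groups, n_perm, seed
    )
    out = {}
    for m in settings.global_metrics:
        obs = parts[0][0][m] - parts[1][0][m]
        obs_auc = float(_auc(grid, obs))
        out[m] = _result_for(m, grid, obs, obs_auc, g_null[m], seed, n_perm)
    return out


def compare_nodal(
    table: pd.DataFrame,
    density_range: DensityRange,
    settings: ComparisonSettings | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    regions: list[str] | None = None,
    adjust: bool = False,
) -> tuple[dict[str, PermutationResult], pd.DataFrame]:
    """Permutation test of mean-normalized nodal metrics, per region.

    Returns the per-metric :class:`PermutationResult` objects (region axis
    last) and a tidy summary frame with per-region AUC differences and
    p-values; Benjamini-Hochberg-adjusted p-values are included when
    ``adjust`` is set (the default reports uncorrected p, labelled as such).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    settings = settings or ComparisonSettings()
    if not settings.nodal_metrics:
        settings = ComparisonSettings(
            scope=settings.scope,
            global_metrics=(),
            nodal_metrics=gm.NODAL_METRICS,
            modularity_restarts=settings.modularity_restarts,
            n_random=settings.n_random,
            rewires_per_edge=settings.rewires_per_edge,
            seed=settings.seed,
        )
    regions, groups, thick, age, sex, idx = _extract(table, regions)
    grid = density_range.grid
    parts = _group_curves(thick, age, sex, idx, grid, settings, groups, strict=True)
    sizes = tuple(len(i) for i in idx)
    _, n_null = _null_distributions(
        thick, age, sex, sizes, grid, settings, groups, n_perm, seed
    )
    results = {}
    rows = []
    for m in settings.nodal_metrics:
        obs = parts[0][1][m] - parts[1][1][m]  # grid x regions
        obs_auc = _auc(grid, obs)
        res = _result_for(m, grid, obs, obs_auc, n_null[m], seed, n_perm)
        results[m] = res
        for ri, region in enumerate(regions):
            rows.append(
                {
                    "metric": m,
                    "region": region,
                    "auc_difference": obs_auc[ri],
                    "p_uncorrected": res.p_auc[ri],
                }
            )
    summary = pd.DataFrame(rows)
    if adjust:
        from scipy.stats import false_discovery_control

        summary["p_bh"] = np.concatenate(
            [
                false_discovery_control(
                    summary.loc[summary.metric == m, "p_uncorrected"]
                )
                for m in settings.nodal_metrics
            ]
        )
    return results, summary


def compare_hubs(
    table: pd.DataFrame,
    density_range: DensityRange,
    settings: ComparisonSettings | None = None,
    hub_density: float | None = None,
    mode: str = "single",
    regions: list[str] | None = None,
) -> HubComparison:
    """Hub sets per group and their overlap.

    mode="single" detects hubs at ``hub_density`` (default: the lower end
    of the analysis range); mode="majority" flags a region that qualifies
    as a hub at more than half of the grid densities.
    """
    if mode not in ("single", "majority"):
        raise ValueError(f"unknown hub mode {mode!r}")
    settings = settings or ComparisonSettings()
    regions, groups, thick, age, sex, idx = _extract(table, regions)
    densities = (
        [hub_density if hub_density is not None else density_range.d_min]
        if mode == "single"
        else list(density_range.grid)
    )
    hub_sets = {}
    for i, g in zip(idx, groups):
        if settings.scope == "pooled":
            resid = residualize_matrix(thick, age, sex)[i]
        else:
            resid = residualize_matrix(thick[i], age[i], sex[i])
        r = np.corrcoef(resid, rowvar=False)
        np.fill_diagonal(r, 0.0)
        ranking = EdgeRanking(CorrelationMatrix(r, regions))
        flags = np.zeros(len(regions))
        last = None
        for d in densities:
            bc = gm.betweenness(ranking.adjacency(d))
            last = gm.detect_hubs(bc, regions)
            flags[[regions.index(h) for h in last.regions]] += 1
        if mode == "single":
            hub_sets[g] = last
        else:
            chosen = [regions[k] for k in np.nonzero(flags > len(densities) / 2)[0]]
            hub_sets[g] = gm.HubSet(chosen, np.nan, np.nan)
    return HubComparison(
        tuple(groups), hub_sets, densities[0] if mode == "single" else None, mode
    )
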