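"""End-to-end orchestration: config in, report bundle out.

A :class:`RunConfig` (typically loaded from YAML) fully determines a run:
inputs, parcellation, density range, ensemble and permutation settings,
seeds, output directory.  ``run_pipeline`` executes residualize ->
correlate -> threshold -> metrics -> permutation -> hubs and writes tidy
CSV artifacts plus a JSON manifest (settings, seeds, input checksum), so a
persisted config re-executes to byte-identical tables.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import (
    ComparisonSettings,
    compare_hubs,
    compare_nodal,
    metric_curves,
    permute_groups,
)
from .network import DensityRange, correlation_matrix, select_density_range
from .parcellation import desikan_killiany_68, load_parcellation
from .preprocess import load_thickness, residualize

__all__ = ["RunConfig", "ValidationError", "run_pipeline"]

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Configuration problem detected before any computation."""


@dataclass
class RunConfig:
    input: str
    output_dir: str
    parcellation: str | None = None  # path; None = packaged Desikan-Killiany 68
    density_min: float = 0.15
    density_max: float = 0.40
    density_step: float = 0.01
    auto_range: bool = False  # derive the range from the data instead
    sigma_rule: float = 1.2
    scope: str = "per-group"
    global_metrics: tuple[str, ...] = ComparisonSettings.global_metrics
    nodal: bool = False
    nodal_adjust: bool = False
    n_perm: int = 1000
    hub_mode: str = "single"
    hub_density: float | None = None
    n_random: int = 100
    rewires_per_edge: int = 10
    modularity_restarts: int = 1
    seed: int = 42

    def __post_init__(self):
        self.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not (0 < self.density_min <= self.density_max < 1):
            raise ValidationError(
                f"need 0 < density_min <= density_max < 1, got "
                f"[{self.density_min}, {self.density_max}]"
            )
        if self.density_step <= 0:
            raise ValidationError("density_step must be positive")
        if self.n_perm < 1:
            raise ValidationError("n_perm must be at least 1")
        if self.scope not in ("per-group", "pooled"):
            raise ValidationError(f"unknown scope {self.scope!r}")
        if not Path(self.input).exists():
            raise ValidationError(f"input file not found: {self.input}")

    def settings(self, nodal: bool = False) -> ComparisonSettings:
        return ComparisonSettings(
            scope=self.scope,
            global_metrics=tuple(self.global_metrics),
            nodal_metrics=("degree", "clustering", "betweenness") if nodal else (),
            modularity_restarts=self.modularity_restarts,
            n_random=self.n_random,
            rewires_per_edge=self.rewires_per_edge,
            seed=self.seed,
        )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis described by ``config``.

    Returns a manifest dict (also written to ``manifest.json``); artifact
    tables land in ``config.output_dir``.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run(config, out)
    except Exception as exc:
        # flag partial outputs so a half-written directory is never
        # mistaken for a finished run
        (out / "manifest.json").write_text(
            json.dumps(
                {
                    "covnet_version": __version__,
                    "config": dataclasses.asdict(config),
                    "complete": False,
                    "error": f"{type(exc).__name__}: {exc}",
                },
                indent=2,
                default=list,
            )
            + "\n"
        )
        raise


def _run(config: RunConfig, out: Path) -> dict:
    regions = (
        load_parcellation(config.parcellation)
        if config.parcellation
        else desikan_killiany_68()
    )

    table = load_thickness(config.input, regions)
    groups = list(dict.fromkeys(table["group"]))
    logger.info("stage residualize: scope=%s", config.scope)
    resid = residualize(table, regions, scope=config.scope)
    resid.to_csv(out / "residuals.csv", index=False)

    logger.info("stage correlation")
    corr = {
        g: correlation_matrix(resid.loc[resid["group"] == g, regions])
        for g in groups
    }
    for g, c in corr.items():
        c.to_frame().to_csv(out / f"correlation_{g}.csv")

    if config.auto_range:
        logger.info("stage density-range selection (sigma rule %s)", config.sigma_rule)
        density_range = select_density_range(
            corr[groups[0]],
            corr[groups[1]],
            sigma_rule=config.sigma_rule,
            probe_step=config.density_step,
            n_random=config.n_random,
            rewires_per_edge=config.rewires_per_edge,
            seed=config.seed,
        )
    else:
        density_range = DensityRange(
            config.density_min, config.density_max, config.density_step
        )

    logger.info("stage metric curves over %s", density_range)
    curves = metric_curves(table, density_range, config.settings(), regions)
    tidy = [
        {"metric": m, "group": g, "density": d, "value": v}
        for m, curve in curves.items()
        for g in groups
        for d, v in zip(curve.grid, curve.values[g])
    ]
    pd.DataFrame(tidy).to_csv(out / "metric_curves.csv", index=False)
    pd.DataFrame(
        [
            {"metric": m, "group": g, "auc": curve.auc[g]}
            for m, curve in curves.items()
            for g in groups
        ]
    ).to_csv(out / "metric_auc.csv", index=False)

    logger.info("stage permutation (%d repetitions)", config.n_perm)
    perm = permute_groups(
        table, density_range, config.settings(), config.n_perm, config.seed, regions
    )
    rows = []
    for m, res in perm.items():
        rows.append(
            {
                "metric": m,
                "density": "AUC",
                "observed_difference": res.observed_auc,
                "p": res.p_auc,
                "band_low": np.nan,
                "band_high": np.nan,
            }
        )
        for k, d in enumerate(res.grid):
            rows.append(
                {
                    "metric": m,
                    "density": d,
                    "observed_difference": res.observed[k],
                    "p": res.p_per_density[k],
                    "band_low": res.band_low[k],
                    "band_high": res.band_high[k],
                }
            )
    pd.DataFrame(rows).to_csv(out / "permutation_global.csv", index=False)

    if config.nodal:
        logger.info("stage nodal comparison")
        _, nodal_summary = compare_nodal(
            table,
            density_range,
            config.settings(nodal=True),
            config.n_perm,
            config.seed,
            regions,
            adjust=config.nodal_adjust,
        )
        nodal_summary.to_csv(out / "permutation_nodal.csv", index=False)

    logger.info("stage hubs (mode=%s)", config.hub_mode)
    hubs = compare_hubs(
        table,
        density_range,
        config.settings(),
        hub_density=config.hub_density,
        mode=config.hub_mode,
        regions=regions,
    )
    hub_report = {
        "mode": hubs.mode,
        "density": hubs.density,
        "hubs": {g: hubs.hub_sets[g].regions for g in groups},
        "shared": hubs.shared,
        **{f"only_{g}": hubs.only_in(g) for g in groups},
    }
    (out / "hubs.json").write_text(json.dumps(hub_report, indent=2) + "\n")

    manifest = {
        "covnet_version": __version__,
        "config": dataclasses.asdict(config),
        "input_sha256": _sha256(config.input),
        "groups": groups,
        "n_subjects": {g: int((table["group"] == g).sum()) for g in groups},
        "density_range": {
            "d_min": density_range.d_min,
            "d_max": density_range.d_max,
            "step": density_range.step,
        },
        "artifacts": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
        "complete": True,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list) + "\n")
    logger.info("run complete: %s", out)
    return manifest
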