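"""Synthetic two-group cortical-thickness cohorts with known covariance.

Regional thickness is modelled as

    thickness = baseline + beta_age * age + beta_sex * sex + noise_sd * z

where ``z`` is a multivariate-normal draw whose region-by-region
correlation follows a planted-partition (block) structure: regions in the
same block correlate at ``within_block_r``, regions in different blocks at
``between_block_r``, each settable per group.  Because the downstream
pipeline removes linear age/sex effects and correlates the residuals, the
block matrix is the ground-truth structural covariance network, which makes
parameter-recovery and calibration experiments possible without any real
MRI-derived data.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parcellation import desikan_killiany_68

__all__ = [
    "SyntheticSpec",
    "block_correlation",
    "bridge_correlation",
    "generate_cohort",
    "write_cohort",
]

logger = logging.getLogger(__name__)

# Above this (absolute) most-negative eigenvalue a requested correlation
# matrix is considered structurally broken rather than numerically off.
_PSD_HARD_LIMIT = 0.05


def _pair(x) -> tuple:
    """Broadcast a scalar to a per-group pair."""
    if np.isscalar(x):
        return (x, x)
    a, b = x
    return (a, b)


@dataclass
class SyntheticSpec:
    """Parameters of a simulated two-group cohort.

    ``within_block_r`` / ``between_block_r`` accept a scalar (both groups)
    or a per-group pair.  ``correlation_override`` replaces the block
    construction with explicit per-group correlation matrices, e.g. for
    planted-bridge designs.
    """

    n_regions: int = 68
    group_sizes: tuple[int, int] = (67, 88)
    group_labels: tuple[str, str] = ("patient", "control")
    n_blocks: int = 4
    block_partition: np.ndarray | None = None  # region -> block id
    # modest default correlations: after the downstream global-mean
    # correction (which forces every region's residual covariances to sum
    # to zero) stronger blocks would leave too few positive correlations
    # to support the upper end of the usual density range
    within_block_r: float | tuple[float, float] = 0.25
    between_block_r: float | tuple[float, float] = 0.10
    baseline_thickness: float = 2.5  # mm, typical adult cortex
    age_range: tuple[float, float] = (30.0, 68.0)  # years
    age_effect: float | np.ndarray = -0.005  # mm per year (cortical thinning)
    sex_effect: float | np.ndarray = 0.05  # mm, sex = 1 minus sex = 0
    noise_sd: float = 0.12  # mm, SD of the structured residual
    seed: int = 0
    correlation_override: tuple[np.ndarray, np.ndarray] | None = None
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.region_names:
            if self.n_regions == 68:
                self.region_names = desikan_killiany_68()
            else:
                width = len(str(self.n_regions))
                self.region_names = [
                    f"region_{i:0{width}d}" for i in range(self.n_regions)
                ]
        if len(self.region_names) != self.n_regions:
            raise ValueError(
                f"{len(self.region_names)} region names for {self.n_regions} regions"
            )
        if self.block_partition is None:
            self.block_partition = np.arange(self.n_regions) % self.n_blocks
        self.block_partition = np.asarray(self.block_partition)
        if self.block_partition.shape != (self.n_regions,):
            raise ValueError("block_partition must assign every region to a block")
        self.validate()

    def validate(self) -> None:
        if any(n < 3 for n in self.group_sizes):
            raise ValueError(
                f"group sizes {self.group_sizes} too small: Pearson correlation "
                "needs at least 3 subjects per group"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.correlation_override is None:
            for g in range(2):
                w = _pair(self.within_block_r)[g]
                b = _pair(self.between_block_r)[g]
                if not (0 <= w < 1) or not (0 <= b < 1):
                    raise ValueError(
                        f"group {g}: correlations must lie in [0, 1), "
                        f"got within={w}, between={b}"
                    )
                if b > w:
                    raise ValueError(
                        f"group {g}: between_block_r={b} exceeds within_block_r={w}"
                    )

    def correlation_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """Ground-truth region-region correlation matrix per group."""
        if self.correlation_override is not None:
            out = []
            for g, c in enumerate(self.correlation_override):
                c = np.asarray(c, dtype=float)
                if c.shape != (self.n_regions, self.n_regions):
                    raise ValueError(f"override matrix {g} has shape {c.shape}")
                out.append(_ensure_psd(c, f"correlation_override[{g}]"))
            return tuple(out)
        mats = []
        for g in range(2):
            c = block_correlation(
                self.block_partition,
                _pair(self.within_block_r)[g],
                _pair(self.between_block_r)[g],
            )
            mats.append(_ensure_psd(c, f"group {g} block parameters"))
        return tuple(mats)


def block_correlation(
    partition: np.ndarray, within_r: float, between_r: float
) -> np.ndarray:
    """Planted-partition correlation matrix: ``within_r`` inside a block,
    ``between_r`` across blocks, unit diagonal."""
    partition = np.asarray(partition)
    same = partition[:, None] == partition[None, :]
    c = np.where(same, within_r, between_r)
    np.fill_diagonal(c, 1.0)
    return c


def bridge_correlation(
    partition: np.ndarray,
    within_r: float,
    between_r: float,
    bridge: int,
    bridge_strength: float = 0.7,
    span: tuple[int, int] | None = None,
) -> np.ndarray:
    """Factor-model correlation matrix with one planted bridge region.

    Ordinary regions follow the usual planted-partition structure, realised
    as loadings sqrt(between_r) on a global factor and
    sqrt(within_r - between_r) on their block factor.  The bridge region
    instead loads ``bridge_strength`` on the block factors of the blocks
    in ``span`` (default: the first two), so it correlates with both at
    bridge_strength * sqrt(within_r - between_r) while the blocks stay
    weakly coupled to each other.  After density thresholding the bridge
    is essentially the only path between the spanned blocks, which gives
    it extreme betweenness — the design used to validate hub detection.
    Positive semi-definite by construction provided
    len(span) * bridge_strength**2 <= 1.

    With only two blocks in total, removing the subject global mean
    downstream makes the blocks anti-correlated and erases any bridge, so
    use at least three blocks (e.g. four) with a two-block span.
    """
    if not 0 <= between_r <= within_r < 1:
        raise ValueError("need 0 <= between_r <= within_r < 1")
    partition = np.asarray(partition)
    blocks = list(np.unique(partition))
    if span is None:
        span = (blocks[0], blocks[1])
    if len(span) * bridge_strength**2 > 1:
        raise ValueError(
            f"bridge_strength {bridge_strength} too large for a span of "
            f"{len(span)} blocks (need len(span) * strength^2 <= 1)"
        )
    n = len(partition)
    loadings = np.zeros((n, 1 + len(blocks)))
    loadings[:, 0] = np.sqrt(between_r)
    for bi, b in enumerate(blocks):
        loadings[partition == b, 1 + bi] = np.sqrt(within_r - between_r)
    loadings[bridge, :] = 0.0
    for b in span:
        loadings[bridge, 1 + blocks.index(b)] = bridge_strength
    c = loadings @ loadings.T
    np.fill_diagonal(c, 1.0)
    return c


def _ensure_psd(c: np.ndarray, origin: str) -> np.ndarray:
    """Validate positive semi-definiteness, clipping mild violations.

    Gross violations (most-negative eigenvalue beyond ``_PSD_HARD_LIMIT``)
    are rejected with a diagnostic naming the offending parameters; mild
    ones are repaired by eigenvalue clipping with a warning, which keeps
    behaviour predictable near parameter boundaries.
    """
    if not np.allclose(c, c.T, atol=1e-12):
        raise ValueError(f"{origin}: correlation matrix is not symmetric")
    w = np.linalg.eigvalsh(c)
    if w[0] >= -1e-10:
        return c
    if w[0] < -_PSD_HARD_LIMIT:
        raise ValueError(
            f"implied correlation matrix from {origin} is not positive "
            f"semi-definite (minimum eigenvalue {w[0]:.4f})"
        )
    warnings.warn(
        f"{origin}: implied correlation matrix has minimum eigenvalue "
        f"{w[0]:.2e}; clipping negative eigenvalues to zero",
        stacklevel=2,
    )
    vals, vecs = np.linalg.eigh(c)
    vals = np.clip(vals, 0.0, None)
    fixed = (vecs * vals) @ vecs.T
    # restore unit diagonal after clipping
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def generate_cohort(spec: SyntheticSpec) -> pd.DataFrame:
    """Draw a two-group thickness table from ``spec``.

    Returns a DataFrame with columns ``subject_id, group, age, sex`` then
    one column per region.  Identical spec (including seed) gives a
    bit-identical table.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    corr = spec.correlation_matrices()

    age_eff = np.broadcast_to(np.asarray(spec.age_effect, float), (spec.n_regions,))
    sex_eff = np.broadcast_to(np.asarray(spec.sex_effect, float), (spec.n_regions,))

    frames = []
    sid = 0
    for g, (n, label) in enumerate(zip(spec.group_sizes, spec.group_labels)):
        age = rng.uniform(*spec.age_range, size=n)
        sex = rng.integers(0, 2, size=n)
        # factor the correlation once; z = e @ (V sqrt(w))^T is MVN(0, C)
        vals, vecs = np.linalg.eigh(corr[g])
        factor = vecs * np.sqrt(np.clip(vals, 0.0, None))
        z = rng.standard_normal((n, spec.n_regions)) @ factor.T
        thick = (
            spec.baseline_thickness
            + age[:, None] * age_eff
            + sex[:, None] * sex_eff
            + spec.noise_sd * z
        )
        df = pd.DataFrame(thick, columns=spec.region_names)
        df.insert(0, "sex", sex)
        df.insert(0, "age", age)
        df.insert(0, "group", label)
        df.insert(0, "subject_id", [f"sub-{sid + i:04d}" for i in range(n)])
        sid += n
        frames.append(df)
    cohort = pd.concat(frames, ignore_index=True)
    logger.info(
        "generated cohort: %d + %d subjects, %d regions, seed=%d",
        *spec.group_sizes,
        spec.n_regions,
        spec.seed,
    )
    return cohort


def write_cohort(cohort: pd.DataFrame, path, sep: str = ",") -> None:
    """Persist a cohort table as delimited text (CSV by default)."""
    cohort.to_csv(path, sep=sep, index=False)
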