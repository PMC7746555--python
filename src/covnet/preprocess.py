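"""Thickness-table ingestion and covariate residualization.

Each region's thickness is corrected by ordinary least squares on

    thickness ~ 1 + age + sex + global_mean_thickness

fitted within the chosen scope (per group by default).  The residuals —
"corrected thickness" — are what the network stage correlates across
subjects.  Global mean thickness is the unweighted mean of the regional
values for each subject.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["load_thickness", "residualize", "residualize_matrix"]

logger = logging.getLogger(__name__)

META_COLUMNS = ("subject_id", "group", "age", "sex")


def load_thickness(path, parcellation: list[str], sep: str | None = None) -> pd.DataFrame:
    """Read and validate a thickness table.

    The file must contain ``subject_id, group, age, sex`` and one column
    per region of ``parcellation``; region columns are reordered to match.
    Unknown extra columns are dropped with a log line (tolerant of
    aparc-stats-style exports); rows with missing thickness are rejected
    and logged.
    """
    table = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    missing_meta = [c for c in META_COLUMNS if c not in table.columns]
    if missing_meta:
        raise ValueError(f"missing required columns: {missing_meta}")
    have = set(table.columns) - set(META_COLUMNS)
    want = set(parcellation)
    if want - have:
        raise ValueError(
            f"missing region columns: {sorted(want - have)}"
        )
    extra = sorted(have - want)
    if extra:
        logger.info("ignoring %d unexpected columns: %s", len(extra), extra)
    table = table[list(META_COLUMNS) + list(parcellation)]
    bad = ~np.isfinite(table[parcellation].apply(pd.to_numeric, errors="coerce")).all(
        axis=1
    )
    if bad.any():
        logger.warning(
            "excluding %d rows with missing/non-numeric thickness: subjects %s",
            int(bad.sum()),
            table.loc[bad, "subject_id"].tolist(),
        )
        table = table.loc[~bad].reset_index(drop=True)
    for col in parcellation:
        if not np.issubdtype(table[col].dtype, np.number):
            row = table.index[pd.to_numeric(table[col], errors="coerce").isna()][0]
            raise ValueError(f"non-numeric thickness at row {row}, column {col!r}")
    table["sex"] = encode_sex(table["sex"])
    logger.info("loaded %d subjects x %d regions", len(table), len(parcellation))
    return table


def encode_sex(sex: pd.Series) -> np.ndarray:
    """Map any two-level sex encoding onto 0/1 (levels in sorted order)."""
    levels = sorted(pd.unique(sex))
    if len(levels) > 2:
        raise ValueError(f"sex column has {len(levels)} levels: {levels}")
    if set(levels) <= {0, 1}:
        return sex.to_numpy(dtype=int)
    mapping = {lv: i for i, lv in enumerate(levels)}
    logger.info("sex encoding mapped as %s", mapping)
    return sex.map(mapping).to_numpy(dtype=int)


def residualize_matrix(
    thickness: np.ndarray, age: np.ndarray, sex: np.ndarray
) -> np.ndarray:
    """OLS residuals of every region on [1, age, sex, global mean].

    Core numeric routine shared by the public API and the permutation
    engine; operates on plain arrays, no validation beyond rank checks.
    """
    n = thickness.shape[0]
    gm = thickness.mean(axis=1)
    design = [np.ones(n), np.asarray(age, float), np.asarray(sex, float), gm]
    names = ["intercept", "age", "sex", "global_mean"]
    # a covariate without variation cannot be estimated; the derived
    # global-mean column may legitimately collapse to a constant when the
    # input is already residualized, in which case it is dropped
    keep, dropped = [], []
    for i, (col, name) in enumerate(zip(design, names)):
        if i > 0 and np.ptp(col) < 1e-12 * max(1.0, np.abs(col).max()):
            if name == "global_mean":
                dropped.append(name)
                continue
            raise ValueError(f"rank-deficient design: column {name!r} is constant")
        keep.append(col)
    if dropped:
        logger.info("dropping constant derived columns: %s", dropped)
    kept_names = [nm for nm, _ in zip(names, design) if nm not in dropped]
    x = np.column_stack(keep)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # the derived global-mean column is redundant whenever thickness is
        # an exact linear function of the covariates; drop it, not the
        # user's covariates
        if "global_mean" in kept_names:
            xr = x[:, :-1]
            if np.linalg.matrix_rank(xr) == xr.shape[1]:
                logger.info("dropping collinear derived column: global_mean")
                x = xr
                kept_names = kept_names[:-1]
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # locate the collinear column by leave-one-out rank
        for i in range(1, x.shape[1]):
            xi = np.delete(x, i, axis=1)
            if np.linalg.matrix_rank(xi) == np.linalg.matrix_rank(x):
                raise ValueError(
                    f"rank-deficient design: column {kept_names[i]!r} is collinear"
                )
        raise ValueError("rank-deficient design")
    if n < x.shape[1] + 1:
        raise ValueError(
            f"{n} subjects cannot support a {x.shape[1]}-parameter regression"
        )
    beta, *_ = np.linalg.lstsq(x, thickness, rcond=None)
    return thickness - x @ beta


def residualize(
    table: pd.DataFrame, regions: list[str], scope: str = "per-group"
) -> pd.DataFrame:
    """Corrected cortical thickness for every subject.

    scope="per-group" fits the regression separately inside each group
    (matching group-wise network construction); scope="pooled" fits one
    regression over all subjects.  Returns a DataFrame of residuals with
    the group column retained.
    """
    if scope not in ("per-group", "pooled"):
        raise ValueError(f"scope must be 'per-group' or 'pooled', got {scope!r}")
    thick = table[regions].to_numpy(dtype=float)
    age = table["age"].to_numpy(dtype=float)
    sex = encode_sex(table["sex"])
    res = np.empty_like(thick)
    if scope == "pooled":
        res[:] = residualize_matrix(thick, age, sex)
    else:
        for _, idx in table.groupby("group", sort=False).indices.items():
            res[idx] = residualize_matrix(thick[idx], age[idx], sex[idx])
    out = pd.DataFrame(res, columns=regions, index=table.index)
    out.insert(0, "group", table["group"].to_numpy())
    return out
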