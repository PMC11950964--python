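"""Species-level predictor construction.

Site-level environments are lifted to species level as the mean over the
plots where each species occurs (the species' realized niche).  Soil
variables with heterogeneous units are collapsed to a single composite:
the first axis of a PCA on the correlation matrix, sign-fixed so the
loading of the first soil column is non-negative.  Collinearity among
candidate predictors is screened with variance inflation factors
(iteratively dropping the worst predictor above the threshold, default
10).  Photosynthetic-pathway relative abundance divides each species'
abundance by the plot total of species sharing its pathway (C3 or C4).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "species_env_means",
    "soil_pca_composite",
    "vif_screen",
    "c3_relative_abundance",
    "specific_leaf_area",
    "assemble_predictor_table",
]


def species_env_means(Y, env: pd.DataFrame) -> pd.DataFrame:
    """Mean of each site variable over the sites where each species occurs.

    Raises if a species occurs nowhere (it cannot be assigned a niche) or
    if some site lacks environmental data.
    """
    df = Y if isinstance(Y, pd.DataFrame) else pd.DataFrame(np.asarray(Y, float))
    missing_sites = sorted(set(map(str, df.index)) - set(map(str, env.index)))
    if missing_sites:
        raise ValueError(f"sites without environmental data: {missing_sites}")
    env = env.reindex(df.index)
    A = df.to_numpy(dtype=float)
    present = A > 0
    absent_everywhere = ~present.any(axis=0)
    if absent_everywhere.any():
        bad = list(df.columns[absent_everywhere])
        raise ValueError(f"species absent from every site: {bad}")
    E = env.to_numpy(dtype=float)
    # occupancy-weighted mean: (P^T E) / occupancy
    counts = present.sum(axis=0).astype(float)
    sums = present.T.astype(float) @ E
    means = sums / counts[:, None]
    return pd.DataFrame(means, index=df.columns, columns=env.columns)


def soil_pca_composite(soil: pd.DataFrame):
    """First-axis PCA composite of the soil table.

    Columns are standardized to zero mean and unit variance and the
    correlation matrix eigendecomposed.  Returns ``(scores, variance_explained,
    loadings)`` where ``scores`` is the per-site first-axis score,
    ``variance_explained`` the fraction of total variance on that axis, and
    ``loadings`` the full loading matrix (columns PC1, PC2, ...).  The first
    axis sign is fixed so the first retained soil column loads non-negatively.
    Zero-variance columns are dropped with a warning.
    """
    if soil.shape[0] < 2:
        raise ValueError("PCA needs at least 2 sites")
    X = soil.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(soil.columns[~keep])
        logger.warning("dropping zero-variance soil column(s): %s", dropped)
        soil = soil.loc[:, keep]
        X, sd = X[:, keep], sd[keep]
    if soil.shape[1] == 0:
        raise ValueError("no soil columns with positive variance")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    R = np.atleast_2d(R)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
    if evecs[0, 0] < 0:
        evecs[:, 0] = -evecs[:, 0]
    scores = pd.Series(Z @ evecs[:, 0], index=soil.index, name="soil_composite")
    variance_explained = float(evals[0] / evals.sum())
    loadings = pd.DataFrame(
        evecs, index=soil.columns, columns=[f"PC{i+1}" for i in range(soil.shape[1])]
    )
    return scores, variance_explained, loadings


def _vif_values(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1 / (1 - R^2_j) regressing column j on the others + intercept."""
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        tss = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
        out[j] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_screen(X: pd.DataFrame, threshold: float = 10.0):
    """Iteratively drop the largest-VIF predictor until all VIF < threshold.

    Returns ``(retained, report)``: the retained DataFrame and a report
    frame with one row per iteration step recording the VIFs and the column
    removed (NaN VIFs denote perfect collinearity, treated as removable
    first).  Ties in VIF are broken by column order.
    """
    if X.shape[0] < X.shape[1] + 1:
        raise ValueError("need at least (number of predictors + 1) observations")
    cols = list(X.columns)
    rows = []
    while True:
        vals = _vif_values(X[cols].to_numpy(dtype=float))
        record = dict(zip(cols, vals))
        worst = int(np.nanargmax(vals))
        if len(cols) > 1 and (np.isinf(vals[worst]) or vals[worst] >= threshold):
            removed = cols[worst]
            rows.append({"removed": removed, **record})
            cols.remove(removed)
            logger.info("VIF screening removed %r (VIF=%.3g)", removed, vals[worst])
        else:
            rows.append({"removed": None, **record})
            break
    report = pd.DataFrame(rows)
    return X[cols], report


def c3_relative_abundance(Y, pathway: pd.Series):
    """Relative abundance within a species' photosynthetic-pathway group.

    Per plot, each species' abundance is divided by the plot total over
    species sharing its pathway (C3 with C3, C4 with C4); within a plot the
    values for each pathway sum to 1.  Plots where a pathway has zero total
    get NaN for that pathway's species.  Returns ``(per_plot, per_species)``
    where the species-level predictor is the mean of the per-plot values
    over the plots where the species occurs.
    """
    df = Y if isinstance(Y, pd.DataFrame) else pd.DataFrame(np.asarray(Y, float))
    pathway = pathway.reindex(df.columns)
    bad = pathway.isna() | ~pathway.isin(["C3", "C4"])
    if bad.any():
        raise ValueError(f"species without C3/C4 label: {list(df.columns[bad])}")
    A = df.to_numpy(dtype=float)
    rel = np.full_like(A, np.nan, dtype=float)
    for pw in ("C3", "C4"):
        sel = (pathway == pw).to_numpy()
        if not sel.any():
            continue
        totals = A[:, sel].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel[:, sel] = np.where(totals[:, None] > 0, A[:, sel] / totals[:, None], np.nan)
    per_plot = pd.DataFrame(rel, index=df.index, columns=df.columns)
    vals = []
    for j, sp in enumerate(df.columns):
        occ = A[:, j] > 0
        v = rel[occ, j]
        v = v[~np.isnan(v)]
        vals.append(float(v.mean()) if v.size else np.nan)
    per_species = pd.Series(vals, index=df.columns, name="c3_relative_abundance")
    return per_plot, per_species


def specific_leaf_area(leaf_area_cm2, dry_weight_g):
    """SLA (cm^2/g) = leaf area / leaf dry weight; inputs must be positive."""
    area = np.asarray(leaf_area_cm2, dtype=float)
    weight = np.asarray(dry_weight_g, dtype=float)
    if np.any(area <= 0) or np.any(weight <= 0):
        raise ValueError("leaf area and dry weight must be positive")
    out = area / weight
    return out.item() if out.ndim == 0 else out


def assemble_predictor_table(
    Y,
    env: pd.DataFrame,
    traits: pd.DataFrame,
    species_mpd: pd.Series,
    scbd_eff: pd.Series,
    soil_columns=None,
    aridity_column: str = "aridity",
) -> tuple[pd.DataFrame, dict]:
    """Build the species-level modeling table.

    Computes the soil PCA composite at site level, lifts aridity and the
    composite to species level over occupied plots, attaches traits, MPD,
    the pathway relative abundance and effective SCBD.  Returns the table
    and a report dict (PCA loadings and variance explained).
    """
    df = Y if isinstance(Y, pd.DataFrame) else pd.DataFrame(np.asarray(Y, float))
    if soil_columns is None:
        soil_columns = [c for c in env.columns if c != aridity_column]
    scores, var_explained, loadings = soil_pca_composite(env[list(soil_columns)])
    site_env = pd.DataFrame({aridity_column: env[aridity_column], "soil": scores})
    sp_env = species_env_means(df, site_env)
    _, c3_rel = c3_relative_abundance(df, traits["pathway"])
    table = pd.DataFrame(
        {
            "aridity": sp_env[aridity_column],
            "soil": sp_env["soil"],
            "height_cm": traits["height_cm"].reindex(df.columns),
            "sla_cm2_per_g": traits["sla_cm2_per_g"].reindex(df.columns),
            "leaf_production": traits["leaf_production"].reindex(df.columns),
            "pathway": traits["pathway"].reindex(df.columns),
            "c3_relative_abundance": c3_rel,
            "species_mpd": species_mpd.reindex(df.columns),
            "scbd_eff": scbd_eff.reindex(df.columns),
        }
    )
    report = {
        "soil_pc1_variance_explained": var_explained,
        "soil_loadings": loadings["PC1"].to_dict(),
    }
    return table, report
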