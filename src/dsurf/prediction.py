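"""Apply a fitted density surface model to a prediction grid.

Produces per-cell density/SE/CV, parkwide totals with log-normal intervals,
threshold-area summaries, and rank correlation between two density surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import lognormal_ci, preseason_backcalc  # re-exported
from .covariates import PcaModel, score
from .dsm import DsmFit

__all__ = [
    "predict_grid",
    "total_abundance",
    "area_fraction_below",
    "spearman_surfaces",
    "preseason_backcalc",
    "SurfaceSummary",
]


@dataclass
class SurfaceSummary:
    n_hat: float
    ci_lo: float
    ci_hi: float
    cv: float
    area_total_km2: float
    n_cells: int
    density_min: float
    density_max: float


def predict_grid(
    fit: DsmFit, pca: PcaModel | None, grid: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Predict density, SE and CV for every usable grid cell.

    PC scores are computed from the grid's landscape covariates with the
    *training* standardization constants when ``pca`` is given.  Cells with
    missing coordinates/covariates are excluded; the count of exclusions is
    returned alongside the cell table.
    """
    grid = grid.copy()
    needed = ["x", "y", "area"]
    if pca is not None:
        missing_cols = [c for c in pca.covariates if c not in grid.columns]
        if missing_cols:
            raise ValueError(f"grid lacks PCA covariates: {missing_cols}")
        needed = needed + list(pca.covariates)
    ok = grid[needed].notna().all(axis=1) & np.isfinite(
        grid[needed].to_numpy(float)
    ).all(axis=1)
    n_excluded = int((~ok).sum())
    cells = grid.loc[ok].copy()
    if pca is not None:
        pcs = score(pca, cells)
        for col in pcs.columns:
            cells[col] = pcs[col].to_numpy()
    pc_terms = [t for t in fit.spec.terms if t != "xy"]
    lacking = [t for t in pc_terms if t not in cells.columns]
    if lacking:
        raise ValueError(f"grid rows lack model terms {lacking}; supply a PCA model")

    X = fit.design(cells)
    eta = X @ fit.beta
    density = np.exp(eta)
    var_eta = np.einsum("ij,jk,ik->i", X, fit.V, X)
    var_eta = np.clip(var_eta, 0.0, None)
    se = density * np.sqrt(var_eta)  # delta method through the log link
    cells["density"] = density
    cells["abundance"] = density * cells["area"].to_numpy(float)
    cells["se"] = se
    cells["cv"] = np.where(density > 0, se / density, np.nan)
    return cells, n_excluded


def total_abundance(
    fit: DsmFit, cells: pd.DataFrame, level: float = 0.95
) -> SurfaceSummary:
    """Parkwide total: N = sum(density * area), CV through the propagated
    coefficient covariance, log-normal interval.

    When detection variance was propagated the reported CV is floored at the
    delta-method combination sqrt(cv_gam_base^2 + cv_detection^2), so
    propagation can never shrink the uncertainty below its components.
    """
    if len(cells) == 0:
        raise ValueError("no prediction cells")
    X = fit.design(cells)
    area = cells["area"].to_numpy(float)
    mu = np.exp(X @ fit.beta) * area
    n_hat = float(mu.sum())
    grad = X.T @ mu  # d N / d beta
    var_n = float(grad @ fit.V @ grad)
    cv = np.sqrt(max(var_n, 0.0)) / n_hat if n_hat > 0 else np.nan
    if fit.V_prop is not None and np.isfinite(fit.cv_det_rel):
        cv_base = np.sqrt(max(float(grad @ fit.V_base @ grad), 0.0)) / n_hat
        cv = max(cv, float(np.hypot(cv_base, fit.cv_det_rel)))
    lo, hi = lognormal_ci(n_hat, cv, level=level)
    dens = cells["density"].to_numpy(float)
    return SurfaceSummary(
        n_hat=n_hat, ci_lo=lo, ci_hi=hi, cv=float(cv),
        area_total_km2=float(area.sum()), n_cells=len(cells),
        density_min=float(dens.min()), density_max=float(dens.max()),
    )


def area_fraction_below(cells: pd.DataFrame, threshold: float) -> float:
    """Percent of total area in cells with density <= threshold (inclusive)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    area = cells["area"].to_numpy(float)
    dens = cells["density"].to_numpy(float)
    return float(100.0 * area[dens <= threshold].sum() / area.sum())


def spearman_surfaces(surface_a: pd.DataFrame, surface_b: pd.DataFrame) -> float:
    """Spearman rank correlation of two density surfaces on shared cell ids."""
    merged = surface_a[["cell_id", "density"]].merge(
        surface_b[["cell_id", "density"]], on="cell_id", suffixes=("_a", "_b")
    )
    if len(merged) < 3:
        raise ValueError("need at least 3 shared cells")
    rho = stats.spearmanr(merged["density_a"], merged["density_b"]).statistic
    return float(rho)
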