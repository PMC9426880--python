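"""Horvitz-Thompson-corrected abundance at segment and survey level.

Each detected group of size ``s_i`` with detection probability ``p_i``
contributes ``s_i / p_i`` estimated individuals; the design-based variance
treats the survey unit as the sampling unit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def ht_correction(sizes, p_i) -> float:
    """Horvitz-Thompson total: sum of s_i / p_i.  Additive over disjoint sets."""
    sizes = np.asarray(sizes, float)
    p_i = np.asarray(p_i, float)
    if p_i.size and (np.any(p_i <= 0) or np.any(p_i > 1)):
        raise ValueError("detection probabilities must lie in (0, 1]")
    return float(np.sum(sizes / p_i)) if sizes.size else 0.0


def ht_segments(obs: pd.DataFrame, segments: pd.DataFrame, p_i: np.ndarray) -> pd.DataFrame:
    """Per-segment HT-corrected abundance table.

    Every segment appears (zero rows for segments without detections) and the
    per-segment values sum to the single-pass HT total.
    """
    obs = obs.copy()
    obs["_ht"] = np.asarray(obs["group_size"], float) / np.asarray(p_i, float)
    if (np.asarray(p_i) <= 0).any():
        raise ValueError("detection probabilities must lie in (0, 1]")
    grouped = obs.groupby("segment_id")
    agg = grouped.agg(
        n_hat=("_ht", "sum"),
        raw_groups=("group_size", "size"),
        raw_individuals=("group_size", "sum"),
    )
    out = segments[["segment_id", "transect_id", "unit_id", "length", "x", "y"]].copy()
    out = out.merge(agg, on="segment_id", how="left")
    out[["n_hat", "raw_groups", "raw_individuals"]] = (
        out[["n_hat", "raw_groups", "raw_individuals"]].fillna(0.0)
    )
    out["raw_groups"] = out["raw_groups"].astype(int)
    out["raw_individuals"] = out["raw_individuals"].astype(int)
    return out


def encounter_rate(n_groups: int, effort_km: float) -> float:
    """Detected groups per km of transect effort."""
    if effort_km <= 0:
        raise ValueError("effort must be > 0")
    return n_groups / effort_km


def _unit_level_var(per_unit_totals: np.ndarray, per_unit_effort: np.ndarray) -> float:
    """Design-based variance of the HT total with survey units as sampling
    units (ratio-estimator form, Fewster-style R2)."""
    K = per_unit_totals.size
    if K < 2:
        return np.nan
    T = per_unit_totals.sum()
    L = per_unit_effort.sum()
    resid = per_unit_totals - per_unit_effort * (T / L)
    return float(K / (K - 1) * np.sum(resid**2))


def cds_total(
    obs: pd.DataFrame,
    p_i: np.ndarray,
    effort_km: float,
    truncation_m: float,
    region_area_km2: float,
    detection_vcov: np.ndarray | None = None,
    detection_grad: np.ndarray | None = None,
    unit_ids: pd.Series | None = None,
    unit_efforts: pd.Series | None = None,
) -> dict:
    """Conventional distance-sampling total: N = (A / 2wL) * sum(s_i/p_i).

    The CV combines the unit-level encounter/HT variance with the
    detection-parameter variance (delta method, ``detection_grad`` = gradient
    of the HT sum w.r.t. detection parameters) as summed squared CVs.
    """
    if effort_km <= 0:
        raise ValueError("zero effort")
    w_km = truncation_m / 1000.0
    covered = 2.0 * w_km * effort_km
    if region_area_km2 < covered - 1e-9:
        raise ValueError("region area smaller than covered area")
    ht = ht_correction(obs["group_size"], p_i)
    n_hat = (region_area_km2 / covered) * ht

    cv = np.nan
    if unit_ids is not None and unit_efforts is not None and ht > 0:
        per_unit = (
            pd.DataFrame({"unit_id": np.asarray(unit_ids), "ht": np.asarray(obs["group_size"], float) / np.asarray(p_i, float)})
            .groupby("unit_id")["ht"].sum()
        )
        eff = unit_efforts.astype(float)
        totals = per_unit.reindex(eff.index).fillna(0.0).to_numpy()
        var_er = _unit_level_var(totals, eff.to_numpy())
        cv_er2 = var_er / ht**2 if ht > 0 else np.nan
        cv_det2 = 0.0
        if detection_vcov is not None and detection_grad is not None:
            var_det = float(detection_grad @ detection_vcov @ detection_grad)
            cv_det2 = max(var_det, 0.0) / ht**2
        cv = float(np.sqrt(cv_er2 + cv_det2))
    return {
        "N_hat": float(n_hat),
        "CV": cv,
        "ht_total": ht,
        "covered_area_km2": covered,
        "coverage_fraction": covered / region_area_km2,
    }


def ht_gradient(obs: pd.DataFrame, fit) -> np.ndarray:
    """Gradient of the HT sum w.r.t. the detection parameter vector."""
    from .detection import average_p

    design = fit.design_for(obs)
    sizes = obs["group_size"].to_numpy(float)
    theta = fit.theta

    def ht_of(t):
        if fit.log_b is not None:
            beta, b = t[:-1], float(np.exp(t[-1]))
        else:
            beta, b = t, None
        p = average_p(np.exp(design @ beta), fit.model.truncation, key=fit.model.key, b=b)
        return float(np.sum(sizes / p))

    grad = np.empty_like(theta)
    for i in range(theta.size):
        step = 1e-5 * max(1.0, abs(theta[i]))
        tp = theta.copy(); tp[i] += step
        tm = theta.copy(); tm[i] -= step
        grad[i] = (ht_of(tp) - ht_of(tm)) / (2 * step)
    return grad


def lognormal_ci(n_hat: float, cv: float, level: float = 0.95) -> tuple[float, float]:
    """Log-normal interval: C = exp(z * sqrt(ln(1 + CV^2))); (N/C, N*C)."""
    if cv < 0:
        raise ValueError("CV must be >= 0")
    if cv == 0:
        return (n_hat, n_hat)
    z = stats.norm.ppf(0.5 + level / 2.0)
    c = float(np.exp(z * np.sqrt(np.log1p(cv**2))))
    return (n_hat / c, n_hat * c)


def preseason_backcalc(winter_n: float, harvest_n: float, area_km2: float) -> dict:
    """Back-calculate the pre-hunting-season population from winter estimate
    plus harvest: preseason = winter + harvest."""
    if winter_n < 0 or harvest_n < 0:
        raise ValueError("inputs must be >= 0")
    if area_km2 <= 0:
        raise ValueError("area must be > 0")
    preseason = winter_n + harvest_n
    return {
        "preseason_n": preseason,
        "preseason_density": preseason / area_km2,
        "harvest_fraction": (harvest_n / preseason) if preseason > 0 else 0.0,
    }
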