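"""End-to-end orchestration: truncate -> detection -> HT -> PCA -> DSM ->
variance propagation -> prediction -> summary report.

Every stage's artifacts are serialized under the output directory; the
machine-readable report embeds a provenance block (input hashes, seed,
package version) so identical configuration and inputs yield identical
reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abundance import encounter_rate, ht_segments, lognormal_ci
from .covariates import contributions, fit_pca, score
from .detection import (
    DetectionModel,
    all_subsets_models,
    fit_detection,
    rank_and_select,
    rank_table,
)
from .dsm import DsmSpec, all_subsets_select, fit_dsm, propagate_detection_variance, term_significance
from .prediction import area_fraction_below, predict_grid, total_abundance
from .survey_data import (
    LANDSCAPE_COVARIATES,
    effort_area_km2,
    read_grid,
    read_observations,
    read_segments,
    truncate_observations,
    write_table,
)

log = logging.getLogger("dsurf")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")


@dataclass
class RunConfig:
    obs_path: str
    segments_path: str
    grid_path: str | None = None
    out_dir: str = "dsurf_run"
    truncation: float = 350.0
    detection_keys: tuple[str, ...] = ("half_normal", "hazard_rate")
    detection_covariates: tuple[str, ...] = ("canopy",)
    detection_all_subsets: bool = True
    use_pca: bool = True
    dsm_pool: tuple[str, ...] = ("xy", "PC1", "PC2", "PC3")
    k_xy: int = 25
    k_pc: int = 10
    delta_aic: float = 2.0
    density_threshold: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.delta_aic <= 0:
            raise ValueError("delta_aic window must be > 0")

    def validate_paths(self):
        for p in (self.obs_path, self.segments_path, self.grid_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full two-stage analysis; returns the report dict."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "truncation_m": config.truncation,
            "inputs": {
                "obs": _sha256(config.obs_path),
                "segments": _sha256(config.segments_path),
                "grid": _sha256(config.grid_path) if config.grid_path else None,
            },
        }
    }

    stage = "ingest"
    try:
        obs = read_observations(config.obs_path)
        segments = read_segments(config.segments_path)
        n_before = len(obs)
        obs_t = truncate_observations(obs, config.truncation)
        log.info("truncation: %d -> %d observations", n_before, len(obs_t))
        effort_km = segments["length"].sum() / 1000.0
        report[stage] = {
            "n_obs": n_before,
            "n_obs_truncated": len(obs_t),
            "n_segments": len(segments),
            "effort_km": float(effort_km),
            "encounter_rate_groups_per_km": encounter_rate(n_before, effort_km),
        }

        stage = "detection"
        if config.detection_all_subsets:
            models = all_subsets_models(
                config.detection_covariates, keys=config.detection_keys,
                truncation=config.truncation,
            )
        else:
            models = [
                DetectionModel(key=k, covariates=config.detection_covariates, truncation=config.truncation)
                for k in config.detection_keys
            ]
        fits = []
        for m in models:
            try:
                fits.append(fit_detection(obs_t, m, seed=config.seed))
            except Exception as exc:  # noqa: BLE001 - per-model failure tolerated
                log.warning("detection fit failed for %s: %s", m.label, exc)
        det = rank_and_select(fits, delta_aic=config.delta_aic)
        dtable = rank_table(fits)
        write_table(dtable, out / "detection_models.csv")
        report[stage] = {
            "selected": det.model.label,
            "p_bar": det.p_bar,
            "p_bar_se": det.p_bar_se,
            "cvm_p": det.cvm_p,
            "n_candidates": len(fits),
        }

        stage = "ht_abundance"
        p_i = det.p_for(obs_t)
        seg_ab = ht_segments(obs_t, segments, p_i)
        seg_ab["effort_area"] = effort_area_km2(segments, config.truncation).to_numpy()
        for cov in LANDSCAPE_COVARIATES:
            if cov in segments.columns:
                seg_ab[cov] = segments[cov].to_numpy()
        write_table(seg_ab, out / "segment_abundance.csv")
        report[stage] = {"ht_total_surveyed": float(seg_ab["n_hat"].sum())}

        stage = "pca"
        pca = None
        if config.use_pca:
            covs = [c for c in LANDSCAPE_COVARIATES if c in seg_ab.columns]
            pca = fit_pca(seg_ab, covs)
            pcs = score(pca, seg_ab, n_components=max(pca.n_retained, 3))
            for col in pcs.columns:
                seg_ab[col] = pcs[col].to_numpy()
            (out / "pca_model.json").write_text(pca.to_json())
            write_table(contributions(pca).reset_index(names="covariate"), out / "pca_contributions.csv")
            report[stage] = {
                "eigenvalues": pca.eigenvalues.tolist(),
                "pct_variance": pca.pct_variance.tolist(),
                "n_retained": pca.n_retained,
            }
        pool = tuple(t for t in config.dsm_pool if t == "xy" or pca is not None)

        if not pool:
            # stage-1-only (CDS) report
            stage = "cds"
            from .abundance import cds_total, ht_gradient

            if config.grid_path:
                grid = read_grid(config.grid_path)
                region_area = float(grid["area"].sum())
            else:
                region_area = 2.0 * (config.truncation / 1000.0) * effort_km
            unit_eff = segments.groupby("unit_id")["length"].sum() / 1000.0
            cds = cds_total(
                obs_t, p_i, effort_km, config.truncation, region_area,
                detection_vcov=det.vcov, detection_grad=ht_gradient(obs_t, det),
                unit_ids=obs_t["unit_id"], unit_efforts=unit_eff,
            )
            ci = lognormal_ci(cds["N_hat"], cds["CV"]) if np.isfinite(cds["CV"]) else (np.nan, np.nan)
            report[stage] = {**cds, "ci_lo": ci[0], "ci_hi": ci[1], "region_area_km2": region_area}
            (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
            return report

        stage = "dsm"
        spec = DsmSpec(terms=pool, k_xy=config.k_xy, k_pc=config.k_pc)
        table, fits_by_terms, selected = all_subsets_select(
            seg_ab, pool=pool, spec=spec, delta_aic=config.delta_aic
        )
        write_table(table, out / "dsm_models.csv")
        report[stage] = {
            "selected_terms": list(selected.spec.terms),
            "edf": selected.edf_by_term,
            "power": selected.power,
            "aic": selected.aic,
        }

        stage = "variance_propagation"
        propagate_detection_variance(selected, det, obs_t)
        sig = term_significance(selected)
        write_table(sig, out / "dsm_terms.csv")
        report[stage] = {"cv_det_rel": selected.cv_det_rel}

        stage = "prediction"
        if config.grid_path:
            grid = read_grid(config.grid_path)
            cells, n_excluded = predict_grid(selected, pca, grid)
            write_table(
                cells[["cell_id", "x", "y", "area", "density", "abundance", "se", "cv"]],
                out / "cells.csv",
            )
            summary = total_abundance(selected, cells)
            report[stage] = {
                "N_hat": summary.n_hat,
                "ci_lo": summary.ci_lo,
                "ci_hi": summary.ci_hi,
                "cv": summary.cv,
                "n_cells": summary.n_cells,
                "n_cells_excluded": n_excluded,
                "area_km2": summary.area_total_km2,
                "density_min": summary.density_min,
                "density_max": summary.density_max,
                "pct_area_below_threshold": area_fraction_below(cells, config.density_threshold),
                "density_threshold": config.density_threshold,
            }
    except Exception as exc:
        (out / "report.partial.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        raise PipelineError(stage, exc) from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
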