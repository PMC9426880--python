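"""Survey domain types, flat-file I/O, truncation, segmentization and
observation-to-segment assignment.

Tables move through the pipeline as :class:`pandas.DataFrame` objects with a
fixed column dialect (see :data:`OBS_COLUMNS`, :data:`SEGMENT_COLUMNS`,
:data:`GRID_COLUMNS`).  Coordinates are carried in kilometres internally;
readers convert from metres when a schema declares metre units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CANOPY_LEVELS = ("hardwood", "mixed", "open")

#: canonical observation-table columns
OBS_COLUMNS = [
    "obs_id",
    "unit_id",
    "transect_id",
    "segment_id",
    "perp_distance",
    "group_size",
    "canopy",
    "cloud_cover",
    "temperature",
    "fatigue_hours",
    "along_track",
]

#: canonical segment-table columns (landscape covariates follow these)
SEGMENT_COLUMNS = ["segment_id", "transect_id", "unit_id", "length", "x", "y"]

#: canonical prediction-grid columns (landscape covariates follow these)
GRID_COLUMNS = ["cell_id", "x", "y", "area"]

#: landscape covariates at segment and grid level
LANDSCAPE_COVARIATES = [
    "elevation",
    "snow_days",
    "dist_agriculture",
    "dist_developed",
    "dist_forest",
    "dist_shrub",
    "dist_timber",
    "dist_wetland",
    "dist_water",
]


class SchemaError(ValueError):
    """A required column is missing or a value fails validation."""


@dataclass(frozen=True)
class SurveyDesign:
    """Geometry of the repeating survey unit.

    Defaults mirror a 10 km x 3 km unit holding 3 parallel 10-km transects
    1 km apart, each cut into four 2.5-km segments.
    """

    truncation: float = 350.0  # m
    unit_length_km: float = 10.0
    unit_width_km: float = 3.0
    transect_spacing_km: float = 1.0
    transects_per_unit: int = 3
    segments_per_transect: int = 4

    def __post_init__(self) -> None:
        if self.truncation <= 0:
            raise ValueError("truncation must be > 0")
        if self.segments_per_transect < 1:
            raise ValueError("segments_per_transect must be >= 1")

    @property
    def segment_length_km(self) -> float:
        return self.unit_length_km / self.segments_per_transect

    @property
    def transect_length_km(self) -> float:
        return self.unit_length_km


DEFAULT_OBS_SCHEMA: Mapping[str, str] = {c: c for c in OBS_COLUMNS}


def _require_columns(df: pd.DataFrame, required: Sequence[str], schema: Mapping[str, str]) -> None:
    for canonical in required:
        source = schema.get(canonical, canonical)
        if source not in df.columns:
            raise SchemaError(f"missing required column {source!r} (for {canonical!r})")


def read_observations(path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read an observation table from CSV.

    Parameters
    ----------
    path : str or file-like
        CSV file with one detected group per row.
    schema : mapping, optional
        Maps canonical column names (:data:`OBS_COLUMNS`) to the file's
        column names.  Unmapped canonical names are looked up verbatim.

    Returns
    -------
    pandas.DataFrame
        Canonical observation table; optional columns absent from the file
        are filled with NA.
    """
    schema = dict(DEFAULT_OBS_SCHEMA, **(schema or {}))
    raw = pd.read_csv(path)
    _require_columns(raw, ["perp_distance", "group_size"], schema)
    out = pd.DataFrame(index=raw.index)
    for canonical in OBS_COLUMNS:
        source = schema.get(canonical, canonical)
        out[canonical] = raw[source] if source in raw.columns else pd.NA
    try:
        out["perp_distance"] = pd.to_numeric(out["perp_distance"], errors="raise")
    except (ValueError, TypeError) as exc:
        bad = pd.to_numeric(out["perp_distance"], errors="coerce")
        rows = list(out.index[bad.isna() & out["perp_distance"].notna()])
        raise SchemaError(f"non-numeric perp_distance at rows {rows}") from exc
    out["group_size"] = pd.to_numeric(out["group_size"], errors="raise").astype(int)
    validate_observations(out)
    return out


def validate_observations(obs: pd.DataFrame) -> None:
    """Enforce record invariants: distances >= 0, sizes >= 1, canopy levels."""
    if (obs["perp_distance"] < 0).any():
        raise SchemaError("perp_distance must be >= 0")
    if (obs["group_size"] < 1).any():
        raise SchemaError("group_size must be >= 1")
    canopy = obs["canopy"].dropna()
    bad = set(canopy.unique()) - set(CANOPY_LEVELS)
    if bad:
        raise SchemaError(f"unknown canopy levels {sorted(bad)!r}; expected {CANOPY_LEVELS}")


def read_segments(path) -> pd.DataFrame:
    """Read a segment table (CSV, canonical dialect, coordinates in km)."""
    df = pd.read_csv(path)
    for col in SEGMENT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    if (df["length"] <= 0).any():
        raise SchemaError("segment length must be > 0")
    return df


def read_grid(path) -> pd.DataFrame:
    """Read a prediction-grid table (CSV, canonical dialect)."""
    df = pd.read_csv(path)
    for col in GRID_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write any pipeline table as RFC-4180 CSV with a header row."""
    df.to_csv(path, index=False, lineterminator="\r\n")


def truncate_observations(obs: pd.DataFrame, w: float) -> pd.DataFrame:
    """Keep observations with perpendicular distance <= ``w`` (metres).

    The boundary is inclusive, order is preserved, and truncating twice at
    w' >= w equals a single truncation at w.
    """
    if not w > 0:
        raise ValueError(f"truncation distance must be > 0, got {w}")
    return obs.loc[obs["perp_distance"] <= w].copy()


def segmentize(design: SurveyDesign, transects: pd.DataFrame) -> pd.DataFrame:
    """Cut transects into contiguous equal segments.

    Parameters
    ----------
    design : SurveyDesign
    transects : DataFrame
        One row per transect with columns ``transect_id``, ``unit_id``,
        ``length`` (m), ``x0``, ``y0`` (km, transect start) and ``heading``
        (radians, direction of travel; optional, default 0 = +x).

    Returns
    -------
    DataFrame
        Segment table with midpoints on the transect line.  Per-transect
        segment lengths sum exactly to the transect length.
    """
    if (transects["length"] <= 0).any():
        raise ValueError("zero-length transect")
    nseg = design.segments_per_transect
    rows = []
    for t in transects.itertuples(index=False):
        length_m = float(t.length)
        heading = float(getattr(t, "heading", 0.0))
        dx, dy = np.cos(heading), np.sin(heading)
        seg_len = length_m / nseg
        for k in range(nseg):
            mid_m = (k + 0.5) * seg_len
            rows.append(
                {
                    "segment_id": f"{t.transect_id}-s{k + 1}",
                    "transect_id": t.transect_id,
                    "unit_id": t.unit_id,
                    "length": seg_len,
                    "x": float(t.x0) + dx * mid_m / 1000.0,
                    "y": float(t.y0) + dy * mid_m / 1000.0,
                    "seg_index": k,
                    "along_start": k * seg_len,
                    "along_end": (k + 1) * seg_len,
                }
            )
    return pd.DataFrame(rows)


class UnassignedObservationError(ValueError):
    """Observations fall outside every transect's along-track extent."""

    def __init__(self, obs_ids):
        self.obs_ids = list(obs_ids)
        super().__init__(f"observations outside transect extent: {self.obs_ids}")


def assign_to_segments(obs: pd.DataFrame, segments: pd.DataFrame) -> pd.DataFrame:
    """Fill ``segment_id`` from ``transect_id`` + ``along_track`` position.

    Bins are left-closed right-open; the final segment is right-closed, and a
    tie at an interior boundary goes to the downstream segment.
    """
    obs = obs.copy()
    by_transect = {tid: g.sort_values("along_start") for tid, g in segments.groupby("transect_id")}
    assigned = []
    missing = []
    for row in obs.itertuples():
        tid = row.transect_id
        pos = float(row.along_track)
        segs = by_transect.get(tid)
        if segs is None:
            missing.append(row.obs_id)
            assigned.append(None)
            continue
        ends = segs["along_end"].to_numpy()
        starts = segs["along_start"].to_numpy()
        total = ends[-1]
        if pos < starts[0] or pos > total:
            missing.append(row.obs_id)
            assigned.append(None)
            continue
        # left-closed/right-open except the last bin
        idx = int(np.searchsorted(ends, pos, side="right"))
        idx = min(idx, len(ends) - 1)
        assigned.append(segs["segment_id"].iloc[idx])
    if missing:
        raise UnassignedObservationError(missing)
    obs["segment_id"] = assigned
    return obs


def effort_area_km2(segments: pd.DataFrame, truncation_m: float) -> pd.Series:
    """Strip area per segment, km^2 = 2 * w * length."""
    if truncation_m <= 0:
        raise ValueError("truncation must be > 0")
    return 2.0 * (truncation_m / 1000.0) * (segments["length"] / 1000.0)
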