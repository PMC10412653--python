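"""Reading/writing cell tables, ROI polygons and the cohort table.

Cell tables are plain CSV/TSV with micrometer coordinates (origin top-left,
y increasing downward).  ROIs are GeoJSON in the QuPath annotation dialect
(FeatureCollection of Polygon features; coordinates assumed μm unless the
dialect declares pixels).  All writers emit a schema-version header comment
so round-trips are self-describing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, shape

SCHEMA_VERSION = "iopn-tme/cell-table-v1"

REQUIRED_COLUMNS = ("cell_id", "x_um", "y_um", "stain", "class")

STAINS = ("HE", "CD3", "CD4", "CD8", "CD20", "CD68", "CD163", "PD1", "PDL1", "MMR")
CLASSES = ("tumor", "immune", "stroma", "unknown")


class SchemaError(ValueError):
    """A table does not conform to the expected column schema."""


@dataclass(frozen=True)
class Dialect:
    """How a foreign cell table encodes coordinates.

    ``units="um"`` passes coordinates through; ``units="px"`` multiplies by
    ``um_per_px``.  Column names may be remapped via ``columns`` (foreign
    name -> canonical name).
    """

    units: str = "um"
    um_per_px: float = 1.0
    columns: dict | None = None
    sep: str = ","


def read_cells(path, dialect: Dialect | None = None) -> pd.DataFrame:
    """Read and validate a cell table.

    Raises :class:`SchemaError` naming the first missing column, and a
    row-level ``ValueError`` (with the offending line) for non-numeric
    coordinates.
    """
    dialect = dialect or Dialect()
    df = pd.read_csv(path, sep=dialect.sep, comment="#", dtype=str)
    if dialect.columns:
        df = df.rename(columns=dialect.columns)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    for col in ("x_um", "y_um"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric {col} {df[col].iloc[row]!r} at data row {row}"
                f" (file line {row + 2})"
            )
        df[col] = coerced
    if df[["x_um", "y_um"]].isna().any().any() or not np.isfinite(
        df[["x_um", "y_um"]].to_numpy(dtype=float)
    ).all():
        raise ValueError(f"{path}: coordinates must be finite")
    if dialect.units == "px":
        df["x_um"] = df["x_um"] * dialect.um_per_px
        df["y_um"] = df["y_um"] * dialect.um_per_px
    elif dialect.units != "um":
        raise ValueError(f"unknown units {dialect.units!r}")
    if "pdl1_pos" in df.columns:
        df["pdl1_pos"] = df["pdl1_pos"].map(
            {"True": True, "False": False, "1": True, "0": False}
        ).astype(bool)
    if "positive" in df.columns:
        df["positive"] = df["positive"].map(
            {"True": True, "False": False, "1": True, "0": False}
        ).astype(bool)
    if df.duplicated(subset=["cell_id", "stain"]).any():
        raise SchemaError(f"{path}: duplicate (cell_id, stain) records")
    return df


def write_cells(cells: pd.DataFrame, path) -> None:
    """Write a cell table as CSV with a schema-version header comment."""
    with open(path, "w") as fh:
        fh.write(f"# {SCHEMA_VERSION}\n")
        cells.to_csv(fh, index=False)


def read_roi_geojson(path) -> list[tuple[str, Polygon]]:
    """Read ROI polygons from a QuPath-style GeoJSON export.

    Accepts a FeatureCollection, a bare Feature, or a bare geometry; the
    label is taken from ``properties.classification.name``, then
    ``properties.name``, else ``"ROI"``.
    """
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("type") == "FeatureCollection":
        features = payload["features"]
    elif payload.get("type") == "Feature":
        features = [payload]
    else:
        features = [{"geometry": payload, "properties": {}}]
    out = []
    for feat in features:
        geom = shape(feat["geometry"])
        props = feat.get("properties") or {}
        label = (props.get("classification") or {}).get("name") or props.get(
            "name", "ROI"
        )
        polys = [geom] if geom.geom_type == "Polygon" else list(geom.geoms)
        for poly in polys:
            out.append((label, poly))
    return out


def _validate_roi(roi: Polygon) -> Polygon:
    if roi.is_empty or roi.area == 0:
        raise ValueError("degenerate ROI polygon (zero area)")
    if not roi.is_valid:
        raise ValueError("ROI polygon is not simple (self-intersecting)")
    return roi


def clip_to_roi(cells: pd.DataFrame, roi: Polygon) -> pd.DataFrame:
    """Keep cells whose centers fall inside the ROI (boundary included)."""
    roi = _validate_roi(roi)
    pts = shapely.points(
        cells["x_um"].to_numpy(dtype=float), cells["y_um"].to_numpy(dtype=float)
    )
    keep = shapely.covers(roi, pts)
    return cells[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Cohort table (per-case IHC scores and clinicopathologic fields)

COHORT_SCORE_COLUMNS = ("CD3", "CD4", "CD8", "CD20", "PD1", "CD68", "CD163")
COHORT_MMR_COLUMNS = ("MLH1", "PMS2", "MSH2", "MSH6")


def load_cohort_table() -> pd.DataFrame:
    """Load the packaged 15-case IOPN cohort table.

    Columns mirror the published per-case layout; values measured on the
    invasive component of the two invasive cases are carried in separate
    ``*_inv`` columns (the bracketed values of the source table).
    """
    with resources.files("iopn_tme.data").joinpath("cohort_iopn.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("id", "CD3", "CD20") if c not in df.columns]
    if missing:
        warnings.warn(f"cohort table missing columns {missing}", stacklevel=2)
    return df
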