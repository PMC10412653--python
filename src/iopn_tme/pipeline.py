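"""End-to-end study pipelines used by the CLI, the analysis drivers and tests.

Two canned study conditions are provided:

* a single-component two-zone slide (tumor-core disc inside a periphery
  annulus) planted at the published core/periphery region composition
  vectors, ~21,000 cells — the region-recovery condition;
* a two-component case (intraductal + invasive tissue) in which the
  invasive component has a proportionally smaller core zone and a
  CD4-down / CD8-up composition shift — the invasive-vs-intraductal
  comparison condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from shapely.ops import unary_union

from . import PHENOTYPES
from .neighborhoods import (
    DEFAULT_GRID_PITCH_UM,
    DEFAULT_WINDOW_DIAMETER_UM,
    composition_matrix,
    raster_neighborhoods,
)
from .regionizer import (
    DEFAULT_K_RANGE,
    RegionModel,
    discover_regions,
    region_composition_summary,
    region_extension,
)
from .synthetic import (
    TUMOR_CORE_COMPOSITION,
    TUMOR_PERIPHERY_COMPOSITION,
    TissueSpec,
    Zone,
    annulus,
    disc,
    generate_tissue,
    two_zone_spec,
)

#: Invasive-component zone compositions: CD4 down, CD8 up relative to the
#: intraductal core/periphery vectors, tumor balancing the simplex.
INVASIVE_CORE_COMPOSITION = {"tumor": 0.4031, "CD4": 0.05, "CD8": 0.50, "CD20": 0.0469}
INVASIVE_PERIPHERY_COMPOSITION = {"tumor": 0.8046, "CD4": 0.010, "CD8": 0.18, "CD20": 0.0054}


def simulate_two_zone_case(seed: int = 0, **kwargs):
    """Single-component study slide: core disc + periphery annulus.

    Returns (cells, ground truth, spec).  ~21,000 cells at the default
    geometry/density.
    """
    spec = two_zone_spec(seed=seed, **kwargs)
    cells, truth = generate_tissue(spec)
    return cells, truth, spec


def simulate_two_component_case(
    seed: int = 0,
    density_per_mm2: float = 1700.0,
    outer_radius_um: float = 2000.0,
    intraductal_core_radius_um: float = 1150.0,
    invasive_core_radius_um: float = 800.0,
):
    """Two-component case: intraductal and invasive tissue side by side.

    The invasive component carries a proportionally smaller core zone and
    zone compositions shifted CD4-down / CD8-up, the pattern seen in the
    invasive components of real cases.  Returns (cells, spec).
    """
    intra_center = (outer_radius_um + 100.0, outer_radius_um + 100.0)
    inv_center = (3 * outer_radius_um + 300.0, outer_radius_um + 100.0)
    zones = (
        Zone(disc(intra_center, intraductal_core_radius_um), TUMOR_CORE_COMPOSITION,
             density_per_mm2, "core_intraductal", "intraductal"),
        Zone(annulus(intra_center, intraductal_core_radius_um, outer_radius_um),
             TUMOR_PERIPHERY_COMPOSITION, density_per_mm2, "periphery_intraductal",
             "intraductal"),
        Zone(disc(inv_center, invasive_core_radius_um), INVASIVE_CORE_COMPOSITION,
             density_per_mm2, "core_invasive", "invasive"),
        Zone(annulus(inv_center, invasive_core_radius_um, outer_radius_um),
             INVASIVE_PERIPHERY_COMPOSITION, density_per_mm2, "periphery_invasive",
             "invasive"),
    )
    spec = TissueSpec(
        width_um=inv_center[0] + outer_radius_um + 100.0,
        height_um=intra_center[1] + outer_radius_um + 100.0,
        zones=zones,
        seed=seed,
    )
    cells, _ = generate_tissue(spec)
    return cells, spec


def tissue_roi(spec: TissueSpec) -> Polygon:
    """ROI covering the whole planted tumor (union of all zones)."""
    return unary_union([z.geometry for z in spec.zones])


@dataclass
class RegionAnalysis:
    """Everything the region-discovery pipeline produces for one case."""

    neighborhoods: pd.DataFrame  # populated + empty windows, with region column
    model: RegionModel
    labels: np.ndarray  # region ids of populated neighborhoods
    composition_summary: pd.DataFrame
    extension: pd.DataFrame | None


def analyze_regions(
    cells: pd.DataFrame,
    roi: Polygon | None = None,
    window_diameter_um: float = DEFAULT_WINDOW_DIAMETER_UM,
    grid_pitch_um: float = DEFAULT_GRID_PITCH_UM,
    k_range=DEFAULT_K_RANGE,
    seed: int = 0,
    **som_kwargs,
) -> RegionAnalysis:
    """Raster neighborhoods → SOM → Davies-Bouldin region discovery."""
    neigh = raster_neighborhoods(
        cells, window_diameter_um=window_diameter_um, grid_pitch_um=grid_pitch_um,
        roi=roi,
    )
    comps = composition_matrix(neigh)
    model = discover_regions(comps, k_range=k_range, seed=seed, **som_kwargs)
    labels = model.labels
    neigh = neigh.copy()
    region_col = pd.Series(pd.NA, index=neigh.index, dtype="Int64")
    region_col.loc[neigh["populated"].to_numpy()] = labels
    neigh["region"] = region_col

    summary = region_composition_summary(labels, comps)
    populated = neigh[neigh["populated"]]
    comp_labels = populated["component"].to_numpy()
    named = pd.unique(comp_labels[(comp_labels != "NA") & (comp_labels != "mixed")])
    extension = None
    if len(named) >= 1:
        mask = np.isin(comp_labels, named)
        extension = region_extension(labels[mask], comp_labels[mask])
    return RegionAnalysis(neigh, model, labels, summary, extension)


def core_periphery_medians(analysis: RegionAnalysis) -> dict[str, float]:
    """Key recovered quantities of the two-region analysis (percent units).

    ``core_median_cd8_pct``: median per-neighborhood CD8 fraction in the
    region with the LOWER median tumor fraction (the immune-rich core
    region, Re1); ``periphery_median_tumor_pct``: median tumor fraction in
    the region with the HIGHER median tumor fraction (Re2).
    """
    s = analysis.composition_summary.set_index("region")
    core_region = s["median_frac_tumor"].idxmin()
    peri_region = s["median_frac_tumor"].idxmax()
    return {
        "k": analysis.model.k,
        "core_median_cd8_pct": 100.0 * float(s.loc[core_region, "median_frac_CD8"]),
        "periphery_median_tumor_pct": 100.0
        * float(s.loc[peri_region, "median_frac_tumor"]),
    }
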