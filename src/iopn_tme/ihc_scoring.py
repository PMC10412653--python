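"""Semi-quantitative IHC scoring: 0-5 HPF score, TPS/CPS, MMR calls.

Lymphocyte/macrophage markers are scored on an ordinal 0-5 scale from
positive-cell counts per 40× high power field (HPF): 0 = negative,
1 = rare (1-10 per HPF), 2 = low (11-20), 3 = moderate (21-30),
4 = high (31-50), 5 = very high (>50).  PD-1 is scored on the single most
positive HPF; CD3, CD4, CD8, CD20, CD68 and CD163 on the mean of the five
most positive HPFs (the mean of counts is binned, so the result is a
single well-defined ordinal score).  PD-L1 is summarized by the tumor
proportion score (TPS, % of viable tumor cells with membrane staining) and
the combined positive score (CPS, positive tumor + immune cells per 100
viable tumor cells, capped at 100).  Mismatch-repair proteins are called
retained/loss from the fraction of stained tumor nuclei.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: 40× field modeled as a circle of diameter 0.55 mm (area ≈ 0.237 mm²).
DEFAULT_HPF_DIAMETER_MM = 0.55

#: right-closed bin edges of the 0-5 score: 0, (0,10], (10,20], (20,30], (30,50], >50
SCORE_BIN_UPPER_EDGES = (0.0, 10.0, 20.0, 30.0, 50.0)

SINGLE_MAX_MARKERS = ("PD1",)
MEAN_TOP5_MARKERS = ("CD3", "CD4", "CD8", "CD20", "CD68", "CD163")


def bin_count(count_per_hpf: float) -> int:
    """Bin a positive-cell count per HPF into the ordinal 0-5 score.

    Accepts non-integer counts (means of several HPFs); bins are closed on
    the right: 0→0, (0,10]→1, (10,20]→2, (20,30]→3, (30,50]→4, (50,∞)→5.
    """
    c = float(count_per_hpf)
    if c < 0:
        raise ValueError("positive-cell count cannot be negative")
    for score, upper in enumerate(SCORE_BIN_UPPER_EDGES):
        if c <= upper:
            return score
    return 5


def marker_score(hpf_counts, rule: str) -> int:
    """Aggregate per-HPF positive counts into one 0-5 marker score.

    ``rule="single_max"`` bins the single most positive HPF (the PD-1
    rule); ``rule="mean_top5"`` bins the mean of the five most positive
    HPFs (the rule for the lymphocyte/macrophage markers).  With fewer
    than five HPFs, mean_top5 falls back to the mean of all with a
    warning.
    """
    counts = np.asarray(list(hpf_counts), dtype=float)
    if counts.size == 0:
        raise ValueError("need at least one HPF count")
    if (counts < 0).any():
        raise ValueError("positive-cell counts cannot be negative")
    if rule == "single_max":
        return bin_count(counts.max())
    if rule == "mean_top5":
        if counts.size < 5:
            warnings.warn(
                f"mean_top5 with only {counts.size} HPFs: using all of them",
                stacklevel=2,
            )
        top = np.sort(counts)[-5:]
        return bin_count(top.mean())
    raise ValueError(f"unknown aggregation rule {rule!r}")


@dataclass(frozen=True)
class HpfSample:
    """One candidate high power field and its positive-cell count."""

    hpf_id: str
    center: tuple[float, float]
    area_mm2: float
    positive_count: int

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0:
            raise ValueError("HPF area must be > 0")
        if self.positive_count < 0:
            raise ValueError("positive count cannot be negative")


def sample_hpfs(
    cells: pd.DataFrame,
    n_hpf: int = 5,
    hpf_diameter_mm: float = DEFAULT_HPF_DIAMETER_MM,
    strategy: str = "most_positive",
    seed: int = 0,
    positive_column: str = "positive",
) -> list[HpfSample]:
    """Emulate the pathologist's choice of HPFs over a slide.

    Candidate circular fields are tiled over the bounding box of the cells
    at one diameter pitch; ``strategy="most_positive"`` returns the
    ``n_hpf`` fields with the highest positive-cell counts (the "five most
    positive HPFs" selection), ``strategy="random"`` a seeded random
    choice of fields.  A slide smaller than one HPF yields a single field
    covering it, with a warning.
    """
    if n_hpf < 1:
        raise ValueError("n_hpf must be >= 1")
    diameter_um = hpf_diameter_mm * 1000.0
    radius_um = diameter_um / 2.0
    area_mm2 = np.pi * (hpf_diameter_mm / 2.0) ** 2
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    pos = (
        cells[positive_column].to_numpy(dtype=bool)
        if positive_column in cells.columns
        else np.ones(len(cells), dtype=bool)
    )
    minx, miny = xy.min(axis=0)
    maxx, maxy = xy.max(axis=0)
    if (maxx - minx) < diameter_um and (maxy - miny) < diameter_um:
        warnings.warn("ROI smaller than one HPF: single covering field", stacklevel=2)
        center = ((minx + maxx) / 2.0, (miny + maxy) / 2.0)
        return [HpfSample("hpf000", center, area_mm2, int(pos.sum()))]

    xs = np.arange(minx + radius_um, maxx - radius_um + 1e-9, diameter_um)
    ys = np.arange(miny + radius_um, maxy - radius_um + 1e-9, diameter_um)
    if xs.size == 0:
        xs = np.array([(minx + maxx) / 2.0])
    if ys.size == 0:
        ys = np.array([(miny + maxy) / 2.0])
    from scipy.spatial import cKDTree

    centers = np.column_stack([g.ravel() for g in np.meshgrid(xs, ys)])
    tree = cKDTree(xy[pos]) if pos.any() else None
    counts = (
        np.array([len(h) for h in tree.query_ball_point(centers, r=radius_um)])
        if tree is not None
        else np.zeros(len(centers), dtype=int)
    )
    fields = [
        HpfSample(f"hpf{i:03d}", (float(cx), float(cy)), area_mm2, int(c))
        for i, ((cx, cy), c) in enumerate(zip(centers, counts))
    ]
    if strategy == "most_positive":
        fields.sort(key=lambda f: (-f.positive_count, f.hpf_id))
        return fields[:n_hpf]
    if strategy == "random":
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(fields), size=min(n_hpf, len(fields)), replace=False)
        return [fields[i] for i in sorted(idx)]
    raise ValueError(f"unknown strategy {strategy!r}")


def tps(pos_tumor_cells: int, viable_tumor_cells: int) -> float:
    """Tumor proportion score: % of viable tumor cells that are PD-L1+."""
    if viable_tumor_cells <= 0:
        raise ValueError("TPS needs a positive viable-tumor-cell denominator")
    if viable_tumor_cells < 100:
        warnings.warn(
            "TPS on fewer than 100 viable tumor cells is unreliable", stacklevel=2
        )
    return 100.0 * pos_tumor_cells / viable_tumor_cells


def cps(pos_tumor_cells: int, pos_immune_cells: int, viable_tumor_cells: int) -> float:
    """Combined positive score: (PD-L1+ tumor + immune cells) per 100
    viable tumor cells, capped at 100."""
    if viable_tumor_cells <= 0:
        raise ValueError("CPS needs a positive viable-tumor-cell denominator")
    raw = 100.0 * (pos_tumor_cells + pos_immune_cells) / viable_tumor_cells
    return min(raw, 100.0)


def mmr_call(fraction_tumor_nuclei_stained: float, threshold: float = 0.01) -> str:
    """Call one MMR protein retained/loss from stained tumor-nucleus fraction.

    Any unequivocal nuclear staining counts as retained expression
    (default threshold 1%); below threshold is expression loss.
    """
    f = float(fraction_tumor_nuclei_stained)
    if not 0 <= f <= 1:
        raise ValueError("stained fraction must lie in [0, 1]")
    return "retained" if f >= threshold else "loss"


MMR_PROTEINS = ("MLH1", "PMS2", "MSH2", "MSH6")


@dataclass
class ScorePanel:
    """Per-case IHC result set in the cohort-table layout."""

    case_id: str
    scores: dict[str, int] = field(default_factory=dict)  # marker -> 0-5
    tps: float | None = None
    cps: float | None = None
    mmr: dict[str, str] = field(default_factory=dict)  # protein -> retained/loss

    def __post_init__(self) -> None:
        for marker, s in self.scores.items():
            if not (isinstance(s, (int, np.integer)) and 0 <= s <= 5):
                raise ValueError(f"{marker}: score must be an integer in 0-5, got {s!r}")
        if self.tps is not None and not 0 <= self.tps <= 100:
            raise ValueError("TPS must lie in [0, 100]")
        if self.cps is not None and not 0 <= self.cps <= 100:
            raise ValueError("CPS must lie in [0, 100]")

    @property
    def mmr_proficient(self) -> bool:
        """True when every MMR protein shows retained expression."""
        return all(self.mmr.get(p) == "retained" for p in MMR_PROTEINS)

    def to_row(self) -> dict:
        row = {"id": self.case_id, **self.scores}
        if self.tps is not None:
            row["TPS"] = self.tps
        if self.cps is not None:
            row["CPS"] = self.cps
        row.update(self.mmr)
        return row


def score_slide(
    cells: pd.DataFrame,
    marker: str,
    n_hpf: int = 5,
    hpf_diameter_mm: float = DEFAULT_HPF_DIAMETER_MM,
    seed: int = 0,
) -> int:
    """Score one marker slide end-to-end: sample HPFs, apply the marker rule."""
    rule = "single_max" if marker in SINGLE_MAX_MARKERS else "mean_top5"
    n_fields = 1 if rule == "single_max" else n_hpf
    # the most-positive selection needs the full candidate ranking either way
    fields = sample_hpfs(
        cells, n_hpf=max(n_fields, n_hpf), hpf_diameter_mm=hpf_diameter_mm,
        strategy="most_positive", seed=seed,
    )
    return marker_score([f.positive_count for f in fields], rule)
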