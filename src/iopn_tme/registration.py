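"""Serial-section alignment and composite multi-marker map construction.

Serial 4 μm sections are nearly rigid replicas of each other, so alignment
is modeled as a least-squares rigid/similarity/affine point transform
(similarity by default — serial sections shear negligibly), optionally
refined by iterative closest point when no explicit landmarks exist.
Positive cells from each aligned IHC section are then projected onto the
H&E reference by greedy nearest-neighbor matching, yielding one composite
map holding tumor/immune/stroma classes and all marker phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.transform import estimate_transform

MODELS = ("rigid", "similarity", "affine")
_SKIMAGE_NAME = {"rigid": "euclidean", "similarity": "similarity", "affine": "affine"}

DEFAULT_MATCH_RADIUS_UM = 10.0  # about one nucleus diameter


@dataclass(frozen=True)
class SectionTransform:
    """A fitted 2-D section-to-reference map (homogeneous 3×3, μm).

    ``rmse`` is the root-mean-square residual per coordinate axis, so for
    isotropic Gaussian jitter of sd σ on perfectly corresponding points it
    converges to σ (not σ√2).
    """

    matrix: np.ndarray
    model: str
    rmse: float
    n_pairs: int

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix[:2, :2].T + self.matrix[:2, 2]

    def inverse(self) -> "SectionTransform":
        inv = np.linalg.inv(self.matrix)
        return replace(self, matrix=inv)

    @property
    def affine_2x3(self) -> np.ndarray:
        return self.matrix[:2, :]


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    # per-axis RMS residual: equals the noise sd under isotropic jitter
    return float(np.sqrt(np.mean((a - b) ** 2)))


def fit_transform(src_points, dst_points, model: str = "similarity") -> SectionTransform:
    """Least-squares transform mapping ``src_points`` onto ``dst_points``.

    Requires ≥2 pairs for rigid/similarity and ≥3 non-collinear pairs for
    affine; reports the residual RMSE on the fitting pairs.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    src = np.asarray(src_points, dtype=float)
    dst = np.asarray(dst_points, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("src and dst must be matching (n, 2) arrays")
    n_min = 3 if model == "affine" else 2
    if len(src) < n_min:
        raise ValueError(f"{model} fit needs at least {n_min} pairs, got {len(src)}")
    if model == "affine":
        centered = src - src.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(src).max())) < 2:
            raise ValueError("affine fit needs non-collinear source points")
    tform = estimate_transform(_SKIMAGE_NAME[model], src, dst)
    mat = np.asarray(tform.params, dtype=float)
    if not np.all(np.isfinite(mat)) or abs(np.linalg.det(mat[:2, :2])) < 1e-12:
        raise ValueError("degenerate correspondence set: transform not invertible")
    fitted = src @ mat[:2, :2].T + mat[:2, 2]
    return SectionTransform(mat, model, _rmse(fitted, dst), len(src))


def refine_icp(
    src_cells: np.ndarray,
    dst_cells: np.ndarray,
    init: SectionTransform | None = None,
    model: str = "similarity",
    max_iter: int = 50,
    tol: float = 1e-3,
) -> SectionTransform:
    """Iterative-closest-point refinement of a section alignment.

    Alternates nearest-neighbor correspondence (src → dst) with a fresh
    least-squares fit until the correspondence RMSE improves by less than
    ``tol`` μm or ``max_iter`` is reached.  The RMSE is non-increasing
    across accepted iterations; a 2× blow-up over the initial RMSE aborts
    with diagnostics.
    """
    src = np.asarray(src_cells, dtype=float)
    dst = np.asarray(dst_cells, dtype=float)
    if len(src) == 0 or len(dst) == 0:
        raise ValueError("ICP requires non-empty source and destination clouds")
    if init is None:
        init = SectionTransform(np.eye(3), model, np.inf, 0)
    tree = cKDTree(dst)

    best = init
    moved = best.apply(src)
    d, idx = tree.query(moved)
    best_rmse = float(np.sqrt(np.mean(d**2) / 2.0))
    initial_rmse = best_rmse
    for _ in range(max_iter):
        candidate = fit_transform(src, dst[idx], model=model)
        moved = candidate.apply(src)
        d, idx = tree.query(moved)
        rmse = float(np.sqrt(np.mean(d**2) / 2.0))
        if rmse > 2 * initial_rmse and rmse > 1e-9:
            raise RuntimeError(
                f"ICP diverged: rmse {rmse:.3f} μm > 2 × initial {initial_rmse:.3f} μm"
            )
        if rmse <= best_rmse:
            best = replace(candidate, rmse=rmse)
            if best_rmse - rmse < tol:
                best_rmse = rmse
                break
            best_rmse = rmse
        else:
            break
    return best


def build_composite(
    he_cells: pd.DataFrame,
    marker_tables: dict[str, pd.DataFrame],
    match_radius_um: float = DEFAULT_MATCH_RADIUS_UM,
) -> pd.DataFrame:
    """Project aligned marker-positive cells onto the H&E reference map.

    Each marker cell is matched to at most one H&E cell (and vice versa)
    by greedy ascending-distance assignment within ``match_radius_um``;
    ties break toward the lowest marker cell_id.  Matched H&E cells gain a
    boolean ``<stain>_pos`` flag and, for previously phenotype-less cells,
    the marker phenotype; unmatched marker cells are appended as immune
    cells of that phenotype.
    """
    if match_radius_um <= 0:
        raise ValueError("match radius must be > 0")
    out = he_cells.copy().reset_index(drop=True)
    he_xy = out[["x_um", "y_um"]].to_numpy(dtype=float)
    tree = cKDTree(he_xy) if len(out) else None

    for stain, table in marker_tables.items():
        flag = f"{stain}_pos"
        out[flag] = False
        pos = table[table["positive"]] if "positive" in table.columns else table
        pos = pos.reset_index(drop=True)
        if len(pos) == 0:
            continue
        m_xy = pos[["x_um", "y_um"]].to_numpy(dtype=float)
        matched_m = np.zeros(len(pos), dtype=bool)
        if tree is not None:
            pairs = tree.query_ball_point(m_xy, r=match_radius_um)
            cand = [
                (np.hypot(*(m_xy[mi] - he_xy[hi])), str(pos["cell_id"].iloc[mi]), mi, hi)
                for mi, hits in enumerate(pairs)
                for hi in hits
            ]
            cand.sort(key=lambda t: (t[0], t[1]))
            used_he = np.zeros(len(out), dtype=bool)
            he_flag = out[flag].to_numpy()
            for _, _, mi, hi in cand:
                if matched_m[mi] or used_he[hi]:
                    continue
                matched_m[mi] = True
                used_he[hi] = True
                he_flag[hi] = True
            out[flag] = he_flag
        if (~matched_m).any():
            extra = pos[~matched_m].copy()
            extra["class"] = "immune"
            extra["phenotype"] = stain
            extra["stain"] = stain
            extra[flag] = True
            out = pd.concat([out, extra], ignore_index=True)
            # appended cells extend the table; existing flags default False
            for col in out.columns:
                if col.endswith("_pos"):
                    out[col] = out[col].fillna(False).astype(bool)
    return out
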