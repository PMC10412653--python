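"""Cell classification: neighborhood-smoothed features and positivity calls.

On the real H&E slides a supervised ensemble-of-randomized-trees classifier
separates tumor / immune / stromal cells from per-cell morphology features
augmented with spatially smoothed copies (mean over 25 and 50 μm discs).
The module reproduces that contract on tabular features; image-based
feature extraction and nuclear segmentation are upstream and out of scope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.ensemble import ExtraTreesClassifier

DEFAULT_SMOOTHING_RADII_UM = (25.0, 50.0)

CLASS_LABELS = ("tumor", "immune", "stroma")


def smooth_features(
    cells: pd.DataFrame,
    features: pd.DataFrame,
    radius_um: float,
) -> pd.DataFrame:
    """Append disc-mean smoothed copies of every feature column.

    For each cell the smoothed value of a feature is the unweighted mean of
    that feature over all cells (the cell itself included) within
    ``radius_um`` of its center (closed disc).  New columns are suffixed
    ``_r<radius>``; radius 0 returns an exact copy of the raw features.
    """
    if radius_um < 0:
        raise ValueError("radius must be >= 0")
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    if len(xy) != len(features):
        raise ValueError("cells and features must align row-wise")
    suffix = f"_r{radius_um:g}"
    out = features.copy()
    if radius_um == 0 or len(xy) == 0:
        for col in features.columns:
            out[col + suffix] = features[col].to_numpy()
        return out
    tree = cKDTree(xy)
    neighbor_lists = tree.query_ball_point(xy, r=radius_um)
    vals = features.to_numpy(dtype=float)
    smoothed = np.empty_like(vals)
    for i, idx in enumerate(neighbor_lists):
        smoothed[i] = vals[idx].mean(axis=0)
    for j, col in enumerate(features.columns):
        out[col + suffix] = smoothed[:, j]
    return out


def train_classifier(
    features: pd.DataFrame,
    labels,
    seed: int = 0,
    n_estimators: int = 200,
) -> ExtraTreesClassifier:
    """Fit the tumor/immune/stroma classifier (randomized-tree ensemble).

    Deterministic given ``seed``; exposes class probabilities through
    ``predict_proba``.  Raises on a single-class training set.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    clf = ExtraTreesClassifier(n_estimators=n_estimators, random_state=seed)
    clf.fit(features.to_numpy(dtype=float), labels)
    clf.feature_names_ = list(features.columns)
    return clf


def apply_classifier(clf: ExtraTreesClassifier, features: pd.DataFrame) -> np.ndarray:
    return clf.predict(features.to_numpy(dtype=float))


def retrain_with_corrections(
    clf: ExtraTreesClassifier,
    features: pd.DataFrame,
    labels,
    corrections: dict[int, str],
    seed: int = 0,
) -> ExtraTreesClassifier:
    """One round of classification review: retrain with corrected labels.

    ``corrections`` maps row index -> corrected class label, mirroring a
    pathologist's review pass; the model is refit from scratch on the
    corrected label vector.
    """
    labels = np.asarray(labels, dtype=object).copy()
    for idx, lab in corrections.items():
        labels[idx] = lab
    return train_classifier(features, labels, seed=seed,
                            n_estimators=clf.n_estimators)


def call_positive(
    cells: pd.DataFrame,
    stain: str,
    threshold: float | None = None,
    intensity_column: str = "intensity",
) -> pd.DataFrame:
    """Flag marker-positive cells on one IHC slide.

    If ``threshold`` is given, ``positive := intensity > threshold``;
    otherwise an existing boolean ``positive`` column is passed through.
    """
    out = cells.copy()
    if threshold is not None:
        if intensity_column not in out.columns:
            raise ValueError(
                f"no {intensity_column!r} column to threshold for stain {stain!r}"
            )
        out["positive"] = out[intensity_column].to_numpy(dtype=float) > threshold
    elif "positive" not in out.columns:
        raise ValueError(
            f"stain {stain!r}: need either an intensity column with a "
            "threshold or a precomputed 'positive' flag"
        )
    out["stain"] = stain
    return out
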