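"""Region discovery: SOM clustering of neighborhood compositions.

Neighborhood composition vectors are quantized with a self-organizing map
(SOM); the map's node weight vectors are then grouped into k regions by
Ward agglomerative clustering, with k chosen by minimizing the
Davies-Bouldin index over a candidate range (ties toward the smallest k).
Each neighborhood inherits the region of its best-matching node.  Region
ids are canonicalized by tumor content: the last region (Re2 when k = 2)
is the one with the highest median tumor-cell fraction, matching the
tumor-dense-periphery / immune-rich-core convention.

The SOM is trained online: at each step one sample is drawn at random, its
best-matching unit (BMU) found by Euclidean distance, and all node weights
pulled toward the sample under a Gaussian neighborhood kernel whose radius
decays from ``sigma`` to 1 while the learning rate decays linearly to ~0.
``n_iter`` counts single-sample weight updates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans

from . import PHENOTYPES

DEFAULT_GRID = (8, 8)
DEFAULT_N_ITER = 2000
DEFAULT_LEARNING_RATE = 0.5
DEFAULT_K_RANGE = (2, 3, 4, 5, 6)


def fit_som(
    data: np.ndarray,
    grid: tuple[int, int] = DEFAULT_GRID,
    n_iter: int = DEFAULT_N_ITER,
    learning_rate: float = DEFAULT_LEARNING_RATE,
    sigma: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Train a SOM on row vectors; returns node weights, shape (rows·cols, d).

    Weights are initialized uniformly within the per-dimension data range.
    Deterministic given ``seed``.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or len(data) < 2:
        raise ValueError("need a 2-D array with at least 2 samples")
    if not np.all(np.isfinite(data)):
        raise ValueError("data must be finite")
    rows, cols = grid
    n_nodes = rows * cols
    if sigma is None:
        sigma = max(rows, cols) / 2.0
    rng = np.random.default_rng(seed)

    lo, hi = data.min(axis=0), data.max(axis=0)
    weights = rng.uniform(lo, hi, size=(n_nodes, data.shape[1]))

    gx, gy = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    node_pos = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
    # pairwise squared grid distances between nodes, precomputed
    grid_d2 = ((node_pos[:, None, :] - node_pos[None, :, :]) ** 2).sum(axis=2)

    sample_idx = rng.integers(0, len(data), size=n_iter)
    for t in range(n_iter):
        frac = t / n_iter
        lr = learning_rate * (1.0 - frac)
        sig = 1.0 + (sigma - 1.0) * (1.0 - frac)
        x = data[sample_idx[t]]
        bmu = int(np.argmin(((weights - x) ** 2).sum(axis=1)))
        h = np.exp(-grid_d2[bmu] / (2.0 * sig * sig))
        weights += (lr * h)[:, None] * (x - weights)
    return weights


def quantization_error(weights: np.ndarray, data: np.ndarray) -> float:
    """Mean distance of each sample to its best-matching node."""
    d = np.linalg.norm(data[:, None, :] - weights[None, :, :], axis=2)
    return float(d.min(axis=1).mean())


def bmu_indices(weights: np.ndarray, data: np.ndarray) -> np.ndarray:
    d2 = ((np.asarray(data, dtype=float)[:, None, :] - weights[None, :, :]) ** 2).sum(
        axis=2
    )
    return d2.argmin(axis=1)


def davies_bouldin(points: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index: mean over clusters of the worst (Sᵢ+Sⱼ)/Mᵢⱼ.

    Sᵢ is the mean Euclidean distance of cluster-i members to their
    centroid, Mᵢⱼ the distance between centroids i and j.  Lower is
    better.  Returns +inf when two clusters share a centroid; raises for
    fewer than 2 clusters or when every pair shares a centroid.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("Davies-Bouldin needs at least 2 clusters")
    centroids = np.stack([points[labels == u].mean(axis=0) for u in uniq])
    spread = np.array(
        [
            np.linalg.norm(points[labels == u] - c, axis=1).mean()
            for u, c in zip(uniq, centroids)
        ]
    )
    m = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=2)
    if np.all(m[np.triu_indices(len(uniq), 1)] == 0):
        raise ValueError("all centroids coincide: dispersion ratio undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (spread[:, None] + spread[None, :]) / m
    np.fill_diagonal(ratio, -np.inf)
    return float(np.max(ratio, axis=1).mean())


def select_regions(
    node_weights: np.ndarray,
    k_range=DEFAULT_K_RANGE,
    method: str = "ward",
    seed: int = 0,
) -> tuple[np.ndarray, int, dict[int, float]]:
    """Group SOM nodes into regions; choose the region count by DB index.

    For each candidate k the node weight vectors are clustered (Ward
    agglomerative by default, k-means behind ``method="kmeans"``), the
    Davies-Bouldin index is computed on the node weights, and the k with
    the minimal index wins (ties toward the smallest k).  Returns
    (per-node region labels in 1..k, k, {k: DB score}).
    """
    node_weights = np.asarray(node_weights, dtype=float)
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValueError("empty candidate region-count range")
    if k_range[0] < 2 or k_range[-1] > len(node_weights) - 1:
        raise ValueError("candidate k must lie in [2, n_nodes - 1]")
    db_scores: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for k in k_range:
        if method == "ward":
            lab = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(
                node_weights
            )
        elif method == "kmeans":
            lab = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(
                node_weights
            )
        else:
            raise ValueError(f"unknown node-clustering method {method!r}")
        labelings[k] = lab
        db_scores[k] = davies_bouldin(node_weights, lab)
    best_k = min(k_range, key=lambda k: (db_scores[k], k))
    return labelings[best_k] + 1, best_k, db_scores


@dataclass
class RegionModel:
    """A fitted SOM-plus-region-mapping model for one case (or pooled set)."""

    som_grid: tuple[int, int]
    node_weights: np.ndarray
    node_region: np.ndarray  # per-node region id, 1..k
    k: int
    db_scores: dict[int, float]
    seed: int
    phenotypes: tuple[str, ...] = PHENOTYPES
    labels: np.ndarray | None = None  # per-neighborhood region ids

    def to_json(self, path) -> None:
        payload = {
            "som_grid": list(self.som_grid),
            "node_weights": self.node_weights.tolist(),
            "node_region": self.node_region.tolist(),
            "k": self.k,
            "db_scores": {str(k): v for k, v in self.db_scores.items()},
            "seed": self.seed,
            "phenotypes": list(self.phenotypes),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RegionModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            som_grid=tuple(payload["som_grid"]),
            node_weights=np.asarray(payload["node_weights"], dtype=float),
            node_region=np.asarray(payload["node_region"], dtype=int),
            k=int(payload["k"]),
            db_scores={int(k): float(v) for k, v in payload["db_scores"].items()},
            seed=int(payload["seed"]),
            phenotypes=tuple(payload["phenotypes"]),
        )


def label_neighborhoods(
    model: RegionModel, compositions: np.ndarray
) -> np.ndarray:
    """Region id (1..k) per neighborhood via its best-matching SOM node.

    Region ids are canonicalized so that higher ids have higher median
    tumor-cell fraction (for k = 2: region 2 is the tumor-dense one).
    """
    if model.node_region is None or len(model.node_region) == 0:
        raise ValueError("RegionModel is not fitted")
    compositions = np.asarray(compositions, dtype=float)
    raw = model.node_region[bmu_indices(model.node_weights, compositions)]

    tumor_col = model.phenotypes.index("tumor")
    medians = {}
    for r in range(1, model.k + 1):
        mask = raw == r
        medians[r] = (
            float(np.median(compositions[mask, tumor_col])) if mask.any() else -1.0
        )
    order = sorted(range(1, model.k + 1), key=lambda r: medians[r])
    remap = {old: new + 1 for new, old in enumerate(order)}
    model.node_region = np.array([remap[r] for r in model.node_region])
    labels = np.array([remap[r] for r in raw])
    model.labels = labels
    return labels


def discover_regions(
    compositions: np.ndarray,
    grid: tuple[int, int] = DEFAULT_GRID,
    n_iter: int = DEFAULT_N_ITER,
    learning_rate: float = DEFAULT_LEARNING_RATE,
    sigma: float | None = None,
    k_range=DEFAULT_K_RANGE,
    method: str = "ward",
    seed: int = 0,
) -> RegionModel:
    """Full region-discovery pipeline on a composition matrix."""
    weights = fit_som(
        compositions, grid=grid, n_iter=n_iter, learning_rate=learning_rate,
        sigma=sigma, seed=seed,
    )
    node_region, k, db_scores = select_regions(weights, k_range, method=method,
                                               seed=seed)
    model = RegionModel(
        som_grid=grid, node_weights=weights, node_region=node_region, k=k,
        db_scores=db_scores, seed=seed,
    )
    label_neighborhoods(model, compositions)
    return model


def region_extension(
    labels: np.ndarray, component_labels: np.ndarray
) -> pd.DataFrame:
    """Percent of each component's neighborhoods falling in each region.

    Rows: components; columns: region ids; each row sums to 100 (NaN row
    for an empty component never arises since components are taken from
    the data).
    """
    labels = np.asarray(labels)
    component_labels = np.asarray(component_labels)
    if len(labels) != len(component_labels):
        raise ValueError("labels and component labels must align")
    regions = sorted(np.unique(labels))
    rows = {}
    for comp in pd.unique(component_labels):
        mask = component_labels == comp
        n = mask.sum()
        rows[comp] = {
            r: 100.0 * float((labels[mask] == r).sum()) / n for r in regions
        }
    out = pd.DataFrame(rows).T
    out.columns = [f"region_{r}" for r in regions]
    out.index.name = "component"
    return out


def region_composition_summary(
    labels: np.ndarray,
    compositions: np.ndarray,
    phenotypes=PHENOTYPES,
) -> pd.DataFrame:
    """Per-region median composition (tidy frame, one row per region).

    Medians are taken per phenotype across the neighborhoods of each
    region — the quantity shown by per-region composition circle plots.
    """
    labels = np.asarray(labels)
    compositions = np.asarray(compositions, dtype=float)
    rows = []
    for r in sorted(np.unique(labels)):
        sub = compositions[labels == r]
        med = np.median(sub, axis=0)
        rows.append({"region": r, "n_neighborhoods": len(sub),
                     **{f"median_frac_{p}": m for p, m in zip(phenotypes, med)}})
    return pd.DataFrame(rows)
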