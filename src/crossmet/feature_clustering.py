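"""Feature-space embedding and clustering into compound-class groups.

Features from both platforms are embedded jointly into 2-D (UMAP on cosine
distance by default) and partitioned with k-means; the number of clusters
is chosen by silhouette score with an elbow tie-break, and clusters are
named after their predominant compound class.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .preprocess import PlatformMatrix

__all__ = [
    "EmbeddingParams",
    "ClusterAssignment",
    "embed_features",
    "select_k",
    "assign_clusters",
    "label_clusters",
    "cluster_features",
]


@dataclass
class EmbeddingParams:
    metric: str = "cosine"
    n_components: int = 2
    n_neighbors: int = 35
    min_dist: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_components < 2 or self.n_neighbors < 2 or self.min_dist < 0:
            raise ValueError("invalid embedding parameters")


@dataclass
class ClusterAssignment:
    feature_ids: list[str]
    coords: np.ndarray  # features x 2
    labels: np.ndarray  # int per feature in [0, k)
    k: int
    cluster_names: dict[int, str] = field(default_factory=dict)
    silhouette_by_k: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.min() < 0 or labels.max() >= self.k:
            raise ValueError("labels outside [0, k)")
        if self.cluster_names and set(self.cluster_names) != set(range(self.k)):
            raise ValueError("cluster_names must cover all labels")

    def members(self, label: int) -> list[str]:
        return [f for f, lab in zip(self.feature_ids, self.labels) if lab == label]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "cluster": self.labels,
                "cluster_name": [self.cluster_names.get(int(l), "") for l in self.labels],
            }
        )

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(out / "cluster_assignment.csv", index=False)
        with open(out / "silhouette_by_k.json", "w") as fh:
            json.dump({str(k): v for k, v in self.silhouette_by_k.items()}, fh, indent=2)


def _feature_table(input_matrix: PlatformMatrix, target_matrix: PlatformMatrix) -> tuple[np.ndarray, list[str]]:
    """Stack features (rows) by their values across shared samples;
    residual missing entries are mean-completed for embedding only."""
    if input_matrix.sample_ids != target_matrix.sample_ids:
        raise ValueError("platform matrices must share sample ordering")
    blocks, ids = [], []
    for m in (input_matrix, target_matrix):
        vals = np.where(m.observed_mask, m.values, np.nan)
        col_means = np.nanmean(vals, axis=0)
        vals = np.where(np.isnan(vals), col_means, vals)
        blocks.append(vals.T)
        ids.extend(m.feature_ids)
    return np.vstack(blocks), ids


def embed_features(
    input_matrix: PlatformMatrix,
    target_matrix: PlatformMatrix,
    params: EmbeddingParams | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Embed every feature of both platforms jointly into 2-D.

    Returns (coords, feature_ids) with one row per feature; deterministic
    given ``params.seed``.
    """
    params = params or EmbeddingParams()
    table, ids = _feature_table(input_matrix, target_matrix)
    if len(ids) <= params.n_neighbors:
        raise ValueError(
            f"need more than n_neighbors={params.n_neighbors} features, got {len(ids)}"
        )
    import umap  # deferred: slow numba import

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            metric=params.metric,
            n_components=params.n_components,
            n_neighbors=params.n_neighbors,
            min_dist=params.min_dist,
            random_state=params.seed,
        )
        coords = reducer.fit_transform(table)
    return np.asarray(coords, dtype=np.float64), ids


def select_k(
    coords: np.ndarray, k_range: range = range(2, 11), seed: int = 0
) -> tuple[int, dict[int, float]]:
    """Pick k by maximal mean silhouette; ties go to the elbow of the
    within-cluster sum-of-squares curve (largest second difference)."""
    coords = np.asarray(coords)
    if np.allclose(coords, coords[0]):
        raise ValueError("degenerate coordinates: all points identical")
    ks = [k for k in k_range if 2 <= k <= len(coords) - 1]
    if not ks:
        raise ValueError("empty k_range after bounds check")
    sil: dict[int, float] = {}
    wcss: dict[int, float] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(coords)
        sil[k] = float(silhouette_score(coords, km.labels_)) if k > 1 else float("nan")
        wcss[k] = float(km.inertia_)
    best = max(sil.values())
    tied = [k for k in ks if abs(sil[k] - best) < 1e-9]
    if len(tied) == 1:
        return tied[0], sil
    # elbow tie-break: largest second difference of the WCSS curve
    second_diff = {}
    for k in tied:
        lo, hi = wcss.get(k - 1), wcss.get(k + 1)
        if lo is None or hi is None:
            second_diff[k] = -np.inf
        else:
            second_diff[k] = lo - 2 * wcss[k] + hi
    return max(tied, key=lambda k: second_diff[k]), sil


def assign_clusters(coords: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """k-means labels with >= 10 restarts; refits with a new seed (up to 5
    attempts) if a cluster comes back empty."""
    if k < 2:
        raise ValueError("k must be >= 2")
    for attempt in range(5):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed + attempt).fit(coords)
        if len(np.unique(km.labels_)) == k:
            return km.labels_.astype(int)
    raise RuntimeError(f"k-means produced an empty cluster in 5 attempts (k={k})")


def label_clusters(
    feature_ids: list[str],
    labels: np.ndarray,
    feature_metadata: pd.DataFrame,
    others_threshold: float = 0.5,
    others_name: str = "Others",
) -> dict[int, str]:
    """Name each cluster by its modal compound class; a cluster whose modal
    class holds less than ``others_threshold`` of members becomes Others."""
    classes = feature_metadata.set_index("feature_id")["compound_class"]
    names: dict[int, str] = {}
    for label in sorted(set(int(l) for l in labels)):
        members = [f for f, lab in zip(feature_ids, labels) if int(lab) == label]
        counts = classes.loc[members].value_counts()
        if counts.empty:
            names[label] = others_name
            continue
        modal_frac = counts.iloc[0] / len(members)
        names[label] = counts.index[0] if modal_frac >= others_threshold else others_name
    return names


def cluster_features(
    input_matrix: PlatformMatrix,
    target_matrix: PlatformMatrix,
    feature_metadata: pd.DataFrame,
    params: EmbeddingParams | None = None,
    k_range: range = range(2, 11),
    others_threshold: float = 0.5,
) -> ClusterAssignment:
    """embed -> select_k -> assign -> label, as one pipeline step."""
    params = params or EmbeddingParams()
    coords, ids = embed_features(input_matrix, target_matrix, params)
    k, sil = select_k(coords, k_range, seed=params.seed)
    labels = assign_clusters(coords, k, seed=params.seed)
    names = label_clusters(ids, labels, feature_metadata, others_threshold)
    return ClusterAssignment(ids, coords, labels, k, names, sil)
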