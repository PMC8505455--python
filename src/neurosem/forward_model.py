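"""Forward model: predict activation patterns from behavioural ratings.

A linear regression with the four semantic dimension ratings as predictors
(plus intercept) maps concept ratings to the mean activation of each
factor-derived cluster. The cluster activation feature is the mean of the
most stable voxels inside a cuboid around the cluster centroid; clusters
too small to supply the required voxel count are excluded (reported). The
model is evaluated by leave-one-concept-out prediction: per held-out
concept, R-squared is the squared Pearson correlation between the
predicted and observed cluster vectors, and identification performance is
the normalized rank of the held-out concept when its observed pattern is
compared (by correlation distance) against the predicted patterns of all
concepts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .decoding import RankAccuracyResult, rank_accuracy
from .factors import ClusterMap
from .geometry import BrainGeometry
from .preprocess import StabilityScores


@dataclass
class ClusterFeatures:
    """Concepts x clusters activation means with provenance."""

    values: np.ndarray
    cluster_indices: list[int]  # indices into the source ClusterMap
    feature_voxels: list[tuple[int, ...]]  # voxels averaged per kept cluster
    excluded: list[dict]


@dataclass
class PredictiveModel:
    weights: np.ndarray  # (1 + n_dimensions) x clusters; row 0 = intercept
    dimension_names: list[str]

    @property
    def n_clusters(self) -> int:
        return self.weights.shape[1]


def cluster_mean_activation(
    profiles: np.ndarray,
    stability: StabilityScores | np.ndarray,
    cluster_map: ClusterMap,
    geometry: BrainGeometry,
    n_voxels: int = 5,
    cuboid_radius: int = 1,
) -> ClusterFeatures:
    """Per-cluster mean activation over the most stable cuboid voxels.

    For each cluster, the cuboid of half-width ``cuboid_radius`` (so 3x3x3
    voxels at the default radius 1) around the grid voxel nearest the
    centroid is ranked by stability and the top ``n_voxels`` are averaged.
    Clusters smaller than ``n_voxels`` members, or whose cuboid holds fewer
    than ``n_voxels`` scoreable voxels, are excluded and reported.
    """
    if len(cluster_map.clusters) == 0:
        raise ValueError("cluster map is empty")
    s = stability.scores if isinstance(stability, StabilityScores) else np.asarray(stability, float)
    P = np.asarray(profiles, float)
    shape = np.asarray(geometry.grid_shape)
    values, kept, voxsets, excluded = [], [], [], []
    for ci, cluster in enumerate(cluster_map.clusters):
        if cluster.size < n_voxels:
            excluded.append({"cluster": ci, "reason": f"size {cluster.size} < {n_voxels}"})
            continue
        center = geometry.index_to_grid(geometry.nearest_voxel(cluster.centroid_mm))
        lo = np.maximum(center - cuboid_radius, 0)
        hi = np.minimum(center + cuboid_radius, shape - 1)
        ii, jj, kk = np.meshgrid(
            *(np.arange(lo[a], hi[a] + 1) for a in range(3)), indexing="ij"
        )
        cuboid = geometry.grid_to_index(
            np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        )
        eligible = cuboid[np.isfinite(s[cuboid])]
        if eligible.size < n_voxels:
            excluded.append(
                {"cluster": ci, "reason": f"{eligible.size} scoreable cuboid voxels < {n_voxels}"}
            )
            continue
        order = np.lexsort((eligible, -s[eligible]))
        top = np.sort(eligible[order[:n_voxels]])
        values.append(P[:, top].mean(axis=1))
        kept.append(ci)
        voxsets.append(tuple(int(v) for v in top))
    if not kept:
        raise ValueError("all clusters were excluded from the predictive analysis")
    return ClusterFeatures(
        values=np.column_stack(values),
        cluster_indices=kept,
        feature_voxels=voxsets,
        excluded=excluded,
    )


def _design(ratings: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(ratings.shape[0]), ratings])


def fit_ratings_regression(
    ratings: np.ndarray,
    activations: np.ndarray,
    dimension_names: list[str] | None = None,
) -> PredictiveModel:
    """Independent ordinary least squares per cluster, with intercept.

    ``ratings`` is (n_train x n_dimensions) mean rater values, not
    z-scored; ``activations`` is (n_train x n_clusters). A rank-deficient
    design (constant or duplicated rating column) raises an error naming
    the offending column.
    """
    R = np.asarray(ratings, float)
    A = np.atleast_2d(np.asarray(activations, float))
    if dimension_names is None:
        dimension_names = [f"dimension_{i}" for i in range(R.shape[1])]
    if R.shape[0] <= R.shape[1] + 1:
        raise ValueError("need more training concepts than predictors + intercept")
    X = _design(R)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        for j in range(R.shape[1]):
            if R[:, j].std() == 0:
                raise ValueError(f"design is rank deficient: column {dimension_names[j]!r} is constant")
            for j2 in range(j):
                if np.allclose(R[:, j], R[:, j2]):
                    raise ValueError(
                        f"design is rank deficient: columns {dimension_names[j2]!r} "
                        f"and {dimension_names[j]!r} are identical"
                    )
        raise ValueError("design matrix is rank deficient")
    weights, *_ = np.linalg.lstsq(X, A, rcond=None)
    return PredictiveModel(weights=weights, dimension_names=list(dimension_names))


def predict_concept_pattern(model: PredictiveModel, rating_row: np.ndarray) -> np.ndarray:
    """Predicted per-cluster activation for one concept's ratings."""
    r = np.asarray(rating_row, float).ravel()
    if r.size != model.weights.shape[0] - 1:
        raise ValueError(
            f"rating row has {r.size} dimensions; model expects "
            f"{model.weights.shape[0] - 1} ({model.dimension_names})"
        )
    return _design(r[None, :])[0] @ model.weights


@dataclass
class LooResult:
    r2_per_concept: np.ndarray  # NaN where undefined
    mean_r2: float
    rank: RankAccuracyResult
    fold_weights: list[np.ndarray]


def loo_evaluate(
    ratings: np.ndarray,
    activations: np.ndarray,
    dimension_names: list[str] | None = None,
) -> LooResult:
    """Leave-one-concept-out evaluation of the ratings->activation model.

    Per held-out concept: fit on the remaining concepts, predict all
    concepts' patterns from that fold's weights, score R-squared (squared
    Pearson r of predicted vs observed cluster vectors for the held-out
    concept) and the normalized rank of the held-out concept by ascending
    correlation distance ``1 - r`` to every concept's predicted pattern.
    """
    R = np.asarray(ratings, float)
    A = np.asarray(activations, float)
    n = R.shape[0]
    if n < 7:
        raise ValueError("need at least 7 concepts for leave-one-concept-out")
    r2 = np.full(n, np.nan)
    score_rows = np.empty((n, n))
    weights = []
    for i in range(n):
        keep = np.arange(n) != i
        model = fit_ratings_regression(R[keep], A[keep], dimension_names)
        weights.append(model.weights)
        preds = _design(R) @ model.weights  # all concepts' predicted patterns
        obs = A[i]
        if obs.std() == 0:
            warnings.warn(f"concept {i}: observed pattern has zero variance; R^2 undefined")
        else:
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(preds[i], obs)[0, 1]
            r2[i] = r**2
        # similarity = -distance = pearson r with each predicted pattern
        pc = preds - preds.mean(axis=1, keepdims=True)
        oc = obs - obs.mean()
        denom = np.linalg.norm(pc, axis=1) * np.linalg.norm(oc)
        denom[denom == 0] = np.inf
        score_rows[i] = (pc @ oc) / denom
    rank = rank_accuracy(score_rows, np.arange(n))
    valid = ~np.isnan(r2)
    return LooResult(
        r2_per_concept=r2,
        mean_r2=float(r2[valid].mean()) if valid.any() else float("nan"),
        rank=rank,
        fold_weights=weights,
    )
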