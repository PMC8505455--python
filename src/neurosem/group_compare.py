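"""Expert-vs-novice discrimination on the shared concept subset.

The two cohorts' factor analyses each yield per-participant cluster maps;
clusters replicated in enough participants of their group (same factor,
centroid within one voxel) enter the union feature set. Per participant,
each cluster contributes the mean activation of its most stable voxels for
the shared concepts; a leave-one-participant-out Gaussian naive Bayes
classifier then predicts group membership, and a reiterative stepwise
search identifies the concepts whose activation best discriminates the
groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .decoding import gnb_log_posterior, train_gnb
from .factors import ClusterMap
from .geometry import BrainGeometry
from .preprocess import select_stable_voxels, voxel_stability
from .synth import ActivationDataset


@dataclass(frozen=True)
class GroupCluster:
    voxels: tuple[int, ...]
    centroid_mm: tuple[float, float, float]
    source_group: str
    factor: int
    n_participants: int


@dataclass
class GroupFeatureTable:
    """Per-participant concepts x clusters activation means, with group labels."""

    features: np.ndarray  # participants x concepts x clusters
    groups: list[str]
    participant_ids: list[str]
    concept_labels: list[str]

    @property
    def n_participants(self) -> int:
        return self.features.shape[0]

    @property
    def n_concepts(self) -> int:
        return self.features.shape[1]


def _centroid_close(
    a: tuple[float, float, float],
    b: tuple[float, float, float],
    geometry: BrainGeometry,
    tol_voxels: float,
) -> bool:
    d = np.abs(np.asarray(a) - np.asarray(b)) / np.asarray(geometry.voxel_size_mm)
    return bool((d <= tol_voxels).all())


def _replicated_clusters(
    maps: list[ClusterMap],
    geometry: BrainGeometry,
    group_name: str,
    min_participants: int,
    tol_voxels: float,
) -> list[GroupCluster]:
    """Agglomerate per-participant clusters by (factor, centroid proximity)
    and keep those present in >= min_participants distinct participants."""
    pooled = [
        (pi, c) for pi, cmap in enumerate(maps) for c in cmap.clusters
    ]
    used = [False] * len(pooled)
    out: list[GroupCluster] = []
    for i, (pi, ci) in enumerate(pooled):
        if used[i]:
            continue
        members = [(pi, ci)]
        used[i] = True
        for j in range(i + 1, len(pooled)):
            if used[j]:
                continue
            pj, cj = pooled[j]
            if cj.factor != ci.factor:
                continue
            if _centroid_close(ci.centroid_mm, cj.centroid_mm, geometry, tol_voxels):
                members.append((pj, cj))
                used[j] = True
        participants = {p for p, _ in members}
        if len(participants) < min_participants:
            continue
        voxels = sorted({v for _, c in members for v in c.voxels})
        centroid = geometry.voxel_mm(np.asarray(voxels)).mean(axis=0)
        out.append(
            GroupCluster(
                voxels=tuple(voxels),
                centroid_mm=tuple(float(x) for x in centroid),
                source_group=group_name,
                factor=int(ci.factor),
                n_participants=len(participants),
            )
        )
    return out


def union_factor_clusters(
    cluster_maps_group_a: list[ClusterMap],
    cluster_maps_group_b: list[ClusterMap],
    geometry: BrainGeometry,
    min_participants: int = 4,
    tol_voxels: float = 1.0,
    group_names: tuple[str, str] = ("faculty", "student"),
) -> list[GroupCluster]:
    """Union of replicated factor-cluster locations from the two groups.

    A cluster survives iff it replicates (same factor identity, centroid
    within ``tol_voxels`` in voxel units, Chebyshev) in at least
    ``min_participants`` participants of its source group. Overlapping
    survivors from the two groups (centroids within ``tol_voxels``) are
    merged into one location.
    """
    a = _replicated_clusters(
        cluster_maps_group_a, geometry, group_names[0], min_participants, tol_voxels
    )
    b = _replicated_clusters(
        cluster_maps_group_b, geometry, group_names[1], min_participants, tol_voxels
    )
    merged: list[GroupCluster] = list(a)
    for gc in b:
        overlap = None
        for i, other in enumerate(merged):
            if _centroid_close(gc.centroid_mm, other.centroid_mm, geometry, tol_voxels):
                overlap = i
                break
        if overlap is None:
            merged.append(gc)
        else:
            other = merged[overlap]
            voxels = sorted(set(other.voxels) | set(gc.voxels))
            centroid = geometry.voxel_mm(np.asarray(voxels)).mean(axis=0)
            merged[overlap] = GroupCluster(
                voxels=tuple(voxels),
                centroid_mm=tuple(float(x) for x in centroid),
                source_group="both",
                factor=other.factor,
                n_participants=max(other.n_participants, gc.n_participants),
            )
    if not merged:
        raise ValueError("empty cluster union: no cluster replicated in enough participants")
    merged.sort(key=lambda c: c.voxels)
    return merged


def build_group_features(
    datasets: list[ActivationDataset],
    cluster_set: list[GroupCluster],
    shared_concepts: np.ndarray,
    n_voxels: int = 6,
) -> GroupFeatureTable:
    """Per-participant cluster activation means over the shared concepts.

    Stability is computed per participant on the shared concepts across all
    presentations; each cluster contributes the mean activation of its
    ``n_voxels`` most stable member voxels (all members, with a warning, if
    the cluster is smaller).
    """
    shared = np.asarray(shared_concepts)
    if shared.size == 0:
        raise ValueError("shared_concepts must be nonempty")
    feats = np.empty((len(datasets), shared.size, len(cluster_set)))
    for di, ds in enumerate(datasets):
        sub = ds.psc[shared]
        stab = voxel_stability(sub)
        profiles = sub.mean(axis=1)
        for ki, gc in enumerate(cluster_set):
            members = np.asarray(gc.voxels)
            k = n_voxels
            if members.size < n_voxels:
                warnings.warn(
                    f"cluster {ki}: only {members.size} voxels for a request of "
                    f"{n_voxels}; using all"
                )
                k = members.size
            scoreable = members[np.isfinite(stab.scores[members])]
            if scoreable.size == 0:
                chosen = members  # degenerate: flat voxels carry no ranking
            else:
                chosen = select_stable_voxels(stab, min(k, scoreable.size), mask=_mask(ds, members))
            feats[di, :, ki] = profiles[:, chosen].mean(axis=1)
    return GroupFeatureTable(
        features=feats,
        groups=[ds.group for ds in datasets],
        participant_ids=[ds.participant_id for ds in datasets],
        concept_labels=[datasets[0].concept_labels[i] for i in shared],
    )


def _mask(ds: ActivationDataset, members: np.ndarray) -> np.ndarray:
    m = np.zeros(ds.geometry.n_voxels, bool)
    m[members] = True
    return m


def classify_group_membership(
    table: GroupFeatureTable, concept_subset: np.ndarray | list | None = None
) -> dict:
    """Leave-one-participant-out group classification.

    The feature vector is the flattened (concepts-in-subset x clusters)
    block; the classifier is Gaussian naive Bayes with pooled variance.
    Returns the mean accuracy and per-participant predictions.
    """
    if concept_subset is None:
        concept_subset = np.arange(table.n_concepts)
    sub = np.asarray(concept_subset)
    if sub.size == 0:
        raise ValueError("concept subset is empty")
    X = table.features[:, sub, :].reshape(table.n_participants, -1)
    y = np.asarray(table.groups)
    names = sorted(set(y.tolist()))
    if len(names) != 2 or any((y == n).sum() < 2 for n in names):
        raise ValueError("need at least 2 participants in each of 2 groups")
    preds, correct = [], 0
    for left_out in range(table.n_participants):
        keep = np.arange(table.n_participants) != left_out
        model = train_gnb(X[keep], y[keep])
        post = gnb_log_posterior(model, X[left_out][None, :])[0]
        pred = model.class_labels[int(np.argmax(post))]
        preds.append(
            {"participant": table.participant_ids[left_out], "true": str(y[left_out]),
             "predicted": str(pred)}
        )
        correct += int(pred == y[left_out])
    return {
        "accuracy": correct / table.n_participants,
        "predictions": preds,
        "n_folds": table.n_participants,
    }


def stepwise_concept_selection(
    table: GroupFeatureTable, beam_width: int | None = 16
) -> dict:
    """Reiterative stepwise search for the most group-discriminating concepts.

    Iteration 1 scores every single concept; iteration k extends every
    surviving (k-1)-set with each remaining concept; survivors are the
    extensions whose accuracy is at least the previous iteration's best.
    The search stops when every extension strictly decreases accuracy (or
    accuracy reaches 1.0, which no extension can improve on). Ties for the
    final set are broken by the lexicographically smallest concept-index
    set. ``beam_width`` caps the survivor count deterministically (sorted
    by accuracy, then lexicographic index set); ``None`` disables the cap.

    Returns the selected concept indices (in addition order along the best
    path), their labels, the final accuracy and the full accuracy trace.
    """
    n = table.n_concepts
    if n < 1:
        raise ValueError("need at least one concept")

    def score(subset: tuple[int, ...]) -> float:
        return classify_group_membership(table, np.asarray(subset))["accuracy"]

    # iteration 1: single concepts; survivors = argmax ties
    singles = [((c,), score((c,))) for c in range(n)]
    best_acc = max(a for _, a in singles)
    survivors = [(s, a, s) for s, a in singles if a == best_acc]  # (set, acc, path)
    trace = [{"iteration": 1, "best_accuracy": best_acc,
              "n_candidates": n, "n_survivors": len(survivors)}]
    best_final = min(survivors, key=lambda t: t[0])
    if n == 1:
        return _stepwise_result(best_final, trace, table)
    it = 1
    while best_acc < 1.0:
        it += 1
        seen: set[tuple[int, ...]] = set()
        candidates: list[tuple[tuple[int, ...], float, tuple[int, ...]]] = []
        for subset, _, path in survivors:
            for c in range(n):
                if c in subset:
                    continue
                ext = tuple(sorted(subset + (c,)))
                if ext in seen:
                    continue
                seen.add(ext)
                candidates.append((ext, score(ext), path + (c,)))
        if not candidates:
            break
        ext_best = max(a for _, a, _ in candidates)
        trace.append({"iteration": it, "best_accuracy": max(ext_best, best_acc),
                      "n_candidates": len(candidates), "n_survivors": 0})
        if ext_best < best_acc:
            break  # every extension decreased accuracy
        survivors = sorted(
            ((s, a, p) for s, a, p in candidates if a >= best_acc),
            key=lambda t: (-t[1], t[0]),
        )
        if beam_width is not None:
            survivors = survivors[:beam_width]
        trace[-1]["n_survivors"] = len(survivors)
        best_acc = ext_best
        best_final = min(
            (t for t in survivors if t[1] == best_acc), key=lambda t: t[0]
        )
    return _stepwise_result(best_final, trace, table)


def _stepwise_result(best, trace, table) -> dict:
    subset, acc, path = best
    return {
        "selected": list(path),
        "selected_labels": [table.concept_labels[i] for i in path],
        "accuracy": float(acc),
        "trace": trace,
    }
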