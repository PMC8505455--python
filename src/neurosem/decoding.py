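"""Gaussian naive Bayes concept decoding and normalized rank accuracy.

The classifier models each concept's activation over the selected stable
voxels as an axis-aligned Gaussian (pooled within-class variance by
default, since only a handful of exemplars per concept exist) with uniform
priors. Performance is summarised as normalized rank accuracy: the correct
concept's rank in the posterior-ordered list of the n classes, mapped to
(n - rank) / (n - 1), so a perfect classifier scores 1.0 and chance 0.5.

All feature selection happens inside each cross-validation fold, from the
training presentations (within-participant) or training participants
(cross-participant) only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .preprocess import (
    cross_participant_consistency,
    select_stable_voxels,
    voxel_stability,
)
from .synth import ActivationDataset

_ABS_VAR_FLOOR = 1e-12


@dataclass
class GnbModel:
    class_labels: list
    means: np.ndarray  # classes x features
    variances: np.ndarray  # (features,) pooled or (classes, features)
    log_priors: np.ndarray
    var_mode: str = "pooled"

    @property
    def n_classes(self) -> int:
        return self.means.shape[0]


@dataclass
class RankAccuracyResult:
    per_item: np.ndarray  # normalized ranks in [0, 1]
    n_classes: int
    folds: list = field(default_factory=list)  # per-fold bookkeeping dicts

    @property
    def mean(self) -> float:
        return float(self.per_item.mean())


def train_gnb(
    features: np.ndarray,
    labels: np.ndarray | list,
    var_mode: str = "pooled",
    var_floor_frac: float = 1e-6,
) -> GnbModel:
    """Fit a Gaussian naive Bayes model.

    Class means come from the training exemplars; the default variance is
    the pooled within-class variance per feature (``var_mode="per_class"``
    for class-specific variances). Variances are floored at
    ``var_floor_frac`` of the feature's total variance (and at a tiny
    absolute floor) so constant features never divide by zero. Priors are
    uniform.
    """
    X = np.asarray(features, float)
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    K, F = len(classes), X.shape[1]
    means = np.empty((K, F))
    within_ss = np.zeros(F)
    n_total = 0
    per_class_var = np.empty((K, F))
    for k, c in enumerate(classes):
        Xc = X[y == c]
        if Xc.shape[0] == 0:
            raise ValueError(f"class {c!r} has no exemplars")
        means[k] = Xc.mean(axis=0)
        within_ss += ((Xc - means[k]) ** 2).sum(axis=0)
        per_class_var[k] = Xc.var(axis=0)
        n_total += Xc.shape[0]
    dof = max(n_total - K, 1)
    pooled = within_ss / dof
    floor = np.maximum(var_floor_frac * X.var(axis=0), _ABS_VAR_FLOOR)
    if var_mode == "pooled":
        variances = np.maximum(pooled, floor)
    elif var_mode == "per_class":
        variances = np.maximum(per_class_var, floor)
    else:
        raise ValueError(f"unknown var_mode {var_mode!r}")
    return GnbModel(
        class_labels=classes,
        means=means,
        variances=variances,
        log_priors=np.full(K, -np.log(K)),
        var_mode=var_mode,
    )


def gnb_log_posterior(model: GnbModel, X: np.ndarray) -> np.ndarray:
    """Log posterior probabilities (normalized) for each item and class."""
    X = np.atleast_2d(np.asarray(X, float))
    if model.var_mode == "pooled":
        var = np.broadcast_to(model.variances, model.means.shape)
    else:
        var = model.variances
    # log N(x | mu_k, var_k) summed over features, per class
    ll = np.empty((X.shape[0], model.n_classes))
    for k in range(model.n_classes):
        ll[:, k] = -0.5 * (
            np.log(2 * np.pi * var[k]) + (X - model.means[k]) ** 2 / var[k]
        ).sum(axis=1)
    joint = ll + model.log_priors
    return joint - logsumexp(joint, axis=1, keepdims=True)


def rank_accuracy(
    class_scores: np.ndarray, true_labels: np.ndarray | list, folds: list | None = None
) -> RankAccuracyResult:
    """Normalized rank of the true class in the score-ordered class list.

    ``class_scores`` is items x classes (higher = more probable); ties get
    the average rank, so a completely uninformative classifier scores 0.5
    in expectation. The per-item value is ``(n - rank) / (n - 1)``.
    """
    S = np.atleast_2d(np.asarray(class_scores, float))
    n = S.shape[1]
    if n < 2:
        raise ValueError("need at least 2 classes")
    idx = np.asarray(true_labels)
    if idx.ndim == 0:
        idx = idx[None]
    if (idx < 0).any() or (idx >= n).any():
        raise ValueError("true label outside the score vector's class range")
    ranks = stats.rankdata(-S, axis=1, method="average")
    r = ranks[np.arange(S.shape[0]), idx]
    return RankAccuracyResult(
        per_item=(n - r) / (n - 1), n_classes=n, folds=folds or []
    )


# ---------------------------------------------------------------------------
# cross-validation protocols
# ---------------------------------------------------------------------------


def _fold_partitions(n_presentations: int, n_test: int = 2) -> list[tuple]:
    """All choose-``n_test``-as-test partitions of the presentations."""
    return [
        (tuple(p for p in range(n_presentations) if p not in test), test)
        for test in combinations(range(n_presentations), n_test)
    ]


def within_participant_cv(
    dataset: ActivationDataset,
    n_features: int = 120,
    exclude_region: str | None = None,
    n_test: int = 2,
    collect_artifacts: bool = False,
) -> RankAccuracyResult:
    """Within-participant concept decoding.

    Every fold holds out ``n_test`` presentations: voxel stability and the
    top-``n_features`` selection are computed from the training
    presentations only; the classifier is trained on the individual
    training presentations and tested on the mean of the held-out
    presentations. ``exclude_region`` drops one lobe's voxels from
    selection (e.g. occipital, to remove word-form signal).
    """
    P = dataset.n_presentations
    if P < 3:
        raise ValueError("need at least 3 presentations for the CV protocol")
    C = dataset.n_concepts
    mask = None
    if exclude_region is not None:
        mask = ~dataset.geometry.lobe_mask(exclude_region)
    per_item, fold_info = [], []
    for train, test in _fold_partitions(P, n_test):
        stab = voxel_stability(dataset.psc[:, train, :], presentations=train)
        sel = select_stable_voxels(stab, n_features, mask)
        X_train = dataset.psc[:, train, :][:, :, sel].reshape(C * len(train), -1)
        y_train = np.repeat(np.arange(C), len(train))
        model = train_gnb(X_train, y_train)
        X_test = dataset.mean_profiles(np.asarray(test))[:, sel]
        post = gnb_log_posterior(model, X_test)
        ra = rank_accuracy(post, np.arange(C))
        per_item.append(ra.per_item)
        info = {"train": train, "test": test}
        if collect_artifacts:
            info.update(selected=sel, model=model, stability=stab)
        fold_info.append(info)
    return RankAccuracyResult(
        per_item=np.concatenate(per_item), n_classes=C, folds=fold_info
    )


def cross_participant_cv(
    datasets: list[ActivationDataset],
    n_features: int = 120,
    collect_artifacts: bool = False,
) -> list[RankAccuracyResult]:
    """Leave-one-participant-out concept decoding.

    Data are presentation-averaged; features are the ``n_features`` voxels
    with the most consistent concept profiles across the *training*
    participants; the model is trained on one exemplar per concept per
    training participant and tested on the left-out participant.
    """
    if len(datasets) < 3:
        raise ValueError("need at least 3 participants")
    labels0 = datasets[0].concept_labels
    for d in datasets[1:]:
        if d.concept_labels != labels0:
            raise ValueError("mismatched concept sets across participants")
    profiles = [d.mean_profiles() for d in datasets]
    C = len(labels0)
    out = []
    for left_out in range(len(datasets)):
        train_profiles = [p for i, p in enumerate(profiles) if i != left_out]
        consistency = cross_participant_consistency(train_profiles)
        sel = select_stable_voxels(consistency, n_features)
        X_train = np.concatenate([p[:, sel] for p in train_profiles])
        y_train = np.tile(np.arange(C), len(train_profiles))
        model = train_gnb(X_train, y_train)
        post = gnb_log_posterior(model, profiles[left_out][:, sel])
        ra = rank_accuracy(post, np.arange(C))
        if collect_artifacts:
            ra.folds = [{"left_out": left_out, "selected": sel, "model": model,
                         "consistency": consistency}]
        out.append(ra)
    return out


def permutation_test(
    observed_mean_accuracy: float,
    datasets: ActivationDataset | list[ActivationDataset],
    cv_spec: dict | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Permutation p-value for a mean rank accuracy.

    Concept labels are permuted and the full cross-validation re-run for
    each permutation; the add-one estimate is
    ``p = (1 + #{perm >= observed}) / (1 + n_permutations)``, which never
    returns 0. For the within-participant protocol the concept axis is
    permuted independently per presentation (a single consistent
    relabelling would leave within-participant accuracy invariant); for
    the cross-participant protocol one relabelling per participant is
    drawn, following the labels-permuted-within-participant scheme.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    spec = dict(cv_spec or {})
    kind = spec.pop("kind", "within")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 17])
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        if kind == "within":
            ds: ActivationDataset = datasets  # type: ignore[assignment]
            psc = np.empty_like(ds.psc)
            for p in range(ds.n_presentations):
                psc[:, p, :] = ds.psc[rng.permutation(ds.n_concepts), p, :]
            permuted = ActivationDataset(
                ds.participant_id, ds.participant_index, ds.group, psc,
                ds.concept_labels, ds.geometry,
            )
            null[b] = within_participant_cv(permuted, **spec).mean
        elif kind == "cross":
            shuffled = []
            for ds in datasets:  # type: ignore[union-attr]
                psc = ds.psc[rng.permutation(ds.n_concepts)]
                shuffled.append(
                    ActivationDataset(
                        ds.participant_id, ds.participant_index, ds.group, psc,
                        ds.concept_labels, ds.geometry,
                    )
                )
            results = cross_participant_cv(shuffled, **spec)
            null[b] = float(np.mean([r.mean for r in results]))
        else:
            raise ValueError(f"unknown cv kind {kind!r}")
    p = (1 + int((null >= observed_mean_accuracy).sum())) / (1 + n_permutations)
    return {"p": p, "null": null, "observed": float(observed_mean_accuracy)}


def classify_category_means(
    datasets: ActivationDataset | list[ActivationDataset],
    category_labels: np.ndarray | list,
    n_features: int = 120,
) -> dict:
    """Distinguish the two categories' mean signatures within each participant.

    Per participant, leave-one-presentation-out: category-mean signatures
    are computed from the training presentations (over the stable voxels
    selected from them) and each held-out presentation's category mean is
    classified by the nearest (highest Pearson correlation) training
    signature. Reports per-participant accuracies and their grand mean.
    """
    if isinstance(datasets, ActivationDataset):
        datasets = [datasets]
    cats = np.asarray(category_labels)
    names = sorted(set(cats.tolist()))
    if len(names) != 2:
        raise ValueError("exactly two categories are required")
    groups = [np.flatnonzero(cats == name) for name in names]
    for name, g in zip(names, groups):
        if g.size < 2:
            raise ValueError(f"category {name!r} has fewer than 2 concepts")
    per_participant = []
    for ds in datasets:
        P = ds.n_presentations
        correct = 0
        total = 0
        for test_p in range(P):
            train = tuple(p for p in range(P) if p != test_p)
            stab = voxel_stability(ds.psc[:, train, :], presentations=train)
            sel = select_stable_voxels(stab, n_features)
            train_prof = ds.mean_profiles(np.asarray(train))[:, sel]
            test_prof = ds.psc[:, test_p, :][:, sel]
            train_sigs = np.stack([train_prof[g].mean(axis=0) for g in groups])
            test_sigs = np.stack([test_prof[g].mean(axis=0) for g in groups])
            for true_k in range(2):
                r = [
                    stats.pearsonr(test_sigs[true_k], train_sigs[k])[0]
                    for k in range(2)
                ]
                correct += int(np.argmax(r) == true_k)
                total += 1
        per_participant.append(correct / total)
    return {
        "per_participant": per_participant,
        "grand_mean": float(np.mean(per_participant)),
        "categories": names,
    }
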