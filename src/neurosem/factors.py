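"""Two-level exploratory factor analysis of concept-level activation profiles.

Level one runs a separate principal-axis factor analysis (squared-multiple-
correlation priors, single pass, varimax rotation) on the intercorrelations
of the most stable voxels within each of the four lobes of one participant.
Level two factor-analyses the concatenated individual-level factor scores
(participants x lobes x factors columns, one score vector per column over
the concepts) and retains the factors explaining at least a configurable
fraction of the total input variance. Voxels are then uniquely assigned to
the retained factor on which they load most strongly (|loading| above a
threshold, 0.4 by default) and grouped into spatial clusters of face-
adjacent voxels (minimum size 2). Columns not absorbed by any retained
factor can be fed to a secondary group-level analysis, which is how
low-variance but coherent dimensions (such as the word-length nuisance
factor confined to the occipital lobe) surface.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy import ndimage, stats

from .geometry import BrainGeometry
from .preprocess import StabilityScores, select_per_lobe
from .synth import ActivationDataset, RatingsMatrix

logger = logging.getLogger(__name__)

_EIG_TOL = 1e-10


@dataclass
class FactorSolution:
    """Loadings, factor scores and bookkeeping of one factor analysis.

    ``loadings`` is input-columns x factors (correlation-metric, |value|<=1
    for well-conditioned input); ``scores`` is concepts x factors (z-scored
    columns); ``column_info`` records what each input column was (voxel
    index, or (participant, lobe, factor) at the group level).
    """

    loadings: np.ndarray
    communalities: np.ndarray
    variance_explained: np.ndarray
    scores: np.ndarray | None = None
    column_info: list | None = None

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    @property
    def n_columns(self) -> int:
        return self.loadings.shape[0]


@dataclass(frozen=True)
class Cluster:
    factor: int
    voxels: tuple[int, ...]
    centroid_mm: tuple[float, float, float]

    @property
    def size(self) -> int:
        return len(self.voxels)


@dataclass
class ClusterMap:
    clusters: list[Cluster]
    unassigned: tuple[int, ...]  # factor-assigned voxels left out of any cluster

    def __len__(self) -> int:
        return len(self.clusters)

    def for_factor(self, factor: int) -> list[Cluster]:
        return [c for c in self.clusters if c.factor == factor]


# ---------------------------------------------------------------------------
# core algorithms
# ---------------------------------------------------------------------------


def _check_correlation(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have a unit diagonal")
    return corr


def squared_multiple_correlations(corr: np.ndarray) -> np.ndarray:
    """SMC prior communalities, ``1 - 1/diag(R^-1)``.

    For singular correlation matrices (more variables than observations is
    routine here) the pseudo-inverse is used and the result clipped to
    [0, 1].
    """
    try:
        inv = np.linalg.inv(corr)
        if not np.isfinite(inv).all():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        logger.info("correlation matrix singular; SMC via pseudo-inverse")
        inv = np.linalg.pinv(corr)
    d = np.diag(inv)
    with np.errstate(divide="ignore"):
        smc = 1.0 - 1.0 / d
    return np.clip(np.nan_to_num(smc, nan=0.0), 0.0, 1.0)


def principal_factor_analysis(corr: np.ndarray, n_factors: int) -> FactorSolution:
    """Single-pass principal-axis factoring on the reduced correlation matrix.

    The diagonal of ``corr`` is replaced by SMC prior communalities; the
    loadings are the top eigenvectors of the reduced matrix scaled by the
    square roots of their (positive) eigenvalues. If fewer than
    ``n_factors`` positive eigenvalues exist, fewer factors are returned
    with a warning (and a zero-loading solution if none are positive, as
    for an identity correlation matrix).
    """
    corr = _check_correlation(corr)
    m = corr.shape[0]
    if n_factors < 1 or n_factors > m:
        raise ValueError("n_factors must be in [1, n_variables]")
    reduced = corr.copy()
    np.fill_diagonal(reduced, squared_multiple_correlations(corr))
    eigval, eigvec = np.linalg.eigh(reduced)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_pos = int((eigval > _EIG_TOL).sum())
    if n_pos == 0:
        warnings.warn("no positive eigenvalues; returning a zero-loading solution")
        loadings = np.zeros((m, n_factors))
    else:
        if n_pos < n_factors:
            warnings.warn(
                f"only {n_pos} positive eigenvalues for {n_factors} requested factors"
            )
        k = min(n_factors, n_pos)
        loadings = eigvec[:, :k] * np.sqrt(eigval[:k])
        loadings = _fix_column_signs(loadings)
    return FactorSolution(
        loadings=loadings,
        communalities=(loadings**2).sum(axis=1),
        variance_explained=(loadings**2).sum(axis=0),
    )


def _fix_column_signs(loadings: np.ndarray) -> np.ndarray:
    """Flip columns so each column's largest-|loading| entry is positive."""
    out = loadings.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        if col.any() and col[np.argmax(np.abs(col))] < 0:
            out[:, j] = -col
    return out


def varimax_criterion(loadings: np.ndarray) -> float:
    """Raw varimax criterion: sum over factors of the variance of squared loadings."""
    sq = np.asarray(loadings, float) ** 2
    return float((sq.var(axis=0)).sum())


def varimax_rotate(
    loadings: np.ndarray,
    normalize: bool = True,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> np.ndarray:
    """Orthogonal varimax rotation (Kaiser row normalization by default).

    Iterates the standard SVD update until the criterion change falls below
    ``tol``. Column signs are fixed so each column's largest-|loading|
    entry is positive; a single factor is returned unchanged.
    """
    L = np.asarray(loadings, float)
    if not np.isfinite(L).all():
        raise ValueError("loadings contain non-finite values")
    if L.ndim != 2:
        raise ValueError("loadings must be 2-D")
    p, k = L.shape
    if k < 2:
        return L.copy()
    if normalize:
        h = np.sqrt((L**2).sum(axis=1))
        h[h == 0] = 1.0
        X = L / h[:, None]
    else:
        X = L
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        Lr = X @ R
        tmp = Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p
        u, s, vt = np.linalg.svd(X.T @ tmp)
        R = u @ vt
        d_new = s.sum()
        if d_new - d < tol:
            break
        d = d_new
    out = X @ R
    if normalize:
        out = out * h[:, None]
    return _fix_column_signs(out)


def factor_scores(
    standardized_data: np.ndarray,
    solution: FactorSolution,
    corr: np.ndarray | None = None,
    ridge: float = 1e-6,
) -> np.ndarray:
    """Regression-method factor score estimates, ``Z R^-1 Lambda``, z-scored.

    A small ridge is added to the correlation matrix when it is singular
    (logged); the resulting score columns are standardized to mean 0, sd 1.
    """
    Z = np.asarray(standardized_data, float)
    if corr is None:
        corr = np.corrcoef(Z, rowvar=False)
    corr = np.atleast_2d(corr)
    try:
        W = np.linalg.solve(corr, solution.loadings)
        if not np.isfinite(W).all():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        logger.info("singular correlation matrix; ridge (%g) regularized scores", ridge)
        W = np.linalg.solve(corr + ridge * np.eye(corr.shape[0]), solution.loadings)
    scores = Z @ W
    scores = scores - scores.mean(axis=0)
    sd = scores.std(axis=0)
    sd[sd == 0] = 1.0
    return scores / sd


def _standardize(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, float)
    sd = X.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    return (X - X.mean(axis=0)) / sd_safe


# ---------------------------------------------------------------------------
# pipeline-level operations
# ---------------------------------------------------------------------------


def individual_level_fa(
    dataset: ActivationDataset,
    stability: StabilityScores | np.ndarray,
    n_per_lobe: int = 120,
    n_factors: int = 10,
) -> dict[str, FactorSolution]:
    """Per-lobe factor analysis of one participant's stable voxels.

    The activation profiles are averaged over presentations; within each
    lobe the ``n_per_lobe`` most stable voxels' intercorrelation matrix is
    factor-analysed (principal axis, varimax) for up to ``n_factors``
    factors. A lobe with fewer than ``n_factors + 1`` stable voxels gets a
    reduced factor count with a warning. Each solution records the voxel
    index behind every input column.
    """
    profiles = dataset.mean_profiles()
    selections = select_per_lobe(stability, dataset.geometry, n_per_lobe)
    out: dict[str, FactorSolution] = {}
    for lobe, voxels in selections.items():
        nf = n_factors
        if len(voxels) < n_factors + 1:
            nf = max(1, len(voxels) - 1)
            warnings.warn(
                f"lobe {lobe!r}: only {len(voxels)} stable voxels; "
                f"reducing factor count to {nf}"
            )
        X = _standardize(profiles[:, voxels])
        corr = np.corrcoef(X, rowvar=False)
        sol = principal_factor_analysis(corr, nf)
        sol.loadings = varimax_rotate(sol.loadings)
        sol.variance_explained = (sol.loadings**2).sum(axis=0)
        sol.scores = factor_scores(X, sol, corr)
        sol.column_info = [int(v) for v in voxels]
        out[lobe] = sol
    return out


def _fa_on_score_columns(
    X: np.ndarray,
    column_info: list,
    variance_threshold: float,
    n_factors_max: int,
) -> FactorSolution:
    """Shared engine for the (primary and secondary) group-level analyses.

    ``X`` is concepts x columns of factor scores; factors are retained when
    their post-rotation variance explained is at least ``variance_threshold``
    times the total input variance (the number of columns, in the
    correlation metric).
    """
    C, M = X.shape
    Z = _standardize(X)
    corr = np.corrcoef(Z, rowvar=False) if M > 1 else np.ones((1, 1))
    nf = min(n_factors_max, M, C - 1)
    sol = principal_factor_analysis(corr, nf)
    sol.loadings = varimax_rotate(sol.loadings)
    var = (sol.loadings**2).sum(axis=0)
    keep = np.flatnonzero(var >= variance_threshold * M)
    if keep.size == 0:
        warnings.warn("no factor reached the variance threshold; empty solution")
    keep = keep[np.argsort(var[keep])[::-1]]
    loadings = sol.loadings[:, keep]
    retained = FactorSolution(
        loadings=loadings,
        communalities=(loadings**2).sum(axis=1),
        variance_explained=var[keep],
        column_info=list(column_info),
    )
    if keep.size:
        retained.scores = factor_scores(Z, retained, corr)
    else:
        retained.scores = np.zeros((C, 0))
    return retained


def group_level_fa(
    solutions: dict[str, dict[str, FactorSolution]],
    variance_threshold: float = 0.02,
    n_factors_max: int = 12,
) -> FactorSolution:
    """Group-level factor analysis over individual-level factor scores.

    ``solutions`` maps participant id -> lobe -> individual
    :class:`FactorSolution`. The input matrix has one column per
    (participant, lobe, factor) score vector over the shared concept set.
    Retains (and varimax-rotates) the factors whose variance explained is
    at least ``variance_threshold`` of the total input variance.
    """
    cols, info = [], []
    n_concepts = None
    for pid, by_lobe in solutions.items():
        for lobe, sol in by_lobe.items():
            if sol.scores is None:
                raise ValueError("individual solutions must carry factor scores")
            if n_concepts is None:
                n_concepts = sol.scores.shape[0]
            elif sol.scores.shape[0] != n_concepts:
                raise ValueError("inconsistent concept sets across participants")
            for f in range(sol.n_factors):
                cols.append(sol.scores[:, f])
                info.append((pid, lobe, f))
    if not cols:
        raise ValueError("no input factor score columns")
    X = np.column_stack(cols)
    return _fa_on_score_columns(X, info, variance_threshold, n_factors_max)


def secondary_fa(
    residual_columns: np.ndarray,
    column_info: list | None = None,
    variance_threshold: float = 0.02,
    n_factors_max: int = 8,
) -> FactorSolution:
    """Second group-level factor analysis on unabsorbed score columns.

    Applied to the individual-level factor score columns whose clusters were
    not claimed by any retained first-level group factor. An empty input
    yields an empty solution (not an error); a single column is passed
    through as a 1-factor solution.
    """
    X = np.asarray(residual_columns, float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] == 0:
        return FactorSolution(
            loadings=np.zeros((0, 0)),
            communalities=np.zeros(0),
            variance_explained=np.zeros(0),
            scores=np.zeros((X.shape[0], 0)),
            column_info=[],
        )
    if column_info is None:
        column_info = list(range(X.shape[1]))
    if X.shape[1] == 1:
        z = _standardize(X)
        return FactorSolution(
            loadings=np.ones((1, 1)),
            communalities=np.ones(1),
            variance_explained=np.ones(1),
            scores=z,
            column_info=list(column_info),
        )
    return _fa_on_score_columns(X, column_info, variance_threshold, n_factors_max)


def residual_columns(
    group_solution: FactorSolution, threshold: float = 0.4
) -> np.ndarray:
    """Indices of input columns not loading above ``threshold`` on any retained factor."""
    if group_solution.n_factors == 0:
        return np.arange(group_solution.n_columns)
    absorbed = (np.abs(group_solution.loadings) > threshold).any(axis=1)
    return np.flatnonzero(~absorbed)


def voxel_factor_loadings(
    profiles: np.ndarray, scores: np.ndarray
) -> np.ndarray:
    """Loadings of every voxel on each factor.

    Computed as the Pearson correlation between the voxel's mean activation
    profile over the concepts and the factor score vector (the standard
    variable-factor correlation in the correlation metric). Zero-variance
    voxels load 0.
    """
    P = np.asarray(profiles, float)
    S = np.asarray(scores, float)
    if S.ndim == 1:
        S = S[:, None]
    Pc = P - P.mean(axis=0)
    Sc = S - S.mean(axis=0)
    psd = Pc.std(axis=0)
    ssd = Sc.std(axis=0)
    ssd[ssd == 0] = np.inf
    psd_safe = np.where(psd == 0, np.inf, psd)
    return (Pc.T @ Sc) / P.shape[0] / np.outer(psd_safe, ssd)


def assign_voxels_to_factors(
    voxel_loadings: np.ndarray, threshold: float = 0.4
) -> np.ndarray:
    """Unique voxel-to-factor assignment by highest absolute loading.

    Returns an int array (one entry per voxel): the factor index where
    ``|loading|`` is maximal, provided that maximum exceeds ``threshold``;
    ``-1`` otherwise. An all-below-threshold input yields an empty mapping.
    """
    L = np.asarray(voxel_loadings, float)
    if not np.isfinite(L).all():
        raise ValueError("voxel loadings contain non-finite values")
    if L.ndim != 2 or L.shape[1] == 0:
        return np.full(L.shape[0], -1, dtype=int)
    best = np.argmax(np.abs(L), axis=1)
    best_val = np.abs(L)[np.arange(L.shape[0]), best]
    out = np.where(best_val > threshold, best, -1)
    return out.astype(int)


def extract_clusters(
    assignment: np.ndarray,
    geometry: BrainGeometry,
    min_size: int = 2,
    connectivity: int = 6,
) -> ClusterMap:
    """Connected components of factor-assigned voxels on the grid.

    Components are found per factor under face adjacency (6-connectivity;
    26-connectivity available behind the flag). Components smaller than
    ``min_size`` are dropped into the unassigned pool. Centroids are the
    mean physical (mm) coordinates of the member voxels.
    """
    if connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    elif connectivity == 26:
        structure = ndimage.generate_binary_structure(3, 3)
    else:
        raise ValueError("connectivity must be 6 or 26")
    assignment = np.asarray(assignment)
    clusters: list[Cluster] = []
    unassigned: list[int] = []
    for factor in sorted(set(assignment[assignment >= 0].tolist())):
        vol = (assignment == factor).reshape(geometry.grid_shape)
        labeled, n = ndimage.label(vol, structure=structure)
        flat = labeled.ravel()
        for comp in range(1, n + 1):
            members = np.flatnonzero(flat == comp)
            if members.size < min_size:
                unassigned.extend(int(v) for v in members)
                continue
            centroid = geometry.voxel_mm(members).mean(axis=0)
            clusters.append(
                Cluster(
                    factor=int(factor),
                    voxels=tuple(int(v) for v in np.sort(members)),
                    centroid_mm=tuple(float(x) for x in centroid),
                )
            )
    clusters.sort(key=lambda c: (c.factor, c.voxels))
    return ClusterMap(clusters=clusters, unassigned=tuple(sorted(unassigned)))


def align_two(
    scores_a: np.ndarray, scores_b: np.ndarray, exhaustive: bool = False
) -> list[tuple[int, int, float]]:
    """Match the factors of two solutions by their score correlations.

    Greedy maximum-|r| bipartite matching by default; ``exhaustive=True``
    searches all permutations (for small factor counts, used as an oracle).
    Returns ``(factor_a, factor_b, r)`` triples (r signed).
    """
    A = np.asarray(scores_a, float)
    B = np.asarray(scores_b, float)
    ka, kb = A.shape[1], B.shape[1]
    if ka == 0 or kb == 0:
        return []
    R = voxel_factor_loadings(A, B)  # correlation matrix ka x kb
    if exhaustive:
        k = min(ka, kb)
        best, best_sum = None, -np.inf
        for perm in permutations(range(kb), k):
            s = sum(abs(R[i, j]) for i, j in zip(range(k), perm))
            if s > best_sum:
                best_sum, best = s, perm
        return [(i, int(j), float(R[i, j])) for i, j in zip(range(k), best)]
    pairs = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    flat = sorted(
        ((abs(R[i, j]), i, j) for i in range(ka) for j in range(kb)),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    for _, i, j in flat:
        if i in used_a or j in used_b:
            continue
        pairs.append((i, j, float(R[i, j])))
        used_a.add(i)
        used_b.add(j)
    pairs.sort()
    return pairs


def align_factors(solutions: list[FactorSolution]) -> list[dict]:
    """Align each solution's factors to the first solution's factors.

    Returns one record per (solution, factor) with the matched reference
    factor, the score correlation and its sign; unmatched factors carry
    ``reference = None``.
    """
    if not solutions:
        return []
    ref = solutions[0].scores
    records: list[dict] = []
    for s_idx, sol in enumerate(solutions):
        matches = {i: (j, r) for i, j, r in align_two(sol.scores, ref)}
        for f in range(sol.n_factors):
            j_r = matches.get(f)
            records.append(
                {
                    "solution": s_idx,
                    "factor": f,
                    "reference": None if j_r is None else j_r[0],
                    "r": None if j_r is None else j_r[1],
                    "sign": None if j_r is None else (1 if j_r[1] >= 0 else -1),
                }
            )
    return records


def correlate_scores_with_ratings(
    scores: np.ndarray,
    ratings: RatingsMatrix | np.ndarray,
    subset: str | tuple[str, int] = "all",
) -> list[dict]:
    """Validate factor interpretations against independent behavioural ratings.

    Each rating dimension is matched to its best factor by greedy maximum
    |r|, then the Pearson correlation and two-sided p-value (t transform)
    are reported. ``subset=("extremes", k)`` restricts to the k/2 highest
    and k/2 lowest concepts by factor score, mirroring the check that
    ratings track factor scores most tightly at the dimension extremes.
    """
    S = np.asarray(scores, float)
    if isinstance(ratings, RatingsMatrix):
        R = ratings.values
        names = list(ratings.dimension_names)
    else:
        R = np.asarray(ratings, float)
        names = [f"dimension_{i}" for i in range(R.shape[1])]
    if S.shape[0] != R.shape[0]:
        raise ValueError("scores and ratings must cover the same concepts")
    if (R.std(axis=0) == 0).any():
        bad = names[int(np.flatnonzero(R.std(axis=0) == 0)[0])]
        raise ValueError(f"undefined correlation: ratings for {bad!r} are constant")
    matches = align_two(R, S)  # (rating dim, factor, r)
    out = []
    for d, f, _ in matches:
        x = S[:, f]
        y = R[:, d]
        if subset == "all":
            sel = np.arange(len(x))
        else:
            kind, k = subset
            if kind != "extremes":
                raise ValueError(f"unknown subset {subset!r}")
            order = np.argsort(x)
            sel = np.concatenate([order[: k // 2], order[-(k - k // 2):]])
        r, p = stats.pearsonr(x[sel], y[sel])
        out.append(
            {"dimension": names[d], "factor": int(f), "r": float(r), "p": float(p),
             "n": int(len(sel))}
        )
    return out
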