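"""Synthetic multi-participant fMRI dataset generator with known ground truth.

The generator plants a low-rank factor structure: each latent semantic
dimension has z-scored concept scores and a set of spatially contiguous
voxel clusters (face-adjacent, size >= 2) carrying its loadings. A
participant's percent-signal-change (PSC) tensor is

    psc[c, p, v] = sum_d scores[c, d] * (loading[v, d] + participant perturbation)
                   + N(0, noise_sd)

so that with zero noise every presentation of a concept is identical and
in-cluster voxels are perfectly stable. One designated ``word_length``
nuisance dimension has scores proportional to the character counts of the
concept labels and clusters confined to the occipital partition, emulating
low-level visual encoding of the stimulus word. A second participant group
("student") may differ from the first ("faculty") in cluster topography.

All randomness derives from a single integer seed through named substreams,
so participant i is reproducible independently of cohort size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .concepts import default_concept_labels
from .geometry import LOBES, BrainGeometry, face_neighbors, make_geometry

GROUPS = ("faculty", "student")

WORD_LENGTH_DIM = "word_length"

DEFAULT_DIMENSIONS = (
    "measurability",
    "mathematical_formulation",
    "periodicity",
    "classical_post_classical",
    WORD_LENGTH_DIM,
)

# substream tags for the counter-based seed-splitting scheme
_STREAM_STRUCTURE = 7
_STREAM_PARTICIPANT = 11
_STREAM_RATINGS = 13


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *map(int, tags)])


@dataclass(frozen=True)
class PlantedCluster:
    dimension: str
    lobe: str
    seed_voxel: int
    voxels: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.voxels)


@dataclass
class GroundTruth:
    """Everything the generator planted; consumed only by tests and reports."""

    geometry: BrainGeometry
    concept_labels: list[str]
    dimension_names: tuple[str, ...]
    concept_scores: np.ndarray  # concepts x dimensions, z-scored per column
    loading_maps: dict[str, np.ndarray]  # group -> voxels x dimensions
    cluster_specs: dict[str, list[PlantedCluster]]
    noise_sd: float
    participant_sd: float
    group_effect: float
    seed: int

    @property
    def loading_map(self) -> np.ndarray:
        """The reference (faculty) loading map."""
        return self.loading_maps["faculty"]

    @property
    def n_concepts(self) -> int:
        return self.concept_scores.shape[0]

    def semantic_dimensions(self) -> list[str]:
        return [d for d in self.dimension_names if d != WORD_LENGTH_DIM]

    def scores_for(self, dimension: str) -> np.ndarray:
        return self.concept_scores[:, self.dimension_names.index(dimension)]


@dataclass
class ActivationDataset:
    """One participant's concepts x presentations x voxels PSC tensor."""

    participant_id: str
    participant_index: int
    group: str
    psc: np.ndarray  # (C, P, V), percent signal change
    concept_labels: list[str]
    geometry: BrainGeometry

    def __post_init__(self) -> None:
        if self.psc.ndim != 3:
            raise ValueError("psc must be a (concepts, presentations, voxels) tensor")
        if self.psc.shape[1] < 2:
            raise ValueError("at least 2 presentations are required")
        if not np.isfinite(self.psc).all():
            raise ValueError("psc contains non-finite values")
        if len(set(self.concept_labels)) != len(self.concept_labels):
            raise ValueError("concept_labels must be unique")

    @property
    def n_concepts(self) -> int:
        return self.psc.shape[0]

    @property
    def n_presentations(self) -> int:
        return self.psc.shape[1]

    def mean_profiles(self, presentations: np.ndarray | None = None) -> np.ndarray:
        """Concepts x voxels activation, averaged over (a subset of) presentations."""
        if presentations is None:
            return self.psc.mean(axis=1)
        return self.psc[:, np.asarray(presentations), :].mean(axis=1)


@dataclass
class RatingsMatrix:
    """Mean behavioural ratings (over raters) of concepts on 1-7 scales."""

    values: np.ndarray  # concepts x rated dimensions
    dimension_names: tuple[str, ...]
    concept_labels: list[str]
    rater_count: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.min() < 1.0 or v.max() > 7.0:
            raise ValueError("ratings must lie in [1, 7]")
        self.values = v

    def column(self, dimension: str) -> np.ndarray:
        return self.values[:, self.dimension_names.index(dimension)]


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    return (x - x.mean()) / sd


def _grow_cluster(
    geom: BrainGeometry,
    lobe: str,
    size: int,
    free: np.ndarray,
    rng: np.random.Generator,
    max_tries: int = 50,
) -> list[int]:
    """Grow one face-connected cluster of `size` free voxels inside a lobe."""
    in_lobe = geom.lobe_mask(lobe)
    for _ in range(max_tries):
        candidates = np.flatnonzero(in_lobe & free)
        if len(candidates) < size:
            break
        seed = int(rng.choice(candidates))
        members = [seed]
        taken = {seed}
        frontier = [seed]
        while len(members) < size and frontier:
            v = frontier.pop(0)
            nbrs = [
                n
                for n in face_neighbors(geom, v)
                if in_lobe[n] and free[n] and n not in taken
            ]
            rng.shuffle(nbrs)
            for n in nbrs:
                if len(members) >= size:
                    break
                members.append(n)
                taken.add(n)
                frontier.append(n)
        if len(members) == size:
            return members
    raise ValueError(
        f"requested clusters exceed the capacity of lobe {lobe!r} "
        f"(could not place a size-{size} cluster)"
    )


def sample_ground_truth(
    geometry: BrainGeometry | None = None,
    concept_labels: list[str] | None = None,
    n_concepts: int | None = None,
    dimension_names: tuple[str, ...] = DEFAULT_DIMENSIONS,
    category_labels: list[str] | None = None,
    clusters_per_dimension: int = 3,
    cluster_size_range: tuple[int, int] = (6, 10),
    loading_scale: float = 1.0,
    noise_sd: float = 0.1,
    participant_sd: float = 0.1,
    group_effect: float = 0.5,
    seed: int = 0,
) -> GroundTruth:
    """Sample a planted factor structure.

    Semantic dimensions get ``clusters_per_dimension`` clusters cycled over
    the three non-occipital lobes; the ``word_length`` dimension (if present)
    gets two clusters confined to the occipital lobe and scores proportional
    to concept-label character counts. A dimension named
    ``classical_post_classical`` is tied to ``category_labels`` when given
    (classical high, post-classical low, plus jitter). The "student" group's
    loading map relocates ``round(group_effect * n_clusters)`` clusters per
    semantic dimension to fresh locations in the same lobe.

    Deterministic given ``seed``; planted clusters are disjoint across
    dimensions and groups.
    """
    if geometry is None:
        geometry = make_geometry((12, 12, 8))
    if concept_labels is None:
        if n_concepts is None:
            concept_labels = default_concept_labels()
        else:
            concept_labels = [f"concept_{i:02d}" for i in range(n_concepts)]
    n_concepts = len(concept_labels)
    if n_concepts < 2:
        raise ValueError("need at least 2 concepts")
    lo, hi = cluster_size_range
    if lo < 2:
        raise ValueError("cluster sizes must be >= 2")
    dimension_names = tuple(dimension_names)

    rng = _rng(seed, _STREAM_STRUCTURE)
    D = len(dimension_names)
    scores = np.empty((n_concepts, D))
    for d, name in enumerate(dimension_names):
        if name == WORD_LENGTH_DIM:
            lengths = np.array([len(lab) for lab in concept_labels], float)
            scores[:, d] = _zscore(lengths)
        elif name == "classical_post_classical" and category_labels is not None:
            base = np.where(np.asarray(category_labels) == "classical", 1.0, -1.0)
            scores[:, d] = _zscore(base + 0.5 * rng.standard_normal(n_concepts))
        else:
            scores[:, d] = _zscore(rng.standard_normal(n_concepts))

    V = geometry.n_voxels
    free = np.ones(V, bool)
    semantic_lobes = [l for l in LOBES if l != "occipital"]
    clusters: list[PlantedCluster] = []
    loading = np.zeros((V, D))
    for d, name in enumerate(dimension_names):
        if name == WORD_LENGTH_DIM:
            lobes = ["occipital", "occipital"]
        else:
            lobes = [
                semantic_lobes[(d + k) % len(semantic_lobes)]
                for k in range(clusters_per_dimension)
            ]
        for lobe in lobes:
            size = int(rng.integers(lo, hi + 1))
            members = _grow_cluster(geometry, lobe, size, free, rng)
            free[members] = False
            loading[members, d] = loading_scale * rng.uniform(0.8, 1.2, size)
            clusters.append(PlantedCluster(name, lobe, members[0], tuple(members)))

    # student topography: relocate a fraction of each semantic dimension's clusters
    student_loading = loading.copy()
    student_clusters = list(clusters)
    for d, name in enumerate(dimension_names):
        if name == WORD_LENGTH_DIM:
            continue
        own = [i for i, c in enumerate(student_clusters) if c.dimension == name]
        n_move = int(round(group_effect * len(own)))
        for i in own[:n_move]:
            old = student_clusters[i]
            size = old.size
            members = _grow_cluster(geometry, old.lobe, size, free, rng)
            free[members] = False
            student_loading[list(old.voxels), d] = 0.0
            student_loading[members, d] = loading_scale * rng.uniform(0.8, 1.2, size)
            student_clusters[i] = PlantedCluster(name, old.lobe, members[0], tuple(members))

    return GroundTruth(
        geometry=geometry,
        concept_labels=list(concept_labels),
        dimension_names=dimension_names,
        concept_scores=scores,
        loading_maps={"faculty": loading, "student": student_loading},
        cluster_specs={"faculty": clusters, "student": student_clusters},
        noise_sd=float(noise_sd),
        participant_sd=float(participant_sd),
        group_effect=float(group_effect),
        seed=int(seed),
    )


def simulate_participant(
    gt: GroundTruth,
    participant_index: int,
    n_presentations: int = 6,
    group: str = "faculty",
) -> ActivationDataset:
    """Simulate one participant's PSC tensor from the planted structure.

    Deterministic given ``(gt.seed, participant_index, group)``.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    if n_presentations < 2:
        raise ValueError("n_presentations must be >= 2")
    rng = _rng(gt.seed, _STREAM_PARTICIPANT, participant_index, GROUPS.index(group))
    L = gt.loading_maps[group]
    mask = L != 0
    pert = np.zeros_like(L)
    pert[mask] = gt.participant_sd * rng.standard_normal(int(mask.sum()))
    signal = gt.concept_scores @ (L + pert).T  # C x V
    C, V = signal.shape
    psc = np.repeat(signal[:, None, :], n_presentations, axis=1)
    if gt.noise_sd > 0:
        psc = psc + gt.noise_sd * rng.standard_normal((C, n_presentations, V))
    prefix = "F" if group == "faculty" else "S"
    return ActivationDataset(
        participant_id=f"{prefix}{participant_index:02d}",
        participant_index=participant_index,
        group=group,
        psc=psc,
        concept_labels=list(gt.concept_labels),
        geometry=gt.geometry,
    )


def simulate_cohort(
    gt: GroundTruth,
    n_faculty: int = 10,
    n_students: int = 0,
    n_presentations: int = 6,
) -> list[ActivationDataset]:
    """Simulate a cohort sharing one geometry; participant indices are unique
    across groups (faculty first)."""
    if n_faculty + n_students < 1:
        raise ValueError("cohort must contain at least one participant")
    out = [
        simulate_participant(gt, i, n_presentations, "faculty")
        for i in range(n_faculty)
    ]
    out += [
        simulate_participant(gt, n_faculty + j, n_presentations, "student")
        for j in range(n_students)
    ]
    return out


def simulate_ratings(
    gt: GroundTruth,
    rated_dimensions: tuple[str, ...] | None = None,
    n_raters: int = 6,
    rater_noise_sd: float = 1.0,
    seed: int | None = None,
) -> RatingsMatrix:
    """Simulate 7-point-scale ratings of the true dimension scores.

    Each rater's rating is an affine map of the true z-score (±2 sd to the
    scale endpoints 1 and 7: ``4 + 1.5 z``) plus Gaussian rater noise,
    rounded and clipped to integers 1..7; a cell is the mean over raters.
    """
    if rated_dimensions is None:
        rated_dimensions = tuple(gt.semantic_dimensions())
    rated_dimensions = tuple(rated_dimensions)
    for d in rated_dimensions:
        if d not in gt.dimension_names:
            raise ValueError(f"unknown dimension {d!r}")
        if d == WORD_LENGTH_DIM:
            raise ValueError("the word_length nuisance dimension is not rated")
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    rng = _rng(gt.seed if seed is None else seed, _STREAM_RATINGS)
    cols = []
    for d in rated_dimensions:
        z = gt.scores_for(d)
        per_rater = 4.0 + 1.5 * z[:, None] + rater_noise_sd * rng.standard_normal(
            (len(z), n_raters)
        )
        per_rater = np.clip(np.floor(per_rater + 0.5), 1, 7)
        cols.append(per_rater.mean(axis=1))
    return RatingsMatrix(
        values=np.column_stack(cols),
        dimension_names=rated_dimensions,
        concept_labels=list(gt.concept_labels),
        rater_count=int(n_raters),
    )


def simulate_timecourse(
    gt: GroundTruth,
    participant_index: int,
    n_presentations: int = 6,
    group: str = "faculty",
    baseline: float = 100.0,
    trial_spacing_s: int = 10,
    window_offset_s: int = 5,
    window_len_s: int = 4,
) -> tuple[np.ndarray, list[tuple[int, int, int]], float]:
    """Emit per-voxel raw time series realising a participant's PSC tensor.

    Trials follow the 4 s stimulus / 6 s rest cadence (one trial every
    ``trial_spacing_s`` seconds, 1 Hz sampling). During the hemodynamic
    window of each trial the series equals ``baseline * (1 + psc / 100)``;
    elsewhere it sits at baseline, so trial-window PSC extraction recovers
    the tensor exactly.

    Returns ``(series, events, baseline)`` where ``series`` is voxels x time
    and ``events`` lists ``(concept, presentation, onset_sample)``.
    """
    ds = simulate_participant(gt, participant_index, n_presentations, group)
    C, P, V = ds.psc.shape
    order_rng = _rng(gt.seed, _STREAM_PARTICIPANT, participant_index, 99)
    events: list[tuple[int, int, int]] = []
    t = 0
    for p in range(P):
        for c in order_rng.permutation(C):
            events.append((int(c), p, t))
            t += trial_spacing_s
    T = t + trial_spacing_s
    series = np.full((V, T), baseline)
    for c, p, onset in events:
        w = slice(onset + window_offset_s, onset + window_offset_s + window_len_s)
        series[:, w] = baseline * (1.0 + ds.psc[c, p, :, None] / 100.0)
    return series, events, baseline
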