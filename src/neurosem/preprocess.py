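"""Trial-window PSC extraction, voxel stability scoring and voxel selection.

A *stable* voxel is one whose 45-concept activation profile replicates
across stimulus presentations; its score is the mean pairwise Pearson
correlation between the profile vectors of every pair of presentations.
Stability (and hence feature selection) is always computed from the
training presentations of the current cross-validation fold only.

Voxels that are constant within some presentation have an undefined
correlation; they receive a ``-inf`` sentinel so they can never be
selected, and their count is logged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .geometry import BrainGeometry

logger = logging.getLogger(__name__)

#: sentinel for voxels whose stability is undefined (zero variance somewhere)
UNSELECTABLE = -np.inf


def compute_psc(
    timecourse: np.ndarray,
    onsets: np.ndarray | list[int],
    baseline_level: float,
    window_offset_s: int = 5,
    window_len_s: int = 4,
) -> np.ndarray:
    """Extract trial activations as percent signal change from raw series.

    For each event, the activation is the mean of the ``window_len_s``
    samples (1 Hz sampling) starting ``window_offset_s`` after the onset,
    expressed as percent change relative to ``baseline_level``.

    Parameters
    ----------
    timecourse
        ``(T,)`` series for one voxel or ``(V, T)`` for many.
    onsets
        Event onset sample indices.

    Returns
    -------
    ``(n_events, V)`` matrix of PSC values (``V = 1`` for a 1-D series).
    """
    if baseline_level == 0:
        raise ValueError("baseline_level must be nonzero")
    tc = np.atleast_2d(np.asarray(timecourse, float))
    T = tc.shape[1]
    out = np.empty((len(onsets), tc.shape[0]))
    for e, onset in enumerate(onsets):
        start = int(onset) + window_offset_s
        stop = start + window_len_s
        if start < 0 or stop > T:
            raise ValueError(
                f"event {e} (onset {onset}): window [{start}, {stop}) "
                f"exceeds the series of length {T}"
            )
        out[e] = (tc[:, start:stop].mean(axis=1) - baseline_level) / baseline_level * 100.0
    return out


@dataclass(frozen=True)
class StabilityScores:
    """Per-voxel stability with provenance of the presentations used."""

    scores: np.ndarray
    presentations: tuple[int, ...]

    @property
    def n_unscoreable(self) -> int:
        return int(np.isneginf(self.scores).sum())


def _pairwise_profile_correlations(stack: np.ndarray) -> np.ndarray:
    """Mean pairwise Pearson r over the first axis of a (P, C, V) stack.

    Returns a (V,) score with ``-inf`` where any member has zero variance.
    """
    P, C, V = stack.shape
    centered = stack - stack.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1)  # (P, V)
    degenerate = (sd == 0).any(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.zeros(V)
        n_pairs = 0
        for p, q in combinations(range(P), 2):
            cov = (centered[p] * centered[q]).mean(axis=0)
            scores += cov / (sd[p] * sd[q])
            n_pairs += 1
        scores /= n_pairs
    scores[degenerate] = UNSELECTABLE
    return scores


def voxel_stability(
    psc_subset: np.ndarray, presentations: tuple[int, ...] | None = None
) -> StabilityScores:
    """Mean pairwise presentation-to-presentation profile correlation per voxel.

    Parameters
    ----------
    psc_subset
        ``(concepts, presentations, voxels)`` PSC tensor restricted to the
        training presentations of the current fold.
    presentations
        Optional provenance record of which presentations these are.
    """
    psc = np.asarray(psc_subset, float)
    if psc.ndim != 3:
        raise ValueError("expected a (concepts, presentations, voxels) tensor")
    C, P, V = psc.shape
    if P < 2:
        raise ValueError("need at least 2 presentations")
    if C < 2:
        raise ValueError("need at least 2 concepts")
    scores = _pairwise_profile_correlations(psc.transpose(1, 0, 2))
    n_bad = int(np.isneginf(scores).sum())
    if n_bad:
        logger.info("voxel_stability: %d voxel(s) had zero variance; marked unselectable", n_bad)
    if presentations is None:
        presentations = tuple(range(P))
    return StabilityScores(scores=scores, presentations=tuple(presentations))


def cross_participant_consistency(mean_activations: list[np.ndarray]) -> np.ndarray:
    """Per-voxel consistency of concept profiles across participants.

    ``score[v]`` is the mean over all participant pairs of the Pearson
    correlation between their concept-profile vectors at voxel v. Inputs are
    presentation-averaged ``(concepts, voxels)`` matrices on a shared
    geometry. Zero-variance profiles yield the ``-inf`` sentinel.
    """
    if len(mean_activations) < 2:
        raise ValueError("need at least 2 participants")
    stack = np.stack([np.asarray(m, float) for m in mean_activations])
    return _pairwise_profile_correlations(stack)


def select_stable_voxels(
    scores: StabilityScores | np.ndarray,
    n: int,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Indices of the ``n`` highest-scoring selectable voxels.

    Ties at the cutoff are broken by ascending voxel index. ``mask``
    restricts selection to a region (e.g. one lobe); without it the whole
    brain is ranked (classification mode). If fewer than ``n`` scoreable
    voxels exist, all of them are returned with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    s = scores.scores if isinstance(scores, StabilityScores) else np.asarray(scores, float)
    eligible = np.isfinite(s)
    if mask is not None:
        eligible = eligible & np.asarray(mask, bool)
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        raise ValueError("region contains no scoreable voxels")
    # stable sort on (-score, index): lexsort's last key dominates
    order = np.lexsort((idx, -s[idx]))
    ranked = idx[order]
    if ranked.size < n:
        warnings.warn(
            f"only {ranked.size} scoreable voxels available for a request of {n}",
            stacklevel=2,
        )
        return ranked
    return ranked[:n]


def select_per_lobe(
    scores: StabilityScores | np.ndarray,
    geometry: BrainGeometry,
    n_per_lobe: int,
) -> dict[str, np.ndarray]:
    """Top-``n_per_lobe`` stable voxels within each lobe."""
    return {
        lobe: select_stable_voxels(scores, n_per_lobe, geometry.lobe_mask(lobe))
        for lobe in geometry.lobe_names
    }
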