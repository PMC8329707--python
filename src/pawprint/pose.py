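"""Pose-track statistics: initial limb spread and nose return distance.

These quantify the two movement alterations the network analysis points
at: *posture* — the spread between front and hind limbs in the first
frame (larger spread = limbs extended, reduced postural support) — and
*stereotypy* — the distance between the nose position at the 1st and
11th analysis frames (small when a periodic movement returns the animal
to its starting pose).

Frame indices in this module are 1-based, matching how the measures are
reported ("the 1st and 11th frame"); the conversion to 0-based array
indexing happens here and nowhere else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synthetic import KeypointTrack

__all__ = [
    "PoseStatsResult",
    "limb_spread",
    "return_distance",
    "align_trajectories",
    "group_compare",
    "pose_statistics",
]

_LIMBS = ("left_fore", "right_fore", "left_hind", "right_hind")


@dataclass
class PoseStatsResult:
    """Per-trial metric values with a two-group comparison."""

    metric: str
    values_a: np.ndarray
    values_b: np.ndarray
    label_a: str
    label_b: str
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    test: str
    statistic: float
    p_value: float


def _idx(frame_index: int, n_frames: int, what: str) -> int:
    """1-based user-facing frame index -> 0-based array index."""
    if not 1 <= frame_index <= n_frames:
        raise IndexError(
            f"{what}: frame {frame_index} out of range for a {n_frames}-frame track"
        )
    return frame_index - 1


def limb_spread(
    track: KeypointTrack,
    frame_index: int = 1,
    pairs: str = "all",
    likelihood_gate: float = 0.6,
) -> float:
    """Mean front–hind limb distance (pixels) at a frame (1-based).

    ``pairs="all"`` averages the four fore x hind Euclidean distances;
    ``pairs="ipsilateral"`` only the two same-side pairs.  Returns NaN
    (metric undefined) when any required limb falls below the
    likelihood gate.
    """
    t = _idx(frame_index, track.n_frames, "limb_spread")
    if any(track.part_likelihood(p)[t] < likelihood_gate for p in _LIMBS):
        warnings.warn(
            f"limb_spread undefined at frame {frame_index}: limb keypoint below "
            f"likelihood gate {likelihood_gate}",
            stacklevel=2,
        )
        return float("nan")
    lf, rf, lh, rh = (track.part(p)[t] for p in _LIMBS)
    if pairs == "all":
        combos = [(lf, lh), (lf, rh), (rf, lh), (rf, rh)]
    elif pairs == "ipsilateral":
        combos = [(lf, lh), (rf, rh)]
    else:
        raise ValueError(f"unknown pairs mode {pairs!r}")
    return float(np.mean([np.linalg.norm(a - b) for a, b in combos]))


def return_distance(track: KeypointTrack, i: int = 1, j: int = 11) -> float:
    """Euclidean distance (pixels) between nose positions at frames i and j
    (1-based).  Small values indicate a movement cycle returning to its
    starting pose."""
    nose = track.part("nose")
    ti = _idx(i, track.n_frames, "return_distance")
    tj = _idx(j, track.n_frames, "return_distance")
    return float(np.linalg.norm(nose[ti] - nose[tj]))


def align_trajectories(tracks, n_frames: int = 16) -> np.ndarray:
    """Nose paths over the first ``n_frames`` frames, each translated so
    frame 1 sits at the origin.  Tracks shorter than ``n_frames`` are
    excluded with a warning."""
    paths = []
    for k, track in enumerate(tracks):
        if track.n_frames < n_frames:
            warnings.warn(
                f"track {k} excluded from alignment: {track.n_frames} < {n_frames} frames",
                stacklevel=2,
            )
            continue
        nose = track.part("nose")[:n_frames]
        paths.append(nose - nose[0])
    if not paths:
        raise ValueError("no track long enough to align")
    return np.stack(paths)


def group_compare(values_a, values_b, test: str = "t") -> tuple[float, float]:
    """Two-sided comparison of two value sets.

    ``test`` is ``"t"`` (Welch), ``"mann_whitney_u"`` or
    ``"kolmogorov_smirnov"``.  Degenerate zero-variance identical groups
    return p = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 non-missing values")
    if a.std() == 0 and b.std() == 0 and len(a) == len(b) and np.allclose(np.sort(a), np.sort(b)):
        warnings.warn("degenerate identical zero-variance groups: p = 1", stacklevel=2)
        return 0.0, 1.0
    if test == "t":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif test == "mann_whitney_u":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "kolmogorov_smirnov":
        res = stats.ks_2samp(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def pose_statistics(
    tracks_a,
    tracks_b,
    label_a: str,
    label_b: str,
    metric: str = "limb_spread",
    test: str = "t",
    **metric_kwargs,
) -> PoseStatsResult:
    """Per-trial metric values for two groups plus their comparison."""
    fn = {"limb_spread": limb_spread, "return_distance": return_distance}[metric]
    va = np.array([fn(t, **metric_kwargs) for t in tracks_a], dtype=float)
    vb = np.array([fn(t, **metric_kwargs) for t in tracks_b], dtype=float)
    stat, p = group_compare(va, vb, test=test)

    def _ms(v):
        v = v[~np.isnan(v)]
        return float(v.mean()), float(v.std(ddof=1) / np.sqrt(len(v)))

    ma, sa = _ms(va)
    mb, sb = _ms(vb)
    return PoseStatsResult(
        metric=metric, values_a=va, values_b=vb, label_a=label_a, label_b=label_b,
        mean_a=ma, sem_a=sa, mean_b=mb, sem_b=sb, test=test, statistic=stat, p_value=p,
    )
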