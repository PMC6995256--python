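"""Low-level local visual-motion quantification for short video clips.

The measure is deliberately simple: estimate a scalar noise level from the
frame-to-frame luminance change in the (static) background, then count, for
every pair of consecutive frames, the pixels anywhere in the frame whose
absolute luminance change exceeds that noise level.  The mean count over
frame pairs is the clip's motion value; the sum over the five clips of a
stimulation block is the block's cumulative motion, which enters the fMRI
model as a covariate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: Rec.601 luma weights (R, G, B); they sum to 1.
REC601_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class VideoClip:
    """A stack of luminance frames plus a static-background mask.

    Parameters
    ----------
    frames:
        ``(n_frames, height, width)`` luminance rasters on a 0-255 scale.
    background_mask:
        ``(height, width)`` boolean raster, ``True`` where no foreground
        object ever appears (used for the noise surrogate).
    fps:
        Frame rate in frames per second.
    rgb:
        Optional ``(n_frames, height, width, 3)`` source frames.
    label:
        Free-form tags (condition, actor, emotion, clip id).
    meta:
        Generator-side ground truth (realized noise level, planted motion).
    """

    frames: np.ndarray
    background_mask: np.ndarray
    fps: float = 25.0
    rgb: np.ndarray | None = None
    label: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("clip needs >= 2 frames of identical shape")
        self.background_mask = np.asarray(self.background_mask, dtype=bool)
        if self.background_mask.shape != self.frames.shape[1:]:
            raise ValueError("background mask shape must match frame shape")
        if not self.background_mask.any():
            raise ValueError("background mask is empty")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def n_pixels(self) -> int:
        return int(np.prod(self.frames.shape[1:]))


@dataclass
class MotionResult:
    """Per-clip motion: supra-noise pixel counts for each frame pair."""

    noise_level: float
    per_pair_counts: np.ndarray
    clip_motion: float
    clip_id: str = ""

    def __post_init__(self) -> None:
        self.per_pair_counts = np.asarray(self.per_pair_counts, dtype=float)
        if not np.isclose(self.clip_motion, self.per_pair_counts.mean()):
            raise ValueError("clip_motion must equal mean(per_pair_counts)")


@dataclass
class BlockMotion:
    """Cumulative motion of the five clips shown in one stimulation block."""

    block_id: str
    clip_ids: tuple
    cumulative_motion: float
    condition: str

    def __post_init__(self) -> None:
        if len(self.clip_ids) != 5:
            raise ValueError("a stimulation block holds exactly 5 clips")


def to_luminance(rgb_frame: np.ndarray) -> np.ndarray:
    """Convert an RGB raster (last axis = 3 channels, 0-255) to luminance.

    Uses the Rec.601 weighting 0.299 R + 0.587 G + 0.114 B, so grayscale
    inputs map to themselves.
    """
    rgb_frame = np.asarray(rgb_frame, dtype=np.float64)
    if rgb_frame.shape[-1] != 3:
        raise ValueError("expected 3 channels on the last axis")
    return rgb_frame @ REC601_WEIGHTS


def background_mask_from_color(
    rgb_frames: np.ndarray, key_rgb, tol: float = 8.0
) -> np.ndarray:
    """Mask of pixels that stay within ``tol`` of the key color in all frames.

    The stimuli carry a uniform chroma-key border; a pixel belongs to the
    background if every frame keeps it within ``tol`` intensity units of the
    key color in every channel.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    rgb_frames = np.asarray(rgb_frames, dtype=np.float64)
    key = np.asarray(key_rgb, dtype=np.float64)
    close = np.abs(rgb_frames - key) <= tol  # (n, h, w, 3)
    mask = close.all(axis=(0, 3))
    if not mask.any():
        raise ValueError(
            "no pixel matched the key color in all frames; "
            "increase tol or supply a background mask manually"
        )
    return mask


def _pair_abs_diffs(clip: VideoClip) -> np.ndarray:
    return np.abs(np.diff(clip.frames, axis=0))


def _pair_statistic(values: np.ndarray, stat: str) -> float:
    """One noise summary for a single frame pair's background |Δluminance|."""
    if stat == "max":
        return float(values.max())
    if stat == "mean":
        return float(values.mean())
    m = re.fullmatch(r"mean\+(\d+(?:\.\d+)?)sd", stat)
    if m:
        return float(values.mean() + float(m.group(1)) * values.std())
    m = re.fullmatch(r"p(\d+(?:\.\d+)?)", stat)
    if m:
        return float(np.percentile(values, float(m.group(1))))
    raise ValueError(f"unknown noise statistic {stat!r}")


def estimate_noise(clip: VideoClip, stat: str = "p95") -> float:
    """Estimate the clip's noise level from background luminance change.

    For each consecutive frame pair the statistic ``stat`` is computed over
    the absolute luminance differences inside the background mask; the
    per-pair values are averaged.  ``stat`` may be ``"pNN"`` (percentile,
    default ``p95``), ``"mean"``, ``"mean+Ksd"`` or ``"max"``.
    """
    diffs = _pair_abs_diffs(clip)[:, clip.background_mask]
    return float(np.mean([_pair_statistic(d, stat) for d in diffs]))


def clip_motion(
    clip: VideoClip,
    noise_level: float | None = None,
    noise_stat: str = "p95",
    clip_id: str = "",
) -> MotionResult:
    """Count supra-noise pixels for every frame pair and average the counts.

    ``noise_level`` defaults to :func:`estimate_noise` with ``noise_stat``.
    A pixel contributes to a pair's count when its absolute luminance change
    exceeds (strictly) the noise level; the whole frame is counted, not only
    the region inside the border.
    """
    if noise_level is None:
        noise_level = estimate_noise(clip, noise_stat)
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    diffs = _pair_abs_diffs(clip)
    counts = (diffs > noise_level).sum(axis=(1, 2))
    return MotionResult(
        noise_level=float(noise_level),
        per_pair_counts=counts.astype(float),
        clip_motion=float(counts.mean()),
        clip_id=clip_id or str(clip.label.get("clip_id", "")),
    )


def block_motion(clips, condition: str, block_id: str = "") -> BlockMotion:
    """Sum the motion values of the five clips shown in one block."""
    clips = list(clips)
    if len(clips) != 5:
        raise ValueError(f"expected exactly 5 clip results, got {len(clips)}")
    return BlockMotion(
        block_id=block_id,
        clip_ids=tuple(c.clip_id for c in clips),
        cumulative_motion=float(sum(c.clip_motion for c in clips)),
        condition=condition,
    )


def correlate_ratings(motions, ratings) -> tuple[float, int, float]:
    """Pearson correlation between clip motion and perceived-motion ratings.

    Returns ``(r, n, p)`` with a two-sided p-value from the t distribution
    with ``n - 2`` degrees of freedom.
    """
    motions = np.asarray(motions, dtype=float)
    ratings = np.asarray(ratings, dtype=float)
    if motions.shape != ratings.shape or motions.ndim != 1:
        raise ValueError("motions and ratings must be 1-D vectors of equal length")
    n = motions.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if motions.std() == 0 or ratings.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.corrcoef(motions, ratings)[0, 1])
    if abs(r) >= 1.0:
        return r, n, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, n, float(p)


def compare_block_motion(
    body_motions, object_motions, welch: bool = False
) -> tuple[float, float, float]:
    """Two-sample t-test of body-block vs object-block cumulative motion.

    Default is the pooled-variance Student test with ``df = n1 + n2 - 2``;
    set ``welch=True`` for the unequal-variance Welch test with
    Welch-Satterthwaite degrees of freedom.  Returns ``(t, df, p)``.
    """
    a = np.asarray(body_motions, dtype=float)
    b = np.asarray(object_motions, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    if welch:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = (va + vb) ** 2 / (
            va**2 / (a.size - 1) + vb**2 / (b.size - 1)
        )
    else:
        df = a.size + b.size - 2
    return float(res.statistic), float(df), float(res.pvalue)
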