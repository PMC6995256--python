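"""Synthetic stimuli, ratings and BOLD data with planted ground truth.

Every downstream stage of the localizer is testable against these
generators: video clips with an analytically known number of moving pixels
per frame pair, perceived-motion rating vectors built to an exact target
correlation, and 4-D BOLD volumes with block-design activations planted at
chosen MNI coordinates on top of drift, head-motion components and Gaussian
noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import nibabel as nib

from . import glm
from .design import BlockSchedule
from .motion import REC601_WEIGHTS, VideoClip

DEFAULT_BACKGROUND_RGB = (159, 202, 145)  # chroma-key green of the stimuli


@dataclass(frozen=True)
class SyntheticClipSpec:
    """Parameters of one motion-controlled clip.

    ``moving_pixels_per_frame`` is the exact number of pixels whose
    luminance change between consecutive frames exceeds the clip's realized
    noise level; it must be even (a rigid object of edge length ``s``
    translating one pixel per frame changes ``2 s`` pixels).
    """

    width: int = 960
    height: int = 540
    n_frames: int = 50
    fps: float = 25.0
    background_rgb: tuple = DEFAULT_BACKGROUND_RGB
    noise_sd: float = 0.0
    moving_pixels_per_frame: int = 120
    object_shape: str = "square"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if not 0 <= self.moving_pixels_per_frame <= self.width * self.height:
            raise ValueError("moving pixel count out of range")
        if self.moving_pixels_per_frame % 2:
            raise ValueError(
                "moving_pixels_per_frame must be even (leading plus trailing "
                "edge of a rigid object translating 1 px/frame)"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.object_shape not in ("square", "bar"):
            raise ValueError("object_shape must be 'square' or 'bar'")


def _object_extent(spec: SyntheticClipSpec) -> tuple[int, int]:
    """(rows, cols) of the moving object; 2*rows pixels change per step."""
    edge = spec.moving_pixels_per_frame // 2
    if spec.object_shape == "square":
        return edge, edge
    return edge, max(1, edge // 4)  # tall thin bar


def make_clip(spec: SyntheticClipSpec, keep_rgb: bool = False) -> VideoClip:
    """Render a clip with a dark object translating 1 px/frame on green.

    Achromatic Gaussian noise of sd ``noise_sd`` is added to every pixel of
    every frame (the same draw on all three channels, so luminance noise has
    exactly that sd).  The clip's ``meta`` records the realized noise level
    (the largest background luminance change actually drawn), chosen so that
    thresholding at it recovers exactly ``moving_pixels_per_frame`` changed
    pixels per frame pair; the background mask excludes the object's sweep.
    """
    rows, cols = _object_extent(spec)
    n_steps = spec.n_frames - 1
    if spec.moving_pixels_per_frame:
        if rows > spec.height or cols + n_steps >= spec.width:
            raise ValueError(
                "object sweep exceeds the frame: reduce moving_pixels_per_frame "
                "or n_frames, or enlarge the frame"
            )
    bg_lum = float(np.asarray(spec.background_rgb, float) @ REC601_WEIGHTS)
    clean = np.full((spec.n_frames, spec.height, spec.width), bg_lum)
    mask = np.ones((spec.height, spec.width), dtype=bool)
    if spec.moving_pixels_per_frame:
        y0 = (spec.height - rows) // 2
        x0 = (spec.width - (cols + n_steps)) // 2
        for f in range(spec.n_frames):
            clean[f, y0 : y0 + rows, x0 + f : x0 + f + cols] = 0.0
        mask[y0 : y0 + rows, x0 : x0 + cols + n_steps] = False

    rng = np.random.default_rng(spec.seed)
    noise = (
        rng.normal(0.0, spec.noise_sd, clean.shape) if spec.noise_sd > 0 else 0.0
    )
    frames = clean + noise

    # realized noise level: the largest |Δluminance| among pixels whose
    # noise-free luminance did not change
    diffs = np.abs(np.diff(frames, axis=0))
    changed = np.abs(np.diff(clean, axis=0)) > 0
    if changed.any():
        noise_level = float(diffs[~changed].max()) if (~changed).any() else 0.0
        min_signal = float(diffs[changed].min())
        if min_signal <= noise_level:
            raise ValueError(
                "noise_sd too large relative to the object/background "
                "contrast: the planted motion count would be ambiguous"
            )
        assert int((diffs[0] > noise_level).sum()) == spec.moving_pixels_per_frame
    else:
        noise_level = float(diffs.max()) if spec.noise_sd > 0 else 0.0

    rgb = None
    if keep_rgb:
        base = np.zeros((spec.n_frames, spec.height, spec.width, 3))
        base += np.where(
            (clean == bg_lum)[..., None],
            np.asarray(spec.background_rgb, float),
            0.0,
        )
        rgb = base + (np.asarray(noise)[..., None] if spec.noise_sd > 0 else 0.0)

    return VideoClip(
        frames=frames,
        background_mask=mask,
        fps=spec.fps,
        rgb=rgb,
        meta={
            "true_moving_pixels": spec.moving_pixels_per_frame,
            "noise_level": noise_level,
            "noise_sd": spec.noise_sd,
            "spec": dataclasses.asdict(spec),
        },
    )


def make_stimulus_set(
    n_actors: int,
    emotions,
    spec_template: SyntheticClipSpec | None = None,
    actor_sexes=None,
    motion_range: tuple | None = None,
) -> list:
    """One clip per actor x emotion, with labels and varied planted motion.

    ``motion_range`` bounds the per-clip planted moving-pixel count (even
    integers drawn deterministically from the template seed); by default it
    spans 0.5-1.5x the template's count so clips differ in motion the way a
    filmed stimulus set would.
    """
    if n_actors < 1:
        raise ValueError("need at least one actor")
    emotions = list(emotions)
    if not emotions:
        raise ValueError("need at least one emotion")
    if actor_sexes is not None and len(actor_sexes) != n_actors:
        raise ValueError("one sex label per actor required")
    spec_template = spec_template or SyntheticClipSpec()
    base = spec_template.moving_pixels_per_frame
    if motion_range is None:
        motion_range = (max(2, base // 2), max(2, (3 * base) // 2))
    rng = np.random.default_rng(spec_template.seed)
    clips = []
    for a in range(n_actors):
        for emo in emotions:
            moving = 2 * int(rng.integers(motion_range[0] // 2, motion_range[1] // 2 + 1))
            spec = dataclasses.replace(
                spec_template,
                moving_pixels_per_frame=moving,
                seed=int(rng.integers(2**31 - 1)),
            )
            clip = make_clip(spec)
            clip.label = {
                "clip_id": f"actor{a:02d}_{emo}",
                "actor": f"actor{a:02d}",
                "emotion": emo,
            }
            if actor_sexes is not None:
                clip.label["sex"] = actor_sexes[a]
            clips.append(clip)
    return clips


@dataclass(frozen=True)
class SyntheticBoldSpec:
    """Parameters of one synthetic 4-D BOLD acquisition.

    ``active_sites`` is a list of ``(mni_xyz, condition_group, amplitude)``
    with amplitude in signal units: the planted time course at a site voxel
    is ``amplitude`` times the unit-peak HRF-convolved condition boxcar.
    The affine maps the grid center to MNI (0, 0, 0).
    """

    grid_shape: tuple = (20, 24, 20)
    voxel_size_mm: float = 3.0
    n_volumes: int = 246
    tr_s: float = 2.6
    schedule: BlockSchedule | None = None
    active_sites: tuple = ()
    noise_sd: float = 1.0
    drift_amplitude: float = 0.0
    head_motion_sd: float = 0.0
    baseline: float = 100.0
    site_radius_mm: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes < 1 or self.voxel_size_mm <= 0:
            raise ValueError("invalid grid/timing parameters")
        for site in self.active_sites:
            if not np.isfinite(site[2]):
                raise ValueError("site amplitudes must be finite")


def bold_affine(grid_shape, voxel_size_mm: float) -> np.ndarray:
    """Voxel-to-mm affine putting MNI (0,0,0) at the grid center."""
    shape = np.asarray(grid_shape, float)
    aff = np.eye(4)
    aff[:3, :3] = np.eye(3) * voxel_size_mm
    aff[:3, 3] = -voxel_size_mm * (shape - 1) / 2.0
    return aff


def _head_motion_traces(rng, n_volumes: int, sd: float) -> np.ndarray:
    """Six smooth random walks (3 translations, 3 rotations), sd-scaled."""
    steps = rng.normal(size=(n_volumes, 6))
    walk = np.cumsum(steps, axis=0)
    kernel = np.ones(5) / 5.0
    smooth = np.column_stack(
        [np.convolve(walk[:, j], kernel, mode="same") for j in range(6)]
    )
    smooth -= smooth.mean(axis=0)
    scale = smooth.std(axis=0)
    scale[scale == 0] = 1.0
    return smooth / scale * sd


def make_bold(spec: SyntheticBoldSpec):
    """Generate a synthetic run; returns ``(nifti_image, ground_truth)``.

    Signal model per voxel: baseline + planted condition responses + drift
    (linear plus slow cosine, random per-voxel weights) + head-motion
    components (the six traces times random per-voxel weights) + white
    Gaussian noise.  The ground-truth record lists planted voxel indices and
    amplitudes per site, the head-motion traces, and the affine.
    """
    if spec.schedule is None:
        raise ValueError("a BlockSchedule is required")
    if spec.schedule.total_duration_s > spec.n_volumes * spec.tr_s + 1e-9:
        raise ValueError("schedule is longer than the acquisition")
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    affine = bold_affine(shape, spec.voxel_size_mm)
    inv = np.linalg.inv(affine)
    data = np.full(shape + (spec.n_volumes,), spec.baseline, dtype=np.float64)

    regressors = {
        g: glm.condition_regressor(spec.schedule, g, spec.n_volumes, spec.tr_s)
        for g in ("body", "object")
    }
    ijk = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ).astype(float)
    mm = ijk @ (affine[:3, :3].T) + affine[:3, 3]

    sites = []
    for xyz, condition, amplitude in spec.active_sites:
        xyz = np.asarray(xyz, float)
        center = inv[:3, :3] @ xyz + inv[:3, 3]
        center_idx = np.round(center).astype(int)
        if np.any(center_idx < 0) or np.any(center_idx >= np.array(shape)):
            raise ValueError(f"active site {tuple(xyz)} falls outside the grid")
        dist = np.linalg.norm(mm - xyz, axis=-1)
        blob = dist <= spec.site_radius_mm
        data[blob] += amplitude * regressors[condition]
        sites.append(
            {
                "mni": [float(v) for v in xyz],
                "voxel": [int(v) for v in center_idx],
                "voxels": [list(map(int, v)) for v in np.argwhere(blob)],
                "condition": condition,
                "amplitude": float(amplitude),
            }
        )

    t = np.arange(spec.n_volumes) / spec.n_volumes
    if spec.drift_amplitude > 0:
        drift_shapes = np.stack(
            [t - t.mean(), np.cos(2 * np.pi * t * spec.n_volumes * spec.tr_s / 300.0)]
        )
        weights = rng.normal(size=shape + (2,)) * spec.drift_amplitude
        data += weights @ drift_shapes

    hm_traces = np.zeros((spec.n_volumes, 6))
    if spec.head_motion_sd > 0:
        hm_traces = _head_motion_traces(rng, spec.n_volumes, spec.head_motion_sd)
        weights = rng.normal(size=shape + (6,))
        data += weights @ hm_traces.T

    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)

    img = nib.Nifti1Image(data, affine)
    truth = {
        "sites": sites,
        "head_motion": hm_traces,
        "noise_sd": spec.noise_sd,
        "affine": affine,
        "grid_shape": shape,
        "n_volumes": spec.n_volumes,
        "tr_s": spec.tr_s,
    }
    return img, truth


def make_ratings(
    motions,
    target_r: float,
    seed: int = 0,
    loc: float = 4.0,
    scale: float = 1.5,
) -> np.ndarray:
    """Rating vector whose sample Pearson r with ``motions`` hits target_r.

    Constructed from the standardized motion vector plus an orthogonalized
    noise component mixed as ``r x + sqrt(1 - r^2) z``, so the sample
    correlation equals the target up to floating point; ``loc``/``scale``
    place the ratings on a plausible 1-7-style scale.
    """
    motions = np.asarray(motions, dtype=float)
    if motions.size < 3:
        raise ValueError("need at least 3 motion values")
    if not -1.0 <= target_r <= 1.0:
        raise ValueError("target correlation must lie in [-1, 1]")
    sd = motions.std()
    if sd == 0:
        raise ValueError("motions are constant; correlation undefined")
    x = (motions - motions.mean()) / sd
    if abs(target_r) == 1.0:
        return loc + scale * np.sign(target_r) * x
    rng = np.random.default_rng(seed)
    for _ in range(10):
        z = rng.normal(size=motions.size)
        z = z - z.mean()
        z = z - (z @ x) / (x @ x) * x
        if z.std() > 1e-9:
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not draw a non-degenerate noise vector")
    z = z / z.std()
    y = target_r * x + np.sqrt(1.0 - target_r**2) * z
    return loc + scale * y
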