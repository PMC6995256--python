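"""File-format helpers: clips, motion tables, seed tables, NIfTI maps."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .glm import StatMap
from .motion import VideoClip


def save_clip_npz(clip: VideoClip, path) -> None:
    """Store a clip as a single .npz stack (lossless)."""
    np.savez_compressed(
        path,
        frames=clip.frames,
        background_mask=clip.background_mask,
        fps=np.array(clip.fps),
        label=np.array(json.dumps(clip.label)),
        meta=np.array(json.dumps(clip.meta, default=str)),
    )


def load_clip_npz(path) -> VideoClip:
    with np.load(path, allow_pickle=False) as z:
        return VideoClip(
            frames=z["frames"],
            background_mask=z["background_mask"],
            fps=float(z["fps"]),
            label=json.loads(str(z["label"])),
            meta=json.loads(str(z["meta"])),
        )


def save_clip_png_dir(clip: VideoClip, directory) -> None:
    """Write a clip as per-frame 8-bit PNGs (lossy: values are rounded).

    RGB source frames are written when present, otherwise grayscale
    luminance; the background mask goes to ``mask.png``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stack = clip.rgb if clip.rgb is not None else clip.frames
    for i in range(clip.n_frames):
        frame = np.clip(np.round(stack[i]), 0, 255).astype(np.uint8)
        iio.imwrite(directory / f"frame{i:04d}.png", frame)
    iio.imwrite(directory / "mask.png", clip.background_mask.astype(np.uint8) * 255)
    (directory / "clip.json").write_text(
        json.dumps({"fps": clip.fps, "label": clip.label}, indent=2)
    )


def load_clip_png_dir(directory) -> VideoClip:
    directory = Path(directory)
    paths = sorted(directory.glob("frame*.png"))
    if len(paths) < 2:
        raise ValueError(f"no frame PNGs found in {directory}")
    frames = np.stack([iio.imread(p) for p in paths]).astype(float)
    rgb = None
    if frames.ndim == 4:
        rgb = frames
        from .motion import to_luminance

        frames = to_luminance(rgb)
    mask_path = directory / "mask.png"
    if mask_path.exists():
        mask = iio.imread(mask_path) > 0
    else:
        mask = np.ones(frames.shape[1:], dtype=bool)
    info = {}
    info_path = directory / "clip.json"
    if info_path.exists():
        info = json.loads(info_path.read_text())
    return VideoClip(
        frames=frames,
        background_mask=mask,
        fps=float(info.get("fps", 25.0)),
        rgb=rgb,
        label=info.get("label", {}),
    )


def write_motions(results, path) -> pd.DataFrame:
    """clip_id / noise_level / clip_motion TSV from MotionResult list."""
    df = pd.DataFrame(
        [
            {
                "clip_id": r.clip_id,
                "noise_level": r.noise_level,
                "clip_motion": r.clip_motion,
            }
            for r in results
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def read_motions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_block_motions(blocks, path) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "block_id": b.block_id,
                "condition": b.condition,
                "cumulative_motion": b.cumulative_motion,
            }
            for b in blocks
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def read_seed_table(path) -> pd.DataFrame:
    """Seed TSV with columns name, x, y, z and optional radius_mm."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"seed table needs columns {sorted(required)}")
    if "radius_mm" not in df.columns:
        df["radius_mm"] = 10.0
    return df


def save_stat_map(stat_map: StatMap, path) -> None:
    img = nib.Nifti1Image(stat_map.values.astype(np.float32), stat_map.affine)
    img.header["descrip"] = f"df={stat_map.df}".encode()
    nib.save(img, str(path))


def load_stat_map(path, df: int, contrast_name: str = "") -> StatMap:
    img = nib.load(str(path))
    return StatMap(
        values=np.asarray(img.dataobj, dtype=float),
        affine=img.affine,
        df=df,
        contrast_name=contrast_name,
    )
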