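"""Thresholding of t-maps and ROI peak extraction for the localizer.

Statistical maps from the body > object contrast are thresholded at the
voxel level (uncorrected p or family-wise-error corrected via Bonferroni or
permutation max-T), filtered by cluster extent, and searched for peaks
within 10-mm spheres around canonical coordinates of the dynamic
body-selective network (right/left extrastriate and fusiform body areas,
posterior STS, precentral and inferior frontal nodes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .glm import StatMap

#: Canonical group-peak seed coordinates (MNI mm) for the dynamic
#: body-selective network, with the conventional 10-mm search radius.
CANONICAL_SEEDS = pd.DataFrame(
    [
        ("rFBA", 45, -46, -17),
        ("rEBA", 45, -79, -11),
        ("rpSTS", 54, -46, 7),
        ("rPCG", 48, 5, 46),
        ("lEBA", -48, -73, 7),
        ("lpSTS", -63, -49, 19),
        ("rIFG", 42, 20, 22),
    ],
    columns=["name", "x", "y", "z"],
).assign(radius_mm=10.0)

#: Average individual-subject peaks reported with this localizer (MNI mm).
METHOD_MEAN_PEAKS = pd.DataFrame(
    [
        ("rFBA", 42, -44, -19),
        ("rEBA", 49, -71, -3),
        ("rpSTS", 56, -56, 11),
        ("rPCG", 49, 5, 46),
        ("lEBA", -48, -75, -2),
        ("lpSTS", -46, -56, 13),
        ("rIFG", 46, 18, 23),
    ],
    columns=["name", "x", "y", "z"],
)

#: Average peaks for the same regions from prior localizer literature.
LITERATURE_PEAKS = pd.DataFrame(
    [
        ("rFBA", 42, -44, -24),
        ("rEBA", 47, -69, 0),
        ("rpSTS", 54, -52, 12),
        ("rPCG", 43, 9, 42),
        ("lEBA", -47, -74, 4),
        ("lpSTS", -49, -57, 16),
        ("rIFG", 44, 14, 15),
    ],
    columns=["name", "x", "y", "z"],
)

_LEVEL_P = {"fwe_05": 0.05, "unc_001": 0.001, "unc_05": 0.05}


@dataclass(frozen=True)
class ThresholdSpec:
    """Height + extent threshold: FWE-corrected or uncorrected voxel level.

    ``level`` is one of ``fwe_05`` (p < .05 family-wise corrected),
    ``unc_001`` and ``unc_05`` (uncorrected); ``t_threshold`` may carry a
    precomputed height cut (e.g. from :func:`permutation_max_t`) that
    overrides the analytic one.
    """

    level: str = "fwe_05"
    p: float | None = None
    cluster_extent_min: int = 10
    fwe_method: str = "bonferroni"
    connectivity: int = 6
    t_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.level not in _LEVEL_P and self.p is None:
            raise ValueError(f"unknown threshold level {self.level!r}")
        p = self.p if self.p is not None else _LEVEL_P[self.level]
        if not 0 < p < 1:
            raise ValueError("p must lie in (0, 1)")
        if self.cluster_extent_min < 0:
            raise ValueError("cluster extent must be >= 0")
        if self.fwe_method not in ("bonferroni", "permutation_maxT"):
            raise ValueError(f"unknown FWE method {self.fwe_method!r}")

    @property
    def alpha(self) -> float:
        return self.p if self.p is not None else _LEVEL_P[self.level]

    @property
    def is_fwe(self) -> bool:
        return self.level.startswith("fwe")


DEFAULT_THRESHOLDS = (
    ThresholdSpec("fwe_05"),
    ThresholdSpec("unc_001"),
    ThresholdSpec("unc_05"),
)


@dataclass(frozen=True)
class RoiSeed:
    name: str
    mni_xyz: tuple
    radius_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")


def seeds_from_table(table: pd.DataFrame) -> list:
    """RoiSeed list from a (name, x, y, z[, radius_mm]) table."""
    if table["name"].duplicated().any():
        raise ValueError("ROI names must be unique")
    out = []
    for _, row in table.iterrows():
        out.append(
            RoiSeed(
                name=row["name"],
                mni_xyz=(float(row["x"]), float(row["y"]), float(row["z"])),
                radius_mm=float(row.get("radius_mm", 10.0)),
            )
        )
    return out


def t_threshold_value(
    spec: ThresholdSpec, df: int, n_voxels: int | None = None
) -> float:
    """Height threshold in t units for a map with ``df`` residual dof."""
    if spec.t_threshold is not None:
        return float(spec.t_threshold)
    if df <= 0:
        raise ValueError("df must be positive")
    if spec.is_fwe:
        if spec.fwe_method == "permutation_maxT":
            raise ValueError(
                "permutation max-T needs a precomputed t_threshold "
                "(see permutation_max_t)"
            )
        if not n_voxels:
            raise ValueError("Bonferroni correction needs the mask voxel count")
        p_voxel = spec.alpha / n_voxels
        if p_voxel <= 0:
            raise ValueError("per-voxel alpha underflow")
        return float(stats.t.isf(p_voxel, df))
    return float(stats.t.isf(spec.alpha, df))


def voxel_threshold(
    stat_map: StatMap, spec: ThresholdSpec, mask: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Binary map of voxels whose t exceeds the height threshold.

    One-sided (positive) thresholding, matching a directional contrast.
    Returns the binary map and the t threshold used.
    """
    if mask is None:
        mask = np.ones(stat_map.values.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    thr = t_threshold_value(spec, stat_map.df, int(mask.sum()))
    return (stat_map.values > thr) & mask, thr


def _structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


def cluster_filter(
    binary: np.ndarray, extent_min: int = 10, connectivity: int = 6
) -> tuple[np.ndarray, dict]:
    """Label connected components and drop those below the extent minimum.

    Returns ``(labels, sizes)`` where ``labels`` is 0 outside surviving
    clusters and ``sizes`` maps surviving label -> voxel count.
    """
    binary = np.asarray(binary, dtype=bool)
    labels, n = ndimage.label(binary, structure=_structure(connectivity))
    sizes = {}
    if n:
        counts = np.bincount(labels.ravel())
        for lab in range(1, n + 1):
            if counts[lab] < extent_min:
                labels[labels == lab] = 0
            else:
                sizes[lab] = int(counts[lab])
    return labels, sizes


def apply_threshold(
    stat_map: StatMap, spec: ThresholdSpec, mask: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Height threshold followed by the cluster-extent filter.

    Returns the surviving binary map and the height threshold used.
    """
    binary, thr = voxel_threshold(stat_map, spec, mask)
    labels, _ = cluster_filter(binary, spec.cluster_extent_min, spec.connectivity)
    return labels > 0, thr


def permutation_max_t(
    contrast_images: np.ndarray,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """FWE height threshold from the sign-flip max-T null distribution.

    ``contrast_images`` is ``(n_subjects, n_voxels)`` (or subjects x grid);
    under exchangeable symmetric errors, flipping subject signs generates
    the null of the one-sample group t; the (1 - alpha) quantile of the
    maximum t over voxels controls the family-wise error exactly.
    """
    imgs = np.asarray(contrast_images, dtype=float)
    imgs = imgs.reshape(imgs.shape[0], -1)
    n_subj = imgs.shape[0]
    if n_subj < 2:
        raise ValueError("need at least two subjects")
    rng = np.random.default_rng(seed)

    def one_sample_t(data):
        m = data.mean(axis=0)
        se = data.std(axis=0, ddof=1) / np.sqrt(n_subj)
        out = np.zeros_like(m)
        ok = se > 0
        out[ok] = m[ok] / se[ok]
        return out

    max_ts = np.empty(n_permutations)
    for i in range(n_permutations):
        signs = rng.choice([-1.0, 1.0], size=(n_subj, 1))
        max_ts[i] = one_sample_t(imgs * signs).max()
    return float(np.quantile(max_ts, 1.0 - alpha))


@dataclass
class RoiPeak:
    """Outcome of a seeded peak search in one subject/threshold."""

    name: str
    present: bool
    peak_xyz: tuple | None = None
    peak_t: float | None = None
    n_voxels: int = 0


def find_roi_peak(
    stat_map: StatMap,
    seed: RoiSeed,
    spec: ThresholdSpec,
    mask: np.ndarray | None = None,
    surviving: np.ndarray | None = None,
) -> RoiPeak:
    """Peak voxel within ``radius_mm`` of the seed among surviving voxels.

    The cluster-extent filter runs on the whole map before the sphere
    restriction, so clusters straddling the sphere boundary count their full
    extent.  Returns an absent :class:`RoiPeak` when nothing survives inside
    the sphere; ties resolve to the first voxel in C index order.
    """
    shape = stat_map.values.shape
    ijk = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), -1)
    mm = stat_map.voxel_to_mm(ijk.reshape(-1, 3)).reshape(shape + (3,))
    dist = np.linalg.norm(mm - np.asarray(seed.mni_xyz, float), axis=-1)
    sphere = dist <= seed.radius_mm
    if not sphere.any():
        raise ValueError(f"seed sphere {seed.name} lies outside the image grid")
    if surviving is None:
        surviving, _ = apply_threshold(stat_map, spec, mask)
    candidates = sphere & surviving
    n_vox = int(candidates.sum())
    if n_vox == 0:
        return RoiPeak(name=seed.name, present=False)
    t_vals = np.where(candidates, stat_map.values, -np.inf)
    peak_idx = np.unravel_index(np.argmax(t_vals), shape)
    peak_mm = stat_map.voxel_to_mm(np.asarray(peak_idx))[0]
    return RoiPeak(
        name=seed.name,
        present=True,
        peak_xyz=tuple(float(v) for v in peak_mm),
        peak_t=float(stat_map.values[peak_idx]),
        n_voxels=n_vox,
    )


def roi_report(
    stat_map: StatMap,
    seeds,
    specs=DEFAULT_THRESHOLDS,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-ROI peak table for one subject at each threshold level."""
    rows = []
    for spec in specs:
        surviving, thr = apply_threshold(stat_map, spec, mask)
        for seed in seeds:
            peak = find_roi_peak(stat_map, seed, spec, mask, surviving=surviving)
            rows.append(
                {
                    "roi": peak.name,
                    "level": spec.level,
                    "present": peak.present,
                    "peak_x": peak.peak_xyz[0] if peak.present else np.nan,
                    "peak_y": peak.peak_xyz[1] if peak.present else np.nan,
                    "peak_z": peak.peak_xyz[2] if peak.present else np.nan,
                    "peak_t": peak.peak_t if peak.present else np.nan,
                    "n_voxels": peak.n_voxels,
                    "t_threshold": thr,
                }
            )
    return pd.DataFrame(rows)


def subject_tally(reports, specs=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Group table: per ROI and threshold, how many subjects show the ROI.

    ``reports`` is a list of per-subject tables from :func:`roi_report`.
    Reports subject counts, presence fraction, mean surviving-voxel count,
    and mean/SD of the peak coordinates over subjects showing the ROI.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("need at least one subject report")
    allr = pd.concat(
        [r.assign(subject=i) for i, r in enumerate(reports)], ignore_index=True
    )
    rows = []
    for (roi, level), grp in allr.groupby(["roi", "level"], sort=False):
        present = grp[grp["present"]]
        rows.append(
            {
                "roi": roi,
                "level": level,
                "n_subjects": len(grp),
                "n_present": int(grp["present"].sum()),
                "fraction_present": float(grp["present"].mean()),
                "mean_n_voxels": float(grp["n_voxels"].mean()),
                "mean_x": float(present["peak_x"].mean()) if len(present) else np.nan,
                "mean_y": float(present["peak_y"].mean()) if len(present) else np.nan,
                "mean_z": float(present["peak_z"].mean()) if len(present) else np.nan,
                "sd_x": float(present["peak_x"].std(ddof=0)) if len(present) else np.nan,
                "sd_y": float(present["peak_y"].std(ddof=0)) if len(present) else np.nan,
                "sd_z": float(present["peak_z"].std(ddof=0)) if len(present) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def compare_to_reference(
    group_means: pd.DataFrame, reference: pd.DataFrame = LITERATURE_PEAKS
) -> pd.DataFrame:
    """Euclidean mm distance between estimated and reference peaks per ROI."""
    merged = group_means.merge(reference, on="name", suffixes=("", "_ref"))
    missing = set(reference["name"]) - set(group_means["name"])
    if missing:
        raise ValueError(f"missing ROIs: {sorted(missing)}")
    d = np.sqrt(
        (merged["x"] - merged["x_ref"]) ** 2
        + (merged["y"] - merged["y_ref"]) ** 2
        + (merged["z"] - merged["z_ref"]) ** 2
    )
    return merged.assign(distance_mm=d)[["name", "distance_mm"]]
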