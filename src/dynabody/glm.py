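"""Voxelwise general linear model for the block-design localizer.

The design matrix holds one HRF-convolved boxcar for the body blocks and one
for the object blocks, a parametric motion covariate (block cumulative
motion, mean-centered and HRF-convolved), six head-motion nuisance
regressors, a discrete-cosine drift basis implementing the 128-s high-pass
cut-off, and an intercept.  Fitting is ordinary least squares per voxel;
contrasts yield t-maps with ``df = n_volumes - rank(X)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy import ndimage, stats

if TYPE_CHECKING:  # pragma: no cover
    from .design import BlockSchedule

#: cap applied to t-values at zero-residual voxels carrying a real effect
T_CAP = 1e6

_HRF_DT = 0.1  # seconds; oversampling grid for convolution
_HRF_LENGTH_S = 32.0


def canonical_hrf(t_grid: np.ndarray) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak normalized to 1.

    ``h(t) = g(t; 6, 1) - g(t; 16, 1) / 6`` with gamma densities ``g``;
    the positive lobe peaks near 5 s and the undershoot near 15 s.
    """
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0):
        raise ValueError("time grid must be non-negative")
    h = stats.gamma.pdf(t, a=6.0, scale=1.0) - stats.gamma.pdf(t, a=16.0, scale=1.0) / 6.0
    return h / _HRF_PEAK


def _hrf_peak() -> float:
    t = np.arange(0.0, _HRF_LENGTH_S, 1e-3)
    h = stats.gamma.pdf(t, a=6.0, scale=1.0) - stats.gamma.pdf(t, a=16.0, scale=1.0) / 6.0
    return float(h.max())


_HRF_PEAK = _hrf_peak()


def hrf_regressor(
    onsets,
    durations,
    heights,
    n_volumes: int,
    tr_s: float,
    dt: float = _HRF_DT,
    normalize: bool = False,
) -> np.ndarray:
    """Boxcar train convolved with the canonical HRF, sampled at the TR.

    Each event contributes a boxcar of its duration and height on a fine
    time grid; the train is convolved with the HRF and sampled at
    ``t = i * tr_s``.  With ``normalize=True`` the result is scaled to peak
    absolute value 1 (left untouched when it is identically zero).
    """
    n_grid = int(np.ceil(n_volumes * tr_s / dt)) + 1
    neural = np.zeros(n_grid)
    for onset, dur, h in zip(onsets, durations, heights):
        i0 = int(round(onset / dt))
        i1 = min(int(round((onset + dur) / dt)), n_grid)
        neural[i0:i1] += h
    hrf = canonical_hrf(np.arange(0.0, _HRF_LENGTH_S, dt))
    conv = np.convolve(neural, hrf)[:n_grid] * dt
    idx = np.round(np.arange(n_volumes) * tr_s / dt).astype(int)
    reg = conv[idx]
    if normalize:
        peak = np.abs(reg).max()
        if peak > 1e-12:
            reg = reg / peak
    return reg


def condition_regressor(
    schedule: "BlockSchedule",
    group: str,
    n_volumes: int,
    tr_s: float,
    normalize: bool = True,
) -> np.ndarray:
    """HRF-convolved unit boxcar over the blocks of one condition group."""
    blocks = schedule.condition_blocks(group)
    return hrf_regressor(
        [b.onset_s for b in blocks],
        [b.duration_s for b in blocks],
        np.ones(len(blocks)),
        n_volumes,
        tr_s,
        normalize=normalize,
    )


def dct_basis(n_volumes: int, tr_s: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Orthonormal DCT drift columns for periods longer than ``cutoff_s``.

    The number of non-constant columns is ``floor(2 * T / cutoff)`` with
    ``T = n_volumes * tr_s``; the constant term is excluded (the design has
    its own intercept).
    """
    if cutoff_s <= 2 * tr_s:
        raise ValueError("cutoff must exceed twice the TR")
    n = n_volumes
    k_max = int(np.floor(2.0 * n * tr_s / cutoff_s))
    i = np.arange(n)
    cols = [
        np.sqrt(2.0 / n) * np.cos(np.pi * k * (2 * i + 1) / (2.0 * n))
        for k in range(1, k_max + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n, 0))


@dataclass
class DesignMatrix:
    matrix: np.ndarray
    names: list
    tr_s: float
    highpass_cutoff_s: float = 128.0
    full_rank: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("one name per column required")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def contrast(self, weights: dict) -> np.ndarray:
        """Contrast vector from a {name: weight} mapping (others zero)."""
        c = np.zeros(len(self.names))
        for name, w in weights.items():
            c[self.names.index(name)] = w
        return c

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, columns=self.names)

    def plot(self, path) -> None:
        """Save a heat-map rendering of the (column-normalized) matrix."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        scale = np.abs(self.matrix).max(axis=0)
        scale[scale == 0] = 1.0
        fig, ax = plt.subplots(figsize=(0.5 * len(self.names) + 2, 6))
        ax.imshow(self.matrix / scale, aspect="auto", cmap="gray",
                  interpolation="nearest")
        ax.set_xticks(range(len(self.names)))
        ax.set_xticklabels(self.names, rotation=90, fontsize=7)
        ax.set_ylabel("volume")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def build_design(
    schedule: "BlockSchedule",
    block_motions=None,
    head_motion: np.ndarray | None = None,
    n_volumes: int = 246,
    tr_s: float = 2.6,
    highpass_cutoff_s: float = 128.0,
    covariate_mode: str = "hrf",
    per_condition_covariate: bool = False,
) -> DesignMatrix:
    """Assemble the localizer design matrix.

    ``block_motions`` is a list of :class:`~dynabody.motion.BlockMotion`
    covering every stimulus block in schedule order; the covariate boxcar
    takes each block's mean-centered cumulative motion as height and is
    convolved with the HRF (``covariate_mode="raw"`` enters the centered
    per-scan box value without convolution).  ``head_motion`` is an
    ``(n_volumes, 6)`` table of realignment parameters, mean-centered here.
    """
    if schedule.total_duration_s > n_volumes * tr_s + 1e-9:
        raise ValueError("schedule is longer than the acquisition")
    cols, names = [], []
    cols.append(condition_regressor(schedule, "body", n_volumes, tr_s))
    names.append("body")
    cols.append(condition_regressor(schedule, "object", n_volumes, tr_s))
    names.append("non_body")

    if block_motions is not None:
        stim = schedule.stimulus_blocks()
        if len(block_motions) != len(stim):
            raise ValueError("need one block motion per stimulus block")
        values = np.array([bm.cumulative_motion for bm in block_motions], float)
        centered = values - values.mean()
        if per_condition_covariate:
            groups = [("motion_body", lambda b: b.condition.startswith("body")),
                      ("motion_object", lambda b: b.condition == "object")]
        else:
            groups = [("motion_covariate", lambda b: True)]
        for name, keep in groups:
            onsets = [b.onset_s for b, v in zip(stim, centered) if keep(b)]
            durs = [b.duration_s for b, v in zip(stim, centered) if keep(b)]
            hts = [v for b, v in zip(stim, centered) if keep(b)]
            if covariate_mode == "hrf":
                col = hrf_regressor(onsets, durs, hts, n_volumes, tr_s)
            elif covariate_mode == "raw":
                col = np.zeros(n_volumes)
                t = np.arange(n_volumes) * tr_s
                for onset, dur, h in zip(onsets, durs, hts):
                    col[(t >= onset) & (t < onset + dur)] = h
            else:
                raise ValueError(f"unknown covariate mode {covariate_mode!r}")
            cols.append(col)
            names.append(name)

    if head_motion is not None:
        head_motion = np.asarray(head_motion, dtype=float)
        if head_motion.shape != (n_volumes, 6):
            raise ValueError("head motion table must be (n_volumes, 6)")
        hm = head_motion - head_motion.mean(axis=0)
        for j in range(6):
            cols.append(hm[:, j])
            names.append(f"motion_param_{j + 1}")

    drift = dct_basis(n_volumes, tr_s, highpass_cutoff_s)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        names.append(f"drift_{k + 1}")
    cols.append(np.ones(n_volumes))
    names.append("intercept")

    X = np.column_stack(cols)
    full_rank = np.linalg.matrix_rank(X) == X.shape[1]
    if not full_rank:
        warnings.warn(
            "design matrix is rank deficient (e.g. a constant motion "
            "covariate); fitting falls back to the pseudo-inverse",
            RuntimeWarning,
        )
    return DesignMatrix(
        matrix=X,
        names=names,
        tr_s=tr_s,
        highpass_cutoff_s=highpass_cutoff_s,
        full_rank=full_rank,
    )


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian sigma for a given full width at half maximum."""
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def smooth_volume(
    volume: np.ndarray, fwhm_mm: float = 8.0, voxel_size_mm: float = 3.0
) -> np.ndarray:
    """Spatially smooth a 3-D volume or 4-D (x, y, z, t) series.

    Separable Gaussian with sigma ``fwhm / (2 sqrt(2 ln 2))`` per axis,
    converted from mm to voxels.  ``fwhm_mm = 0`` is the identity.
    """
    if voxel_size_mm <= 0:
        raise ValueError("voxel size must be positive")
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    volume = np.asarray(volume, dtype=float)
    if fwhm_mm == 0:
        return volume.copy()
    sigma_vox = fwhm_to_sigma(fwhm_mm) / voxel_size_mm
    if volume.ndim == 3:
        sigma = (sigma_vox,) * 3
    elif volume.ndim == 4:
        sigma = (sigma_vox,) * 3 + (0.0,)
    else:
        raise ValueError("expected a 3-D or 4-D array")
    return ndimage.gaussian_filter(volume, sigma=sigma, mode="constant", truncate=6.0)


def highpass_filter(
    ts: np.ndarray, cutoff_s: float = 128.0, tr_s: float = 2.6
) -> np.ndarray:
    """Remove slow drifts by projecting out the DCT basis (plus the mean).

    Equivalent to including the drift columns in the design; a pure drift
    component (or a constant) filters to zero.
    """
    ts = np.asarray(ts, dtype=float)
    n = ts.shape[0]
    if n < 2:
        raise ValueError("series too short")
    basis = np.column_stack(
        [np.ones(n) / np.sqrt(n), dct_basis(n, tr_s, cutoff_s)]
    )
    proj = basis @ (basis.T @ ts)
    return ts - proj


@dataclass
class GlmFit:
    beta: np.ndarray  # (p, n_voxels)
    sigma2: np.ndarray  # (n_voxels,)
    df_resid: int
    xtx_inv: np.ndarray  # (p, p) pseudo-inverse of X'X
    names: list = field(default_factory=list)
    rank: int = 0


def fit_glm(Y: np.ndarray, X: DesignMatrix | np.ndarray) -> GlmFit:
    """Ordinary least squares per voxel.

    ``Y`` is ``(n_volumes, n_voxels)``.  A rank-deficient design triggers a
    warning and is fitted with the Moore-Penrose pseudo-inverse, with the
    residual degrees of freedom reduced to ``n - rank(X)``.
    """
    names = []
    if isinstance(X, DesignMatrix):
        names = list(X.names)
        X = X.matrix
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    rank = int(np.linalg.matrix_rank(X))
    if n <= rank:
        raise ValueError("need more volumes than effective regressors")
    if rank < p:
        warnings.warn(
            f"rank-deficient design (rank {rank} < {p}); using pseudo-inverse",
            RuntimeWarning,
        )
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    df = n - rank
    sigma2 = (resid**2).sum(axis=0) / df
    return GlmFit(
        beta=beta,
        sigma2=sigma2,
        df_resid=df,
        xtx_inv=np.linalg.pinv(X.T @ X),
        names=names,
        rank=rank,
    )


@dataclass
class StatMap:
    """A 3-D t-statistic volume in register with an affine to MNI mm."""

    values: np.ndarray
    affine: np.ndarray
    df: int
    contrast_name: str = ""
    zero_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("StatMap values must be 3-D")
        if self.affine.shape != (4, 4) or np.isclose(np.linalg.det(self.affine), 0):
            raise ValueError("affine must be an invertible 4x4 matrix")

    def voxel_to_mm(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return (self.affine @ np.column_stack([idx, np.ones(len(idx))]).T).T[:, :3]

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return (inv @ np.column_stack([xyz, np.ones(len(xyz))]).T).T[:, :3]


def contrast_t(fit: GlmFit, c: np.ndarray) -> np.ndarray:
    """Per-voxel t-values for contrast ``c`` (flat vector over voxels).

    Voxels with zero residual variance get ``t = 0`` when the effect is also
    zero and ``±T_CAP`` otherwise.
    """
    c = np.asarray(c, dtype=float)
    if c.shape != (fit.beta.shape[0],):
        raise ValueError("contrast length must match the number of regressors")
    eff = c @ fit.beta
    var_unit = float(c @ fit.xtx_inv @ c)
    se = np.sqrt(fit.sigma2 * var_unit)
    t = np.zeros_like(eff)
    ok = se > 0
    t[ok] = eff[ok] / se[ok]
    degenerate = ~ok & (np.abs(eff) > 0)
    t[degenerate] = np.sign(eff[degenerate]) * T_CAP
    return t


def contrast_tmap(
    fit: GlmFit,
    c: np.ndarray,
    grid_shape: tuple,
    affine: np.ndarray,
    mask: np.ndarray | None = None,
    contrast_name: str = "",
) -> StatMap:
    """Assemble a :class:`StatMap` from voxelwise contrast t-values.

    ``mask`` (3-D boolean) says which grid voxels the columns of the fitted
    data correspond to; without it the fit must cover the full grid in
    C order.
    """
    t_flat = contrast_t(fit, c)
    se_zero_flat = fit.sigma2 <= 0
    values = np.zeros(grid_shape)
    zero_var = np.zeros(grid_shape, dtype=bool)
    if mask is None:
        values = t_flat.reshape(grid_shape)
        zero_var = se_zero_flat.reshape(grid_shape)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() != t_flat.size:
            raise ValueError("mask voxel count must match fitted voxel count")
        values[mask] = t_flat
        zero_var[mask] = se_zero_flat
    return StatMap(
        values=values,
        affine=affine,
        df=fit.df_resid,
        contrast_name=contrast_name,
        zero_variance=zero_var,
    )
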